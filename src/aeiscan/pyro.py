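"""Pyrosequencing allele-quantification comparison of DNA vs RNA.

Pyrosequencing allele quantification (AQ) reports the percentage of each
allele at a SNP. Run on genomic DNA of a heterozygote it should read close
to 50/50; run on cDNA it reveals allelic expression imbalance. This module
aggregates technical replicates per sample/SNP/level into mean +/- SEM and
classifies each level as balanced (allele A percentage within the inclusive
40-60% band) or imbalanced. AEI is confirmed for a sample/SNP when the DNA
level is balanced and the RNA level is not; an imbalanced DNA level
invalidates the assay for AEI purposes (flagged, never confirmed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

Level = Literal["DNA", "RNA"]

PYRO_COLUMNS = ["sample", "rsid", "level", "replicate", "allele_a_percent"]

RESULT_COLUMNS = [
    "sample",
    "rsid",
    "n_dna",
    "dna_mean_percent",
    "dna_sem",
    "n_rna",
    "rna_mean_percent",
    "rna_sem",
    "dna_balanced",
    "rna_balanced",
    "aei_confirmed",
]


class PyroFormatError(ValueError):
    """Raised for malformed pyrosequencing measurement tables."""


@dataclass(frozen=True)
class PyroMeasurement:
    """One technical replicate: allele A percentage at one sample/SNP/level."""

    sample_id: str
    rsid: str
    level: Level
    replicate_id: str
    allele_a_percent: float

    def __post_init__(self) -> None:
        if self.level not in ("DNA", "RNA"):
            raise ValueError(f"level must be DNA or RNA, got {self.level!r}")
        if not 0 <= self.allele_a_percent <= 100:
            raise ValueError(
                f"allele percentage must be in [0, 100], got {self.allele_a_percent}"
            )

    @property
    def allele_b_percent(self) -> float:
        return 100.0 - self.allele_a_percent


@dataclass(frozen=True)
class PyroAssayResult:
    """Replicate-aggregated DNA and RNA allele percentages for one sample/SNP."""

    sample_id: str
    rsid: str
    dna_mean_percent: float
    dna_sem: float
    rna_mean_percent: float
    rna_sem: float
    n_dna: int
    n_rna: int
    dna_balanced: bool
    rna_balanced: bool
    aei_confirmed: bool


def aggregate_replicates(percents: Sequence[float]) -> tuple[float, float]:
    """Mean and SEM of replicate allele percentages.

    SEM uses the n-1 sample SD over sqrt(n); a single replicate yields
    SEM 0 with a warning.
    """
    values = np.asarray(percents, dtype=float)
    if values.size == 0:
        raise ValueError("aggregate_replicates requires at least one replicate")
    if values.size == 1:
        warnings.warn("SEM reported as 0 for a single replicate", stacklevel=2)
        return float(values[0]), 0.0
    return float(values.mean()), float(values.std(ddof=1) / math.sqrt(values.size))


def classify_balance(
    mean_percent: float, low: float = 40.0, high: float = 60.0
) -> bool:
    """True iff the mean allele percentage lies inside the inclusive band."""
    if not 0 <= mean_percent <= 100:
        raise ValueError(f"percentage must be in [0, 100], got {mean_percent}")
    return low <= mean_percent <= high


def confirm_aei(
    sample_id: str,
    rsid: str,
    dna_percents: Sequence[float],
    rna_percents: Sequence[float],
    *,
    band: tuple[float, float] = (40.0, 60.0),
) -> PyroAssayResult:
    """Aggregate both levels and decide whether AEI is confirmed.

    Confirmed iff DNA is balanced and RNA is not. Both levels must carry at
    least one replicate.
    """
    for level, percents in (("DNA", dna_percents), ("RNA", rna_percents)):
        if len(percents) == 0:
            raise ValueError(f"missing measurements for level {level}")
    dna_mean, dna_sem = aggregate_replicates(dna_percents)
    rna_mean, rna_sem = aggregate_replicates(rna_percents)
    dna_balanced = classify_balance(dna_mean, *band)
    rna_balanced = classify_balance(rna_mean, *band)
    return PyroAssayResult(
        sample_id=sample_id,
        rsid=rsid,
        dna_mean_percent=dna_mean,
        dna_sem=dna_sem,
        rna_mean_percent=rna_mean,
        rna_sem=rna_sem,
        n_dna=len(dna_percents),
        n_rna=len(rna_percents),
        dna_balanced=dna_balanced,
        rna_balanced=rna_balanced,
        aei_confirmed=dna_balanced and not rna_balanced,
    )


def read_pyro_table(path: str | Path) -> list[PyroMeasurement]:
    """Read a measurement TSV: sample, rsid, level, replicate, allele_a_percent."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise PyroFormatError(f"{path}: empty file, header expected") from exc
    missing = [c for c in PYRO_COLUMNS if c not in df.columns]
    if missing:
        raise PyroFormatError(f"missing column(s): {', '.join(missing)}")
    measurements = []
    for idx, row in df.iterrows():
        try:
            measurements.append(
                PyroMeasurement(
                    sample_id=str(row["sample"]),
                    rsid=str(row["rsid"]),
                    level=str(row["level"]).upper(),  # type: ignore[arg-type]
                    replicate_id=str(row["replicate"]),
                    allele_a_percent=float(row["allele_a_percent"]),
                )
            )
        except ValueError as exc:
            raise PyroFormatError(f"row {idx}: {exc}") from exc
    return measurements


def evaluate_assays(
    measurements: Iterable[PyroMeasurement],
    *,
    band: tuple[float, float] = (40.0, 60.0),
) -> list[PyroAssayResult]:
    """Aggregate all measurements into per-sample/SNP assay results.

    Sample/SNP pairs measured at only one level are an error naming the
    missing level.
    """
    grouped: dict[tuple[str, str], dict[str, list[float]]] = {}
    for m in measurements:
        entry = grouped.setdefault((m.sample_id, m.rsid), {"DNA": [], "RNA": []})
        entry[m.level].append(m.allele_a_percent)
    results = []
    for (sample_id, rsid), levels in grouped.items():
        for level in ("DNA", "RNA"):
            if not levels[level]:
                raise ValueError(
                    f"sample {sample_id!r} SNP {rsid!r}: missing level {level}"
                )
        results.append(
            confirm_aei(sample_id, rsid, levels["DNA"], levels["RNA"], band=band)
        )
    return results


def write_pyro_results(
    results: Iterable[PyroAssayResult], path: str | Path
) -> None:
    """Write assay results as a TSV mirroring :class:`PyroAssayResult`."""
    rows = []
    for r in results:
        rows.append(
            {
                "sample": r.sample_id,
                "rsid": r.rsid,
                "n_dna": r.n_dna,
                "dna_mean_percent": f"{r.dna_mean_percent:.2f}",
                "dna_sem": f"{r.dna_sem:.3f}",
                "n_rna": r.n_rna,
                "rna_mean_percent": f"{r.rna_mean_percent:.2f}",
                "rna_sem": f"{r.rna_sem:.3f}",
                "dna_balanced": r.dna_balanced,
                "rna_balanced": r.rna_balanced,
                "aei_confirmed": r.aei_confirmed,
            }
        )
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)
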