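"""Synthetic RNA-seq allele-count cohorts with known AEI ground truth.

The generator emulates the statistical structure the detection pipeline
assumes, without simulating reads:

* per variant, diploid genotypes at a marker SNP are drawn under
  Hardy-Weinberg equilibrium at a configurable allele frequency;
* cis-regulated (AEI) variants carry a linked biallelic regulatory locus;
  haplotype frequencies follow from the marker/regulatory allele
  frequencies and a target LD r^2, with the repressive regulatory allele
  coupled to the alternative marker allele. In a heterozygous sample the
  haplotype carrying the repressive allele contributes a reduced fraction
  of transcripts, so the direction of imbalance tracks phase;
* read depth per record is negative-binomial around a mean, resampled to
  stay at or above a floor so depth filters are not the discriminating
  factor (a separate low-depth fraction deliberately injects shallow
  records to exercise them);
* allele counts at heterozygous sites are beta-binomial with intra-class
  correlation rho, capturing the overdispersion of real allelic counts;
  null variants use allelic fraction 0.5, AEI variants the configured
  fraction, oriented by phase.

All randomness flows from one seed; each variant draws from its own
counter-derived substream, so adding variants never perturbs earlier ones
and outputs are bit-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .detection import AeiCall
from .io import AlleleDepthRecord, CountTable, Genotype, VariantSite

_GENOTYPES = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults emulate the study conditions the pipeline targets: a cohort of
    52 retina donors, mean allelic depth ~80x with a floor of 20x, marker
    allele frequency 0.3, and cis-regulated variants in complete LD
    (r^2 = 1) with a repressive allele that leaves its haplotype
    contributing 30% of transcripts (oriented linear ratio 3/7 ~ 0.43,
    within the range of oriented mean ratios typical of real AEI SNPs).
    rho is the beta-binomial intra-class correlation; 0.01 keeps balanced
    variants mostly inside the 40-60% band at depth >= 20.
    """

    n_samples: int = 52
    n_null_variants: int = 200
    n_aei_variants: int = 50
    marker_af: float = 0.3
    ld_r2: float = 1.0
    mean_depth: float = 80.0
    depth_dispersion: float = 10.0
    min_depth: int = 20
    low_depth_fraction: float = 0.0
    aei_fraction: float = 0.30
    rho: float = 0.01
    qual: float = 999.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_null_variants < 0 or self.n_aei_variants < 0:
            raise ValueError("variant counts must be non-negative")
        if self.n_null_variants + self.n_aei_variants == 0:
            raise ValueError("at least one variant must be simulated")
        if not 0 < self.marker_af < 1:
            raise ValueError("marker_af must be in (0, 1)")
        if not 0 <= self.ld_r2 <= 1:
            raise ValueError("ld_r2 must be in [0, 1]")
        if not 0 < self.aei_fraction < 1:
            raise ValueError("aei_fraction must be in (0, 1)")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if not 0 <= self.low_depth_fraction < 1:
            raise ValueError("low_depth_fraction must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated cohort.

    ``variants``: one row per variant (rsid, is_aei, true allelic fraction).
    ``samples``: one row per variant x sample (genotype, phase of the
    repressive allele relative to the marker alleles, expressed alt
    fraction).
    """

    variants: pd.DataFrame
    samples: pd.DataFrame


@dataclass(frozen=True)
class DetectionMetrics:
    """Variant-level confusion counts of a detector against simulated truth."""

    tp: int
    fp: int
    fn: int
    tn: int
    thresholds: dict = field(default_factory=dict)

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def false_positive_rate(self) -> float:
        neg = self.fp + self.tn
        return self.fp / neg if neg else float("nan")


def _haplotype_freqs(p_marker: float, r2: float) -> np.ndarray:
    """Frequencies of (marker, regulatory) haplotypes 11, 10, 01, 00.

    The regulatory allele frequency is set equal to the marker alt-allele
    frequency, and the coupling D = r * p(1-p) puts the repressive allele
    preferentially on the alt-marker haplotype. r^2 = 1 gives perfect
    coupling; r^2 = 0 gives independence.
    """
    p = p_marker
    d = np.sqrt(r2) * p * (1 - p)
    freqs = np.array(
        [
            p * p + d,  # alt marker, repressive allele
            p * (1 - p) - d,  # alt marker, neutral allele
            (1 - p) * p - d,  # ref marker, repressive allele
            (1 - p) * (1 - p) + d,  # ref marker, neutral allele
        ]
    )
    freqs = np.clip(freqs, 0.0, None)
    return freqs / freqs.sum()


def _draw_depths(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    """Negative-binomial depths resampled to respect the depth floor."""
    size = cfg.depth_dispersion
    p = size / (size + cfg.mean_depth)
    depths = rng.negative_binomial(size, p, size=n)
    for _ in range(100):
        low = depths < cfg.min_depth
        if not low.any():
            break
        depths[low] = rng.negative_binomial(size, p, size=int(low.sum()))
    depths = np.maximum(depths, cfg.min_depth)
    if cfg.low_depth_fraction > 0:
        shallow = rng.random(n) < cfg.low_depth_fraction
        depths[shallow] = rng.integers(1, cfg.min_depth, size=int(shallow.sum()))
    return depths


def _beta_binomial(
    rng: np.random.Generator, depths: np.ndarray, fractions: np.ndarray, rho: float
) -> np.ndarray:
    """Alt counts ~ BetaBinomial(depth, fraction, rho); binomial when rho = 0."""
    if rho <= 0:
        return rng.binomial(depths, fractions)
    scale = (1.0 - rho) / rho
    p = rng.beta(fractions * scale, (1.0 - fractions) * scale)
    return rng.binomial(depths, p)


def simulate_cohort(config: SimConfig) -> tuple[CountTable, SimTruth]:
    """Generate a cohort count table plus its ground truth.

    Null variants come first, AEI variants after; variants are laid out on
    chromosome ``chr1`` at 1 kb spacing with synthesized rsIDs and one
    synthetic gene symbol each, and site QUAL above any realistic filter
    threshold.
    """
    n_total = config.n_null_variants + config.n_aei_variants
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    table = CountTable()
    variant_rows = []
    sample_rows = []

    for v in range(n_total):
        is_aei = v >= config.n_null_variants
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(v,))
        )
        site = VariantSite(
            chrom="chr1",
            pos=10_000 + 1_000 * v,
            ref_allele="A",
            alt_allele="G",
            rsid=f"rs9{v + 1:07d}",
            qual=config.qual,
            gene=f"SIMG{v + 1:04d}",
        )
        if is_aei:
            freqs = _haplotype_freqs(config.marker_af, config.ld_r2)
            haps = rng.choice(4, size=(config.n_samples, 2), p=freqs)
            marker = (haps < 2).astype(int)  # hap codes 0,1 carry alt marker
            repressive = (haps % 2 == 0).astype(int)  # codes 0,2 carry it
        else:
            marker = (
                rng.random((config.n_samples, 2)) < config.marker_af
            ).astype(int)
            repressive = np.zeros_like(marker)

        n_alt_alleles = marker.sum(axis=1)
        depths = _draw_depths(rng, config.n_samples, config)

        # expressed alt-allele fraction per sample
        fractions = np.full(config.n_samples, 0.5)
        phases = np.array(["none"] * config.n_samples, dtype=object)
        if is_aei:
            for i in range(config.n_samples):
                if n_alt_alleles[i] != 1:
                    continue
                alt_hap = int(np.flatnonzero(marker[i] == 1)[0])
                ref_hap = 1 - alt_hap
                on_alt = bool(repressive[i, alt_hap])
                on_ref = bool(repressive[i, ref_hap])
                if on_alt and not on_ref:
                    fractions[i] = config.aei_fraction
                    phases[i] = "alt"
                elif on_ref and not on_alt:
                    fractions[i] = 1.0 - config.aei_fraction
                    phases[i] = "ref"
                elif on_alt and on_ref:
                    phases[i] = "both"

        alt_counts = np.zeros(config.n_samples, dtype=int)
        het = n_alt_alleles == 1
        alt_counts[het] = _beta_binomial(
            rng, depths[het], fractions[het], config.rho
        )
        alt_counts[n_alt_alleles == 2] = depths[n_alt_alleles == 2]

        for i, sample in enumerate(samples):
            geno = _GENOTYPES[n_alt_alleles[i]]
            alt_c = int(alt_counts[i])
            table.add(
                AlleleDepthRecord(
                    site=site,
                    sample_id=sample,
                    ref_count=int(depths[i]) - alt_c,
                    alt_count=alt_c,
                    genotype=geno,
                )
            )
            sample_rows.append(
                {
                    "rsid": site.rsid,
                    "sample": sample,
                    "genotype": geno.value,
                    "phase": phases[i] if geno is Genotype.HET else "none",
                    "expressed_alt_fraction": (
                        fractions[i] if geno is Genotype.HET else float("nan")
                    ),
                }
            )
        variant_rows.append(
            {
                "rsid": site.rsid,
                "chrom": site.chrom,
                "pos": site.pos,
                "gene": site.gene,
                "is_aei": is_aei,
                "true_fraction": config.aei_fraction if is_aei else 0.5,
            }
        )

    truth = SimTruth(
        variants=pd.DataFrame(variant_rows),
        samples=pd.DataFrame(sample_rows),
    )
    return table, truth


def truth_eval(
    calls: Iterable[AeiCall] | Iterable[str],
    truth: SimTruth,
    *,
    use_multi: bool = False,
) -> DetectionMetrics:
    """Variant-level confusion counts of detected AEI against truth.

    ``calls`` may be AEI calls (detection read from the retained flag, or
    retained_multi when ``use_multi``) or a plain collection of detected
    rsIDs. Variants absent from the calls count as undetected; detected
    identifiers absent from the truth are an error.
    """
    detected: set[str] = set()
    for item in calls:
        if isinstance(item, str):
            detected.add(item)
        else:
            flag = item.retained_multi if use_multi else item.retained
            if flag:
                detected.add(item.site.rsid)
    truth_ids = set(truth.variants["rsid"])
    unknown = detected - truth_ids
    if unknown:
        raise ValueError(f"detected variant(s) not in truth: {sorted(unknown)[:5]}")
    is_aei = dict(zip(truth.variants["rsid"], truth.variants["is_aei"]))
    tp = sum(1 for r, flag in is_aei.items() if flag and r in detected)
    fn = sum(1 for r, flag in is_aei.items() if flag and r not in detected)
    fp = sum(1 for r, flag in is_aei.items() if not flag and r in detected)
    tn = sum(1 for r, flag in is_aei.items() if not flag and r not in detected)
    return DetectionMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn, thresholds={"use_multi": use_multi}
    )


def write_truth(truth: SimTruth, variants_path, samples_path) -> None:
    """Write the two truth tables as TSV."""
    truth.variants.to_csv(variants_path, sep="\t", index=False)
    truth.samples.to_csv(samples_path, sep="\t", index=False, na_rep="NA")


def read_truth(variants_path, samples_path) -> SimTruth:
    return SimTruth(
        variants=pd.read_csv(variants_path, sep="\t"),
        samples=pd.read_csv(samples_path, sep="\t", na_values=["NA"]),
    )
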