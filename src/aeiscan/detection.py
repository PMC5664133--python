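"""Variant selection filters and per-variant AEI calling.

At a heterozygous transcribed SNP, unequal expression of the two alleles
(allelic expression imbalance, AEI) shows up as an alternative/reference
read-count ratio away from 1. Detection proceeds in three steps:

1. keep het calls at well-supported sites (site quality strictly above a
   threshold, total depth and per-allele read support at least a minimum,
   and optionally a dbSNP identifier);
2. compute the natural-log allelic ratio ln(alt/ref) per retained record and
   fit a normal outlier model — values outside mean +/- k*SD of a reference
   population are flagged (k defaults to 2, i.e. ~4.6% two-sided tail);
3. retain variants with an outlier in at least one sample, and separately
   flag those that survive the stricter multi-hit rule (two or more outlier
   samples, or a single outlier backed by at least one further moderately
   imbalanced sample).

"Moderate" imbalance is a linear ratio strictly outside the balance band
[0.666, 1.5], i.e. one allele contributing less than ~40% of reads.

The reference population for the outlier model is, by default, all passing
records within one sample (``per_sample`` scope); ``per_variant`` scope
(across samples at one site) is available as an alternative.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .io import AlleleDepthRecord, CountTable, Genotype, VariantSite

logger = logging.getLogger(__name__)

#: Balance band on the linear allelic ratio alt/ref; a ratio strictly
#: outside it corresponds to an allele contributing <40% or >60% of reads.
RATIO_LOW = 0.666
RATIO_HIGH = 1.5

OutlierScope = Literal["per_sample", "per_variant"]


class DegenerateModelError(ValueError):
    """Raised when an outlier model is requested for fewer than two values."""


@dataclass(frozen=True)
class FilterConfig:
    """Record-level selection thresholds.

    min_qual is strict (a site at exactly the threshold fails); min_depth and
    min_allele_reads are at-least thresholds. require_rsid keeps only sites
    whose VCF ID column is non-missing, as a proxy for dbSNP membership.
    """

    min_qual: float = 225.0
    min_depth: int = 20
    min_allele_reads: int = 2
    require_rsid: bool = True

    def __post_init__(self) -> None:
        if self.min_qual < 0 or self.min_depth < 0 or self.min_allele_reads < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass
class SampleRatio:
    """Linear and log allelic ratio of one het sample at one site."""

    sample_id: str
    linear_ratio: float
    log_ratio: float
    is_outlier: bool = False
    is_moderate: bool = False


@dataclass(frozen=True)
class OutlierModel:
    """Normal mean +/- k*SD outlier rule fitted to a log-ratio population."""

    scope: OutlierScope
    k: float
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    def is_outlier(self, log_ratio: float) -> bool:
        """Strictly outside [mean - k*sd, mean + k*sd].

        Values numerically indistinguishable from a bound (or from the mean
        when the population is constant) count as inside: equality with a
        bound is not "outside", and rounding noise must not flag it.
        """
        diff = abs(log_ratio - self.mean)
        bound = self.k * self.sd
        return diff > bound and not math.isclose(
            diff, bound, rel_tol=1e-9, abs_tol=1e-12
        )


@dataclass
class AeiCall:
    """Per-variant AEI decision with the per-sample ratios behind it."""

    site: VariantSite
    ratios: list[SampleRatio] = field(default_factory=list)
    n_outlier_samples: int = 0
    retained: bool = False
    retained_multi: bool = False


def passes_filters(record: AlleleDepthRecord, config: FilterConfig) -> bool:
    """True iff the record is a usable het observation under ``config``."""
    if record.genotype is not Genotype.HET:
        return False
    if not record.site.qual > config.min_qual:
        return False
    if record.depth < config.min_depth:
        return False
    if min(record.ref_count, record.alt_count) < config.min_allele_reads:
        return False
    if config.require_rsid and record.site.rsid is None:
        return False
    return True


def compute_ratios(record: AlleleDepthRecord) -> SampleRatio:
    """Linear ratio alt/ref and its natural log for one het record.

    Requires both counts positive (guaranteed for filtered records with
    min_allele_reads >= 1); outlier/moderate flags start unset.
    """
    if record.ref_count == 0 or record.alt_count == 0:
        raise ValueError(
            f"ratio undefined with a zero count "
            f"({record.ref_count}, {record.alt_count}); filter first"
        )
    linear = record.alt_count / record.ref_count
    return SampleRatio(
        sample_id=record.sample_id,
        linear_ratio=linear,
        log_ratio=math.log(linear),
    )


def moderate_flag(
    linear_ratio: float, low: float = RATIO_LOW, high: float = RATIO_HIGH
) -> bool:
    """True iff the linear ratio lies strictly outside the balance band."""
    if linear_ratio <= 0:
        raise ValueError("linear ratio must be positive")
    return linear_ratio < low or linear_ratio > high


def fit_outlier_model(
    log_ratios: Sequence[float],
    scope: OutlierScope = "per_sample",
    k: float = 2.0,
) -> OutlierModel:
    """Fit the normal outlier rule to a reference population of log-ratios.

    Uses the sample mean and the n-1 sample standard deviation. At least two
    values are required; a constant population yields SD 0, whose collapsed
    bounds flag nothing (values equal to a bound are not outside it).
    """
    values = np.asarray(log_ratios, dtype=float)
    if values.size < 2:
        raise DegenerateModelError(
            f"outlier model needs >= 2 reference values, got {values.size}"
        )
    # a constant population has SD exactly 0; np.std would report rounding
    # noise of order 1e-17 for non-representable constants
    sd = 0.0 if np.ptp(values) == 0 else float(values.std(ddof=1))
    return OutlierModel(
        scope=scope,
        k=k,
        mean=float(values.mean()),
        sd=sd,
        n=int(values.size),
    )


def call_aei(
    table: CountTable,
    config: FilterConfig | None = None,
    *,
    scope: OutlierScope = "per_sample",
    k: float = 2.0,
    ratio_low: float = RATIO_LOW,
    ratio_high: float = RATIO_HIGH,
) -> list[AeiCall]:
    """Apply filters, fit outlier models, and call AEI per variant.

    A variant is ``retained`` when at least one het sample is a log-ratio
    outlier. ``retained_multi`` additionally requires a second outlier
    sample, or one outlier plus at least one other sample with moderate
    imbalance — the rule used to exclude single AEI hits.

    Sites with no passing het record yield no call. Samples (or sites, for
    per_variant scope) whose reference population has fewer than two values
    cannot be outlier-flagged and are left unflagged with a log message.

    The result is invariant to the ordering of samples and variants; calls
    are returned in the table's site order.
    """
    if config is None:
        config = FilterConfig()
    if not (ratio_low < 1.0 < ratio_high):
        raise ValueError("ratio band must straddle 1")

    passing = [r for r in table.records if passes_filters(r, config)]
    ratios: dict[tuple, SampleRatio] = {}
    by_group: dict[object, list[float]] = defaultdict(list)
    by_site: dict[tuple, list[tuple[AlleleDepthRecord, SampleRatio]]] = defaultdict(list)
    site_by_key: dict[tuple, VariantSite] = {}

    for rec in passing:
        sr = compute_ratios(rec)
        sr.is_moderate = moderate_flag(sr.linear_ratio, ratio_low, ratio_high)
        ratios[(rec.site.key, rec.sample_id)] = sr
        group = rec.sample_id if scope == "per_sample" else rec.site.key
        by_group[group].append(sr.log_ratio)
        by_site[rec.site.key].append((rec, sr))
        site_by_key.setdefault(rec.site.key, rec.site)

    models: dict[object, OutlierModel] = {}
    for group, values in by_group.items():
        if len(values) < 2:
            logger.info(
                "call_aei: %s %r has %d passing record(s); outlier model "
                "not fitted, values left unflagged",
                "sample" if scope == "per_sample" else "site",
                group,
                len(values),
            )
            continue
        models[group] = fit_outlier_model(values, scope=scope, k=k)

    calls: list[AeiCall] = []
    for site in table.sites:
        entries = by_site.get(site.key)
        if not entries:
            continue
        site_ratios: list[SampleRatio] = []
        n_out = 0
        n_mod_extra = 0
        for rec, sr in entries:
            group = rec.sample_id if scope == "per_sample" else rec.site.key
            model = models.get(group)
            sr.is_outlier = model.is_outlier(sr.log_ratio) if model else False
            if sr.is_outlier:
                n_out += 1
            elif sr.is_moderate:
                n_mod_extra += 1
            site_ratios.append(sr)
        retained = n_out >= 1
        retained_multi = n_out >= 2 or (n_out == 1 and n_mod_extra >= 1)
        calls.append(
            AeiCall(
                site=site,
                ratios=site_ratios,
                n_outlier_samples=n_out,
                retained=retained,
                retained_multi=retained_multi,
            )
        )
    return calls


def outlier_fraction_by_sample(calls: Iterable[AeiCall]) -> dict[str, float]:
    """Fraction of passing records flagged as outliers, per sample.

    Diagnostic for the calibration of the mean +/- k*SD rule: under a
    balanced null it should sit near the two-sided normal tail mass
    (about 4.6% for k = 2).
    """
    seen: dict[str, int] = defaultdict(int)
    flagged: dict[str, int] = defaultdict(int)
    for call in calls:
        for sr in call.ratios:
            seen[sr.sample_id] += 1
            if sr.is_outlier:
                flagged[sr.sample_id] += 1
    return {s: flagged[s] / seen[s] for s in seen}
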