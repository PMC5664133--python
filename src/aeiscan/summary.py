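"""Per-variant cohort aggregation of AEI calls.

For each variant the cohort report counts het samples, splits the
moderately imbalanced ones by direction of the linear ratio (below 0.666
vs above 1.5), and derives:

* AEI frequency among het samples and in the whole cohort (percent);
* the absolute (oriented) mean allelic ratio +/- SEM over the imbalanced
  samples, where each ratio is re-expressed as lesser-expressed allele over
  greater-expressed allele, min(r, 1/r) in (0, 1];
* bias-corrected excess kurtosis G2 of those oriented ratios with its
  standard error (SEK) — high kurtosis means the imbalanced samples cluster
  at one ratio, suggesting a single molecular cause (e.g. one regulatory
  variant in strong LD with the SNP);
* the orientation fraction max(n_below, n_above)/n_imbalanced, which is
  near 1 when all imbalanced samples tilt the same way (again an LD
  signature).

Frequency counting uses the moderate band, matching the two directional
report columns; the mean +/- 2SD outlier rule drives variant *selection*
only (see :mod:`aeiscan.detection`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .detection import AeiCall
from .io import VariantSite


@dataclass(frozen=True)
class AllelePercentPair:
    """The two allele percentages equivalent to a linear allelic ratio."""

    minor_percent: float
    major_percent: float

    def __post_init__(self) -> None:
        if not 0 <= self.minor_percent <= self.major_percent <= 100:
            raise ValueError("percentages must satisfy 0 <= minor <= major <= 100")
        if abs((self.minor_percent + self.major_percent) - 100.0) > 1e-9:
            raise ValueError("allele percentages must sum to 100")


@dataclass(frozen=True)
class VariantSummary:
    """Cohort-level AEI summary for one variant (one report row)."""

    site: VariantSite
    n_het: int
    n_below: int
    n_above: int
    n_imbalanced: int
    freq_het: float
    freq_cohort: float
    abs_mean_ratio: float
    sem_ratio: float
    kurtosis: float
    sek: float
    orientation_fraction: float
    dominant: Optional[bool] = None

    def with_dominant(self, flag: Optional[bool]) -> "VariantSummary":
        return replace(self, dominant=flag)


def aei_frequencies(
    n_imbalanced: int, n_het: int, cohort_size: int
) -> tuple[float, float]:
    """AEI frequency among het samples and in the full cohort, in percent.

    Returned at full precision; reports round to one decimal.
    """
    if n_het == 0:
        raise ValueError("frequency undefined with zero heterozygous samples")
    if not 0 <= n_imbalanced <= n_het <= cohort_size:
        raise ValueError(
            f"need 0 <= n_imbalanced <= n_het <= cohort_size, got "
            f"({n_imbalanced}, {n_het}, {cohort_size})"
        )
    return 100.0 * n_imbalanced / n_het, 100.0 * n_imbalanced / cohort_size


def orient_ratio(linear_ratio: float) -> float:
    """Re-orient a linear ratio towards the lesser-expressed allele: min(r, 1/r)."""
    if linear_ratio <= 0:
        raise ValueError("linear ratio must be positive")
    return min(linear_ratio, 1.0 / linear_ratio)


def oriented_mean_sem(oriented_ratios: Sequence[float]) -> tuple[float, float]:
    """Mean and SEM (n-1 SD / sqrt(n)) of oriented ratios.

    A single value yields SEM 0 by convention, with a warning.
    """
    values = np.asarray(oriented_ratios, dtype=float)
    if values.size == 0:
        raise ValueError("oriented_mean_sem requires at least one value")
    if values.size == 1:
        warnings.warn(
            "SEM reported as 0 for a single imbalanced sample", stacklevel=2
        )
        return float(values[0]), 0.0
    return float(values.mean()), float(values.std(ddof=1) / math.sqrt(values.size))


def ratio_to_percent(linear_ratio: float) -> AllelePercentPair:
    """Convert a linear ratio r to the allele-percentage pair.

    The two alleles contribute 100*r/(1+r) and 100/(1+r) percent of reads;
    the pair is returned ordered (minor, major). The balance band
    [0.666, 1.5] maps onto the 40-60% window.
    """
    if linear_ratio <= 0:
        raise ValueError("linear ratio must be positive")
    alt = 100.0 * linear_ratio / (1.0 + linear_ratio)
    minor = min(alt, 100.0 - alt)
    return AllelePercentPair(minor_percent=minor, major_percent=100.0 - minor)


def excess_kurtosis(values: Sequence[float]) -> float:
    """Bias-corrected excess kurtosis G2.

    G2 = n(n+1)/((n-1)(n-2)(n-3)) * sum(((x-mean)/s)^4) - 3(n-1)^2/((n-2)(n-3))
    with s the n-1 sample SD — the convention whose standard error is
    :func:`sek`. Undefined (NaN, with a warning) for n < 4 or zero SD.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4 or np.std(x, ddof=1) == 0:
        warnings.warn(
            f"excess kurtosis undefined for n={x.size} or constant values",
            stacklevel=2,
        )
        return float("nan")
    return float(stats.kurtosis(x, fisher=True, bias=False))


def sek(n: int) -> float:
    """Standard error of sample kurtosis for sample size n.

    SEK = 2*SES*sqrt((n^2-1)/((n-3)(n+5))), with the standard error of
    skewness SES = sqrt(6n(n-1)/((n-2)(n+1)(n+3))). Requires n >= 6;
    smaller n returns NaN with a warning.
    """
    if n < 6:
        warnings.warn(f"SEK undefined for n={n} < 6", stacklevel=2)
        return float("nan")
    ses = math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))
    return 2.0 * ses * math.sqrt((n * n - 1) / ((n - 3.0) * (n + 5.0)))


def summarize_variant(call: AeiCall, cohort_size: int) -> VariantSummary:
    """Aggregate one AEI call into a report row.

    Imbalanced samples are those with the moderate flag set; they are split
    by direction of the linear ratio. Ratio statistics (oriented mean, SEM,
    kurtosis, SEK) are computed over the imbalanced samples only and are NaN
    whenever their defining sample size is too small.
    """
    n_het = len(call.ratios)
    if n_het == 0:
        raise ValueError("summarize_variant requires at least one het sample")
    imbalanced = [sr for sr in call.ratios if sr.is_moderate]
    n_below = sum(1 for sr in imbalanced if sr.linear_ratio < 1.0)
    n_above = len(imbalanced) - n_below
    n_imb = len(imbalanced)
    freq_het, freq_cohort = aei_frequencies(n_imb, n_het, cohort_size)

    if n_imb == 0:
        mean = sem_ = kurt = sek_ = orientation = float("nan")
    else:
        oriented = [orient_ratio(sr.linear_ratio) for sr in imbalanced]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean, sem_ = oriented_mean_sem(oriented)
            kurt = excess_kurtosis(oriented)
            sek_ = sek(n_imb)
        orientation = max(n_below, n_above) / n_imb
    return VariantSummary(
        site=call.site,
        n_het=n_het,
        n_below=n_below,
        n_above=n_above,
        n_imbalanced=n_imb,
        freq_het=freq_het,
        freq_cohort=freq_cohort,
        abs_mean_ratio=mean,
        sem_ratio=sem_,
        kurtosis=kurt,
        sek=sek_,
        orientation_fraction=orientation,
    )


def frequency_filter(
    summaries: Iterable[VariantSummary], min_freq_cohort: float = 10.0
) -> list[VariantSummary]:
    """Keep variants whose cohort AEI frequency strictly exceeds the threshold."""
    if not 0 <= min_freq_cohort <= 100:
        raise ValueError("min_freq_cohort must be a percentage in [0, 100]")
    return [s for s in summaries if s.freq_cohort > min_freq_cohort]
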