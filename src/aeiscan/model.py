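"""Model/results interface over the AEI pipeline.

:class:`AllelicImbalanceModel` is built from a :class:`~aeiscan.io.CountTable`
(or directly from a VCF / count-table file) together with the selection
thresholds; :meth:`AllelicImbalanceModel.fit` fits the per-scope normal
outlier models to the log allelic ratios and returns
:class:`AllelicImbalanceResults`, which carries the per-variant calls,
cohort summaries, a report-style ``summary()`` table, panel/blacklist/
frequency selection, evaluation against simulated truth, and a simple
allele-percentage plot.
"""

from __future__ import annotations

from dataclasses import asdict
from functools import cached_property
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from . import io as _io
from .detection import (
    RATIO_HIGH,
    RATIO_LOW,
    AeiCall,
    FilterConfig,
    OutlierScope,
    call_aei,
)
from .panel import GenePanel, Region, filter_by_blacklist, filter_by_panel
from .simulate import DetectionMetrics, SimTruth, truth_eval
from .summary import (
    VariantSummary,
    frequency_filter,
    ratio_to_percent,
    summarize_variant,
)


class AllelicImbalanceModel:
    """Cohort-wide allelic expression imbalance screen.

    Parameters
    ----------
    counts
        Per-sample allele depths at biallelic SNVs.
    cohort_size
        Number of individuals the cohort-frequency denominators refer to.
        Explicit (never inferred from the table) so partially genotyped
        cohorts behave predictably; defaults to the number of samples in
        the table.
    filters
        Record-level thresholds (site quality, depth, per-allele support,
        dbSNP membership).
    ratio_low, ratio_high
        Balance band on the linear ratio; strictly outside it counts as
        moderate imbalance.
    outlier_scope, k_sd
        Reference population of the normal outlier model (per_sample:
        across a sample's variants; per_variant: across a variant's
        samples) and the number of SDs defining an outlier.
    """

    def __init__(
        self,
        counts: _io.CountTable,
        cohort_size: Optional[int] = None,
        filters: Optional[FilterConfig] = None,
        *,
        ratio_low: float = RATIO_LOW,
        ratio_high: float = RATIO_HIGH,
        outlier_scope: OutlierScope = "per_sample",
        k_sd: float = 2.0,
    ) -> None:
        self.counts = counts
        self.cohort_size = (
            cohort_size if cohort_size is not None else len(counts.samples)
        )
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        self.filters = filters if filters is not None else FilterConfig()
        self.ratio_low = ratio_low
        self.ratio_high = ratio_high
        self.outlier_scope: OutlierScope = outlier_scope
        self.k_sd = k_sd

    @classmethod
    def from_vcf(cls, path: str | Path, **kwargs) -> "AllelicImbalanceModel":
        return cls(_io.read_vcf(path), **kwargs)

    @classmethod
    def from_count_table(cls, path: str | Path, **kwargs) -> "AllelicImbalanceModel":
        return cls(_io.read_count_table(path), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "AllelicImbalanceModel":
        return cls(_io.CountTable.from_dataframe(df), **kwargs)

    def config_dict(self) -> dict:
        """Flat snapshot of all thresholds, for manifests and reports."""
        cfg = asdict(self.filters)
        cfg.update(
            cohort_size=self.cohort_size,
            ratio_low=self.ratio_low,
            ratio_high=self.ratio_high,
            outlier_scope=self.outlier_scope,
            k_sd=self.k_sd,
        )
        return cfg

    def fit(self) -> "AllelicImbalanceResults":
        """Run filtering, ratio computation, and outlier calling."""
        calls = call_aei(
            self.counts,
            self.filters,
            scope=self.outlier_scope,
            k=self.k_sd,
            ratio_low=self.ratio_low,
            ratio_high=self.ratio_high,
        )
        return AllelicImbalanceResults(self, calls)


class AllelicImbalanceResults:
    """Fitted AEI screen: per-variant calls plus cohort summaries."""

    def __init__(self, model: AllelicImbalanceModel, calls: list[AeiCall]) -> None:
        self.model = model
        self.calls = calls

    @property
    def retained_calls(self) -> list[AeiCall]:
        return [c for c in self.calls if c.retained]

    @cached_property
    def summaries(self) -> list[VariantSummary]:
        """Cohort summaries of every retained variant."""
        return [
            summarize_variant(c, self.model.cohort_size) for c in self.retained_calls
        ]

    def select(
        self,
        *,
        panel: Optional[GenePanel] = None,
        blacklist: Optional[str | Path | Iterable[Region]] = None,
        min_cohort_freq: Optional[float] = None,
        multi_only: bool = False,
    ) -> list[VariantSummary]:
        """Apply the report-level selection steps in pipeline order.

        Multi-hit restriction, then gene panel, then region blacklist, then
        the strict cohort-frequency threshold (percent).
        """
        if multi_only:
            multi_keys = {c.site.key for c in self.calls if c.retained_multi}
            selected = [s for s in self.summaries if s.site.key in multi_keys]
        else:
            selected = list(self.summaries)
        if panel is not None:
            selected = filter_by_panel(selected, panel)
        if blacklist is not None:
            selected = filter_by_blacklist(selected, blacklist)
        if min_cohort_freq is not None:
            selected = frequency_filter(selected, min_cohort_freq)
        return selected

    def summary(
        self, summaries: Optional[Iterable[VariantSummary]] = None
    ) -> pd.DataFrame:
        """Report-style table, one row per variant."""
        if summaries is None:
            summaries = self.summaries
        rows = []
        for s in summaries:
            rows.append(
                {
                    "gene_snp": s.site.label,
                    "n_het": s.n_het,
                    "n_ratio_below": s.n_below,
                    "n_ratio_above": s.n_above,
                    "n_imbalanced": s.n_imbalanced,
                    "freq_het_pct": s.freq_het,
                    "freq_cohort_pct": s.freq_cohort,
                    "abs_mean_ratio": s.abs_mean_ratio,
                    "sem_ratio": s.sem_ratio,
                    "kurtosis": s.kurtosis,
                    "sek": s.sek,
                    "orientation_fraction": s.orientation_fraction,
                    "dominant": s.dominant,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(
        self,
        path: str | Path,
        summaries: Optional[Iterable[VariantSummary]] = None,
    ) -> None:
        """Write the report TSV via :func:`aeiscan.io.write_summary_table`."""
        _io.write_summary_table(
            self.summaries if summaries is None else summaries, path
        )

    def evaluate(self, truth: SimTruth, *, use_multi: bool = False) -> DetectionMetrics:
        """Confusion counts against simulated ground truth."""
        return truth_eval(self.calls, truth, use_multi=use_multi)

    def plot_allele_percentages(
        self,
        summaries: Optional[Iterable[VariantSummary]] = None,
        ax=None,
    ):
        """Horizontal bars of mean minor/major allele percentages per variant.

        The oriented mean ratio of each variant's imbalanced samples is
        converted to its allele-percentage pair; the 40-60% balance band is
        shaded.
        """
        import matplotlib.pyplot as plt

        if summaries is None:
            summaries = self.summaries
        summaries = [s for s in summaries if s.n_imbalanced > 0]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(summaries))))
        labels = [s.site.label for s in summaries]
        minors = [ratio_to_percent(s.abs_mean_ratio).minor_percent for s in summaries]
        y = range(len(summaries))
        ax.barh(y, minors, color="tab:blue", label="minor allele")
        ax.barh(
            y,
            [100 - m for m in minors],
            left=minors,
            color="tab:orange",
            label="major allele",
        )
        ax.axvspan(40, 60, color="grey", alpha=0.25, label="balance band")
        ax.set_yticks(list(y), labels)
        ax.set_xlabel("allele percentage")
        ax.set_xlim(0, 100)
        ax.legend(loc="lower right", fontsize="small")
        return ax
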