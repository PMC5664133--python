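"""Gene-panel restriction and region blacklisting of variant summaries.

A panel is a plain-text list of gene symbols (one per line, optional second
column with an inheritance annotation such as ``AD`` for autosomal
dominant), in the style of disease-gene registries for inherited retinal
disease. A blacklist is a BED file (0-based half-open intervals) of regions
the user has judged mapping-conflictive; variants falling inside any
interval are removed. Gene assignment is taken from the input's gene
annotation column, never recomputed from a gene model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .summary import VariantSummary

#: Inheritance annotations understood as "autosomal dominant".
_DOMINANT_TOKENS = {"AD", "DOMINANT", "AUTOSOMAL_DOMINANT", "AUTOSOMAL DOMINANT"}


class PanelFormatError(ValueError):
    """Raised for unusable panel files."""


class BedFormatError(ValueError):
    """Raised for malformed BED lines."""


@dataclass(frozen=True)
class Region:
    """One blacklist interval: chrom, 0-based half-open [start, end), label."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"need 0 <= start < end, got [{self.start}, {self.end})"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether a 1-based variant position falls inside this interval."""
        return chrom == self.chrom and self.start <= pos - 1 < self.end


class GenePanel:
    """Case-normalized set of gene symbols with optional inheritance flags."""

    def __init__(self, genes: dict[str, Optional[str]]):
        self._genes = {g.upper(): ann for g, ann in genes.items()}

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self._genes

    def __len__(self) -> int:
        return len(self._genes)

    @property
    def symbols(self) -> set[str]:
        return set(self._genes)

    def annotation(self, symbol: str) -> Optional[str]:
        return self._genes.get(symbol.upper())

    def is_dominant(self, symbol: str) -> Optional[bool]:
        """True/False for annotated genes, None when no annotation exists."""
        ann = self._genes.get(symbol.upper())
        if ann is None:
            return None
        return ann.upper() in _DOMINANT_TOKENS


def load_panel(path: str | Path) -> GenePanel:
    """Load a one-symbol-per-line panel file.

    Duplicate symbols (case-insensitive) are collapsed with a warning; an
    annotation from any duplicate line wins over none. Empty files are
    rejected.
    """
    path = Path(path)
    genes: dict[str, Optional[str]] = {}
    duplicates = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        symbol = parts[0].upper()
        annotation = parts[1] if len(parts) > 1 else None
        if symbol in genes:
            duplicates.append(symbol)
            if genes[symbol] is None:
                genes[symbol] = annotation
            continue
        genes[symbol] = annotation
    if duplicates:
        warnings.warn(
            f"panel contains duplicate symbol(s): {sorted(set(duplicates))}",
            stacklevel=2,
        )
    if not genes:
        raise PanelFormatError(f"panel file {path} contains no gene symbols")
    return GenePanel(genes)


def filter_by_panel(
    summaries: Iterable[VariantSummary], panel: GenePanel
) -> list[VariantSummary]:
    """Keep summaries whose gene is in the panel; annotate the dominant flag.

    Summaries without a gene annotation cannot be matched and are dropped
    with a warning.
    """
    kept: list[VariantSummary] = []
    n_unannotated = 0
    for s in summaries:
        gene = s.site.gene
        if gene is None:
            n_unannotated += 1
            continue
        if gene in panel:
            kept.append(s.with_dominant(panel.is_dominant(gene)))
    if n_unannotated:
        warnings.warn(
            f"dropped {n_unannotated} summar(ies) lacking a gene annotation",
            stacklevel=2,
        )
    return kept


def load_blacklist(path: str | Path) -> list[Region]:
    """Parse a BED3+label file into blacklist regions."""
    path = Path(path)
    regions: list[Region] = []
    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise BedFormatError(f"{path} line {line_no}: expected >= 3 columns")
        try:
            region = Region(
                chrom=parts[0],
                start=int(parts[1]),
                end=int(parts[2]),
                label=parts[3] if len(parts) > 3 else "",
            )
        except ValueError as exc:
            raise BedFormatError(f"{path} line {line_no}: {exc}") from exc
        regions.append(region)
    return regions


def filter_by_blacklist(
    summaries: Iterable[VariantSummary],
    blacklist: str | Path | Iterable[Region],
) -> list[VariantSummary]:
    """Remove summaries whose position falls inside any blacklist interval."""
    if isinstance(blacklist, (str, Path)):
        regions = load_blacklist(blacklist)
    else:
        regions = list(blacklist)
    return [
        s
        for s in summaries
        if not any(r.contains(s.site.chrom, s.site.pos) for r in regions)
    ]


def example_blacklist_path() -> Path:
    """Path to the bundled example blacklist BED (approximate intervals)."""
    return Path(resources.files("aeiscan").joinpath("data/blacklist_example.bed"))
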