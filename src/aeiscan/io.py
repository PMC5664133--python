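"""Reading and writing of variant call and allele-count data.

The pipeline consumes either a multi-sample VCF with per-sample ``GT:AD:DP``
fields (the output of an upstream RNA-seq variant caller) or an equivalent
long-format tab-separated allele-count table, and normalizes both into a
:class:`CountTable` of per-sample reference/alternative read counts at
biallelic SNVs. Only biallelic single-nucleotide sites are represented;
multi-allelic records and indels are dropped (or rejected) at read time.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

COUNT_TABLE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "rsid",
    "qual",
    "gene",
    "sample",
    "ref_count",
    "alt_count",
    "genotype",
]

SUMMARY_TABLE_COLUMNS = [
    "gene_snp",
    "n_het",
    "n_ratio_below",
    "n_ratio_above",
    "n_imbalanced",
    "freq_het_pct",
    "freq_cohort_pct",
    "abs_mean_ratio",
    "sem_ratio",
    "kurtosis",
    "sek",
]


class VcfFormatError(ValueError):
    """Raised when a VCF record violates the expected layout."""


class CountTableFormatError(ValueError):
    """Raised when a count-table file violates the expected layout."""


class Genotype(str, enum.Enum):
    """Diploid genotype of one sample at one biallelic site."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    def __str__(self) -> str:  # write the bare value into tables
        return self.value


@dataclass(frozen=True)
class VariantSite:
    """One biallelic single-nucleotide site.

    Coordinates are 1-based as in VCF. ``rsid`` is the dbSNP identifier from
    the VCF ID column (``None`` when the column is '.'), ``qual`` the site
    quality score, and ``gene`` an optional gene-symbol annotation carried
    over from the upstream annotator.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    rsid: Optional[str] = None
    qual: float = 0.0
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(
                f"only single-nucleotide alleles are representable, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.qual < 0:
            raise ValueError(f"qual must be non-negative, got {self.qual}")

    @property
    def key(self) -> tuple:
        """Positional identity (chromosome, position, alleles)."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def label(self) -> str:
        """Human-readable ``GENE_rsID``-style label for reports."""
        left = self.gene if self.gene else self.chrom
        right = self.rsid if self.rsid else f"{self.chrom}:{self.pos}"
        return f"{left}_{right}"


@dataclass(frozen=True)
class AlleleDepthRecord:
    """Reference/alternative read counts of one sample at one site."""

    site: VariantSite
    sample_id: str
    ref_count: int
    alt_count: int
    genotype: Genotype

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError(
                f"read counts must be non-negative, got "
                f"({self.ref_count}, {self.alt_count})"
            )

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


class CountTable:
    """Collection of :class:`AlleleDepthRecord` keyed by (site, sample).

    Sites and samples keep their first-seen order; duplicate (site, sample)
    keys are rejected.
    """

    def __init__(self, records: Iterable[AlleleDepthRecord] = ()) -> None:
        self._records: dict[tuple, AlleleDepthRecord] = {}
        self._sites: dict[tuple, VariantSite] = {}
        self._samples: dict[str, None] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: AlleleDepthRecord) -> None:
        key = (record.site.key, record.sample_id)
        if key in self._records:
            raise ValueError(
                f"duplicate record for site {record.site.key} "
                f"sample {record.sample_id!r}"
            )
        self._records[key] = record
        self._sites.setdefault(record.site.key, record.site)
        self._samples.setdefault(record.sample_id)

    @property
    def sites(self) -> list[VariantSite]:
        return list(self._sites.values())

    @property
    def samples(self) -> list[str]:
        return list(self._samples)

    @property
    def records(self) -> list[AlleleDepthRecord]:
        return list(self._records.values())

    def get(self, site: VariantSite, sample_id: str) -> Optional[AlleleDepthRecord]:
        return self._records.get((site.key, sample_id))

    def records_for_site(self, site: VariantSite) -> list[AlleleDepthRecord]:
        return [r for r in self._records.values() if r.site.key == site.key]

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[AlleleDepthRecord]:
        return iter(self._records.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self._records == other._records

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self._records.values():
            s = rec.site
            rows.append(
                {
                    "chrom": s.chrom,
                    "pos": s.pos,
                    "ref": s.ref_allele,
                    "alt": s.alt_allele,
                    "rsid": s.rsid,
                    "qual": s.qual,
                    "gene": s.gene,
                    "sample": rec.sample_id,
                    "ref_count": rec.ref_count,
                    "alt_count": rec.alt_count,
                    "genotype": rec.genotype.value,
                }
            )
        return pd.DataFrame(rows, columns=COUNT_TABLE_COLUMNS)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        missing = [c for c in COUNT_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise CountTableFormatError(f"missing column(s): {', '.join(missing)}")
        table = cls()
        for idx, row in df.iterrows():
            try:
                geno = Genotype(str(row["genotype"]))
            except ValueError as exc:
                raise CountTableFormatError(
                    f"row {idx}: unknown genotype {row['genotype']!r}"
                ) from exc
            rsid = row["rsid"]
            gene = row["gene"]
            rsid = None if _is_missing(rsid) else str(rsid)
            gene = None if _is_missing(gene) else str(gene)
            try:
                site = VariantSite(
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ref_allele=str(row["ref"]),
                    alt_allele=str(row["alt"]),
                    rsid=rsid,
                    qual=float(row["qual"]),
                    gene=gene,
                )
                rec = AlleleDepthRecord(
                    site=site,
                    sample_id=str(row["sample"]),
                    ref_count=int(row["ref_count"]),
                    alt_count=int(row["alt_count"]),
                    genotype=geno,
                )
            except (ValueError, TypeError) as exc:
                raise CountTableFormatError(f"row {idx}: {exc}") from exc
            table.add(rec)
        return table


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return str(value) in {"", "."}


def _genotype_from_gt(gt: Optional[tuple]) -> Genotype:
    if gt is None or any(a is None for a in gt):
        return Genotype.MISSING
    alleles = set(gt)
    if alleles == {0}:
        return Genotype.HOM_REF
    if alleles == {1}:
        return Genotype.HOM_ALT
    if alleles == {0, 1}:
        return Genotype.HET
    return Genotype.MISSING


def read_vcf(path: str | Path, drop_nonbiallelic: bool = True) -> CountTable:
    """Read a multi-sample VCF into a :class:`CountTable`.

    Per-sample genotypes are taken from GT (never re-derived from counts)
    and allele depths from AD. Samples lacking AD at a site get zero counts
    and a missing genotype. An optional ``GENE`` INFO key populates the
    site's gene annotation.

    Parameters
    ----------
    path
        VCF file (plain or bgzipped).
    drop_nonbiallelic
        When true (default), multi-allelic records and records whose alleles
        are not single nucleotides are silently dropped (a count is logged).
        When false such records raise :class:`VcfFormatError`.
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read VCF {path}: {exc}") from exc

    table = CountTable()
    n_dropped = 0
    with vcf:
        sample_names = list(vcf.header.samples)
        for line_no, rec in enumerate(vcf, start=1):
            alts = rec.alts or ()
            biallelic_snv = (
                len(alts) == 1
                and rec.ref is not None
                and len(rec.ref) == 1
                and len(alts[0]) == 1
                and rec.ref.upper() in _BASES
                and alts[0].upper() in _BASES
            )
            if not biallelic_snv:
                if not drop_nonbiallelic:
                    raise VcfFormatError(
                        f"record {line_no} ({rec.chrom}:{rec.pos}) is not a "
                        f"biallelic SNV"
                    )
                n_dropped += 1
                continue
            gene = rec.info.get("GENE") if "GENE" in rec.info else None
            if isinstance(gene, tuple):
                gene = gene[0]
            site = VariantSite(
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref.upper(),
                alt_allele=alts[0].upper(),
                rsid=rec.id,
                qual=float(rec.qual) if rec.qual is not None else 0.0,
                gene=gene,
            )
            for sample in sample_names:
                fmt = rec.samples[sample]
                ad = fmt.get("AD")
                if ad is None or all(v is None for v in ad):
                    table.add(
                        AlleleDepthRecord(site, sample, 0, 0, Genotype.MISSING)
                    )
                    continue
                if len(ad) != 2:
                    raise VcfFormatError(
                        f"record {line_no} ({rec.chrom}:{rec.pos}) sample "
                        f"{sample!r}: AD has {len(ad)} values for 2 alleles"
                    )
                geno = _genotype_from_gt(fmt.get("GT"))
                table.add(
                    AlleleDepthRecord(
                        site,
                        sample,
                        int(ad[0] or 0),
                        int(ad[1] or 0),
                        geno,
                    )
                )
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic/non-SNV record(s)", n_dropped)
    return table


def write_vcf(table: CountTable, path: str | Path) -> None:
    """Write a :class:`CountTable` as an uncompressed VCF with GT:AD:DP.

    The header is fully deterministic (no timestamps), so identical tables
    produce byte-identical files.
    """
    path = Path(path)
    header = pysam.VariantHeader()
    header.add_line('##source=aeiscan')
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.info.add("GENE", 1, "String", "Gene symbol annotation")
    max_pos: dict[str, int] = {}
    for site in table.sites:
        max_pos[site.chrom] = max(max_pos.get(site.chrom, 0), site.pos)
    for chrom, pos in max_pos.items():
        header.contigs.add(chrom, length=pos + 1000)
    samples = table.samples
    for sample in samples:
        header.add_sample(sample)

    gt_map = {
        Genotype.HOM_REF: (0, 0),
        Genotype.HET: (0, 1),
        Genotype.HOM_ALT: (1, 1),
        Genotype.MISSING: (None, None),
    }
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in table.sites:
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos,
                alleles=(site.ref_allele, site.alt_allele),
                id=site.rsid,
                qual=site.qual,
            )
            if site.gene:
                rec.info["GENE"] = site.gene
            for sample in samples:
                r = table.get(site, sample)
                if r is None:
                    rec.samples[sample]["GT"] = (None, None)
                    continue
                rec.samples[sample]["GT"] = gt_map[r.genotype]
                rec.samples[sample]["AD"] = (r.ref_count, r.alt_count)
                rec.samples[sample]["DP"] = r.depth
            out.write(rec)


def read_count_table(path: str | Path) -> CountTable:
    """Read the long-format tab-separated allele-count table.

    Expected header: ``chrom pos ref alt rsid qual gene sample ref_count
    alt_count genotype``. Missing rsid/gene are written and read as '.'.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except OSError as exc:
        raise OSError(f"cannot read count table {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise CountTableFormatError(f"{path}: empty file, header expected") from exc
    return CountTable.from_dataframe(df)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a :class:`CountTable`; round-trips losslessly via read_count_table."""
    df = table.to_dataframe()
    df["rsid"] = df["rsid"].fillna(".")
    df["gene"] = df["gene"].fillna(".")
    df.to_csv(path, sep="\t", index=False)


def _fmt(value: float, spec: str) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return format(value, spec)


def write_summary_table(summaries: Iterable, path: str | Path) -> None:
    """Write per-variant cohort summaries as a report-style TSV.

    Columns follow the standard AEI report layout: per-SNP heterozygote
    count, directional imbalance counts, AEI frequencies (percent, one
    decimal), oriented mean allelic ratio and its SEM (three decimals), and
    excess kurtosis with its standard error (four significant figures).
    """
    rows = []
    for s in summaries:
        rows.append(
            {
                "gene_snp": s.site.label,
                "n_het": s.n_het,
                "n_ratio_below": s.n_below,
                "n_ratio_above": s.n_above,
                "n_imbalanced": s.n_imbalanced,
                "freq_het_pct": _fmt(s.freq_het, ".1f"),
                "freq_cohort_pct": _fmt(s.freq_cohort, ".1f"),
                "abs_mean_ratio": _fmt(s.abs_mean_ratio, ".3f"),
                "sem_ratio": _fmt(s.sem_ratio, ".3f"),
                "kurtosis": _fmt(s.kurtosis, ".4g"),
                "sek": _fmt(s.sek, ".4g"),
            }
        )
    df = pd.DataFrame(rows, columns=SUMMARY_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_summary_table(path: str | Path) -> pd.DataFrame:
    """Re-parse a summary TSV written by :func:`write_summary_table`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in SUMMARY_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise CountTableFormatError(f"missing column(s): {', '.join(missing)}")
    return df
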