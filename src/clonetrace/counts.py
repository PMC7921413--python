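"""Per-cell allele count tables.

The raw data for everything downstream is, for each cell and each genomic
site of interest (every position of the mitochondrial contig plus targeted
nuclear sites), the number of reads supporting each base A/C/G/T and the
number of reads spanning the position with a deletion. This module builds
those tables from coordinate-sorted, indexed BAM files (one file per cell,
or one file with a cell-barcode tag) and (de)serializes them as TSV.

Coordinates are 1-based inclusive throughout the package; the conversion to
pysam's 0-based half-open convention happens only at the alignment boundary
in :func:`count_alleles_from_alignments`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Counted alleles. Insertions are deliberately not genotyped; a read with an
#: inserted sequence adjacent to the site contributes its aligned base.
ALLELES = ("A", "C", "G", "T", "DEL")

BASES = ("A", "C", "G", "T")

#: Column layout of the TSV count-table format.
COLUMNS = ("cell_id", "contig", "position", "ref", "A", "C", "G", "T", "DEL")


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A single reference position, 1-based inclusive."""

    contig: str
    position: int
    ref_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele not in BASES:
            raise ValueError(f"ref_allele must be one of {BASES}, got {self.ref_allele!r}")

    def label(self, alt: str) -> str:
        """Human-readable variant label, e.g. ``mt:11559G>A`` or ``mt:7527DEL``."""
        if alt == "DEL":
            return f"{self.contig}:{self.position}DEL"
        return f"{self.contig}:{self.position}{self.ref_allele}>{alt}"


class AlleleCountTable:
    """Per-cell, per-site allele counts for one individual.

    Backed by a DataFrame with columns ``cell_id, contig, position, ref,
    A, C, G, T, DEL``. A (cell, site) pair with no aligned reads has no row;
    absence is interpreted downstream as missing data (dropout). Coverage is
    defined as the sum of the five allele counts.
    """

    def __init__(self, df: pd.DataFrame, individual_id: str = "unknown"):
        df = df.copy()
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        df = df.loc[:, list(COLUMNS)]
        for col in ALLELES:
            counts = pd.to_numeric(df[col], errors="raise")
            if (counts < 0).any():
                bad = int(np.flatnonzero(counts.to_numpy() < 0)[0])
                raise ValueError(f"invalid count: negative {col} count in row {bad}")
            df[col] = counts.astype(np.int64)
        df["position"] = pd.to_numeric(df["position"], errors="raise").astype(np.int64)
        if (df["position"] < 1).any():
            raise ValueError("invalid count table: position < 1")
        if not df["ref"].isin(BASES).all():
            bad = df.loc[~df["ref"].isin(BASES), "ref"].iloc[0]
            raise ValueError(f"invalid reference allele {bad!r}")
        dup = df.duplicated(subset=["cell_id", "contig", "position"])
        if dup.any():
            raise ValueError("duplicate (cell, site) records in count table")
        df = df.sort_values(["contig", "position", "cell_id"], kind="stable").reset_index(drop=True)
        self.df = df
        self.individual_id = individual_id

    # ------------------------------------------------------------------ views

    @property
    def cells(self) -> list[str]:
        return sorted(self.df["cell_id"].unique())

    @property
    def n_cells(self) -> int:
        return self.df["cell_id"].nunique()

    @property
    def sites(self) -> list[GenomicSite]:
        sub = self.df.drop_duplicates(subset=["contig", "position"])
        return [GenomicSite(r.contig, int(r.position), r.ref) for r in sub.itertuples()]

    @property
    def coverage(self) -> pd.Series:
        """Per-record coverage = sum of the five allele counts."""
        return self.df[list(ALLELES)].sum(axis=1)

    def ref_at(self, contig: str, position: int) -> str:
        sub = self.df[(self.df["contig"] == contig) & (self.df["position"] == position)]
        if sub.empty:
            raise KeyError(f"no records at {contig}:{position}")
        refs = sub["ref"].unique()
        if len(refs) > 1:
            raise ValueError(f"reference conflict at {contig}:{position}: {sorted(refs)}")
        return refs[0]

    def site_counts(self, site: GenomicSite) -> pd.DataFrame:
        """Counts at one site, indexed by cell_id (covered cells only)."""
        sub = self.df[(self.df["contig"] == site.contig) & (self.df["position"] == site.position)]
        return sub.set_index("cell_id")[list(ALLELES)]

    def matrix(self, value: str, cells: Sequence[str] | None = None) -> pd.DataFrame:
        """Cells x sites matrix of one allele count or of total coverage.

        Cells without a record at a site get 0 (no reads).
        """
        df = self.df
        if value == "coverage":
            vals = self.coverage
        elif value in ALLELES:
            vals = df[value]
        else:
            raise ValueError(f"unknown value {value!r}")
        wide = pd.DataFrame(
            {"cell_id": df["cell_id"], "contig": df["contig"], "position": df["position"], "v": vals}
        ).pivot(index="cell_id", columns=["contig", "position"], values="v")
        if cells is None:
            cells = self.cells
        return wide.reindex(index=cells).fillna(0).astype(np.int64)

    # -------------------------------------------------------------------- io

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, individual_id: str | None = None) -> "AlleleCountTable":
        return read_count_table(path, individual_id=individual_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleCountTable):
            return NotImplemented
        return self.df.equals(other.df)

    def __repr__(self) -> str:
        return (
            f"AlleleCountTable(individual={self.individual_id!r}, "
            f"cells={self.n_cells}, records={len(self.df)})"
        )


def read_count_table(path: str | Path, individual_id: str | None = None) -> AlleleCountTable:
    """Load a count table from TSV; raises on malformed rows with the line number."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "contig": str, "ref": str})
    except Exception as exc:  # malformed file
        raise ValueError(f"parse error in {path}: {exc}") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"parse error in {path}: missing columns {missing}")
    for col in ("position",) + ALLELES:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            line = int(np.flatnonzero((bad | df[col].isna()).to_numpy())[0]) + 2  # +header +1-based
            raise ValueError(f"parse error in {path} at line {line}: bad value in column {col}")
        if col in ALLELES and (vals < 0).any():
            line = int(np.flatnonzero((vals < 0).to_numpy())[0]) + 2
            raise ValueError(f"invalid count in {path} at line {line}: negative {col}")
        df[col] = vals.astype(np.int64)
    if individual_id is None:
        individual_id = path.stem
    return AlleleCountTable(df, individual_id=individual_id)


def write_count_table(table: AlleleCountTable, path: str | Path) -> None:
    table.to_tsv(path)


# ---------------------------------------------------------------------------
# Counting from alignments


def _resolve_sites(
    reference, sites: Sequence[GenomicSite] | str
) -> list[GenomicSite]:
    """A whole-contig specification (a contig name) expands to every position."""
    if isinstance(sites, str):
        contig = sites
        if contig not in reference.references:
            raise ValueError(f"reference mismatch: contig {contig!r} absent from reference")
        seq = reference.fetch(contig).upper()
        return [
            GenomicSite(contig, i + 1, base)
            for i, base in enumerate(seq)
            if base in BASES
        ]
    out = []
    for s in sites:
        if s.contig not in reference.references:
            raise ValueError(f"reference mismatch: contig {s.contig!r} absent from reference")
        ref_base = reference.fetch(s.contig, s.position - 1, s.position).upper()
        if ref_base != s.ref_allele:
            raise ValueError(
                f"reference mismatch at {s.contig}:{s.position}: "
                f"expected {s.ref_allele}, reference has {ref_base}"
            )
        out.append(s)
    return out


def _pileup_counts(bam, site: GenomicSite, min_base_quality: int, min_mapping_quality: int):
    """Pooled-strand allele counts for one site from one alignment file handle."""
    counts = dict.fromkeys(ALLELES, 0)
    for column in bam.pileup(
        site.contig,
        site.position - 1,
        site.position,
        truncate=True,
        min_base_quality=min_base_quality,
        min_mapping_quality=min_mapping_quality,
        ignore_overlaps=False,
        stepper="samtools",
    ):
        for read in column.pileups:
            if read.is_refskip:
                continue
            if read.is_del:
                counts["DEL"] += 1
                continue
            base = read.alignment.query_sequence[read.query_position].upper()
            if base in BASES:
                counts[base] += 1
    return counts


def count_alleles_from_alignments(
    alignments: Mapping[str, str | Path] | Sequence[str | Path] | str | Path,
    reference: str | Path,
    sites: Sequence[GenomicSite] | str,
    min_base_quality: int = 20,
    min_mapping_quality: int = 20,
    barcode_tag: str | None = None,
    individual_id: str = "unknown",
) -> AlleleCountTable:
    """Build an :class:`AlleleCountTable` by pileup over indexed BAM files.

    Parameters
    ----------
    alignments
        Either a mapping ``cell_id -> BAM path``, a sequence of BAM paths
        (the file stem becomes the cell id), or — with ``barcode_tag`` set —
        a single BAM path whose reads carry the cell identity in a tag
        (e.g. ``"CB"``).
    reference
        FASTA covering all requested contigs (indexed or indexable).
    sites
        Explicit sites, or a contig name to count every position of that
        contig (the usual choice for the mitochondrial genome).

    Forward- and reverse-strand reads are pooled. Sites with zero covering
    reads in a cell produce no record (missing downstream).
    """
    import pysam

    ref = pysam.FastaFile(str(reference))
    try:
        resolved = _resolve_sites(ref, sites)
        if barcode_tag is not None:
            if isinstance(alignments, (Mapping,)) or (
                isinstance(alignments, Sequence) and not isinstance(alignments, (str, Path))
            ):
                raise ValueError("cell identity unresolved: barcode_tag requires a single BAM path")
            rows = _count_barcoded(alignments, barcode_tag, resolved, min_base_quality, min_mapping_quality)
        else:
            if isinstance(alignments, Mapping):
                per_cell = dict(alignments)
            else:
                per_cell = {Path(p).stem: p for p in alignments}
            rows = []
            for cell_id, bam_path in sorted(per_cell.items()):
                with pysam.AlignmentFile(str(bam_path), "rb") as bam:
                    if not bam.has_index():
                        raise ValueError(f"unindexed alignment input: {bam_path}")
                    for site in resolved:
                        counts = _pileup_counts(bam, site, min_base_quality, min_mapping_quality)
                        if sum(counts.values()) > 0:
                            rows.append((cell_id, site, counts))
    finally:
        ref.close()

    records = [
        {
            "cell_id": cell_id,
            "contig": site.contig,
            "position": site.position,
            "ref": site.ref_allele,
            **counts,
        }
        for cell_id, site, counts in rows
    ]
    df = pd.DataFrame(records, columns=list(COLUMNS))
    return AlleleCountTable(df, individual_id=individual_id)


def _count_barcoded(bam_path, tag: str, sites: Iterable[GenomicSite], min_bq: int, min_mq: int):
    """Per-cell counts from a single BAM with a cell-barcode tag."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if not bam.has_index():
            raise ValueError(f"unindexed alignment input: {bam_path}")
        for site in sites:
            per_cell: dict[str, dict[str, int]] = {}
            n_reads = 0
            n_tagged = 0
            for column in bam.pileup(
                site.contig,
                site.position - 1,
                site.position,
                truncate=True,
                min_base_quality=min_bq,
                min_mapping_quality=min_mq,
                ignore_overlaps=False,
                stepper="samtools",
            ):
                for read in column.pileups:
                    if read.is_refskip:
                        continue
                    n_reads += 1
                    aln = read.alignment
                    if not aln.has_tag(tag):
                        continue
                    n_tagged += 1
                    cell = str(aln.get_tag(tag))
                    counts = per_cell.setdefault(cell, dict.fromkeys(ALLELES, 0))
                    if read.is_del:
                        counts["DEL"] += 1
                    else:
                        base = aln.query_sequence[read.query_position].upper()
                        if base in BASES:
                            counts[base] += 1
            if n_reads > 0 and n_tagged == 0:
                raise ValueError(
                    f"cell identity unresolved: no read at {site.contig}:{site.position} "
                    f"carries tag {tag!r}"
                )
            for cell, counts in sorted(per_cell.items()):
                if sum(counts.values()) > 0:
                    rows.append((cell, site, counts))
    return rows
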