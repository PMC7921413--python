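"""Ternary observed-call matrix.

Selected variants are turned into a cells x variants matrix N with entries
mutant (1) when the variant allele frequency exceeds 5%, reference (0) when
it does not but the site is covered, and missing when the site has no reads
in that cell (allelic dropout). Supporting mutant/reference read counts are
kept alongside for quantitative displays. All downstream likelihood
computations operate on this matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import CandidateVariant
from .counts import ALLELES, AlleleCountTable, GenomicSite

logger = logging.getLogger(__name__)

#: Sentinel for a dropout (uncovered) entry in N.
MISSING = -1

VariantSpec = tuple[GenomicSite, str]


def _normalize_variants(variants: Iterable) -> list[VariantSpec]:
    out: list[VariantSpec] = []
    for v in variants:
        if isinstance(v, CandidateVariant):
            out.append((v.site, v.alt_allele))
        else:
            site, alt = v
            out.append((site, alt))
    for site, alt in out:
        if alt not in ALLELES or alt == site.ref_allele:
            raise ValueError(f"invalid alt {alt!r} for {site}")
    return out


@dataclass
class CallMatrix:
    """Ternary calls plus supporting counts for one individual's cells.

    ``N[c, g]`` is 0 (reference), 1 (mutant) or :data:`MISSING`. ``alt_reads``
    and ``ref_reads`` hold the reads supporting the variant and the reference
    allele; ``coverage`` the total reads over all five alleles (the VAF
    denominator).
    """

    N: np.ndarray
    alt_reads: np.ndarray
    ref_reads: np.ndarray
    coverage: np.ndarray
    cells: list[str]
    variants: list[str]
    variant_specs: list[VariantSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_c, n_g = self.N.shape
        if len(self.cells) != n_c or len(self.variants) != n_g:
            raise ValueError("matrix dimensions do not match cell/variant labels")
        bad = (self.N == MISSING) != (self.coverage == 0)
        if bad.any():
            raise ValueError("MISSING entries must coincide with zero coverage")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def missing_fraction(self) -> np.ndarray:
        """Per-variant fraction of cells with a dropout entry."""
        return (self.N == MISSING).mean(axis=0)

    def subset_cells(self, keep: Sequence[str]) -> "CallMatrix":
        idx = [self.cells.index(c) for c in keep]
        return CallMatrix(
            self.N[idx], self.alt_reads[idx], self.ref_reads[idx], self.coverage[idx],
            list(keep), list(self.variants), list(self.variant_specs),
        )

    # -------------------------------------------------------------------- io

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.N.astype(float), index=self.cells, columns=self.variants)
        df[self.N == MISSING] = np.nan
        df.to_csv(path, sep="\t", index_label="cell_id", na_rep="NA")

    def counts_to_tsv(self, path: str | Path) -> None:
        rows = []
        for i, cell in enumerate(self.cells):
            for j, var in enumerate(self.variants):
                rows.append(
                    (cell, var, int(self.alt_reads[i, j]), int(self.ref_reads[i, j]),
                     int(self.coverage[i, j]))
                )
        pd.DataFrame(
            rows, columns=["cell_id", "variant", "alt_reads", "ref_reads", "coverage"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, counts_path: str | Path | None = None) -> "CallMatrix":
        df = pd.read_csv(path, sep="\t", index_col="cell_id")
        N = df.to_numpy(dtype=float)
        out = np.where(np.isnan(N), MISSING, N).astype(np.int8)
        cells = [str(c) for c in df.index]
        variants = list(df.columns)
        alt = np.zeros_like(out, dtype=np.int64)
        ref = np.zeros_like(out, dtype=np.int64)
        cov = (out != MISSING).astype(np.int64)  # placeholder coverage if counts absent
        if counts_path is not None:
            cdf = pd.read_csv(counts_path, sep="\t")
            ci = {c: i for i, c in enumerate(cells)}
            vi = {v: j for j, v in enumerate(variants)}
            for r in cdf.itertuples():
                i, j = ci[str(r.cell_id)], vi[r.variant]
                alt[i, j], ref[i, j], cov[i, j] = r.alt_reads, r.ref_reads, r.coverage
        cov = np.where(out == MISSING, 0, cov)
        return cls(out, alt, ref, cov, cells, variants, [])


def select_covered_variants(
    table: AlleleCountTable,
    variants: Iterable,
    min_cell_fraction: float = 0.20,
) -> list[VariantSpec]:
    """Keep variants whose site is covered (>0 reads) in enough cells."""
    specs = _normalize_variants(variants)
    if not specs:
        raise ValueError("candidate list is empty")
    cov = table.matrix("coverage")
    n = table.n_cells
    kept = []
    for site, alt in specs:
        key = (site.contig, site.position)
        frac = (cov[key] > 0).sum() / n if key in cov.columns else 0.0
        if frac >= min_cell_fraction:
            kept.append((site, alt))
    if not kept:
        logger.warning("no variants pass the %.0f%% coverage filter", 100 * min_cell_fraction)
    return kept


def build_call_matrix(
    table: AlleleCountTable,
    variants: Iterable,
    vaf_cutoff: float = 0.05,
    min_coverage_for_call: int = 1,
) -> CallMatrix:
    """Ternary calls from allele counts.

    An entry is mutant when VAF > ``vaf_cutoff`` (strictly above; a VAF
    exactly at the cutoff is reference), reference when covered but at or
    below the cutoff, and missing when coverage is below
    ``min_coverage_for_call`` (default 1 read, i.e. missing means uncovered).
    The VAF denominator is total coverage over all alleles at the site.
    """
    specs = _normalize_variants(variants)
    cells = table.cells
    site_keys = {(s.contig, s.position) for s in table.sites}
    for site, alt in specs:
        if (site.contig, site.position) not in site_keys:
            raise ValueError(f"unknown variant: {site.label(alt)} not in count table")

    cov_m = table.matrix("coverage", cells=cells)
    allele_m = {a: table.matrix(a, cells=cells) for a in ALLELES}

    n_c, n_g = len(cells), len(specs)
    N = np.full((n_c, n_g), MISSING, dtype=np.int8)
    alt_reads = np.zeros((n_c, n_g), dtype=np.int64)
    ref_reads = np.zeros((n_c, n_g), dtype=np.int64)
    coverage = np.zeros((n_c, n_g), dtype=np.int64)

    for j, (site, alt) in enumerate(specs):
        key = (site.contig, site.position)
        cov = cov_m[key].to_numpy()
        a = allele_m[alt][key].to_numpy()
        r = allele_m[site.ref_allele][key].to_numpy()
        coverage[:, j] = cov
        alt_reads[:, j] = a
        ref_reads[:, j] = r
        covered = cov >= max(min_coverage_for_call, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            vaf = np.where(cov > 0, a / np.maximum(cov, 1), 0.0)
        N[covered & (vaf > vaf_cutoff), j] = 1
        N[covered & (vaf <= vaf_cutoff), j] = 0

    # treat sub-threshold coverage as uncovered so the MISSING invariant holds
    coverage = np.where(N == MISSING, 0, coverage)
    labels = [site.label(alt) for site, alt in specs]
    return CallMatrix(N, alt_reads, ref_reads, coverage, cells, labels, specs)
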