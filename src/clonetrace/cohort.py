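"""Cohort filtering of mitochondrial variants.

Somatic mitochondrial mutations are private to an individual, whereas RNA
editing creates apparent variants at the same sites in unrelated individuals.
This module implements the cohort filter that separates the two: a candidate
variant must be carried by at least 1% of an individual's cells while
appearing in no more than 10 cells of any other individual; a variant
recurrently mutant (>10 cells) in two or more individuals is recorded in a
cross-individual blacklist of presumed editing or artefact sites.

A cell counts as "mutant" at a (site, alt) pair when at least 10% of its
reads at the site support the alternative allele; sites enter the analysis
only when covered by at least five reads in at least 20 cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .counts import ALLELES, AlleleCountTable, GenomicSite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateVariant:
    """A putative somatic variant retained for one individual."""

    site: GenomicSite
    alt_allele: str
    individual_id: str
    n_mutant_cells: int
    fraction_mutant: float

    def __post_init__(self) -> None:
        if self.alt_allele == self.site.ref_allele:
            raise ValueError("alt_allele equals ref_allele")
        if not 0.0 <= self.fraction_mutant <= 1.0:
            raise ValueError("fraction_mutant outside [0, 1]")

    @property
    def label(self) -> str:
        return self.site.label(self.alt_allele)


class Blacklist:
    """Cross-individual excluded (site, alt) entries with provenance."""

    def __init__(self, provenance: Mapping[tuple[str, int, str], list[str]] | None = None):
        self.provenance: dict[tuple[str, int, str], list[str]] = {
            k: sorted(v) for k, v in (provenance or {}).items()
        }

    @property
    def entries(self) -> set[tuple[str, int, str]]:
        return set(self.provenance)

    def __contains__(self, entry: tuple[str, int, str]) -> bool:
        return entry in self.provenance

    def __len__(self) -> int:
        return len(self.provenance)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"contig": c, "position": p, "alt": a, "individuals": ",".join(inds)}
            for (c, p, a), inds in sorted(self.provenance.items())
        ]
        pd.DataFrame(rows, columns=["contig", "position", "alt", "individuals"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Blacklist":
        df = pd.read_csv(path, sep="\t", dtype={"contig": str, "alt": str, "individuals": str})
        prov = {
            (r.contig, int(r.position), r.alt): str(r.individuals).split(",")
            for r in df.itertuples()
        }
        return cls(prov)


def site_coverage_filter(
    tables: Mapping[str, AlleleCountTable] | AlleleCountTable,
    min_reads: int = 5,
    min_cells: int = 20,
) -> list[GenomicSite]:
    """Sites with coverage >= ``min_reads`` in >= ``min_cells`` cells.

    With a mapping of per-individual tables, a site qualifies if it passes
    the threshold within at least one individual (candidate discovery later
    re-checks the focal individual).
    """
    if isinstance(tables, AlleleCountTable):
        tables = {tables.individual_id: tables}
    passing: dict[tuple[str, int], GenomicSite] = {}
    for ind, table in tables.items():
        if len(table.df) == 0:
            logger.warning("empty count table for individual %s", ind)
            continue
        cov = table.coverage
        ok = table.df.loc[cov >= min_reads, ["contig", "position", "ref"]]
        counts = ok.groupby(["contig", "position", "ref"]).size()
        for (contig, position, ref), n in counts.items():
            if n >= min_cells:
                key = (contig, int(position))
                site = GenomicSite(contig, int(position), ref)
                if key in passing and passing[key].ref_allele != ref:
                    raise ValueError(f"reference conflict at {contig}:{position}")
                passing[key] = site
    return [passing[k] for k in sorted(passing)]


def call_mutant_cells(
    table: AlleleCountTable,
    site: GenomicSite,
    alt: str,
    min_vaf: float = 0.10,
) -> set[str]:
    """Cells whose reads at ``site`` support ``alt`` at a fraction >= ``min_vaf``."""
    if alt == site.ref_allele:
        raise ValueError(f"not a variant: alt {alt!r} equals reference at {site}")
    if alt not in ALLELES:
        raise ValueError(f"unknown allele {alt!r}")
    counts = table.site_counts(site)
    if counts.empty:
        return set()
    coverage = counts.sum(axis=1)
    vaf = counts[alt] / coverage.replace(0, np.nan)
    return set(counts.index[(coverage > 0) & (vaf >= min_vaf)])


def discover_cohort_variants(
    tables: Mapping[str, AlleleCountTable],
    min_reads: int = 5,
    min_cells: int = 20,
    min_cell_vaf: float = 0.10,
    min_fraction_in_patient: float = 0.01,
    max_cells_other: int = 10,
) -> tuple[dict[str, list[CandidateVariant]], Blacklist]:
    """Per-individual candidate somatic variants plus the cross-individual blacklist.

    For each (site, alt) pair at cohort-coverage-passing sites, cells are
    called mutant per :func:`call_mutant_cells`. The pair becomes a candidate
    for individual *i* when the site passes the coverage filter within *i*,
    mutant cells make up at least ``min_fraction_in_patient`` of *i*'s cells,
    and no other individual has more than ``max_cells_other`` mutant cells.
    Pairs mutant in more than ``max_cells_other`` cells in two or more
    individuals are blacklisted (and are candidates for no one).
    """
    if len(tables) < 2:
        logger.warning(
            "cohort has %d individual(s); blacklist requires >=2 and will be empty",
            len(tables),
        )

    per_individual_sites = {
        ind: {(s.contig, s.position): s for s in site_coverage_filter({ind: t}, min_reads, min_cells)}
        for ind, t in tables.items()
    }
    union_sites: dict[tuple[str, int], GenomicSite] = {}
    for sites in per_individual_sites.values():
        for key, site in sites.items():
            if key in union_sites and union_sites[key].ref_allele != site.ref_allele:
                raise ValueError(f"reference conflict at {key[0]}:{key[1]}")
            union_sites[key] = site

    n_cells = {ind: t.n_cells for ind, t in tables.items()}
    candidates: dict[str, list[CandidateVariant]] = {ind: [] for ind in tables}
    blacklist_prov: dict[tuple[str, int, str], list[str]] = {}

    for key in sorted(union_sites):
        site = union_sites[key]
        for alt in ALLELES:
            if alt == site.ref_allele:
                continue
            mutant = {
                ind: call_mutant_cells(t, site, alt, min_vaf=min_cell_vaf)
                for ind, t in tables.items()
            }
            heavy = sorted(ind for ind, cells in mutant.items() if len(cells) > max_cells_other)
            entry = (site.contig, site.position, alt)
            if len(heavy) >= 2:
                blacklist_prov[entry] = heavy
                continue
            for ind in tables:
                if key not in per_individual_sites[ind]:
                    continue
                m = len(mutant[ind])
                if n_cells[ind] == 0 or m < min_fraction_in_patient * n_cells[ind]:
                    continue
                if any(len(mutant[other]) > max_cells_other for other in tables if other != ind):
                    continue
                candidates[ind].append(
                    CandidateVariant(
                        site=site,
                        alt_allele=alt,
                        individual_id=ind,
                        n_mutant_cells=m,
                        fraction_mutant=m / n_cells[ind],
                    )
                )

    for ind in candidates:
        candidates[ind].sort(key=lambda v: (v.site.contig, v.site.position, v.alt_allele))
    return candidates, Blacklist(blacklist_prov)


def write_candidates(candidates: Mapping[str, list[CandidateVariant]], path: str | Path) -> None:
    rows = [
        {
            "individual": ind,
            "contig": v.site.contig,
            "position": v.site.position,
            "ref": v.site.ref_allele,
            "alt": v.alt_allele,
            "n_mutant_cells": v.n_mutant_cells,
            "fraction_mutant": v.fraction_mutant,
        }
        for ind in sorted(candidates)
        for v in candidates[ind]
    ]
    cols = ["individual", "contig", "position", "ref", "alt", "n_mutant_cells", "fraction_mutant"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
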