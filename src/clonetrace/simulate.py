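"""Seeded synthetic cohorts with planted clonal structure.

The generator emulates the data this package consumes: per-cell allele count
tables over mitochondrial-like sites, produced by a planted mutation tree.
Cells are drawn into clones by fixed proportions; per (cell, site) a coverage
is drawn from a negative-binomial model (expression-like overdispersion),
zeroed with a per-variant dropout probability, and alternative reads are
binomial at the cell's true variant allele frequency — a heteroplasmic
``mutant_vaf`` for carriers, a small ``error_vaf`` otherwise, with error
reads spread uniformly over the three non-reference bases. Somatic variants
are private to an individual (their positions differ between individuals);
RNA-editing-like sites are planted at identical positions with identical
levels in every individual, which is exactly the signature the cohort filter
blacklists.

Every draw is a pure function of (config, seed); truth files record the
planted clone of every cell, the clone genotypes and the variant classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .counts import BASES, COLUMNS, AlleleCountTable, GenomicSite
from .tree import ROOT

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Planted-cohort parameters.

    ``tree_spec`` maps variant name to parent variant (or ``"root"``);
    ``clone_fractions`` maps attachment node (variant name or ``"root"``)
    to the fraction of cells attached there and must sum to 1.
    """

    n_individuals: int = 1
    cells_per_individual: int = 200
    tree_spec: dict[str, str] = field(
        default_factory=lambda: {"v1": ROOT, "v2": "v1", "v3": "v2", "v4": "v1"}
    )
    clone_fractions: dict[str, float] = field(
        default_factory=lambda: {ROOT: 0.25, "v1": 0.15, "v3": 0.35, "v4": 0.25}
    )
    mutant_vaf: float | Mapping[str, float] = 0.9
    error_vaf: float = 0.005
    coverage_mean: float = 50.0
    coverage_dispersion: float = 2.0
    dropout_rate: float | Mapping[str, float] = 0.10
    dropout_tracks_coverage: bool = False
    n_shared_editing_sites: int = 0
    editing_vaf: float = 0.5
    contig: str = "mt"
    seed: int = 17

    def __post_init__(self) -> None:
        total = sum(self.clone_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"invalid clone fractions: sum to {total}, expected 1")
        for node in self.clone_fractions:
            if node != ROOT and node not in self.tree_spec:
                raise ValueError(f"clone fraction for unknown node {node!r}")
        for rates in (self.error_vaf, self.editing_vaf):
            if not 0 <= rates <= 1:
                raise ValueError("rates must lie in [0, 1]")

    def variant_value(self, mapping, variant: str) -> float:
        if isinstance(mapping, Mapping):
            return float(mapping[variant])
        return float(mapping)


@dataclass
class TruthSet:
    """Planted ground truth accompanying a simulated cohort."""

    clone_of_cell: dict[str, dict[str, str]]  # individual -> cell -> attachment node
    genotype_of_clone: dict[str, frozenset[str]]  # attachment node -> variant set
    variants: pd.DataFrame  # individual, label, contig, position, ref, alt, class
    true_vaf: pd.DataFrame  # individual, cell_id, contig, position, vaf

    def write(self, outdir: str | Path, prefix: str = "truth") -> None:
        outdir = Path(outdir)
        rows = [
            {"individual": ind, "cell_id": cell, "clone": node}
            for ind, cells in self.clone_of_cell.items()
            for cell, node in cells.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / f"{prefix}_cells.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"clone": node, "genotype": ";".join(sorted(geno))}
                for node, geno in self.genotype_of_clone.items()
            ]
        ).to_csv(outdir / f"{prefix}_clones.tsv", sep="\t", index=False)
        self.variants.to_csv(outdir / f"{prefix}_variants.tsv", sep="\t", index=False)
        self.true_vaf.to_csv(outdir / f"{prefix}_vaf.tsv", sep="\t", index=False)


def _genotypes(tree_spec: dict[str, str]) -> dict[str, frozenset[str]]:
    out = {ROOT: frozenset()}

    def geno(node: str) -> frozenset[str]:
        if node in out:
            return out[node]
        out[node] = geno(tree_spec[node]) | {node}
        return out[node]

    for v in tree_spec:
        geno(v)
    return out


def _nb_coverage(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative binomial with given mean and dispersion r (variance m + m^2/r)."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_cohort(config: SimulationConfig) -> tuple[dict[str, AlleleCountTable], TruthSet]:
    """Generate per-individual allele count tables and the planted truth."""
    rng = np.random.default_rng(config.seed)
    variants = sorted(config.tree_spec)
    genotypes = _genotypes(config.tree_spec)
    nodes = sorted(config.clone_fractions)
    fracs = np.array([config.clone_fractions[n] for n in nodes])

    # private somatic positions per individual; shared editing positions
    n_som = len(variants)
    editing_positions = [1000 + 10 * e for e in range(config.n_shared_editing_sites)]
    ref_rng = np.random.default_rng(config.seed + 1)
    editing_ref = [BASES[ref_rng.integers(0, 4)] for _ in editing_positions]
    editing_alt = [
        BASES[(BASES.index(r) + 1 + ref_rng.integers(0, 3)) % 4] for r in editing_ref
    ]

    tables: dict[str, AlleleCountTable] = {}
    clone_of_cell: dict[str, dict[str, str]] = {}
    var_rows = []
    vaf_rows = []

    for i in range(config.n_individuals):
        ind = f"I{i + 1}"
        positions = {v: 2000 + i * 1000 + 10 * j for j, v in enumerate(variants)}
        refs = {v: BASES[ref_rng.integers(0, 4)] for v in variants}
        alts = {
            v: BASES[(BASES.index(refs[v]) + 1 + ref_rng.integers(0, 3)) % 4]
            for v in variants
        }
        cells = [f"{ind}_c{j:04d}" for j in range(config.cells_per_individual)]
        attach = rng.choice(len(nodes), size=len(cells), p=fracs)
        clone_of_cell[ind] = {c: nodes[a] for c, a in zip(cells, attach)}

        sites = []
        for v in variants:
            sites.append((positions[v], refs[v], alts[v], "somatic_private", v))
            var_rows.append(
                {"individual": ind, "label": v, "contig": config.contig,
                 "position": positions[v], "ref": refs[v], "alt": alts[v],
                 "class": "somatic_private"}
            )
        for pos, r, a in zip(editing_positions, editing_ref, editing_alt):
            sites.append((pos, r, a, "editing_shared", None))
            var_rows.append(
                {"individual": ind, "label": f"edit{pos}", "contig": config.contig,
                 "position": pos, "ref": r, "alt": a, "class": "editing_shared"}
            )

        rows = []
        for pos, ref, alt, klass, vname in sites:
            n_cells = len(cells)
            # dropout is the only source of zero coverage: floor the NB draw at 1
            cov = np.maximum(
                _nb_coverage(rng, config.coverage_mean, config.coverage_dispersion, n_cells), 1
            )
            if klass == "somatic_private":
                drop = config.variant_value(config.dropout_rate, vname)
                dropped = rng.random(n_cells) < drop
                cov = np.where(dropped, 0, cov)
                carrier = np.array(
                    [vname in genotypes[nodes[a]] for a in attach]
                )
                vaf = np.where(
                    carrier, config.variant_value(config.mutant_vaf, vname), config.error_vaf
                )
            else:
                vaf = np.full(n_cells, config.editing_vaf)
                carrier = np.ones(n_cells, dtype=bool)
            alt_reads = rng.binomial(cov, vaf)
            other = np.array([b for b in BASES if b != ref])
            for c_idx, cell in enumerate(cells):
                if cov[c_idx] == 0:
                    continue
                counts = dict.fromkeys(("A", "C", "G", "T", "DEL"), 0)
                a_reads = int(alt_reads[c_idx])
                if carrier[c_idx]:
                    counts[alt] += a_reads
                else:
                    # sequencing errors land uniformly on the three non-reference bases
                    spread = rng.multinomial(a_reads, [1 / 3] * 3)
                    for b, s in zip(other, spread):
                        counts[b] += int(s)
                counts[ref] += int(cov[c_idx]) - a_reads
                rows.append(
                    {"cell_id": cell, "contig": config.contig, "position": pos,
                     "ref": ref, **counts}
                )
                vaf_rows.append(
                    {"individual": ind, "cell_id": cell, "contig": config.contig,
                     "position": pos, "vaf": float(vaf[c_idx])}
                )
        tables[ind] = AlleleCountTable(
            pd.DataFrame(rows, columns=list(COLUMNS)), individual_id=ind
        )

    truth = TruthSet(
        clone_of_cell=clone_of_cell,
        genotype_of_clone=genotypes,
        variants=pd.DataFrame(var_rows),
        true_vaf=pd.DataFrame(vaf_rows),
    )
    return tables, truth


# ---------------------------------------------------------------------------
# Single-site count simulation for the association scan


@dataclass
class SiteSimConfig:
    """Per-cell counts at one nuclear site with clone-specific true VAFs."""

    clone_sizes: dict[str, int] = field(default_factory=lambda: {"A": 40, "B": 30, "C": 30})
    vaf_by_clone: dict[str, float] = field(default_factory=lambda: {"A": 0.02, "B": 0.02, "C": 0.02})
    coverage_mean: float = 30.0
    coverage_dispersion: float = 4.0
    seed: int = 23


def simulate_site_counts(config: SiteSimConfig, seed: int | None = None):
    """Draw (alt_counts, coverages, clone labels) for one candidate site.

    Coverage is negative-binomial, floored at 1 read so every cell counts as
    covered; alternative reads are binomial at the clone's true VAF.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    labels = []
    cov_all = []
    alt_all = []
    for clone in sorted(config.clone_sizes):
        size = config.clone_sizes[clone]
        cov = np.maximum(
            _nb_coverage(rng, config.coverage_mean, config.coverage_dispersion, size), 1
        )
        alt = rng.binomial(cov, config.vaf_by_clone[clone])
        labels.extend([clone] * size)
        cov_all.append(cov)
        alt_all.append(alt)
    return np.concatenate(alt_all), np.concatenate(cov_all), labels


def standard_fixtures() -> dict[str, object]:
    """Named configurations exercising the full pipeline.

    - ``threeclones``: one individual, 200 cells, four variants — a chain
      v1 -> v2 -> v3 plus a branch v4 off v1 — in three clones ({v1},
      {v2, v3}, {v4}; no cells sit at the intermediate node v2, so v2/v3
      order is unidentifiable and they merge). Heteroplasmic mutant VAF 0.9,
      background error VAF 0.005, dropout 0.10.
    - ``cohort4``: four individuals with private two-variant chains plus
      three RNA-editing-like sites shared across all individuals, for
      blacklist construction.
    - ``h0site`` / ``h1site``: single-site count draws for calibrating the
      beta-binomial scan — homogeneous low VAF vs. one clone at VAF 0.45.
    """
    return {
        "threeclones": SimulationConfig(),
        "cohort4": SimulationConfig(
            n_individuals=4,
            cells_per_individual=120,
            tree_spec={"v1": ROOT, "v2": "v1"},
            clone_fractions={ROOT: 0.4, "v1": 0.3, "v2": 0.3},
            n_shared_editing_sites=3,
            editing_vaf=0.5,
            seed=29,
        ),
        "h0site": SiteSimConfig(
            clone_sizes={"A": 40, "B": 30, "C": 30},
            vaf_by_clone={"A": 0.02, "B": 0.02, "C": 0.02},
            seed=23,
        ),
        "h1site": SiteSimConfig(
            clone_sizes={"A": 40, "B": 30, "C": 30},
            vaf_by_clone={"A": 0.45, "B": 0.0, "C": 0.0},
            seed=31,
        ),
    }


def with_seed(config, seed: int):
    """A copy of a fixture config with a different seed."""
    return replace(config, seed=seed)
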