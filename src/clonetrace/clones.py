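"""Grouping tree nodes into clones and assigning cells to clones.

The maximum-likelihood tree imposes a total order on mutations within each
linear branch, but when few or no cells represent an intermediate state that
order is arbitrary and noise-driven. Mutations are therefore merged into
clones: within each maximal linear branch, adjacent nodes whose exchange
costs the likelihood little (average swap cost below a per-cell threshold,
default 1 log-likelihood unit per cell) are grouped together. Branch points
always delimit clones.

Cells are then assigned a posterior over clone genotypes (including an
always-present wildtype clone) under the same dropout/false-positive
likelihood, with a uniform prior. The posterior is summarized by the best
clone, its probability (the confidence used for the 0.8 quantitative-analysis
filter), and the Kullback-Leibler information relative to the uniform prior
in bits:  D_KL = sum_k p_k log2(p_k |C|).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .callmatrix import CallMatrix
from .tree import ROOT, ClonalTree, NoiseModel, _log_factor_arrays, tree_loglik

logger = logging.getLogger(__name__)


@dataclass
class CloneStructure:
    """An ordered partition of tree nodes into clones.

    Each clone is a contiguous segment of a linear branch, ordered root to
    leaf; ``clone_genotype`` is the full root-path genotype of the clone's
    deepest node (the variants a cell of that clone carries).
    """

    clones: list[list[str]]
    clone_genotype: list[frozenset[str]] = field(default_factory=list)
    clone_of_variant: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.clone_of_variant:
            self.clone_of_variant = {
                v: i for i, clone in enumerate(self.clones) for v in clone
            }

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"variant": v, "clone": i, "clone_genotype": ";".join(sorted(self.clone_genotype[i]))}
            for i, clone in enumerate(self.clones)
            for v in clone
        ]
        pd.DataFrame(rows, columns=["variant", "clone", "clone_genotype"]).to_csv(
            path, sep="\t", index=False
        )


def split_linear_branches(tree: ClonalTree) -> list[list[str]]:
    """Maximal chains of single-child nodes; branch points and leaves delimit.

    Every variant belongs to exactly one chain. Chains are ordered root to
    leaf and listed in deterministic (depth, label) order of their heads.
    """
    children = tree.children()
    chains: list[list[str]] = []
    heads = [
        v for v in tree.parent
        if tree.parent[v] == ROOT or len(children[tree.parent[v]]) != 1
    ]
    for head in sorted(heads, key=lambda v: (len(tree.genotype(v)), v)):
        chain = [head]
        cur = head
        while len(children[cur]) == 1:
            cur = children[cur][0]
            chain.append(cur)
        chains.append(chain)
    return chains


def _swap_parent_map(parent: dict[str, str], a: str, b: str) -> dict[str, str]:
    """Topology with variants ``a`` and ``b`` exchanging positions."""
    swap = {a: b, b: a}
    return {swap.get(v, v): swap.get(p, p) for v, p in parent.items()}


def swap_cost(
    tree: ClonalTree,
    chain: list[str],
    i: int,
    j: int,
    matrix: CallMatrix,
    model: NoiseModel,
) -> float:
    """Per-cell log-likelihood lost by exchanging chain positions ``i`` and ``j``.

    Cells are re-attached optimally under the swapped topology; for the
    maximum-likelihood tree the cost is non-negative.
    """
    if chain[i] not in tree.parent or chain[j] not in tree.parent:
        raise ValueError("cross-branch swap undefined: node not in tree")
    if i == j:
        return 0.0
    ll_orig, _ = tree_loglik(tree.parent, matrix, model)
    swapped = _swap_parent_map(tree.parent, chain[i], chain[j])
    ll_swap, _ = tree_loglik(swapped, matrix, model)
    return (ll_orig - ll_swap) / matrix.n_cells


def cluster_metaclones(
    tree: ClonalTree,
    matrix: CallMatrix,
    model: NoiseModel,
    threshold_per_cell: float = 1.0,
) -> CloneStructure:
    """Greedy root-to-leaf merging of chain nodes into clones.

    Within each linear branch, the next node joins the current clone while
    the average pairwise swap cost among the candidate clone's members stays
    below ``threshold_per_cell``; otherwise it starts a new clone. The
    threshold is an interpretability cutoff, not a statistical test.
    """
    chains = split_linear_branches(tree)
    clones: list[list[str]] = []
    for chain in chains:
        # pairwise costs within the chain, computed once
        cost = {}
        for a in range(len(chain)):
            for b in range(a + 1, len(chain)):
                cost[(a, b)] = swap_cost(tree, chain, a, b, matrix, model)
        current = [0]
        for nxt in range(1, len(chain)):
            members = current + [nxt]
            pair_costs = [cost[(a, b)] for a in members for b in members if a < b]
            if float(np.mean(pair_costs)) < threshold_per_cell:
                current.append(nxt)
            else:
                clones.append([chain[a] for a in current])
                current = [nxt]
        clones.append([chain[a] for a in current])
    genotypes = [tree.genotype(clone[-1]) for clone in clones]
    return CloneStructure(clones=clones, clone_genotype=genotypes)


def clone_level_key(tree: ClonalTree, clones: CloneStructure):
    """Canonical clone-level form of a tree: the set of (clone, parent-clone)
    edges with clones as variant sets. Two trees that differ only in node
    order within clones share the same key."""
    member = {v: frozenset(clone) for clone in clones.clones for v in clone}
    edges = set()
    for clone in clones.clones:
        head = clone[0]
        p = tree.parent[head]
        parent_clone = frozenset() if p == ROOT else member[p]
        edges.add((frozenset(clone), parent_clone))
    return frozenset(edges)


# ---------------------------------------------------------------------------
# Cell assignment


@dataclass
class CloneAssignment:
    """Per-cell posterior over clones (clone 0 is always wildtype)."""

    posterior: np.ndarray
    clone_labels: list[str]
    clone_genotypes: list[frozenset[str]]
    cells: list[str]
    best_clone: list[str]
    confidence: np.ndarray
    kl_bits: np.ndarray
    assigned: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": self.cells,
                "best_clone": self.best_clone,
                "confidence": self.confidence,
                "kl_bits": self.kl_bits,
                "assigned": self.assigned,
            }
        )
        for k, label in enumerate(self.clone_labels):
            df[f"p_{label}"] = self.posterior[:, k]
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def kl_information(posterior: np.ndarray, n_clones: int | None = None) -> float:
    """Bits of information in one cell's clone posterior relative to the
    uniform prior: sum_k p_k log2(p_k |C|), with 0 log 0 = 0."""
    p = np.asarray(posterior, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"unnormalized posterior: sums to {p.sum()!r}")
    k = n_clones if n_clones is not None else p.size
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] * k)))


def assign_cells(
    matrix: CallMatrix,
    clones: CloneStructure,
    model: NoiseModel,
    min_confidence: float = 0.8,
) -> CloneAssignment:
    """Posterior clone membership for every cell under a uniform prior.

    A wildtype clone (empty genotype) is always prepended. ``assigned`` marks
    cells whose best-clone probability reaches ``min_confidence`` (default
    0.8); only those cells should enter quantitative per-clone analyses.
    """
    genotypes = [frozenset()] + list(clones.clone_genotype)
    labels = ["wildtype"] + [
        "+".join(clone) if clone else f"clone{i}" for i, clone in enumerate(clones.clones)
    ]
    base, delta = _log_factor_arrays(matrix, model)
    vi = {v: j for j, v in enumerate(matrix.variants)}
    G = np.zeros((len(genotypes), matrix.n_variants))
    for i, geno in enumerate(genotypes):
        for v in geno:
            G[i, vi[v]] = 1.0
    ll = base[:, None] + delta @ G.T  # cells x clones
    log_post = ll - logsumexp(ll, axis=1, keepdims=True)
    posterior = np.exp(log_post)
    posterior /= posterior.sum(axis=1, keepdims=True)
    best_idx = np.argmax(posterior, axis=1)
    confidence = posterior[np.arange(len(best_idx)), best_idx]
    kl = np.array([kl_information(row) for row in posterior])
    assigned = confidence >= min_confidence
    return CloneAssignment(
        posterior=posterior,
        clone_labels=labels,
        clone_genotypes=genotypes,
        cells=list(matrix.cells),
        best_clone=[labels[i] for i in best_idx],
        confidence=confidence,
        kl_bits=kl,
        assigned=assigned,
    )
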