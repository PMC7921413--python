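"""Maximum-likelihood clonal mutation trees under a dropout/false-positive model.

The clonal history of a sample is modelled as a rooted mutation tree: each
node is a variant, the root is the unmutated (wildtype) state, and a clone's
genotype is the set of variants on its root path. Each cell attaches to the
node whose genotype best explains its observed ternary calls. Observations
are noisy: a truly mutant site may be observed as reference through allelic
dropout (rate alpha), and a truly reference site may be observed as mutant
with a false-positive rate beta. The per-entry likelihood factor is

    alpha                  if M = 1 and N = 0      (dropout)
    beta                   if M = 0 and N = 1      (false positive)
    1                      if N is missing
    (1 - alpha)(1 - beta)  otherwise               (concordant)

where M is the model genotype and N the observed call. The two concordant
cases share the same factor and no renormalization is applied. The total
tree likelihood is the product over cells of the factor at each cell's best
attachment.

Small trees are optimized by exhaustive enumeration of all (k+1)^(k-1)
rooted labelled mutation trees; larger ones by seeded steepest-ascent
hill-climbing over subtree-regraft moves with random restarts. A robustness
procedure re-infers the tree under Latin-hypercube-sampled perturbations of
the per-variant dropout rates and reports how many runs agree at clone level.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .callmatrix import MISSING, CallMatrix

logger = logging.getLogger(__name__)

#: Label of the wildtype root node.
ROOT = "root"


@dataclass
class NoiseModel:
    """Allelic dropout rate(s) alpha and false-positive rate beta.

    ``alpha`` may be a scalar (shared across variants) or a per-variant
    vector aligned with the call matrix's variant order.
    """

    alpha: float | np.ndarray = 0.10
    beta: float = 0.03

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if not np.all((a > 0) & (a < 1)):
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie in (0, 1)")

    def alpha_vector(self, n_variants: int) -> np.ndarray:
        a = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if a.size == 1:
            return np.full(n_variants, float(a[0]))
        if a.size != n_variants:
            raise ValueError(f"alpha vector length {a.size} != {n_variants} variants")
        return a.astype(float)


@dataclass
class ClonalTree:
    """A rooted mutation tree with per-cell attachments.

    ``parent`` maps each variant label to its parent variant (or :data:`ROOT`).
    """

    parent: dict[str, str]
    cell_attachment: dict[str, str]
    log_likelihood: float
    variants: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.variants:
            self.variants = sorted(self.parent)
        _validate_topology(self.parent)

    def children(self) -> dict[str, list[str]]:
        ch: dict[str, list[str]] = {ROOT: []}
        for v in self.parent:
            ch.setdefault(v, [])
        for v, p in sorted(self.parent.items()):
            ch[p].append(v)
        return ch

    def genotype(self, node: str) -> frozenset[str]:
        """Variants on the root path down to ``node`` (inclusive)."""
        if node == ROOT:
            return frozenset()
        out = []
        while node != ROOT:
            out.append(node)
            node = self.parent[node]
        return frozenset(out)

    def newick(self) -> str:
        ch = self.children()

        def fmt(node: str) -> str:
            kids = ch.get(node, [])
            inner = ",".join(fmt(k) for k in kids)
            name = node.replace(",", "_").replace("(", "_").replace(")", "_")
            return f"({inner}){name}" if kids else name

        return fmt(ROOT) + ";"

    def to_dict(self) -> dict:
        return {
            "variants": self.variants,
            "parent": dict(self.parent),
            "cell_attachment": dict(self.cell_attachment),
            "log_likelihood": self.log_likelihood,
            "newick": self.newick(),
        }


def _validate_topology(parent: dict[str, str]) -> None:
    for v, p in parent.items():
        if p != ROOT and p not in parent:
            raise ValueError(f"parent {p!r} of {v!r} is not a node")
        seen = {v}
        node = v
        while node != ROOT:
            node = parent[node]
            if node in seen:
                raise ValueError("parent map contains a cycle")
            seen.add(node)


# ---------------------------------------------------------------------------
# Likelihood


def cell_node_loglik(
    calls: np.ndarray,
    genotype: frozenset[str] | set[str],
    model: NoiseModel,
    variants: list[str],
) -> float:
    """Log-likelihood of one cell's calls given a node genotype.

    ``calls`` is the cell's row of N over ``variants`` (0/1/:data:`MISSING`);
    missing entries contribute a factor of 1.
    """
    alpha = model.alpha_vector(len(variants))
    beta = model.beta
    total = 0.0
    for g, v in enumerate(variants):
        n = calls[g]
        if n == MISSING:
            continue
        m = 1 if v in genotype else 0
        if m == 1 and n == 0:
            total += np.log(alpha[g])
        elif m == 0 and n == 1:
            total += np.log(beta)
        else:
            total += np.log((1 - alpha[g]) * (1 - beta))
    return float(total)


def _log_factor_arrays(matrix: CallMatrix, model: NoiseModel):
    """Per-cell base log-likelihood (all-reference genotype) and per-variant
    increments for flipping a variant to mutant.

    Returns ``(base, delta)`` with ``base`` shape (cells,) and ``delta``
    shape (cells, variants); the log-likelihood of a cell at a node with
    genotype G is ``base[c] + sum_{g in G} delta[c, g]``.
    """
    N = matrix.N
    alpha = model.alpha_vector(matrix.n_variants)[None, :]
    beta = model.beta
    log_conc = np.log((1 - alpha) * (1 - beta))
    logf0 = np.where(N == 1, np.log(beta), log_conc)
    logf1 = np.where(N == 0, np.log(alpha), log_conc)
    logf0 = np.where(N == MISSING, 0.0, logf0)
    logf1 = np.where(N == MISSING, 0.0, logf1)
    return logf0.sum(axis=1), (logf1 - logf0)


def _node_order(parent: dict[str, str]) -> list[str]:
    """Attachment nodes sorted for tie-breaking: root first, then by genotype
    size, then lexicographically."""
    depth: dict[str, int] = {ROOT: 0}

    def d(v: str) -> int:
        if v not in depth:
            depth[v] = 1 + d(parent[v])
        return depth[v]

    return [ROOT] + sorted(parent, key=lambda v: (d(v), v))


def _genotype_indicator(parent: dict[str, str], variants: list[str], nodes: list[str]) -> np.ndarray:
    vi = {v: j for j, v in enumerate(variants)}
    G = np.zeros((len(nodes), len(variants)))
    for i, node in enumerate(nodes):
        v = node
        while v != ROOT:
            G[i, vi[v]] = 1.0
            v = parent[v]
    return G


def tree_loglik(
    parent: dict[str, str],
    matrix: CallMatrix,
    model: NoiseModel,
) -> tuple[float, dict[str, str]]:
    """Total log-likelihood of a topology with optimal per-cell attachments.

    Each cell attaches to the node maximizing its own log-likelihood; ties
    go to the node nearest the root, then to the lexicographically smaller
    label. Raises if the matrix contains a variant absent from the topology.
    """
    missing = [v for v in matrix.variants if v not in parent]
    if missing:
        raise ValueError(f"topology incomplete: variants {missing} not in parent map")
    _validate_topology(parent)
    base, delta = _log_factor_arrays(matrix, model)
    nodes = _node_order(parent)
    G = _genotype_indicator(parent, matrix.variants, nodes)
    ll = base[:, None] + delta @ G.T  # cells x nodes
    best = np.argmax(ll, axis=1)  # first max wins -> tie-break by node order
    total = float(ll[np.arange(len(best)), best].sum())
    attachment = {cell: nodes[b] for cell, b in zip(matrix.cells, best)}
    return total, attachment


# ---------------------------------------------------------------------------
# Search


def enumerate_topologies(variants: list[str]):
    """All rooted mutation trees on ``variants`` — (k+1)^(k-1) of them —
    via Prüfer sequences on k+1 labelled nodes rooted at the wildtype."""
    k = len(variants)
    labels = [ROOT] + list(variants)
    if k == 1:
        yield {variants[0]: ROOT}
        return
    n = k + 1
    for seq in itertools.product(range(n), repeat=n - 2):
        yield _prufer_to_parent(seq, labels)


def _prufer_to_parent(seq, labels) -> dict[str, str]:
    import heapq

    n = len(labels)
    degree = [1] * n
    for s in seq:
        degree[s] += 1
    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    edges = []
    for s in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, s))
        degree[leaf] -= 1
        degree[s] -= 1
        if degree[s] == 1:
            heapq.heappush(leaves, s)
    u, v = [i for i in range(n) if degree[i] == 1]
    edges.append((u, v))
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    parent: dict[str, str] = {}
    stack = [0]
    seen = {0}
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                parent[labels[nb]] = labels[node]
                stack.append(nb)
    return parent


def _canonical_key(parent: dict[str, str]) -> tuple:
    return tuple(sorted(parent.items()))


def infer_tree(
    matrix: CallMatrix,
    model: NoiseModel,
    max_exhaustive: int = 7,
    n_restarts: int = 20,
    seed: int = 0,
) -> ClonalTree:
    """Maximum-likelihood mutation tree.

    Up to ``max_exhaustive`` variants the global optimum is found by full
    enumeration; beyond that, seeded steepest-ascent hill-climbing over
    parent-reassignment (subtree regraft) moves with ``n_restarts`` random
    restarts. Deterministic given the seed. Likelihood ties are broken by
    the canonical (sorted parent map) ordering.
    """
    k = matrix.n_variants
    if k == 0:
        raise ValueError("no variants to place")
    if k <= max_exhaustive:
        best = None
        for parent in enumerate_topologies(list(matrix.variants)):
            ll, _ = tree_loglik(parent, matrix, model)
            key = (-ll, _canonical_key(parent))
            if best is None or key < best[0]:
                best = (key, parent)
        parent = best[1]
    else:
        parent = _hill_climb(matrix, model, n_restarts, seed)
    ll, attachment = tree_loglik(parent, matrix, model)
    return ClonalTree(parent, attachment, ll, list(matrix.variants))


def _random_parent_map(variants: list[str], rng: np.random.Generator) -> dict[str, str]:
    k = len(variants)
    if k == 1:
        return {variants[0]: ROOT}
    seq = rng.integers(0, k + 1, size=k - 1)
    return _prufer_to_parent(tuple(int(s) for s in seq), [ROOT] + list(variants))


def _descendants(parent: dict[str, str], node: str) -> set[str]:
    out = set()
    for v in parent:
        p = v
        while p != ROOT:
            if p == node:
                out.add(v)
                break
            p = parent[p]
    return out


def _hill_climb(matrix: CallMatrix, model: NoiseModel, n_restarts: int, seed: int) -> dict[str, str]:
    rng = np.random.default_rng(seed)
    variants = list(matrix.variants)
    best_overall = None
    for _ in range(max(1, n_restarts)):
        parent = _random_parent_map(variants, rng)
        ll, _ = tree_loglik(parent, matrix, model)
        improved = True
        while improved:
            improved = False
            best_move = None
            for v in variants:
                forbidden = _descendants(parent, v) | {v, parent[v]}
                for p in [ROOT] + variants:
                    if p in forbidden:
                        continue
                    cand = dict(parent)
                    cand[v] = p
                    cll, _ = tree_loglik(cand, matrix, model)
                    key = (-cll, _canonical_key(cand))
                    if best_move is None or key < best_move[0]:
                        best_move = (key, cand, cll)
            if best_move is not None and best_move[2] > ll + 1e-12:
                parent, ll = best_move[1], best_move[2]
                improved = True
        key = (-ll, _canonical_key(parent))
        if best_overall is None or key < best_overall[0]:
            best_overall = (key, parent)
    return best_overall[1]


# ---------------------------------------------------------------------------
# Dropout estimation and robustness


def estimate_dropout_per_variant(matrix: CallMatrix) -> np.ndarray:
    """Per-variant dropout rate from the fraction of complete dropouts,
    clamped to (0.01, 0.99)."""
    if matrix.n_cells == 0:
        raise ValueError("empty call matrix")
    frac = matrix.missing_fraction()
    if np.any(frac >= 1.0):
        logger.warning("variant with 100%% dropout; it should have been filtered earlier")
    return np.clip(frac, 0.01, 0.99)


@dataclass
class RobustnessResult:
    """Per-run trees and clone-level agreement of the perturbation procedure."""

    trees: list[ClonalTree]
    clone_keys: list
    modal_key: object
    n_agreeing_runs: int
    alphas: np.ndarray


def latin_hypercube_beta(
    means: np.ndarray, concentration: float, n_runs: int, rng: np.random.Generator
) -> np.ndarray:
    """Stratified (Latin hypercube) draws from Beta distributions.

    Each variant g gets one draw per run from Beta(m_g c, (1 - m_g) c) —
    mean m_g, concentration c — with the unit interval stratified into
    ``n_runs`` equal bins covered exactly once per variant.
    """
    if concentration <= 0:
        raise ValueError("invalid concentration: must be > 0")
    means = np.asarray(means, dtype=float)
    out = np.empty((n_runs, means.size))
    for g, m in enumerate(means):
        perm = rng.permutation(n_runs)
        u = (perm + rng.random(n_runs)) / n_runs
        out[:, g] = stats.beta.ppf(u, m * concentration, (1 - m) * concentration)
    return np.clip(out, 1e-6, 1 - 1e-6)


def robustness_analysis(
    matrix: CallMatrix,
    alpha_means: np.ndarray,
    beta: float = 0.03,
    concentration: float = 10.0,
    n_runs: int = 80,
    seed: int = 0,
    max_exhaustive: int = 7,
    n_restarts: int = 20,
    clone_threshold_per_cell: float = 1.0,
) -> RobustnessResult:
    """Re-infer the tree under perturbed dropout rates; count agreeing runs.

    Per-variant dropout rates are Latin-hypercube sampled around
    ``alpha_means``; the tree is re-inferred per draw and topologies are
    compared at the clone level (within-clone node order ignored, since
    node order inside a clone is by construction not supported by the data).
    """
    from .clones import clone_level_key, cluster_metaclones

    rng = np.random.default_rng(seed)
    alphas = latin_hypercube_beta(np.asarray(alpha_means, float), concentration, n_runs, rng)
    trees: list[ClonalTree] = []
    keys = []
    for r in range(n_runs):
        model = NoiseModel(alpha=alphas[r], beta=beta)
        tree = infer_tree(
            matrix, model, max_exhaustive=max_exhaustive,
            n_restarts=n_restarts, seed=int(rng.integers(0, 2**31 - 1)),
        )
        clones = cluster_metaclones(tree, matrix, model, threshold_per_cell=clone_threshold_per_cell)
        trees.append(tree)
        keys.append(clone_level_key(tree, clones))
    counts: dict = {}
    for key in keys:
        counts[key] = counts.get(key, 0) + 1
    modal_key = max(counts, key=lambda k: (counts[k], str(k)))
    return RobustnessResult(trees, keys, modal_key, counts[modal_key], alphas)
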