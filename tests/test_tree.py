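"""Tree likelihood and search: closed forms, brute-force oracles, recovery."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

import clonetrace as ct
from clonetrace.callmatrix import MISSING, CallMatrix
from clonetrace.tree import ROOT, enumerate_topologies, latin_hypercube_beta

# ---------------------------------------------------------------------------
# Independent oracles (pure-python, no shared code with the implementation)


def oracle_cell_loglik(calls, genotype, variants, alpha, beta):
    total = 0.0
    for g, v in enumerate(variants):
        n = calls[g]
        a = alpha[g] if np.ndim(alpha) else alpha
        if n == MISSING:
            continue
        m = 1 if v in genotype else 0
        if m == 1 and n == 0:
            total += math.log(a)
        elif m == 0 and n == 1:
            total += math.log(beta)
        else:
            total += math.log((1 - a) * (1 - beta))
    return total


def oracle_genotypes(parent):
    out = {ROOT: frozenset()}

    def geno(v):
        if v not in out:
            out[v] = geno(parent[v]) | {v}
        return out[v]

    for v in parent:
        geno(v)
    return out


def oracle_tree_loglik(parent, matrix, alpha, beta):
    """Enumerate every attachment of every cell; sum the per-cell maxima."""
    genos = oracle_genotypes(parent)
    total = 0.0
    for i in range(matrix.n_cells):
        best = -math.inf
        for node, geno in genos.items():
            ll = oracle_cell_loglik(matrix.N[i], geno, matrix.variants, alpha, beta)
            best = max(best, ll)
        total += best
    return total


def oracle_all_parent_maps(variants):
    """All acyclic parent maps: each variant's parent in {root} + others."""
    options = [ [ROOT] + [u for u in variants if u != v] for v in variants ]
    for combo in itertools.product(*options):
        parent = dict(zip(variants, combo))
        # acyclicity
        ok = True
        for v in variants:
            seen = set()
            node = v
            while node != ROOT:
                if node in seen:
                    ok = False
                    break
                seen.add(node)
                node = parent[node]
            if not ok:
                break
        if ok:
            yield parent


def random_matrix(rng, n_cells, variants, missing_p=0.15):
    N = rng.integers(0, 2, size=(n_cells, len(variants))).astype(np.int8)
    N[rng.random(N.shape) < missing_p] = MISSING
    cov = np.where(N == MISSING, 0, 10).astype(np.int64)
    alt = np.where(N == 1, 9, 0).astype(np.int64)
    return CallMatrix(N, alt, cov - alt, cov, [f"c{i}" for i in range(n_cells)],
                      list(variants), [])


# ---------------------------------------------------------------------------
# Closed-form factors


class TestCellNodeLoglik:
    def test_dropout_factor(self):
        model = ct.NoiseModel(alpha=0.10, beta=0.03)
        ll = ct.cell_node_loglik(np.array([0]), {"v"}, model, ["v"])
        assert ll == pytest.approx(math.log(0.10))

    def test_all_missing_is_zero(self):
        model = ct.NoiseModel()
        calls = np.array([MISSING, MISSING, MISSING])
        assert ct.cell_node_loglik(calls, {"a", "c"}, model, ["a", "b", "c"]) == 0.0

    def test_mixed_concordant_and_false_positive(self):
        model = ct.NoiseModel(alpha=0.10, beta=0.03)
        ll = ct.cell_node_loglik(np.array([1, 1]), {"a"}, model, ["a", "b"])
        assert ll == pytest.approx(math.log(0.9 * 0.97) + math.log(0.03))

    def test_false_negative_uses_per_variant_alpha(self):
        model = ct.NoiseModel(alpha=np.array([0.2, 0.4]), beta=0.03)
        ll = ct.cell_node_loglik(np.array([0, 0]), {"a", "b"}, model, ["a", "b"])
        assert ll == pytest.approx(math.log(0.2) + math.log(0.4))


class TestTreeLoglik:
    def test_star_single_variant_closed_form(self):
        """All cells mutant at one variant -> n * log((1-a)(1-b))."""
        n = 30
        N = np.ones((n, 1), dtype=np.int8)
        cov = np.full((n, 1), 10, dtype=np.int64)
        m = CallMatrix(N, cov - 1, np.ones_like(cov), cov, [f"c{i}" for i in range(n)], ["v"], [])
        model = ct.NoiseModel(alpha=0.10, beta=0.03)
        ll, attach = ct.tree_loglik({"v": ROOT}, m, model)
        assert ll == pytest.approx(n * math.log(0.9 * 0.97))
        assert all(node == "v" for node in attach.values())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_attachment_oracle(self, seed):
        """<=5 variants, <=50 cells: equals brute-force attachment enumeration."""
        rng = np.random.default_rng(seed)
        variants = ["a", "b", "c", "d", "e"][: 3 + seed % 3]
        m = random_matrix(rng, 50, variants)
        parent = next(iter(oracle_all_parent_maps(variants)))
        model = ct.NoiseModel(alpha=0.10, beta=0.03)
        ll, _ = ct.tree_loglik(parent, m, model)
        expected = oracle_tree_loglik(parent, m, 0.10, 0.03)
        assert ll == pytest.approx(expected, rel=1e-9)

    def test_invariant_to_cell_order(self):
        rng = np.random.default_rng(7)
        m = random_matrix(rng, 20, ["a", "b", "c"])
        perm = rng.permutation(20)
        m2 = CallMatrix(m.N[perm], m.alt_reads[perm], m.ref_reads[perm],
                        m.coverage[perm], [m.cells[i] for i in perm], m.variants, [])
        parent = {"a": ROOT, "b": "a", "c": "b"}
        model = ct.NoiseModel()
        assert ct.tree_loglik(parent, m, model)[0] == pytest.approx(
            ct.tree_loglik(parent, m2, model)[0]
        )

    def test_incomplete_topology_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="topology incomplete"):
            ct.tree_loglik({"vA": ROOT}, tiny_matrix, ct.NoiseModel())


# ---------------------------------------------------------------------------
# Topology enumeration and search


class TestEnumeration:
    @pytest.mark.parametrize("k,count", [(1, 1), (2, 3), (3, 16), (4, 125)])
    def test_cayley_count(self, k, count):
        variants = [f"v{i}" for i in range(k)]
        tops = list(enumerate_topologies(variants))
        assert len(tops) == count == (k + 1) ** (k - 1)
        keys = {tuple(sorted(t.items())) for t in tops}
        assert len(keys) == count  # all distinct
        # agrees with the independent acyclic-parent-map enumeration
        oracle = {tuple(sorted(t.items())) for t in oracle_all_parent_maps(variants)}
        assert keys == oracle


def matrix_from_genotypes(genotypes, variants, cells_per=20):
    rows = []
    for geno in genotypes:
        row = [1 if v in geno else 0 for v in variants]
        rows.extend([row] * cells_per)
    N = np.array(rows, dtype=np.int8)
    cov = np.full(N.shape, 10, dtype=np.int64)
    alt = np.where(N == 1, 9, 0).astype(np.int64)
    return CallMatrix(N, alt, cov - alt, cov,
                      [f"c{i}" for i in range(N.shape[0])], list(variants), [])


class TestInferTree:
    def test_recovers_planted_chain(self):
        """Noise-free linear accumulation a -> b -> c; brute force confirms."""
        m = matrix_from_genotypes(
            [set(), {"a"}, {"a", "b"}, {"a", "b", "c"}], ["a", "b", "c"]
        )
        model = ct.NoiseModel(alpha=0.10, beta=0.03)
        tree = ct.infer_tree(m, model)
        assert tree.parent == {"a": ROOT, "b": "a", "c": "b"}
        best_oracle = max(
            oracle_tree_loglik(p, m, 0.10, 0.03) for p in oracle_all_parent_maps(["a", "b", "c"])
        )
        assert tree.log_likelihood == pytest.approx(best_oracle, rel=1e-9)

    def test_recovers_planted_branching(self):
        """Two variants on separate branches must not be chained."""
        m = matrix_from_genotypes([set(), {"a"}, {"b"}], ["a", "b"])
        tree = ct.infer_tree(m, ct.NoiseModel())
        assert tree.parent == {"a": ROOT, "b": ROOT}

    def test_planted_tree_is_global_optimum_noise_free(self):
        """For k<=5 the planted topology maximizes over all enumerated trees."""
        variants = ["a", "b", "c", "d"]
        m = matrix_from_genotypes(
            [set(), {"a"}, {"a", "b"}, {"a", "b", "c"}, {"a", "d"}], variants
        )
        planted = {"a": ROOT, "b": "a", "c": "b", "d": "a"}
        lls = {
            tuple(sorted(p.items())): oracle_tree_loglik(p, m, 0.10, 0.03)
            for p in oracle_all_parent_maps(variants)
        }
        assert max(lls, key=lls.get) == tuple(sorted(planted.items()))
        tree = ct.infer_tree(m, ct.NoiseModel())
        assert tree.parent == planted

    def test_attachments_equal_planted_memberships_noise_free(self):
        m = matrix_from_genotypes([set(), {"a"}, {"a", "b"}], ["a", "b"])
        tree = ct.infer_tree(m, ct.NoiseModel())
        expected = [ROOT] * 20 + ["a"] * 20 + ["b"] * 20
        assert [tree.cell_attachment[c] for c in m.cells] == expected

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        m = random_matrix(rng, 40, list("abcdefgh"))  # k=8 -> stochastic search
        model = ct.NoiseModel()
        t1 = ct.infer_tree(m, model, max_exhaustive=4, n_restarts=5, seed=42)
        t2 = ct.infer_tree(m, model, max_exhaustive=4, n_restarts=5, seed=42)
        assert t1.parent == t2.parent
        assert t1.log_likelihood == t2.log_likelihood

    def test_hill_climb_matches_exhaustive_on_clean_data(self):
        m = matrix_from_genotypes(
            [set(), {"a"}, {"a", "b"}, {"a", "b", "c"}], ["a", "b", "c"]
        )
        model = ct.NoiseModel()
        exact = ct.infer_tree(m, model, max_exhaustive=7)
        climbed = ct.infer_tree(m, model, max_exhaustive=1, n_restarts=5, seed=0)
        assert climbed.log_likelihood == pytest.approx(exact.log_likelihood)

    def test_empty_matrix_rejected(self):
        m = CallMatrix(np.zeros((3, 0), dtype=np.int8), np.zeros((3, 0), dtype=int),
                       np.zeros((3, 0), dtype=int), np.zeros((3, 0), dtype=int),
                       ["c0", "c1", "c2"], [], [])
        with pytest.raises(ValueError, match="no variants"):
            ct.infer_tree(m, ct.NoiseModel())


class TestDropoutEstimation:
    def test_fraction_and_clamps(self):
        def mat(n_missing, n=100):
            N = np.zeros((n, 1), dtype=np.int8)
            N[:n_missing] = MISSING
            cov = np.where(N == MISSING, 0, 10).astype(np.int64)
            return CallMatrix(N, np.zeros_like(cov), cov, cov,
                              [f"c{i}" for i in range(n)], ["v"], [])

        assert ct.estimate_dropout_per_variant(mat(10))[0] == pytest.approx(0.10)
        assert ct.estimate_dropout_per_variant(mat(0))[0] == 0.01
        assert ct.estimate_dropout_per_variant(mat(100))[0] == 0.99


class TestLatinHypercube:
    def test_empirical_mean_near_target(self):
        rng = np.random.default_rng(0)
        draws = latin_hypercube_beta(np.array([0.10]), 10.0, 80, rng)
        assert draws.mean() == pytest.approx(0.10, abs=0.02)

    def test_stratification_covers_all_bins(self):
        rng = np.random.default_rng(1)
        n = 40
        draws = latin_hypercube_beta(np.array([0.5]), 10.0, n, rng)
        from scipy.stats import beta as beta_dist

        u = beta_dist.cdf(draws[:, 0], 5.0, 5.0)
        bins = np.floor(u * n).astype(int)
        assert sorted(bins) == list(range(n))

    def test_invalid_concentration_rejected(self):
        with pytest.raises(ValueError, match="invalid concentration"):
            latin_hypercube_beta(np.array([0.1]), 0.0, 10, np.random.default_rng(0))


class TestRobustness:
    def test_single_run_trivially_agrees(self, threeclones):
        m = threeclones["matrix"]
        means = ct.estimate_dropout_per_variant(m)
        res = ct.robustness_analysis(m, means, n_runs=1, seed=0)
        assert res.n_agreeing_runs == 1
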