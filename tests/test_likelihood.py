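import itertools

import dendropy
import numpy as np
import pytest

from aflphylo.data import BinaryCharacterMatrix
from aflphylo.errors import AflPhyloError
from aflphylo.likelihood import (
    BinaryModel,
    McmcSettings,
    bayes_factor,
    estimate_state_frequencies,
    marginal_likelihood_harmonic,
    matrix_log_likelihood,
    optimize_branch_lengths,
    sh_test,
    site_log_likelihood,
)
from aflphylo.trees import from_newick, leaf_labels


# ---------------------------------------------------------------------------
# independent oracle: brute-force sum over internal state assignments
# ---------------------------------------------------------------------------

def brute_force_pattern_prob(tree, model, leaf_states):
    """P(pattern) by exhaustive enumeration over internal node states."""

    def p_trans(i, j, t):
        pi = (model.pi0, model.pi1)
        mu = model.rate_scale / (2.0 * model.pi0 * model.pi1)
        e = np.exp(-mu * t)
        return pi[j] + ((1.0 if i == j else 0.0) - pi[j]) * e

    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    total = 0.0
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        state = {id(n): s for n, s in zip(internal, assignment)}
        for n in leaves:
            state[id(n)] = leaf_states[n.taxon.label]
        root = nodes[-1]
        prob = (model.pi0, model.pi1)[state[id(root)]]
        for n in nodes:
            if n.parent_node is not None:
                prob *= p_trans(state[id(n.parent_node)], state[id(n)],
                                n.edge.length or 0.0)
        total += prob
    return total


def random_tree_newick(n_leaves, rng):
    labels = [chr(ord("a") + i) for i in range(n_leaves)]
    items = [f"{lab}:{rng.uniform(0.01, 2.0):.6f}" for lab in labels]
    rng.shuffle(items)
    while len(items) > 2:
        i = rng.integers(0, len(items))
        a = items.pop(i)
        j = rng.integers(0, len(items))
        b = items.pop(j)
        items.append(f"({a},{b}):{rng.uniform(0.01, 2.0):.6f}")
    return f"({items[0]},{items[1]});"


class TestSiteLikelihood:
    def test_two_leaf_zero_length_limit(self):
        tree = from_newick("(a:0.0,b:0.0);")
        model = BinaryModel(0.7, 0.3)
        assert np.exp(site_log_likelihood(tree, model, [1, 1])) == pytest.approx(0.3)
        assert np.exp(site_log_likelihood(tree, model, [0, 0])) == pytest.approx(0.7)
        with np.errstate(all="ignore"):
            assert np.exp(site_log_likelihood(tree, model, [0, 1])) == pytest.approx(0.0)

    def test_two_leaf_infinite_length_independence(self):
        tree = from_newick("(a:400.0,b:400.0);")
        model = BinaryModel(0.7, 0.3)
        assert np.exp(site_log_likelihood(tree, model, [1, 0])) == pytest.approx(
            0.3 * 0.7, abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_pruning_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        tree = from_newick(random_tree_newick(n, rng))
        pi1 = float(rng.uniform(0.1, 0.9))
        model = BinaryModel(1.0 - pi1, pi1)
        labels = sorted(leaf_labels(tree))
        pattern = rng.integers(0, 2, n)
        got = site_log_likelihood(tree, model, pattern)
        want = brute_force_pattern_prob(tree, model, dict(zip(labels, pattern)))
        assert got == pytest.approx(np.log(want), abs=1e-10)

    def test_rerooting_invariance(self):
        rng = np.random.default_rng(11)
        tree = from_newick(random_tree_newick(5, rng))
        model = BinaryModel(0.6, 0.4)
        pattern = [1, 0, 1, 1, 0]
        base = site_log_likelihood(tree, model, pattern)
        # reroot on every internal edge and compare
        for edge in list(tree.preorder_edge_iter()):
            if edge.head_node.parent_node is None or edge.length is None:
                continue
            t2 = tree.clone(depth=1)
            e2 = [e for e in t2.preorder_edge_iter()
                  if e.length == edge.length][0]
            t2.reroot_at_edge(e2, length1=e2.length / 2, length2=e2.length / 2)
            assert site_log_likelihood(t2, model, pattern) == pytest.approx(base, abs=1e-10)

    def test_pattern_length_mismatch(self):
        tree = from_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(AflPhyloError):
            site_log_likelihood(tree, BinaryModel(0.5, 0.5), [0, 1])


def _matrix_from_patterns(patterns, labels):
    arr = np.asarray(patterns, dtype=np.int8).T  # (n_samples, n_loci)
    return BinaryCharacterMatrix(arr, labels, [f"L{i}" for i in range(arr.shape[1])])


class TestMatrixLikelihood:
    def _four_leaf(self):
        rng = np.random.default_rng(5)
        return from_newick(random_tree_newick(4, rng))

    def test_unconditioned_normalization(self):
        tree = self._four_leaf()
        model = BinaryModel(0.65, 0.35)
        pats = list(itertools.product((0, 1), repeat=4))
        m = _matrix_from_patterns(pats, list("abcd"))
        site = matrix_log_likelihood(tree, model, m)
        assert np.exp(site.per_locus_loglik).sum() == pytest.approx(1.0, abs=1e-10)

    def test_noabsencesites_normalization(self):
        tree = self._four_leaf()
        model = BinaryModel(0.65, 0.35, conditioning="noabsencesites")
        pats = [p for p in itertools.product((0, 1), repeat=4) if any(p)]
        m = _matrix_from_patterns(pats, list("abcd"))
        site = matrix_log_likelihood(tree, model, m)
        assert np.exp(site.per_locus_loglik).sum() == pytest.approx(1.0, abs=1e-10)

    def test_conditioning_shift_identity(self):
        tree = self._four_leaf()
        pats = [p for p in itertools.product((0, 1), repeat=4) if any(p)]
        m = _matrix_from_patterns(pats, list("abcd"))
        plain = matrix_log_likelihood(tree, BinaryModel(0.65, 0.35), m)
        cond = matrix_log_likelihood(
            tree, BinaryModel(0.65, 0.35, conditioning="noabsencesites"), m
        )
        shift = plain.total_loglik - m.n_loci * cond.conditioning_correction
        assert cond.total_loglik == pytest.approx(shift, abs=1e-9)


class TestEstimateFrequencies:
    def test_half_ones(self):
        calls = np.array([[1, 0], [0, 1]], dtype=np.int8)
        m = BinaryCharacterMatrix(calls, ["x", "y"], ["A", "B"])
        model = estimate_state_frequencies(m)
        assert model.pi1 == pytest.approx(0.5)

    def test_dirichlet_prior_ratio(self):
        # frequencies in the ratio (2.44, 1.00) -> pi1 = 1.00/3.44
        n0, n1 = 244, 100
        calls = np.array([[0] * n0 + [1] * n1], dtype=np.int8)
        m = BinaryCharacterMatrix(calls, ["x"], [f"L{i}" for i in range(n0 + n1)])
        model = estimate_state_frequencies(m)
        assert model.pi1 == pytest.approx(1.00 / 3.44, abs=1e-4)
        assert model.pi1 == pytest.approx(0.2907, abs=1e-4)

    def test_counting_oracle(self, rng):
        calls = rng.integers(0, 2, (7, 31)).astype(np.int8)
        calls[0, 0] = 1
        calls[1, 1] = 0
        m = BinaryCharacterMatrix(calls, [f"s{i}" for i in range(7)],
                                  [f"L{j}" for j in range(31)])
        model = estimate_state_frequencies(m)
        count = sum(int(v) for row in calls for v in row)
        assert model.pi1 == pytest.approx(count / calls.size)

    def test_degenerate_rejected(self):
        calls = np.ones((2, 3), dtype=np.int8)
        m = BinaryCharacterMatrix(calls, ["x", "y"], ["A", "B", "C"])
        with pytest.raises(AflPhyloError):
            estimate_state_frequencies(m)


class TestOptimizeBranchLengths:
    def test_two_leaf_matches_grid_search(self):
        from aflphylo.simulate import SimulationConfig

        rng = np.random.default_rng(2)
        true_t = 0.35
        model = BinaryModel(0.7, 0.3)
        tree = from_newick(f"(a:{true_t / 2},b:{true_t / 2});")
        # simulate loci on the 2-leaf tree directly
        mu = 1.0 / (2.0 * 0.7 * 0.3)
        e = np.exp(-mu * true_t)
        n = 3000
        x = (rng.random(n) < 0.3).astype(np.int8)
        p_same = np.where(x == 1, 0.3 + 0.7 * e, 0.7 + 0.3 * e)
        y = np.where(rng.random(n) < p_same, x, 1 - x).astype(np.int8)
        m = BinaryCharacterMatrix(np.vstack([x, y]), ["a", "b"],
                                  [f"L{i}" for i in range(n)])
        opt_tree, site = optimize_branch_lengths(tree, model, m)
        total_len = sum(lf.edge.length for lf in opt_tree.leaf_node_iter())
        # independent dense grid over the single path length
        grid = np.linspace(1e-4, 2.0, 4000)
        n11 = int(np.sum((x == 1) & (y == 1)))
        n00 = int(np.sum((x == 0) & (y == 0)))
        n_diff = n - n11 - n00
        ee = np.exp(-mu * grid)
        lnl = (n11 * np.log(0.3 * (0.3 + 0.7 * ee))
               + n00 * np.log(0.7 * (0.7 + 0.3 * ee))
               + n_diff * np.log(0.3 * 0.7 * (1 - ee)))
        t_grid = grid[np.argmax(lnl)]
        assert total_len == pytest.approx(t_grid, abs=2e-3)
        assert site.converged

    def test_duplicated_columns_double_loglik(self):
        rng = np.random.default_rng(8)
        tree = from_newick(random_tree_newick(4, rng))
        model = BinaryModel(0.6, 0.4)
        calls = rng.integers(0, 2, (4, 60)).astype(np.int8)
        m1 = BinaryCharacterMatrix(calls, list("abcd"),
                                   [f"L{i}" for i in range(60)])
        m2 = BinaryCharacterMatrix(np.hstack([calls, calls]), list("abcd"),
                                   [f"L{i}" for i in range(120)])
        t1, s1 = optimize_branch_lengths(tree, model, m1)
        t2, s2 = optimize_branch_lengths(tree, model, m2)
        assert s2.total_loglik == pytest.approx(2 * s1.total_loglik, rel=1e-6)
        bl1 = sorted(e.length for e in t1.preorder_edge_iter() if e.length)
        bl2 = sorted(e.length for e in t2.preorder_edge_iter() if e.length)
        assert np.allclose(bl1, bl2, atol=1e-5)


class TestShTest:
    def _data_and_topologies(self, seed=3, n_loci=500):
        from aflphylo.simulate import SimulationConfig, simulate_binary_characters, simulate_species_tree

        rng = np.random.default_rng(seed)
        tree = simulate_species_tree(6, 1.0, 0.3, rng=rng)
        cfg = SimulationConfig(n_species=6, individuals_per_species=1,
                               n_loci=n_loci, tree_height=0.3,
                               polymorphism_rate=0.0, seed=seed)
        matrix, _ = simulate_binary_characters(tree, cfg, rng=rng,
                                               require_polymorphic=False)
        matrix = BinaryCharacterMatrix(
            matrix.calls, [s.rsplit("_", 1)[0] for s in matrix.sample_ids],
            matrix.locus_ids)
        return matrix, tree

    def test_self_comparison_p_one(self):
        matrix, tree = self._data_and_topologies()
        model = BinaryModel(0.71, 0.29)
        res = sh_test(matrix, {"t1": tree, "t2": tree.clone(depth=1)}, model,
                      n_rell=200, seed=1)
        assert res.sh_pvalues["t1"] == 1.0
        assert res.sh_pvalues["t2"] == 1.0
        assert res.deltas["t1"] == pytest.approx(0.0, abs=1e-6)

    def test_order_invariance(self):
        matrix, tree = self._data_and_topologies()
        alt = from_newick("((sp01:.1,sp03:.1):.1,(sp02:.1,(sp04:.1,(sp05:.1,sp06:.1):.1):.1):.1);")
        model = BinaryModel(0.71, 0.29)
        r1 = sh_test(matrix, {"a": tree, "b": alt}, model, n_rell=300, seed=9)
        r2 = sh_test(matrix, {"b": alt, "a": tree}, model, n_rell=300, seed=9)
        assert r1.sh_pvalues["a"] == pytest.approx(r2.sh_pvalues["a"], abs=0.05)
        assert r1.deltas["b"] == pytest.approx(r2.deltas["b"], abs=1e-6)

    def test_mismatched_leafset_rejected(self):
        matrix, tree = self._data_and_topologies()
        bad = from_newick("((x:1,y:1):1,z:1);")
        with pytest.raises(AflPhyloError):
            sh_test(matrix, {"a": tree, "bad": bad}, BinaryModel(0.7, 0.3))


class TestHarmonicMeanAndBayesFactor:
    def test_zero_iterations_rejected(self):
        with pytest.raises(AflPhyloError):
            McmcSettings(n_generations=0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        tree = from_newick("(a:0.2,b:0.2);")
        calls = rng.integers(0, 2, (2, 30)).astype(np.int8)
        m = BinaryCharacterMatrix(calls, ["a", "b"], [f"L{i}" for i in range(30)])
        model = BinaryModel(0.6, 0.4)
        s = McmcSettings(n_generations=2000)
        r1 = marginal_likelihood_harmonic(tree, model, m, s, seed=7)
        r2 = marginal_likelihood_harmonic(tree, model, m, s, seed=7)
        assert r1.per_run == r2.per_run

    def test_acceptance_rate_warning_flag(self):
        rng = np.random.default_rng(3)
        tree = from_newick("(a:0.2,b:0.2);")
        calls = rng.integers(0, 2, (2, 40)).astype(np.int8)
        m = BinaryCharacterMatrix(calls, ["a", "b"], [f"L{i}" for i in range(40)])
        model = BinaryModel(0.6, 0.4)
        # near-zero proposal window -> acceptance rate ~1 -> warning set
        s = McmcSettings(n_generations=800, proposal_lambda=1e-6)
        est = marginal_likelihood_harmonic(tree, model, m, s, seed=2)
        assert est.warning
        assert all(a > 0.8 for a in est.acceptance_rates)

    def test_bayes_factor_arithmetic(self):
        assert bayes_factor(-100.0, -100.0) == (0.0, "not_strong")
        value, verdict = bayes_factor(-95.0, -100.0001)
        assert value == pytest.approx(10.0002)
        assert verdict == "strong"
        value, verdict = bayes_factor(-107.0, -100.0)
        assert value == pytest.approx(-14.0)
        assert verdict == "not_strong"
        with pytest.raises(AflPhyloError):
            bayes_factor(float("nan"), -1.0)

    def test_two_leaf_harmonic_vs_quadrature(self):
        # small two-leaf problem: marginal likelihood has a 1-D integral form
        from scipy.integrate import quad

        rng = np.random.default_rng(6)
        model = BinaryModel(0.7, 0.3)
        mu = 1.0 / (2.0 * 0.7 * 0.3)
        true_t = 0.3
        n = 25
        x = (rng.random(n) < 0.3).astype(np.int8)
        e = np.exp(-mu * true_t)
        p_same = np.where(x == 1, 0.3 + 0.7 * e, 0.7 + 0.3 * e)
        y = np.where(rng.random(n) < p_same, x, 1 - x).astype(np.int8)
        m = BinaryCharacterMatrix(np.vstack([x, y]), ["a", "b"],
                                  [f"L{i}" for i in range(n)])
        n11 = int(np.sum((x == 1) & (y == 1)))
        n00 = int(np.sum((x == 0) & (y == 0)))
        nd = n - n11 - n00

        prior_mean = 0.1

        def lik(t):  # t = total path length; two edges t/2 each
            ee = np.exp(-mu * t)
            return ((0.3 * (0.3 + 0.7 * ee)) ** n11
                    * (0.7 * (0.7 + 0.3 * ee)) ** n00
                    * (0.3 * 0.7 * (1 - ee)) ** nd)

        # both branch lengths have independent Exp(prior_mean) priors; the
        # likelihood depends on their sum, whose density is Gamma(2, mean/1)
        def integrand(t):
            dens = t / prior_mean**2 * np.exp(-t / prior_mean)
            return lik(t) * dens

        truth, _ = quad(integrand, 0, 20, limit=200)
        ln_truth = np.log(truth)
        s = McmcSettings(n_generations=40000, burnin_frac=0.25, sample_every=5)
        est = marginal_likelihood_harmonic(from_newick("(a:0.1,b:0.1);"),
                                           model, m, s, seed=13)
        spread = max(abs(a - b) for a in est.per_run for b in est.per_run)
        tol = max(3 * spread, 1.0)  # harmonic mean is noisy; spread-scaled check
        assert est.estimate == pytest.approx(ln_truth, abs=tol)
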