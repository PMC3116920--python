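import numpy as np
import pytest

from ancres import (
    Alignment,
    SimulationSpec,
    log_likelihood,
    optimize,
    read_tree,
    simulate_alignment,
)
from ancres.io import Node, Phylogeny
from ancres.likelihood import (
    PruningEngine,
    PruningError,
    branch_support,
    mixture_p_value,
    rate_equality_lrt,
    reroot_at_edge,
)
from ancres.substitution_models import build_model

from .oracles import enumeration_site_logliks, random_alignment, random_small_tree


class TestPruning:
    def test_single_tip_is_log_pi(self, jtt1):
        tree = Phylogeny(Node(name="A"))
        aln = Alignment.from_sequences(["A"], ["ACD"])
        res = log_likelihood(tree, aln, jtt1)
        expected = np.log(jtt1.pi[[0, 4, 3]])  # A, C, D
        assert np.abs(res.site_lnl - expected).max() < 1e-12

    def test_total_is_sum_of_sites(self, quartet_tree, quartet_alignment, jtt4):
        res = log_likelihood(quartet_tree, quartet_alignment, jtt4)
        assert res.lnl == pytest.approx(res.site_lnl.sum(), abs=1e-8)

    @pytest.mark.parametrize("K", [1, 4])
    def test_matches_enumeration_on_random_trees(self, K):
        rng = np.random.default_rng(2024)
        model = build_model(alpha=0.6, K=K)
        for _ in range(8):
            tree = random_small_tree(rng, int(rng.integers(2, 6)))
            aln = random_alignment(rng, tree.tip_names, nsites=6)
            got = log_likelihood(tree, aln, model).site_lnl
            want = enumeration_site_logliks(tree, aln, model)
            assert np.abs(got - want).max() < 1e-10

    def test_missing_data_contributes_ones(self, jtt1):
        tree = read_tree("(A:0.1,B:0.2);")
        full = Alignment.from_sequences(["A", "B"], ["C", "C"])
        gapped = Alignment.from_sequences(["A", "B"], ["C", "-"])
        lnl_gap = log_likelihood(tree, gapped, jtt1).lnl
        # with B missing, the site likelihood reduces to pi(C)
        assert lnl_gap == pytest.approx(np.log(jtt1.pi[4]), abs=1e-12)
        assert lnl_gap > log_likelihood(tree, full, jtt1).lnl

    def test_unbound_tree_is_error(self, quartet_tree, jtt1):
        aln = Alignment.from_sequences(["A", "B", "C", "E"], ["A"] * 4)
        with pytest.raises(Exception, match="differ"):
            log_likelihood(quartet_tree, aln, jtt1)

    def test_tip_order_invariance(self, quartet_tree, quartet_alignment, jtt4):
        shuffled = Alignment.from_sequences(
            ["D", "B", "A", "C"],
            [quartet_alignment.sequence(n) for n in "DBAC"],
        )
        assert log_likelihood(quartet_tree, shuffled, jtt4).lnl == pytest.approx(
            log_likelihood(quartet_tree, quartet_alignment, jtt4).lnl, abs=1e-10
        )


class TestRerooting:
    def test_pulley_principle(self, jtt4):
        rng = np.random.default_rng(5)
        tree = random_small_tree(rng, 5)
        aln = random_alignment(rng, tree.tip_names, nsites=8)
        base = log_likelihood(tree, aln, jtt4).lnl
        for nd in tree.branches():
            if nd.name is None:
                continue
            for frac in (0.25, 0.5, 0.9):
                rerooted = reroot_at_edge(tree, nd.name, frac)
                assert log_likelihood(rerooted, aln, jtt4).lnl == pytest.approx(
                    base, abs=1e-8
                )

    def test_rerooting_preserves_total_length(self, quartet_tree):
        total = sum(nd.length for nd in quartet_tree.branches())
        rerooted = reroot_at_edge(quartet_tree, "A", 0.3)
        assert sum(nd.length for nd in rerooted.branches()) == pytest.approx(total)


class TestOptimize:
    def test_branch_length_recovery_within_3se(self, jtt1):
        spec = SimulationSpec(seed=8, ntaxa=6, nsites=500, alpha=1.0, K=1)
        aln, _, tree = simulate_alignment(spec, model=jtt1)
        res = optimize(tree, aln, jtt1, optimize_alpha=False)
        engine = PruningEngine(res.tree, aln, jtt1)
        for nd in res.tree.branches():
            f = engine.branch_lnl_function(nd.index)
            t = nd.length
            h = max(1e-4, 1e-3 * t)
            curv = (f(t + h) - 2 * f(t) + f(max(t - h, 1e-9))) / h**2
            se = 1.0 / np.sqrt(max(-curv, 1e-12))
            truth = tree.find(nd.name).length
            assert abs(t - truth) < 3 * se + 1e-6

    def test_stationary_at_generating_parameters(self, jtt1):
        # with plenty of data, optimizing from the truth barely moves lnL
        spec = SimulationSpec(seed=9, ntaxa=5, nsites=2000, alpha=1.0, K=1)
        aln, _, tree = simulate_alignment(spec, model=jtt1)
        at_truth = log_likelihood(tree, aln, jtt1).lnl
        res = optimize(tree, aln, jtt1, optimize_alpha=False)
        assert res.lnl >= at_truth - 1e-9
        assert (res.lnl - at_truth) / abs(at_truth) < 1e-3

    def test_monotone_nesting_free_vs_constrained(self, jtt1):
        spec = SimulationSpec(seed=10, ntaxa=4, nsites=120, alpha=1.0, K=1)
        aln, _, tree = simulate_alignment(spec, model=jtt1)
        tips = tree.tip_names
        free = optimize(tree, aln, jtt1, optimize_alpha=False)
        constrained = optimize(
            tree, aln, jtt1, optimize_alpha=False, shared=[[tips[0], tips[1]]]
        )
        assert free.lnl >= constrained.lnl - 1e-6

    def test_alpha_recovery_study_scale(self, study_scale_sim):
        spec, aln, _, tree = study_scale_sim
        model = build_model(alpha=1.0, K=4)
        res = optimize(tree, aln, model, optimize_alpha=True, max_cycles=20)
        assert 0.7 <= res.alpha <= 1.4

    def test_gamma_categories_never_hurt_fit(self, study_scale_sim):
        # data simulated with rate heterogeneity: the gamma mixture fit
        # should beat the single-rate fit
        spec, aln, _, tree = study_scale_sim
        one = optimize(tree, aln, build_model(alpha=1.0, K=1), optimize_alpha=False)
        four = optimize(tree, aln, build_model(alpha=1.0, K=4), optimize_alpha=True)
        assert four.lnl >= one.lnl - 1e-6


class TestBranchSupport:
    def test_mixture_tail_closed_form(self):
        assert mixture_p_value(0.0) == 1.0
        assert mixture_p_value(3.84) == pytest.approx(0.025, abs=5e-4)

    def test_zero_length_generating_branch_low_support(self, jtt1):
        tree = read_tree(
            "(((A:0.15,B:0.2)u:0.00000001,C:0.25)w:0.1,(D:0.1,E:0.12)v:0.15)r;"
        )
        spec = SimulationSpec(seed=13, nsites=150, alpha=1.0, K=1)
        aln, _, tr = simulate_alignment(spec, tree=tree, model=jtt1)
        res = branch_support(tr, aln, jtt1, "u")
        # a branch absent from the generating tree must never look
        # significantly supported
        assert res.p_value > 0.05 and res.support < 0.95
        assert res.statistic < 3.84

    def test_real_branch_has_support(self, jtt1):
        tree = read_tree("((A:0.1,B:0.1)u:0.5,(C:0.1,D:0.1)v:0.1)r;")
        spec = SimulationSpec(seed=14, nsites=200, alpha=1.0, K=1)
        aln, _, tr = simulate_alignment(spec, tree=tree, model=jtt1)
        res = branch_support(tr, aln, jtt1, "u")
        assert res.support > 0.95
        assert res.statistic >= -1e-6

    def test_tip_branch_rejected(self, quartet_tree, quartet_alignment, jtt1):
        with pytest.raises(PruningError):
            branch_support(quartet_tree, quartet_alignment, jtt1, "A")


class TestRateEqualityLRT:
    def test_chi2_tail_at_reported_statistic(self):
        from scipy.stats import chi2

        assert chi2.sf(2.874, 1) == pytest.approx(0.090, abs=1e-3)

    def test_identical_branches_give_ratio_one(self, jtt1):
        tree = read_tree("((A:0.2,B:0.2)u:0.1,(C:0.15,D:0.15)v:0.1)r;")
        spec = SimulationSpec(seed=15, nsites=300, alpha=1.0, K=1)
        aln, _, tr = simulate_alignment(spec, tree=tree, model=jtt1)
        constrained = optimize(
            tr, aln, jtt1, optimize_alpha=False, shared=[["A", "B"]]
        )
        fitted = {nd.name: nd.length for nd in constrained.tree.branches()}
        assert fitted["A"] == pytest.approx(fitted["B"], abs=1e-9)
        res = rate_equality_lrt(tr, aln, jtt1, "A", "B")
        assert res.statistic >= -1e-6
        assert res.p_value > 0.05  # truth satisfies the constraint

    def test_unequal_branches_detected(self, jtt1):
        tree = read_tree("((A:0.02,B:0.7)u:0.1,(C:0.15,D:0.15)v:0.1)r;")
        spec = SimulationSpec(seed=16, nsites=400, alpha=1.0, K=1)
        aln, _, tr = simulate_alignment(spec, tree=tree, model=jtt1)
        res = rate_equality_lrt(tr, aln, jtt1, "A", "B")
        assert res.p_value < 0.01

    def test_same_branch_twice_rejected(self, quartet_tree, quartet_alignment, jtt1):
        with pytest.raises(PruningError):
            rate_equality_lrt(quartet_tree, quartet_alignment, jtt1, "A", "A")
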