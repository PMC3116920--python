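import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ancres import (
    Alignment,
    SimulationSpec,
    TreeEnsemble,
    alternate_states,
    combine_over_trees,
    compare_reconstructions,
    marginal_reconstruction,
    read_tree,
    simulate_alignment,
)
from ancres.asr import AncestralReconstruction, ASRError
from ancres.io import AA_INDEX, AMINO_ACIDS
from ancres.substitution_models import build_model

from .oracles import enumeration_node_posterior, random_alignment, random_small_tree


def _pp_vectors(draw_lists):
    arr = np.asarray(draw_lists, dtype=float) + 1e-9
    return arr / arr.sum(axis=1, keepdims=True)


class TestMarginalReconstruction:
    def test_star_tree_zero_lengths_unanimous(self, jtt1):
        tree = read_tree("(A:0.0000001,B:0.0000001,C:0.0000001)anc;")
        aln = Alignment.from_sequences(["A", "B", "C"], ["W", "W", "W"])
        rec = marginal_reconstruction(tree, aln, jtt1, "anc")
        assert rec.ml_sequence == "W"
        assert rec.pp[0, AA_INDEX["W"]] > 0.9999

    @pytest.mark.parametrize("K", [1, 4])
    def test_matches_enumeration_oracle(self, K):
        rng = np.random.default_rng(77)
        model = build_model(alpha=0.8, K=K)
        for _ in range(5):
            tree = random_small_tree(rng, int(rng.integers(3, 6)))
            aln = random_alignment(rng, tree.tip_names, nsites=5)
            node = tree.internal_nodes()[0].name
            got = marginal_reconstruction(tree, aln, model, node).pp
            want = enumeration_node_posterior(tree, aln, model, node)
            assert np.abs(got - want).max() < 1e-10

    def test_tip_node_rejected(self, quartet_tree, quartet_alignment, jtt1):
        with pytest.raises(ASRError):
            marginal_reconstruction(quartet_tree, quartet_alignment, jtt1, "A")

    def test_posteriors_normalised_and_argmax_consistent(
        self, quartet_tree, quartet_alignment, jtt4
    ):
        rec = marginal_reconstruction(quartet_tree, quartet_alignment, jtt4, "u")
        assert np.abs(rec.pp.sum(axis=1) - 1.0).max() < 1e-8
        assert np.all(rec.ml_pp == rec.pp.max(axis=1))

    def test_accuracy_improves_with_shorter_branches(self, jtt1):
        # statistical monotonicity: shrinking branch lengths makes ancestors
        # easier to infer
        def accuracy(scale, seed):
            spec = SimulationSpec(
                seed=seed, ntaxa=8, nsites=300, alpha=1.0, K=1,
                branch_length_mean=scale,
            )
            aln, ancestors, tree = simulate_alignment(spec, model=jtt1)
            node = tree.root.name or tree.internal_nodes()[-1].name
            rec = marginal_reconstruction(tree, aln, jtt1, node)
            truth = ancestors[node]
            return np.mean([a == b for a, b in zip(rec.ml_sequence, truth)])

        short = np.mean([accuracy(0.05, s) for s in (1, 2, 3)])
        long = np.mean([accuracy(0.8, s) for s in (1, 2, 3)])
        assert short > long


class TestCombineOverTrees:
    def test_single_tree_identity(self, quartet_tree, quartet_alignment, jtt1):
        single = marginal_reconstruction(quartet_tree, quartet_alignment, jtt1, "u")
        ens = TreeEnsemble([quartet_tree], np.array([1.0]))
        combined = combine_over_trees(ens, quartet_alignment, jtt1, "u")
        assert np.allclose(combined.pp, single.pp, atol=1e-12)

    def test_two_identical_trees_half_weights(
        self, quartet_tree, quartet_alignment, jtt1
    ):
        single = marginal_reconstruction(quartet_tree, quartet_alignment, jtt1, "u")
        ens = TreeEnsemble(
            [quartet_tree, quartet_tree.copy()], np.array([0.5, 0.5])
        )
        combined = combine_over_trees(ens, quartet_alignment, jtt1, "u")
        assert np.allclose(combined.pp, single.pp, atol=1e-12)

    def test_weighted_average_arithmetic(self):
        pp1 = np.zeros((2, 20)); pp1[:, 0] = 0.9; pp1[:, 1] = 0.1
        pp2 = np.zeros((2, 20)); pp2[:, 0] = 0.5; pp2[:, 1] = 0.5
        r1 = AncestralReconstruction("n", pp1)
        r2 = AncestralReconstruction("n", pp2)
        w = np.array([0.7, 0.3])
        combined = w[0] * r1.pp + w[1] * r2.pp
        assert combined[0, 0] == pytest.approx(0.78)
        assert combined[0, 1] == pytest.approx(0.22)

    def test_convex_hull_property(self, quartet_alignment, jtt1):
        t1 = read_tree("((A:0.1,B:0.2)u:0.15,(C:0.3,D:0.05)v:0.08)r;")
        t2 = read_tree("((A:0.3,C:0.2)u:0.05,(B:0.1,D:0.15)v:0.18)r;")
        r1 = marginal_reconstruction(t1, quartet_alignment, jtt1, "u")
        r2 = marginal_reconstruction(t2, quartet_alignment, jtt1, "u")
        ens = TreeEnsemble([t1, t2], np.array([0.6, 0.4]))
        combined = combine_over_trees(ens, quartet_alignment, jtt1, "u")
        lo = np.minimum(r1.pp, r2.pp) - 1e-12
        hi = np.maximum(r1.pp, r2.pp) + 1e-12
        assert np.all(combined.pp >= lo) and np.all(combined.pp <= hi)

    def test_missing_node_is_mapping_error(self, quartet_tree, quartet_alignment, jtt1):
        ens = TreeEnsemble([quartet_tree], np.array([1.0]))
        with pytest.raises(ASRError, match="missing"):
            combine_over_trees(ens, quartet_alignment, jtt1, "nope")

    def test_weights_from_likelihoods(self, quartet_tree):
        ens = TreeEnsemble.from_log_likelihoods(
            [quartet_tree, quartet_tree.copy()], [-100.0, -100.0 + np.log(3)]
        )
        assert ens.weights == pytest.approx([0.25, 0.75])


class TestAlternateStates:
    def _recon(self, probs_per_site):
        pp = np.zeros((len(probs_per_site), 20))
        for s, pairs in enumerate(probs_per_site):
            for aa, p in pairs:
                pp[s, AA_INDEX[aa]] = p
        return AncestralReconstruction("n", pp)

    def test_one_alternate(self):
        rec = self._recon([[("A", 0.79), ("R", 0.21)]])
        alts = alternate_states(rec, 0.20)
        assert alts == {1: [("R", 0.21)]}

    def test_strict_threshold_boundary(self):
        rec = self._recon([[("A", 0.80), ("R", 0.20)]])
        assert alternate_states(rec, 0.20) == {}

    def test_threshold_domain(self):
        rec = self._recon([[("A", 1.0)]])
        with pytest.raises(ASRError):
            alternate_states(rec, 1.5)

    @given(st.lists(st.lists(st.floats(0.01, 1.0), min_size=20, max_size=20),
                    min_size=1, max_size=6))
    def test_pigeonhole_at_half(self, raw):
        rec = AncestralReconstruction("n", _pp_vectors(raw))
        alts = alternate_states(rec, 0.5)
        assert all(len(v) <= 1 for v in alts.values())


class TestCompareReconstructions:
    def _uniformish(self, seq, pp_major=0.9):
        pp = np.full((len(seq), 20), (1 - pp_major) / 19)
        for s, aa in enumerate(seq):
            pp[s, AA_INDEX[aa]] = pp_major
        return AncestralReconstruction("n", pp)

    def test_identical_reconstructions(self):
        r = self._uniformish("ACDEFGHIKL")
        rep = compare_reconstructions(r, r)
        assert rep.n_differences == 0
        assert rep.mean_pp_a == rep.mean_pp_b

    def test_two_of_ten_differ(self):
        ra = self._uniformish("ACDEFGHIKL")
        rb = self._uniformish("MCDEFGHIKW")
        rep = compare_reconstructions(ra, rb)
        assert rep.n_differences == 2
        assert rep.fraction_differing == pytest.approx(0.2)

    def test_report_matches_direct_recomputation(self, study_scale_sim, jtt1):
        spec, aln, ancestors, tree = study_scale_sim
        nodes = [nd.name for nd in tree.internal_nodes() if nd.name][:2]
        ra = marginal_reconstruction(tree, aln, jtt1, nodes[0])
        rb = marginal_reconstruction(tree, aln, jtt1, nodes[1])
        rep = compare_reconstructions(ra, rb)
        assert rep.mean_pp_a == pytest.approx(float(ra.pp.max(axis=1).mean()))
        assert rep.n_differences == int(
            (np.argmax(ra.pp, 1) != np.argmax(rb.pp, 1)).sum()
        )
        assert rep.n_certain_a == int((ra.pp.max(axis=1) >= 0.995).sum())

    def test_length_mismatch(self):
        with pytest.raises(ASRError):
            compare_reconstructions(
                self._uniformish("ACD"), self._uniformish("ACDE")
            )


class TestCalibration:
    def test_high_pp_sites_are_usually_correct(self, study_scale_sim):
        # among sites reconstructed with posterior in [0.90, 0.95], the true
        # state should be recovered at a matching rate
        model = build_model(alpha=1.0, K=4)
        hits = total = 0
        seed = 42
        while total < 500 and seed < 60:
            spec = SimulationSpec(seed=seed, ntaxa=12, nsites=240, alpha=1.0, K=4)
            aln, ancestors, tree = simulate_alignment(spec, model=model)
            for nd in tree.internal_nodes():
                if not nd.name:
                    continue
                rec = marginal_reconstruction(tree, aln, model, nd.name)
                truth = np.array([AA_INDEX[a] for a in ancestors[nd.name]])
                band = (rec.ml_pp >= 0.90) & (rec.ml_pp < 0.95)
                hits += int((rec.ml_indices[band] == truth[band]).sum())
                total += int(band.sum())
            seed += 1
        assert total >= 500
        assert 0.85 <= hits / total <= 0.99
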