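"""Mk model machinery: rate matrices, likelihoods, ASR, origins, resampling."""

import numpy as np
import pandas as pd
import pytest

from flpscape import mk, synthdata, trees
from flpscape.errors import InvalidArgumentError, NonConvergenceError

from conftest import random_q, random_small_tree
from oracles import mk_likelihood_enumeration, mk_marginals_enumeration


class TestRateMatrix:
    def test_er_construction(self):
        q = mk.build_rate_matrix("ER", [0.9])
        off = q.matrix[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.9)
        assert np.allclose(np.diag(q.matrix), -1.8)

    def test_sym_is_symmetric_ard_is_not(self):
        qs = mk.build_rate_matrix("SYM", [0.2, 0.5, 0.9])
        assert np.allclose(qs.matrix, qs.matrix.T)
        qa = mk.build_rate_matrix("ARD", [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        assert qa.matrix[0, 1] != qa.matrix[1, 0]
        assert np.allclose(qa.matrix.sum(axis=1), 0.0)

    @pytest.mark.parametrize("model,theta", [
        ("ER", [0.0]), ("ER", [-1.0]), ("SYM", [1.0]), ("XX", [1.0]),
    ])
    def test_invalid_construction(self, model, theta):
        with pytest.raises(InvalidArgumentError):
            mk.build_rate_matrix(model, theta)


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        q = mk.build_rate_matrix("ARD", [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        assert np.allclose(mk.transition_probabilities(q, 0.0), np.eye(3))

    def test_two_state_closed_form(self):
        """With states {0,1} exchanging at rate r and state 2 frozen,
        P_stay(t) = (1 + exp(-2 r t)) / 2."""
        r, t = 0.7, 1.3
        Q = np.array([[-r, r, 0.0], [r, -r, 0.0], [0.0, 0.0, 0.0]])
        P = mk.transition_probabilities(Q, t)
        assert P[0, 0] == pytest.approx(0.5 * (1 + np.exp(-2 * r * t)), abs=1e-12)
        assert P[2, 2] == pytest.approx(1.0)

    def test_long_time_reaches_uniform_stationary_under_er(self):
        q = mk.build_rate_matrix("ER", [1.0])
        P = mk.transition_probabilities(q, 200.0)
        assert np.allclose(P, 1.0 / 3.0, atol=1e-9)


class TestLikelihood:
    def test_matches_enumeration_on_small_trees(self):
        """Pruning equals the exhaustive sum over internal-node states."""
        rng = np.random.default_rng(42)
        for trial in range(10):
            tree = random_small_tree(rng, int(rng.integers(2, 7)))
            Q = random_q(rng, ["ER", "SYM", "ARD"][trial % 3])
            tips = {lb: int(rng.integers(3)) for lb in trees.tip_labels(tree)}
            prior = rng.dirichlet([1.0, 1.0, 1.0])
            got = mk.mk_log_likelihood(tree, tips, Q, prior)
            want = mk_likelihood_enumeration(tree, tips, Q, prior)
            assert got == pytest.approx(want, abs=1e-8)

    def test_frozen_chain_likelihood_is_shared_state_prior(self):
        t = trees.read_newick("(A:1,B:1);", from_string=True)
        Q = np.zeros((3, 3))
        prior = np.array([0.5, 0.3, 0.2])
        ll = mk.mk_log_likelihood(t, {"A": 1, "B": 1}, Q, prior)
        assert ll == pytest.approx(np.log(0.3), abs=1e-10)
        # discordant tips are impossible without evolution
        assert mk.mk_log_likelihood(t, {"A": 0, "B": 1}, Q, prior) == -np.inf

    def test_invariant_to_tip_enumeration_order(self, six_tip_tree):
        rng = np.random.default_rng(1)
        Q = random_q(rng)
        labels = trees.tip_labels(six_tip_tree)
        tips = {lb: int(rng.integers(3)) for lb in labels}
        a = mk.mk_log_likelihood(six_tip_tree, tips, Q)
        b = mk.mk_log_likelihood(six_tip_tree,
                                 dict(reversed(list(tips.items()))), Q)
        assert a == b

    def test_rejects_malformed_q(self, balanced_tree):
        with pytest.raises(InvalidArgumentError):
            mk.mk_log_likelihood(balanced_tree, {"A": 0, "B": 0, "C": 1},
                                 np.ones((3, 3)))


class TestFitAndSelection:
    def test_nested_models_never_lose_likelihood(self):
        tree = trees.simulate_yule_tree(120, 1.0, 7)
        q = mk.build_rate_matrix("ER", [0.9])
        tips, _ = synthdata.simulate_mk_tips(tree, q.matrix,
                                             mk.UNIFORM_PRIOR, 7)
        lls = {m: mk.fit_mk_model(tree, tips, m, restarts=2, seed=0)
               .log_likelihood for m in ("ER", "SYM", "ARD")}
        assert lls["SYM"] >= lls["ER"] - 1e-6
        assert lls["ARD"] >= lls["SYM"] - 1e-6

    def test_same_seed_same_fit(self):
        tree = trees.simulate_yule_tree(60, 1.0, 3)
        tips, _ = synthdata.simulate_mk_tips(
            tree, mk.build_rate_matrix("ER", [0.9]).matrix,
            mk.UNIFORM_PRIOR, 3)
        f1 = mk.fit_mk_model(tree, tips, "SYM", seed=11)
        f2 = mk.fit_mk_model(tree, tips, "SYM", seed=11)
        assert np.array_equal(f1.theta, f2.theta)

    def test_constant_states_pinned_to_lower_bound(self):
        tree = trees.simulate_yule_tree(20, 1.0, 5)
        tips = {lb: "FLP" for lb in trees.tip_labels(tree)}
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit = mk.fit_mk_model(tree, tips, "ER", restarts=1, seed=0)
        assert fit.at_lower_bound

    def test_aicc_formula_and_asymptote(self):
        assert mk.aicc(-10.0, 1, 100) == pytest.approx(
            20 + 2 + 2 * 1 * 2 / 98, abs=1e-10)
        assert mk.aicc(-10.0, 2, 10 ** 9) == pytest.approx(24.0, abs=1e-6)
        with pytest.raises(InvalidArgumentError):
            mk.aicc(-10.0, 3, 4)

    def test_selection_rules(self):
        def fake(model, a):
            return mk.MkFit(model=model, theta=np.ones(1), q=None,
                            log_likelihood=0.0, k=mk.MODEL_K[model],
                            n_tips=100, aicc=a, converged=True)
        # the published ordering: ER 360.47 < SYM 362.95 < ARD 367.15,
        # with only ER within 2 units
        ranked, best = mk.select_models([fake("ER", 360.47),
                                         fake("ARD", 367.15),
                                         fake("SYM", 362.95)])
        assert [f.model for f in ranked] == ["ER", "SYM", "ARD"]
        assert [f.model for f in best] == ["ER"]
        _, both = mk.select_models([fake("ER", 100.0), fake("SYM", 101.5)])
        assert len(both) == 2
        ranked, _ = mk.select_models([fake("ARD", 50.0), fake("ER", 50.0)])
        assert ranked[0].model == "ER"  # tie goes to fewer parameters
        with pytest.raises(NonConvergenceError):
            mk.select_models([])


class TestMarginalASR:
    def test_matches_enumeration_posteriors(self):
        rng = np.random.default_rng(13)
        for trial in range(6):
            tree = random_small_tree(rng, int(rng.integers(3, 6)))
            Q = random_q(rng, ["ER", "ARD"][trial % 2])
            tips = {lb: int(rng.integers(3)) for lb in trees.tip_labels(tree)}
            prior = rng.dirichlet([1.0, 1.0, 1.0])
            asr = mk.marginal_asr(tree, tips, Q, prior)
            want = mk_marginals_enumeration(tree, tips, Q, prior)
            for label, expect in want.items():
                assert np.allclose(asr.node(label), expect, atol=1e-8), label

    def test_normalization_and_tip_mass(self, six_tip_tree):
        rng = np.random.default_rng(2)
        Q = random_q(rng)
        tips = {lb: int(rng.integers(3)) for lb in trees.tip_labels(six_tip_tree)}
        asr = mk.marginal_asr(six_tip_tree, tips, Q)
        probs = asr.probs[list(mk.STATES)].to_numpy(dtype=float)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-10)
        for lb, s in tips.items():
            assert asr.node(lb)[s] == pytest.approx(1.0, abs=1e-10)

    def test_invariant_to_child_rotation(self):
        a = trees.read_newick("((A:1,B:2):1,C:3);", from_string=True)
        b = trees.read_newick("(C:3,(B:2,A:1):1);", from_string=True)
        Q = mk.build_rate_matrix("SYM", [0.3, 0.6, 0.9])
        tips = {"A": 0, "B": 2, "C": 1}
        assert (mk.mk_log_likelihood(a, tips, Q)
                == pytest.approx(mk.mk_log_likelihood(b, tips, Q), abs=1e-10))
        ra, rb = (mk.marginal_asr(t, tips, Q) for t in (a, b))
        assert np.allclose(ra.node(ra.root_label), rb.node(rb.root_label),
                           atol=1e-10)


class TestOrigins:
    def test_trivial_cases(self, six_tip_tree):
        labels = trees.tip_labels(six_tip_tree)
        all_flp = mk.marginal_asr(six_tip_tree, {lb: 2 for lb in labels},
                                  mk.build_rate_matrix("ER", [0.1]))
        assert mk.count_independent_origins(six_tip_tree, all_flp, "FLP") == 1
        none_flp = mk.marginal_asr(six_tip_tree, {lb: 0 for lb in labels},
                                   mk.build_rate_matrix("ER", [0.1]))
        assert mk.count_independent_origins(six_tip_tree, none_flp, "FLP") == 0

    def test_two_disjoint_focal_clades(self, six_tip_tree):
        """Hand-built marginals: A,B gain androchromy in one clade and D,E
        in another while the backbone and root stay non-focal -> 2 gains."""
        p_flp = {"A": 1.0, "B": 1.0, "C": 0.0, "D": 1.0, "E": 1.0, "F": 0.0}
        for nd in six_tip_tree.postorder_node_iter():
            if nd.is_leaf():
                continue
            leaves = {lf.taxon.label for lf in nd.leaf_iter()}
            # the two cherries are focal, every deeper node is not
            p_flp[nd.label] = 0.9 if leaves in ({"A", "B"}, {"D", "E"}) else 0.2
        probs = pd.DataFrame(
            {"monochromic": [(1 - v) for v in p_flp.values()],
             "dichromic": 0.0, "FLP": list(p_flp.values())},
            index=list(p_flp))
        asr = mk.ASRResult(probs=probs, root_prior=mk.UNIFORM_PRIOR,
                           root_label="nd4")
        assert mk.count_independent_origins(six_tip_tree, asr, "FLP") == 2


class TestRootResampling:
    def test_deterministic_and_bounded(self):
        tree = trees.simulate_yule_tree(40, 1.0, 9)
        tips, _ = synthdata.simulate_mk_tips(
            tree, mk.build_rate_matrix("ER", [0.9]).matrix,
            mk.UNIFORM_PRIOR, 9)
        rs1 = mk.root_state_resampling(tree, tips, "ER", reps=5, seed=4,
                                       refit=False)
        rs2 = mk.root_state_resampling(tree, tips, "ER", reps=5, seed=4,
                                       refit=False)
        assert np.allclose(rs1["mean"], rs2["mean"])
        assert ((rs1["mean"] >= 0) & (rs1["mean"] <= 1)).all()
        assert (rs1["sd"] >= 0).all()

    def test_guards(self):
        tree = trees.simulate_yule_tree(6, 1.0, 0)
        tips = {lb: 0 for lb in trees.tip_labels(tree)}
        with pytest.raises(InvalidArgumentError):
            mk.root_state_resampling(tree, tips, "ER", drop_frac=0.6, reps=5)
        with pytest.raises(InvalidArgumentError):
            mk.root_state_resampling(tree, tips, "ER", reps=1)
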