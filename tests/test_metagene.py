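import numpy as np
import pandas as pd
import pytest

from neumo.expression import ExpressionMatrix
from neumo.metagene import (
    MetageneSignature,
    StudyEffect,
    compare_scores,
    consensus_signature,
    expand_signature,
    majority_leading_edge,
    module_score_cells,
    pool_mean_differences,
    score_samples,
)
from neumo.simulate import simulate_cells


def _em(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestMajorityAndConsensus:
    def test_enumerated_majority(self):
        out = majority_leading_edge([{"a", "b"}, {"a", "c"}, {"a", "d"}], threshold=0.5)
        assert out == {"a"}  # only 'a' is in >= 2 of 3 sets

    def test_single_set_is_itself(self):
        assert majority_leading_edge([{"x", "y"}]) == {"x", "y"}

    def test_disjoint_sets_empty(self):
        assert majority_leading_edge([{"a"}, {"b"}, {"c"}], threshold=0.5) == frozenset()

    def test_even_count_boundary(self):
        # 2 of 6 sets is below the >=50% bound; 3 of 6 meets it exactly
        sets = [{"a", "b"}] * 3 + [{"c"}] * 3
        out = majority_leading_edge(sets, threshold=0.5)
        assert out == {"a", "b", "c"}
        assert majority_leading_edge(sets, threshold=0.5, strict=True) == frozenset()

    def test_consensus_commutative_idempotent(self):
        a, b = {"x", "y", "z"}, {"y", "z", "w"}
        s1 = consensus_signature(a, b)
        s2 = consensus_signature(b, a)
        assert s1.genes == s2.genes == {"y", "z"}
        assert consensus_signature(s1.genes, s1.genes).genes == s1.genes

    def test_disjoint_consensus_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            sig = consensus_signature({"a"}, {"b"})
        assert sig.genes == frozenset()


class TestScoreSamples:
    def test_constant_matrix(self):
        em = _em(np.full((3, 4), 2.5))
        sig = MetageneSignature("s", frozenset(["g0", "g1"]))
        sv = score_samples(em, sig)
        assert (sv.scores == 2.5).all()
        assert sv.n_genes_used == 2

    def test_arithmetic_mean(self):
        em = _em([[1.0], [3.0], [99.0]])
        sv = score_samples(em, MetageneSignature("s", frozenset(["g0", "g1"])))
        assert sv.scores.iloc[0] == 2.0

    def test_row_order_invariance(self, rng):
        vals = rng.normal(size=(20, 6))
        em = _em(vals)
        sig = MetageneSignature("s", frozenset([f"g{i}" for i in range(0, 20, 3)]))
        shuffled = em.values.sample(frac=1, random_state=1)
        em2 = ExpressionMatrix(shuffled)
        pd.testing.assert_series_equal(score_samples(em, sig).scores,
                                       score_samples(em2, sig).scores)

    def test_linearity(self, rng):
        vals = rng.normal(size=(10, 5))
        sig = MetageneSignature("s", frozenset(["g1", "g4", "g7"]))
        base = score_samples(_em(vals), sig).scores
        scaled = score_samples(_em(3.0 * vals + 2.0), sig).scores
        assert np.allclose(scaled, 3.0 * base + 2.0)

    def test_missing_policy(self):
        em = _em([[1.0, 2.0]])
        sig = MetageneSignature("s", frozenset(["g0", "absent"]))
        with pytest.warns(UserWarning, match="missing"):
            sv = score_samples(em, sig)
        assert sv.n_genes_used == 1
        with pytest.raises(ValueError, match="missing"):
            score_samples(em, sig, missing_policy="error")
        with pytest.raises(ValueError, match="no gene"):
            score_samples(em, MetageneSignature("s", frozenset(["absent"])))


class TestExpandSignature:
    def test_perfectly_correlated_gene_included(self, rng):
        vals = rng.normal(size=(5, 10))
        em = _em(vals)
        sig = MetageneSignature("s", frozenset(["g0", "g1"]))
        sv = score_samples(em, sig)
        # g0/g1 mean is the score itself; plant a copy and its negation
        em2 = ExpressionMatrix(pd.concat(
            [em.values,
             pd.DataFrame([sv.scores, -sv.scores], index=["copy", "anticopy"])]))
        out = expand_signature(em2, sv)
        assert "copy" in out and "anticopy" not in out

    def test_too_few_samples(self):
        em = _em(np.ones((3, 2)))
        sv = score_samples(em, MetageneSignature("s", frozenset(["g0"])))
        with pytest.raises(ValueError, match="3 samples"):
            expand_signature(em, sv)

    def test_planted_correlation_recovered(self, rng):
        n = 20
        driver = rng.normal(size=n)
        noise_genes = rng.normal(size=(50, n))
        correlated = 0.8 * driver + 0.4 * rng.normal(size=(30, n))  # r ~ 0.89
        vals = np.vstack([driver, correlated, noise_genes])
        genes = ["driver"] + [f"cor{i}" for i in range(30)] + [f"n{i}" for i in range(50)]
        em = _em(vals, genes=genes)
        sv = score_samples(em, MetageneSignature("s", frozenset(["driver"])))
        out = expand_signature(em, sv, r_min=0.7)
        sensitivity = len([g for g in out if g.startswith("cor")]) / 30
        assert sensitivity >= 0.9


class TestCompareScores:
    def _sv(self, values, samples):
        from neumo.metagene import ScoreVector

        return ScoreVector(pd.Series(values, index=samples), "s", 1)

    def test_identical_groups(self):
        sv = self._sv([1, 2, 3, 1, 2, 3], list("abcdef"))
        groups = dict(zip("abcdef", ["g1"] * 3 + ["g2"] * 3))
        delta, p, test = compare_scores(sv, groups)
        assert delta == 0.0
        assert p == pytest.approx(1.0)
        assert test == "wilcoxon_rank_sum"

    def test_exact_rank_sum_enumeration(self):
        # most extreme labeling of C(6,3)=20 arrangements: p = 2/20 = 0.1
        sv = self._sv([1, 2, 3, 10, 11, 12], list("abcdef"))
        groups = dict(zip("abcdef", ["g1"] * 3 + ["g2"] * 3))
        delta, p, _ = compare_scores(sv, groups)
        assert delta == pytest.approx(-9.0)
        assert p == pytest.approx(0.1)

    def test_paired_test_used_when_pairing_given(self):
        samples = [f"m{i}" for i in range(6)] + [f"c{i}" for i in range(6)]
        sv = self._sv(list(np.arange(6) + 2.0) + list(np.arange(6)), samples)
        groups = {s: ("MDSC" if s.startswith("m") else "Mono") for s in samples}
        pairs = {s: f"subj{s[1]}" for s in samples}
        delta, p, test = compare_scores(sv, groups, paired_by=pairs)
        assert test == "wilcoxon_signed_rank"
        assert delta == pytest.approx(2.0)
        assert p < 0.05

    def test_power_increases_with_shift(self, rng):
        pvals = []
        for shift in (0.0, 1.0, 2.0):
            a = rng.normal(size=30)
            b = rng.normal(size=30) + shift
            sv = self._sv(np.concatenate([a, b]),
                          [f"x{i}" for i in range(60)])
            groups = {f"x{i}": ("g1" if i < 30 else "g2") for i in range(60)}
            pvals.append(compare_scores(sv, groups)[1])
        assert pvals[0] > pvals[1] > pvals[2]


class TestPooling:
    def test_single_study_identity(self):
        s = StudyEffect("only", 5, 5, 2.0, 1.0, 0.5, 0.5)
        pe = pool_mean_differences([s])
        assert pe.effect == pytest.approx(s.mean_difference)
        assert pe.se == pytest.approx(np.sqrt(s.variance))
        assert pe.ci_low <= pe.effect <= pe.ci_high

    def test_two_identical_studies(self):
        s = StudyEffect("a", 5, 5, 2.0, 1.0, 0.5, 0.5)
        t = StudyEffect("b", 5, 5, 2.0, 1.0, 0.5, 0.5)
        pe = pool_mean_differences([s, t], model="random")
        assert pe.effect == pytest.approx(1.0)
        assert pe.tau2 == 0.0
        assert pe.se == pytest.approx(np.sqrt(s.variance) / np.sqrt(2))
        assert sum(pe.weights.values()) == pytest.approx(1.0)

    def test_random_ci_contains_fixed_ci(self):
        studies = [
            StudyEffect("a", 10, 10, 2.0, 1.0, 0.5, 0.5),
            StudyEffect("b", 10, 10, 0.2, 1.0, 0.5, 0.5),
            StudyEffect("c", 10, 10, 3.5, 1.0, 0.5, 0.5),
        ]
        fixed = pool_mean_differences(studies, model="fixed")
        random = pool_mean_differences(studies, model="random")
        assert random.tau2 > 0
        assert random.ci_high - random.ci_low >= fixed.ci_high - fixed.ci_low

    def test_matches_independent_meta_analysis(self):
        """DerSimonian-Laird pooling agrees with statsmodels' combine_effects."""
        from statsmodels.stats.meta_analysis import combine_effects

        studies = [
            StudyEffect("a", 10, 12, 2.0, 1.0, 0.5, 0.6),
            StudyEffect("b", 8, 9, 1.2, 1.0, 0.4, 0.5),
            StudyEffect("c", 20, 20, 1.8, 0.9, 0.7, 0.7),
        ]
        ref = combine_effects(
            np.array([s.mean_difference for s in studies]),
            np.array([s.variance for s in studies]), method_re="dl")
        mine = pool_mean_differences(studies, model="random")
        assert mine.effect == pytest.approx(float(ref.mean_effect_re))
        assert mine.tau2 == pytest.approx(float(ref.tau2))

    def test_degenerate_zero_variance(self):
        s = StudyEffect("a", 5, 5, 2.0, 1.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="zero variance"):
            pool_mean_differences([s])


class TestModuleScore:
    def test_simple_mode_constant_matrix(self):
        expr = pd.DataFrame(np.full((10, 6), 3.0),
                            columns=[f"g{i}" for i in range(6)])
        score = module_score_cells(expr, {"g0", "g1"}, n_ctrl=0)
        assert (score == 3.0).all()

    def test_separates_planted_states(self):
        pop = simulate_cells(n_cells=500, state_props=(0.5, 0.5), fold_up=8.0, seed=10)
        expr = np.log1p(pop.counts)
        score = module_score_cells(expr, pop.marker_sets["state0"],
                                   n_bins=10, n_ctrl=30, seed=0)
        in_state = score[pop.true_state == "state0"].to_numpy()
        out_state = score[pop.true_state == "state1"].to_numpy()
        # AUC of the score as a classifier of the true state
        from sklearn.metrics import roc_auc_score

        y = np.concatenate([np.ones(in_state.size), np.zeros(out_state.size)])
        assert roc_auc_score(y, np.concatenate([in_state, out_state])) >= 0.9

    def test_determinism(self, rng):
        expr = pd.DataFrame(rng.poisson(2.0, size=(40, 50)),
                            columns=[f"g{i}" for i in range(50)]).astype(float)
        a = module_score_cells(expr, {"g0", "g5", "g9"}, seed=3)
        b = module_score_cells(expr, {"g0", "g5", "g9"}, seed=3)
        pd.testing.assert_series_equal(a, b)

    def test_no_module_gene_errors(self):
        expr = pd.DataFrame(np.ones((4, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="no module gene"):
            module_score_cells(expr, {"zzz"})
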