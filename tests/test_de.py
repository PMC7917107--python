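import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heterosis.de import (
    CallThresholds,
    bh_adjust,
    call_differential,
    estimate_dispersion,
    make_mpv_pseudosamples,
    nb_wald_test,
)
from conftest import triad_from_means
from oracles import oracle_bh, oracle_nb_wald_p

UNIT3 = np.ones(3)


def _nb(rng, mu, alpha, size):
    if alpha == 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), size=size)


class TestDispersion:
    def test_poisson_counts_give_near_zero_alpha(self):
        rng = np.random.default_rng(0)
        mu = 10 ** rng.uniform(1, 3, 1000)
        a = _nb(rng, mu[:, None], 0.0, (1000, 3))
        b = _nb(rng, mu[:, None], 0.0, (1000, 3))
        alpha = estimate_dispersion(a, b, UNIT3, UNIT3)
        assert np.median(alpha) <= 0.01

    def test_true_alpha_recovered_at_ten_reps(self):
        rng = np.random.default_rng(1)
        mu = 10 ** rng.uniform(1.5, 3, 1000)
        a = _nb(rng, mu[:, None], 0.2, (1000, 10))
        b = _nb(rng, mu[:, None], 0.2, (1000, 10))
        alpha = estimate_dispersion(a, b, np.ones(10), np.ones(10))
        assert 0.1 <= np.median(alpha) <= 0.3

    def test_constant_counts_floored(self):
        a = np.full((1, 3), 50)
        b = np.full((1, 3), 50)
        alpha = estimate_dispersion(a, b, UNIT3, UNIT3)
        assert alpha[0] == pytest.approx(1e-8)

    def test_all_zero_feature_untestable(self):
        a = np.zeros((1, 3))
        b = np.zeros((1, 3))
        alpha = estimate_dispersion(a, b, UNIT3, UNIT3)
        assert np.isnan(alpha[0])


class TestWald:
    def test_identical_groups_null(self):
        a = np.array([[100, 100, 100]])
        res = nb_wald_test(a, a.copy(), UNIT3, UNIT3, np.array([0.05]))
        assert res["log2fc"].iloc[0] == 0.0
        assert res["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_doubling_matches_hand_formula(self):
        """(100,100,100) vs (200,200,200), alpha=0: agrees with the
        independently coded longhand evaluation."""
        a = np.array([[100, 100, 100]])
        b = np.array([[200, 200, 200]])
        res = nb_wald_test(a, b, UNIT3, UNIT3, np.array([1e-8]))
        assert res["log2fc"].iloc[0] == pytest.approx(1.0, abs=0.01)
        expected_p = oracle_nb_wald_p([100, 100, 100], [200, 200, 200], 1e-8)
        assert res["p_raw"].iloc[0] == pytest.approx(expected_p, rel=1e-9)

    def test_oracle_agreement_random_features(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 500, (50, 3))
        b = rng.integers(0, 500, (50, 3))
        alpha = np.full(50, 0.07)
        res = nb_wald_test(a, b, UNIT3, UNIT3, alpha)
        for i in range(50):
            assert res["p_raw"].iloc[i] == pytest.approx(
                oracle_nb_wald_p(a[i], b[i], 0.07), rel=1e-9
            )

    def test_group_swap_negates_log2fc_preserves_p(self):
        rng = np.random.default_rng(4)
        a = rng.integers(1, 500, (30, 3))
        b = rng.integers(1, 500, (30, 3))
        alpha = np.full(30, 0.05)
        fwd = nb_wald_test(a, b, UNIT3, UNIT3, alpha)
        rev = nb_wald_test(b, a, UNIT3, UNIT3, alpha)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"])
        np.testing.assert_allclose(fwd["p_raw"], rev["p_raw"])

    def test_null_calibration(self):
        """Equal means, alpha=0.05, n=3: raw p<=0.05 fraction in [0.03, 0.07]."""
        rng = np.random.default_rng(1)
        mu = 10 ** rng.uniform(1, 3, 2000)
        a = _nb(rng, mu[:, None], 0.05, (2000, 3))
        b = _nb(rng, mu[:, None], 0.05, (2000, 3))
        alpha = estimate_dispersion(a, b, UNIT3, UNIT3)
        res = nb_wald_test(a, b, UNIT3, UNIT3, alpha)
        frac = (res["p_raw"] <= 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_monotone_power_in_effect_size(self):
        """Recall is non-decreasing in the planted |log2fc| (0.5, 1, 2)."""
        rng = np.random.default_rng(5)
        thresholds = CallThresholds()
        recalls = []
        for lfc in (0.5, 1.0, 2.0):
            mu_a = 10 ** rng.uniform(1.5, 2.5, 500)
            mu_b = mu_a * 2**lfc
            a = _nb(rng, mu_a[:, None], 0.05, (500, 3))
            b = _nb(rng, mu_b[:, None], 0.05, (500, 3))
            alpha = estimate_dispersion(a, b, UNIT3, UNIT3)
            res = nb_wald_test(a, b, UNIT3, UNIT3, alpha)
            recalls.append(call_differential(res, thresholds)["called"].mean())
        assert recalls[0] <= recalls[1] <= recalls[2]
        assert recalls[2] >= 0.8


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.03])), [0.03])

    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    def test_nan_excluded_from_m(self):
        adj = bh_adjust(np.array([0.01, np.nan, 0.02]))
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]], oracle_bh([0.01, 0.02]))

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_textbook_oracle_and_dominates_raw(self, p):
        adj = bh_adjust(np.array(p))
        np.testing.assert_allclose(adj, oracle_bh(p), atol=1e-12)
        assert (adj >= np.array(p) - 1e-12).all()


class TestMpv:
    def test_identical_parents_mpv_equals_parent(self, toy_matrix):
        m = toy_matrix
        m.counts[m.samples_for("P2", "S")] = m.counts[m.samples_for("P1", "S")].to_numpy()
        factors = pd.Series(1.0, index=m.sample_ids)
        aug = make_mpv_pseudosamples(m, "S", factors=factors)
        mpv_cols = aug.samples_for("MPV", "S")
        np.testing.assert_array_equal(
            aug.counts[mpv_cols].to_numpy(), m.counts[m.samples_for("P1", "S")].to_numpy()
        )

    def test_average_arithmetic(self):
        m = triad_from_means(100, 1, 300, n_features=5, n_reps=3, dispersion=0, seed=0)
        m.counts[m.samples_for("P1", "S")] = 100
        m.counts[m.samples_for("P2", "S")] = 300
        factors = pd.Series(1.0, index=m.sample_ids)
        aug = make_mpv_pseudosamples(m, "S", factors=factors)
        assert (aug.counts[aug.samples_for("MPV", "S")].to_numpy() == 200).all()

    def test_unequal_replicates_truncate_with_warning(self, toy_matrix):
        m = toy_matrix
        dropped = m.counts.drop(columns=["P2_S_r3"])
        meta = m.sample_meta.drop(index=["P2_S_r3"])
        from heterosis.io_formats import TriadCountMatrix

        m2 = TriadCountMatrix(counts=dropped, sample_meta=meta)
        with pytest.warns(UserWarning, match="unequal"):
            aug = make_mpv_pseudosamples(m2, "S", factors=pd.Series(1.0, index=m2.sample_ids))
        assert len(aug.samples_for("MPV", "S")) == 2

    def test_additive_features_null_nonadditive_called(self):
        """Additive truth -> F1 vs MPV near-uniform p; fold-4 nonadditive
        truth -> >= 80% called at the default thresholds.

        Unit size factors are supplied: every feature in this fixture
        shares one mean triple, so data-driven normalization would be
        confounded with the planted genotype effect.
        """
        from heterosis.de import run_triad_de

        # additive: F1 exactly at the mid-parent
        m = triad_from_means(400, 250, 100, n_features=400, n_reps=3, dispersion=0.05, seed=8)
        unit = pd.Series(1.0, index=m.sample_ids)
        de = run_triad_de(m, "S", factors=unit)
        called = call_differential(de.results["F1_vs_MPV"], CallThresholds())
        assert called["called"].mean() < 0.15
        # nonadditive: F1 at 4x the mid-parent
        m2 = triad_from_means(400, 1000, 100, n_features=400, n_reps=3, dispersion=0.05, seed=9)
        unit2 = pd.Series(1.0, index=m2.sample_ids)
        de2 = run_triad_de(m2, "S", factors=unit2)
        called2 = call_differential(de2.results["F1_vs_MPV"], CallThresholds())
        assert called2["called"].mean() >= 0.8


class TestCallThresholds:
    def test_fold_just_below_threshold_not_called(self):
        res = pd.DataFrame(
            {
                "feature_id": ["x"],
                "log2fc": [np.log2(1.49)],
                "p_raw": [0.001],
                "p_adj": [0.001],
            }
        )
        assert not call_differential(res, CallThresholds())["called"].iloc[0]

    def test_exact_thresholds_inclusive(self):
        res = pd.DataFrame(
            {
                "feature_id": ["x", "y"],
                "log2fc": [np.log2(1.5), -np.log2(1.5)],
                "p_raw": [0.05, 0.05],
                "p_adj": [0.05, 0.05],
            }
        )
        out = call_differential(res, CallThresholds())
        assert out["called"].all()
        assert list(out["direction"]) == ["up", "down"]

    def test_adjusted_mode_uses_p_adj(self):
        res = pd.DataFrame(
            {"feature_id": ["x"], "log2fc": [2.0], "p_raw": [0.01], "p_adj": [0.2]}
        )
        assert call_differential(res, CallThresholds())["called"].iloc[0]
        assert not call_differential(res, CallThresholds(use_adjusted=True))["called"].iloc[0]

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError, match="min_fold"):
            call_differential(pd.DataFrame(), CallThresholds(min_fold=0.9))
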