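"""Transfer-selection metrics: sensitivities, contributions, elasticities,
fertility equivalents, mean ages and cumulative shares."""

import numpy as np
import pytest

import transferforce as tf
from transferforce.selection import cumulative_share, mean_age, mean_ages


def flat_social(omega, r=0.2, k=0.5):
    return tf.SocialProfile(r_x=np.full(omega + 1, r), k=k)


class TestProductionSensitivity:
    def test_full_defection_kills_transfers(self, human_state):
        s = tf.production_sensitivity(human_state, flat_social(human_state.lh0.omega, k=0.0))
        assert np.all(s == 0.0)

    def test_benchmark_scaling(self, human_state, offspring_social):
        # r = 0.5, k = 1 removes the social discount entirely
        s = tf.production_sensitivity(human_state, offspring_social)
        S = tf.recipient_sum(human_state)
        expected = S * human_state.survivorship() / human_state.total_demand()
        np.testing.assert_allclose(s, expected, rtol=1e-12)
        assert np.all(s >= 0)

    def test_linearity_in_k_and_relatedness(self, human_state):
        omega = human_state.lh0.omega
        base = tf.production_sensitivity(human_state, flat_social(omega, r=0.1, k=0.5))
        double_r = tf.production_sensitivity(human_state, flat_social(omega, r=0.2, k=0.5))
        double_k = tf.production_sensitivity(human_state, flat_social(omega, r=0.1, k=1.0))
        np.testing.assert_allclose(double_r, 2 * base, rtol=1e-12)
        np.testing.assert_allclose(double_k, 2 * base, rtol=1e-12)


class TestIndirectContribution:
    def test_no_production_no_contribution(self):
        out = tf.indirect_contribution(np.array([0.0, 5.0]), np.array([1e-6, 1e-6]))
        assert out[0] == 0.0 and out[1] > 0

    def test_donor_age_factorization(self, human_state, offspring_social):
        # Delta-lambda_Px / (P_x l_x r~_x) is donor-independent under flat k
        rep = tf.selection_report(human_state, offspring_social)
        denom = rep.P_x * rep.l_x
        ok = denom > 0
        ratio = rep.dlambda_Px[ok] / denom[ok]
        assert np.ptp(ratio) <= 1e-12 * np.abs(ratio).max()

    def test_post50_share_social_invariant(self, human_state):
        # flat r_x and k change the magnitude, not the age distribution
        omega = human_state.lh0.omega
        a = tf.selection_report(human_state, flat_social(omega, r=0.5, k=1.0))
        b = tf.selection_report(human_state, flat_social(omega, r=0.1, k=0.3))
        np.testing.assert_allclose(
            a.indirect_shares((50,)), b.indirect_shares((50,)), rtol=1e-10
        )
        # and that share equals the survivorship-weighted production share
        np.testing.assert_allclose(
            a.indirect_shares((50,)),
            tf.cumulative_shares(a.P_x * a.l_x, (50,)),
            rtol=1e-10,
        )


class TestProductionElasticity:
    def test_rescaling_preserves_total_and_peak(self, human_state, offspring_social):
        rep = tf.selection_report(human_state, offspring_social)
        assert rep.e_Px_scaled.sum() == pytest.approx(rep.e_mx.sum(), abs=1e-10)
        assert np.argmax(rep.e_Px_scaled) == np.argmax(rep.e_Px_raw)

    def test_degenerate_production_warns(self):
        with pytest.warns(UserWarning):
            raw, scaled = tf.production_elasticity(
                np.zeros(3), np.zeros(3), 1.0, np.array([0.1, 0.2, 0.0])
            )
        assert np.all(scaled == 0)


class TestFertilityEquivalent:
    def test_defining_identity(self, human_state, offspring_social):
        rep = tf.selection_report(human_state, offspring_social)
        ok = np.isfinite(rep.m_star)
        np.testing.assert_allclose(
            rep.s_mx[ok] * rep.m_star[ok], rep.s_Px[ok] * rep.P_x[ok], rtol=1e-10
        )

    def test_tfr50_linear_in_k(self, human_state):
        omega = human_state.lh0.omega
        t1 = tf.selection_report(human_state, flat_social(omega, k=0.5)).tfr50
        t2 = tf.selection_report(human_state, flat_social(omega, k=1.0)).tfr50
        assert t2 == pytest.approx(2 * t1, rel=1e-10)

    def test_window_truncated_at_omega(self):
        m_star = np.ones(61)  # omega = 60 < 80
        assert tf.tfr50(m_star) == pytest.approx(2 * 11)  # ages 50..60


class TestMeanAgesAndShares:
    def test_point_mass_recovers_the_age(self):
        m = np.zeros(50)
        m[23] = 0.4
        assert mean_age(m) == 23

    def test_uniform_schedule_centers(self):
        P = np.ones(81)
        assert mean_age(P) == pytest.approx(40.0)

    def test_weighting_modes(self, human_state, offspring_social):
        rep = tf.selection_report(human_state, offspring_social)
        xM_f, xP_f, xD_f = rep.mean_ages("formula")
        xM_s, xP_s, xD_s = rep.mean_ages("survivorship")
        # survivorship weighting shifts every mean age younger
        assert xM_s < xM_f and xP_s < xP_f and xD_s < xD_f
        with pytest.raises(ValueError):
            mean_ages(rep.m_x, rep.P_x, rep.D_x, weighting="nonsense")

    def test_share_boundaries_and_monotonicity(self, human_state, offspring_social):
        rep = tf.selection_report(human_state, offspring_social)
        vals = rep.P_x * rep.l_x
        assert cumulative_share(vals, -1) == 1.0
        assert cumulative_share(vals, rep.ages[-1]) == 0.0
        shares = tf.cumulative_shares(vals, range(-1, rep.ages[-1] + 1))
        assert np.all(np.diff(shares) <= 1e-15)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            cumulative_share(np.zeros(5), 2)


class TestReportAssembly:
    def test_report_shapes_and_columns(self, human_state, offspring_social):
        rep, pv, table, summary = tf.run_pipeline(human_state, offspring_social)
        n = human_state.lh0.omega + 1
        assert len(table) == n
        assert list(table.columns) == [
            "age", "px", "mx", "Px", "Dx", "lx", "s_mx", "s_px", "e_mx",
            "e_px_scaled", "dlambda_Px", "m_star", "RV", "PV",
        ]
        assert summary["r"] == pytest.approx(0.01, abs=1e-8)

    def test_social_profile_length_checked(self, human_state):
        with pytest.raises(ValueError):
            tf.selection_report(human_state, tf.SocialProfile(r_x=np.full(3, 0.2), k=1.0))
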