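import numpy as np
import pytest

from rcnoise.calibration import CalibrationTarget, calibrated_modules
from rcnoise.circuits import (
    CircuitState,
    ResourceContext,
    birth_death_network,
    build_network,
    translation_propensity,
)
from rcnoise.lna import (
    decompose,
    lna_covariance,
    lna_summary,
    noise_vs_rfp_mean,
    rc_fraction_kp_sweep,
    rc_noise_fraction,
    susceptibilities,
    sweep_jp,
)


def test_birth_death_variance_equals_mean():
    net = birth_death_network(k=5.0, d=1.0)
    C = lna_covariance(net)
    assert C[0, 0] == pytest.approx(5.0, rel=1e-12)


def test_unlimited_cascade_matches_symbolic_lyapunov(default_ur):
    """Two-stage cascade CV^2(P) = 1/P + (1/m) * d_p/(d_m+d_p).

    The closed form is re-derived here symbolically from the Lyapunov
    equation, independently of the numerical solver.
    """
    import sympy as sp

    k_m, k_p, d_m, d_p = sp.symbols("k_m k_p d_m d_p", positive=True)
    m, P = k_m / d_m, k_p * k_m / (d_m * d_p)
    A = sp.Matrix([[-d_m, 0], [k_p, -d_p]])
    D = sp.Matrix([[k_m + d_m * m, 0], [0, k_p * m + d_p * P]])
    C = sp.Matrix(sp.symbols("c11 c12 c12 c22")).reshape(2, 2)
    sol = sp.solve(A * C + C * A.T + D, [C[0, 0], C[0, 1], C[1, 1]], dict=True)[0]
    cv2_sym = sp.simplify(sol[C[1, 1]] / P**2 - (1 / P + (1 / m) * d_p / (d_m + d_p)))
    assert cv2_sym == 0

    mods, ctx = default_ur
    s = lna_summary(build_network(mods, ctx))
    expected = 1.0 / 100.0 + (1.0 / 10.0) * 0.1 / 1.1
    assert s["cv2"]["P1"] == pytest.approx(expected, rel=1e-12)


def test_competitive_covariance_is_negative(default_rc):
    s = lna_summary(build_network(*default_rc))
    assert s["corr_P1P2"] < 0


class TestSusceptibilities:
    def test_unlimited_values(self):
        H21, H23 = susceptibilities(ResourceContext("UNLIMITED"),
                                    CircuitState(10, 10, 0, 0))
        assert (H21, H23) == (-1.0, 0.0)

    def test_symmetric_competitive_closed_form(self):
        ctx = ResourceContext("COMPETITIVE", J_p=10.0)
        H21, H23 = susceptibilities(ctx, CircuitState(10, 10, 0, 0))
        assert H21 == pytest.approx(-2.0 / 3.0)
        assert H23 == pytest.approx(1.0 / 3.0)

    @pytest.mark.parametrize("mode,frozen", [
        ("COMPETITIVE", None),
        ("ORTHOGONAL", None),
        ("FROZEN_CROSS", (7.0, 9.0)),
    ])
    def test_closed_forms_match_numerical_log_derivative(self, mode, frozen):
        ctx = ResourceContext(mode, J_p=6.0, frozen_means=frozen)
        mods = calibrated_modules(CalibrationTarget.symmetric(8.0, 50.0), ctx,
                                  check=False)
        m1, m2 = 8.0, 12.0
        H21, H23 = susceptibilities(ctx, CircuitState(m1, m2, 0, 0))
        h = 1e-6

        def logf(lm1, lm2):
            st = CircuitState(np.exp(lm1), np.exp(lm2), 0, 0)
            return np.log(translation_propensity(0, st, ctx, mods))

        n21 = -(logf(np.log(m1) + h, np.log(m2)) - logf(np.log(m1) - h, np.log(m2))) / (2 * h)
        n23 = -(logf(np.log(m1), np.log(m2) + h) - logf(np.log(m1), np.log(m2) - h)) / (2 * h)
        assert H21 == pytest.approx(n21, abs=1e-6)
        assert H23 == pytest.approx(n23, abs=1e-6)

    def test_closed_forms_match_symbolic_differentiation(self):
        import sympy as sp

        m1, m2, J = sp.symbols("m1 m2 J", positive=True)
        f = m1 / (1 + (m1 + m2) / J)
        H21 = sp.simplify(-sp.diff(sp.log(f), m1) * m1 - (-(J + m2) / (J + m1 + m2)))
        H23 = sp.simplify(-sp.diff(sp.log(f), m2) * m2 - m2 / (J + m1 + m2))
        assert H21 == 0
        assert H23 == 0

    def test_unlimited_limit(self):
        """H21 -> -1 and H23 -> 0 as the translational capacity grows."""
        prev = None
        for J in (1e2, 1e4, 1e6, 1e8):
            H21, H23 = susceptibilities(ResourceContext("COMPETITIVE", J_p=J),
                                        CircuitState(10, 10, 0, 0))
            if prev is not None:
                assert abs(H21 + 1.0) < abs(prev[0] + 1.0)
                assert abs(H23) < abs(prev[1])
            prev = (H21, H23)
        assert abs(prev[0] + 1.0) < 1e-6
        assert abs(prev[1]) < 1e-6

    def test_zero_mrna_rejected(self):
        with pytest.raises(ValueError):
            susceptibilities(ResourceContext("COMPETITIVE"),
                             CircuitState(0.0, 10.0, 0, 0))


class TestDecomposition:
    @pytest.mark.parametrize("mode", ["UNLIMITED", "COMPETITIVE", "ORTHOGONAL",
                                      "FROZEN_CROSS"])
    def test_three_terms_close_the_full_lna_cv2(self, mode):
        """The birth/death + own-mRNA + cross-mRNA split is complete."""
        from rcnoise.presets import default_modules

        mods, ctx = default_modules(mode)
        dec = decompose(mods, ctx)
        full = lna_summary(build_network(mods, ctx))["cv2"]["P1"]
        assert dec.eta_total2 == pytest.approx(full, abs=1e-8, rel=1e-8)
        assert dec.eta_p2 == pytest.approx(1.0 / dec.P1, rel=1e-12)

    def test_unlimited_has_no_cross_term(self, default_ur):
        dec = decompose(*default_ur)
        assert dec.eta_rc2 == 0.0

    def test_competitive_has_three_positive_terms(self, default_rc):
        dec = decompose(*default_rc)
        assert dec.eta_p2 > 0 and dec.eta_m2 > 0 and dec.eta_rc2 > 0

    def test_mrna_variances_are_poissonian(self, default_rc):
        dec = decompose(*default_rc)
        assert dec.sigma_m1_2 == pytest.approx(dec.M1, rel=1e-10)


class TestCapacitySweep:
    def test_double_edged_dependence(self, default_rc):
        mods, ctx = default_rc
        grid = np.logspace(-0.5, 4.0, 40)
        df = sweep_jp(mods, ctx, grid)
        rc = df["eta_rc2"].to_numpy()
        own = df["eta_m2"].to_numpy()
        tot = df["eta_total2"].to_numpy()
        assert np.all(np.diff(rc) < 0), "cross term decays with capacity"
        assert np.all(np.diff(own) > 0), "own term grows toward the UR value"
        # own-mRNA term tends to the unlimited-resource value (H21 -> -1)
        ur_own = (df["sigma_m1_2"] / df["M1"] ** 2 * (0.1 / 1.1)).to_numpy()
        np.testing.assert_allclose(own[-1], ur_own[-1], rtol=3e-3)
        imin = int(np.argmin(tot))
        assert 0 < imin < len(tot) - 1, "total noise has an interior minimum"
        assert tot[0] > tot[imin] and tot[-1] > tot[imin]

    def test_mean_matched_competition_never_noisier_than_unlimited(self):
        """At matched means, sharing a finite pool can only reduce noise."""
        target = CalibrationTarget.symmetric(10.0, 100.0)
        ur = decompose(
            calibrated_modules(target, ResourceContext("UNLIMITED")),
            ResourceContext("UNLIMITED"))
        for J_p in np.logspace(-1, 4, 21):
            ctx = ResourceContext("COMPETITIVE", J_p=J_p)
            rc = decompose(calibrated_modules(target, ctx), ctx)
            assert rc.eta_total2 <= ur.eta_total2 + 1e-12
        assert rc.eta_total2 == pytest.approx(ur.eta_total2, rel=1e-3)


class TestRcFraction:
    def test_unlimited_fraction_is_zero(self, default_ur):
        assert rc_noise_fraction(*default_ur) == 0.0

    def test_high_rate_limit(self):
        """As k_p grows the birth/death term vanishes and the fraction
        approaches H23^2/(H21^2+H23^2)."""
        df = rc_fraction_kp_sweep([1e6], m_mean=10.0, J_p=2.0)
        limit = (10.0 / 22.0) ** 2 / ((12.0 / 22.0) ** 2 + (10.0 / 22.0) ** 2)
        assert df["rc_fraction"].iloc[0] == pytest.approx(limit, rel=1e-3)

    def test_strong_competition_fraction_exceeds_30_percent(self):
        df = rc_fraction_kp_sweep(np.logspace(-2, 2, 41), m_mean=10.0, J_p=2.0)
        assert df["rc_fraction"].max() > 0.30


class TestNoiseVsRfpMean:
    @pytest.fixture(scope="class")
    def table(self):
        return noise_vs_rfp_mean(np.linspace(0.0, 40.0, 9))

    def test_models_agree_without_rfp(self, table):
        at0 = table[table["g2"] == 0.0]
        rc, orr = at0[at0.model == "RC"], at0[at0.model == "OR"]
        assert rc["eta_total2"].iloc[0] == pytest.approx(
            orr["eta_total2"].iloc[0], rel=1e-10)

    def test_orthogonal_noise_flat_in_rfp(self, table):
        orr = table[table.model == "OR"]["eta_total2"].to_numpy()
        assert np.max(orr) - np.min(orr) < 1e-10 * np.max(orr)

    def test_competitive_noise_grows_with_rfp(self, table):
        rc = table[table.model == "RC"].sort_values("g2")["eta_total2"].to_numpy()
        assert np.all(np.diff(rc) > 0)
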