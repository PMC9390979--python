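import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rcnoise.circuits import (
    CircuitState,
    GeneModule,
    ResourceContext,
    ResourceMode,
    build_network,
    deterministic_steady_state,
    transcription_propensity,
    translation_propensity,
)
from rcnoise.controllers import ControllerSpec

from conftest import numeric_jacobian


def mods(g1=1.0, g2=1.0, k_m=10.0, k_p=1.0, d_m=1.0, d_p=0.1):
    return (GeneModule(g=g1, k_m=k_m, k_p=k_p, d_m=d_m, d_p=d_p),
            GeneModule(g=g2, k_m=k_m, k_p=k_p, d_m=d_m, d_p=d_p))


STATE = CircuitState(10.0, 10.0, 100.0, 100.0)


class TestPropensityLaws:
    @pytest.mark.parametrize("mode,J_g,expected", [
        ("UNLIMITED", None, 10.0),
        ("COMPETITIVE", 2.0, 5.0),            # 10/(1+(1+1)/2)
        ("ORTHOGONAL", 1.0, 5.0),             # 10/(1+1/1)
        ("COMPETITIVE", 1e12, 10.0),          # unlimited recovered as J_g -> inf
    ])
    def test_transcription(self, mode, J_g, expected):
        ctx = ResourceContext(mode, J_g=J_g) if J_g else ResourceContext(mode)
        assert transcription_propensity(0, STATE, ctx, mods()) == pytest.approx(expected)

    @pytest.mark.parametrize("mode,J_p,expected", [
        ("UNLIMITED", None, 10.0),
        ("COMPETITIVE", 10.0, 10.0 / 3.0),    # 10/(1+20/10)
        ("ORTHOGONAL", 10.0, 5.0),            # 10/(1+10/10)
        ("COMPETITIVE", 1e12, 10.0),          # unlimited recovered as J_p -> inf
    ])
    def test_translation(self, mode, J_p, expected):
        ctx = ResourceContext(mode, J_p=J_p) if J_p else ResourceContext(mode)
        assert translation_propensity(0, STATE, ctx, mods()) == pytest.approx(expected)

    def test_frozen_cross_uses_stored_mean(self):
        ctx = ResourceContext("FROZEN_CROSS", J_p=10.0, frozen_means=(4.0, 6.0))
        # module 0 sees the *other* module's frozen mean (6), not m2 itself
        st = CircuitState(10.0, 55.0, 0.0, 0.0)
        assert translation_propensity(0, st, ctx, mods()) == pytest.approx(
            10.0 / (1.0 + 16.0 / 10.0))

    def test_negative_state_rejected(self):
        bad = CircuitState(-1.0, 10.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="negative"):
            translation_propensity(0, bad, ResourceContext("COMPETITIVE"), mods())

    @pytest.mark.parametrize("kwargs", [
        {"mode": "COMPETITIVE", "J_p": 0.0},
        {"mode": "ORTHOGONAL", "J_g": 0.0},
        {"mode": "FROZEN_CROSS"},  # missing frozen means
    ])
    def test_invalid_context_rejected(self, kwargs):
        mode = kwargs.pop("mode")
        with pytest.raises(ValueError):
            ResourceContext(mode, **kwargs)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown resource mode"):
            ResourceContext("SEMI_LIMITED")

    @given(st.floats(min_value=0.0, max_value=60.0),
           st.floats(min_value=0.0, max_value=60.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_limited_below_unlimited_and_monotone_in_capacity(self, m1, m2):
        """RC propensities are bounded by the UR law and approach it
        monotonically as the capacity grows."""
        state = CircuitState(m1, m2, 0.0, 0.0)
        ur = translation_propensity(0, state, ResourceContext("UNLIMITED"), mods())
        prev = -1.0
        for J_p in (1.0, 10.0, 100.0, 1e4, 1e8):
            rc = translation_propensity(
                0, state, ResourceContext("COMPETITIVE", J_p=J_p), mods())
            assert rc <= ur + 1e-12
            assert rc >= prev - 1e-12
            prev = rc
        assert prev == pytest.approx(ur, rel=2e-6)


class TestNetworkConstruction:
    def test_base_network_shape(self):
        net = build_network(mods(), ResourceContext("UNLIMITED"))
        assert net.n_species == 4
        assert net.n_reactions == 8
        assert all((net.stoich[r] != 0).any() for r in range(net.n_reactions))

    def test_ncr_network_adds_inhibitors(self):
        net = build_network(mods(), ResourceContext("COMPETITIVE"),
                            ControllerSpec(ctype="NCR", placement="MIX"))
        assert set(net.species) == {"m1", "m2", "P1", "P2", "s1", "s2"}
        assert net.n_reactions == 12

    def test_construction_is_deterministic(self):
        a = build_network(mods(), ResourceContext("COMPETITIVE"))
        b = build_network(mods(), ResourceContext("COMPETITIVE"))
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.integers(0, 40, size=4).astype(float)
            np.testing.assert_array_equal(a.propensities(x), b.propensities(x))
        assert a.provenance == b.provenance

    @pytest.mark.parametrize("mode", ["UNLIMITED", "COMPETITIVE", "ORTHOGONAL"])
    @pytest.mark.parametrize("ctrl", [
        None,
        ControllerSpec(ctype="LOCAL", placement="MIL", S_c=3.0),
        ControllerSpec(ctype="GLOBAL", placement="PIX", S_c=3.0),
        ControllerSpec(ctype="NCR", placement="PIL", S_c=3.0),
    ])
    def test_analytic_jacobian_matches_finite_differences(self, mode, ctrl):
        """The hand-coded propensity gradients agree with numerics."""
        net = build_network(mods(), ResourceContext(mode), ctrl)
        rng = np.random.default_rng(7)
        for _ in range(3):
            x = rng.uniform(1.0, 30.0, size=net.n_species)
            J = net.jacobian(x)
            Jn = numeric_jacobian(net.drift, x)
            np.testing.assert_allclose(J, Jn, rtol=2e-5, atol=1e-7)


class TestSteadyState:
    def test_unlimited_linear_balance(self):
        net = build_network(mods(), ResourceContext("UNLIMITED"))
        st = deterministic_steady_state(net)
        assert st.m1 == pytest.approx(10.0)
        assert st.P1 == pytest.approx(100.0)

    def test_competitive_symmetric_value(self):
        # m* = 10 each, k_p = 1, d_p = 0.1, J_p = 10 -> P* = (10/3)/0.1
        net = build_network(mods(k_m=10.0), ResourceContext("COMPETITIVE", J_g=1e12))
        st = deterministic_steady_state(net)
        assert st.m1 == pytest.approx(10.0)
        assert st.P1 == pytest.approx(10.0 / 3.0 / 0.1, rel=1e-12)

    def test_large_capacity_matches_unlimited(self):
        rc = deterministic_steady_state(build_network(
            mods(), ResourceContext("COMPETITIVE", J_p=1e10, J_g=1e10)))
        ur = deterministic_steady_state(build_network(
            mods(), ResourceContext("UNLIMITED")))
        for f in ("m1", "m2", "P1", "P2"):
            assert getattr(rc, f) == pytest.approx(getattr(ur, f), rel=1e-8)

    def test_swap_symmetry(self):
        ctx = ResourceContext("COMPETITIVE")
        a = deterministic_steady_state(build_network(mods(g1=1.0, g2=3.0), ctx))
        b = deterministic_steady_state(build_network(mods(g1=3.0, g2=1.0), ctx))
        assert a.m1 == pytest.approx(b.m2, rel=1e-12)
        assert a.P2 == pytest.approx(b.P1, rel=1e-12)

    def test_frozen_cross_keeps_competitive_fixed_point(self, default_rc,
                                                        default_frozen):
        rc_state = deterministic_steady_state(build_network(*default_rc))
        fz_state = deterministic_steady_state(build_network(*default_frozen))
        for f in ("m1", "m2", "P1", "P2"):
            assert getattr(fz_state, f) == pytest.approx(
                getattr(rc_state, f), abs=1e-8)

    def test_controlled_fixed_point_residual(self, strong_rc):
        m, ctx = strong_rc
        net = build_network(m, ctx, ControllerSpec(ctype="NCR", placement="MIX"))
        st = deterministic_steady_state(net)
        x = st.as_array(net.species)
        assert np.max(np.abs(net.drift(x))) < 1e-10
        assert np.all(x >= 0)
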