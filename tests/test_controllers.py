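import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rcnoise.circuits import (
    CircuitState,
    ResourceContext,
    ResourceMode,
    build_network,
    deterministic_steady_state,
)
from rcnoise.controllers import (
    ControllerSpec,
    attach,
    controlled_point,
    decile_doses,
    deterministic_dose_response,
    effector,
    heatmap,
    mean_matched_network,
    normalized_noise,
    resolve,
    with_orthogonal,
)

ALL_CONFIGS = [(ct, pl) for ct in ("NCR", "LOCAL", "GLOBAL")
               for pl in ("MIX", "PIX", "MIL", "PIL")]


class TestEffector:
    def test_ncr_symmetric_partition(self):
        spec = ControllerSpec(ctype="NCR", placement="MIX", K_b=10.0,
                              dcas_total=50.0, alpha_s=1.0, K_e=10.0)
        state = CircuitState(10, 10, 0, 0, s1=10.0, s2=10.0)
        c1 = effector(spec, state, 0)
        assert c1 == pytest.approx(50.0 * 1.0 / 3.0)
        assert c1 == effector(spec, state, 1)

    @given(st.floats(0, 500), st.floats(0, 500))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_ncr_complexes_bounded_by_pool(self, s1, s2):
        spec = ControllerSpec(ctype="NCR", placement="MIX", K_b=10.0,
                              dcas_total=50.0, alpha_s=1.0, K_e=10.0)
        state = CircuitState(1, 1, 1, 1, s1=s1, s2=s2)
        total = effector(spec, state, 0) + effector(spec, state, 1)
        assert total <= 50.0 + 1e-9

    def test_global_inhibitor_tracks_summed_mediators(self):
        spec = ControllerSpec(ctype="GLOBAL", placement="MIX", alpha_s=1.0,
                              K_e=14.0)
        assert spec.inhibitor_means([10.0, 4.0, 0.0, 0.0]) == {"s1": 14.0}
        state = CircuitState(10, 4, 0, 0, s1=14.0)
        assert effector(spec, state, 0) == pytest.approx(14.0)
        assert effector(spec, state, 1) == pytest.approx(14.0)

    def test_negative_inhibitor_rejected(self):
        spec = ControllerSpec(ctype="LOCAL", placement="MIX", alpha_s=1.0,
                              K_e=10.0)
        with pytest.raises(ValueError):
            effector(spec, CircuitState(1, 1, 1, 1, s1=-1.0), 0)


class TestAttachment:
    @pytest.mark.parametrize("ct,pl", ALL_CONFIGS)
    def test_zero_strength_reproduces_base_propensities(self, strong_rc, ct, pl):
        mods, ctx = strong_rc
        base = build_network(mods, ctx)
        spec = resolve(ControllerSpec(ctype=ct, placement=pl, S_c=0.0), mods, ctx)
        ctrl = build_network(mods, ctx, spec)
        rng = np.random.default_rng(1)
        for _ in range(4):
            x = list(rng.uniform(0, 50, size=ctrl.n_species))
            a_ctrl = {r.name: r.law.value(x) for r in ctrl.reactions}
            a_base = {r.name: r.law.value(x[:4]) for r in base.reactions}
            for name, v in a_base.items():
                assert a_ctrl[name] == v

    def test_double_attachment_rejected(self, strong_rc):
        mods, ctx = strong_rc
        spec = ControllerSpec(ctype="LOCAL", placement="MIX")
        net = build_network(mods, ctx, spec)
        with pytest.raises(ValueError, match="already"):
            attach(net, spec)

    def test_attach_equals_build(self, strong_rc):
        mods, ctx = strong_rc
        spec = resolve(ControllerSpec(ctype="NCR", placement="MIL"), mods, ctx)
        a = attach(build_network(mods, ctx), spec)
        b = build_network(mods, ctx, spec)
        assert a.species == b.species
        x = np.arange(1.0, 1.0 + a.n_species)
        np.testing.assert_allclose(a.propensities(x), b.propensities(x))

    def test_monotone_onset_of_repression(self, strong_rc):
        """Without mean matching, small feedback lowers the controlled means."""
        mods, ctx = strong_rc
        base = deterministic_steady_state(build_network(mods, ctx))
        prev = base.P1
        for sc in (0.5, 1.0, 2.0):
            spec = ControllerSpec(ctype="LOCAL", placement="MIX", S_c=sc)
            st = deterministic_steady_state(build_network(mods, ctx, spec))
            assert st.P1 < prev
            prev = st.P1

    def test_mean_matched_network_restores_base_means(self, strong_rc):
        mods, ctx = strong_rc
        base = deterministic_steady_state(build_network(mods, ctx))
        for ct, pl in (("NCR", "MIX"), ("GLOBAL", "PIL"), ("LOCAL", "MIL")):
            spec = resolve(ControllerSpec(ctype=ct, placement=pl, S_c=14.0),
                           mods, ctx)
            st = deterministic_steady_state(mean_matched_network(spec, mods, ctx))
            for f in ("m1", "m2", "P1", "P2"):
                assert getattr(st, f) == pytest.approx(getattr(base, f), rel=1e-9)


class TestNormalizedNoise:
    @pytest.mark.parametrize("ct,pl", ALL_CONFIGS[:4])
    def test_zero_strength_gives_unity(self, strong_rc, ct, pl):
        mods, ctx = strong_rc
        spec = ControllerSpec(ctype=ct, placement=pl, S_c=0.0)
        assert normalized_noise(spec, mods, ctx, g2=2.0) == pytest.approx(1.0,
                                                                          rel=1e-9)

    def test_ncr_mil_strength_response_saturates(self, strong_rc):
        """At high RFP dose the NCR-MIL fold change falls with strength and
        flattens out beyond a certain point."""
        mods, ctx = strong_rc
        vals = [normalized_noise(
            ControllerSpec(ctype="NCR", placement="MIL", S_c=sc), mods, ctx,
            g2=40.0) for sc in (2.0, 5.0, 10.0, 20.0, 40.0)]
        assert np.all(np.diff(vals) < 0)
        drops = -np.diff(vals)
        assert drops[-1] < 0.25 * drops[0]

    def test_local_vs_ncr_efficacy_crossover(self, strong_rc):
        """NCR wins at low RFP dose, the local controller at high dose."""
        mods, ctx = strong_rc
        def diff(g2):
            ncr = normalized_noise(ControllerSpec(ctype="NCR", placement="MIL",
                                                  S_c=14.0), mods, ctx, g2=g2)
            loc = normalized_noise(ControllerSpec(ctype="LOCAL", placement="MIL",
                                                  S_c=14.0), mods, ctx, g2=g2)
            return ncr - loc
        doses = decile_doses(mods, ctx, n=8, g2_max=40.0, n_dense=40)
        diffs = [diff(g2) for g2 in doses]
        assert min(diffs) < 0 < max(diffs)

    def test_global_mil_amplifies_at_moderate_dose(self, strong_rc):
        mods, ctx = strong_rc
        spec = ControllerSpec(ctype="GLOBAL", placement="MIL", S_c=14.0)
        assert normalized_noise(spec, mods, ctx, g2=2.0) > 1.0


class TestHeatmapAndDoseResponse:
    def test_heatmap_zero_strength_row_is_unity(self, strong_rc):
        mods, ctx = strong_rc
        spec = ControllerSpec(ctype="NCR", placement="MIX")
        df = heatmap(spec, mods, ctx, g2_grid=[0.5, 2.0, 10.0],
                     sc_grid=[0.0, 5.0, 14.0])
        np.testing.assert_allclose(df.iloc[0].to_numpy(), 1.0, rtol=1e-9)

    def test_ncr_mil_has_amplifying_and_deep_reduction_regions(self, strong_rc):
        mods, ctx = strong_rc
        spec = ControllerSpec(ctype="NCR", placement="MIL")
        df = heatmap(spec, mods, ctx, g2_grid=[0.08, 40.0], sc_grid=[0.0, 14.0])
        assert df.loc[14.0, 0.08] > 1.0     # low RFP dose: noise increase
        assert df.loc[14.0, 40.0] < 0.9     # high RFP dose: solid reduction

    def test_ncr_mix_reduces_everywhere(self, strong_rc):
        mods, ctx = strong_rc
        spec = ControllerSpec(ctype="NCR", placement="MIX")
        df = heatmap(spec, mods, ctx, g2_grid=[0.3, 2.0, 40.0],
                     sc_grid=[5.0, 14.0])
        assert (df.to_numpy() < 1.0).all()

    def test_uncontrolled_slopes(self, default_ur, default_rc):
        grid = np.linspace(0.5, 10.0, 8)
        ur = deterministic_dose_response(None, *default_ur, g2_grid=grid)
        assert np.allclose(ur["slope"], 0.0, atol=1e-9)
        rc = deterministic_dose_response(None, *default_rc, g2_grid=grid)
        assert (rc["slope"] < 0).all()

    def test_controllers_flatten_the_coupling(self, strong_rc):
        """Mean-matched at a moderate reference dose, the MIL feedbacks
        reduce the magnitude of dGFP/dRFP around that point."""
        from dataclasses import replace

        mods, ctx = strong_rc
        ref = (mods[0], replace(mods[1], g=5.0))
        grid = np.array([4.8, 5.0, 5.2])
        base = deterministic_dose_response(None, ref, ctx, g2_grid=grid)
        s_base = abs(base["slope"].iloc[1])
        for ct in ("NCR", "LOCAL"):
            spec = ControllerSpec(ctype=ct, placement="MIL", S_c=14.0)
            df = deterministic_dose_response(spec, ref, ctx, g2_grid=grid)
            assert abs(df["slope"].iloc[1]) < s_base


class TestOrthogonalCombinations:
    @pytest.fixture(scope="class")
    def contexts(self):
        from rcnoise.presets import strong_competition

        mods, or_ctx = strong_competition(ResourceMode.ORTHOGONAL)
        rc_ctx = ResourceContext(ResourceMode.COMPETITIVE, J_p=or_ctx.J_p,
                                 J_g=or_ctx.J_g)
        return mods, or_ctx, rc_ctx

    def test_requires_orthogonal_context(self, contexts):
        mods, or_ctx, rc_ctx = contexts
        spec = ControllerSpec(ctype="LOCAL", placement="MIX")
        with pytest.raises(ValueError, match="ORTHOGONAL"):
            with_orthogonal(spec, mods, rc_ctx)

    def test_all_twelve_combinations_build(self, contexts):
        mods, or_ctx, _ = contexts
        for ct, pl in ALL_CONFIGS:
            spec = resolve(ControllerSpec(ctype=ct, placement=pl), mods, or_ctx)
            net = with_orthogonal(spec, mods, or_ctx)
            assert net.controller is spec

    def test_zero_strength_recovers_base_noise(self, contexts):
        mods, or_ctx, rc_ctx = contexts
        spec = ControllerSpec(ctype="LOCAL", placement="MIX", S_c=0.0)
        pt = controlled_point(spec, mods, or_ctx, g2=2.0, base_context=or_ctx)
        assert pt["norm_gfp_noise"] == pytest.approx(1.0, rel=1e-9)

    def test_orthogonal_resources_help_mix_but_not_mil_at_low_dose(self, contexts):
        """Against the competitive base, adding orthogonal resources improves
        the MIX controllers at every dose but hurts NCR-MIL at low dose."""
        mods, or_ctx, rc_ctx = contexts
        for ct in ("LOCAL", "NCR"):
            spec = ControllerSpec(ctype=ct, placement="MIX", S_c=14.0)
            for g2 in (1.0, 20.0):
                combo = controlled_point(spec, mods, or_ctx, g2=g2,
                                         base_context=rc_ctx)["norm_gfp_noise"]
                alone = controlled_point(spec, mods, rc_ctx, g2=g2,
                                         base_context=rc_ctx)["norm_gfp_noise"]
                assert combo < alone
        spec = ControllerSpec(ctype="NCR", placement="MIL", S_c=14.0)
        combo = controlled_point(spec, mods, or_ctx, g2=1.0,
                                 base_context=rc_ctx)["norm_gfp_noise"]
        alone = controlled_point(spec, mods, rc_ctx, g2=1.0,
                                 base_context=rc_ctx)["norm_gfp_noise"]
        assert combo > alone


class TestLnaAgainstStochasticSimulation:
    @pytest.mark.parametrize("ct,pl,g2", [
        ("NCR", "MIX", 2.0),
        ("LOCAL", "MIL", 20.0),
        ("GLOBAL", "PIX", 0.5),
    ])
    def test_controlled_lna_cv_matches_ssa(self, strong_rc, ct, pl, g2):
        """Spot-check the linearised noise against exact sampling at three
        corners of the controller grid."""
        from dataclasses import replace as drep

        from rcnoise.lna import lna_summary
        from rcnoise.ssa import simulate_summary

        mods, ctx = strong_rc
        spec = resolve(ControllerSpec(ctype=ct, placement=pl, S_c=14.0),
                       mods, ctx)
        net = mean_matched_network(spec, (mods[0], drep(mods[1], g=g2)), ctx)
        ref = lna_summary(net)["cv2"]["P1"]
        s = simulate_summary(net, t_end=900.0, burn_in=150.0, seed=77)
        cv2 = s.variance["P1"] / s.mean["P1"] ** 2
        # batch-means error on CV^2 is roughly twice the relative error of the
        # variance; accept 25% in this short spot-check
        assert cv2 == pytest.approx(ref, rel=0.25)
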