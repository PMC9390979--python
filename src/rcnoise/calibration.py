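"""Rate-constant calibration so different resource modes share the same means.

Comparing noise between the unlimited (UR), competitive (RC) and orthogonal
(OR) variants is only fair if they sit at identical stationary means; the
rate constants are therefore rescaled per mode.  Because transcription is
independent of the fluctuating state and translation is linear in its own
rate constant, the inversion is closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .circuits import (
    CircuitState,
    GeneModule,
    ResourceContext,
    ResourceMode,
    build_network,
    deterministic_steady_state,
    translation_propensity,
)

__all__ = [
    "CalibrationTarget",
    "CalibrationError",
    "match_means",
    "calibrated_modules",
    "frozen_context",
    "sweep_copy_number",
]


class CalibrationError(ValueError):
    """Requested stationary means are unreachable for the given context."""


@dataclass(frozen=True)
class CalibrationTarget:
    """Stationary mRNA and protein means (copies) per module."""

    m: tuple[float, float] = (10.0, 10.0)
    P: tuple[float, float] = (100.0, 100.0)

    def __post_init__(self):
        if any(v <= 0 for v in (*self.m, *self.P)):
            raise ValueError("calibration targets must be > 0")

    @classmethod
    def symmetric(cls, m_mean=10.0, p_mean=100.0) -> "CalibrationTarget":
        return cls((m_mean, m_mean), (p_mean, p_mean))


def _tx_share(i, context, g):
    mode = context.mode
    if mode is ResourceMode.UNLIMITED:
        return 1.0
    if mode is ResourceMode.ORTHOGONAL:
        return 1.0 / (1.0 + g[i] / context.J_g)
    return 1.0 / (1.0 + (g[0] + g[1]) / context.J_g)


def _tl_share(i, context, m):
    mode = context.mode
    if mode is ResourceMode.UNLIMITED:
        return 1.0
    if mode is ResourceMode.ORTHOGONAL:
        return 1.0 / (1.0 + m[i] / context.J_p)
    if mode is ResourceMode.FROZEN_CROSS:
        return 1.0 / (1.0 + (m[i] + context.frozen_means[1 - i]) / context.J_p)
    return 1.0 / (1.0 + (m[0] + m[1]) / context.J_p)


def match_means(target: CalibrationTarget, context: ResourceContext,
                d_m=1.0, d_p=0.1, g=(1.0, 1.0)):
    """Invert the mean-field balance for ``(k_m, k_p)`` per module.

    At fixed means the stationary conditions are linear in the rate
    constants: ``k_m = d_m*m*/(g*share_tx)`` and ``k_p = d_p*P*/(m**share_tl)``.
    Returns ``((k_m1, k_m2), (k_p1, k_p2))``.
    """
    g = tuple(float(v) for v in g)
    k_m, k_p = [], []
    for i in (0, 1):
        if g[i] <= 0:
            raise CalibrationError(
                f"module {i + 1}: positive means are unreachable with gene dose {g[i]}"
            )
        share_tx = _tx_share(i, context, g)
        share_tl = _tl_share(i, context, target.m)
        k_m.append(d_m * target.m[i] / (g[i] * share_tx))
        k_p.append(d_p * target.P[i] / (target.m[i] * share_tl))
    return tuple(k_m), tuple(k_p)


def calibrated_modules(target: CalibrationTarget, context: ResourceContext,
                       d_m=1.0, d_p=0.1, g=(1.0, 1.0), check=True):
    """Gene modules whose fixed point reproduces ``target`` in ``context``."""
    (km1, km2), (kp1, kp2) = match_means(target, context, d_m=d_m, d_p=d_p, g=g)
    mods = (
        GeneModule(g=g[0], k_m=km1, k_p=kp1, d_m=d_m, d_p=d_p),
        GeneModule(g=g[1], k_m=km2, k_p=kp2, d_m=d_m, d_p=d_p),
    )
    if check:
        st = deterministic_steady_state(build_network(mods, context))
        achieved = np.array([st.m1, st.m2, st.P1, st.P2])
        wanted = np.array([*target.m, *target.P])
        rel = np.max(np.abs(achieved - wanted) / wanted)
        if rel > 1e-8:
            raise CalibrationError(
                f"calibration failed: relative error {rel:.2e} at state {achieved}"
            )
    return mods


def frozen_context(context: ResourceContext, modules=None,
                   frozen_means=None) -> ResourceContext:
    """FROZEN_CROSS variant of a COMPETITIVE context.

    With no explicit ``frozen_means`` the stationary mRNA means of the
    competitive circuit are used, which leaves the deterministic fixed point
    untouched while severing the stochastic cross-mRNA channel.
    """
    if frozen_means is None:
        if modules is None:
            raise ValueError("either modules or frozen_means must be given")
        st = deterministic_steady_state(build_network(modules, context))
        frozen_means = (st.m1, st.m2)
    return ResourceContext(ResourceMode.FROZEN_CROSS, J_p=context.J_p,
                           J_g=context.J_g, frozen_means=tuple(frozen_means))


def sweep_copy_number(modules, context, g2_grid) -> pd.DataFrame:
    """Mean-field means as the RFP gene dose ``g2`` sweeps a grid.

    Module-1 constants stay fixed (a single up-front calibration); the point
    of the sweep is precisely the uncompensated competition effect.  The
    returned frame carries the asymptotic (dose -> infinity) RFP mean in
    ``df.attrs["rfp_mean_asymptote"]``.
    """
    rows = []
    for g2 in np.asarray(g2_grid, dtype=float):
        if g2 < 0:
            raise ValueError("gene doses must be >= 0")
        mods = (modules[0], replace(modules[1], g=g2))
        st = deterministic_steady_state(build_network(mods, context))
        rows.append({"g2": g2, "m1": st.m1, "m2": st.m2, "P1": st.P1, "P2": st.P2})
    df = pd.DataFrame(rows)

    mode = context.mode
    if mode is ResourceMode.UNLIMITED:
        asym = np.inf
    else:
        # dose -> infinity: transcription saturates at k_m*J_g.
        m2_inf = modules[1].k_m * context.J_g / modules[1].d_m
        m1_inf = 0.0 if mode is not ResourceMode.ORTHOGONAL else df["m1"].iloc[-1]
        st = CircuitState(m1_inf, m2_inf, 0.0, 0.0)
        ctx = context
        if mode is ResourceMode.FROZEN_CROSS:
            ctx = ResourceContext(mode, J_p=context.J_p, J_g=context.J_g,
                                  frozen_means=context.frozen_means)
        asym = translation_propensity(1, st, ctx, (modules[0], replace(modules[1], g=1.0))) \
            / modules[1].d_p
    df.attrs["rfp_mean_asymptote"] = float(asym)
    return df
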