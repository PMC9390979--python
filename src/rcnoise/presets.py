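"""Reference parameter sets used throughout the analyses.

All presets use an arbitrary time unit with mRNA turnover d_m = 1 as the
clock.  The *default* regime (mRNA mean 10, protein mean 100 per module,
J_p = 10, J_g = 20) gives strong competition at desk-scale copy numbers and
is the workhorse for the LNA/FDT sweeps.  The *strong-competition* regime
(J_p = 2, protein mean 1000) is used for trajectory-level anticorrelation:
there the protein birth/death noise is negligible, so the propagated,
resource-coupled component dominates and the two reporters are strongly
anticorrelated.  The *reduced* regime keeps the master-equation state space
tractable for exact cross-validation.
"""

from __future__ import annotations

from .calibration import CalibrationTarget, calibrated_modules, frozen_context
from .circuits import ResourceContext, ResourceMode

__all__ = [
    "DEFAULT_TARGET",
    "default_context",
    "default_modules",
    "strong_competition",
    "reduced_regime",
]

#: Default stationary means per module (copies).
DEFAULT_TARGET = CalibrationTarget.symmetric(10.0, 100.0)

#: Default degradation rates (1/time): mRNA lifetime 1, protein lifetime 10.
D_M, D_P = 1.0, 0.1

#: Default capacities: translational J_p in mRNA copies, transcriptional J_g
#: in gene-dose units.
J_P, J_G = 10.0, 20.0


def default_context(mode=ResourceMode.COMPETITIVE, J_p=J_P, J_g=J_G):
    mode = ResourceMode.coerce(mode)
    if mode is ResourceMode.FROZEN_CROSS:
        # Frozen at the default-target mRNA means: identical fixed point.
        return ResourceContext(mode, J_p=J_p, J_g=J_g,
                               frozen_means=DEFAULT_TARGET.m)
    return ResourceContext(mode, J_p=J_p, J_g=J_g)


def default_modules(mode=ResourceMode.COMPETITIVE, target=DEFAULT_TARGET,
                    J_p=J_P, J_g=J_G):
    """Modules calibrated to the default means under the given mode."""
    ctx = default_context(mode, J_p=J_p, J_g=J_g)
    return calibrated_modules(target, ctx, d_m=D_M, d_p=D_P), ctx


def strong_competition(mode=ResourceMode.COMPETITIVE):
    """Severely limited translation: J_p = 2, protein mean 1000.

    In this regime the stationary reporter cross-correlation predicted by the
    LNA is about -0.8; protein intrinsic noise is negligible against the
    propagated resource-competitive component, which is also the regime in
    which feedback control of the propagated noise is meaningful.  This is
    the base circuit for all controller analyses.
    """
    mode = ResourceMode.coerce(mode)
    target = CalibrationTarget.symmetric(10.0, 1000.0)
    if mode is ResourceMode.FROZEN_CROSS:
        ctx = ResourceContext(mode, J_p=2.0, J_g=J_G, frozen_means=target.m)
    else:
        ctx = ResourceContext(mode, J_p=2.0, J_g=J_G)
    return calibrated_modules(target, ctx, d_m=D_M, d_p=D_P), ctx


def reduced_regime(mode=ResourceMode.COMPETITIVE):
    """Small-copy regime for exact master-equation work.

    Means m* = 3, P* = 6 with J_p = 3 and d_p = 1: competition stays strong
    (the shared pool carries twice its capacity) while 5x-mean truncation
    caps keep the four-species state space near 2.5e5 states.
    """
    mode = ResourceMode.coerce(mode)
    target = CalibrationTarget.symmetric(3.0, 6.0)
    if mode is ResourceMode.FROZEN_CROSS:
        ctx = ResourceContext(mode, J_p=3.0, J_g=J_G, frozen_means=target.m)
    else:
        ctx = ResourceContext(mode, J_p=3.0, J_g=J_G)
    return calibrated_modules(target, ctx, d_m=1.0, d_p=1.0), ctx
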