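"""Linear-noise / fluctuation-dissipation analytics.

Around a stable mean-field fixed point ``x*`` the stationary covariance ``C``
of the copy-number fluctuations solves the continuous Lyapunov equation

    A C + C A^T + D = 0,

with ``A`` the drift Jacobian and ``D = sum_r a_r(x*) s_r s_r^T`` the
diffusion assembled from the reaction propensities and stoichiometries.

For the two-reporter circuit the GFP noise (squared coefficient of variation
of ``P1``) splits exactly into three sources, because the two mRNAs are
independent birth-death processes upstream of the proteins:

    eta_total^2 = eta_p^2 + eta_m^2 + eta_RC^2

    eta_p^2  = 1/P1                                  (protein birth/death)
    eta_m^2  = (sigma_m1^2/M1^2) * H21^2 * T(tau1)    (own mRNA, propagated)
    eta_RC^2 = (sigma_m2^2/M2^2) * H23^2 * T(tau3)    (opposing mRNA via the
                                                      shared ribosome pool)

where ``H2j = -d ln f1 / d ln m_j`` are the static susceptibilities of the
GFP translation propensity ``f1``, and ``T(tau) = (1/tau2)/(1/tau + 1/tau2)``
is the time-averaging factor with lifetimes ``tau1 = 1/d_m`` (gfp mRNA),
``tau2 = 1/d_p`` (GFP protein), ``tau3 = 1/d_m`` (rfp mRNA).  The
resource-competitive term ``eta_RC^2`` vanishes for unlimited, orthogonal and
frozen-cross variants; "noise" without qualification means the coefficient of
variation ``eta``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
from scipy import linalg

from .calibration import CalibrationTarget, calibrated_modules
from .circuits import (
    ReactionNetwork,
    ResourceContext,
    ResourceMode,
    build_network,
    deterministic_steady_state,
)

__all__ = [
    "NoiseDecomposition",
    "lna_covariance",
    "lna_summary",
    "susceptibilities",
    "decompose",
    "sweep_jp",
    "rc_noise_fraction",
    "rc_fraction_kp_sweep",
    "noise_vs_rfp_mean",
]


class UnstableFixedPointError(RuntimeError):
    """The mean-field fixed point is not linearly stable."""


def lna_covariance(network: ReactionNetwork, x_star=None, tol=1e-10) -> np.ndarray:
    """Stationary LNA covariance matrix of all species.

    Verifies linear stability (all Jacobian eigenvalues with negative real
    part) and the Lyapunov residual before returning.
    """
    if x_star is None:
        x_star = deterministic_steady_state(network)
        if hasattr(x_star, "as_array"):
            x_star = x_star.as_array(network.species)
    x_star = np.asarray(x_star, dtype=float)
    A = network.jacobian(x_star)
    eig = np.linalg.eigvals(A)
    if np.any(eig.real >= 0):
        raise UnstableFixedPointError(
            f"fixed point is not stable: Jacobian eigenvalues {eig}"
        )
    D = network.diffusion(x_star)
    C = linalg.solve_continuous_lyapunov(A, -D)
    C = 0.5 * (C + C.T)
    resid = np.max(np.abs(A @ C + C @ A.T + D))
    scale = max(1.0, np.max(np.abs(D)))
    if resid > tol * scale:
        raise RuntimeError(f"Lyapunov residual {resid:.2e} above tolerance")
    return C


def lna_summary(network: ReactionNetwork):
    """Fixed point, covariance, per-species CV^2 and the (P1,P2) correlation."""
    st = deterministic_steady_state(network)
    x = st.as_array(network.species)
    C = lna_covariance(network, x_star=x)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(x > 0, np.diag(C) / np.maximum(x, 1e-300) ** 2, np.nan)
    i1, i2 = network.index["P1"], network.index["P2"]
    denom = np.sqrt(C[i1, i1] * C[i2, i2])
    corr = C[i1, i2] / denom if denom > 0 else 0.0
    return {
        "state": st,
        "mean": dict(zip(network.species, x)),
        "cov": C,
        "cv2": dict(zip(network.species, cv2)),
        "corr_P1P2": float(corr),
    }


def susceptibilities(context: ResourceContext, fixed_point) -> tuple[float, float]:
    """Static susceptibilities (H21, H23) of the GFP translation propensity.

    ``H2j = -d ln f1 / d ln m_j`` evaluated at the fixed point.  Closed forms
    for the saturating sharing law (verified against numerical and symbolic
    differentiation in the test suite):

    - UNLIMITED:    H21 = -1,                          H23 = 0
    - COMPETITIVE:  H21 = -(J_p+m2)/(J_p+m1+m2),       H23 = m2/(J_p+m1+m2)
    - ORTHOGONAL:   H21 = -J_p/(J_p+m1),               H23 = 0
    - FROZEN_CROSS: H21 = -(J_p+mu2)/(J_p+m1+mu2),     H23 = 0

    Only the squares enter the noise decomposition, but the sign convention
    is fixed so that the unlimited-resource value is exactly -1.
    """
    m1 = float(getattr(fixed_point, "m1", None) if hasattr(fixed_point, "m1")
               else fixed_point[0])
    m2 = float(getattr(fixed_point, "m2", None) if hasattr(fixed_point, "m2")
               else fixed_point[1])
    if m1 <= 0 or m2 < 0:
        raise ValueError("susceptibilities need positive mRNA means")
    mode = context.mode
    if mode is ResourceMode.UNLIMITED:
        return -1.0, 0.0
    J = context.J_p
    if mode is ResourceMode.ORTHOGONAL:
        return -J / (J + m1), 0.0
    if mode is ResourceMode.FROZEN_CROSS:
        mu2 = context.frozen_means[1]
        return -(J + mu2) / (J + m1 + mu2), 0.0
    return -(J + m2) / (J + m1 + m2), m2 / (J + m1 + m2)


@dataclass(frozen=True)
class NoiseDecomposition:
    """Three-source decomposition of the GFP noise (all terms are CV^2)."""

    eta_p2: float
    eta_m2: float
    eta_rc2: float
    H21: float
    H23: float
    tau1: float
    tau2: float
    tau3: float
    sigma_m1_2: float
    sigma_m2_2: float
    M1: float
    M2: float
    P1: float

    @property
    def eta_total2(self) -> float:
        return self.eta_p2 + self.eta_m2 + self.eta_rc2

    @property
    def eta_total(self) -> float:
        return float(np.sqrt(self.eta_total2))

    def as_dict(self):
        d = asdict(self)
        d["eta_total2"] = self.eta_total2
        return d


def decompose(modules, context: ResourceContext) -> NoiseDecomposition:
    """FDT decomposition of the GFP (module 1) noise at the fixed point.

    The mRNA variances come from the LNA of the mRNA block rather than being
    assumed Poisson, so the decomposition stays valid for future variants
    with state-dependent transcription (for the present models the two
    coincide: constant gene doses make each mRNA a Poisson birth-death).
    """
    network = build_network(modules, context)
    st = deterministic_steady_state(network)
    x = st.as_array(network.species)
    C = lna_covariance(network, x_star=x)
    i_m1, i_m2 = network.index["m1"], network.index["m2"]
    sigma_m1_2, sigma_m2_2 = C[i_m1, i_m1], C[i_m2, i_m2]
    M1, M2, P1 = st.m1, st.m2, st.P1
    if P1 <= 0 or M1 <= 0:
        raise ValueError("decomposition requires positive GFP means")
    H21, H23 = susceptibilities(context, st)
    d_m1, d_m2 = modules[0].d_m, modules[1].d_m
    d_p = modules[0].d_p
    tau1, tau2, tau3 = 1.0 / d_m1, 1.0 / d_p, 1.0 / d_m2
    t_own = (1.0 / tau2) / (1.0 / tau1 + 1.0 / tau2)
    t_cross = (1.0 / tau2) / (1.0 / tau3 + 1.0 / tau2)
    eta_p2 = 1.0 / P1
    eta_m2 = (sigma_m1_2 / M1**2) * H21**2 * t_own
    eta_rc2 = 0.0 if M2 == 0 else (sigma_m2_2 / M2**2) * H23**2 * t_cross
    return NoiseDecomposition(
        eta_p2=eta_p2, eta_m2=eta_m2, eta_rc2=eta_rc2, H21=H21, H23=H23,
        tau1=tau1, tau2=tau2, tau3=tau3, sigma_m1_2=sigma_m1_2,
        sigma_m2_2=sigma_m2_2, M1=M1, M2=M2, P1=P1,
    )


def sweep_jp(modules, context: ResourceContext, jp_grid) -> pd.DataFrame:
    """Noise decomposition along a translational-capacity grid.

    Rate constants stay fixed across the sweep (no per-point recalibration):
    the curves show how a *given* circuit responds to more or fewer shared
    ribosomes, which is what makes the total noise non-monotone.
    """
    rows = []
    for jp in np.asarray(jp_grid, dtype=float):
        if jp <= 0:
            raise ValueError("J_p grid must be positive")
        ctx = replace(context, J_p=jp)
        dec = decompose(modules, ctx)
        row = {"J_p": jp, **dec.as_dict()}
        rows.append(row)
    return pd.DataFrame(rows)


def rc_noise_fraction(modules, context: ResourceContext) -> float:
    """Fraction of the total GFP noise variance carried by the RC term.

    Variance-fraction convention: ``eta_RC^2 / eta_total^2`` in [0, 1].
    """
    dec = decompose(modules, context)
    return float(dec.eta_rc2 / dec.eta_total2)


def rc_fraction_kp_sweep(kp_grid, m_mean=10.0, J_p=2.0, d_m=1.0, d_p=0.1,
                         J_g=1e9) -> pd.DataFrame:
    """RC-noise fraction along a translational-rate sweep at fixed mRNA means.

    The mRNA means are pinned (k_m chosen once for the target), J_g is left
    effectively unlimited, and k_p sweeps the grid; the protein mean, and with
    it the balance between the birth/death and propagated terms, moves with
    k_p.  Strong competition (small J_p against the total mRNA load) makes
    the RC share peak above 30% at high translational rates.
    """
    ctx = ResourceContext(ResourceMode.COMPETITIVE, J_p=J_p, J_g=J_g)
    base = calibrated_modules(
        CalibrationTarget.symmetric(m_mean, 1.0), ctx, d_m=d_m, d_p=d_p, check=False
    )
    rows = []
    for kp in np.asarray(kp_grid, dtype=float):
        mods = tuple(replace(m, k_p=float(kp)) for m in base)
        dec = decompose(mods, ctx)
        rows.append({
            "k_p": float(kp),
            "P1": dec.P1,
            "eta_p2": dec.eta_p2,
            "eta_m2": dec.eta_m2,
            "eta_rc2": dec.eta_rc2,
            "eta_total2": dec.eta_total2,
            "rc_fraction": dec.eta_rc2 / dec.eta_total2,
        })
    return pd.DataFrame(rows)


def noise_vs_rfp_mean(g2_grid, target=None, d_m=1.0, d_p=0.1, J_p=10.0,
                      J_g=20.0) -> pd.DataFrame:
    """GFP total noise versus achieved RFP mean, competitive vs orthogonal.

    Constants are calibrated once in the orthogonal model (the base for this
    comparison); the competitive variant reuses the identical constants, so
    the two circuits literally coincide when the RFP dose is zero and diverge
    as the dose grows.  Module-1 constants are never retuned along the sweep.
    """
    if target is None:
        target = CalibrationTarget.symmetric(10.0, 100.0)
    or_ctx = ResourceContext(ResourceMode.ORTHOGONAL, J_p=J_p, J_g=J_g)
    rc_ctx = ResourceContext(ResourceMode.COMPETITIVE, J_p=J_p, J_g=J_g)
    mods = calibrated_modules(target, or_ctx, d_m=d_m, d_p=d_p)
    rows = []
    for g2 in np.asarray(g2_grid, dtype=float):
        swept = (mods[0], replace(mods[1], g=g2))
        for label, ctx in (("RC", rc_ctx), ("OR", or_ctx)):
            dec = decompose(swept, ctx)
            rows.append({
                "model": label,
                "g2": g2,
                "rfp_mean": _protein2_mean(swept, ctx),
                "gfp_mean": dec.P1,
                "eta_p2": dec.eta_p2,
                "eta_m2": dec.eta_m2,
                "eta_rc2": dec.eta_rc2,
                "eta_total2": dec.eta_total2,
                "eta_total": dec.eta_total,
            })
    return pd.DataFrame(rows)


def _protein2_mean(modules, context):
    st = deterministic_steady_state(build_network(modules, context))
    return st.P2
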