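"""Negative-feedback controllers for the two-gene circuit.

Three controller types, each in four placements, give the 3x4 family:

types
    ``LOCAL``   — each module carries its own feedback loop (its mediator
                  represses itself).
    ``GLOBAL``  — one shared loop: the *sum* of both mediators represses both
                  modules.
    ``NCR``     — negatively competitive regulation: each module expresses an
                  inhibitory guide RNA at a rate tracking its mediator; the
                  two sgRNAs compete for a fixed pool of CRISPR moiety
                  (dCas9), and only the bound complex represses its own
                  module.  The pool is a conserved parameter, not a dynamic
                  species, and complex formation is a quasi-steady-state
                  partition of that pool.

placements (mediator x target)
    ``MIX`` mRNA represses transcription, ``PIX`` protein represses
    transcription, ``MIL`` mRNA represses translation, ``PIL`` protein
    represses translation.

Repression is non-cooperative and multiplicative: the targeted propensity is
scaled by ``1/(1 + S_c*E/K_e)`` with effector level ``E`` and a single
dimensionless strength knob ``S_c`` (``S_c = 0`` reproduces the uncontrolled
circuit exactly, state by state).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .circuits import (
    LinearEffector,
    PartitionEffector,
    FirstOrder,
    Reaction,
    ReactionNetwork,
    Repressed,
    ResourceContext,
    ResourceMode,
    build_network,
    deterministic_steady_state,
)

__all__ = [
    "ControllerType",
    "Placement",
    "ControllerSpec",
    "INHIBITOR_SCALE",
    "resolve",
    "effector",
    "attach",
    "controller_species",
    "mean_matched_network",
    "normalized_noise",
    "controlled_point",
    "heatmap",
    "deterministic_dose_response",
    "with_orthogonal",
    "decile_doses",
]


class ControllerType(enum.Enum):
    NCR = "NCR"
    LOCAL = "LOCAL"
    GLOBAL = "GLOBAL"

    @classmethod
    def coerce(cls, v):
        if isinstance(v, cls):
            return v
        try:
            return cls[str(v).upper()]
        except KeyError:
            raise ValueError(f"unknown controller type {v!r}") from None


class Placement(enum.Enum):
    MIX = "MIX"  # mRNA inhibits transcription
    PIX = "PIX"  # protein inhibits transcription
    MIL = "MIL"  # mRNA inhibits translation
    PIL = "PIL"  # protein inhibits translation

    @classmethod
    def coerce(cls, v):
        if isinstance(v, cls):
            return v
        try:
            return cls[str(v).upper()]
        except KeyError:
            raise ValueError(f"unknown controller placement {v!r}") from None

    @property
    def mediator_is_mrna(self) -> bool:
        return self in (Placement.MIX, Placement.MIL)

    @property
    def targets_transcription(self) -> bool:
        return self in (Placement.MIX, Placement.PIX)


@dataclass(frozen=True)
class ControllerSpec:
    """Controller type, placement and parameters.

    ``S_c`` is the dimensionless strength; ``K_e`` the effector
    half-inhibition scale (copies).  The NCR parameters are the sgRNA
    production coupling ``alpha_s`` (sgRNA copies tracked per mediator copy),
    sgRNA turnover ``d_s`` (1/time), the conserved dCas9 pool ``dcas_total``
    (copies) and the sgRNA-dCas9 binding scale ``K_b`` (copies).
    """

    ctype: ControllerType
    placement: Placement
    S_c: float = 14.0
    K_e: float | None = None
    alpha_s: float | None = None
    d_s: float = 1.0
    dcas_total: float = 50.0
    K_b: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "ctype", ControllerType.coerce(self.ctype))
        object.__setattr__(self, "placement", Placement.coerce(self.placement))
        self.validate()

    def validate(self):
        if self.S_c < 0:
            raise ValueError("controller strength S_c must be >= 0")
        if self.K_e is not None and self.K_e <= 0:
            raise ValueError("effector scale K_e must be > 0")
        if self.K_b is not None and self.K_b <= 0:
            raise ValueError("binding scale K_b must be > 0")
        if self.alpha_s is not None and self.alpha_s < 0:
            raise ValueError("inhibitor coupling alpha_s must be >= 0")
        if self.d_s <= 0:
            raise ValueError("inhibitor turnover d_s must be > 0")
        if self.ctype is ControllerType.NCR and self.dcas_total <= 0:
            raise ValueError("NCR requires a positive dCas9 pool")

    @property
    def is_resolved(self) -> bool:
        if self.K_e is None or self.alpha_s is None:
            return False
        if self.ctype is ControllerType.NCR and self.K_b is None:
            return False
        return True

    def mediator_indices(self, index) -> tuple[int, int]:
        if self.placement.mediator_is_mrna:
            return index["m1"], index["m2"]
        return index["P1"], index["P2"]

    def mediator_means(self, x_base) -> tuple[float, float]:
        """Mediator levels from a base [m1, m2, P1, P2] fixed point."""
        if self.placement.mediator_is_mrna:
            return float(x_base[0]), float(x_base[1])
        return float(x_base[2]), float(x_base[3])

    def inhibitor_means(self, x_base) -> dict:
        """Tracking means of the inhibitor species at a base fixed point."""
        med = self.mediator_means(x_base)
        if self.ctype is ControllerType.GLOBAL:
            return {"s1": self.alpha_s * (med[0] + med[1])}
        return {"s1": self.alpha_s * med[0], "s2": self.alpha_s * med[1]}

    def provenance(self) -> dict:
        return {
            "ctype": self.ctype.name,
            "placement": self.placement.name,
            "S_c": self.S_c,
            "K_e": self.K_e,
            "alpha_s": self.alpha_s,
            "d_s": self.d_s,
            "dcas_total": self.dcas_total,
            "K_b": self.K_b,
        }


#: Default stationary inhibitor abundance at the reference point (copies).
#: Inhibitory RNAs and repressor molecules are sparse species: a few tens of
#: copies, independent of whether their production tracks an mRNA (tens of
#: copies) or a protein (hundreds to thousands).  Their shot noise therefore
#: matters, and matters equally across placements.
INHIBITOR_SCALE = 30.0


def resolve(spec: ControllerSpec, modules, context) -> ControllerSpec:
    """Fill the controller scales from the reference-point circuit.

    Left unset, the scales are pinned to the stationary state of the
    *uncontrolled* circuit at the supplied reference modules:

    - ``alpha_s`` so the mean inhibitor abundance is :data:`INHIBITOR_SCALE`
      copies regardless of the mediator's copy-number scale;
    - ``K_b`` to the mean sgRNA level (NCR);
    - ``K_e`` to the resulting mean effector (inhibitor, shared inhibitor
      pool, or dCas9 complex).

    Every configuration then represses its target by exactly ``1/(1+S_c)``
    at the reference point, which makes ``S_c`` a dimensionless strength
    comparable across types, placements and copy-number scales.  Resolution
    happens once per analysis; dose or strength sweeps reuse the resolved
    scales.
    """
    from .circuits import _base_fixed_point

    if spec.is_resolved:
        return spec
    x0 = _base_fixed_point(modules, context)
    med = spec.mediator_means(x0)
    med_scale = 0.5 * (med[0] + med[1])
    if med_scale <= 0:
        raise ValueError("cannot resolve controller scales: mediator mean is zero")
    alpha_s = spec.alpha_s
    if alpha_s is None:
        alpha_s = INHIBITOR_SCALE / med_scale
    K_b = spec.K_b
    if spec.ctype is ControllerType.NCR and K_b is None:
        K_b = alpha_s * med_scale
    K_e = spec.K_e
    if K_e is None:
        if spec.ctype is ControllerType.LOCAL:
            K_e = alpha_s * med_scale
        elif spec.ctype is ControllerType.GLOBAL:
            K_e = alpha_s * (med[0] + med[1])
        else:
            u = (alpha_s * med[0] / K_b, alpha_s * med[1] / K_b)
            K_e = spec.dcas_total * 0.5 * (u[0] + u[1]) / (1.0 + u[0] + u[1])
    return replace(spec, K_e=K_e, K_b=K_b, alpha_s=alpha_s)


def _effectors(spec: ControllerSpec, index):
    """Per-module effector objects over the network's species indexing.

    All controller types act through an explicit inhibitor species (an
    sgRNA, small RNA or repressor molecule) whose production tracks the
    mediator; the effector therefore inherits the mediator's fluctuations
    plus its own birth/death noise and a tracking lag.  LOCAL and GLOBAL
    inhibitors act directly, the NCR inhibitors act only as dCas9 complexes
    partitioned from the conserved pool.
    """
    if spec.ctype is ControllerType.GLOBAL:
        shared = LinearEffector([(index["s1"], 1.0)])
        return [shared, shared]
    s1, s2 = index["s1"], index["s2"]
    if spec.ctype is ControllerType.LOCAL:
        return [LinearEffector([(s1, 1.0)]), LinearEffector([(s2, 1.0)])]
    return [
        PartitionEffector(s1, s2, spec.dcas_total, spec.K_b),
        PartitionEffector(s2, s1, spec.dcas_total, spec.K_b),
    ]


def controller_species(spec: ControllerSpec) -> list[str]:
    """Inhibitor species added by the controller (one shared for GLOBAL)."""
    return ["s1"] if spec.ctype is ControllerType.GLOBAL else ["s1", "s2"]


def wrap_laws(spec: ControllerSpec, tx_laws, tl_laws, index):
    """Apply the feedback to the targeted propensities; return extra reactions.

    Used by :func:`rcnoise.circuits.build_network`.  The inhibition wraps
    transcription (MIX/PIX) or translation (MIL/PIL) of *both* modules.  The
    inhibitor species are produced at rate ``alpha_s*d_s*mediator`` (for
    GLOBAL, the shared inhibitor collects both mediators) and decay at
    ``d_s``, so each tracks ``alpha_s`` times its driving mediator.
    """
    effs = _effectors(spec, index)
    if spec.placement.targets_transcription:
        tx_laws = [Repressed(tx_laws[i], effs[i], spec.S_c, spec.K_e) for i in (0, 1)]
    else:
        tl_laws = [Repressed(tl_laws[i], effs[i], spec.S_c, spec.K_e) for i in (0, 1)]

    med = spec.mediator_indices(index)
    extra = []
    if spec.ctype is ControllerType.GLOBAL:
        s1 = index["s1"]
        for i in (0, 1):
            extra.append(Reaction(
                f"inhibitor_production_m{i + 1}", ((s1, +1),),
                FirstOrder(spec.alpha_s * spec.d_s, med[i]),
            ))
        extra.append(Reaction("inhibitor_decay", ((s1, -1),),
                              FirstOrder(spec.d_s, s1)))
    else:
        for i in (0, 1):
            si = index[f"s{i + 1}"]
            extra.append(Reaction(
                f"inhibitor{i + 1}_production", ((si, +1),),
                FirstOrder(spec.alpha_s * spec.d_s, med[i]),
            ))
            extra.append(Reaction(
                f"inhibitor{i + 1}_decay", ((si, -1),),
                FirstOrder(spec.d_s, si),
            ))
    return tx_laws, tl_laws, extra


def effector(spec: ControllerSpec, state, module_index) -> float:
    """Effector level seen by module ``module_index`` (0 or 1) at ``state``.

    LOCAL: the module's own inhibitor ``s_i``; GLOBAL: the shared inhibitor
    ``s_1``; NCR: the dCas9 complex ``c_i`` partitioned from the conserved
    pool, ``c_i = dcas_total*(s_i/K_b)/(1 + s_1/K_b + s_2/K_b)``.
    """
    i = int(module_index)
    if i not in (0, 1):
        raise ValueError("module_index must be 0 or 1")
    s = (state.s1, state.s2)
    if s[0] < 0 or s[1] < 0:
        raise ValueError("effector needs non-negative inhibitor species")
    if spec.ctype is ControllerType.LOCAL:
        return float(s[i])
    if spec.ctype is ControllerType.GLOBAL:
        return float(s[0])
    if spec.K_b is None:
        raise ValueError("resolve() the controller before evaluating NCR effectors")
    u = (s[0] / spec.K_b, s[1] / spec.K_b)
    return float(spec.dcas_total * u[i] / (1.0 + u[0] + u[1]))


def attach(network: ReactionNetwork, spec: ControllerSpec) -> ReactionNetwork:
    """Augment an uncontrolled circuit network with a controller."""
    if network.controller is not None:
        raise ValueError("network already carries a controller")
    if network.modules is None or network.context is None:
        raise ValueError("attach requires a circuit network")
    return build_network(network.modules, network.context, spec)


def _with_dose(modules, g2):
    return (modules[0], replace(modules[1], g=float(g2)))


def _repression_factors(spec, modules, context, x_base):
    """Inhibition factors 1/(1+S_c*E/K_e) at the uncontrolled fixed point.

    For NCR the sgRNAs sit at their tracking means ``alpha_s * mediator``.
    """
    from .circuits import CircuitState

    sbar = spec.inhibitor_means(x_base)
    st = CircuitState(x_base[0], x_base[1], x_base[2], x_base[3],
                      s1=sbar.get("s1", 0.0), s2=sbar.get("s2", 0.0))
    out = []
    for i in (0, 1):
        E = effector(spec, st, i)
        out.append(1.0 / (1.0 + spec.S_c * E / spec.K_e))
    return out


def mean_matched_network(spec, modules, context) -> ReactionNetwork:
    """Controlled network rescaled so its means equal the uncontrolled ones.

    Noise comparisons in this package are made between circuits with
    identical stationary means (the same convention used to compare resource
    modes): after attaching the feedback, the targeted rate constants are
    divided by the repression factor at the uncontrolled fixed point, which
    restores that fixed point exactly — the balance equations are linear in
    the constants.  ``spec`` must carry resolved effector scales.
    """
    from .circuits import _base_fixed_point

    if not spec.is_resolved:
        raise ValueError("resolve() the controller before mean matching")
    x0 = _base_fixed_point(modules, context)
    I = _repression_factors(spec, modules, context, x0)
    if spec.placement.targets_transcription:
        mods = tuple(replace(m, k_m=m.k_m / I[i]) for i, m in enumerate(modules))
    else:
        mods = tuple(replace(m, k_p=m.k_p / I[i]) for i, m in enumerate(modules))
    return build_network(mods, context, spec)


def controlled_point(spec, modules, context, g2=1.0, base_context=None) -> dict:
    """LNA noise of the controlled circuit, normalised to the uncontrolled base.

    The base is the same circuit without a controller (optionally in another
    resource context, e.g. a competitive base for an orthogonal+controller
    combination).  Noise means the coefficient of variation.  The controlled
    circuit is mean-matched to the base at this dose, so the fold change
    isolates the feedback's effect on the noise structure.
    """
    from .lna import lna_summary

    base_context = base_context or context
    spec = resolve(spec, modules, context)  # scales pinned at the reference dose
    mods = _with_dose(modules, g2)
    base = lna_summary(build_network(mods, base_context))
    ctrl = lna_summary(mean_matched_network(spec, mods, context))

    def _cv(summary, name):
        v = summary["cv2"][name]
        return float(np.sqrt(v)) if v is not None else np.nan

    out = {
        "g2": float(g2),
        "rfp_mean_base": base["mean"]["P2"],
        "gfp_mean": ctrl["mean"]["P1"],
        "rfp_mean": ctrl["mean"]["P2"],
        "gfp_noise_base": _cv(base, "P1"),
        "gfp_noise": _cv(ctrl, "P1"),
        "rfp_noise_base": _cv(base, "P2"),
        "rfp_noise": _cv(ctrl, "P2"),
    }
    out["norm_gfp_noise"] = out["gfp_noise"] / out["gfp_noise_base"]
    from .metrics import total_system_noise

    tot_base = total_system_noise(out["gfp_noise_base"], out["rfp_noise_base"])
    tot = total_system_noise(out["gfp_noise"], out["rfp_noise"])
    out["norm_total_noise"] = tot / tot_base
    return out


def normalized_noise(spec, modules, context, g2=1.0, base_context=None) -> float:
    """Fold change of the GFP noise relative to the uncontrolled base."""
    return controlled_point(spec, modules, context, g2=g2,
                            base_context=base_context)["norm_gfp_noise"]


def heatmap(spec, modules, context, g2_grid, sc_grid, base_context=None,
            value="norm_gfp_noise") -> pd.DataFrame:
    """Normalised noise over the (RFP dose, controller strength) plane.

    Rows are controller strengths (the ``S_c = 0`` row is identically one),
    columns are doses; ``df.attrs['rfp_mean']`` maps each dose to the
    achieved base RFP mean.  Cells whose fixed point cannot be located are
    flagged as NaN rather than aborting the grid.
    """
    spec = resolve(spec, modules, context)
    sc_grid = np.asarray(sc_grid, dtype=float)
    g2_grid = np.asarray(g2_grid, dtype=float)
    out = np.full((sc_grid.size, g2_grid.size), np.nan)
    rfp = np.full(g2_grid.size, np.nan)
    for jc, g2 in enumerate(g2_grid):
        for ic, sc in enumerate(sc_grid):
            s = replace(spec, S_c=float(sc))
            try:
                pt = controlled_point(s, modules, context, g2=g2,
                                      base_context=base_context)
            except Exception:
                continue
            out[ic, jc] = pt[value]
            rfp[jc] = pt["rfp_mean_base"]
    df = pd.DataFrame(out, index=pd.Index(sc_grid, name="S_c"),
                      columns=pd.Index(g2_grid, name="g2"))
    df.attrs["rfp_mean"] = dict(zip(g2_grid, rfp))
    df.attrs["value"] = value
    return df


def deterministic_dose_response(spec, modules, context, g2_grid) -> pd.DataFrame:
    """Mean-field GFP level versus RFP level as the RFP dose sweeps.

    Returns the achieved (RFP, GFP) curve and its local slope dGFP/dRFP —
    the qualitative proxy for resource-competitive noise transfer (a
    shallower slope means weaker residual coupling).  The controlled circuit
    is mean-matched once, at the reference dose carried by ``modules``, and
    its constants are then held fixed along the sweep, so the curves of
    different controllers intersect at the reference point and fan out away
    from it.  ``spec=None`` gives the uncontrolled curve.
    """
    if spec is not None:
        spec = resolve(spec, modules, context)
        ref_net = mean_matched_network(spec, modules, context)
        ref_mods = ref_net.modules
    rows = []
    for g2 in np.asarray(g2_grid, dtype=float):
        if spec is not None:
            net = build_network(_with_dose(ref_mods, g2), context, spec)
        else:
            net = build_network(_with_dose(modules, g2), context)
        st = deterministic_steady_state(net)
        rows.append({"g2": g2, "rfp_mean": st.P2, "gfp_mean": st.P1})
    df = pd.DataFrame(rows)
    rfp = df["rfp_mean"].to_numpy()
    gfp = df["gfp_mean"].to_numpy()
    if np.all(np.diff(rfp) == 0):
        df["slope"] = 0.0
    else:
        df["slope"] = np.gradient(gfp, rfp, edge_order=1)
    return df


def with_orthogonal(spec, modules, or_context: ResourceContext) -> ReactionNetwork:
    """Controller on top of the orthogonal-resource rate laws."""
    if or_context.mode is not ResourceMode.ORTHOGONAL:
        raise ValueError("with_orthogonal requires an ORTHOGONAL context")
    return build_network(modules, or_context, spec)


def decile_doses(modules, context, n=10, g2_max=40.0, n_dense=200) -> np.ndarray:
    """RFP doses whose base-circuit RFP means sit at equally spaced deciles.

    The achieved RFP mean saturates in the dose, so comparisons between
    controllers are gridded uniformly in what is actually reached, not in the
    dose itself.
    """
    dense = np.linspace(0.0, g2_max, int(n_dense))
    means = []
    for g2 in dense:
        st = deterministic_steady_state(build_network(_with_dose(modules, g2), context))
        means.append(st.P2)
    means = np.asarray(means)
    targets = np.linspace(means[0], means[-1], int(n) + 1)[1:]
    return np.interp(targets, means, dense)
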