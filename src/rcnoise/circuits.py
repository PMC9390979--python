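"""Reaction networks for a two-reporter gene circuit with shared resources.

The circuit holds two identical, independently regulated genes (a GFP and an
RFP reporter) expressed in the same cell.  Each module transcribes an mRNA
(``m1``, ``m2``) and translates a protein (``P1``, ``P2``); both steps draw on
finite cellular machinery (RNA polymerases for transcription, ribosomes for
translation).  Sharing a finite pool couples the two modules: when one module
loads the pool, the effective rate of the other drops.

Four resource modes are supported:

``UNLIMITED``
    Idealised mass action — transcription ``k_m*g_i``, translation ``k_p*m_i``.
``COMPETITIVE``
    A single shared pool per step.  Propensities saturate in the *total* load:
    ``k*x_i / (1 + (x_1+x_2)/J)`` with capacity ``J`` (``J_g`` for gene dose at
    transcription, ``J_p`` for mRNA load at translation).
``ORTHOGONAL``
    Private pools per module.  Self-saturation is retained but the cross term
    is gone: ``k*x_i / (1 + x_i/J)``.
``FROZEN_CROSS``
    As ``COMPETITIVE``, except that inside each translation propensity the
    *opposing* mRNA copy number is pinned to a constant (normally its
    stationary mean).  This removes the stochastic cross-talk channel while
    leaving the deterministic mean field untouched — the standard trick for
    isolating the resource-competitive noise component.

Since the unshared gene doses are deterministic constants, the transcriptional
capacity ``J_g`` affects means only; all stochastic cross-coupling enters
through translation.

Networks are represented explicitly (species, stoichiometry, per-reaction
propensity laws with analytic gradients) so the same object drives the exact
Gillespie sampler, the truncated master-equation generator, the deterministic
mean field and the linear-noise Jacobian.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ResourceMode",
    "GeneModule",
    "ResourceContext",
    "CircuitState",
    "Reaction",
    "ReactionNetwork",
    "SteadyStateError",
    "transcription_propensity",
    "translation_propensity",
    "build_network",
    "deterministic_steady_state",
    "birth_death_network",
]


class ResourceMode(enum.Enum):
    """Resource-sharing topology of the two-gene circuit."""

    UNLIMITED = "UNLIMITED"
    COMPETITIVE = "COMPETITIVE"
    ORTHOGONAL = "ORTHOGONAL"
    FROZEN_CROSS = "FROZEN_CROSS"

    @classmethod
    def coerce(cls, value) -> "ResourceMode":
        if isinstance(value, cls):
            return value
        try:
            return cls[str(value).upper()]
        except KeyError:
            raise ValueError(
                f"unknown resource mode {value!r}; expected one of "
                f"{[m.name for m in cls]}"
            ) from None


#: Modes in which the capacities J_p / J_g actually constrain the rates.
LIMITED_MODES = frozenset(
    {ResourceMode.COMPETITIVE, ResourceMode.ORTHOGONAL, ResourceMode.FROZEN_CROSS}
)


@dataclass(frozen=True)
class GeneModule:
    """Kinetic constants of one reporter module.

    Parameters
    ----------
    g : float
        Effective gene copy number (plasmid dose), dimensionless, >= 0.
    k_m : float
        Transcription rate constant per unit gene dose (copies/time).
    k_p : float
        Translation rate constant per mRNA (1/time).
    d_m, d_p : float
        mRNA / protein degradation rates (1/time), strictly positive.
    """

    g: float = 1.0
    k_m: float = 10.0
    k_p: float = 1.0
    d_m: float = 1.0
    d_p: float = 0.1

    def __post_init__(self):
        for name in ("g", "k_m", "k_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"GeneModule.{name} must be >= 0")
        if self.d_m <= 0 or self.d_p <= 0:
            raise ValueError("degradation rates d_m, d_p must be > 0")


@dataclass(frozen=True)
class ResourceContext:
    """Resource mode plus the capacities of the shared machinery.

    ``J_p`` is the translational capacity: the mRNA-copy scale at which
    shared translation saturates.  ``J_g`` is the analogous transcriptional
    capacity in gene-dose units.  ``frozen_means`` is the pair of constants
    substituted for the opposing mRNA in ``FROZEN_CROSS`` mode (ignored
    elsewhere); entry ``j`` is the value seen by module ``1-j``'s translation.
    """

    mode: ResourceMode = ResourceMode.COMPETITIVE
    J_p: float = 10.0
    J_g: float = 20.0
    frozen_means: tuple[float, float] | None = None

    def __post_init__(self):
        object.__setattr__(self, "mode", ResourceMode.coerce(self.mode))
        if self.mode in LIMITED_MODES:
            if not (self.J_p > 0):
                raise ValueError(f"J_p must be > 0 in mode {self.mode.name}")
            if not (self.J_g > 0):
                raise ValueError(f"J_g must be > 0 in mode {self.mode.name}")
        if self.frozen_means is not None:
            fm = tuple(float(v) for v in self.frozen_means)
            if len(fm) != 2 or any(v < 0 for v in fm):
                raise ValueError("frozen_means must be a pair of values >= 0")
            object.__setattr__(self, "frozen_means", fm)
        if self.mode is ResourceMode.FROZEN_CROSS and self.frozen_means is None:
            raise ValueError("FROZEN_CROSS mode requires frozen_means")


@dataclass
class CircuitState:
    """Copy numbers of the circuit species.

    Integers in the stochastic setting, reals for the mean field.  ``s1``/``s2``
    are the controller sgRNA species and stay at zero for uncontrolled models.
    """

    m1: float
    m2: float
    P1: float
    P2: float
    s1: float = 0.0
    s2: float = 0.0

    def as_array(self, species: Sequence[str]) -> np.ndarray:
        return np.array([getattr(self, name) for name in species], dtype=float)

    @classmethod
    def from_array(cls, species: Sequence[str], x: Sequence[float]) -> "CircuitState":
        return cls(**{name: float(v) for name, v in zip(species, x)})


def _check_nonnegative(**values):
    for name, v in values.items():
        if v < 0:
            raise ValueError(f"invalid state: {name} = {v} is negative")


def transcription_propensity(module_index, state, context, modules):
    """Transcription propensity of module ``module_index`` (0 or 1).

    ``UNLIMITED``: ``k_m*g_i``.  ``COMPETITIVE``/``FROZEN_CROSS``:
    ``k_m*g_i/(1+(g_1+g_2)/J_g)`` (gene doses are constants, so there is no
    cross-fluctuation to freeze at this stage).  ``ORTHOGONAL``:
    ``k_m*g_i/(1+g_i/J_g)``.
    """
    i = int(module_index)
    if i not in (0, 1):
        raise ValueError("module_index must be 0 or 1")
    if state is not None:
        _check_nonnegative(m1=state.m1, m2=state.m2, P1=state.P1, P2=state.P2)
    mod = modules[i]
    mode = context.mode
    if mode is ResourceMode.UNLIMITED:
        return mod.k_m * mod.g
    if mode is ResourceMode.ORTHOGONAL:
        return mod.k_m * mod.g / (1.0 + mod.g / context.J_g)
    g_tot = modules[0].g + modules[1].g
    return mod.k_m * mod.g / (1.0 + g_tot / context.J_g)


def translation_propensity(module_index, state, context, modules):
    """Translation propensity of module ``module_index`` at ``state``.

    ``UNLIMITED``: ``k_p*m_i``.  ``COMPETITIVE``:
    ``k_p*m_i/(1+(m_1+m_2)/J_p)``.  ``ORTHOGONAL``: ``k_p*m_i/(1+m_i/J_p)``.
    ``FROZEN_CROSS``: ``k_p*m_i/(1+(m_i+mu_other)/J_p)`` with the opposing
    mRNA replaced by the stored constant ``mu_other``.
    """
    i = int(module_index)
    if i not in (0, 1):
        raise ValueError("module_index must be 0 or 1")
    m = (state.m1, state.m2)
    _check_nonnegative(m1=m[0], m2=m[1])
    mod = modules[i]
    mode = context.mode
    if mode is ResourceMode.UNLIMITED:
        return mod.k_p * m[i]
    if mode is ResourceMode.ORTHOGONAL:
        return mod.k_p * m[i] / (1.0 + m[i] / context.J_p)
    if mode is ResourceMode.FROZEN_CROSS:
        mu_other = context.frozen_means[1 - i]
        return mod.k_p * m[i] / (1.0 + (m[i] + mu_other) / context.J_p)
    return mod.k_p * m[i] / (1.0 + (m[0] + m[1]) / context.J_p)


# ---------------------------------------------------------------------------
# Propensity laws with analytic gradients.
#
# Every law exposes value(x) and grad(x) where x is a sequence of scalars (SSA
# and mean field) or of equal-length numpy arrays (vectorised CME assembly).
# grad returns a sparse {species_index: d value / d x_index} mapping.
# ---------------------------------------------------------------------------


class RateLaw:
    def value(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def grad(self, x):  # pragma: no cover - interface
        raise NotImplementedError


class ZeroOrder(RateLaw):
    """State-independent production at rate ``c``."""

    __slots__ = ("c",)

    def __init__(self, c):
        if not (c >= 0 and math.isfinite(c)):
            raise ValueError("zero-order rate must be finite and >= 0")
        self.c = float(c)

    def value(self, x):
        return self.c

    def grad(self, x):
        return {}


class FirstOrder(RateLaw):
    """Mass action ``c * x[idx]``."""

    __slots__ = ("c", "idx")

    def __init__(self, c, idx):
        if not (c >= 0 and math.isfinite(c)):
            raise ValueError("first-order rate constant must be finite and >= 0")
        self.c = float(c)
        self.idx = int(idx)

    def value(self, x):
        return self.c * x[self.idx]

    def grad(self, x):
        return {self.idx: self.c}


class SharedSaturating(RateLaw):
    """Resource-limited catalysis ``c*x[num]/(1 + (sum_j w_j x_j + const)/J)``.

    The denominator encodes the total load on a finite pool of capacity ``J``;
    ``const`` carries any frozen (non-fluctuating) contribution.
    """

    __slots__ = ("c", "num", "weights", "const", "J")

    def __init__(self, c, num, weights, J, const=0.0):
        self.c = float(c)
        self.num = int(num)
        self.weights = tuple((int(j), float(w)) for j, w in weights)
        self.const = float(const)
        self.J = float(J)
        if self.c < 0 or self.J <= 0 or self.const < 0:
            raise ValueError("invalid saturating-rate parameters")

    def _den(self, x):
        load = self.const
        for j, w in self.weights:
            load = load + w * x[j]
        return 1.0 + load / self.J

    def value(self, x):
        return self.c * x[self.num] / self._den(x)

    def grad(self, x):
        den = self._den(x)
        v = self.c * x[self.num] / den
        out = {self.num: self.c / den}
        for j, w in self.weights:
            out[j] = out.get(j, 0.0) - v * (w / self.J) / den
        return out


class Effector:
    def value(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def grad(self, x):  # pragma: no cover - interface
        raise NotImplementedError


class LinearEffector(Effector):
    """Effector level as a weighted sum of species copy numbers."""

    __slots__ = ("weights",)

    def __init__(self, weights):
        self.weights = tuple((int(j), float(w)) for j, w in weights)

    def value(self, x):
        e = 0.0
        for j, w in self.weights:
            e = e + w * x[j]
        return e

    def grad(self, x):
        return {j: w for j, w in self.weights}


class PartitionEffector(Effector):
    """Complex level from a conserved pool partitioned between two ligands.

    With ``u_i = s_i/K_b`` the quasi-steady-state occupancy of a pool of
    ``total`` copies is ``total*u_own/(1+u_own+u_other)``, so the two
    complexes can never exceed the pool.
    """

    __slots__ = ("own", "other", "total", "K_b")

    def __init__(self, own, other, total, K_b):
        if total <= 0 or K_b <= 0:
            raise ValueError("pool size and binding scale must be > 0")
        self.own = int(own)
        self.other = int(other)
        self.total = float(total)
        self.K_b = float(K_b)

    def value(self, x):
        u1 = x[self.own] / self.K_b
        u2 = x[self.other] / self.K_b
        return self.total * u1 / (1.0 + u1 + u2)

    def grad(self, x):
        u1 = x[self.own] / self.K_b
        u2 = x[self.other] / self.K_b
        den = 1.0 + u1 + u2
        return {
            self.own: self.total * (1.0 + u2) / (self.K_b * den * den),
            self.other: -self.total * u1 / (self.K_b * den * den),
        }


class Repressed(RateLaw):
    """A base law multiplied by non-cooperative repression 1/(1+S_c*E/K_e)."""

    __slots__ = ("base", "effector", "S_c", "K_e")

    def __init__(self, base, effector, S_c, K_e):
        if S_c < 0 or K_e <= 0:
            raise ValueError("controller strength must be >= 0 and K_e > 0")
        self.base = base
        self.effector = effector
        self.S_c = float(S_c)
        self.K_e = float(K_e)

    def _inhibition(self, x):
        return 1.0 / (1.0 + self.S_c * self.effector.value(x) / self.K_e)

    def value(self, x):
        return self.base.value(x) * self._inhibition(x)

    def grad(self, x):
        inh = self._inhibition(x)
        bval = self.base.value(x)
        dinh = -(self.S_c / self.K_e) * inh * inh
        out = {j: dv * inh for j, dv in self.base.grad(x).items()}
        for j, de in self.effector.grad(x).items():
            out[j] = out.get(j, 0.0) + bval * dinh * de
        return out


@dataclass(frozen=True)
class Reaction:
    """One reaction channel: a name, net stoichiometry, and a rate law."""

    name: str
    changes: tuple[tuple[int, int], ...]  # (species index, net change)
    law: RateLaw

    def __post_init__(self):
        if not self.changes:
            raise ValueError(f"reaction {self.name!r} changes no species")


class ReactionNetwork:
    """Species, stoichiometry and propensities of one model variant.

    The provenance record (mode, parameters, controller) travels with every
    result derived from the network so outputs are self-describing.
    """

    def __init__(self, species, reactions, modules=None, context=None,
                 controller=None, provenance=None):
        self.species = tuple(species)
        self.reactions = list(reactions)
        self.modules = modules
        self.context = context
        self.controller = controller
        self.provenance = dict(provenance or {})
        index = {name: i for i, name in enumerate(self.species)}
        if len(index) != len(self.species):
            raise ValueError("duplicate species labels")
        self.index = index

    @property
    def n_species(self):
        return len(self.species)

    @property
    def n_reactions(self):
        return len(self.reactions)

    @property
    def stoich(self) -> np.ndarray:
        """Stoichiometry matrix, shape (reactions, species)."""
        S = np.zeros((self.n_reactions, self.n_species), dtype=int)
        for r, rx in enumerate(self.reactions):
            for j, d in rx.changes:
                S[r, j] += d
        return S

    def propensities(self, x) -> np.ndarray:
        x = list(x)
        a = np.array([rx.law.value(x) for rx in self.reactions], dtype=float)
        if not np.all(np.isfinite(a)) or np.any(a < -1e-12):
            bad = [self.reactions[i].name for i in np.where(~(np.isfinite(a) & (a >= -1e-12)))[0]]
            raise ValueError(f"non-finite or negative propensity in {bad} at state {x}")
        return a

    def drift(self, x) -> np.ndarray:
        """Mean-field rate of change of each species."""
        x = list(x)
        f = np.zeros(self.n_species)
        for rx in self.reactions:
            v = rx.law.value(x)
            for j, d in rx.changes:
                f[j] += d * v
        return f

    def jacobian(self, x) -> np.ndarray:
        """Analytic Jacobian of the mean-field drift."""
        x = list(x)
        J = np.zeros((self.n_species, self.n_species))
        for rx in self.reactions:
            g = rx.law.grad(x)
            for j, d in rx.changes:
                for k, dv in g.items():
                    J[j, k] += d * dv
        return J

    def diffusion(self, x) -> np.ndarray:
        """LNA diffusion matrix D = sum_r a_r(x) s_r s_r^T."""
        x = list(x)
        D = np.zeros((self.n_species, self.n_species))
        for rx in self.reactions:
            v = rx.law.value(x)
            for j, dj in rx.changes:
                for k, dk in rx.changes:
                    D[j, k] += dj * dk * v
        return D

    def state(self, x) -> CircuitState:
        """Wrap an array in a :class:`CircuitState` (circuit networks only)."""
        return CircuitState.from_array(self.species, x)

    def __repr__(self):
        mode = self.context.mode.name if self.context else "custom"
        ctrl = ""
        if self.controller is not None:
            ctrl = f", controller={self.controller.ctype.name}-{self.controller.placement.name}"
        return (f"ReactionNetwork({mode}, species={len(self.species)}, "
                f"reactions={len(self.reactions)}{ctrl})")


def _tx_law(i, modules, context) -> RateLaw:
    return ZeroOrder(transcription_propensity(i, None, context, modules))


def _tl_law(i, modules, context, index) -> RateLaw:
    mod = modules[i]
    mi = index[f"m{i + 1}"]
    mo = index[f"m{2 - i}"]
    mode = context.mode
    if mode is ResourceMode.UNLIMITED:
        return FirstOrder(mod.k_p, mi)
    if mode is ResourceMode.ORTHOGONAL:
        return SharedSaturating(mod.k_p, mi, [(mi, 1.0)], context.J_p)
    if mode is ResourceMode.FROZEN_CROSS:
        return SharedSaturating(mod.k_p, mi, [(mi, 1.0)], context.J_p,
                                const=context.frozen_means[1 - i])
    return SharedSaturating(mod.k_p, mi, [(mi, 1.0), (mo, 1.0)], context.J_p)


def build_network(modules, context, controller=None) -> ReactionNetwork:
    """Assemble the reaction network for one model variant.

    The uncontrolled circuit has 4 species and 8 reactions (per module:
    transcription, translation, mRNA decay, protein decay).  Supplying a
    :class:`~rcnoise.controllers.ControllerSpec` appends the feedback; an NCR
    controller adds the two sgRNA species with their production/decay
    channels, while the dCas9 pool enters only as a conserved parameter.
    """
    modules = tuple(modules)
    if len(modules) != 2:
        raise ValueError("exactly two gene modules are required")
    context = context if isinstance(context, ResourceContext) else ResourceContext(context)

    species = ["m1", "m2", "P1", "P2"]
    if controller is not None:
        from .controllers import controller_species, resolve  # avoid import cycle

        controller.validate()
        if not controller.is_resolved:
            # fall back to resolving the effector scales at this network's
            # own fixed point; sweeps resolve once at a reference instead
            controller = resolve(controller, modules, context)
        species += controller_species(controller)
    index = {name: i for i, name in enumerate(species)}

    tx_laws = [_tx_law(i, modules, context) for i in (0, 1)]
    tl_laws = [_tl_law(i, modules, context, index) for i in (0, 1)]

    if controller is not None:
        from .controllers import wrap_laws

        tx_laws, tl_laws, extra = wrap_laws(controller, tx_laws, tl_laws, index)
    else:
        extra = []

    reactions = []
    for i in (0, 1):
        mi, pi = index[f"m{i + 1}"], index[f"P{i + 1}"]
        mod = modules[i]
        reactions.append(Reaction(f"tx{i + 1}", ((mi, +1),), tx_laws[i]))
        reactions.append(Reaction(f"tl{i + 1}", ((pi, +1),), tl_laws[i]))
        reactions.append(Reaction(f"deg_m{i + 1}", ((mi, -1),), FirstOrder(mod.d_m, mi)))
        reactions.append(Reaction(f"deg_P{i + 1}", ((pi, -1),), FirstOrder(mod.d_p, pi)))
    reactions.extend(extra)

    prov = {
        "mode": context.mode.name,
        "J_p": context.J_p,
        "J_g": context.J_g,
        "frozen_means": list(context.frozen_means) if context.frozen_means else None,
        "modules": [
            {"g": m.g, "k_m": m.k_m, "k_p": m.k_p, "d_m": m.d_m, "d_p": m.d_p}
            for m in modules
        ],
        "controller": controller.provenance() if controller is not None else None,
    }
    return ReactionNetwork(species, reactions, modules=modules, context=context,
                           controller=controller, provenance=prov)


class SteadyStateError(RuntimeError):
    """Mean-field fixed point could not be located to tolerance."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def _base_fixed_point(modules, context) -> np.ndarray:
    """Closed-form fixed point of the uncontrolled circuit.

    Transcription does not depend on the state (gene doses are constants), so
    m_i* = tx_i/d_m exactly; the protein balance then follows from the
    translation law evaluated at m*.
    """
    m = np.array([
        transcription_propensity(i, None, context, modules) / modules[i].d_m
        for i in (0, 1)
    ])
    st = CircuitState(m[0], m[1], 0.0, 0.0)
    P = np.array([
        translation_propensity(i, st, context, modules) / modules[i].d_p
        for i in (0, 1)
    ])
    return np.array([m[0], m[1], P[0], P[1]])


def deterministic_steady_state(network: ReactionNetwork, tol=1e-10,
                               max_newton=50) -> CircuitState:
    """Non-negative fixed point of the mean-field rate equations.

    Uncontrolled circuits are solved in closed form.  Controlled circuits
    start from the uncontrolled fixed point (sgRNAs at their tracking values)
    and are refined by damped Newton iteration with the analytic Jacobian; the
    residual infinity-norm is required to fall below ``tol``.
    """
    from scipy import optimize

    if network.modules is None:
        # generic network (no circuit structure): plain root find from ones
        sol = optimize.root(network.drift, np.ones(network.n_species),
                            jac=network.jacobian, method="hybr", tol=1e-13)
        x = np.clip(sol.x, 0.0, None)
        resid = float(np.max(np.abs(network.drift(x))))
        if not sol.success or resid > tol:
            raise SteadyStateError("no mean-field fixed point found",
                                   {"residual": resid})
        return x
    x0 = _base_fixed_point(network.modules, network.context)
    if network.controller is None:
        resid = float(np.max(np.abs(network.drift(x0))))
        if resid > tol:  # pragma: no cover - closed form is exact
            raise SteadyStateError("closed-form fixed point failed residual check",
                                   {"residual": resid})
        return network.state(x0)

    guess = np.zeros(network.n_species)
    guess[:4] = x0
    if "s1" in network.index:
        for name, val in network.controller.inhibitor_means(x0).items():
            guess[network.index[name]] = val

    sol = optimize.root(network.drift, guess, jac=network.jacobian, method="hybr",
                        tol=1e-13)
    x = np.asarray(sol.x, dtype=float)

    # Newton polish (and rescue if hybr wandered): damped steps on the drift.
    for _ in range(max_newton):
        f = network.drift(x)
        resid = float(np.max(np.abs(f)))
        if resid < tol:
            break
        try:
            step = np.linalg.solve(network.jacobian(x), -f)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        ref = float(np.linalg.norm(f))
        for _ in range(30):
            x_new = np.clip(x + lam * step, 0.0, None)
            if np.linalg.norm(network.drift(x_new)) < ref:
                break
            lam *= 0.5
        x = np.clip(x + lam * step, 0.0, None)

    resid = float(np.max(np.abs(network.drift(x))))
    if resid > tol or np.any(x < -tol):
        raise SteadyStateError(
            f"fixed-point residual {resid:.3e} above tolerance {tol:.1e}",
            {"residual": resid, "x": x, "solver_success": bool(sol.success)},
        )
    return network.state(np.clip(x, 0.0, None))


def birth_death_network(k=5.0, d=1.0, name="x") -> ReactionNetwork:
    """One-species birth-death process (stationary law: Poisson(k/d)).

    Handy closed-form oracle for the samplers and solvers.
    """
    reactions = [
        Reaction("birth", ((0, +1),), ZeroOrder(k)),
        Reaction("death", ((0, -1),), FirstOrder(d, 0)),
    ]
    return ReactionNetwork((name,), reactions,
                           provenance={"mode": "BIRTH_DEATH", "k": k, "d": d})
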