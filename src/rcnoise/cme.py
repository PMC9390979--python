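"""Steady state of the truncated chemical master equation.

The state space is a finite box of copy numbers (one cap per species).
Reactions that would leave the box are reflected — their rate is set to
zero — so probability is conserved and a proper stationary distribution
exists; the mass stranded on the boundary is reported as a truncation
diagnostic.  The generator is assembled column-by-column (column = source
state), so every column sums to zero.

Copy numbers are exact integers throughout: marginals and widths are
computed on the integer lattice, never on binned output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla

from .circuits import ReactionNetwork, deterministic_steady_state

__all__ = [
    "StateSpace",
    "StationaryDistribution",
    "FWHMResult",
    "build_generator",
    "stationary_distribution",
    "solve_network",
    "marginal",
    "joint2d",
    "moments",
    "fwhm",
]


@dataclass(frozen=True)
class StateSpace:
    """Box truncation of the copy-number lattice.

    ``caps[i]`` is the largest copy number kept for species ``i``; the box
    holds ``prod(caps+1)`` states, enumerated C-style (last species fastest).
    """

    species: tuple[str, ...]
    caps: tuple[int, ...]

    def __post_init__(self):
        if len(self.species) != len(self.caps):
            raise ValueError("one cap per species is required")
        if any(c < 1 for c in self.caps):
            raise ValueError("caps must be >= 1")

    @property
    def dims(self) -> tuple[int, ...]:
        return tuple(c + 1 for c in self.caps)

    @property
    def n_states(self) -> int:
        return int(np.prod(self.dims))

    def state_arrays(self):
        """Per-species copy-number arrays over all enumerated states."""
        return [a.astype(np.float64) for a in
                np.unravel_index(np.arange(self.n_states), self.dims)]

    @classmethod
    def from_network(cls, network: ReactionNetwork, factor=5.0, caps=None):
        """Caps at ``factor`` times the deterministic mean (minimum 10).

        The 5x default is generous for the Poisson-like marginals of these
        circuits; adequacy is confirmed post hoc by the boundary-mass
        diagnostic rather than assumed.
        """
        if caps is not None:
            return cls(network.species, tuple(int(c) for c in caps))
        xs = _fixed_point_array(network)
        caps = tuple(max(10, int(math.ceil(factor * v))) for v in xs)
        return cls(network.species, caps)


@dataclass
class StationaryDistribution:
    """Normalised stationary probabilities on an enumerated state space."""

    pi: np.ndarray
    space: StateSpace
    residual: float
    boundary_mass: float

    def __post_init__(self):
        if abs(float(self.pi.sum()) - 1.0) > 1e-10:
            raise ValueError("stationary probabilities must sum to 1")
        if np.any(self.pi < -1e-12):
            raise ValueError("stationary probabilities must be non-negative")


def _fixed_point_array(network):
    xs = deterministic_steady_state(network)
    if hasattr(xs, "as_array"):
        xs = xs.as_array(network.species)
    return np.asarray(xs, dtype=float)


def build_generator(network: ReactionNetwork, space: StateSpace) -> sparse.csr_matrix:
    """Sparse CME generator ``G`` with ``dπ/dt = G π``.

    ``G[target, source]`` is the propensity of the reaction taking ``source``
    to ``target``; the diagonal carries minus the outgoing rates, so each
    column sums to zero.  Transitions leaving the truncation box are
    reflected (rate zeroed).  Emits a warning when the caps look too tight
    for the deterministic means.
    """
    if tuple(space.species) != tuple(network.species):
        raise ValueError("state space species do not match the network")
    _warn_if_tight(network, space)

    dims = space.dims
    n = space.n_states
    strides = np.array([int(np.prod(dims[i + 1:])) for i in range(len(dims))])
    xs = space.state_arrays()
    idx = np.arange(n)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for rx in network.reactions:
        a = np.broadcast_to(np.asarray(rx.law.value(xs), dtype=float), (n,))
        if np.any(a < -1e-12) or not np.all(np.isfinite(a)):
            raise ValueError(f"reaction {rx.name!r} has invalid propensities")
        valid = a > 0
        offset = 0
        for j, d in rx.changes:
            new = xs[j] + d
            valid = valid & (new >= 0) & (new <= space.caps[j])
            offset += d * strides[j]
        if not np.any(valid):
            continue
        src = idx[valid]
        rows.append(src + offset)
        cols.append(src)
        vals.append(a[valid])
        np.add.at(diag, src, -a[valid])

    rows = np.concatenate(rows + [idx])
    cols = np.concatenate(cols + [idx])
    vals = np.concatenate(vals + [diag])
    G = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return G


def _warn_if_tight(network, space):
    try:
        xs = _fixed_point_array(network)
    except Exception:
        return
    suggested = []
    for name, cap, mean in zip(space.species, space.caps, xs):
        # Poisson-scale heuristic: the tail needs ~6 sigma of headroom.
        need = mean + 6.0 * math.sqrt(2.0 * max(mean, 1.0))
        if cap < need:
            suggested.append((name, cap, int(math.ceil(need))))
    if suggested:
        msg = ", ".join(f"{n}: cap {c} < suggested {s}" for n, c, s in suggested)
        warnings.warn(f"state-space caps may be too small ({msg}); "
                      "check the boundary-mass diagnostic", RuntimeWarning)


def _boundary_mass(pi, space):
    shaped = pi.reshape(space.dims)
    mass = 0.0
    for axis in range(len(space.dims)):
        sl = [slice(None)] * len(space.dims)
        sl[axis] = -1
        mass += float(shaped[tuple(sl)].sum())
    return mass  # slight over-count where boundaries meet; fine as a diagnostic


def _initial_guess(network, space):
    """Independent truncated-Poisson product at the deterministic means."""
    try:
        xs = _fixed_point_array(network)
    except Exception:
        xs = np.array([c / 2 for c in space.caps], dtype=float)
    pi = np.ones(1)
    for mean, dim in zip(xs, space.dims):
        k = np.arange(dim)
        lam = max(mean, 1e-6)
        logp = k * math.log(lam) - lam - np.array([math.lgamma(v + 1) for v in k])
        p = np.exp(logp - logp.max())
        p /= p.sum()
        pi = np.kron(pi, p)
    return pi


def stationary_distribution(G: sparse.csr_matrix, space: StateSpace,
                            network: ReactionNetwork | None = None,
                            tol=1e-10, max_steps=400_000) -> StationaryDistribution:
    """Null vector of the generator, normalised to a probability vector.

    Small systems are solved directly (one balance equation replaced by the
    normalisation).  Large systems use uniformisation: power iteration with
    the stochastic matrix ``I + G/Λ``, which converges geometrically at the
    slowest relaxation rate, followed by a direct residual check.
    """
    n = G.shape[0]
    if n <= 40_000:
        A = G.tolil(copy=True)
        A[0, :] = 1.0
        b = np.zeros(n)
        b[0] = 1.0
        pi = spla.spsolve(A.tocsr(), b)
    else:
        lam = 1.05 * float(np.abs(G.diagonal()).max())
        P = sparse.eye(n, format="csr") + G * (1.0 / lam)
        pi = _initial_guess(network, space) if network is not None else \
            np.full(n, 1.0 / n)
        check_every = 250
        steps = 0
        while steps < max_steps:
            for _ in range(check_every):
                pi = P @ pi
            s = pi.sum()
            if not np.isfinite(s) or s <= 0:
                raise RuntimeError("power iteration diverged")
            pi /= s
            steps += check_every
            resid = float(np.max(np.abs(G @ pi)))
            if resid < tol:
                break
        else:
            raise RuntimeError(
                f"stationary solve did not converge: residual "
                f"{float(np.max(np.abs(G @ pi))):.2e} after {max_steps} steps"
            )
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    resid = float(np.max(np.abs(G @ pi)))
    if resid > tol:
        raise RuntimeError(f"stationary residual {resid:.2e} above {tol:.1e}")
    bmass = _boundary_mass(pi, space)
    if bmass > 1e-6:
        warnings.warn(f"truncation boundary carries {bmass:.2e} probability; "
                      "increase the caps", RuntimeWarning)
    return StationaryDistribution(pi=pi, space=space, residual=resid,
                                  boundary_mass=bmass)


def solve_network(network: ReactionNetwork, caps=None, factor=5.0,
                  tol=1e-10) -> StationaryDistribution:
    """Convenience wrapper: build the space and generator, then solve."""
    space = StateSpace.from_network(network, factor=factor, caps=caps)
    G = build_generator(network, space)
    return stationary_distribution(G, space, network=network, tol=tol)


def _axis(dist, species_name):
    try:
        return dist.space.species.index(species_name)
    except ValueError:
        raise KeyError(f"unknown species {species_name!r}; "
                       f"have {dist.space.species}") from None


def marginal(dist: StationaryDistribution, species_name) -> np.ndarray:
    """Exact 1D marginal over the integer lattice (index = copy number)."""
    ax = _axis(dist, species_name)
    shaped = dist.pi.reshape(dist.space.dims)
    other = tuple(i for i in range(len(dist.space.dims)) if i != ax)
    return shaped.sum(axis=other)


def joint2d(dist: StationaryDistribution, species_pair) -> np.ndarray:
    """Exact 2D joint of two species; rows index the first species."""
    a = _axis(dist, species_pair[0])
    b = _axis(dist, species_pair[1])
    if a == b:
        raise ValueError("species pair must be distinct")
    shaped = dist.pi.reshape(dist.space.dims)
    other = tuple(i for i in range(len(dist.space.dims)) if i not in (a, b))
    out = shaped.sum(axis=other)
    if a > b:
        out = out.T
    return out


def moments(dist: StationaryDistribution, pair=("P1", "P2")):
    """Means/variances per species plus covariance and correlation of a pair."""
    dims = dist.space.dims
    shaped = dist.pi.reshape(dims)
    means, variances = {}, {}
    for i, name in enumerate(dist.space.species):
        p = marginal(dist, name)
        k = np.arange(dims[i])
        mu = float(p @ k)
        means[name] = mu
        variances[name] = float(p @ (k - mu) ** 2)
    j = joint2d(dist, pair)
    k0 = np.arange(j.shape[0])
    k1 = np.arange(j.shape[1])
    e_xy = float(k0 @ j @ k1)
    cov = e_xy - means[pair[0]] * means[pair[1]]
    sd = math.sqrt(variances[pair[0]] * variances[pair[1]])
    corr = cov / sd if sd > 0 else 0.0
    return {"mean": means, "variance": variances,
            f"cov_{pair[0]}{pair[1]}": cov, f"corr_{pair[0]}{pair[1]}": corr}


@dataclass(frozen=True)
class FWHMResult:
    """Full width at half maximum of a discrete distribution (copy units)."""

    width: float
    left: float
    right: float
    unimodal: bool

    def __float__(self):
        return self.width


def fwhm(p, rel_tol=1e-9) -> FWHMResult:
    """FWHM by linear interpolation between lattice points.

    The half-maximum crossings are interpolated between the bins straddling
    half of the peak probability on each side.  Multimodal inputs (more than
    one local maximum above a relative tolerance) are flagged, not rejected.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 3:
        raise ValueError("fwhm needs a 1D distribution with >= 3 points")
    peak = int(np.argmax(p))
    pmax = p[peak]
    if pmax <= 0:
        raise ValueError("distribution has no mass")
    half = 0.5 * pmax

    # unimodality: strictly rising runs after the first fall signal extra modes
    thresh = rel_tol * pmax
    d = np.diff(p)
    falling = False
    unimodal = True
    for v in d:
        if v < -thresh:
            falling = True
        elif v > thresh and falling:
            unimodal = False
            break

    left = 0.0
    for i in range(peak, 0, -1):
        if p[i - 1] < half <= p[i]:
            left = (i - 1) + (half - p[i - 1]) / (p[i] - p[i - 1])
            break
    right = float(p.size - 1)
    for i in range(peak, p.size - 1):
        if p[i] >= half > p[i + 1]:
            right = i + (p[i] - half) / (p[i] - p[i + 1])
            break
    return FWHMResult(width=right - left, left=left, right=right,
                      unimodal=unimodal)
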