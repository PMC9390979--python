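"""Exact stochastic simulation (Gillespie direct method) and stationary
statistics.

This sampler is the pipeline's synthetic-data generator: it produces
statistically exact sample paths of the jump process defined by a
:class:`~rcnoise.circuits.ReactionNetwork` — birth/death kinetics of the two
mRNAs and proteins with translation propensities coupled through the shared
capacity ``J_p``, which is what makes the two reporters fluctuate in an
anticorrelated fashion under competition.

Stationary summaries are *time-weighted* (trajectory values are step
functions; event-weighted averaging would bias toward fast-firing regions),
with Monte-Carlo standard errors from batch means over the post-burn-in
window.  All randomness flows through a caller-supplied seed via
``numpy.random.default_rng``; identical seed and network give an identical
event sequence.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circuits import ReactionNetwork, deterministic_steady_state

log = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "StationarySummary",
    "simulate",
    "simulate_summary",
    "stationary_statistics",
    "ensemble",
    "write_trajectory",
]


@dataclass
class Trajectory:
    """Time-stamped integer state path after burn-in.

    ``times[i]`` is the instant the system *entered* ``states[i]``; the state
    holds until ``times[i+1]`` (or ``t_end`` for the last one).  The first
    recorded time equals the burn-in horizon.
    """

    times: np.ndarray
    states: np.ndarray  # (n_records, n_species) integers
    species: tuple[str, ...]
    t_end: float
    burn_in: float
    seed: int
    provenance: dict = field(default_factory=dict)
    flag: str | None = None  # e.g. "absorbed" when no event is possible

    def __post_init__(self):
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise ValueError("trajectory times must be strictly increasing")
        if np.any(self.states < 0):
            raise ValueError("trajectory states must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.species))
        df.insert(0, "time", self.times)
        return df


@dataclass
class StationarySummary:
    """Time-weighted stationary moments with batch-means standard errors."""

    species: tuple[str, ...]
    mean: dict
    variance: dict
    cv2: dict
    corr_P1P2: float | None
    se_mean: dict
    se_corr: float | None
    n_batches: int
    total_time: float
    seed: int
    flag: str | None = None

    def as_row(self) -> dict:
        row = {"seed": self.seed, "total_time": self.total_time, "flag": self.flag}
        for s in self.species:
            row[f"mean_{s}"] = self.mean[s]
            row[f"var_{s}"] = self.variance[s]
            row[f"cv2_{s}"] = self.cv2[s]
            row[f"se_mean_{s}"] = self.se_mean[s]
        row["corr_P1P2"] = self.corr_P1P2
        row["se_corr_P1P2"] = self.se_corr
        return row


def _initial_state(network: ReactionNetwork, x0):
    if x0 is not None:
        x = [int(round(v)) for v in x0]
    else:
        xs = deterministic_steady_state(network)
        if hasattr(xs, "as_array"):
            xs = xs.as_array(network.species)
        x = [int(round(v)) for v in np.asarray(xs)]
    if any(v < 0 for v in x):
        raise ValueError("initial state must be non-negative")
    return x


def _core_loop(network, t_end, burn_in, rng, x, on_dwell, record):
    """Shared Gillespie direct-method loop.

    ``on_dwell(t0, t1, x)`` is called for every maximal interval on which the
    post-burn-in state is constant.  When ``record`` is true the visited
    states are also returned.
    """
    laws = [rx.law for rx in network.reactions]
    changes = [rx.changes for rx in network.reactions]
    n_rx = len(laws)

    times, states = [], []
    t = 0.0
    flag = None
    recording = burn_in == 0.0
    if recording and record:
        times.append(0.0)
        states.append(list(x))
    seg_start = burn_in

    while True:
        a = [law.value(x) for law in laws]
        a_tot = 0.0
        for v in a:
            if v < 0 or not math.isfinite(v):
                raise ValueError("propensity became negative or non-finite")
            a_tot += v
        if a_tot <= 0.0:
            flag = "absorbed"
            if not recording:
                recording = True
                if record:
                    times.append(burn_in)
                    states.append(list(x))
            on_dwell(max(t, burn_in), t_end, x)
            break
        dt = rng.exponential(1.0 / a_tot)
        t_next = t + dt
        if t_next >= t_end:
            if not recording:
                recording = True
                if record:
                    times.append(burn_in)
                    states.append(list(x))
            on_dwell(max(t, burn_in), t_end, x)
            break
        if t_next >= burn_in:
            if not recording:
                recording = True
                if record:
                    times.append(burn_in)
                    states.append(list(x))
            on_dwell(max(t, burn_in), t_next, x)
        # choose the reaction channel
        u = rng.random() * a_tot
        acc = 0.0
        r = n_rx - 1
        for i, v in enumerate(a):
            acc += v
            if u < acc:
                r = i
                break
        for j, d in changes[r]:
            x[j] += d
        t = t_next
        if recording and record:
            times.append(t)
            states.append(list(x))
    return times, states, flag


def simulate(network: ReactionNetwork, t_end, burn_in=0.0, seed=None,
             x0=None) -> Trajectory:
    """Exact sample path of the network's jump process on ``[burn_in, t_end]``.

    The initial condition defaults to the rounded deterministic fixed point.
    A seed is mandatory — there is no silent nondeterminism.  If every
    propensity vanishes the trajectory terminates cleanly with
    ``flag='absorbed'``.
    """
    if seed is None:
        raise ValueError("simulate requires an explicit seed")
    if not (t_end > burn_in >= 0.0):
        raise ValueError("need t_end > burn_in >= 0")
    log.info("simulate: %s seed=%d t_end=%g burn_in=%g", network, int(seed),
             t_end, burn_in)
    rng = np.random.default_rng(int(seed))
    x = _initial_state(network, x0)
    times, states, flag = _core_loop(network, t_end, burn_in, rng, x,
                                     on_dwell=lambda t0, t1, s: None, record=True)
    return Trajectory(
        times=np.asarray(times, dtype=float),
        states=np.asarray(states, dtype=np.int64).reshape(len(times), -1),
        species=network.species,
        t_end=float(t_end),
        burn_in=float(burn_in),
        seed=int(seed),
        provenance=dict(network.provenance),
        flag=flag,
    )


class _BatchAccumulator:
    """Streaming time-weighted first/second moments over equal-time batches."""

    def __init__(self, n_species, burn_in, t_end, n_batches, p_pair=None):
        self.n_batches = int(n_batches)
        self.t0 = burn_in
        self.width = (t_end - burn_in) / self.n_batches
        self.T = np.zeros(self.n_batches)
        self.sx = np.zeros((self.n_batches, n_species))
        self.sxx = np.zeros((self.n_batches, n_species))
        self.sxy = np.zeros(self.n_batches)
        self.p_pair = p_pair

    def add(self, t0, t1, x):
        xa = np.asarray(x, dtype=float)
        xy = xa[self.p_pair[0]] * xa[self.p_pair[1]] if self.p_pair else 0.0
        b0 = int((t0 - self.t0) / self.width)
        while t0 < t1 - 1e-300:
            b = min(b0, self.n_batches - 1)
            edge = self.t0 + (b + 1) * self.width
            seg = min(t1, edge) - t0
            if seg > 0:
                self.T[b] += seg
                self.sx[b] += seg * xa
                self.sxx[b] += seg * xa * xa
                self.sxy[b] += seg * xy
            t0 = min(t1, edge)
            b0 = b + 1

    def summary(self, species, seed, flag=None) -> StationarySummary:
        T = self.T.sum()
        mean = self.sx.sum(axis=0) / T
        var = self.sxx.sum(axis=0) / T - mean**2
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv2 = np.where(mean > 0, var / np.maximum(mean, 1e-300) ** 2, np.nan)

        ok = self.T > 0
        bmeans = self.sx[ok] / self.T[ok, None]
        nb = int(ok.sum())
        se_mean = bmeans.std(axis=0, ddof=1) / np.sqrt(nb) if nb > 1 else \
            np.full(mean.shape, np.nan)

        corr = se_corr = None
        if self.p_pair is not None:
            i, j = self.p_pair
            cov = self.sxy.sum() / T - mean[i] * mean[j]
            denom = math.sqrt(var[i] * var[j]) if var[i] > 0 and var[j] > 0 else 0.0
            corr = cov / denom if denom > 0 else 0.0
            # per-batch correlations for the Monte-Carlo error
            bc = []
            for b in np.where(ok)[0]:
                tb = self.T[b]
                mb = self.sx[b] / tb
                vb = self.sxx[b] / tb - mb**2
                cb = self.sxy[b] / tb - mb[i] * mb[j]
                if vb[i] > 0 and vb[j] > 0:
                    bc.append(cb / math.sqrt(vb[i] * vb[j]))
            if len(bc) > 1:
                se_corr = float(np.std(bc, ddof=1) / math.sqrt(len(bc)))
        return StationarySummary(
            species=tuple(species),
            mean=dict(zip(species, mean)),
            variance=dict(zip(species, var)),
            cv2=dict(zip(species, cv2)),
            corr_P1P2=float(corr) if corr is not None else None,
            se_mean=dict(zip(species, se_mean)),
            se_corr=se_corr,
            n_batches=nb,
            total_time=float(T),
            seed=seed,
            flag=flag,
        )


def _protein_pair(network):
    if "P1" in network.index and "P2" in network.index:
        return (network.index["P1"], network.index["P2"])
    return None


def simulate_summary(network: ReactionNetwork, t_end, burn_in=0.0, seed=None,
                     x0=None, n_batches=20) -> StationarySummary:
    """Run the sampler and accumulate stationary statistics on the fly.

    Equivalent to ``stationary_statistics(simulate(...))`` but without
    storing the event path — the right tool for long horizons.
    """
    if seed is None:
        raise ValueError("simulate_summary requires an explicit seed")
    if not (t_end > burn_in >= 0.0):
        raise ValueError("need t_end > burn_in >= 0")
    log.info("simulate_summary: %s seed=%d t_end=%g burn_in=%g", network,
             int(seed), t_end, burn_in)
    rng = np.random.default_rng(int(seed))
    x = _initial_state(network, x0)
    acc = _BatchAccumulator(network.n_species, burn_in, t_end, n_batches,
                            p_pair=_protein_pair(network))
    _, _, flag = _core_loop(network, t_end, burn_in, rng, x,
                            on_dwell=acc.add, record=False)
    return acc.summary(network.species, int(seed), flag=flag)


def _required_horizon(trajectory, min_lifetimes):
    mods = trajectory.provenance.get("modules")
    if not mods:
        return None
    d_p = min(m["d_p"] for m in mods)
    return min_lifetimes / d_p


def stationary_statistics(trajectory: Trajectory, n_batches=20,
                          min_lifetimes=100.0) -> StationarySummary:
    """Time-weighted moments and (P1,P2) correlation of a stored trajectory.

    Requires the post-burn-in window to cover at least ``min_lifetimes``
    protein lifetimes so the batch means are close to independent.
    """
    span = trajectory.t_end - trajectory.burn_in
    need = _required_horizon(trajectory, min_lifetimes)
    if need is not None and span < need:
        raise ValueError(
            f"trajectory spans {span:g} time units after burn-in but "
            f">= {need:g} (= {min_lifetimes:g} protein lifetimes) are required"
        )
    if trajectory.times.size == 0:
        raise ValueError("empty trajectory")
    species = trajectory.species
    pair = None
    if "P1" in species and "P2" in species:
        pair = (species.index("P1"), species.index("P2"))
    acc = _BatchAccumulator(len(species), trajectory.burn_in, trajectory.t_end,
                            n_batches, p_pair=pair)
    times = trajectory.times
    ends = np.append(times[1:], trajectory.t_end)
    for t0, t1, x in zip(times, ends, trajectory.states):
        if t1 > t0:
            acc.add(t0, t1, x)
    return acc.summary(species, trajectory.seed, flag=trajectory.flag)


def ensemble(network: ReactionNetwork, n_reps, seed_base, t_end, burn_in=0.0,
             n_batches=20) -> pd.DataFrame:
    """Independent replicate summaries with seeds ``seed_base .. seed_base+n-1``.

    The returned frame has one row per replicate; ensemble means and standard
    deviations across replicates are stored in ``df.attrs["aggregate"]``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for k in range(int(n_reps)):
        s = simulate_summary(network, t_end, burn_in=burn_in,
                             seed=int(seed_base) + k, n_batches=n_batches)
        rows.append(s.as_row())
    df = pd.DataFrame(rows)
    numeric = df.select_dtypes("number")
    df.attrs["aggregate"] = {
        "mean": numeric.mean().to_dict(),
        "std": numeric.std(ddof=1).to_dict() if len(df) > 1 else None,
    }
    return df


def write_trajectory(trajectory: Trajectory, path) -> Path:
    """CSV of (time, species...) plus a JSON sidecar with seed/provenance."""
    path = Path(path)
    trajectory.to_frame().to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {
        "seed": trajectory.seed,
        "burn_in": trajectory.burn_in,
        "t_end": trajectory.t_end,
        "flag": trajectory.flag,
        "provenance": trajectory.provenance,
    }
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path
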