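"""Figure-level experiment orchestration.

Each registered experiment reruns one analysis of the study end to end and
writes CSV tables plus a JSON metadata record (seeds, parameters, package
version, wall clock) into an output directory.  Reruns with the same
configuration and seed produce byte-identical CSVs; the metadata's wall
clock is the only field allowed to differ.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import frozen_context
from .circuits import build_network, ResourceContext, ResourceMode
from .cme import fwhm, joint2d, marginal, moments, solve_network
from .controllers import ControllerSpec, deterministic_dose_response, heatmap
from .lna import noise_vs_rfp_mean, sweep_jp
from .metrics import coefficient_table, controller_grid
from .presets import default_modules, reduced_regime, strong_competition
from .ssa import simulate_summary, simulate, write_trajectory

__all__ = ["EXPERIMENTS", "run_experiment", "ExperimentError"]


class ExperimentError(ValueError):
    """Unknown experiment or invalid experiment options."""


def _seed_for(seed, k):
    # stable, well-separated child seeds below 2**31
    return int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0] % (2**31))


def _write(df: pd.DataFrame, out_dir: Path, name: str, index=False):
    path = out_dir / name
    df.to_csv(path, index=index, float_format="%.12g")
    return path.name


def fig1_trajectories(opts, out_dir, seed):
    """Anticorrelated reporter trajectories under strong competition, and the
    frozen-cross variant in which the resource-competitive channel is cut."""
    t_end = float(opts.get("t_end", 2500.0))
    burn_in = float(opts.get("burn_in", 500.0))
    mods, ctx = strong_competition()
    fz_ctx = frozen_context(ctx, mods)
    files, rows = [], []
    for k, (label, context) in enumerate((("RC", ctx), ("FROZEN_CROSS", fz_ctx))):
        net = build_network(mods, context)
        traj = simulate(net, t_end=min(t_end, burn_in + 500.0), burn_in=burn_in,
                        seed=_seed_for(seed, k))
        files.append(write_trajectory(traj, out_dir / f"trajectory_{label}.csv").name)
        summ = simulate_summary(net, t_end=t_end, burn_in=burn_in,
                                seed=_seed_for(seed, k))
        rows.append({"model": label, **summ.as_row()})
    files.append(_write(pd.DataFrame(rows), out_dir, "stationary_summaries.csv"))
    return files


def fig1_cme(opts, out_dir, seed):
    """Joint and marginal stationary distributions from the master equation
    in the reduced-copy regime, with and without the cross-mRNA channel."""
    files = []
    widths = []
    for label, mode in (("RC", "COMPETITIVE"), ("FROZEN_CROSS", "FROZEN_CROSS"),
                        ("UR", "UNLIMITED")):
        mods, ctx = reduced_regime(mode)
        dist = solve_network(build_network(mods, ctx))
        m = marginal(dist, "P1")
        pd.DataFrame({"P1": np.arange(m.size), "probability": m}).to_csv(
            out_dir / f"gfp_marginal_{label}.csv", index=False, float_format="%.12g")
        files.append(f"gfp_marginal_{label}.csv")
        if label in ("RC", "FROZEN_CROSS"):
            j = joint2d(dist, ("P1", "P2"))
            pd.DataFrame(j).to_csv(out_dir / f"joint_P1P2_{label}.csv",
                                   float_format="%.12g")
            files.append(f"joint_P1P2_{label}.csv")
        mom = moments(dist)
        w = fwhm(m)
        widths.append({"model": label, "fwhm_P1": w.width,
                       "corr_P1P2": mom["corr_P1P2"],
                       "boundary_mass": dist.boundary_mass})
    files.append(_write(pd.DataFrame(widths), out_dir, "cme_summaries.csv"))
    return files


def fig1h_jp_sweep(opts, out_dir, seed):
    """Noise decomposition along a translational-capacity grid."""
    grid = opts.get("jp_grid") or np.logspace(
        float(opts.get("log10_min", -0.5)), float(opts.get("log10_max", 3.0)),
        int(opts.get("n_points", 60)))
    (mods, ctx) = default_modules()
    df = sweep_jp(mods, ctx, grid)
    cols = ["J_p", "eta_p2", "eta_m2", "eta_rc2", "eta_total2", "M1", "M2", "P1",
            "H21", "H23"]
    return [_write(df[cols], out_dir, "jp_sweep.csv")]


def fig2_orthogonal(opts, out_dir, seed):
    """Orthogonal resources: decorrelated trajectories and the GFP-noise-vs-
    RFP-mean comparison between competitive and orthogonal circuits."""
    t_end = float(opts.get("t_end", 6000.0))
    mods, ctx = default_modules(ResourceMode.ORTHOGONAL)
    summ = simulate_summary(build_network(mods, ctx), t_end=t_end, burn_in=500.0,
                            seed=_seed_for(seed, 0))
    files = [_write(pd.DataFrame([summ.as_row()]), out_dir, "or_trajectory_summary.csv")]
    g2_grid = opts.get("g2_grid") or np.linspace(0.0, 40.0, 25)
    df = noise_vs_rfp_mean(np.asarray(g2_grid, dtype=float))
    files.append(_write(df, out_dir, "noise_vs_rfp_mean.csv"))
    return files


def fig3_ncr_grid(opts, out_dir, seed):
    """Normalised GFP noise of the four NCR placements over the
    (RFP mean, controller strength) plane."""
    mods, ctx = strong_competition()
    g2_grid = np.asarray(opts.get("g2_grid") or np.linspace(0.0, 40.0, 11), float)
    sc_grid = np.asarray(opts.get("sc_grid") or np.linspace(0.0, 20.0, 11), float)
    files = []
    for placement in ("MIX", "PIX", "MIL", "PIL"):
        spec = ControllerSpec(ctype="NCR", placement=placement)
        df = heatmap(spec, mods, ctx, g2_grid, sc_grid)
        rfp = pd.DataFrame({"g2": list(df.attrs["rfp_mean"]),
                            "rfp_mean": list(df.attrs["rfp_mean"].values())})
        files.append(_write(df, out_dir, f"ncr_{placement.lower()}_heatmap.csv",
                            index=True))
        files.append(_write(rfp, out_dir, f"ncr_{placement.lower()}_rfp_axis.csv"))
    return files


def fig4_controller_compare(opts, out_dir, seed):
    """Local vs global vs NCR controllers: normalised-noise curves, the
    deterministic GFP-vs-RFP dose response, and average reduction
    coefficients by type and placement."""
    mods, ctx = strong_competition()
    g2_grid = np.asarray(opts.get("g2_grid") or np.linspace(0.0, 40.0, 9), float)
    sc_grid = np.asarray(opts.get("sc_grid") or
                         np.concatenate([[0.0], np.logspace(np.log10(0.2),
                                                            np.log10(20.0), 8)]),
                         float)
    files = []
    curves = []
    for ctype in ("LOCAL", "GLOBAL", "NCR"):
        for placement in ("MIX", "MIL"):
            spec = ControllerSpec(ctype=ctype, placement=placement,
                                  S_c=float(opts.get("S_c", 14.0)))
            grid = controller_grid(spec, mods, ctx, g2_grid, [spec.S_c])
            grid["controller"] = f"{ctype}-{placement}"
            curves.append(grid)
            dr = deterministic_dose_response(spec, mods, ctx, g2_grid)
            dr.insert(0, "controller", f"{ctype}-{placement}")
            curves.append(dr.assign(S_c=spec.S_c, norm_gfp_noise=np.nan))
    files.append(_write(pd.concat(curves, ignore_index=True), out_dir,
                        "controller_curves.csv"))
    table = coefficient_table(mods, ctx, g2_grid[1:], sc_grid[1:])
    files.append(_write(table, out_dir, "reduction_coefficients.csv"))
    by_type = table.groupby("ctype")["coefficient"].mean().reset_index()
    by_place = table.groupby("placement")["coefficient"].mean().reset_index()
    files.append(_write(by_type, out_dir, "coefficient_by_type.csv"))
    files.append(_write(by_place, out_dir, "coefficient_by_placement.csv"))
    return files


def fig5_or_combinations(opts, out_dir, seed):
    """Controllers combined with orthogonal resources, normalised to the
    competitive base, plus reduction coefficients in the orthogonal system."""
    mods, or_ctx = strong_competition(ResourceMode.ORTHOGONAL)
    rc_ctx = ResourceContext(ResourceMode.COMPETITIVE, J_p=or_ctx.J_p,
                             J_g=or_ctx.J_g)
    g2_grid = np.asarray(opts.get("g2_grid") or np.linspace(0.0, 40.0, 9), float)
    sc_grid = np.asarray(opts.get("sc_grid") or
                         np.concatenate([[0.0], np.logspace(np.log10(0.2),
                                                            np.log10(20.0), 8)]),
                         float)
    files = []
    curves = []
    for ctype in ("LOCAL", "NCR"):
        for placement in ("MIX", "MIL"):
            spec = ControllerSpec(ctype=ctype, placement=placement,
                                  S_c=float(opts.get("S_c", 14.0)))
            for label, context, base in (("OR", or_ctx, rc_ctx),
                                         ("RC", rc_ctx, rc_ctx)):
                grid = controller_grid(spec, mods, context, g2_grid, [spec.S_c],
                                       base_context=base)
                grid["controller"] = f"{ctype}-{placement}"
                grid["resources"] = label
                curves.append(grid)
    files.append(_write(pd.concat(curves, ignore_index=True), out_dir,
                        "or_combination_curves.csv"))
    table = coefficient_table(mods, or_ctx, g2_grid[1:], sc_grid[1:],
                              base_context=or_ctx)
    files.append(_write(table, out_dir, "or_reduction_coefficients.csv"))
    return files


EXPERIMENTS = {
    "fig1_trajectories": fig1_trajectories,
    "fig1_cme": fig1_cme,
    "fig1h_jp_sweep": fig1h_jp_sweep,
    "fig2_orthogonal": fig2_orthogonal,
    "fig3_ncr_grid": fig3_ncr_grid,
    "fig4_controller_compare": fig4_controller_compare,
    "fig5_or_combinations": fig5_or_combinations,
}


def run_experiment(config: dict, out_dir, seed=0) -> dict:
    """Run one registered experiment; returns the metadata record.

    ``config`` is a mapping with an ``experiment`` block naming the
    experiment (see :data:`EXPERIMENTS`) plus optional experiment-specific
    options.  Output CSVs land in ``out_dir`` next to ``metadata.json``.
    """
    block = dict(config.get("experiment") or {})
    name = block.pop("name", None)
    if name not in EXPERIMENTS:
        raise ExperimentError(
            f"unknown experiment {name!r}; registered: {sorted(EXPERIMENTS)}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    files = EXPERIMENTS[name](block, out_dir, int(seed))
    meta = {
        "experiment": name,
        "options": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in block.items()},
        "seed": int(seed),
        "files": files,
        "version": __version__,
        "wall_clock_s": round(time.time() - t0, 3),
    }
    (out_dir / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return meta
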