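"""Aggregate noise-control metrics.

Total system noise is the Pythagorean sum of both reporters' coefficients of
variation.  A controller's average noise reduction coefficient is the grid
average of ``1 - (normalised total system noise)`` over achieved-RFP-mean and
controller-strength grids: positive means net reduction, negative means the
controller amplifies noise on average.  Coefficients are only comparable
between controllers evaluated on the identical grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "total_system_noise",
    "ReductionCoefficient",
    "average_noise_reduction_coefficient",
    "controller_grid",
    "coefficient_table",
]


def total_system_noise(eta_gfp, eta_rfp) -> float:
    """Pythagorean sum ``sqrt(eta_GFP^2 + eta_RFP^2)`` of the two CVs."""
    eta_gfp = float(eta_gfp)
    eta_rfp = float(eta_rfp)
    if eta_gfp < 0 or eta_rfp < 0:
        raise ValueError("noise levels must be >= 0")
    return float(np.hypot(eta_gfp, eta_rfp))


@dataclass(frozen=True)
class ReductionCoefficient:
    """Average noise reduction coefficient of one controller configuration."""

    controller: str
    coefficient: float
    n_cells: int
    grid: dict

    def __post_init__(self):
        if self.coefficient > 1.0 + 1e-12:
            raise ValueError("a fold change cannot be negative, so the "
                             "coefficient cannot exceed 1")


def average_noise_reduction_coefficient(grid_result: pd.DataFrame,
                                        value="norm_total_noise",
                                        label=None) -> ReductionCoefficient:
    """Grid-averaged ``1 - fold change`` of the total system noise.

    ``grid_result`` is a tidy frame with at least columns ``S_c`` and
    ``value``.  The ``S_c = 0`` rows are the normalisation reference, not a
    sample, and are excluded; an empty remainder is rejected.
    """
    if "S_c" not in grid_result.columns or value not in grid_result.columns:
        raise ValueError(f"grid must have columns 'S_c' and {value!r}")
    cells = grid_result.loc[grid_result["S_c"] > 0, value].dropna()
    if cells.empty:
        raise ValueError("grid holds no controller-on cells (S_c > 0)")
    meta = {
        "sc_values": sorted(grid_result["S_c"].unique().tolist()),
        "n_doses": int(grid_result["g2"].nunique()) if "g2" in grid_result else None,
        "value": value,
    }
    if label is None:
        label = str(grid_result["controller"].iloc[0]) if "controller" in grid_result \
            else "controller"
    return ReductionCoefficient(controller=label,
                                coefficient=float((1.0 - cells).mean()),
                                n_cells=int(cells.size), grid=meta)


def controller_grid(spec, modules, context, g2_values, sc_values,
                    base_context=None) -> pd.DataFrame:
    """Tidy grid of normalised GFP and total system noise for one controller."""
    from .controllers import controlled_point

    rows = []
    for g2 in np.asarray(g2_values, dtype=float):
        for sc in np.asarray(sc_values, dtype=float):
            s = replace(spec, S_c=float(sc))
            try:
                pt = controlled_point(s, modules, context, g2=g2,
                                      base_context=base_context)
            except Exception:
                pt = {"g2": float(g2), "norm_gfp_noise": np.nan,
                      "norm_total_noise": np.nan, "rfp_mean_base": np.nan}
            pt["S_c"] = float(sc)
            pt["controller"] = f"{spec.ctype.name}-{spec.placement.name}"
            rows.append(pt)
    return pd.DataFrame(rows)


def coefficient_table(modules, context, g2_values, sc_values, ctypes=None,
                      placements=None, base_context=None,
                      spec_defaults=None) -> pd.DataFrame:
    """Average reduction coefficients for every (type, placement) pair.

    All configurations are evaluated on the identical grid so the
    coefficients are mutually comparable; aggregate by type or by placement
    downstream with a plain group-by.
    """
    from .controllers import ControllerSpec, ControllerType, Placement

    ctypes = [ControllerType.coerce(c) for c in (ctypes or list(ControllerType))]
    placements = [Placement.coerce(p) for p in (placements or list(Placement))]
    defaults = dict(spec_defaults or {})
    rows = []
    for ct in ctypes:
        for pl in placements:
            spec = ControllerSpec(ctype=ct, placement=pl, **defaults)
            grid = controller_grid(spec, modules, context, g2_values, sc_values,
                                   base_context=base_context)
            coeff = average_noise_reduction_coefficient(grid)
            gfp_coeff = average_noise_reduction_coefficient(
                grid, value="norm_gfp_noise", label=coeff.controller)
            rows.append({
                "ctype": ct.name,
                "placement": pl.name,
                "coefficient": coeff.coefficient,
                "coefficient_gfp": gfp_coeff.coefficient,
                "n_cells": coeff.n_cells,
            })
    return pd.DataFrame(rows)
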