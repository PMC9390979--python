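"""Model/experiment configuration files (YAML or JSON).

Schema (all blocks optional unless noted)::

    mode: COMPETITIVE | UNLIMITED | ORTHOGONAL | FROZEN_CROSS
    params:                     # kinetic constants and capacities
      d_m: 1.0                  # mRNA degradation rate (1/time)
      d_p: 0.1                  # protein degradation rate (1/time)
      J_p: 10.0                 # translational capacity (mRNA copies)
      J_g: 20.0                 # transcriptional capacity (gene-dose units)
      g1: 1.0                   # gene doses
      g2: 1.0
      frozen_means: [10, 10]    # FROZEN_CROSS only
    targets:                    # calibrate k_m/k_p to these means
      mrna_mean: 10.0
      protein_mean: 100.0
    rates:                      # alternative to targets: explicit constants
      k_m: 10.0
      k_p: 1.0
    controller:
      type: NCR | LOCAL | GLOBAL
      placement: MIX | PIX | MIL | PIL
      S_c: 14.0
      K_e: 10.0
      K_b: 10.0
      alpha_s: 1.0
      d_s: 1.0
      dcas_total: 50.0
    experiment:
      name: fig1h_jp_sweep      # see rcnoise.experiments.EXPERIMENTS
      ...                       # experiment-specific options

Unknown keys raise a :class:`ConfigError` naming the offending keys.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .calibration import CalibrationTarget, calibrated_modules
from .circuits import GeneModule, ResourceContext, ResourceMode
from .controllers import ControllerSpec

__all__ = ["ConfigError", "load_config", "model_from_config", "controller_from_config"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


_PARAM_KEYS = {"d_m", "d_p", "J_p", "J_g", "g1", "g2", "frozen_means"}
_TARGET_KEYS = {"mrna_mean", "protein_mean"}
_RATE_KEYS = {"k_m", "k_p"}
_CTRL_KEYS = {"type", "placement", "S_c", "K_e", "K_b", "alpha_s", "d_s", "dcas_total"}
_TOP_KEYS = {"mode", "params", "targets", "rates", "controller", "experiment"}


def _reject_unknown(block: dict, allowed: set, where: str):
    unknown = sorted(set(block) - allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {unknown}; "
                          f"allowed: {sorted(allowed)}")


def load_config(path) -> dict:
    """Parse and validate a YAML/JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _reject_unknown(cfg, _TOP_KEYS, str(path))
    for key, allowed in (("params", _PARAM_KEYS), ("targets", _TARGET_KEYS),
                         ("rates", _RATE_KEYS), ("controller", _CTRL_KEYS)):
        if key in cfg:
            if not isinstance(cfg[key], dict):
                raise ConfigError(f"'{key}' must be a mapping")
            _reject_unknown(cfg[key], allowed, f"'{key}'")
    if "targets" in cfg and "rates" in cfg:
        raise ConfigError("give either 'targets' (calibrate) or 'rates', not both")
    return cfg


def model_from_config(cfg: dict):
    """Build ``(modules, context)`` from a validated configuration mapping."""
    mode = ResourceMode.coerce(cfg.get("mode", "COMPETITIVE"))
    p = dict(cfg.get("params", {}))
    d_m = float(p.get("d_m", 1.0))
    d_p = float(p.get("d_p", 0.1))
    g = (float(p.get("g1", 1.0)), float(p.get("g2", 1.0)))
    frozen = p.get("frozen_means")
    try:
        context = ResourceContext(
            mode, J_p=float(p.get("J_p", 10.0)), J_g=float(p.get("J_g", 20.0)),
            frozen_means=tuple(frozen) if frozen is not None else None,
        )
    except ValueError as exc:
        raise ConfigError(f"invalid resource context: {exc}") from exc

    if "rates" in cfg:
        r = cfg["rates"]
        mods = tuple(
            GeneModule(g=g[i], k_m=float(r.get("k_m", 10.0)),
                       k_p=float(r.get("k_p", 1.0)), d_m=d_m, d_p=d_p)
            for i in (0, 1)
        )
        return mods, context
    t = cfg.get("targets", {})
    target = CalibrationTarget.symmetric(float(t.get("mrna_mean", 10.0)),
                                         float(t.get("protein_mean", 100.0)))
    if mode is ResourceMode.FROZEN_CROSS and context.frozen_means is None:
        context = ResourceContext(mode, J_p=context.J_p, J_g=context.J_g,
                                  frozen_means=target.m)
    try:
        mods = calibrated_modules(target, context, d_m=d_m, d_p=d_p, g=g)
    except ValueError as exc:
        raise ConfigError(f"calibration failed: {exc}") from exc
    return mods, context


def controller_from_config(cfg: dict) -> ControllerSpec | None:
    block = cfg.get("controller")
    if block is None:
        return None
    if "type" not in block or "placement" not in block:
        raise ConfigError("controller block requires 'type' and 'placement'")
    kwargs = {k: float(v) for k, v in block.items()
              if k not in ("type", "placement")}
    try:
        return ControllerSpec(ctype=block["type"], placement=block["placement"],
                              **kwargs)
    except ValueError as exc:
        raise ConfigError(f"invalid controller block: {exc}") from exc
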