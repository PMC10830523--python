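"""Configuration loading with unit conversion.

Experiment configuration travels as YAML/JSON in convenient lab units
(mm, um, uL/s, mPa s); everything is converted to SI on load.  All internal
computation is SI.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .flow import C2_DEFAULT, ChannelGeometry, FluidProperties

__all__ = ["load_config", "channel_from_config", "fluid_from_config"]

UL_PER_S = 1e-9   # m^3/s per uL/s
MM = 1e-3
UM = 1e-6
MPA_S = 1e-3
PN = 1e-12


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def channel_from_config(cfg: dict) -> ChannelGeometry:
    """Build a channel from {L_mm, w_mm, h0_um, alpha, beta_per_m}."""
    return ChannelGeometry(
        length=cfg["L_mm"] * MM,
        width=cfg["w_mm"] * MM,
        h0=cfg["h0_um"] * UM,
        alpha=cfg.get("alpha", 0.0),
        beta=cfg.get("beta_per_m", 0.0),
    )


def fluid_from_config(cfg: dict) -> FluidProperties:
    """Build fluid properties from {eta_mPas, rho_kgm3, temperature_c}."""
    return FluidProperties(
        rho=cfg.get("rho_kgm3", 993.36),
        eta=cfg.get("eta_mPas", 0.6922) * MPA_S,
        temperature_c=cfg.get("temperature_c"),
    )


def force_config_si(cfg: dict) -> dict:
    """SI view of a force-calibration block:
    {r_um, C1, C2, r_piston_mm, F_target_pN} -> meters/newtons."""
    return {
        "r": cfg["r_um"] * UM,
        "c1": cfg.get("C1", 1.0),
        "c2": cfg.get("C2", C2_DEFAULT),
        "r_piston": cfg.get("r_piston_mm", 6.135) * MM,
        "force_target": cfg.get("F_target_pN", 50.0) * PN,
    }
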