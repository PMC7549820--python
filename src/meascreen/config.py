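"""Flat key-value configuration files (documented schema).

Every numerical default of the well simulation is addressable as a
``section.key = value`` line; unknown keys raise. Example::

    grid.nx = 21
    grid.sigma_i = 0.5
    electrode.c_el = 1e-6
    stimulus.t0 = 20.0
    noise.fp_sd = 10.0
    solver.dt_pde = 0.1
    well.backend = surrogate
"""

from __future__ import annotations

from dataclasses import fields, replace
from pathlib import Path

from .tissue import (ElectrodeModel, TissueGrid, TissueSolverConfig,
                     WellConfig, grid_preset)

_SECTIONS = {
    "grid": TissueGrid,
    "electrode": ElectrodeModel,
    "solver": TissueSolverConfig,
    "well": WellConfig,
}

# keys routed elsewhere than a dataclass field
_ALIASES = {
    "grid.preset": None,
    "stimulus.t0": ("well", "stim_t0"),
    "noise.fp_sd": ("well", "fp_noise_sd"),
    "noise.ca_sd": ("well", "ca_noise_sd"),
}


def _coerce(text: str):
    text = text.strip()
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    return text


def load_flat_config(path) -> dict:
    """Parse ``key = value`` lines ('#' comments allowed) to a dict."""
    out = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        out[key] = _coerce(val)
    return out


def save_flat_config(cfg: dict, path) -> None:
    Path(path).write_text(
        "".join(f"{k} = {v}\n" for k, v in sorted(cfg.items())))


def well_setup_from_config(cfg: dict):
    """Build (TissueGrid, ElectrodeModel, WellConfig) from a flat dict."""
    overrides: dict[str, dict] = {name: {} for name in _SECTIONS}
    preset = cfg.get("grid.preset")
    for key, val in cfg.items():
        if key == "grid.preset":
            continue
        if key in _ALIASES:
            section, field_name = _ALIASES[key]
        else:
            section, _, field_name = key.partition(".")
            if section not in _SECTIONS:
                raise KeyError(f"unknown config section in {key!r}")
            if field_name not in {f.name for f in fields(_SECTIONS[section])}:
                raise KeyError(f"unknown config key {key!r}")
        overrides[section][field_name] = val

    if preset:
        grid = grid_preset(preset, nx=overrides["grid"].pop("nx", None))
        overrides["grid"].pop("ny", None)
        overrides["grid"].pop("dx", None)
        if overrides["grid"]:
            grid = replace(grid, **overrides["grid"])
    else:
        grid = TissueGrid(**overrides["grid"])
    electrode = ElectrodeModel(**overrides["electrode"])
    solver = TissueSolverConfig(**overrides["solver"])
    well = WellConfig(**overrides["well"], solver=solver)
    return grid, electrode, well
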