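"""Structured configuration: defaults, YAML loading, object construction."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .electrics import MonodomainParams
from .mechanics import MaterialParams, TwitchParams
from .synthetic_heart import MeshSpec

DEFAULTS: dict = {
    "mesh": {
        "lv_endo_radii": [16.0, 16.0, 40.0],
        "wall_thickness_lv": 10.0,
        "wall_thickness_rv": 4.0,
        "wall_thickness_septum": 8.0,
        "n_layers": 14,
        "n_circumferential": 36,
        "n_transmural": 4,
        "base_truncation_fraction": 0.75,
        "rv_sector_deg": 130.0,
        "rv_bulge_mm": 9.0,
        "n_transmural_rv": 1,
    },
    "fibers": {"endo_angle_deg": 60.0, "epi_angle_deg": -60.0},
    "conduction": {"fast_shell_multiplier": 6.0, "lbbb": True},
    "electrics": {
        "dt_ms": 0.05,
        "t_end_ms": 300.0,
        "threshold": 0.5,
        "d_long": 1.6,
        "d_trans": 0.32,
        "beta": 0.2,
        "k_ratio": 1.0,
        "frame_interval_ms": 1.0,
    },
    "stimulus": {"amplitude": 100.0, "duration_ms": 0.5, "radius_mm": 10.0},
    "mechanics": {
        "tmax_kpa": 12.0,
        "t_rise_ms": 60.0,
        "t_decay_ms": 80.0,
        "twitch_duration_ms": 380.0,
        "frame_ms": 10.0,
        "frame_end_ms": 400.0,
        "base_spring": 100.0,
    },
    "material": {
        "e_fiber_kpa": 60.0,
        "e_cross_kpa": 20.0,
        "nu_ft": 0.45,
        "nu_tt": 0.45,
        "g_ft_kpa": 10.0,
    },
    "indices": {"cure_layers": [6, 7, 8, 9], "n_ring_samples": 30, "di_layer": 7},
    "sweep": {
        "lv_sites": ["POST-B", "POST-E", "LAT-B", "LAT-E", "ANT-B", "ANT-E"],
        "vvd_ms": [-72, -60, -48, -36, -24, -12, 0, 12, 24, 36, 48, 60, 72],
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, deep-merged with an optional YAML file and a dict."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def mesh_spec_from(cfg: dict) -> MeshSpec:
    m = cfg["mesh"]
    return MeshSpec(
        lv_endo_radii=tuple(m["lv_endo_radii"]),
        wall_thickness_lv=m["wall_thickness_lv"],
        wall_thickness_rv=m["wall_thickness_rv"],
        wall_thickness_septum=m["wall_thickness_septum"],
        n_layers=m["n_layers"],
        n_circumferential=m["n_circumferential"],
        n_transmural=m["n_transmural"],
        base_truncation_fraction=m["base_truncation_fraction"],
        rv_sector_deg=m["rv_sector_deg"],
        rv_bulge_mm=m["rv_bulge_mm"],
        n_transmural_rv=m["n_transmural_rv"],
    )


def monodomain_params_from(cfg: dict) -> MonodomainParams:
    e = cfg["electrics"]
    return MonodomainParams(
        beta=e["beta"], k_ratio=e["k_ratio"], d_long=e["d_long"],
        d_trans=e["d_trans"], dt=e["dt_ms"], t_end=e["t_end_ms"],
        activation_threshold=e["threshold"], frame_interval=e["frame_interval_ms"],
    )


def material_from(cfg: dict) -> MaterialParams:
    m = cfg["material"]
    return MaterialParams(E_f=m["e_fiber_kpa"], E_t=m["e_cross_kpa"],
                          nu_ft=m["nu_ft"], nu_tt=m["nu_tt"], G_ft=m["g_ft_kpa"])


def twitch_from(cfg: dict) -> TwitchParams:
    m = cfg["mechanics"]
    return TwitchParams(T_max=m["tmax_kpa"], t_rise=m["t_rise_ms"],
                        t_decay=m["t_decay_ms"], duration=m["twitch_duration_ms"])
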