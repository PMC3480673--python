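"""Exhaustive pacing-configuration sweep and optimum selection.

Enumerates the Cartesian product of LV lead sites and interventricular
delays (default 6 sites x 13 delays = 78 configurations), runs the
electromechanical pipeline for each, and selects the optimum under the
mechanical (maximum CURE) or electrical (minimum E_RMS) strategy.  The two
strategies may legitimately name different optima; the report surfaces both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULTS
from .electrics import PacingProtocol
from .pipeline import HeartModel


@dataclass
class SweepGrid:
    """The pacing-configuration grid."""

    lv_sites: tuple[str, ...] = tuple(DEFAULTS["sweep"]["lv_sites"])
    vvd_values: tuple[float, ...] = tuple(DEFAULTS["sweep"]["vvd_ms"])
    rv_site: str = "RVA"

    def __post_init__(self) -> None:
        if not self.lv_sites or not len(self.vvd_values):
            raise ValueError("sweep grid must have at least one site and one VVD")
        self.vvd_values = tuple(sorted(self.vvd_values))

    @property
    def n_configs(self) -> int:
        return len(self.lv_sites) * len(self.vvd_values)


@dataclass
class SyncReport:
    """Sweep outcome: per-configuration records, baselines, optima."""

    records: list[dict]
    baselines: dict[str, dict] = field(default_factory=dict)
    optima: dict[str, dict] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_dict(self) -> dict:
        return {"records": self.records, "baselines": self.baselines,
                "optima": {k: v for k, v in self.optima.items()}}


def enumerate_configs(grid: SweepGrid, model: HeartModel) -> list[PacingProtocol]:
    """Site-major, VVD-ascending enumeration of the grid (deterministic)."""
    out = []
    for site in grid.lv_sites:
        for vvd in grid.vvd_values:
            out.append(model.make_protocol(site, float(vvd)))
    return out


def run_config(model: HeartModel, protocol: PacingProtocol) -> dict:
    """Run one paced configuration end to end; failures are recorded, not raised."""
    label = f"{protocol.lv_site.name}@{protocol.vvd:+g}ms"
    try:
        amap = model.paced_map(protocol)
        return model.evaluate(amap, label=label, lv_site=protocol.lv_site.name,
                              vvd=protocol.vvd)
    except Exception as exc:  # noqa: BLE001 - sweep must continue
        return {"label": label, "lv_site": protocol.lv_site.name,
                "vvd_ms": protocol.vvd, "status": f"failed:{type(exc).__name__}",
                "error": str(exc)}


def select_optimum(records: list[dict], strategy: str,
                   site_order: tuple[str, ...] | None = None) -> dict:
    """Argmax CURE (mechanical) or argmin E_RMS (electrical).

    Ties break toward the smaller ``|vvd|``, then catalogue site order.
    """
    ok = [r for r in records if r.get("status") == "ok"]
    if not ok:
        raise ValueError("no successful configuration records to select from")
    order = {s: i for i, s in enumerate(site_order or DEFAULTS["sweep"]["lv_sites"])}

    def tiebreak(r):
        return (abs(r.get("vvd_ms") or 0.0), order.get(r.get("lv_site"), 99))

    if strategy == "mechanical":
        best = min(ok, key=lambda r: (-r["cure"], tiebreak(r)))
    elif strategy == "electrical":
        best = min(ok, key=lambda r: (r["e_rms_ms"], tiebreak(r)))
    else:
        raise ValueError("strategy must be 'mechanical' or 'electrical'")
    return best


def run_sweep(model: HeartModel, grid: SweepGrid | None = None,
              strategies: tuple[str, ...] = ("mechanical", "electrical"),
              progress: bool = False) -> SyncReport:
    """Full sweep: baselines (sinus, LBBB) plus every grid configuration."""
    grid = grid or SweepGrid()
    baselines = {
        "sinus": model.evaluate(model.sinus_map(), label="sinus"),
        "lbbb": model.evaluate(model.lbbb_map(), label="lbbb"),
    }
    records = []
    for i, proto in enumerate(enumerate_configs(grid, model)):
        rec = run_config(model, proto)
        records.append(rec)
        if progress:
            print(f"[{i + 1}/{grid.n_configs}] {rec['label']}: "
                  f"{rec.get('cure', float('nan'))}")
    optima = {s: select_optimum(records, s, grid.lv_sites) for s in strategies}
    return SyncReport(records=records, baselines=baselines, optima=optima)


def plot_cure_map(report: SyncReport, path: str) -> None:
    """Column map of CURE vs VVD, grouped per LV pacing site."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.to_dataframe()
    df = df[df["status"] == "ok"]
    sites = list(dict.fromkeys(df["lv_site"]))
    vvds = sorted(df["vvd_ms"].unique())
    width = 0.8 / max(1, len(sites))
    fig, ax = plt.subplots(figsize=(10, 4))
    for si, site in enumerate(sites):
        sub = df[df["lv_site"] == site].set_index("vvd_ms").reindex(vvds)
        x = np.arange(len(vvds)) + (si - len(sites) / 2) * width
        ax.bar(x, sub["cure"], width=width, label=site)
    ax.set_xticks(np.arange(len(vvds)))
    ax.set_xticklabels([f"{v:+g}" for v in vvds])
    ax.set_xlabel("VV delay (ms)")
    ax.set_ylabel("CURE")
    ax.legend(fontsize=8, ncol=3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
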