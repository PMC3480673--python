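"""End-to-end electromechanical pipeline for one heart configuration.

:class:`HeartModel` bundles the synthetic anatomy, the monodomain solver, the
assembled contraction model and the index sampling machinery, caching every
protocol-independent factorization so a pacing sweep only pays for the time
stepping of each configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import config as _config
from . import electrics, indices, mechanics, synthetic_heart
from .electrics import ActivationMap, MonodomainSolver, PacingProtocol
from .indices import RingStrainSeries, SegmentStrainTraces, VolumePair
from .synthetic_heart import segment_of_angle


@dataclass
class MechanicsRun:
    """Per-frame mechanics output for one activation map."""

    times: np.ndarray                    # (T,) ms
    ring_ecc: np.ndarray                 # (n_slices, T, n_samples)
    e1_di_ring: np.ndarray               # (T, n_samples) at the DI layer
    volumes: np.ndarray                  # (T,) mL
    displacements: np.ndarray | None = None  # (T, N, 3), optional


class HeartModel:
    """Synthetic biventricular electromechanical model, config-driven."""

    def __init__(self, cfg: dict | None = None):
        self.cfg = _config._merge(_config.DEFAULTS, cfg or {})
        spec = _config.mesh_spec_from(self.cfg)
        mesh = synthetic_heart.build_biventricular_mesh(spec)
        synthetic_heart.label_segments(mesh)
        synthetic_heart.assign_fiber_orientations(
            mesh, self.cfg["fibers"]["endo_angle_deg"],
            self.cfg["fibers"]["epi_angle_deg"])
        self.mesh = mesh
        self.sites = {s.name: s for s in synthetic_heart.default_lead_sites(mesh)}
        self.conduction = synthetic_heart.default_conduction(
            mesh, lbbb=self.cfg["conduction"]["lbbb"],
            velocity_scale_fast=self.cfg["conduction"]["fast_shell_multiplier"])
        self.eparams = _config.monodomain_params_from(self.cfg)
        self.material = _config.material_from(self.cfg)
        self.twitch = _config.twitch_from(self.cfg)
        self._solver: MonodomainSolver | None = None
        self._mech: mechanics.AssembledModel | None = None
        self._samples: dict[int, mechanics.SamplePoints] = {}
        self._maps: dict[str, ActivationMap] = {}

    # -- cached heavy pieces ------------------------------------------------

    @property
    def solver(self) -> MonodomainSolver:
        if self._solver is None:
            self._solver = MonodomainSolver(self.mesh, self.eparams, self.conduction)
        return self._solver

    @property
    def mech_model(self) -> mechanics.AssembledModel:
        if self._mech is None:
            self._mech = mechanics.assemble_global(
                self.mesh, self.material,
                base_spring=self.cfg["mechanics"]["base_spring"])
        return self._mech

    def ring_samples(self, layer: int) -> mechanics.SamplePoints:
        if layer not in self._samples:
            self._samples[layer] = mechanics.midwall_ring_samples(
                self.mesh, layer, self.cfg["indices"]["n_ring_samples"])
        return self._samples[layer]

    # -- activation protocols ----------------------------------------------

    def sinus_map(self) -> ActivationMap:
        if "sinus" not in self._maps:
            self._maps["sinus"] = electrics.sinus_reference(
                self.mesh, self.eparams, self.conduction, solver=self.solver)
        return self._maps["sinus"]

    def lbbb_map(self) -> ActivationMap:
        if "lbbb" not in self._maps:
            self._maps["lbbb"] = electrics.lbbb_protocol(
                self.mesh, self.eparams, self.conduction, solver=self.solver)
        return self._maps["lbbb"]

    def paced_map(self, protocol: PacingProtocol) -> ActivationMap:
        return electrics.paced_protocol(self.mesh, self.eparams, self.conduction,
                                        protocol, solver=self.solver)

    def make_protocol(self, lv_site: str, vvd: float) -> PacingProtocol:
        st = self.cfg["stimulus"]
        return PacingProtocol(lv_site=self.sites[lv_site], rv_site=self.sites["RVA"],
                              vvd=vvd, amplitude=st["amplitude"],
                              duration=st["duration_ms"], stim_radius=st["radius_mm"])

    # -- mechanics and indices ----------------------------------------------

    def run_mechanics(self, amap: ActivationMap, keep_displacements: bool = False) -> MechanicsRun:
        m = self.cfg["mechanics"]
        times = np.arange(0.0, m["frame_end_ms"] + 0.5 * m["frame_ms"], m["frame_ms"])
        cure_layers = self.cfg["indices"]["cure_layers"]
        di_layer = self.cfg["indices"]["di_layer"]
        n_s = self.cfg["indices"]["n_ring_samples"]
        ring_ecc = np.zeros((len(cure_layers), len(times), n_s))
        e1_ring = np.zeros((len(times), n_s))
        vols = np.zeros(len(times))
        disp_store = [] if keep_displacements else None
        for fi, t in enumerate(times):
            d = mechanics.solve_frame(self.mech_model, self.mesh, amap.times,
                                      self.twitch, float(t))
            for li, layer in enumerate(cure_layers):
                s = mechanics.strain_at_samples(self.mesh, d, self.ring_samples(layer))
                ring_ecc[li, fi] = s.ecc
                if layer == di_layer:
                    e1_ring[fi] = s.e1
            if di_layer not in cure_layers:
                s = mechanics.strain_at_samples(self.mesh, d, self.ring_samples(di_layer))
                e1_ring[fi] = s.e1
            vols[fi] = indices.cavity_volume(self.mesh, d.u)
            if keep_displacements:
                disp_store.append(d.u)
        return MechanicsRun(times=times, ring_ecc=ring_ecc, e1_di_ring=e1_ring,
                            volumes=vols,
                            displacements=np.array(disp_store) if keep_displacements else None)

    def ring_series(self, amap: ActivationMap, run: MechanicsRun) -> RingStrainSeries:
        """Systolic-window ring strain: earliest activation to minimum volume."""
        t0 = amap.earliest()
        i_end = int(np.argmin(run.volumes))
        mask = (run.times >= t0) & (np.arange(len(run.times)) <= i_end)
        if not mask.any():
            mask = np.arange(len(run.times)) <= max(i_end, 1)
        layers = tuple(self.cfg["indices"]["cure_layers"])
        return RingStrainSeries(values=run.ring_ecc[:, mask, :],
                                angles=self.ring_samples(layers[0]).angles,
                                layers=layers, times=run.times[mask])

    def segment_traces(self, run: MechanicsRun) -> SegmentStrainTraces:
        di_layer = self.cfg["indices"]["di_layer"]
        samples = self.ring_samples(di_layer)
        seg = segment_of_angle(samples.angles - self.mesh.meta["phi_septum"])
        traces = {}
        for name in synthetic_heart.SEGMENTS_LV:
            sel = seg == name
            traces[name] = run.e1_di_ring[:, sel].mean(axis=1)
        return SegmentStrainTraces(times=run.times, traces=traces)

    def evaluate(self, amap: ActivationMap, label: str = "",
                 lv_site: str | None = None, vvd: float | None = None) -> dict:
        """All four indices for one activation map; one record of the sweep."""
        run = self.run_mechanics(amap)
        series = self.ring_series(amap, run)
        edv = indices.cavity_volume(self.mesh)
        esv = float(run.volumes.min())
        vol = VolumePair(EDV=edv, ESV=esv)
        traces = self.segment_traces(run)
        peaks = traces.peak_times()
        return {
            "label": label or amap.protocol,
            "lv_site": lv_site,
            "vvd_ms": vvd,
            "cure": indices.cure(series),
            "e_rms_ms": indices.e_rms(amap, self.sinus_map()),
            "di_ms": indices.dyssynchrony_index(traces),
            "lvef": indices.lvef(vol),
            "edv_ml": edv,
            "esv_ml": esv,
            "pmps": float(max(t.max() for t in traces.traces.values())),
            "peak_times_ms": peaks,
            "latest_activation_ms": amap.latest(),
            "status": "ok",
        }
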