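"""Scalar synchrony and function indices.

* CURE -- circumferential uniformity ratio estimate,
  ``sqrt(A0^2 / (A0^2 + 2 A1^2))``, where ``A0^2`` and ``A1^2`` are the
  spatial-and-temporal sums of the zero- and first-order Fourier power of
  circumferential strain around mid-wall short-axis rings (1 = perfectly
  synchronous, 0 = pure first-harmonic dyssynchrony).
* E_RMS -- root-mean-square difference between a pathological/paced
  activation map and the sinus-rhythm reference, in ms.
* DI -- dyssynchrony index: spread of time-to-peak strain across the four LV
  wall segments, in ms.
* LVEF -- (EDV - ESV)/EDV from the deformed LV cavity volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .electrics import ActivationMap
from .synthetic_heart import SEGMENTS_LV, HeartMesh


@dataclass
class RingStrainSeries:
    """Circumferential strain sampled on mid-wall rings.

    ``values[slice, frame, sample]`` holds epsilon_cc at equiangular,
    angle-ordered circumferential samples; ``angles`` are the sample angles
    (radians) shared by all slices and frames.
    """

    values: np.ndarray              # (n_slices, n_frames, n_samples)
    angles: np.ndarray              # (n_samples,)
    layers: tuple[int, ...] = ()    # source short-axis layers, informative
    times: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_slices, n_frames, n_samples)")
        if self.values.shape[2] != len(self.angles):
            raise ValueError("sample count mismatch between values and angles")


@dataclass
class FourierPowerSums:
    """Summed zero- and first-order circumferential Fourier powers."""

    A0_sq: float
    A1_sq: float


@dataclass
class SegmentStrainTraces:
    """Per-segment mean maximum-principal-strain traces on a common time axis."""

    times: np.ndarray                       # (T,) ms
    traces: dict[str, np.ndarray]           # segment -> (T,)

    def peak_times(self) -> dict[str, float]:
        """Time of each trace's global maximum (earliest frame on ties)."""
        out = {}
        for seg, y in self.traces.items():
            if np.allclose(y, y[0]):
                raise ValueError(f"flat strain trace for segment '{seg}': no peak")
            out[seg] = float(self.times[int(np.argmax(y))])
        return out


@dataclass
class VolumePair:
    """End-diastolic and end-systolic LV cavity volumes, mL."""

    EDV: float
    ESV: float

    def __post_init__(self) -> None:
        if self.EDV <= 0:
            raise ValueError("EDV must be positive")
        if self.ESV < 0:
            raise ValueError("ESV must be non-negative")


# ---------------------------------------------------------------------------
# CURE
# ---------------------------------------------------------------------------

def fourier_ring_power(ring: np.ndarray) -> tuple[float, float]:
    """Zero- and first-order circumferential Fourier power of one ring.

    For ``N`` equiangular samples ``e_j``: the zero-order power is the squared
    ring mean and the first-order power the squared amplitude of the first
    circumferential harmonic with the ``2/N`` convention,
    ``a1 = |(2/N) sum_j e_j exp(-i theta_j)|``.
    """
    ring = np.asarray(ring, dtype=float)
    n = ring.shape[-1]
    if n < 4:
        raise ValueError("ring needs at least 4 samples")
    X = np.fft.rfft(ring, axis=-1)
    p0 = np.abs(X[..., 0] / n) ** 2
    p1 = np.abs(2.0 * X[..., 1] / n) ** 2
    return p0, p1


def fourier_power_sums(series: RingStrainSeries) -> FourierPowerSums:
    """Sum ring powers over all slices and frames (uniform frame weights)."""
    p0, p1 = fourier_ring_power(series.values)
    return FourierPowerSums(A0_sq=float(np.sum(p0)), A1_sq=float(np.sum(p1)))


def cure(series: RingStrainSeries) -> float:
    """Circumferential uniformity ratio estimate in [0, 1].

    Returns 1 for spatially uniform strain (all segments synchronous) and 0
    for a pure first circumferential harmonic.  Identically zero strain has
    no defined uniformity and raises.
    """
    sums = fourier_power_sums(series)
    denom = sums.A0_sq + 2.0 * sums.A1_sq
    if denom == 0.0:
        raise ValueError("CURE undefined: strain series is identically zero")
    return float(np.sqrt(sums.A0_sq / denom))


# ---------------------------------------------------------------------------
# Electrical index
# ---------------------------------------------------------------------------

def e_rms(pathological: ActivationMap, reference: ActivationMap) -> float:
    """RMS nodal activation-time difference against the sinus reference (ms)."""
    x = reference.times
    e = pathological.times
    if x.shape != e.shape:
        raise ValueError("activation maps are defined on different node sets")
    bad = np.where(np.isnan(x) | np.isnan(e))[0]
    if bad.size:
        raise ValueError(f"unactivated nodes in activation map: {bad[:10].tolist()}")
    return float(np.sqrt(np.mean((x - e) ** 2)))


# ---------------------------------------------------------------------------
# Mechanical dispersion and hemodynamics
# ---------------------------------------------------------------------------

def dyssynchrony_index(traces: SegmentStrainTraces) -> float:
    """Latest minus earliest segmental time-to-peak strain, ms."""
    missing = [s for s in SEGMENTS_LV if s not in traces.traces]
    if missing:
        raise ValueError(f"missing segment trace(s): {missing}")
    peaks = traces.peak_times()
    vals = [peaks[s] for s in SEGMENTS_LV]
    return float(max(vals) - min(vals))


def _cavity_triangles(mesh: HeartMesh) -> np.ndarray:
    """Triangulation of the LV endocardial surface closed with a basal cap.

    The cap fans the basal boundary ring to its centroid; the centroid is a
    virtual point re-evaluated per deformed configuration and encoded as node
    index -1.
    """
    quads = mesh.surfaces["lv_endo"]
    tris = []
    for q in quads:
        if q[0] != q[1] and q[1] != q[2] and q[0] != q[2]:
            tris.append([q[0], q[1], q[2]])
        if q[0] != q[2] and q[2] != q[3] and q[0] != q[3]:
            tris.append([q[0], q[2], q[3]])
    # boundary edges appear once over the quad set
    edge_count: dict[tuple[int, int], tuple[int, int]] = {}
    for q in quads:
        for aa, bb in ((q[0], q[1]), (q[1], q[2]), (q[2], q[3]), (q[3], q[0])):
            if aa == bb:
                continue
            key = (min(aa, bb), max(aa, bb))
            if key in edge_count:
                edge_count.pop(key)
            else:
                edge_count[key] = (aa, bb)
    for aa, bb in edge_count.values():
        tris.append([bb, aa, -1])  # reversed: cap normal opposes shell winding
    return np.array(tris, dtype=np.int64)


def cavity_volume(mesh: HeartMesh, displacement: np.ndarray | None = None) -> float:
    """Deformed LV cavity volume (mL) by the divergence theorem.

    The endocardial shell is triangulated and capped at the basal ring.  A
    deformation that turns the surface inside-out (non-positive signed
    volume) is rejected.
    """
    tris = mesh.meta.get("_cavity_tris")
    if tris is None:
        tris = _cavity_triangles(mesh)
        mesh.meta["_cavity_tris"] = tris

    def signed(disp):
        x = mesh.nodes if disp is None else mesh.nodes + disp
        ring = np.unique(tris[tris[:, 2] == -1][:, :2].ravel())
        centroid = x[ring].mean(axis=0) if ring.size else np.zeros(3)
        pts = np.vstack([x, centroid[None]])
        p = pts[tris]  # -1 resolves to the appended centroid
        return np.einsum("ti,ti->t", p[:, 0], np.cross(p[:, 1], p[:, 2])).sum() / 6.0

    v0 = signed(None)
    sign = 1.0 if v0 >= 0 else -1.0
    v = sign * signed(displacement) if displacement is not None else abs(v0)
    if v <= 0:
        raise ValueError("inverted LV endocardial surface: non-positive cavity volume")
    return float(v) / 1000.0  # mm^3 -> mL


def lvef(vol: VolumePair) -> float:
    """Left-ventricular ejection fraction (EDV - ESV)/EDV, as a fraction."""
    return (vol.EDV - vol.ESV) / vol.EDV
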