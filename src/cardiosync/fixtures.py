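"""Synthetic micro-fixtures for stage-by-stage testing.

Analytic ring-strain series with prescribed zero/first-harmonic content,
regular slab meshes, prescribed activation maps, and simple cavity surfaces.
Every generator is deterministic and stamps its parameters into the output
metadata.  The core contract: ``cure(make_ring_series(c, a, ...))`` equals
``sqrt(c^2 / (c^2 + 2 a^2))`` in closed form.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .indices import RingStrainSeries
from .synthetic_heart import HeartMesh


@dataclass
class AnalyticRingSpec:
    """Mean-plus-first-harmonic circumferential strain pattern.

    ``eps(theta_j) = c + a sin(theta_j + phase)`` at every slice and frame.
    """

    c: float
    a: float
    phase: float = 0.0
    n_samples: int = 30
    n_frames: int = 10
    n_slices: int = 4

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("need at least 4 circumferential samples")

    @property
    def expected_cure(self) -> float:
        """Closed-form CURE of the generated series."""
        return float(np.sqrt(self.c ** 2 / (self.c ** 2 + 2.0 * self.a ** 2)))


def make_ring_series(spec: AnalyticRingSpec) -> RingStrainSeries:
    """Generate the analytic ring-strain series for ``spec``."""
    theta = 2.0 * np.pi * np.arange(spec.n_samples) / spec.n_samples
    ring = spec.c + spec.a * np.sin(theta + spec.phase)
    values = np.broadcast_to(ring, (spec.n_slices, spec.n_frames, spec.n_samples)).copy()
    return RingStrainSeries(values=values, angles=theta,
                            layers=tuple(range(6, 6 + spec.n_slices)),
                            meta={"fixture": "analytic_ring", **asdict(spec)})


def make_slab_mesh(nx: int, ny: int, nz: int, h: float = 1.0,
                   fiber: tuple[float, float, float] = (1.0, 0.0, 0.0)) -> HeartMesh:
    """Regular hexahedral slab with a uniform fiber field.

    Faces are tagged ``xmin/xmax/ymin/ymax/zmin/zmax``; elements carry layer 1
    and no anatomical segment.  Drop-in input for the excitation and
    contraction solvers.
    """
    if min(nx, ny, nz) < 1 or h <= 0:
        raise ValueError("element counts and spacing must be positive")
    xs = np.arange(nx + 1) * h
    ys = np.arange(ny + 1) * h
    zs = np.arange(nz + 1) * h
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    elems = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                elems.append([nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k),
                              nid(i, j + 1, k), nid(i, j, k + 1), nid(i + 1, j, k + 1),
                              nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)])
    elements = np.array(elems, dtype=np.int64)

    def face_quads(axis, side):
        quads = []
        sel = {0: (0 if side == 0 else nx), 1: (0 if side == 0 else ny),
               2: (0 if side == 0 else nz)}[axis]
        if axis == 0:
            for j in range(ny):
                for k in range(nz):
                    quads.append([nid(sel, j, k), nid(sel, j + 1, k),
                                  nid(sel, j + 1, k + 1), nid(sel, j, k + 1)])
        elif axis == 1:
            for i in range(nx):
                for k in range(nz):
                    quads.append([nid(i, sel, k), nid(i + 1, sel, k),
                                  nid(i + 1, sel, k + 1), nid(i, sel, k + 1)])
        else:
            for i in range(nx):
                for j in range(ny):
                    quads.append([nid(i, j, sel), nid(i + 1, j, sel),
                                  nid(i + 1, j + 1, sel), nid(i, j + 1, sel)])
        return np.array(quads, dtype=np.int64)

    surfaces = {"xmin": face_quads(0, 0), "xmax": face_quads(0, 1),
                "ymin": face_quads(1, 0), "ymax": face_quads(1, 1),
                "zmin": face_quads(2, 0), "zmax": face_quads(2, 1)}

    E = len(elements)
    f = np.asarray(fiber, dtype=float)
    f = f / np.linalg.norm(f)
    return HeartMesh(
        nodes=nodes, elements=elements,
        layer=np.ones(E, dtype=np.int64),
        part=np.array(["lv"] * E, dtype=object),
        grid_index=np.zeros((E, 3), dtype=np.int64),
        surfaces=surfaces,
        segment=np.array(["anterior"] * E, dtype=object),
        fibers=np.tile(f, (E, 1)),
        meta={"fixture": "slab", "nx": nx, "ny": ny, "nz": nz, "h": h},
    )


def make_activation_fixture(mesh: HeartMesh, pattern: str, *, t0: float = 0.0,
                            gradient_ms_per_mm: float = 1.0, axis: int = 0,
                            offset_ms: float = 60.0) -> np.ndarray:
    """Prescribed analytic activation times per node (ms).

    Patterns: ``uniform`` (all ``t0``), ``linear`` (``t0`` plus a gradient
    along a coordinate axis), ``two-zone`` (septal-early / lateral-late split
    at the mesh mid-plane of the axis, offset by ``offset_ms``).
    """
    x = mesh.nodes[:, axis]
    if pattern == "uniform":
        return np.full(mesh.n_nodes, float(t0))
    if pattern == "linear":
        return t0 + gradient_ms_per_mm * (x - x.min())
    if pattern == "two-zone":
        mid = 0.5 * (x.min() + x.max())
        return np.where(x <= mid, float(t0), float(t0) + offset_ms)
    raise ValueError(f"unknown activation pattern '{pattern}'")


def make_spherical_cavity_fixture(radius: float = 10.0, n_theta: int = 32,
                                  n_phi: int = 64) -> HeartMesh:
    """Closed sphere tagged ``lv_endo``: synthetic stand-in cavity surface.

    Used to verify the divergence-theorem volume against ``4 pi r^3 / 3``.
    Carries no volumetric elements.
    """
    th = np.linspace(0.0, np.pi, n_theta + 1)
    ph = 2.0 * np.pi * np.arange(n_phi) / n_phi
    nid = {}
    nodes = []
    for i, t in enumerate(th):
        for k, p in enumerate(ph):
            key = (0, 0) if i == 0 else ((n_theta, 0) if i == n_theta else (i, k))
            if key not in nid:
                nid[key] = len(nodes)
                nodes.append([radius * np.sin(t) * np.cos(p),
                              radius * np.sin(t) * np.sin(p),
                              radius * np.cos(t)])

    def g(i, k):
        key = (0, 0) if i == 0 else ((n_theta, 0) if i == n_theta else (i, k % n_phi))
        return nid[key]

    quads = []
    for i in range(n_theta):
        for k in range(n_phi):
            quads.append([g(i, k), g(i + 1, k), g(i + 1, k + 1), g(i, k + 1)])
    E = 0
    return HeartMesh(
        nodes=np.array(nodes), elements=np.zeros((E, 8), dtype=np.int64),
        layer=np.zeros(E, dtype=np.int64), part=np.array([], dtype=object),
        grid_index=np.zeros((E, 3), dtype=np.int64),
        surfaces={"lv_endo": np.array(quads, dtype=np.int64)},
        meta={"fixture": "synthetic_sphere_cavity", "radius": radius},
    )


def make_box_cavity_fixture(lx: float, ly: float, lz: float) -> HeartMesh:
    """Open-top box tagged ``lv_endo``: exercises the basal-cap closure."""
    pts = np.array([[0, 0, 0], [lx, 0, 0], [lx, ly, 0], [0, ly, 0],
                    [0, 0, lz], [lx, 0, lz], [lx, ly, lz], [0, ly, lz]], dtype=float)
    quads = np.array([
        [0, 3, 2, 1],              # bottom, outward -z
        [0, 1, 5, 4], [1, 2, 6, 5], [2, 3, 7, 6], [3, 0, 4, 7],  # sides
    ], dtype=np.int64)
    E = 0
    return HeartMesh(
        nodes=pts, elements=np.zeros((E, 8), dtype=np.int64),
        layer=np.zeros(E, dtype=np.int64), part=np.array([], dtype=object),
        grid_index=np.zeros((E, 3), dtype=np.int64),
        surfaces={"lv_endo": quads},
        meta={"fixture": "synthetic_box_cavity", "dims": (lx, ly, lz)},
    )
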