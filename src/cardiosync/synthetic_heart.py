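"""Idealized biventricular anatomy generator.

Builds a two-ellipsoid truncated biventricular hexahedral mesh: a thick-walled
prolate-ellipsoid left ventricle (whose septal sector carries the septum) and a
right-ventricular free wall bulging from the LV epicardium over a
circumferential sector.  Elements carry a longitudinal layer index (1 at the
apex to ``n_layers`` at the base, equal-height bands), a wall-segment label
(anterior / lateral / posterior / septum / rv_free_wall), and a rule-based
transmurally rotating fiber field.  An endocardial fast-conduction shell with
bilateral bundle entry nodes stands in for the Purkinje network; suppressing
the left entry produces the left-bundle-branch-block substrate.

All lengths are in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import hexfem

SEGMENTS_LV = ("anterior", "lateral", "posterior", "septum")
LEAD_NAMES = ("RVA", "POST-B", "POST-E", "LAT-B", "LAT-E", "ANT-B", "ANT-E")


class MeshError(ValueError):
    """Raised for degenerate mesh specifications or invalid elements."""


@dataclass
class MeshSpec:
    """Geometric parameters of the idealized biventricular mesh.

    Parameters
    ----------
    lv_endo_radii : (a, b, c) semi-axes of the LV cavity ellipsoid, mm.
        ``c`` is the long (apex-base) axis.
    wall_thickness_lv, wall_thickness_rv, wall_thickness_septum : mm.
    n_layers : longitudinal element bands, apex (1) to base (n_layers).
    n_circumferential : elements per ring.
    n_transmural : LV wall elements across the wall.
    base_truncation_fraction : fraction of the full long axis retained from
        the apex; the flat base plane sits at ``z = c*(2f - 1)``.
    rv_sector_deg : circumferential extent of the RV attachment.
    rv_bulge_mm : maximal RV cavity gap between LV epicardium and RV wall.
    rv_apex_layer : layer at which the RV free wall begins (tapered closed).
    n_transmural_rv : RV free-wall elements across the wall.
    septal_center_deg : circumferential position of the septal bisector.
    """

    lv_endo_radii: tuple[float, float, float] = (16.0, 16.0, 40.0)
    wall_thickness_lv: float = 10.0
    wall_thickness_rv: float = 4.0
    wall_thickness_septum: float = 8.0
    n_layers: int = 14
    n_circumferential: int = 36
    n_transmural: int = 4
    base_truncation_fraction: float = 0.75
    rv_sector_deg: float = 130.0
    rv_bulge_mm: float = 9.0
    rv_apex_layer: int | None = None
    n_transmural_rv: int = 1
    septal_center_deg: float = 180.0

    def validate(self) -> None:
        a, b, c = self.lv_endo_radii
        if min(a, b, c) <= 0:
            raise MeshError("LV endocardial semi-axes must be positive")
        for name in ("wall_thickness_lv", "wall_thickness_rv", "wall_thickness_septum"):
            if getattr(self, name) <= 0:
                raise MeshError(f"{name} must be positive")
        if self.n_layers < 6:
            raise MeshError("n_layers must be >= 6 so equatorial layers 6-9 exist")
        if not 0.0 < self.base_truncation_fraction < 1.0:
            raise MeshError("base_truncation_fraction must lie in (0, 1)")
        if self.n_circumferential < 8:
            raise MeshError("n_circumferential must be >= 8")
        if self.n_transmural < 1 or self.n_transmural_rv < 1:
            raise MeshError("transmural element counts must be >= 1")

    @property
    def rv_start_layer(self) -> int:
        if self.rv_apex_layer is not None:
            return self.rv_apex_layer
        return max(2, self.n_layers // 3)


@dataclass
class LeadSite:
    """A resolved pacing-electrode site on the mesh."""

    name: str
    wall: str  # 'rv_endo_apex' or 'lv_epi'
    circumferential_position: str | None
    longitudinal_level: str
    node_id: int


@dataclass
class ConductionConfig:
    """Endocardial fast-shell stand-in for the Purkinje network.

    ``fast_shell_mask`` flags the full bilateral shell; ``lv_shell_mask`` its
    LV-endocardial portion.  In the left-bundle-branch-block substrate the LV
    portion is functionally disconnected from its input and conducts as
    ordinary myocardium (the LV then activates only by transseptal myocardial
    spread), while the right network and the septal face stay intact.
    """

    fast_shell_mask: np.ndarray  # (E,) bool, full bilateral shell
    lbbb: bool
    right_bundle_site: int
    left_bundle_site: int
    velocity_scale_fast: float = 6.0
    lv_shell_mask: np.ndarray | None = None  # (E,) bool, LV-endocardial portion

    def active_mask(self) -> np.ndarray:
        """The shell elements that actually conduct fast for this substrate."""
        if self.lbbb and self.lv_shell_mask is not None:
            return self.fast_shell_mask & ~self.lv_shell_mask
        return self.fast_shell_mask


@dataclass
class HeartMesh:
    """Hexahedral biventricular mesh with per-element anatomy labels."""

    nodes: np.ndarray            # (N, 3) mm
    elements: np.ndarray         # (E, 8) int, VTK corner order
    layer: np.ndarray            # (E,) int, 1..n_layers
    part: np.ndarray             # (E,) str, 'lv' | 'rv'
    grid_index: np.ndarray       # (E, 3) int, (level, transmural, circumferential)
    surfaces: dict[str, np.ndarray]  # tag -> (F, 4) node quads
    segment: np.ndarray | None = None   # (E,) str after label_segments
    fibers: np.ndarray | None = None    # (E, 3) unit vectors after assign_fiber_orientations
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_coords(self) -> np.ndarray:
        return self.nodes[self.elements]

    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def surface_nodes(self, tag: str) -> np.ndarray:
        return np.unique(self.surfaces[tag].ravel())


def _wrap(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to (-pi, pi]."""
    return np.pi - np.mod(np.pi - angle, 2.0 * np.pi)


def build_biventricular_mesh(spec: MeshSpec) -> HeartMesh:
    """Build the truncated two-ellipsoid biventricular hexahedral mesh.

    The LV wall is meshed on a (level, transmural, circumferential) grid of an
    ellipsoidal shell; the apex pole is closed with collapsed-hex wedges
    sharing on-axis nodes.  The RV free wall is extruded outward from the LV
    epicardium over ``rv_sector_deg``, tapering to zero thickness (shared
    nodes) at the sector edges and at its apical end so the two walls are
    mechanically and electrically continuous.

    Raises
    ------
    MeshError
        If the specification is degenerate or any retained element has a
        non-positive Jacobian determinant at a quadrature point.
    """
    spec.validate()
    a, b, c = spec.lv_endo_radii
    nL, nC, nT = spec.n_layers, spec.n_circumferential, spec.n_transmural
    z_base = c * (2.0 * spec.base_truncation_fraction - 1.0)
    phi_sep = np.deg2rad(spec.septal_center_deg)
    half_sector = 0.5 * np.deg2rad(spec.rv_sector_deg)

    def wall_thickness(phi: float) -> float:
        d = abs(float(_wrap(phi - phi_sep)))
        if d >= half_sector:
            return spec.wall_thickness_lv
        u = 0.5 * (1.0 + np.cos(np.pi * d / half_sector))  # 1 at center, 0 at edge
        return spec.wall_thickness_lv + (spec.wall_thickness_septum - spec.wall_thickness_lv) * u

    phis = 2.0 * np.pi * np.arange(nC) / nC

    nodes: list[np.ndarray] = []
    nid: dict[tuple, int] = {}

    def add(key: tuple, xyz) -> int:
        if key not in nid:
            nid[key] = len(nodes)
            nodes.append(np.asarray(xyz, dtype=float))
        return nid[key]

    # --- LV shell nodes -----------------------------------------------------
    def lv_point(i: int, j: int, k: int) -> np.ndarray:
        s = j / nT
        phi = phis[k]
        t = wall_thickness(phi)
        A, B = a + s * t, b + s * t
        C = c + s * spec.wall_thickness_lv
        z = -C + (i / nL) * (z_base + C)
        cosmu = np.clip(-z / C, -1.0, 1.0)
        sinmu = np.sqrt(max(0.0, 1.0 - cosmu * cosmu))
        return np.array([A * sinmu * np.cos(phi), B * sinmu * np.sin(phi), z])

    for j in range(nT + 1):
        add(("lv", 0, j), lv_point(0, j, 0))  # apex pole, one node per surface
    for i in range(1, nL + 1):
        for j in range(nT + 1):
            for k in range(nC):
                add(("lv", i, j, k), lv_point(i, j, k))

    def lvn(i: int, j: int, k: int) -> int:
        return nid[("lv", 0, j)] if i == 0 else nid[("lv", i, j, k)]

    elems: list[list[int]] = []
    layer: list[int] = []
    part: list[str] = []
    gidx: list[tuple[int, int, int]] = []

    for i in range(1, nL + 1):
        for j in range(nT):
            for k in range(nC):
                k2 = (k + 1) % nC
                elems.append(
                    [lvn(i - 1, j, k), lvn(i - 1, j + 1, k), lvn(i - 1, j + 1, k2),
                     lvn(i - 1, j, k2), lvn(i, j, k), lvn(i, j + 1, k),
                     lvn(i, j + 1, k2), lvn(i, j, k2)]
                )
                layer.append(i)
                part.append("lv")
                gidx.append((i, j, k))

    # --- RV free wall -------------------------------------------------------
    i0 = spec.rv_start_layer
    nTr = spec.n_transmural_rv
    m = int(round(nC * spec.rv_sector_deg / 360.0)) + 1
    m = max(4, m + (1 - m % 2))  # odd count, centered on the septal bisector
    kc = int(round(phi_sep / (2.0 * np.pi / nC)))
    cols = [(kc + o) % nC for o in range(-(m // 2), m // 2 + 1)]

    def w_circ(ci: int) -> float:
        u = ci / (m - 1)
        return float(np.sin(np.pi * u))

    def w_long(i: int) -> float:
        u = (i - i0) / max(1, nL - i0)
        return float(np.sin(0.5 * np.pi * min(1.0, u / 0.5)))

    for i in range(i0, nL + 1):
        for ci, k in enumerate(cols):
            w = w_long(i) * w_circ(ci)
            if w <= 1e-12:
                for jr in range(nTr + 1):
                    nid[("rv", i, jr, ci)] = lvn(i, nT, k)
                continue
            base_pt = nodes[lvn(i, nT, k)]
            u_out = np.array([np.cos(phis[k]), np.sin(phis[k]), 0.0])
            for jr in range(nTr + 1):
                off = w * (spec.rv_bulge_mm + spec.wall_thickness_rv * jr / nTr)
                add(("rv", i, jr, ci), base_pt + off * u_out)

    def rvn(i: int, jr: int, ci: int) -> int:
        return nid[("rv", i, jr, ci)]

    node_arr = np.array(nodes)
    rv_elems: list[list[int]] = []
    rv_gidx: list[tuple[int, int, int]] = []
    for i in range(i0 + 1, nL + 1):
        for ci in range(m - 1):
            for jr in range(nTr):
                conn = [rvn(i - 1, jr, ci), rvn(i - 1, jr + 1, ci),
                        rvn(i - 1, jr + 1, ci + 1), rvn(i - 1, jr, ci + 1),
                        rvn(i, jr, ci), rvn(i, jr + 1, ci),
                        rvn(i, jr + 1, ci + 1), rvn(i, jr, ci + 1)]
                rv_elems.append(conn)
                rv_gidx.append((i, jr, ci))

    # Drop degenerate RV corner slivers (collapsed in two directions).
    dropped = 0
    if rv_elems:
        minJ = hexfem.min_jacobian(node_arr[np.array(rv_elems)])
        # absolute floor (mm^3 per unit reference volume): keeps tapered
        # attachment wedges, drops corner slivers and zero-thickness films
        keep = minJ > 1e-3
        dropped = int((~keep).sum())
        rv_kept = [e for e, ok in zip(rv_elems, keep) if ok]
        rv_gidx = [g for g, ok in zip(rv_gidx, keep) if ok]
    else:
        rv_kept = []

    for (i, jr, ci), conn in zip(rv_gidx, rv_kept):
        elems.append(conn)
        layer.append(i)
        part.append("rv")
        gidx.append((i, jr, ci))

    elements = np.array(elems, dtype=np.int64)
    layer_arr = np.array(layer, dtype=np.int64)
    part_arr = np.array(part, dtype=object)
    gidx_arr = np.array(gidx, dtype=np.int64)

    # --- validity -----------------------------------------------------------
    minJ = hexfem.min_jacobian(node_arr[elements])
    bad = np.where(minJ <= 0.0)[0]
    if bad.size:
        raise MeshError(
            f"degenerate spec: non-positive Jacobian determinant in element(s) "
            f"{bad[:5].tolist()} (part={part_arr[bad[0]]}, grid={gidx_arr[bad[0]].tolist()})"
        )

    # --- surface tags -------------------------------------------------------
    in_sector = {k: ci for ci, k in enumerate(cols)}
    lv_endo, rv_endo, epi, base = [], [], [], []
    for e, conn in enumerate(elements):
        i, j, k = gidx_arr[e]
        if part_arr[e] == "lv":
            if j == 0:
                lv_endo.append([conn[0], conn[3], conn[7], conn[4]])
            if j == nT - 1:
                face = [conn[1], conn[2], conn[6], conn[5]]
                ci = in_sector.get(int(k))
                ci2 = in_sector.get(int((k + 1) % nC))
                gap = (spec.rv_bulge_mm + spec.wall_thickness_rv) * w_long(int(i))
                covered = (
                    ci is not None and ci2 is not None and i > i0
                    and gap * min(w_circ(ci), w_circ(ci2)) > 1e-3
                )
                (rv_endo if covered else epi).append(face)
        else:
            if j == 0:
                rv_endo.append([conn[0], conn[3], conn[7], conn[4]])
            if j == nTr - 1:
                epi.append([conn[1], conn[2], conn[6], conn[5]])
        if i == nL:
            base.append([conn[4], conn[5], conn[6], conn[7]])

    surfaces = {
        "lv_endo": np.array(lv_endo, dtype=np.int64),
        "rv_endo": np.array(rv_endo, dtype=np.int64).reshape(-1, 4),
        "epi": np.array(epi, dtype=np.int64),
        "base": np.array(base, dtype=np.int64),
    }

    # Compact away nodes orphaned by dropped sliver elements.
    used = np.unique(elements)
    if used.size < len(node_arr):
        remap = -np.ones(len(node_arr), dtype=np.int64)
        remap[used] = np.arange(used.size)
        node_arr = node_arr[used]
        elements = remap[elements]
        surfaces = {t: remap[q].reshape(-1, 4) if len(q) else q
                    for t, q in surfaces.items()}

    meta = {
        "spec": spec,
        "z_base": z_base,
        "phi_septum": phi_sep,
        "rv_cols": cols,
        "rv_start_layer": i0,
        "dropped_rv_slivers": dropped,
        "apex": np.array([0.0, 0.0, -(c + spec.wall_thickness_lv)]),
    }
    return HeartMesh(
        nodes=node_arr, elements=elements, layer=layer_arr, part=part_arr,
        grid_index=gidx_arr, surfaces=surfaces, meta=meta,
    )


# ---------------------------------------------------------------------------
# Fibers
# ---------------------------------------------------------------------------

def element_frames(mesh: HeartMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-element local wall frame (circumferential, longitudinal, normal).

    The transmural normal is the direction from the inner to the outer element
    face; the circumferential direction is its horizontal tangent.  Returns
    ``(c_hat, l_hat, n_hat, degenerate)`` where ``degenerate`` flags elements
    (apex cap) whose frame is ill-defined.
    """
    X = mesh.element_coords()
    inner = X[:, [0, 3, 4, 7]].mean(axis=1)
    outer = X[:, [1, 2, 5, 6]].mean(axis=1)
    n_hat = outer - inner
    n_hat /= np.linalg.norm(n_hat, axis=1, keepdims=True)
    zhat = np.array([0.0, 0.0, 1.0])
    c_raw = np.cross(np.broadcast_to(zhat, n_hat.shape), n_hat)
    c_norm = np.linalg.norm(c_raw, axis=1)
    degenerate = c_norm < 0.1
    c_hat = np.zeros_like(c_raw)
    ok = ~degenerate
    c_hat[ok] = c_raw[ok] / c_norm[ok, None]
    l_hat = np.cross(n_hat, c_hat)
    ln = np.linalg.norm(l_hat, axis=1, keepdims=True)
    l_hat = np.divide(l_hat, ln, out=np.zeros_like(l_hat), where=ln > 0)
    return c_hat, l_hat, n_hat, degenerate


def assign_fiber_orientations(mesh: HeartMesh, endo_angle: float = 60.0,
                              epi_angle: float = -60.0) -> HeartMesh:
    """Rule-based transmural helix fiber field.

    The helix angle (degrees, measured from the circumferential direction
    toward the longitudinal direction in the local wall tangent plane) is
    interpolated linearly in normalized transmural depth from ``endo_angle``
    at the endocardium to ``epi_angle`` at the epicardium.  Apex-cap elements
    with no defined circumferential direction inherit the fiber of the nearest
    well-defined neighbor.  Deterministic: repeated calls are bit-identical.
    """
    for ang in (endo_angle, epi_angle):
        if not -90.0 <= ang <= 90.0:
            raise ValueError("helix angles must lie in [-90, 90] degrees")
    spec: MeshSpec = mesh.meta["spec"]
    c_hat, l_hat, _, degenerate = element_frames(mesh)

    nT = np.where(mesh.part == "lv", spec.n_transmural, spec.n_transmural_rv)
    depth = (mesh.grid_index[:, 1] + 0.5) / nT
    alpha = np.deg2rad(endo_angle + (epi_angle - endo_angle) * depth)
    fibers = np.cos(alpha)[:, None] * c_hat + np.sin(alpha)[:, None] * l_hat

    if degenerate.any():
        cent = mesh.centroids()
        good = np.where(~degenerate)[0]
        for e in np.where(degenerate)[0]:
            d2 = np.einsum("ij,ij->i", cent[good] - cent[e], cent[good] - cent[e])
            fibers[e] = fibers[good[np.argmin(d2)]]

    fibers /= np.linalg.norm(fibers, axis=1, keepdims=True)
    mesh.fibers = fibers
    return mesh


# ---------------------------------------------------------------------------
# Segments, lead sites, conduction system
# ---------------------------------------------------------------------------

def segment_of_angle(delta: np.ndarray) -> np.ndarray:
    """LV wall-segment label from the angle to the septal bisector.

    Quadrants about the LV long axis in the anatomical circumferential order
    septum -> anterior -> lateral -> posterior: septum within 45 degrees of the
    bisector, lateral opposite it.
    """
    delta = _wrap(np.asarray(delta, dtype=float))
    out = np.empty(delta.shape, dtype=object)
    out[np.abs(delta) <= np.pi / 4] = "septum"
    out[(delta > np.pi / 4) & (delta < 3 * np.pi / 4)] = "anterior"
    out[np.abs(delta) >= 3 * np.pi / 4] = "lateral"
    out[(delta < -np.pi / 4) & (delta > -3 * np.pi / 4)] = "posterior"
    return out


def label_segments(mesh: HeartMesh) -> HeartMesh:
    """Assign one wall-segment label per element (idempotent)."""
    cent = mesh.centroids()
    phi = np.arctan2(cent[:, 1], cent[:, 0])
    seg = segment_of_angle(phi - mesh.meta["phi_septum"])
    seg[mesh.part == "rv"] = "rv_free_wall"
    mesh.segment = seg
    return mesh


def _pick_node(mesh: HeartMesh, candidates: np.ndarray, phi_target: float,
               z_target: float, radius_ref: float) -> int:
    p = mesh.nodes[candidates]
    phi = np.arctan2(p[:, 1], p[:, 0])
    score = (radius_ref * _wrap(phi - phi_target)) ** 2 + (p[:, 2] - z_target) ** 2
    return int(candidates[np.argmin(score)])


def default_lead_sites(mesh: HeartMesh) -> list[LeadSite]:
    """Resolve the 7-site lead catalogue: RVA plus {POST, LAT, ANT} x {B, E}.

    The six LV sites are epicardial nodes at the centers of the posterior,
    lateral and anterior quadrants; equator sites sit within layers 6-9 and
    base sites in the top two layers below the basal ring.  RVA is the RV
    endocardial node nearest the apex.
    """
    if mesh.segment is None:
        raise MeshError("label_segments must run before lead-site resolution")
    spec: MeshSpec = mesh.meta["spec"]
    a, _, c = spec.lv_endo_radii
    nL = spec.n_layers
    phi_sep = mesh.meta["phi_septum"]
    z_base = mesh.meta["z_base"]

    rv_nodes = mesh.surface_nodes("rv_endo")
    if rv_nodes.size == 0:
        raise MeshError("unresolvable site RVA: mesh has no rv_endo surface")
    d2 = np.einsum("ij,ij->i", mesh.nodes[rv_nodes] - mesh.meta["apex"],
                   mesh.nodes[rv_nodes] - mesh.meta["apex"])
    sites = [LeadSite("RVA", "rv_endo_apex", None, "apex", int(rv_nodes[np.argmin(d2)]))]

    epi_nodes = mesh.surface_nodes("epi")
    # keep basal-ring nodes out of the 'base' level targets
    epi_nodes = epi_nodes[mesh.nodes[epi_nodes, 2] < z_base - 1e-9]
    if epi_nodes.size == 0:
        raise MeshError("unresolvable LV sites: mesh has no epicardial surface")
    c_epi = c + spec.wall_thickness_lv
    # longitudinal targets on the endocardial axis scale
    z_eq = -c + (7.5 / nL) * (z_base + c)          # middle of layers 6-9
    z_b = -c + ((nL - 1.0) / nL) * (z_base + c)    # top two layers below base
    offsets = {"posterior": -np.pi / 2, "lateral": np.pi, "anterior": np.pi / 2}
    for pos, dphi in offsets.items():
        for lvl, z_t in (("base", z_b), ("equator", z_eq)):
            name = {"posterior": "POST", "lateral": "LAT", "anterior": "ANT"}[pos]
            node = _pick_node(mesh, epi_nodes, phi_sep + dphi, z_t, a)
            sites.append(LeadSite(f"{name}-{'B' if lvl == 'base' else 'E'}",
                                  "lv_epi", pos, lvl, node))
    order = {n: i for i, n in enumerate(LEAD_NAMES)}
    sites.sort(key=lambda s: order[s.name])
    return sites


def default_conduction(mesh: HeartMesh, lbbb: bool = True,
                       velocity_scale_fast: float = 6.0) -> ConductionConfig:
    """Fast endocardial shell plus bilateral bundle entry nodes.

    The shell comprises the LV subendocardial element layer, the RV
    subendocardial layer, and the RV-facing septal element layer.  Bundle
    entries sit on the septal endocardium near the base.  With ``lbbb`` the
    left entry receives no stimulus; the shell itself stays intact.
    """
    spec: MeshSpec = mesh.meta["spec"]
    nT, i0 = spec.n_transmural, mesh.meta["rv_start_layer"]
    cols = set(mesh.meta["rv_cols"])
    lv = mesh.part == "lv"
    j = mesh.grid_index[:, 1]
    i = mesh.grid_index[:, 0]
    k = mesh.grid_index[:, 2]
    septal_rv_side = lv & (j == nT - 1) & (i > i0) & np.isin(k, list(cols))
    lv_shell = lv & (j == 0)
    mask = lv_shell | (~lv & (j == 0)) | septal_rv_side

    phi_sep = mesh.meta["phi_septum"]
    spec_nL = spec.n_layers
    z_t = -spec.lv_endo_radii[2] + ((spec_nL - 2.0) / spec_nL) * (
        mesh.meta["z_base"] + spec.lv_endo_radii[2])
    left = _pick_node(mesh, mesh.surface_nodes("lv_endo"), phi_sep, z_t,
                      spec.lv_endo_radii[0])
    right = _pick_node(mesh, mesh.surface_nodes("rv_endo"), phi_sep, z_t,
                       spec.lv_endo_radii[0])
    return ConductionConfig(
        fast_shell_mask=mask, lbbb=lbbb, right_bundle_site=right,
        left_bundle_site=left, velocity_scale_fast=velocity_scale_fast,
        lv_shell_mask=lv_shell,
    )


def refine(spec: MeshSpec) -> MeshSpec:
    """Double the angular and longitudinal resolution of a spec."""
    return replace(
        spec,
        n_layers=spec.n_layers * 2,
        n_circumferential=spec.n_circumferential * 2,
        rv_apex_layer=spec.rv_start_layer * 2,
    )


def truncated_ellipsoid_volume(radii: tuple[float, float, float],
                               base_truncation_fraction: float) -> float:
    """Analytic volume of the LV cavity: ellipsoid below the base plane."""
    a, b, c = radii
    z0 = c * (2.0 * base_truncation_fraction - 1.0)
    return np.pi * a * b * ((z0 + c) - (z0 ** 3 + c ** 3) / (3.0 * c ** 2))
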