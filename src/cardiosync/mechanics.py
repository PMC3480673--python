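"""Quasi-static activation-triggered contraction mechanics.

Excitation and contraction are weakly coupled: the activation-time map
triggers an active fiber-stress twitch per element, whose statically
equivalent nodal forces load a linear transversely isotropic stiffness
``K d = F_f``.  Green--Lagrange strain is computed from the resulting
displacement field as a finite-strain post-process,
``E = (F^T F - I)/2`` with ``F = I + grad u``.

Stresses in kPa, lengths in mm, times in ms; forces are then in mN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from . import hexfem
from .hexfem import DEFAULT_QUADRATURE, ElementQuadrature
from .synthetic_heart import HeartMesh, MeshError


@dataclass
class MaterialParams:
    """Transversely isotropic elasticity about the fiber axis.

    ``E_f``/``E_t`` are the fiber-axis and cross-fiber Young moduli (kPa),
    ``nu_ft`` the axial and ``nu_tt`` the in-plane Poisson ratio, ``G_ft``
    the axial shear modulus (kPa); the transverse shear modulus follows from
    in-plane isotropy.  The resulting 6x6 elasticity matrix (Voigt order
    xx, yy, zz, yz, xz, xy with fiber along x) must be SPD.
    """

    E_f: float = 60.0
    E_t: float = 20.0
    nu_ft: float = 0.45
    nu_tt: float = 0.45
    G_ft: float = 10.0

    def elasticity_matrix(self) -> np.ndarray:
        S = np.zeros((6, 6))
        S[0, 0] = 1.0 / self.E_f
        S[1, 1] = S[2, 2] = 1.0 / self.E_t
        S[0, 1] = S[1, 0] = S[0, 2] = S[2, 0] = -self.nu_ft / self.E_f
        S[1, 2] = S[2, 1] = -self.nu_tt / self.E_t
        G_tt = self.E_t / (2.0 * (1.0 + self.nu_tt))
        S[3, 3] = 1.0 / G_tt
        S[4, 4] = S[5, 5] = 1.0 / self.G_ft
        C = np.linalg.inv(S)
        if np.any(np.linalg.eigvalsh(C) <= 0):
            raise ValueError("material parameters give a non-SPD elasticity matrix")
        return C


@dataclass
class TwitchParams:
    """Active fiber-stress twitch triggered at the local activation time.

    Sine-squared rise to ``T_max`` over ``t_rise``, exponential decay with
    time constant ``t_decay`` tapered smoothly to exactly zero at
    ``duration`` after onset.  Continuous in time; zero before activation.

    The default peak stress is set so that, against the default moduli, peak
    fiber strain is ~0.15-0.2, keeping the small-displacement solve valid.
    """

    T_max: float = 12.0     # kPa
    t_rise: float = 60.0    # ms
    t_decay: float = 80.0   # ms
    duration: float = 380.0  # ms

    def __post_init__(self) -> None:
        if min(self.T_max, self.t_rise, self.t_decay, self.duration) <= 0:
            raise ValueError("twitch parameters must be positive")
        if self.duration <= self.t_rise:
            raise ValueError("twitch duration must exceed the rise time")


@dataclass
class DisplacementField:
    """Per-node displacement vectors, mm."""

    u: np.ndarray  # (N, 3)


@dataclass
class StrainSample:
    """Strain quantities at a set of material sample points, one frame."""

    E: np.ndarray        # (S, 3, 3) Green-Lagrange tensors
    F: np.ndarray        # (S, 3, 3) deformation gradients
    ecc: np.ndarray      # (S,) circumferential strain
    e1: np.ndarray       # (S,) maximum principal strain


# ---------------------------------------------------------------------------
# Fiber-frame rotation (Voigt/Bond transformation)
# ---------------------------------------------------------------------------

def _complete_frame(fiber: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame with the fiber as first axis."""
    f = np.asarray(fiber, dtype=float)
    n = np.linalg.norm(f)
    if n < 1e-12:
        raise ValueError("degenerate fiber vector")
    f = f / n
    helper = np.array([0.0, 0.0, 1.0])
    if abs(f @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    s = np.cross(helper, f)
    s /= np.linalg.norm(s)
    t = np.cross(f, s)
    return np.column_stack([f, s, t])  # columns: local axes in global coords


def bond_stress_matrix(Q: np.ndarray) -> np.ndarray:
    """6x6 Voigt stress transformation for a 3x3 rotation ``Q`` (local->global).

    With Voigt order (11, 22, 33, 23, 13, 12): ``sigma_g = M sigma_l`` where
    ``sigma_g = Q sigma_l Q^T``.
    """
    Q = np.asarray(Q, dtype=float)
    pairs = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]
    M = np.empty((6, 6))
    for I, (i, j) in enumerate(pairs):
        for J, (k, l) in enumerate(pairs):
            if J < 3:
                M[I, J] = Q[i, k] * Q[j, k]
            else:
                M[I, J] = Q[i, k] * Q[j, l] + Q[i, l] * Q[j, k]
    return M


_MANDEL = np.diag([1.0, 1.0, 1.0, np.sqrt(2.0), np.sqrt(2.0), np.sqrt(2.0)])
_MANDEL_INV = np.diag([1.0, 1.0, 1.0, 1.0 / np.sqrt(2.0), 1.0 / np.sqrt(2.0),
                       1.0 / np.sqrt(2.0)])


def fiber_rotation_matrix(fiber: np.ndarray, frame: np.ndarray | None = None) -> np.ndarray:
    """6x6 strain/stress rotation from the fiber frame to the global frame.

    Returned in the orthonormal (Mandel) tensor basis, so the matrix is
    orthogonal, composes like the underlying 3x3 rotations, and maps the
    identity elasticity matrix to itself.  ``frame`` may supply the full
    orthonormal local frame (columns = local axes in global coordinates,
    fiber first); otherwise a transverse frame is completed arbitrarily,
    which is immaterial for transversely isotropic material.
    """
    Q = _complete_frame(fiber) if frame is None else np.asarray(frame, dtype=float)
    if not np.allclose(Q @ Q.T, np.eye(3), atol=1e-8):
        raise ValueError("degenerate local frame: not orthonormal")
    return _MANDEL @ bond_stress_matrix(Q) @ _MANDEL_INV


def rotate_elasticity(C_local: np.ndarray, fiber: np.ndarray,
                      frame: np.ndarray | None = None) -> np.ndarray:
    """Engineering-Voigt elasticity matrix in global coordinates.

    Conjugates by the Bond stress transformation, which equals the Mandel
    rotation expressed in the engineering basis.
    """
    R = fiber_rotation_matrix(fiber, frame)
    M = _MANDEL_INV @ R @ _MANDEL  # Bond stress matrix
    return M @ C_local @ M.T


# ---------------------------------------------------------------------------
# Element integrals and assembly
# ---------------------------------------------------------------------------

def element_stiffness(coords: np.ndarray, C_global: np.ndarray,
                      quad: ElementQuadrature = DEFAULT_QUADRATURE) -> np.ndarray:
    """24x24 stiffness ``integral B^T C B |J|`` over the reference cube."""
    detJ, dN_dx = hexfem.jacobians(coords[None], quad)
    if detJ.min() <= 0:
        raise MeshError("non-positive Jacobian determinant in element")
    B = hexfem.strain_displacement_matrices(dN_dx[0])  # (q, 6, 24)
    w = detJ[0] * quad.weights
    return np.einsum("qia,ij,qjb,q->ab", B, C_global, B, w)


def element_active_force(coords: np.ndarray, sigma: float, fiber: np.ndarray,
                         quad: ElementQuadrature = DEFAULT_QUADRATURE) -> np.ndarray:
    """Statically equivalent nodal forces of a uniaxial fiber stress.

    ``f = -integral B^T sigma (f (x) f) |J|``; self-equilibrated (zero net
    force and moment).
    """
    return sigma * unit_active_force(coords, fiber, quad)


def unit_active_force(coords: np.ndarray, fiber: np.ndarray,
                      quad: ElementQuadrature = DEFAULT_QUADRATURE) -> np.ndarray:
    """Active nodal-force vector for unit fiber stress (24,)."""
    detJ, dN_dx = hexfem.jacobians(coords[None], quad)
    B = hexfem.strain_displacement_matrices(dN_dx[0])
    f = np.asarray(fiber, dtype=float)
    sv = np.array([f[0] ** 2, f[1] ** 2, f[2] ** 2,
                   f[1] * f[2], f[0] * f[2], f[0] * f[1]])
    w = detJ[0] * quad.weights
    return -np.einsum("qia,i,q->a", B, sv, w)


@dataclass
class AssembledModel:
    """Assembled, constrained stiffness plus per-element active-force basis."""

    K: sparse.csr_matrix            # (3N, 3N), basal springs included
    G: np.ndarray                   # (E, 24) unit active-force vectors
    dof_index: np.ndarray           # (E, 24) global dof of each element slot
    basal_nodes: np.ndarray
    _lu: object = field(default=None, repr=False)

    def factorize(self):
        if self._lu is None:
            self._lu = splu(self.K.tocsc())
        return self._lu


def assemble_global(mesh: HeartMesh, material: MaterialParams,
                    base_spring: float = 100.0,
                    constraint_surface: str = "base",
                    quad: ElementQuadrature = DEFAULT_QUADRATURE) -> AssembledModel:
    """Assemble the global stiffness over 3*n_nodes dofs.

    The basal restraint enters as elastic springs (stiffness ``base_spring``
    per node and axis, kPa*mm) on the nodes of the basal surface, rendering
    the constrained system positive definite.
    """
    if mesh.fibers is None:
        raise MeshError("mesh has no fiber field; run assign_fiber_orientations first")
    coords = mesh.element_coords()
    detJ, dN_dx = hexfem.jacobians(coords, quad)
    if detJ.min() <= 0:
        raise MeshError("non-positive Jacobian determinant during assembly")
    B = hexfem.strain_displacement_matrices(dN_dx)      # (E, q, 6, 24)
    w = detJ * quad.weights                             # (E, q)

    C_local = material.elasticity_matrix()
    C_e = np.empty((mesh.n_elements, 6, 6))
    for e in range(mesh.n_elements):
        C_e[e] = rotate_elasticity(C_local, mesh.fibers[e])
    Ke = np.einsum("eqia,eij,eqjb,eq->eab", B, C_e, B, w)

    f = mesh.fibers
    sv = np.stack([f[:, 0] ** 2, f[:, 1] ** 2, f[:, 2] ** 2,
                   f[:, 1] * f[:, 2], f[:, 0] * f[:, 2], f[:, 0] * f[:, 1]], axis=1)
    G = -np.einsum("eqia,ei,eq->ea", B, sv, w)

    dof = (3 * mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(
        mesh.n_elements, 24)
    n_dof = 3 * mesh.n_nodes
    rows = np.repeat(dof, 24, axis=1).ravel()
    cols = np.tile(dof, (1, 24)).ravel()
    K = sparse.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n_dof, n_dof)).tocsr()

    if len(mesh.surfaces.get(constraint_surface, ())):
        basal = mesh.surface_nodes(constraint_surface)
    else:
        basal = np.array([], dtype=np.int64)
    if basal.size:
        bd = (3 * basal[:, None] + np.arange(3)).ravel()
        spring = sparse.coo_matrix(
            (np.full(bd.size, base_spring), (bd, bd)), shape=(n_dof, n_dof))
        K = (K + spring).tocsr()
    return AssembledModel(K=K, G=G, dof_index=dof, basal_nodes=basal)


# ---------------------------------------------------------------------------
# Active stress twitch
# ---------------------------------------------------------------------------

def active_stress(t: np.ndarray | float, t_act: np.ndarray | float,
                  twitch: TwitchParams) -> np.ndarray | float:
    """Active fiber stress (kPa) at time ``t`` for activation time ``t_act``.

    Zero before activation, peaks at exactly ``T_max`` at the end of the
    rise, decays exponentially with a smooth taper to zero at the twitch
    duration.  Shifting ``t_act`` shifts the whole trace.
    """
    s = np.asarray(t, dtype=float) - np.asarray(t_act, dtype=float)
    tw = twitch
    rise = np.sin(0.5 * np.pi * np.clip(s / tw.t_rise, 0.0, 1.0)) ** 2
    d = np.clip((s - tw.t_rise) / (tw.duration - tw.t_rise), 0.0, 1.0)
    decay = np.exp(-np.maximum(s - tw.t_rise, 0.0) / tw.t_decay) * (1.0 - d ** 2)
    out = tw.T_max * np.where(s <= tw.t_rise, rise, decay)
    out = np.where((s <= 0.0) | (s >= tw.duration), 0.0, out)
    return float(out) if np.isscalar(t) and np.isscalar(t_act) else out


def solve_frame(model: AssembledModel, mesh: HeartMesh, activation: np.ndarray,
                twitch: TwitchParams, t: float) -> DisplacementField:
    """Solve ``K d = F_f(t)`` for one time frame.

    Element activation time is the mean of its nodes' activation times.
    Uses the cached sparse LU factorization; deterministic for fixed inputs.
    """
    t_act_e = activation[mesh.elements].mean(axis=1)
    sig = active_stress(np.full(mesh.n_elements, t), t_act_e, twitch)
    F = np.zeros(model.K.shape[0])
    np.add.at(F, model.dof_index.ravel(), (sig[:, None] * model.G).ravel())
    if not np.any(sig):
        return DisplacementField(u=np.zeros((mesh.n_nodes, 3)))
    u = model.factorize().solve(F)
    if not np.all(np.isfinite(u)):
        raise RuntimeError("singular constrained system in frame solve")
    return DisplacementField(u=u.reshape(-1, 3))


# ---------------------------------------------------------------------------
# Strain sampling
# ---------------------------------------------------------------------------

@dataclass
class SamplePoints:
    """Material sample points with element membership and local directions."""

    points: np.ndarray       # (S, 3) reference positions
    element: np.ndarray      # (S,) containing element
    xi: np.ndarray           # (S, 3) local coordinates
    chat: np.ndarray         # (S, 3) circumferential unit vectors
    angles: np.ndarray       # (S,) circumferential angle
    layer: np.ndarray        # (S,) source layer
    _dN_dx: np.ndarray | None = None  # (S, 8, 3) cached reference gradients

    def reference_gradients(self, mesh: HeartMesh) -> np.ndarray:
        if self._dN_dx is None:
            coords = mesh.nodes[mesh.elements[self.element]]
            _, dN = hexfem.shape_functions(self.xi)  # (S, 8, 3)
            J = np.einsum("sai,saj->sij", coords, dN)
            self._dN_dx = np.einsum("saj,sji->sai", dN, np.linalg.inv(J))
        return self._dN_dx


def strain_at_samples(mesh: HeartMesh, disp: DisplacementField,
                      samples: SamplePoints) -> StrainSample:
    """Green--Lagrange strain and derived scalars at the sample points.

    ``F = I + grad u`` from trilinear shape-function gradients in the
    reference configuration; objective under rigid rotations by construction.
    """
    dN_dx = samples.reference_gradients(mesh)
    u_nodes = disp.u[mesh.elements[samples.element]]     # (S, 8, 3)
    gradu = np.einsum("sai,saj->sij", u_nodes, dN_dx)    # du_i/dX_j
    F = np.eye(3)[None] + gradu
    E = 0.5 * (np.einsum("ski,skj->sij", F, F) - np.eye(3)[None])
    ecc = np.einsum("si,sij,sj->s", samples.chat, E, samples.chat)
    e1 = np.linalg.eigvalsh(E)[:, -1]
    return StrainSample(E=E, F=F, ecc=ecc, e1=e1)


def midwall_ring_samples(mesh: HeartMesh, layer: int, n_points: int = 30) -> SamplePoints:
    """Equiangular mid-wall sample ring on the LV+septum of one layer.

    Points sit at the transmural center of the mid-depth element row (the
    exact half-depth surface is an element interface when the transmural
    count is even, where the FE strain is discontinuous), at the
    longitudinal center of the layer band, ordered by circumferential angle,
    each with its local circumferential unit vector (perpendicular to the
    local radial direction).
    """
    if n_points < 4:
        raise ValueError("need at least 4 ring samples")
    spec = mesh.meta["spec"]
    if layer < 1 or layer > spec.n_layers:
        raise ValueError(f"layer {layer} outside 1..{spec.n_layers}")
    lv_in_layer = np.where((mesh.part == "lv") & (mesh.layer == layer))[0]
    if lv_in_layer.size == 0:
        raise ValueError(f"no LV elements in layer {layer}")

    # geometric target: mid-wall surface of the shell parametrization
    a, b, c = spec.lv_endo_radii
    z_base = mesh.meta["z_base"]
    nL, nT = spec.n_layers, spec.n_transmural
    thetas = 2.0 * np.pi * np.arange(n_points) / n_points

    j_mid = (nT - 1) // 2
    s_t = (j_mid + 0.5) / nT  # center of the mid-depth element row
    cand = lv_in_layer[np.isin(mesh.grid_index[lv_in_layer, 1],
                               [j_mid, max(0, j_mid - 1), min(nT - 1, j_mid + 1)])]
    cent = mesh.centroids()[cand]
    cand_phi = np.arctan2(cent[:, 1], cent[:, 0])

    C_mid = c + s_t * spec.wall_thickness_lv
    z_t = -C_mid + ((layer - 0.5) / nL) * (z_base + C_mid)

    pts, elem, xis = [], [], []
    for th in thetas:
        t_w = spec.wall_thickness_lv  # sample radius uses the free-wall scale
        A = a + s_t * t_w
        Bv = b + s_t * t_w
        cosmu = np.clip(-z_t / C_mid, -1.0, 1.0)
        sinmu = np.sqrt(1.0 - cosmu ** 2)
        x = np.array([A * sinmu * np.cos(th), Bv * sinmu * np.sin(th), z_t])
        # search candidate elements nearest in angle first
        dphi = np.abs(np.angle(np.exp(1j * (cand_phi - th))))
        order = cand[np.argsort(dphi)]
        found = False
        for e in order[:12]:
            xi, ok = hexfem.invert_trilinear(mesh.nodes[mesh.elements[e]], x)
            if ok and np.all(np.abs(xi) <= 1.0 + 1e-6):
                pts.append(x); elem.append(e); xis.append(np.clip(xi, -1, 1))
                found = True
                break
        if not found:  # fall back: nearest containing element in the layer
            for e in lv_in_layer:
                xi, ok = hexfem.invert_trilinear(mesh.nodes[mesh.elements[e]], x)
                if ok and np.all(np.abs(xi) <= 1.0 + 1e-6):
                    pts.append(x); elem.append(e); xis.append(np.clip(xi, -1, 1))
                    found = True
                    break
        if not found:
            raise MeshError(f"mid-wall sample at angle {th:.3f} not inside any layer-{layer} element")

    xis = np.array(xis)
    elem = np.array(elem)
    # Evaluate at the element's circumferential center: the FE strain is
    # discontinuous across faces, and end-of-element values carry facet noise.
    xis[:, 1] = 0.0
    pts = np.einsum("sa,sai->si",
                    hexfem.shape_functions(xis)[0], mesh.nodes[mesh.elements[elem]])
    phi_eval = np.arctan2(pts[:, 1], pts[:, 0])
    chat = np.column_stack([-np.sin(phi_eval), np.cos(phi_eval), np.zeros(n_points)])
    return SamplePoints(points=pts, element=elem, xi=xis,
                        chat=chat, angles=thetas, layer=np.full(n_points, layer))
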