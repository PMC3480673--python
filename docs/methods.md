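# Methods

`cardiosync` is a desk-scale forward model of cardiac resynchronization
therapy (CRT) optimization: it simulates electrical activation and
activation-triggered contraction of an idealized failing biventricular heart
with complete left bundle branch block (LBBB), scores each pacing
configuration with a mechanical and an electrical dyssynchrony index, and
selects the optimal left-ventricular (LV) lead site and interventricular
delay (VVD) under each criterion.  This note documents the model, its
assumptions, the parameters that matter, and what the synthetic setting can
and cannot show.

## Synthetic anatomy

The heart is a two-ellipsoid idealization, meshed with 8-node (trilinear
isoparametric) hexahedra:

- **LV**: a thick-walled prolate ellipsoid truncated by a flat basal plane.
  Default cavity semi-axes (16, 16, 40) mm, free-wall thickness 10 mm,
  septal thickness 8 mm (blended smoothly over the septal sector),
  truncation keeping 75 % of the long axis.  The apex pole is closed with
  collapsed-hex wedges sharing on-axis nodes; their Jacobians remain
  positive at the 2×2×2 Gauss points.
- **RV free wall**: a 4 mm shell bulging 9 mm from the LV epicardium over a
  130° sector centered on the septum, tapering to zero thickness (shared
  nodes) at the sector edges and at its apical end so the two walls are
  electrically and mechanically continuous.  Corner slivers whose minimum
  Gauss-point Jacobian falls below an absolute floor (10⁻³) are dropped at
  build time.
- **Labels**: 14 equal-height longitudinal layers from apex (1) to base
  (14); wall segments by circumferential quadrant about the LV long axis in
  the anatomical order septum → anterior → lateral → posterior (lateral
  opposite the septum); surface tags `lv_endo`, `rv_endo`, `epi`, `base`.
  The default resolution (36 circumferential × 4 transmural) yields ~2,150
  elements; reduced test resolutions are config-driven.
- **Fibers**: rule-based transmural helix, linear in normalized wall depth
  from +60° (endocardium) to −60° (epicardium), lying in the local
  circumferential–longitudinal tangent plane.  Apex-cap elements with no
  defined circumferential direction inherit the nearest well-defined
  neighbor's fiber.
- **Conduction system**: the Purkinje network is idealized as a
  one-element-thick endocardial fast shell (LV subendocardium, RV
  subendocardium, and the RV-facing septal layer) with bundle entry patches
  on the septal endocardium near the base.  In the LBBB substrate the LV
  portion of the shell conducts as ordinary myocardium — a blocked left
  bundle no longer feeds its network, and a continuous shell would otherwise
  grossly overstate retrograde engagement — while the right network and
  septal face stay intact.  The sinus reference always uses the full shell.

Seven pacing sites are resolved by anatomical rule: RVA (right-ventricular
endocardial node nearest the apex) plus {posterior, lateral, anterior} ×
{base, equator} on the LV epicardium, with equator sites inside layers 6–9.

## Excitation

Activation spreads by a monodomain reaction–diffusion equation

  ∂V/∂t = −(1/C_m)(ΣI_ion + I_app) + (1/β)(k/(k+1)) ∇·(D∇V),

with a fiber-aligned diffusion tensor
D = d_trans·I + (d_long − d_trans)·f⊗f and zero-flux boundaries.  Fast-shell
elements get an isotropic tensor at `velocity_scale_fast` (default 6) times
d_long: a conduction network is fast in every surface direction, unlike
fibered working myocardium.

The ionic kinetics is a two-variable excitable model (Aliev–Panfilov form:
normalized potential with a cubic upstroke, slow recovery variable) behind a
narrow interface; the pipeline consumes only threshold-crossing activation
times (0.5 on the normalized upstroke, linearly interpolated between stored
frames) and refractoriness, both of which the stand-in preserves.  The
kinetics clock (`tau_ms` = 25 ms per normalized time unit) and diffusion
coefficients (d_long = 1.6, d_trans = 0.32 mm²/ms before monodomain scaling)
were chosen jointly so the planar conduction velocity along the fiber is
≈0.6 m/s (measured on a slab; the convergence test reports it) with an
excitation front wide enough (~5 mm) to propagate on coarse meshes.  The
refractory period is several hundred ms, so a lead firing into activated
tissue within the beat is silent — the mechanism behind VVD saturation.

Numerics: operator splitting with an explicit (forward-Euler) reaction
substep and an implicit-Euler finite-element diffusion substep with lumped
mass; the constant system matrix is LU-factorized once per substrate, so a
pacing sweep pays only for time stepping.  Default dt 0.05 ms, horizon
300 ms, snapshots every 1 ms.

Stimuli follow the convention of a 100 µA/cm² transmembrane current for
0.5 ms.  Because the smoothed desk-scale kinetics has a critical ignition
nucleus of roughly D/c (~6 mm in bulk myocardium, ~15 mm in the fast
shell), stimuli are applied over finite capture regions: a 10 mm ball around
a lead node and a 16 mm patch around a bundle entry, each with a
nearest-node floor so the region never degenerates to a point on coarse
meshes.  These sizes come from the ignition physics, not from tuning any
outcome index.

Pacing protocols: positive VVD means the LV lead fires first (LV at t = 0,
RV at t = VVD; mirrored for negative values).  Intrinsic right-bundle
activation fires at t = 0 alongside the leads, as the pathological rhythm
continues during BiV pacing.

## Contraction

Excitation and mechanics are weakly coupled: each element's activation time
(mean of its nodes) triggers an active fiber-stress twitch
σ′(t − t_act) — sine-squared rise over t_rise = 60 ms to T_max, exponential
decay (τ = 80 ms) tapered smoothly to zero at 380 ms.  The statically
equivalent nodal forces, F_f = −∫Bᵀσ′(f⊗f)|J|, load a linear transversely
isotropic stiffness K (fiber modulus 60 kPa, cross-fiber 20 kPa, Poisson
ratios 0.45, axial shear 10 kPa), assembled from 24×24 element matrices
with 2×2×2 Gauss quadrature and solved quasi-statically per frame
(default every 10 ms over 0–400 ms) with a cached sparse LU.  The basal
ring is restrained by elastic springs (default 100 kPa·mm per node and
axis) rather than hard fixation, standing in for pericardial attachment.

T_max defaults to 12 kPa: with the default moduli this produces peak fiber
strains of ~0.15–0.2.  A peak stress of physiological magnitude (~60 kPa)
against these moduli would imply order-unity strains and invalidate the
small-displacement solve; since the mechanical synchrony index below is
scale-free, the choice affects absolute strain and volume amplitudes only.

Green–Lagrange strain is a finite-strain post-process: F = I + ∇u from the
trilinear shape-function gradients at material sample points,
E = ½(FᵀF − I), circumferential strain ε_cc = ĉᵀEĉ, and maximum principal
strain E1 = λ_max(E).  Strain is evaluated at the circumferential center of
the containing element (FE strain is discontinuous across faces; end-of-
element values carry facet noise — with this choice, simultaneous
activation on an axisymmetric mesh yields a circumferentially uniform ring
to machine precision).  Sarcomere-length dependence of active stress,
cavity pressure afterload and circulation coupling are out of scope; the
reference configuration is end-diastole.

## Indices

- **CURE** (circumferential uniformity ratio estimate): ε_cc is sampled at
  30 equiangular mid-wall points on the four short-axis slices near the
  equator (layers 6–9, LV+septum only).  Per ring, the zero-order power is
  the squared ring mean and the first-order power the squared amplitude of
  the first circumferential harmonic (2/N convention, computed by FFT);
  powers are summed over slices and frames with uniform weights, and
  CURE = √(A₀²/(A₀² + 2A₁²)).  1 means perfectly synchronous; a pure first
  harmonic gives 0.  Frames entering the sums are the systolic window: from
  the earliest activation to the frame of minimum cavity volume.
  Identically zero strain has no defined uniformity and is reported as an
  error, not as 0 or 1.
- **E_RMS**: root-mean-square nodal activation-time difference between a
  pathological/paced map and the sinus reference, over all mesh nodes;
  unactivated nodes are a hard error.
- **DI**: the four LV wall segments' mean-E1 traces at layer 7; DI = latest
  minus earliest time-to-peak (ties break to the earliest frame).
- **LVEF** = (EDV − ESV)/EDV, with EDV the undeformed cavity volume and ESV
  the minimum over frames.  The LV endocardial surface is triangulated,
  capped at the basal ring, and integrated by the divergence theorem
  (verified to 0.5 % against an analytic sphere); this LVEF is purely
  kinematic (active contraction, no pressure).

## Optimization

The sweep enumerates the Cartesian product of the 6 LV sites and the 13 VVD
values −72…+72 ms in 12 ms steps (78 configurations), site-major and VVD-
ascending, plus sinus and LBBB baselines.  The mechanical strategy selects
argmax CURE; the electrical strategy argmin E_RMS.  Score ties break toward
the smaller |VVD| (simpler device programming), then catalogue site order.
Failed configurations are recorded with their stage and excluded from
selection.  Reports serialize to JSON and CSV, with an optional CURE-vs-VVD
column map per site.

## What the synthetic setting shows — and what it does not

The generator emulates the geometric and physiological structure the
analysis depends on: a two-cavity anisotropic wall with rotating fibers, a
fast endocardial conduction system with a blockable left input, and
activation-triggered contraction.  On this substrate the pipeline
reproduces the qualitative physiology of CRT at reduced resolution
(asserted by the test suite): LBBB activates the septum before the lateral
wall and its latest depolarization is ~105 ms; LBBB lowers CURE and LVEF
and raises DI relative to sinus; biventricular pacing recovers CURE, DI and
LVEF; and CURE saturates for large positive VVDs because the intrinsic
wavefront pre-empts the RV lead.

It does not reproduce any real heart's numbers: the published headline
values for this problem class derive from a specific DT-MRI canine anatomy
with measured fibers and a detailed ionic model, none of which are public.
Absolute index values here depend on the idealized geometry, the stand-in
kinetics clock and the twitch parameters; only formula-level quantities
(CURE boundary cases and closed forms, the index definitions) and the
qualitative orderings above are transferable claims.  Test problem sizes
(16 circumferential × 2 transmural, dt 0.1 ms; a reduced paced set LAT-E ×
VVD {0, 24, 60, 72} ms) were chosen as the smallest substrate on which
those orderings are resolved.

## Numerical and design choices

- Per-element material homogeneity with 2×2×2 Gauss quadrature: each
  element carries one layer/segment label, so per-layer/per-segment
  integration bounds collapse to per-element integrals with identical
  results.
- The 6×6 fiber rotation is returned in the orthonormal (Mandel) tensor
  basis — orthogonal, composing like the underlying 3×3 rotations —
  and applied to engineering-Voigt elasticity via the equivalent Bond
  congruence.
- Layer bands are equal-height (the alternative, equal arc length, is not
  distinguishable by any index used here).
- DI peak ties break to the earliest frame; CURE frame weights are uniform.
- Degenerate inputs are rejected loudly: non-positive Jacobians name the
  offending element, unactivated nodes list their ids, identically zero
  strain and inverted cavity surfaces raise.
- Determinism: every stage is seed-free and bit-reproducible; repeated
  runs of any protocol return identical maps and records.

## Known limitations

Linear small-displacement mechanics with a finite-strain measure (mirroring
the quasi-static stiffness formulation), no pressure–volume loop, a
phenomenological twitch without length dependence, a shell surrogate for a
branching conduction tree, and an idealized symmetric anatomy.  AV-delay
optimization is out of scope (held fixed).  These bound the fidelity of
absolute LVEF/DI/PMPS values; orderings between substrates are the robust
output.
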