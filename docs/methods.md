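# Methods

This note documents the model, the numerical choices and the limits of what
the test suite demonstrates. Units throughout: lengths in mm, pressures and
stresses in kPa, cap thicknesses in µm; 1 mmHg = 0.133322 kPa.

## Scope and modelling stance

The package computes *cyclic* (pressure-change) stress, not absolute stress.
The imaged cross-section is acquired at diastole; we therefore take the
imaged geometry as the stress-free reference configuration and load it only
with the relative pressure Δp(t) = P(x,t) − min P(x,t). This deliberately
sidesteps zero-pressure-state and residual-stress estimation: the quantities
reported (ΔPSS, LDC, LDC%) are differences over the cycle, which are the
well-posed observables under this choice. Absolute wall stress is *not*
computed and would require an initial-stress method.

The model is 2D plane strain: out-of-plane stretch is fixed at 1 and axial
forces, shear stresses and 3D vessel curvature are outside the model. For
gently tapering coronary segments this is the standard per-frame
approximation; it is also why each frame can be analyzed independently.

## Geometry construction

- Contours are simple closed polylines, normalized counterclockwise and
  resampled to uniform arc length (default 128 vertices) before offsetting,
  which stabilizes the normal field.
- Media and adventitia are outward offsets of the IEL (polygon buffering
  with round joins); a self-intersecting offset is an error naming the
  offending thickness.
- The intima is the lumen–IEL annulus. Lipid and calcium inclusion polygons
  are clipped to it (clipped-away area triggers a warning); where lipid and
  calcium overlap, calcium wins, because calcium delineation on OCT is the
  higher-confidence label. Fibrous tissue is the remaining background.
- Partially visible IELs can be completed by a direct algebraic ellipse fit
  (numerically stable Halir–Flusser partitioning) when the visible arc spans
  ≥180° about the fitted centre; shallower arcs are refused with the advice
  to substitute an adjacent frame's IEL, mirroring clinical practice.
- Representative frames: MLA = argmin lumen area (ties resolved to the most
  proximal frame, logged); shoulders = floor midpoints in frame index
  between the reference (or lesion edge when no reference exists) and the
  MLA. Floor (more proximal) midpoints are a deterministic convention.

## Materials

Lipid and calcium are isotropic exponential Mooney–Rivlin; fibrous intima,
media and adventitia are a two-term Holzapfel-type model with one in-plane
circumferential fiber family — a 2D plane-strain section cannot represent
out-of-plane helical fiber pairs, so the single family with the dispersion
weight ρ kept as printed is the faithful planar reduction. The fiber term is
tension-only by default (active for I₄ ≥ 1, the standard collagen
convention; configurable off).

Deviatoric/volumetric split: energies are evaluated on isochoric invariants
(J^{-2/3}-scaled, built from the 3D C with λ_z = 1) plus a volumetric
penalty κ(J−1)²/2 with κ = 1000 × the material's leading shear scale
(2(c₁+c₂+d₁d₂) or 2μ+k₁). The penalty stands in for the mixed
displacement–pressure ("hybrid") elements of commercial codes.

Default constants (kPa; configuration data echoed into every run manifest,
overridable per run):

| tissue     | model          | parameters                              |
|------------|----------------|-----------------------------------------|
| lipid      | Mooney–Rivlin  | c1=2, c2=0, d1=2, d2=1.5                |
| calcium    | Mooney–Rivlin  | c1=368, c2=0, d1=144, d2=2              |
| fibrous    | Holzapfel      | μ=14, k1=20, k2=15, ρ=0.8               |
| media      | Holzapfel      | μ=1.3, k1=21.6, k2=8.2, ρ=0.85          |
| adventitia | Holzapfel      | μ=3.8, k1=40, k2=30, ρ=0.9              |

These are transcriptions (rounded, exponents moderated for the squared
(I₁−3) coupling of the two-term form) from the arterial-plaque FE
literature: lipid ~2 kPa scale soft inclusion, calcification ~10² stiffer
than soft tissue, media the most compliant ground matrix with strong fiber
stiffening, adventitia strongly strain-stiffening. Small-strain
circumferential tangent moduli come out ≈150–200 kPa for the fiber-bearing
layers, which places normal-segment LDC% in the observed 5–8% band — a
consistency check, not a fitted target.

## Load path

One representative beat is cut foot-to-foot (diastolic minima of the aortic
channel, prominence-based); among complete beats the one with the largest
pulse pressure is used — a deterministic alternative to ensemble averaging.
The OFR pullback is normalized linearly between the aortic and distal
tracings (endpoints reproduce Pa and Pd bit-exactly). The diastolic
reference subtracted is the beat minimum of the *position-specific*
waveform, so the load vanishes at the frame's own diastole — consistent with
treating the imaged geometry as stress-free. The exact functional form of
the pullback normalization is the minimal linear map consistent with its
endpoint behaviour; it is an assumption of this implementation and is
surfaced here deliberately.

## Meshing

Constant-strain triangles, generated in-package: face-boundary segments are
densified/decimated deterministically to a graded size field (h = 0.045 mm
at the lumen, ramping to 0.15 mm at 0.5 mm depth, with a 2h guard band), a
structured point layer half an element behind the lumen keeps every
lumen-adjacent element below the 50 µm superficial readout scale, interior
points come from stacked hexagonal lattices thinned to the size field, each
face is Delaunay-triangulated with outside triangles discarded, and free
interior nodes are Laplacian-smoothed. Interface rings are canonicalized
(rotation/orientation-independent), so adjacent faces subdivide shared
boundaries identically and the mesh conforms across material interfaces.

Quality: smooth layer faces meet an 18° minimum-angle target; at the sharp
corners where clipped inclusions meet, isolated elements may dip to ~13–17°
(<0.5% of elements in the shipped tests). Mesh area matches polygon area to
<0.5% at default resolution (the residual is chord sag from ring
decimation) and to <0.1% after one refinement.

The superficial element set (default: centroid within 50 µm of the lumen)
is defined in the reference configuration, so band membership cannot change
between load steps.

## Solver

Implicit quasi-static incremental Newton (total Lagrangian), replacing the
explicit dynamic solvers common in this application: for an elastic,
rate-independent model the quasi-static path is the defined problem, and it
is deterministic and fast at desk scale. Choices that matter:

- Deviatoric residual assembled from the analytic first Piola–Kirchhoff
  stress; the element tangent is a central finite difference of the element
  force (step 10⁻⁶ mm), exactly consistent with the residual by
  construction. Newton converges in 3–5 iterations per step.
- Volumetric term: penalty energy evaluated on the **average nodal
  Jacobian** (volume-weighted mean of element J around each node,
  Bonet–Burton style). A per-element penalty volumetrically locks linear
  triangles; nodal averaging restores the compliant response — the
  thick-walled-cylinder benchmark passes at <1% error where the per-element
  variant misses by an order of magnitude.
- Follower pressure on the deformed lumen edges (consistent, nonsymmetric
  load stiffness assembled); dead load available for testing.
- Rigid-body modes removed by three Lagrange constraints (Σu = 0,
  Σ x₀×u = 0): rotation is restricted so the section cannot roll, while
  radial deformation remains unconstrained.
- Load ramp: n_steps monotone increments (default 10; intermediate
  unloading is redundant for elastic quasi-statics, so min/max lumen
  diameter occur at the always-included zero and peak steps). Diverging
  steps bisect automatically up to 5 levels.
- Convergence: residual ≤ max(10⁻⁸·‖f_ext‖, 10⁻¹⁰); element inversion
  (det F ≤ 0) aborts the update.

Stresses are reported at element centroids (constant-strain elements):
Cauchy stress = isochoric response + averaged nodal penalty pressure,
including the plane-strain σ_zz. ΔPSS is the maximum centroid von Mises
over the superficial set at the peak-load step — no nodal extrapolation,
which keeps the estimator simple and mesh-convergent (<5% change under
refinement in the shipped benchmark, measured at ~3.4%).

LDC uses the area-equivalent diameter 2√(A/π): no caliper direction is
canonical for an irregular lumen, and the area-based diameter is
rotation-invariant and stable under boundary noise.

## Synthetic data

The generator emulates the study conditions of intermediate coronary
lesions: lumen radii 0.85–1.95 mm (diseased vs normal ranges), intimal wall
0.28–0.95 mm giving plaque burdens ~30% (normal) and ~55–70% (diseased),
eccentric lipid pools of 70–140° with caps sampled uniformly in 50–300 µm,
calcium arcs in half the diseased sections, media 0.2 mm and adventitia
0.3 mm, smoothly perturbed (2% harmonic waviness) circular contours. The
aortic waveform is a two-harmonic shape (systolic peak + dicrotic bump)
attaining its systolic/diastolic bounds exactly at ~1 Hz; the distal channel
is a scaled copy (default 12% trans-lesion gradient) plus optional noise;
the OFR pullback is a monotone sigmoid (default drop 0.15 over a 20 mm
pullback). Pullback positions follow the marker anatomy (PR 16 / PS 12 /
MLA 10 / DS 8 / DR 4 mm), so shoulders straddle the OFR transition and the
distal reference feels the damped waveform. Everything is deterministic per
seed.

What the synthetic world does **not** contain: OCT speckle and segmentation
error, non-circular (ruptured, dissected) lumens, thrombus, true
patient-level correlation between morphology and hemodynamics, or any 3D
effect. Passing tests therefore demonstrate correctness of the *method* —
geometry handling, load normalization, hyperelastic equilibrium,
metric extraction — under idealized morphology, not clinical accuracy on
real OCT pullbacks.

## Verification strategy and problem sizes

Solver correctness rests on independent oracles: the linear-elastic Lamé
thick-walled cylinder (hoop and von Mises at the inner wall, <1% strain,
2% tolerance) and the incompressible plane-strain inflation relation
integrated by quadrature (inner stretch at three finite pressures, 5%
tolerance); material laws are checked against finite differences of their
own energies (10⁻⁶ relative on 100 random states each). Method-level
behaviour is checked on seeded synthetic lesions: mesh convergence of ΔPSS,
strict monotone increase of ΔPSS as the cap thins 250→50 µm, and
diseased-vs-normal group directions of mean ΔPSS and mean LDC% on a 5+5
cohort run through the full pipeline, which is also run twice to verify
bit-identical outputs. Benchmark meshes are ~3,000–11,000 elements and each
frame solves in seconds on one core; these sizes were chosen as the point
where the convergence study shows the superficial metric stable to a few
percent.

## Known limitations

- 2D plane strain; no axial/shear stress, no 3D curvature, no
  fluid–structure interaction or wall shear stress.
- Cyclic stress only; absolute stress requires initial-stress estimation,
  which is out of scope by design.
- Homogeneous material per region; no viscoelasticity, damage, perivascular
  tethering or residual-stress (opening-angle) effects.
- Constant-strain triangles with centroid stress readout: superficial peak
  stress is slightly diffused over the <50 µm band; the mesh-convergence
  check bounds this at a few percent.
- The OFR-to-pressure normalization is a documented linear assumption.
- Contours arrive as inputs; segmentation quality is the caller's problem,
  and frames with <180° IEL visibility need an adjacent frame's IEL.
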