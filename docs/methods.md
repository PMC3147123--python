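# Methods

## Physical model

Light propagation is modelled by the frequency-domain diffusion equation in
two dimensions,

∇·[D(r)∇Φ(r,ω)] − (μa(r) + iω/c_n) Φ(r,ω) = −q₀(r,ω),

with diffusion coefficient D = 1/[3(μa+μs′)] (mm), absorption μa and reduced
scattering μs′ (mm⁻¹), modulation angular frequency ω = 2π·100 MHz and light
speed c_n = c₀/n in the medium. The Robin (partial-current) boundary
condition Φ + 2AD ∂Φ/∂n = 0 closes the problem; the measurable photon flux
is φ = Φ/2A. The mismatch parameter A is computed from the angle-averaged
effective Fresnel reflection coefficient, A = (1+R_eff)/(1−R_eff), giving
A ≈ 2.95 for an interior index of 1.4 against air; both n and A are
configurable.

A 2-D model is used throughout: the imaging geometry is a single transverse
slice with a fan-beam arrangement of 8 sources and 8 detectors (64 complex
data per frame), and all quantitative outputs are in-slice maps. Sources are
isotropic points placed one transport mean free path (1/μs′) inside the
boundary under each source fiber, with unit amplitude and zero phase — the
absolute source scale is removed by calibration. With the e^{+iωt}
convention the detected phase is reported as a positive lag, unwrapped along
the detector index of each source.

## Discretisation

The domain is meshed with linear triangles. The weak form gives the complex
symmetric system K(D) + M(μa + iω/c_n) + (1/2A)B, with K the stiffness
matrix, M the consistent mass matrix and B the boundary-edge mass matrix.
Element coefficients are the mean of the three nodal values, which makes the
derivative of the system matrix with respect to any nodal property exact and
cheap — the adjoint Jacobian then matches finite differences of the same
operator to solver precision (verified to ~1e-10 in the tests). One sparse
LU factorisation per frame serves all 8 sources and the 8 adjoint
(detector) solves.

Mesh generation follows the anatomical chain: threshold the intensity image
at half its maximum, keep the largest connected component, trace the
exterior contour, decimate it (default one point in five), and triangulate
the polygon by a Delaunay triangulation of the boundary points plus an
interior hexagonal lattice, restricted to the polygon. Slivers produced by
collinear contour points are removed (they render the FEM system singular).
Pixel size is configurable (default 0.5 mm). Optodes are mapped by casting
16 rays at 22.5° increments from a user-supplied centre and snapping
alternate boundary intersections to boundary nodes (8 sources, 8
detectors). MR/optical co-registration by fiducial markers is replaced by
this synthetic centre, since no imaging hardware exists here.

## Inverse problem

Reconstruction minimises the squared misfit between measured and predicted
data by Levenberg–Marquardt iteration,
X⁽ᵐ⁺¹⁾ = X⁽ᵐ⁾ + (JᵀJ + λR)⁻¹Jᵀε. Residuals are stacked in log-amplitude
and phase rather than raw complex flux: the data span decades of dynamic
range, and both the homogeneous-phantom calibration and the optode coupling
model are multiplicative, i.e. additive in log space.

Numerical choices (the underlying study does not specify them):

* λ₀ = 10·mean(diag(JᵀJ)); halve on an accepted step, ×10 on rejection
  (up to 8 escalations); stop after 20 iterations or when the objective
  changes by less than 0.1% — the truncation also acts as regularisation
  for the underdetermined μa-only inversions.
* μa is floored at 1e-4 mm⁻¹ and μs′ at 1e-3 mm⁻¹ after every step
  (physical positivity; keeps D finite).
* The homogeneous fit (μa, μs′) used for initialisation and for fixing μs′
  is a two-parameter trust-region least squares over the stacked
  log-amplitude + phase residuals, re-placing the sources at depth 1/μs′
  for each trial so the fit is self-consistent.
* Source vectors are frozen at the start of an inversion (placed with the
  homogeneous-fit μs′), so predictions are smooth in the unknowns.

The four analysis methods:

1. 128 data (log-amplitude + phase), unknowns nodal μa and μs′, R = I.
2. 64 log-amplitude data, nodal μa only, μs′ fixed at the homogeneous fit,
   R = I. (This is the continuous-wave-equivalent analysis.)
3. Method 2 plus 16 per-optode gain unknowns (log s_i, log d_j) whose
   Jacobian columns are indicator patterns in log-amplitude space. The
   factorisation s_i·d_j is fixed against its reciprocal-rescaling
   degeneracy by one penalty row, Σlog s = Σlog d; the common mean is left
   free so that a global amplitude scale is absorbed by the gains rather
   than forced into the image. R is block diagonal — identity over nodal
   unknowns and 1e-6·I over the gains: the 16 gains are few and well
   determined, and under-damping them lets per-channel offsets flow into the
   gains before the image can imitate them as near-optode artifacts. A side
   effect, shared with any joint gain/image estimation, is that part of a
   real inclusion's per-channel signature is also absorbed, slightly
   lowering recovered contrast; the tests assert this direction rather than
   perfect equality with Method 2.
4. Method 2 data with R = LᵀL from anatomical region labels, where L has
   1 on the diagonal, −1/N_r between nodes sharing a region of N_r nodes
   and 0 across regions. L nearly annihilates vectors constant within a
   region (‖Lv‖ = ‖v‖/N_r), so region-wide offsets are cheap and
   within-region variation is expensive; an `off_diag_sign=+1` flag exposes
   the alternative sign convention for comparison.

Raw frames are calibrated against a homogeneous reference,
F_cal = F_meas/F_homo_meas × F_homo_forw (complex, element-wise), which
removes data/model mismatch and any gains common to both measurements. In
the synthetic workflow the reference is a homogeneous measurement of the
same geometry acquired with independent mounting, so per-series coupling
gains survive calibration and Method 3 has something real to estimate; the
cylindrical epoxy phantom (μa = 0.006, μs′ = 1.0 mm⁻¹) is retained as the
homogeneous-fit benchmark geometry.

## Synthetic data

The generator defines the study conditions:

* Eight programmatic shapes (circle, ellipse, bean, rounded triangle, pear,
  peanut, D-shape, Fourier blob) stand in for the MR-imaged agar phantoms;
  their geometry is exact ground truth. Characteristic radius 25 mm.
* B-series: background μa = 0.01 mm⁻¹, μs′ = 0.6 mm⁻¹; a 10 mm circular
  inclusion at object-to-background contrasts 1, 2, 4, 6, 8
  (μa = 0.01…0.08 mm⁻¹); μs′ spatially constant.
* Bolus series: 32 frames at 16 s per frame, injection during the 7th
  frame. The enhancement follows a gamma-variate
  (Δt/t_p)^α e^{α(1−Δt/t_p)} with rise time t_p = 48 s, decay constant
  120 s and peak Δμa = 0.06 mm⁻¹ (comparable to the top of the contrast
  series); the background receives 10% of the inclusion curve so that
  difference images have a realistic non-zero background. The in-vivo curve
  is shown but not parameterised in the source study; these values are the
  package's choice of a plausible first-pass bolus at this frame rate.
* Noise: multiplicative Gaussian on amplitude (default CV 1%) and additive
  Gaussian on phase (default 0.1°), the conventional frequency-domain
  instrument model; fully seeded.
* Coupling corruption: optional per-optode log-normal gains shared by all
  frames of a series (fixed fiber contact), not by the calibration
  reference.

What the generator does not emulate: 3-D light transport, MR signal
formation and segmentation errors, physiological motion or blood-flow
dynamics, wavelength dependence, detector nonlinearity. Passing tests
therefore demonstrate correctness of the algorithms under the stated 2-D
diffusion model, not instrument-level realism.

## Problem sizes

Default study meshes are ~500 nodes for reconstruction and ~1000 nodes for
data generation (target edge lengths 2.2 and 1.5 mm on a 25 mm-radius
domain). Data are generated on the finer mesh so the inversion never sees
its own discretisation; a `same_mesh` flag enables inverse-crime mode for
exact-recovery checks. The K₀ Green's-function validation uses a 40 mm disk
at 1.3 mm resolution (~3500 nodes); comparisons are made at 8–16 mm from
the source where boundary effects are negligible.

## Known limitations

* Single-mesh reconstruction (no dual-mesh basis separation); resolution is
  limited by the reconstruction mesh.
* 2-D model; absolute amplitudes are not comparable to 3-D measurements
  (irrelevant after calibration, but a caveat for absolute work).
* The μa-only inversions rely on truncated-LM self-regularisation; no
  explicit smoothness prior is offered except the region Laplacian.
* Phase is unwrapped per source along detectors; layouts whose adjacent
  detectors differ by more than π in phase would need a different unwrap.
* FWHM ROI extraction assumes a single dominant inclusion; the background
  level is estimated by the nodal median.
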