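# Methods

This note documents the model behind `transitdose`, the defaults it ships
with, and the numerical and design choices a maintainer or reviewer would
want spelled out.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. The reconstruction model

A megavoltage beam (gantry 0°, no wedge) traverses a water-equivalent slab
phantom; a planar detector at source-to-detector distance SDD, separated
from the exit surface by an air gap, measures the transit dose
`D_transit(x, y)`.  The dose at a plane at depth `d` inside the phantom
(source-to-plane distance SPD = SSD + d) is reconstructed per segment as

    D_recon = [ D_transit · ISCF · ACF / (1 − SCF) ] ⊗ SK

**ISCF** `= (SDD/SPD)²` undoes beam divergence.  The transit grid is first
rescaled geometrically to SPD (`project_plane`), so coordinates and
intensity are corrected consistently and no resampling beyond the scaling
occurs.

**ACF** `= exp(Σᵢ μᵢ·ℓᵢ)` undoes attenuation between the plane and the
detector; `ℓᵢ` is the in-phantom portion of the central-axis path through
layer `i` and air contributes nothing (µ_air·gap would change the result by
< 0.1%).  Ray tracing is parallel to the beam axis: in the supported slab
geometry, off-axis divergence over a 22 cm field at 160 cm SDD changes path
lengths by < 1%, which the ACF exponent renders negligible.  The effective
attenuation coefficient is a user input; the default used throughout the
synthetic studies is **µ_eff = 0.05 cm⁻¹** (a representative value for a
6 MV beam in solid water — the transmission of a 20 cm slab is then
e⁻¹ ≈ 0.37).

**SCF** restores the in-phantom scatter that a primary-only backprojection
misses.  It is calibrated as the ratio `(total − backprojected)/total` at
the central axis, where *backprojected* is the kernel-convolved product
`(D_transit·ISCF·ACF) ⊗ SK` and *total* is the known dose at the
calibration depth.  Two conventions deserve emphasis:

* *Kernel placement.*  The kernel is applied **before** taking the ratio.
  If SCF were taken from the unconvolved product, the kernel's central-axis
  reduction on peaked fields would be counted twice at reconstruction time
  (once inside SCF, once by the convolution), and the calibration would not
  reproduce its own inputs.  With the kernel included, reconstructing a
  calibration field at a calibration depth returns the known total exactly,
  by construction.
* *Inversion.*  SCF is a scatter-to-total ratio, so the reconstruction
  divides by `(1 − SCF)` rather than multiplying by SCF.
* *Sign.*  SCF can be slightly **negative** at shallow depths: the transit
  still carries a few percent of residual detector-plane scatter, so the
  backprojection overestimates where in-phantom scatter is small.  The
  tables accept any SCF < 1; the calibration remains self-consistent either
  way.

SCF and kernel parameters are tabulated on the calibration grid
(equivalent-square side × depth) and looked up by bilinear interpolation,
clamped at the table edges.  One SCF/kernel per segment, evaluated at the
segment's equivalent square (4·Area/Perimeter of the rasterized aperture,
the standard convention; area uses fractional cells, the perimeter marches
the ≥ 0.5-binarized boundary so rectilinear, raster-aligned apertures are
exact).

**SK** is the radially symmetric triple Gaussian

    SK(r) = exp(−r²/A²) + B·exp(−r²/C²) + D·exp(−r²/E²)

realized on the working grid (support 3× the largest width, ≥ 99.9% of the
analytic mass π(A² + B·C² + D·E²); smaller supports warn) and normalized so
the discrete integral is exactly 1, making convolution dose-conserving.
Convolution is FFT-based and verified against a nested-loop oracle to
1e−9.

## 2. Kernel fitting

Kernels are fitted per (field size, depth) to square calibration fields:
the objective is least squares between the CAX-normalized convolved
backprojection cut and the CAX-normalized reference cut.  Numerical
choices:

* Square fields with isotropic edge blur factorize as
  `P(x,y) = p(x)p(y)/p(0)`, so the 2D convolution inside the objective is
  computed exactly on the outer-product plane — no symmetry approximation.
* Fit region: within ±1.5× the 50% field half-width **plus** all positions
  where the reference exceeds 0.5% of its CAX value.  The tail extension
  matters for small fields with broad kernels: without it, kernels that
  push different amounts of mass beyond the fit window are indistinguishable
  and the kernel's CAX action (hence the SCF) is poorly identified.
* Optimizer: `scipy.optimize.least_squares` (TRF), fixed start
  (A,B,C,D,E) = (0.4, 0.05, 1.2, 0.02, 2.5), bounds widths ∈ [0.05, 6] cm,
  amplitudes ∈ [0, 5], tolerances 1e−8 — fully deterministic.  The three
  Gaussians are exchangeable, so the cost surface has flat valleys; a run
  that exhausts its evaluation budget with an RMS residual below 1e−4 is
  accepted (the kernel is judged by its action, not by parameter values).
* Table building fits depths in increasing order per field size and
  warm-starts each fit from the previous depth's solution, keeping the
  exchangeable parameters on one branch so tabulated parameters interpolate
  smoothly in depth.

## 3. Scatter characterization

Detector-plane scatter is measured operationally: transmission fraction
TF(fs) = CAX dose with slab / without slab, fitted linearly in the
equivalent-square side (the growth is near linear), extrapolated to zero
field size to isolate the primary transmission TF(0), and
SF(fs) = TF(fs) − TF(0).  A decreasing fit or negative SF raises a warning
rather than an error — such data are physically suspect but the caller may
still want the numbers.

## 4. The synthetic forward model

The generator defines the study conditions for every closed-loop test:
20 cm solid-water slab at SSD 90 cm, detector at SDD 160 cm (50 cm air
gap), 24×24 cm² working grid at 2 mm (14 400 cells), reference output
100 cGy at 100 cm, penumbra sigma 0.3 cm at isocenter (scaling with
magnification), no measurement noise by default.  Its physics:

* **Primary**: projected aperture × Gaussian penumbra × inverse square ×
  `exp(−∫µ dz)`.
* **Detector-plane scatter**: a broad Gaussian blur (σ = 1.5 cm at the
  detector) of the primary, scaled so the realized CAX
  transmission-fraction difference equals the configured fraction —
  default 0.0019 per cm of equivalent-square side, i.e. ≈ 0.6% at 3×3 cm²
  rising to ≈ 2.9% at 15×15 cm², gap-independent over 40–60 cm.  The
  TF-difference convention makes "configured" and "recoverable by the
  extrapolation procedure" the same quantity.
* **In-phantom scatter**: the total dose at depth exceeds the backprojected
  primary by `1/(1 − s(fs, d))` with default
  `s = (0.05 + 0.010·fs)·d/10` — about 9% for 5×5 cm² at 10 cm depth up to
  30% for 15×15 cm² at 15 cm, in the range expected for megavoltage beams
  in water-equivalent material.  `s` is bilinear in (fs, d), so tabulated
  SCFs interpolate with negligible model error.
* **Lateral scatter**: the plane is convolved with a true triple-Gaussian
  kernel, widths growing linearly with depth (A = 0.1 + 0.06·d cm, C = 2A,
  E = 3A, B = 0.1, D = 0.05) — deeper kernels are broader and lower, as
  lateral scatter demands.
* **Noise**: optional multiplicative Gaussian noise (fraction of local
  dose), seeded; default 0 so closed-loop discrepancies measure the
  algorithm, not a noise draw.  All stochastic output is bit-reproducible
  from config + seed.

Ground truth at depth d is `GT = [primary(d)/(1 − s)] ⊗ SK_true`, i.e. the
forward model is by construction exactly invertible by the reconstruction
equation once the tables are calibrated from the same model.  What the
closed loop therefore demonstrates is that calibration + interpolation +
reconstruction invert the forward model *consistently* (table nodes are
exact; between nodes the interpolation error is what the depth-dose study
measures).  What it does **not** demonstrate: correctness of the scatter
magnitudes for any real beam, detector energy response, beam hardening of
µ_eff with depth, or heterogeneous anatomy — all outside the model.

Calibration suites use square fields of 3, 5 and 10 cm side at depths 2, 6,
10 and 15 cm, spanning the 2–15 cm reconstruction range so lookups
interpolate rather than extrapolate.

## 5. Evaluation

Profile metrics follow the transit-dosimetry conventions: CAX percent
difference with linear interpolation at 0; mean ± sample SD of per-point
percent differences restricted to within the outermost 50% crossings of the
reference (beyond the 50% penumbra doses are low and percent differences
over-amplify).

The 2D gamma index evaluates, at every reference grid point,
`γ = min √((ΔD/ΔD_crit)² + (|Δr|/DTA)²)` over test positions within a
3·DTA radius.  Choices:

* Normalization: ΔD_crit is a percent of the **reference CAX dose** by
  default (`max` and explicit global value available).  The reference is
  the fixed comparison base; gamma is not symmetrized.
* Low-dose exclusion: points below 10% of the normalization dose are
  excluded from the pass rate (configurable); the gamma map itself is
  filled everywhere.
* Sub-grid search: the test plane is bilinearly interpolated on an integer
  lattice of step `spacing/ceil(spacing/(0.05·DTA))`.  The integer lattice
  makes refinement nested (a finer search can only lower γ), and 0.05·DTA
  keeps the discretization error below 0.05 γ-units against an exhaustive
  0.1 mm search even at penumbra-steep gradients; 0.1·DTA was measurably
  too coarse there.  Fine ticks that coincide with the test-grid edge are
  snapped onto it so floating-point rounding cannot push an exact-edge
  sample into the zero-fill region.
* `γ ≤ 1` counts as passing, with a 1e−9 tolerance so a dose difference of
  exactly the criterion passes.

## 6. Detector and film

The default diode layout reproduces a 445-diode, 22×22 cm² star array from
its verbal description: a checkerboard of 221 diodes over the central
±5 cm (1 cm within-row pitch, rows every 0.5 cm, alternate rows shifted —
0.707 cm diagonal spacing) and 224 outer diodes at double pitch over
±11 cm.  The verbal outer-region rules alone yield 204 positions, so the
generator completes the count with a 20-diode transition ring at |5.5| cm;
the layout is 180°-symmetric and fully parameterized (pitches, extents,
ring) for users with exact vendor drawings.

Stepper sampling translates the layout cross-plane in 2 mm steps, snaps
each diode to the working grid and flags unsampled cells, which film
fill-in completes from a measurement of the same setup — measured cells are
never overwritten.  Film calibration fits a fourth-order polynomial
dose(net OD) by least squares; at least six points are required, and a fit
that is not monotone over the calibration OD domain is rejected outright
(a non-monotone conversion is ambiguous).  Conversions outside the
calibrated OD range warn.

## 7. Known limitations

* Slab/layer phantoms only; no CT-based heterogeneous ray tracing, no
  gantry angles other than 0°, no divergent off-axis backprojection.
* µ_eff is a single user-supplied constant (no beam hardening).
* The scatter model separates a per-segment scalar SCF from a spatially
  invariant kernel; intensity modulation within a segment is handled only
  through the segment-by-segment reconstruction and summation.
* Film handling covers sensitometry and fill-in, not scanner image
  processing or registration.
* Problem sizes in the tests and acceptance script (24×24 cm² planes at
  2 mm, 3×4 calibration grids, 14 depths) are the package's reference
  study conditions; larger grids scale as O(N log N) in the convolutions
  and linearly in the gamma offset count.
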