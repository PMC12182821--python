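# Methods

`sweepflow` simulates and reconstructs a swept-slice ("SWEEP") golden-angle
spiral phase-contrast acquisition and quantifies how well the resulting
slice-to-volume (SVR) 4D-flow measurements agree with conventional 2D
phase-contrast MRI.  Everything runs on a digital pulsatile-flow phantom, so
the whole chain — acquisition physics, compressed-sensing CINE
reconstruction, super-resolution fusion, velocity decoding and agreement
statistics — is testable without scanner data.

## The digital phantom

The phantom is a thorax-like elliptical body of static tissue surrounded by
air, with a low-signal lung compartment and a configurable set of tubular
vessels running along the slice (z) axis.  Each vessel carries laminar
Poiseuille flow, v(r) = v_c (1 − (r/R)²) along the local centreline tangent,
scaled by a periodic raised-cosine waveform of the cardiac phase (diastolic
baseline plus a systolic pulse).  The closed-form instantaneous flow of this
profile, Q = π R² v_c / 2 (1 cm/s · 1 mm² = 0.01 mL/s), is the analytic
oracle for all flow tests.  A bifurcation splits a parent's flow between two
children with stated fractions; child centreline speeds are derived from the
parent flow, so mass conservation holds exactly in the ground truth and can
be tested end to end.

Key default parameters and why:

- grid 64×64×48 at 1.2 mm isotropic — the in-plane acquisition resolution of
  the protocol, at a desk-scale matrix;
- cardiac period 800 ms with 3% R-R jitter — a plausible pediatric R-R; the
  heart rates of the study cohort are not reported;
- vessel radii 3.8–6 mm and peak speeds 45–100 cm/s — great-vessel scale at
  the desk FOV, all below the 150 cm/s VENC except in dedicated aliasing
  experiments;
- background phase: a second-order in-plane polynomial (radians), applied to
  the velocity-encoded readouts only.  Applying it to all four encodings
  equally would cancel in phase-difference decoding and make the correction
  stage untestable.  Default coefficients give a few cm/s of spurious
  velocity at VENC 150, typical of uncorrected eddy-current offsets;
- complex receiver noise: white Gaussian, per-component SD expressed
  relative to the static-tissue signal (default 0.05).

### Inflow enhancement

Blood flowing through the slice is brighter than static tissue because it
carries recently excited, lightly saturated spins.  We use the closed-form
time-of-flight model: a spin at depth d into the slice has experienced
n(d) = d/(v·TR) pulses, and depth-averaging the saturation recursion gives

    S(v) = sin α · [ M_ss + (1 − M_ss) · (r^N − 1)/(N ln r) ],

with r = cos α · e^{−TR/T1}, M_ss the spoiled-GRE steady state, and
N = thickness/(v·TR).  A single-TR "replaced fraction" interpolation was
rejected: it underestimates slow-flow signal several-fold (blood at
12 cm/s in a 4 mm slice has seen only ~4 pulses and still carries ~84% of
the fully relaxed signal), which exaggerates the systole/diastole magnitude
contrast and, downstream, biases the temporally regularised reconstruction.
A full Bloch simulation (per-TR spin tracking) remains out of scope.

### Slice profile

The excitation profile is a smoothed rectangle — a rect of width equal to
the slice thickness convolved with a Gaussian of SD 0.3 mm (a 10–90%
transition of ≈ 0.77 mm, typical of a clinical sinc pulse).  Half-maximum
falls exactly at ± FWHM/2.  The profile shape matters more than is obvious:
a Gaussian of the same FWHM retains only ~5·10⁻⁵ relative amplitude at the
spatial frequency needed to separate structures 2.4 mm apart, making
through-slice super-resolution physically impossible, whereas the sinc-like
profile retains several percent.  The same profile is used as the SVR
point-spread function, so the fusion model is self-consistent with the
simulated acquisition.

## Acquisition simulation

Each TR excites a slice at z = z₀ + i·Δz (default Δz = 0.005 mm at full
scale; desk profiles use larger steps so a short simulation covers the
volume), rotates a uniform-rate Archimedean spiral arm by the golden angle
(137.507764°) and cycles the velocity encoding through (V_o, V_TP, V_X,
V_Y).  The signal is the slice-profile-weighted z-sum of the phantom's
complex signal (magnitude × inflow × exp(i·(π v_k/VENC + background
phase))), sampled at the rotated arm positions by an exact separable
non-uniform DFT (orthonormal scaling; Cartesian sampling reduces to the
`norm="ortho"` FFT).  At desk problem sizes the exact operator is fast
enough that approximate gridding is unnecessary, and it satisfies forward
and adjoint oracles to machine precision.

The spiral arm has 0.5 turns by default and 0.17 turns in experiments that
mirror the protocol's acceleration-12 regime: shrinking the 256-class matrix
to 64 pixels while preserving both the acceleration (12) and the per-frame
arm count (~15) fixes the per-frame azimuthal Nyquist count at ~190 arms and
therefore a flatter arm.  This is the geometric consequence of scaling down,
not a tuning knob.

The 2D PCMRI comparator applies identical physics on a fully sampled
Cartesian grid (flip 20°, 5 mm slice, no sweep), with noise added in
k-space.

## CINE reconstruction

Consecutive TRs are grouped into overlapping windows — 996 arms sharing 332
with the next window, the protocol's numbers.  This window size is not
arbitrary: at TR 7.5 ms it spans ~7.5 s ≈ 9 cardiac cycles, which is what
gives every retrospectively gated cardiac bin arms spread over the full
golden-angle azimuth.  Desk experiments that shrank the window below a few
R-R intervals produced clustered per-bin angles and visibly degraded
reconstructions; the window/R-R ratio is therefore preserved when scaling
down.  Cardiac phases are assigned retrospectively from a jittered trigger
train (fraction of the enclosing R-R interval) and binned to the nearest of
n = round(R-R / 50 ms) cyclic bins (16 at R-R 800 ms).  The protocol's ~50 ms
temporal resolution matters quantitatively: halving the bin count to 8 mixes
early- and late-systolic signal within a bin and biased desk-scale mean
flows by several percent.

Per window and encoding the CINE solves

    argmin_x  ½‖W^{1/2}(A x − y)‖² + λ Σ_t |x_t − x_{t−1}|   (cyclic in t)

where A is the gated non-uniform Fourier operator, W a radial
density-compensation weighting that preconditions the centre-oversampled
spiral, and λ = 0.08 · max|A^H W y|, making the nominal weight transferable
across phantoms.  The solver is a monotone FISTA with a fixed step from a
power-method estimate of ‖A^H W A‖; the TV proximal map is evaluated by a
projected-gradient dual loop (10 inner iterations).  Exactly 30 outer
iterations are run; the objective trace is returned and tested to be
non-increasing.  Plain (unaccelerated) proximal gradient at 30 iterations
under-converges the high spatial frequencies at these problem sizes, which
is why the accelerated, monotone variant is used.

## Slice-to-volume reconstruction

Per encoding and cardiac bin, the stack of overlapping thick-slice CINEs is
fused into an isotropic volume by solving

    argmin_V  ½‖S V − y‖² + μ Σ ρ_δ(∇V)

with S the slice-profile sampling matrix at the known window centres (no
registration stage — SWEEP provides exact positions), ρ_δ the Huber
function on forward differences (edge-preserving; δ = 1% of the normalised
data maximum), μ = 0.01, and 10 iterations of monotone accelerated gradient
descent warm-started from linear interpolation of the slice stack.  The
fusion is complex-valued so the velocity phase survives to decoding;
fusing decoded velocity maps instead would average phases across aliasing
wraps.  The output z grid spans the window centres at 1.2 mm.

## Flow quantification

Velocities are decoded as v_k = VENC·angle(x_k conj(x_0))/π; a second-order
in-plane polynomial fitted to static-tissue velocity is subtracted
(background correction); aliased voxels are restored by shifting values
that differ from their face-neighbour median by more than VENC by 2·VENC
toward that median, iterated at most 10 passes, with remaining inconsistent
voxels reported rather than raised (clinically, some aliasing is simply
uncorrectable).  Lumen masks come either from the phantom labels (the
simulation analogue of expert manual contouring, used in the agreement
experiment) or from a seeded three-class Otsu threshold (air/tissue/lumen;
the upper class isolates the inflow-enhanced lumen), validated by Dice
against the truth.  Mean flow is the cycle average of Σ v·ΔA over the mask;
SNR and CNR divide lumen signal (and lumen-minus-lung contrast) by the air
magnitude SD corrected for Rayleigh bias (÷ √(2 − π/2)).

## Agreement analysis

Paired vessel flows (2D PCMRI vs SVR 4D flow) are compared by OLS of the
SVR values on the 2D values with t-based 95% CIs, and by Bland–Altman
analysis of the differences (2D − SVR), bias ± 1.96 SD.  Mixed-model
covariate analysis over participants is not meaningful for a single
synthetic phantom and is intentionally omitted.

## What the desk-scale experiments do and do not show

The validation experiments run at a 64-pixel matrix, 6 vessels, a ~1-minute
simulated scan, and single-coil reception, with the protocol's
dimensionless parameters (TTV 0.08/30 iterations, SVR 0.01/10 iterations,
996/332 windowing, VENC 150, TR 7.5 ms, flip 15°, 4 mm slice fused to
1.2 mm).  They demonstrate internal consistency of the full chain —
operator exactness, velocity round-trips, aliasing recovery, undersampled
CINE fidelity, through-slice super-resolution, mass conservation at a
bifurcation, and 2D/SVR agreement — under controlled conditions.  They do
not model multi-coil reception, off-resonance, eddy currents beyond the
polynomial phase, respiratory or bulk motion, T2* decay, or realistic
cardiac chamber anatomy, so passing tests bound the algorithmic behaviour,
not clinical performance.  Measurement planes are axial (vessels run along
the sweep axis); oblique reformatting is not implemented.

## Numerical choices and degenerate inputs

- Exact separable NDFT in complex double precision; forward/adjoint agree
  with a brute-force DFT to ~1e-15.
- Power-method operator-norm estimates (20 iterations, seeded) set fixed
  step sizes; both solvers use monotone acceleration so objective traces
  are non-increasing by construction.
- Empty cardiac bins raise a descriptive error naming window, encoding and
  bin; z-coverage gaps larger than the PSF FWHM raise before SVR; SWEEP
  ranges beyond the phantom raise with the overrun in mm.
- Noiseless SNR computation returns an infinite-SNR flag instead of
  dividing by zero.
- All randomness (trigger jitter, receiver noise, power-method init) flows
  from explicit seeds; fixed seeds give byte-identical outputs.
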