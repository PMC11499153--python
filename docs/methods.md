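# Methods

## Point-source diffusion model (RTI)

The forward model treats the iontophoretic pipette as an ideal point
source in an unbounded, isotropic porous medium.  The governing equation
is ∂C/∂t = (D/λ²)∇²C − k′C + (Q/α)δ(r): diffusion is slowed by the
tortuosity λ (apparent coefficient D* = D/λ²), tracer is lost by
first-order non-specific uptake k′, and both the source and the
concentration live in the extracellular fraction α of the tissue volume.
The on-solution is the erfc closed form given in `rti_model`; a finite
current pulse is the linear superposition of an on-solution and a delayed
negative one, so the decay phase costs nothing extra.  The continuously
applied bias current (20 nA) is treated as an already-equilibrated
contribution to the measured baseline, and the fitted source uses the
step amplitude above the bias (i_step − i_bias): by linearity the bias
field is constant throughout the recording and is absorbed by baseline
subtraction.

Units: all internal computation is in cm / s / mol·cm⁻³ / A (the
diffusion literature's units for D); interfaces accept µm and mM through
explicit converters in `ecsastro.units`.  Curves are fitted in mM, so SSE
is in (mM)².

Numerical care: the product e^{rλ√(k′/D)}·erfc(u+s) overflows for strong
uptake (the exponent can exceed 700).  With u = rλ/(2√(Dt)) and
s = √(k′t), the exponent equals 2us, so the term is evaluated as
erfcx(u+s)·e^{−(u²+s²)}; the mirrored term needs the same scaling only
when u ≥ s.  C(r, 0) = 0 by definition; separations below 1 µm are
rejected as unphysical for 50–100 µm electrode arrays.

## Finite-difference cross-check

`radial_fd` integrates the same PDE in spherical symmetry with the
substitution u = rC (plain 1D diffusion), Crank–Nicolson stepping, and
the source distributed over a 1 µm ball whose discrete strength is
normalised so the total release is exactly Q (the node-sampled density
systematically overweights the ball edge otherwise).  Defaults — 0.2 µm
grid over 1.2 mm, 5 ms steps — were chosen by a convergence study against
the analytically exact free-medium solution.  Agreement with the closed
form is assessed where the analytic signal exceeds 10⁻³ of its pulse-end
value: in the deep early-time tail the concentration is many orders of
magnitude below measurement noise and relative error there reflects only
the grid's inability to represent e^{−x²} tails, not model error.  The
solver is validation-only; the fitting path never calls it.

## Electrode calibration

ISM voltages follow the Nicolsky–Eisenmann form with a lumped
interference term, V = v0 + slope·log₁₀(c + interference), with slope in
mV/decade (> 0 for a cation electrode) and interference the equivalent
background concentration in mM.  Fitting uses nonlinear least squares
with (v0, slope) initialised from a log-linear fit of the top three
standards — interference only bends the low end of the curve — and
interference bounded at ≥ 0.  Voltages are assumed already referenced
differentially against the reference barrel.  The inverse transform clips
at 0 mM; voltages far below the calibrated range are reported as zero
concentration.

## Curve fitting

Both fits use the Nelder–Mead simplex (bounded), SSE tolerance 1e-10,
max 5000 iterations, with 3 additional deterministic restarts from
multiplicatively perturbed initial points.  Agar mode fixes
(α, λ, k′) = (1, 1, 0) and recovers (n, D); tissue mode holds (n, D) at
the agar values (an option frees D) and fits α ∈ (0.01, 1], λ ∈ [1, 3],
k′ ∈ [0, 0.1] s⁻¹ from initial guesses (0.2, 1.5, 3×10⁻³) in the
physiological regime.  The fit window runs from pulse onset to two pulse
durations past the pulse end; the pre-pulse window supplies the baseline
(median concentration), which is subtracted and excluded from residuals.
A parameter within 10⁻³ of a bound is flagged "bound-constrained", not
failed — a free-medium curve fitted in tissue mode legitimately pins
α → 1, λ → 1, k′ → 0.  A flat curve (no signal above baseline) returns
`converged=False` rather than a spurious fit.  The pulse onset is taken
from the stimulus trigger when known (the synthetic traces put it at
t = 0); a threshold-crossing detector exists as a fallback but lags the
true onset by the diffusion rise time, so trigger-based onsets are
preferred for unbiased D.

## Morphometry

Stacks are reduced by average-intensity projection along z, registered
translation-only to the first frame by upsampled phase cross-correlation
(subpixel; the reported shift is the frame's displacement, and alignment
removes it with bilinear interpolation), and bleach-corrected by dividing
each frame by the straight line fitted to total frame intensity over the
baseline acquisitions (relative to frame 0; an increasing baseline trend
caps the correction at 1 with a warning).  Bleaching is fitted on total
frame intensity, not ROI intensity, to decouple bleaching from swelling.
Segmentation uses the Isodata intermeans threshold on a 256-bin histogram
of the frame's min–max range (convergence when the threshold moves less
than half a bin; the class split rounds half-up), then the 8-connected
supra-threshold component containing the user-supplied soma seed.  Soma
area Ss = pixel count × pixel area; volume is normalized as
vol% = 100·(Ss/Ss_ref)^{3/2} under the isotropic-swelling assumption,
with the reference at the last baseline stack.  This is a soma-based
volume estimate: thin processes contribute little projected intensity
and the method makes no claim about process volume.  ROI fluorescence is
the integral intensity in a ~2 µm circle inside the soma; the EGFP-style
area statistics threshold a region by Isodata and report the positive
fraction and the mean gray value over positive pixels only.

## Synthetic data

Diffusion traces: forward model at the standard protocol → Nikolski
voltage → multiplicative Gaussian noise on concentration (electrode noise
scales with signal; default studies use 2%) plus optional linear drift in
mV/min.  The trace spans 10 s of pre-pulse baseline and two pulse
durations of decay at 10 Hz.

Astrocyte phantom: an ellipsoidal soma (default semi-axes 4.0 × 3.4 ×
3.0 µm, a typical mouse astrocyte soma) with five tapering processes,
rendered per z-slice on a 4× supersampled xy grid and block-averaged
(anti-aliasing), in a 128 × 128 × 28 field at 0.41 × 0.41 × 0.5 µm
voxels.  The whole cell scales isotropically by (vol%/100)^{1/3} to
follow the programmed volume profile; the default profile follows the
acquisition protocol (3 baseline stacks, 4 treatment stacks at 5-min
intervals peaking at 340%, washout at +20/+40 min).  Per-stack bleaching
(default 2%), xy drift (default ~0.3 px/frame) and Poisson shot noise
(default 5 photons per intensity unit) plus Gaussian read noise complete
the corruption model.  What the phantom does **not** emulate: real
astrocyte arborisation, neuropil background, depth-dependent scattering,
anisotropic swelling, or z-drift — so passing round-trip tests shows the
measurement chain is unbiased for isotropically swelling convex somata,
not that segmentation is robust to every real-tissue artefact.  The
measured volume carries a small positive bias (a few %) at large
swelling factors because the Isodata threshold sits lower on the larger
object's histogram; this is well inside the 10% round-trip tolerance.

## Aggregation conventions

Group summaries are mean ± SEM (sd/√n, ddof = 1) over units sharing a
time grid; single-unit groups get SEM 0 with a warning.  Percent drops
are 100·(initial − value)/initial, signed, rounded half-away-from-zero
to integer percent for reporting.  Washout recovery is reported under an
explicitly recorded convention because the published description is
ambiguous: "fraction-of-deficit" (100·(end − peak)/(initial − peak)) and
"ratio-to-peak" (100·end/peak) are both implemented and neither is
asserted against published washout percentages, which are not
recomputable from printed group means.

## Problem sizes

The validation studies use sizes that keep the full suite fast while
leaving the statistics meaningful: 20 random parameter sets for the
PDE cross-check, 100 seeded replicates for noisy-recovery medians, 100
random frames for threshold agreement, and 128² × 28 voxel phantoms.

## Known limitations

Ideal point source (no electrode geometry), isotropic diffusion only,
single-compartment first-order uptake, translation-only registration
(rotation is not modelled by the generators and not corrected), and
histogram-resolution quantisation of the Isodata threshold (within one
bin of the exact intermeans fixed point).  Inferential statistics
(ANOVA etc.) are deliberately out of scope; tidy per-unit tables are
exported instead.
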