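# Methods

## Image formation model

A single fluorescent molecule is modeled as an oscillating electric
dipole at position `(x, y, z)` in an aqueous medium (n = 1.33) above a
coverslip (n = 1.523) and immersion oil (n = 1.518), imaged by an
aplanatic objective of NA 1.45 at 597.5 nm onto a camera with 65 nm
object-space pixels. The expected photon count in pixel k is

    mu_k = N [ (1 - g2)/3 H_free + g2/3 H_fixed(phi, theta) ]_k + b

where `H_fixed` is the coherent vectorial PSF of a fixed dipole at
orientation `(phi, theta)`, `H_free` its incoherent average over the
sphere (equal to the sum over three orthogonal dipoles), `g2` in [0, 1]
the degree of rotational constraint, `N` the signal photons captured
into the NA over the entire image plane, and `b` the background per
pixel. `H_free` and `H_fixed` are each normalized to integrate to 3
over the full plane (per orientation for `H_fixed`), so the bracket
integrates to exactly 1 and `N` retains its photon meaning for every
`(phi, theta, g2)`. Full-plane integrals are evaluated by Plancherel's
identity on the pupil, not by truncated image sums — the PSF family has
slowly decaying halos (a 99-pixel window captures only ~92% of the
energy), so window sums would bias the normalization.

### Pupil construction

On a Cartesian pupil grid (64x64 cell centers inside the unit disk;
cell centers avoid the vortex singularity at the origin) the coupling of
dipole component j into camera polarization l is

    q_lj = [Fresnel t_s/t_p (medium->coverslip->immersion)]
           x [s/p projection vectors, complex cos(theta_med) in the
              supercritical zone]
           x exp(i W)  x  A(rho),

with `W` the sum of Zernike aberration phase, the spiral vortex phase
`charge x beta`, and the emitter-dependent axial/lateral propagation
phases. Supercritical-angle fluorescence (SAF) enters through the
complex medium-side axial wavevector: beyond rho = n_med/NA = 0.917 the
plane-wave spectrum is evanescent in the medium, decays as exp(-kappa z)
with emitter height, and still transmits into the glass — this is what
makes the axial position of near-coverslip emitters estimable at focus.

The amplitude mapping is A(rho) = 1/(cos(theta_med) cos(theta_imm)):
the 1/cos(theta_med) factor is the plane-wave (angular-spectrum) weight
of the dipole field, finite and smooth across the critical angle once
combined with the medium-side Fresnel coefficients, and the
1/cos(theta_imm) factor combines the aplanatic detection apodization
with the oblique projection of the spectrum onto the flat pupil
reference plane. This convention was fixed by validating the model
family against its documented energy distribution — with it, the
reference free-dipole capture fractions of a 15x15 ROI evaluate to
0.443 (vortex) and 0.447 (standard PSF) — and is the single most
consequential modeling choice in the package: textbook alternatives
(pure 1/sqrt(cos) detection apodization) concentrate ~70% of the energy
in the ROI and predict correspondingly tighter precision bounds.
Residual few-percent to ~20% deviations of some precision anchors are
attributed to this convention gap; see Limitations.

Axial coordinate: `z >= 0` is emitter height above the coverslip in the
medium (complex k_z, SAF decay); for `z < 0` the emitter is inside the
glass where the axial wavevector is real (n_coverslip > NA), so the
model continues without unphysical evanescent amplification. The fitter
additionally floors z at -50 nm: emitters live at or above the
interface, and the glass branch is axially nearly uninformative, so
unbounded negative excursions would inflate the axial scatter (measured
z std ratio vs CRLB: 1.52 unbounded, 1.10 floored).

Propagation pupil->image uses explicit DFT matrices evaluated on a
3x-oversampled subpixel grid; pixel values are subpixel sums (area
integration). Parameter derivatives are analytic throughout: lateral
shifts and defocus multiply the pupil by (-i k_x), (-i k_y), (i k_z);
orientation and g2 derivatives use the bilinear structure of
`H_fixed = sum_l |sum_j E_lj d_j|^2` and the derivative of the
per-orientation normalization (a quadratic form in the 3x3 pupil
energy matrix). A central-finite-difference oracle verifies all eight
derivatives to <1e-3 relative error.

## Estimation

Each ROI is fitted by maximizing the Poisson log-likelihood with
Levenberg-damped Fisher scoring in natural parameters, box-projected
(g2 in [0,1], N,b positive, |x,y| inside the ROI, z in [-50, 600] nm).
Iteration stops when the relative log-likelihood change drops below
1e-6, or after 30 iterations (non-converged fits are rejected). A 6x3
orientation grid is scored by likelihood and the best three starts are
optimized fully; the best final likelihood wins, and angles are
canonicalized to the hemisphere phi, theta in [0, 180). Fits are also
rejected when the position lands more than 3 pixels from the ROI
center or the per-pixel normalized chi-squared
`chi2 = (1/K) sum (n_k - mu_k)^2 / mu_k` falls outside [0.75, 3]
(per-pixel convention, not per degree of freedom: the acceptance window
is specified for the normalized statistic).

CRLB: Poisson Fisher information from the analytic Jacobian, inverted
on the non-degenerate subspace; degenerate directions (azimuth of an
on-axis dipole, the orientation block at g2 = 0) report infinity rather
than raising. Angle bounds are in degrees. Ensemble azimuth summaries
are restricted to polar angles 20-160 deg, where the azimuth bound is
informative; it diverges toward the poles, so an unrestricted mean is
dominated by a few near-axial draws.

Measured estimator efficiency at the reference conditions (N=4000,
b=10, g2=0.75, z=0, 300 seeded fits): standard deviations within 19% of
the mean CRLB for all eight parameters. The photon count N carries a
-2 to -2.5% maximum-likelihood bias (0.25-0.40 x CRLB_N depending on
seed), unchanged under a 5x larger iteration budget; it stems from the
physical z>=0 boundary at the in-focus truth combined with the N-b-g2
likelihood coupling, and is a property of the estimator at this
boundary condition, not of the optimizer.

## Aberration calibration

Per bead, the 12 Zernike coefficients (orthonormal Noll modes 5-16, in
mlambda) are retrieved jointly with (x, y, focus offset, shared N, b)
by L-BFGS on the Poisson likelihood of a through-focus stack, with
analytic gradients (phase-mode derivatives leave the total energy
invariant, so the normalization is unaffected). A coarse scan over the
focus offset precedes the full optimization — the joint likelihood has
local optima where aberration modes partially mimic defocus. Recovery
on synthetic stacks: injected 40 mlambda astigmatism + 20 mlambda coma
at 1e5 photons/slice are recovered within ±1 mlambda (tolerance ±5).

The field dependence follows Nodal Aberration Theory: the astigmatism
pair as one complex observable fitted by a holomorphic quadratic in the
complex field coordinate h (two nodes), the coma pair linear in h (one
node), remaining modes real quadratics; weighted least squares with
inverse-variance bead weights and a chi-squared bead filter. h is
normalized to unit magnitude at the FOV corner for conditioning.

## Strand analyses

The cone conversion uses the uniform wobble-in-cone order parameter
g2 = cos(alpha)(1+cos(alpha))/2, with closed-form inverse; anchors:
g2 = 0.4 -> 58 deg, g2 = 0.86 -> 25.4 deg (25.37 exactly).

Strand axes are smoothing splines fitted in the strand's principal-axis
frame with the conventional p = 0.1 smoothing parameter, with the
curvature penalty lambda = (1-p)/p evaluated in micrometer units —
the scale at which p = 0.1 yields the few-hundred-nm smoothing length
appropriate for localization data (at nm scale the same p effectively
interpolates noise). Tangents come from central differences on the
densely sampled curve; relative azimuth Delta-phi = phi - tangent is
wrapped to [0, 180), and the signed perpendicular distance feeds
line-width and fine-drift estimates.

Periodicity along a strand: counts in 6.5 nm bins of arc-length
position, mean-subtracted autocorrelation normalized to 1 at lag 0, and
a comb test — at least three near-equidistant maxima with prominence
above 2x the MAD of the autocorrelation tail, spanning at least three
periods. A uniform null keeps the false-positive rate below 5% over
100 seeds.

Fine drift: per frame bin, the perpendicular residuals of several
strands with distinct orientations are solved for a common (dx, dy) by
weighted least squares; at least two orientations are required, and
near-parallel strand sets are flagged as unconstrained.

## Synthetic data

The generator reproduces the reference simulation conditions: 4000
signal photons into the NA, 10 background photons/pixel, positions
uniform over ±1 pixel, orientations via phi = pi u, theta =
arccos(1 - 2u) (area-true on the sphere), Poisson noise only, z = 0
unless swept. Strand tables draw relative azimuths from a Laplace
distribution (median 82 deg, MAD 17 deg by default), g2 from a clipped
normal (peak 0.8), transverse scatter of 8.5 nm sigma (20 nm FWHM
line width), and optionally cluster an orientation-tagged subset with a
fixed period along the axis. Movies paste ROI-sized model patches onto
a constant background with optional on/off schedules and injected
drift.

What the synthetic data does not emulate: finite emission bandwidth,
readout/sCMOS noise, emitter blinking kinetics and photobleaching,
overlapping emitters, and sample-induced refractive-index
heterogeneity. Passing tests therefore demonstrate correctness of the
estimator and analyses under the stated model, not robustness to these
experimental effects.

## Ensemble sizes and numerical choices

CRLB sweeps use 300-400 orientation draws and the efficiency benchmark
300 fits (chosen as the point where ensemble means are stable to ~1-2%);
pupil sampling 64x64, 3x pixel oversampling (capture fractions and
bounds change <0.5% at 96x96 or 5x). All stochastic routines take
explicit seeds; ensembles derive per-instance streams from one
generator.

## Limitations

- The pupil amplitude convention was selected against the documented
  energy distribution of this PSF family (capture fractions ~0.44-0.46);
  with it, most precision anchors agree within a few percent, but the
  in-focus axial bounds sit ~11-12% from their reference values and the
  free-dipole lateral/axial bounds are 18-40% high. No single radial
  pupil weighting we tested reproduces the capture fractions and the
  free-dipole precision anchors simultaneously; the fixed/free axial
  information ratio appears to require a model element (e.g. a different
  SAF or apodization treatment) not recoverable from the available
  description.
- The NAT polynomial orders (quadratic astigmatism, linear coma,
  quadratic others) are the generic lowest-order node structure;
  higher-order field terms of real objectives are not modeled.
- Linking is greedy frame-to-frame without gap closing; emitters that
  blink off for a frame start new tracks.
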