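# vortexfit

Simultaneous 3D localization and dipole-orientation estimation of single
fluorescent emitters with the **Vortex point spread function**.

Inserting a spiral phase plate (topological charge 1) in the emission
Fourier plane of a standard high-NA fluorescence microscope breaks the
orientational symmetries of the in-focus PSF: the shape of a single 2D
camera spot then encodes not only the emitter's lateral position but also
its axial position `z`, its dipole orientation (azimuth `φ`, polar angle
`θ`) and its degree of rotational constraint `g2`. `vortexfit` implements
the full analysis chain for this modality:

- a **fully vectorial dipole PSF model** (three-layer medium/coverslip/
  immersion stack with s/p Fresnel transmission, supercritical-angle
  fluorescence, aplanatic pupil mapping, Zernike aberrations, vortex
  phase mask) with analytic parameter derivatives,
- **maximum-likelihood fitting** of the 8 parameters
  `Θ = (x, y, z, N, b, φ, θ, g2)` per 15×15-pixel ROI under Poisson
  noise, with Cramér–Rao lower bounds (CRLB), convergence and χ² filters,
- **field-dependent aberration calibration**: per-bead Zernike retrieval
  from through-focus stacks and a Nodal-Aberration-Theory (NAT)
  polynomial map of 12 Zernike modes across the field of view,
- a **frame-level pipeline** (photon conversion, candidate detection,
  ROI fitting, track linking, strand-based fine drift correction),
- **orientation analyses along DNA strands**: wobble-cone conversion
  `g2 ↔ α`, smoothing-spline strand axes, relative azimuth `Δφ`,
  orientation-subset periodicity detection by binned autocorrelation,
- a seeded **synthetic-data generator and benchmark harness** used by the
  test suite (no external data required).

The image formation model is a weighted sum of the freely rotating and
fixed dipole PSFs,

```
μ_k = N [ (1−g2)/3 · H_free + g2/3 · H_fixed(φ, θ) ]_k + b ,
```

with the mixture normalized to unit integral over the full image plane,
so `N` counts the signal photons captured into the NA. `g2 = 0` is a
freely rotating emitter, `g2 = 1` a fully fixed one; in the
wobble-in-cone picture `g2 = cos α (1+cos α)/2` for a cone half-angle α.

## Worked example

```python
import numpy as np
from vortexfit import OpticalConfig, EmitterParams
from vortexfit.estimator import fit_mle
from vortexfit.synthdata import simulate_roi

cfg = OpticalConfig()            # NA 1.45, 597.5 nm, 65 nm pixels, vortex
truth = EmitterParams(x=20.0, y=-30.0, z=50.0, n_photons=4000,
                      background=10, phi=55.0, theta=70.0, g2=0.8)
roi = simulate_roi(truth, cfg, seed=7)     # Poisson-noised 15x15 image
res = fit_mle(roi, config=cfg)
print(f"x  = {res.theta_hat.x:6.1f} nm   (CRLB {res.crlb[0]:.1f} nm)")
print(f"phi= {res.theta_hat.phi:6.1f} deg  (CRLB {res.crlb[5]:.1f} deg)")
print(f"g2 = {res.theta_hat.g2:6.2f}      (CRLB {res.crlb[7]:.2f})")
print(f"chi2 = {res.chi2:.2f}  accepted = {res.accepted}")
```

prints

```
x  =   18.8 nm   (CRLB 4.4 nm)
phi=   53.0 deg  (CRLB 2.9 deg)
g2 =   0.96      (CRLB 0.08)
chi2 = 0.91  accepted = True
```

i.e. the position is recovered within its ~4 nm bound, the azimuth within
its ~3° bound, and the fit passes the χ² acceptance window [0.75, 3].

A command-line interface covers the common workflows:

```bash
vortexfit simulate --n-frames 10 --n-emitters 5 --seed 7 --out movie.tif
vortexfit fit movie.tif --out locs.csv
vortexfit link locs.csv --out tracks.csv
vortexfit analyze-strand locs.csv --out strand_report.csv
vortexfit benchmark --n-instances 300 --crlb-only --out bench.csv
```

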