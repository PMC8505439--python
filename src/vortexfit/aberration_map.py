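"""Field-dependent aberration calibration.

High-NA objectives show aberrations that vary smoothly across the field of
view.  This module retrieves per-bead Zernike coefficients from
through-focus bead stacks by joint maximum-likelihood fitting, and models
their field dependence with the low-order polynomial structure of Nodal
Aberration Theory (NAT): the paired astigmatism coefficients follow a
quadratic polynomial in the complex field coordinate ``h = h_x + i h_y``
(up to two zero-aberration "nodes" in the FOV), the paired coma
coefficients a linear one (one node), and the remaining modes real 2D
polynomials of total degree <= 2.

Beads are modeled as freely rotating emitters (g2 = 0).  Zernike
coefficients are in mlambda (thousandths of a wavelength RMS, orthonormal
Noll convention, modes 5-16 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .estimator import poisson_loglik
from .optics_model import (
    EmitterParams,
    OpticalConfig,
    _ModelEval,
    build_pupil,
    zernike_noll,
)

__all__ = [
    "BeadCalibration",
    "AberrationMap",
    "retrieve_bead_zernikes",
    "fit_nat_map",
    "evaluate_map",
    "astigmatism_nodes",
    "coma_node",
]

# Noll indices of the paired modes in the default 5..16 ordering
ASTIG_PAIR = (5, 6)   # sin/cos primary astigmatism
COMA_PAIR = (7, 8)    # y/x primary coma


class CalibrationError(RuntimeError):
    pass


@dataclass
class BeadCalibration:
    """Retrieved aberration state of one bead."""

    field_position: tuple[float, float]      # (x, y) in FOV units (pixels)
    zernike_coeffs: np.ndarray               # (12,) mlambda
    chi2: float
    coeff_sigma: np.ndarray | None = None    # (12,) mlambda, approximate
    converged: bool = True


def _free_dipole_stack(config, coeffs, x, y, z0, z_positions, n_photons, b):
    """Model images of a bead stack plus caches for gradients."""
    pupil = build_pupil(config, coeffs)
    mus, caches = [], []
    for zi in z_positions:
        th = EmitterParams(x=x, y=y, z=z0 + zi, n_photons=n_photons,
                           background=b, g2=0.0)
        ev = _ModelEval(pupil, th)
        h, p = ev.free_density()
        mu = n_photons * ev.bin_to_pixels(h / p) + b
        mus.append(mu)
        caches.append(ev)
    return np.array(mus), caches, pupil


def retrieve_bead_zernikes(zstack: np.ndarray,
                           z_positions,
                           config: OpticalConfig,
                           field_position=(0.0, 0.0),
                           init_coeffs=None,
                           max_nfev: int = 200) -> BeadCalibration:
    """Joint MLE of (x, y, z-offset, N, b, 12 Zernike modes) on a z-stack.

    ``zstack`` is (n_slices, roi, roi) in photons; ``z_positions`` the
    nominal stage positions (nm) of the slices relative to focus.  The
    signal photon count is shared across slices.
    """
    zstack = np.asarray(zstack, dtype=float)
    z_positions = np.asarray(z_positions, dtype=float)
    if zstack.ndim != 3 or zstack.shape[0] != z_positions.size:
        raise ValueError("stack/z_positions mismatch")
    nmodes = len(config.zernike_modes)
    if init_coeffs is None:
        init_coeffs = np.zeros(nmodes)

    # crude initialization from the brightest slice
    from .estimator import initial_estimate
    i0 = int(np.argmax(zstack.sum(axis=(1, 2))))
    est0 = initial_estimate(zstack[i0], config)

    # Zernike derivative maps (phase in rad per mlambda)
    npup = config.pupil_samples
    nu = (np.arange(npup) + 0.5 - npup / 2) * (2.0 / npup)
    nux, nuy = np.meshgrid(nu, nu)
    rho = np.minimum(np.hypot(nux, nuy), 1.0)
    beta = np.arctan2(nuy, nux)
    zmaps = np.array([zernike_noll(j, rho, beta) * (2.0 * np.pi / 1000.0)
                      for j in config.zernike_modes])

    n_data = zstack.reshape(len(z_positions), -1)

    def unpack(p):
        return p[0], p[1], p[2], np.exp(p[3]), np.exp(p[4]), p[5:]

    def negloglik_and_grad(p):
        x, y, z0, n_ph, b, coeffs = unpack(p)
        mus, caches, _ = _free_dipole_stack(
            config, coeffs, x, y, z0, z_positions, n_ph, b)
        mu_flat = mus.reshape(len(z_positions), -1)
        nll = -sum(poisson_loglik(n_data[s], mu_flat[s])
                   for s in range(len(z_positions)))
        grad = np.zeros_like(p)
        for s, ev in enumerate(caches):
            w = (1.0 - n_data[s] / mu_flat[s]).reshape(mus[s].shape)
            h, pnorm = ev.free_density()
            hx, hy = ev.free_lateral_derivs()
            hz, pz = ev.free_density_dz()
            scale = n_ph / pnorm
            grad[0] += np.sum(w * ev.bin_to_pixels(hx)) * scale
            grad[1] += np.sum(w * ev.bin_to_pixels(hy)) * scale
            grad[2] += np.sum(w * ev.bin_to_pixels(
                (hz * pnorm - h * pz) / pnorm ** 2)) * n_ph
            # log-N: d(mu)/dlogN = mu - b = N * bin(h)/pnorm
            grad[3] += np.sum(w * ev.bin_to_pixels(h)) * scale
            grad[4] += np.sum(w)
            # phase-mode derivatives: dU = i * Zmap * U (energy unchanged)
            for m in range(nmodes):
                de = ev.transform(1j * zmaps[m])
                dh = 2.0 * np.einsum("ljyx,ljyx->yx",
                                     np.conj(ev.E), de).real
                grad[5 + m] += np.sum(w * ev.bin_to_pixels(dh)) * scale
        grad[4] *= b           # chain rule of log parameterization
        return nll, grad

    # coarse scan over the shared focus offset: the joint likelihood has
    # local optima in z0 that aberration modes can partially mimic
    z0_best, nll_best = 0.0, np.inf
    for z0_try in np.arange(-200.0, 201.0, 50.0):
        p_try = np.concatenate([
            [est0.x, est0.y, z0_try, np.log(max(est0.n_photons, 10.0)),
             np.log(max(est0.background, 0.1))], init_coeffs])
        nll_try, _ = negloglik_and_grad(p_try)
        if nll_try < nll_best:
            z0_best, nll_best = z0_try, nll_try
    p0 = np.concatenate([
        [est0.x, est0.y, z0_best, np.log(max(est0.n_photons, 10.0)),
         np.log(max(est0.background, 0.1))], init_coeffs])
    res = minimize(negloglik_and_grad, p0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_nfev, "ftol": 1e-10,
                            "gtol": 1e-6})
    x, y, z0, n_ph, b, coeffs = unpack(res.x)
    mus, caches, _ = _free_dipole_stack(
        config, coeffs, x, y, z0, z_positions, n_ph, b)
    chi2 = float(np.mean((zstack - mus) ** 2 / mus))

    # Gauss-Newton covariance of the coefficient block for weighting
    jac_cols = []
    for s, ev in enumerate(caches):
        h, pnorm = ev.free_density()
        scale = n_ph / pnorm
        cols = []
        for m in range(nmodes):
            de = ev.transform(1j * zmaps[m])
            dh = 2.0 * np.einsum("ljyx,ljyx->yx", np.conj(ev.E), de).real
            cols.append((ev.bin_to_pixels(dh) * scale).ravel())
        jac_cols.append(np.array(cols).T / np.sqrt(mus[s].ravel())[:, None])
    j = np.vstack(jac_cols)
    try:
        cov = np.linalg.inv(j.T @ j)
        sigma = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        sigma = None
    if not np.isfinite(chi2):
        raise CalibrationError(f"bead calibration failed: {res.message}")
    # L-BFGS may stop on the iteration budget after the fit has already
    # reached photon-noise level; judge convergence by the fit quality too.
    converged = bool(res.success) or chi2 < 2.0
    return BeadCalibration(field_position=tuple(field_position),
                           zernike_coeffs=coeffs, chi2=chi2,
                           coeff_sigma=sigma, converged=converged)


# ---------------------------------------------------------------------------
# NAT field model


@dataclass
class AberrationMap:
    """NAT polynomial field model for 12 Zernike modes.

    ``astig`` holds 3 complex coefficients (degree 0..2 in h), ``coma``
     2 complex coefficients (degree 0..1); ``other`` maps Noll index ->
    6 real coefficients for [1, hx, hy, hx^2, hx*hy, hy^2].  ``h`` is the
    field position divided by ``fov_radius`` (unit magnitude at the FOV
    corner).
    """

    modes: tuple[int, ...]
    astig: np.ndarray          # (3,) complex
    coma: np.ndarray           # (2,) complex
    other: dict                # noll -> (6,) float
    fov_radius: float
    residual_rms: float = np.nan

    def evaluate(self, field_position, allow_extrapolation: bool = True):
        """12-vector of mlambda coefficients at a field position.

        Positions beyond ~5% outside the calibrated radius are flagged via
        ``ExtrapolationWarning`` unless ``allow_extrapolation``.
        """
        hx = field_position[0] / self.fov_radius
        hy = field_position[1] / self.fov_radius
        if np.hypot(hx, hy) > 1.05:
            import warnings
            msg = ("field position outside calibrated FOV radius; "
                   "aberration map extrapolated")
            if allow_extrapolation:
                warnings.warn(msg, ExtrapolationWarning)
            else:
                raise ValueError(msg)
        h = hx + 1j * hy
        a = self.astig[0] + self.astig[1] * h + self.astig[2] * h * h
        c = self.coma[0] + self.coma[1] * h
        basis = np.array([1.0, hx, hy, hx * hx, hx * hy, hy * hy])
        out = np.zeros(len(self.modes))
        for i, j in enumerate(self.modes):
            if j == ASTIG_PAIR[0]:
                out[i] = a.imag
            elif j == ASTIG_PAIR[1]:
                out[i] = a.real
            elif j == COMA_PAIR[0]:
                out[i] = c.imag
            elif j == COMA_PAIR[1]:
                out[i] = c.real
            else:
                out[i] = float(self.other[j] @ basis)
        return out

    def to_dict(self) -> dict:
        return {
            "modes": list(self.modes),
            "fov_radius": float(self.fov_radius),
            "astig_real": [float(v.real) for v in self.astig],
            "astig_imag": [float(v.imag) for v in self.astig],
            "coma_real": [float(v.real) for v in self.coma],
            "coma_imag": [float(v.imag) for v in self.coma],
            "other": {int(k): [float(x) for x in v]
                      for k, v in self.other.items()},
            "residual_rms": float(self.residual_rms),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AberrationMap":
        astig = np.array(d["astig_real"]) + 1j * np.array(d["astig_imag"])
        coma = np.array(d["coma_real"]) + 1j * np.array(d["coma_imag"])
        other = {int(k): np.asarray(v, dtype=float)
                 for k, v in d["other"].items()}
        return cls(modes=tuple(d["modes"]), astig=astig, coma=coma,
                   other=other, fov_radius=d["fov_radius"],
                   residual_rms=d.get("residual_rms", np.nan))


class ExtrapolationWarning(UserWarning):
    pass


def fit_nat_map(calibrations: list[BeadCalibration],
                fov_radius: float | None = None,
                modes: tuple[int, ...] = tuple(range(5, 17)),
                chi2_max: float = 3.0) -> AberrationMap:
    """Weighted least-squares fit of the NAT forms to per-bead coefficients.

    The two astigmatism (coma) coefficients are combined into one complex
    observable per bead and fitted jointly against the holomorphic
    polynomial in ``h``.  Beads failing the chi-squared filter are
    excluded; weights are inverse-variance where per-bead coefficient
    uncertainties are available.
    """
    cals = [c for c in calibrations if c.chi2 <= chi2_max]
    if len(cals) < 12:
        raise CalibrationError(
            f"need >= 12 usable beads spread over the FOV, got {len(cals)}")
    pos = np.array([c.field_position for c in cals])
    if fov_radius is None:
        fov_radius = float(np.max(np.hypot(pos[:, 0], pos[:, 1])))
    h = (pos[:, 0] + 1j * pos[:, 1]) / fov_radius
    coeffs = np.array([c.zernike_coeffs for c in cals])
    sig = np.array([
        c.coeff_sigma if c.coeff_sigma is not None else np.ones(len(modes))
        for c in cals])
    sig = np.clip(sig, 1e-3, None)

    idx = {j: i for i, j in enumerate(modes)}

    def _wlsq(design, obs, w):
        a = design * w[:, None]
        b = obs * w
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
        rank = np.linalg.matrix_rank(a)
        if rank < design.shape[1]:
            raise CalibrationError(
                "rank-deficient NAT design (beads too collinear for "
                f"{design.shape[1]} polynomial terms)")
        return sol, design @ sol - obs

    residuals = []
    # paired astigmatism: quadratic in h
    obs_a = coeffs[:, idx[ASTIG_PAIR[1]]] + 1j * coeffs[:, idx[ASTIG_PAIR[0]]]
    w_a = 1.0 / np.hypot(sig[:, idx[ASTIG_PAIR[0]]],
                         sig[:, idx[ASTIG_PAIR[1]]])
    astig, r = _wlsq(np.stack([np.ones_like(h), h, h * h], axis=1), obs_a, w_a)
    residuals.extend([r.real, r.imag])
    # paired coma: linear in h
    obs_c = coeffs[:, idx[COMA_PAIR[1]]] + 1j * coeffs[:, idx[COMA_PAIR[0]]]
    w_c = 1.0 / np.hypot(sig[:, idx[COMA_PAIR[0]]], sig[:, idx[COMA_PAIR[1]]])
    coma, r = _wlsq(np.stack([np.ones_like(h), h], axis=1), obs_c, w_c)
    residuals.extend([r.real, r.imag])
    # remaining modes: real quadratic polynomials
    hx, hy = h.real, h.imag
    basis = np.stack([np.ones_like(hx), hx, hy, hx * hx, hx * hy, hy * hy],
                     axis=1)
    other = {}
    for j in modes:
        if j in ASTIG_PAIR + COMA_PAIR:
            continue
        sol, r = _wlsq(basis, coeffs[:, idx[j]], 1.0 / sig[:, idx[j]])
        other[j] = sol
        residuals.append(r)
    rms = float(np.sqrt(np.mean(np.concatenate(residuals) ** 2)))
    return AberrationMap(modes=modes, astig=astig, coma=coma, other=other,
                         fov_radius=fov_radius, residual_rms=rms)


def evaluate_map(amap: AberrationMap, field_position) -> np.ndarray:
    """Deterministic evaluation of the NAT map at a field position."""
    return amap.evaluate(field_position)


def astigmatism_nodes(amap: AberrationMap) -> np.ndarray:
    """Field positions (FOV units) where the astigmatism magnitude vanishes.

    Roots of the complex quadratic; generically two nodes.
    """
    c2, c1, c0 = amap.astig[2], amap.astig[1], amap.astig[0]
    if abs(c2) < 1e-14:
        roots = np.array([-c0 / c1]) if abs(c1) > 1e-14 else np.array([])
    else:
        roots = np.roots([c2, c1, c0])
    return np.array([(r.real * amap.fov_radius, r.imag * amap.fov_radius)
                     for r in roots])


def coma_node(amap: AberrationMap):
    """Field position of the single coma node (or None if coma constant)."""
    if abs(amap.coma[1]) < 1e-14:
        return None
    r = -amap.coma[0] / amap.coma[1]
    return (r.real * amap.fov_radius, r.imag * amap.fov_radius)
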