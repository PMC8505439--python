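"""Vectorial dipole PSF forward model with an optional vortex phase mask.

The model describes the expected photon count produced on a camera by a
single fluorescent emitter treated as an oscillating electric dipole close
to the coverslip of a high-NA microscope.  The emission is propagated
through a three-layer stratified medium (imaging medium -> coverslip ->
immersion oil) with s/p Fresnel transmission, supercritical-angle
fluorescence (SAF) via a complex axial wavevector in the medium, aplanatic
apodization, Zernike wavefront aberrations and, optionally, a spiral
("vortex") phase ramp of topological charge +/-1 in the pupil plane.

An emitter with partial rotational freedom is described by the weight
``g2`` between a fully fixed dipole PSF at orientation ``(phi, theta)`` and
the freely rotating (orientation-averaged) dipole PSF:

    mu_k = N * [ (1 - g2)/3 * H_free + g2/3 * H_fixed ]_k + b

where both PSF components are normalized such that the bracketed mixture
integrates to one over the full image plane -- i.e. ``N`` counts the signal
photons captured into the NA and spread over the entire field, and ``b`` is
the background level per pixel.

Coordinates: image arrays are indexed ``(row=y, col=x)``; positions are in
nm relative to the ROI center; ``z > 0`` moves the emitter from the
coverslip surface into the medium; the stage coordinate has the opposing
sign convention.  Angles at the interfaces are in degrees, with the dipole
hemisphere ``0 <= theta < 180``, ``0 <= phi < 180``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

__all__ = [
    "OpticalConfig",
    "EmitterParams",
    "PupilField",
    "PsfImage",
    "PARAM_NAMES",
    "vortex_phase",
    "zernike_noll",
    "build_pupil",
    "psf_fixed",
    "psf_free",
    "image_model",
    "model_derivatives",
    "roi_capture_fraction",
    "canonicalize_angles",
]

#: Order of the fitted parameter vector used throughout the package.
PARAM_NAMES = ("x", "y", "z", "N", "b", "phi", "theta", "g2")

N_ZERNIKE_MODES = 12


class ConfigurationError(ValueError):
    """Raised for physically inconsistent optical configurations."""


@dataclass(frozen=True)
class OpticalConfig:
    """Optical and camera constants of the imaging system.

    Defaults correspond to a 1.45-NA oil objective imaging emitters at
    597.5 nm through a standard coverslip into an aqueous medium, with a
    65 nm object-space pixel pitch and 15x15-pixel fitting ROIs.
    """

    na: float = 1.45
    wavelength: float = 597.5  # nm
    n_medium: float = 1.33
    n_coverslip: float = 1.523
    n_immersion: float = 1.518
    pixel_size: float = 65.0  # nm, object space
    roi_size: int = 15  # pixels, odd
    pupil_samples: int = 64
    vortex_charge: int = 1  # +1 / -1 spiral, 0 = standard PSF
    oversampling: int = 3  # subpixels per pixel side for pixel integration
    zernike_modes: tuple[int, ...] = tuple(range(5, 17))  # Noll indices

    def __post_init__(self) -> None:
        if self.na > self.n_immersion:
            raise ConfigurationError(
                f"NA {self.na} exceeds immersion index {self.n_immersion}"
            )
        if self.roi_size < 7 or self.roi_size % 2 == 0:
            raise ConfigurationError("roi_size must be odd and >= 7")
        if self.pupil_samples < 32:
            raise ConfigurationError("pupil_samples must be >= 32")
        if self.vortex_charge not in (-1, 0, 1):
            raise ConfigurationError("vortex_charge must be in {-1, 0, +1}")
        if self.oversampling < 1:
            raise ConfigurationError("oversampling must be >= 1")

    def with_(self, **kwargs) -> "OpticalConfig":
        return replace(self, **kwargs)


@dataclass
class EmitterParams:
    """The 8 quantities fitted per emitter.

    x, y, z in nm (lateral relative to ROI center, axial from the coverslip
    into the medium), N signal photons captured into the NA over the whole
    image plane, b background photons per pixel, dipole azimuth ``phi`` and
    polar angle ``theta`` in degrees, and degree of orientational
    constraint ``g2`` in [0, 1] (0 = freely rotating, 1 = fixed).
    """

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    n_photons: float = 4000.0
    background: float = 10.0
    phi: float = 0.0
    theta: float = 90.0
    g2: float = 1.0

    def to_vector(self) -> np.ndarray:
        return np.array(
            [self.x, self.y, self.z, self.n_photons, self.background,
             self.phi, self.theta, self.g2], dtype=float)

    @classmethod
    def from_vector(cls, v) -> "EmitterParams":
        v = np.asarray(v, dtype=float)
        return cls(x=v[0], y=v[1], z=v[2], n_photons=v[3], background=v[4],
                   phi=v[5], theta=v[6], g2=v[7])

    def validate(self) -> None:
        if not (0.0 <= self.g2 <= 1.0):
            raise ValueError(f"g2 must lie in [0, 1], got {self.g2}")
        if self.n_photons < 0 or self.background < 0:
            raise ValueError("photon counts must be non-negative")


def canonicalize_angles(phi_deg: float, theta_deg: float) -> tuple[float, float]:
    """Map a dipole orientation onto the canonical hemisphere.

    The dipole is a headless axis: (phi, theta) and (phi+180, 180-theta)
    describe the same emitter.  Estimates are reported with
    ``theta in [0, 180)`` and ``phi in [0, 180)``.
    """
    phi = phi_deg % 360.0
    theta = theta_deg % 360.0
    if theta >= 180.0:  # flip through the origin
        theta = 360.0 - theta
        phi = (phi + 180.0) % 360.0
    if phi >= 180.0:  # antipodal symmetry: negate in-plane component
        phi -= 180.0
        theta = 180.0 - theta
    if theta == 180.0:
        theta = 0.0
    return phi, theta


def vortex_phase(beta: np.ndarray | float, charge: int) -> np.ndarray | float:
    """Phase delay (radians) of a spiral phase plate at pupil azimuth beta.

    A plate of topological charge +/-1 is a single linear ramp from 0 to
    2*pi in the azimuthal coordinate, so radially opposing pupil points
    always differ by pi.  ``charge=0`` disables the mask (standard PSF).
    """
    if charge not in (-1, 0, 1):
        raise ConfigurationError(f"unsupported vortex charge {charge}")
    return charge * np.asarray(beta) if np.ndim(beta) else charge * beta


# ---------------------------------------------------------------------------
# Zernike polynomials (Noll indexing, orthonormal: coefficient = RMS)

def _noll_to_nm(j: int) -> tuple[int, int]:
    if j < 1:
        raise ValueError("Noll index starts at 1")
    n = 0
    j1 = j - 1
    while j1 > n:
        n += 1
        j1 -= n
    m = (-1) ** j * ((n % 2) + 2 * ((j1 + ((n + 1) % 2)) // 2))
    return n, m


def zernike_noll(j: int, rho: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Orthonormal Zernike polynomial of Noll index ``j`` on the unit disk.

    Normalized such that the RMS over the disk equals 1, i.e. a coefficient
    of ``c`` mlambda contributes ``c/1000 * 2*pi`` radians RMS wavefront.
    """
    n, m = _noll_to_nm(j)
    am = abs(m)
    radial = np.zeros_like(rho, dtype=float)
    for k in range((n - am) // 2 + 1):
        c = ((-1) ** k * math.factorial(n - k)
             / (math.factorial(k)
                * math.factorial((n + am) // 2 - k)
                * math.factorial((n - am) // 2 - k)))
        radial += c * rho ** (n - 2 * k)
    norm = math.sqrt(n + 1) if m == 0 else math.sqrt(2 * (n + 1))
    if m > 0:
        return norm * radial * np.cos(am * beta)
    if m < 0:
        return norm * radial * np.sin(am * beta)
    return norm * radial


# ---------------------------------------------------------------------------
# Pupil construction

@dataclass
class PupilField:
    """Sampled pupil-plane description of the imaging path.

    ``q[l, j]`` couples dipole component j in {x, y, z} to camera field
    polarization l in {x, y}; it already contains Fresnel transmission,
    apodization, the static phase (aberrations + vortex) and the aperture
    mask.  ``kx, ky`` are transverse wavevectors (1/nm); ``kz_medium`` is
    complex inside the supercritical (SAF) zone; ``kz_immersion`` is real.
    """

    config: OpticalConfig
    q: np.ndarray               # (2, 3, Np, Np) complex
    kx: np.ndarray              # (Np, Np) 1/nm
    ky: np.ndarray
    kz_medium: np.ndarray       # (Np, Np) complex 1/nm
    kz_coverslip: np.ndarray    # (Np, Np) 1/nm (real: n_coverslip > NA)
    kz_immersion: np.ndarray    # (Np, Np) 1/nm
    mask: np.ndarray            # (Np, Np) bool, rho <= 1
    phase: np.ndarray           # static phase W (radians), aberration+vortex
    dk: float                   # pupil sample spacing (1/nm)

    @property
    def rho(self) -> np.ndarray:
        k_na = 2.0 * np.pi * self.config.na / self.config.wavelength
        return np.hypot(self.kx, self.ky) / k_na


def _fresnel_ts_tp(n1, c1, n2, c2):
    ts = 2.0 * n1 * c1 / (n1 * c1 + n2 * c2)
    tp = 2.0 * n1 * c1 / (n2 * c1 + n1 * c2)
    return ts, tp


def build_pupil(config: OpticalConfig,
                zernike_coeffs=None,
                ) -> PupilField:
    """Construct the pupil-plane field basis for a given configuration.

    Parameters
    ----------
    zernike_coeffs
        Coefficients in mlambda (thousandths of a wavelength RMS) for the
        Noll modes listed in ``config.zernike_modes`` (default Noll 5-16).

    The returned basis is independent of the emitter parameters; axial and
    lateral phases are applied per emitter when forming images.
    """
    if zernike_coeffs is None:
        zernike_coeffs = np.zeros(len(config.zernike_modes))
    zernike_coeffs = np.asarray(zernike_coeffs, dtype=float)
    if zernike_coeffs.shape != (len(config.zernike_modes),):
        raise ValueError(
            f"expected {len(config.zernike_modes)} Zernike coefficients, "
            f"got shape {zernike_coeffs.shape}")

    npup = config.pupil_samples
    k0 = 2.0 * np.pi / config.wavelength
    k_na = k0 * config.na
    # cell centers in (-1, 1); avoids the exact vortex singularity at rho=0
    nu = (np.arange(npup) + 0.5 - npup / 2) * (2.0 / npup)
    nux, nuy = np.meshgrid(nu, nu)          # [row=ky, col=kx]
    rho = np.hypot(nux, nuy)
    beta = np.arctan2(nuy, nux)
    mask = rho <= 1.0

    kx = k_na * nux
    ky = k_na * nuy
    sin_im = np.clip(config.na * rho / config.n_immersion, 0.0, 1.0)
    cos_im = np.sqrt(1.0 - sin_im ** 2)
    # Snell: n_im sin(theta_im) = n_cs sin(theta_cs) = n_med sin(theta_med)
    s_med = config.na * rho / config.n_medium          # may exceed 1 (SAF)
    c_med = np.sqrt((1.0 - s_med ** 2).astype(complex))
    c_med = np.where(np.imag(c_med) < 0, -c_med, c_med)  # decay into medium
    s_cs = config.na * rho / config.n_coverslip
    c_cs = np.sqrt((1.0 - s_cs ** 2).astype(complex))

    # Angular-spectrum (Weyl) amplitude of the dipole field: each plane-wave
    # component carries a 1/k_z factor in the medium, transmitted through
    # the layer stack toward the immersion side.  The product
    # t^(1->3)/cos(theta_med) stays finite and complex at and beyond the
    # medium critical angle, producing the bright supercritical (SAF) rim.
    ts12, tp12 = _fresnel_ts_tp(config.n_medium, c_med,
                                config.n_coverslip, c_cs)
    ts23, tp23 = _fresnel_ts_tp(config.n_coverslip, c_cs,
                                config.n_immersion, cos_im)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_cmed = np.where(mask, 1.0 / np.where(c_med == 0, 1.0, c_med), 0.0)
    ts = ts12 * ts23 * inv_cmed
    tp = tp12 * tp23 * inv_cmed

    # Pupil amplitude mapping: the 1/cos(theta_imm) weighting combines the
    # aplanatic detection apodization with the oblique projection of the
    # plane-wave spectrum onto the flat pupil reference plane.  Together
    # with the 1/cos(theta_med) spectrum factor above it reproduces the
    # documented energy distribution of this PSF family (ROI capture
    # fractions near 0.45 for a 15x15 ROI at the default configuration).
    with np.errstate(divide="ignore"):
        apod = np.where(mask, 1.0 / np.maximum(cos_im, 1e-9), 0.0)

    cb, sb = np.cos(beta), np.sin(beta)
    # Medium-side polarization unit vectors projected on the dipole axes:
    #   s-hat = (-sin b, cos b, 0);  p-hat = (c_med cos b, c_med sin b, -s_med)
    # After the objective p-hat maps to (cos b, sin b, 0), s-hat is unchanged.
    q = np.empty((2, 3, npup, npup), dtype=complex)
    q[0, 0] = tp * c_med * cb * cb + ts * sb * sb        # E_x <- d_x
    q[0, 1] = tp * c_med * cb * sb - ts * sb * cb        # E_x <- d_y
    q[0, 2] = -tp * s_med * cb                           # E_x <- d_z
    q[1, 0] = tp * c_med * sb * cb - ts * cb * sb        # E_y <- d_x
    q[1, 1] = tp * c_med * sb * sb + ts * cb * cb        # E_y <- d_y
    q[1, 2] = -tp * s_med * sb                           # E_y <- d_z

    phase = np.zeros((npup, npup))
    rho_c = np.minimum(rho, 1.0)
    for coeff, j in zip(zernike_coeffs, config.zernike_modes):
        if coeff != 0.0:
            phase += (coeff / 1000.0) * 2.0 * np.pi * zernike_noll(j, rho_c, beta)
    if config.vortex_charge != 0:
        phase = phase + vortex_phase(beta, config.vortex_charge)

    q *= (apod * np.exp(1j * phase) * mask)[None, None]

    return PupilField(
        config=config, q=q, kx=kx, ky=ky,
        kz_medium=k0 * config.n_medium * c_med,
        kz_coverslip=k0 * config.n_coverslip * np.real(c_cs),
        kz_immersion=k0 * config.n_immersion * cos_im,
        mask=mask, phase=np.where(mask, phase, 0.0),
        dk=k_na * 2.0 / npup,
    )


# ---------------------------------------------------------------------------
# Pupil -> image propagation

@lru_cache(maxsize=32)
def _transform_matrices(npup: int, dk: float, n_img: int, dx: float):
    """DFT matrices evaluating the pupil integral on the image subgrid."""
    k = (np.arange(npup) + 0.5 - npup / 2) * dk
    r = (np.arange(n_img) - (n_img - 1) / 2) * dx
    a = np.exp(1j * np.outer(r, k)) * dk  # (n_img, npup)
    return a


class PsfImage:
    """Expected photon counts per pixel over the ROI plus provenance."""

    def __init__(self, mu: np.ndarray, theta: EmitterParams | None,
                 config: OpticalConfig):
        self.mu = mu
        self.theta = theta
        self.config = config

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.mu, dtype=dtype)


class _ModelEval:
    """One forward-model evaluation: fields, energies and derivatives.

    All image-plane quantities live on the oversampled subgrid until they
    are binned to camera pixels; densities carry units of 1/nm^2 and the
    full-plane (Plancherel) energies are used for normalization so that the
    Eq.-style mixture integrates to 1 over the entire image plane.
    """

    def __init__(self, pupil: PupilField, theta: EmitterParams,
                 n_img: int | None = None, dx: float | None = None):
        cfg = pupil.config
        self.cfg = cfg
        self.theta = theta
        ovs = cfg.oversampling
        if n_img is None:
            n_img = cfg.roi_size * ovs
        if dx is None:
            dx = cfg.pixel_size / ovs
        self.n_img = n_img
        self.dx = dx

        # Emitter-dependent pupil phase: axial propagation and lateral
        # shift.  Above the coverslip (z >= 0) axial propagation uses the
        # medium wavevector, complex in the SAF zone so the supercritical
        # rim decays with emitter height; below the interface the emitter
        # sits inside the glass where the axial wavevector is real (the
        # coverslip index exceeds the NA), so no evanescent growth occurs.
        kz = pupil.kz_medium if theta.z >= 0 else pupil.kz_coverslip
        self._kz = kz
        shift = np.exp(
            1j * (kz * theta.z)
            - 1j * (pupil.kx * theta.x + pupil.ky * theta.y))
        u = pupil.q * shift[None, None]                   # (2,3,Np,Np)
        ux = u * (-1j * pupil.kx)[None, None]
        uy = u * (-1j * pupil.ky)[None, None]
        uz = u * (1j * kz)[None, None]

        a = _transform_matrices(cfg.pupil_samples, pupil.dk, n_img, dx)
        self._a = a
        self._u = u
        stack = np.stack([u, ux, uy, uz])                 # (4,2,3,Np,Np)
        # E[c,l,j,y,x] = sum_mn A[y,m] U[c,l,j,m,n] A[x,n]
        e = np.einsum("ym,cljmn,xn->cljyx", a, stack, a, optimize=True)
        self.E, self.Ex, self.Ey, self.Ez = e

        # Full-plane energy matrices via Plancherel: M[j,k] integrates
        # conj(E_j) E_k over the whole plane, summed over polarizations.
        pl = (2.0 * np.pi) ** 2 * pupil.dk ** 2
        self.M = pl * np.einsum("ljmn,lkmn->jk", np.conj(u), u)
        self.Mz = pl * (np.einsum("ljmn,lkmn->jk", np.conj(uz), u)
                        + np.einsum("ljmn,lkmn->jk", np.conj(u), uz))

    def transform(self, factor: np.ndarray) -> np.ndarray:
        """Image fields of the pupil perturbed multiplicatively by ``factor``.

        Used for derivatives with respect to pupil-phase parameters
        (e.g. Zernike coefficients): pass ``1j * phase_map``.
        """
        return np.einsum("ym,ljmn,xn->ljyx", self._a,
                         self._u * factor[None, None], self._a,
                         optimize=True)

    # -- free-dipole component ------------------------------------------
    def free_density(self):
        h = np.einsum("ljyx->yx", np.abs(self.E) ** 2)
        p = np.real(np.trace(self.M))
        return h, p

    def free_density_dz(self):
        hz = 2.0 * np.einsum("ljyx,ljyx->yx",
                             np.conj(self.E), self.Ez).real
        pz = np.real(np.trace(self.Mz))
        return hz, pz

    # -- fixed-dipole component -----------------------------------------
    @staticmethod
    def dipole_vector(phi_deg: float, theta_deg: float):
        ph, th = np.deg2rad(phi_deg), np.deg2rad(theta_deg)
        d = np.array([np.sin(th) * np.cos(ph),
                      np.sin(th) * np.sin(ph),
                      np.cos(th)])
        dphi = np.array([-np.sin(th) * np.sin(ph),
                         np.sin(th) * np.cos(ph), 0.0])
        dth = np.array([np.cos(th) * np.cos(ph),
                        np.cos(th) * np.sin(ph), -np.sin(th)])
        return d, dphi, dth

    def fixed_density(self):
        d, dphi, dth = self.dipole_vector(self.theta.phi, self.theta.theta)
        el = np.einsum("ljyx,j->lyx", self.E, d)
        h = np.einsum("lyx->yx", np.abs(el) ** 2)
        p = float(np.real(d @ self.M @ d))
        return h, p, (d, dphi, dth, el)

    def fixed_derivs(self, cache):
        d, dphi, dth, el = cache
        elz = np.einsum("ljyx,j->lyx", self.Ez, d)
        hz = 2.0 * np.einsum("lyx,lyx->yx", np.conj(el), elz).real
        pz = float(np.real(d @ self.Mz @ d))
        el_phi = np.einsum("ljyx,j->lyx", self.E, dphi)
        el_th = np.einsum("ljyx,j->lyx", self.E, dth)
        hphi = 2.0 * np.einsum("lyx,lyx->yx", np.conj(el), el_phi).real
        hth = 2.0 * np.einsum("lyx,lyx->yx", np.conj(el), el_th).real
        m_re = np.real(self.M)
        pphi = float(2.0 * d @ m_re @ dphi)
        pth = float(2.0 * d @ m_re @ dth)
        return hz, pz, hphi, pphi, hth, pth

    def fixed_lateral_derivs(self, cache):
        d, _, _, el = cache
        elx = np.einsum("ljyx,j->lyx", self.Ex, d)
        ely = np.einsum("ljyx,j->lyx", self.Ey, d)
        hx = 2.0 * np.einsum("lyx,lyx->yx", np.conj(el), elx).real
        hy = 2.0 * np.einsum("lyx,lyx->yx", np.conj(el), ely).real
        return hx, hy

    def free_lateral_derivs(self):
        hx = 2.0 * np.einsum("ljyx,ljyx->yx", np.conj(self.E), self.Ex).real
        hy = 2.0 * np.einsum("ljyx,ljyx->yx", np.conj(self.E), self.Ey).real
        return hx, hy

    def bin_to_pixels(self, sub: np.ndarray) -> np.ndarray:
        """Integrate an oversampled density over camera pixels."""
        ovs = self.cfg.oversampling
        npix = self.n_img // ovs
        area = self.dx ** 2
        return sub.reshape(npix, ovs, npix, ovs).sum(axis=(1, 3)) * area


def psf_free(pupil: PupilField, theta: EmitterParams | None = None) -> PsfImage:
    """Freely rotating dipole PSF component, integrating to 3 full-plane.

    Incoherent orientation average over the sphere, equal to the sum over
    three orthogonal dipoles.  Independent of phi/theta by construction.
    """
    theta = theta or EmitterParams()
    ev = _ModelEval(pupil, theta)
    h, p = ev.free_density()
    return PsfImage(ev.bin_to_pixels(3.0 * h / p), theta, pupil.config)


def psf_fixed(theta: EmitterParams, pupil: PupilField) -> PsfImage:
    """Fixed-dipole PSF component at orientation (phi, theta).

    Normalized per orientation to integrate to 3 over the full plane, so
    the weighted mixture of free and fixed parts integrates to 1.
    """
    ev = _ModelEval(pupil, theta)
    h, p, _ = ev.fixed_density()
    return PsfImage(ev.bin_to_pixels(3.0 * h / p), theta, pupil.config)


def image_model(theta: EmitterParams,
                config: OpticalConfig,
                zernike_coeffs=None,
                pupil: PupilField | None = None) -> PsfImage:
    """Expected photon count per ROI pixel for emitter parameters ``theta``.

    mu_k = N [ (1-g2)/3 H_free + g2/3 H_fixed ]_k (pixel-integrated) + b.
    """
    theta.validate()
    if pupil is None:
        pupil = build_pupil(config, zernike_coeffs)
    ev = _ModelEval(pupil, theta)
    hf, pf = ev.free_density()
    mix = (1.0 - theta.g2) * hf / pf
    if theta.g2 > 0.0:
        hx, px, _ = ev.fixed_density()
        mix = mix + theta.g2 * hx / px
    mu = theta.n_photons * ev.bin_to_pixels(mix) + theta.background
    if theta.background == 0.0 and np.any(mu <= 0.0):
        raise FloatingPointError(
            "model contains zero-expectation pixels with b=0; the Poisson "
            "likelihood is singular there")
    return PsfImage(mu, theta, config)


def model_derivatives(theta: EmitterParams,
                      config: OpticalConfig,
                      zernike_coeffs=None,
                      pupil: PupilField | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Model image and its 8 parameter derivatives.

    Returns ``(mu, jac)`` with ``jac`` of shape (roi, roi, 8) ordered as
    ``PARAM_NAMES``; angle derivatives are per degree.  The derivatives
    account for the per-orientation normalization of the fixed component
    (its full-plane energy varies with z through SAF and with the dipole
    orientation).
    """
    theta.validate()
    if pupil is None:
        pupil = build_pupil(config, zernike_coeffs)
    ev = _ModelEval(pupil, theta)
    g2, n = theta.g2, theta.n_photons

    hf, pf = ev.free_density()
    f = hf / pf
    hfz, pfz = ev.free_density_dz()
    fz = (hfz * pf - hf * pfz) / pf ** 2
    hfx, hfy = ev.free_lateral_derivs()

    hx, px, cache = ev.fixed_density()
    g = hx / px
    hz, pz, hphi, pphi, hth, pth = ev.fixed_derivs(cache)
    gz = (hz * px - hx * pz) / px ** 2
    gphi = (hphi * px - hx * pphi) / px ** 2
    gth = (hth * px - hx * pth) / px ** 2
    gx, gy = ev.fixed_lateral_derivs(cache)

    mix = (1.0 - g2) * f + g2 * g
    mu = n * ev.bin_to_pixels(mix) + theta.background

    deg = np.pi / 180.0
    roi = config.roi_size
    jac = np.empty((roi, roi, 8))
    jac[..., 0] = n * ev.bin_to_pixels((1.0 - g2) * hfx / pf + g2 * gx / px)
    jac[..., 1] = n * ev.bin_to_pixels((1.0 - g2) * hfy / pf + g2 * gy / px)
    jac[..., 2] = n * ev.bin_to_pixels((1.0 - g2) * fz + g2 * gz)
    jac[..., 3] = (mu - theta.background) / n if n > 0 else 0.0
    jac[..., 4] = 1.0
    jac[..., 5] = n * g2 * ev.bin_to_pixels(gphi) * deg
    jac[..., 6] = n * g2 * ev.bin_to_pixels(gth) * deg
    jac[..., 7] = n * ev.bin_to_pixels(g - f)
    return mu, jac


def roi_capture_fraction(config: OpticalConfig,
                         mode: str | None = None,
                         theta: EmitterParams | None = None,
                         zernike_coeffs=None) -> float:
    """Fraction of NA-captured signal photons inside the fitting ROI.

    Reference case: in-focus, centered, freely rotating emitter.  ``mode``
    may force ``"vortex"`` or ``"standard"`` regardless of the configured
    charge.  Override ``theta`` for other emitter states.
    """
    if mode is not None:
        charge = {"vortex": (config.vortex_charge or 1),
                  "standard": 0}[mode]
        config = config.with_(vortex_charge=charge)
    pupil = build_pupil(config, zernike_coeffs)
    if theta is None:
        theta = EmitterParams(g2=0.0)
    ev = _ModelEval(pupil, theta)
    hf, pf = ev.free_density()
    mix = (1.0 - theta.g2) * hf / pf
    if theta.g2 > 0.0:
        hx, px, _ = ev.fixed_density()
        mix = mix + theta.g2 * hx / px
    return float(ev.bin_to_pixels(mix).sum())
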