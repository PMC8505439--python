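"""Orientation analyses along DNA strands.

Converts the rotational-constraint parameter g2 to a wobble-in-cone
half-angle, fits smoothing-spline axes to strand localizations, computes
azimuthal dipole angles relative to the local strand direction, and
detects spatial periodicity of orientation-selected localizations by
binned autocorrelation along the strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

__all__ = [
    "g2_to_cone_angle",
    "cone_angle_to_g2",
    "StrandAxis",
    "OrientationSubset",
    "fit_strand_axis",
    "relative_azimuth",
    "periodicity_autocorrelation",
    "g2_histogram_peak",
]


def cone_angle_to_g2(alpha_deg):
    """g2 of a dipole wobbling uniformly in a cone of half-angle alpha.

    For uniform orientation within a cone the second-order parameter is
    g2 = cos(alpha) (1 + cos(alpha)) / 2: 1 for a fixed dipole (alpha=0),
    0 for free rotation (alpha=180).
    """
    a = np.radians(np.asarray(alpha_deg, dtype=float))
    c = np.cos(a)
    return c * (1.0 + c) / 2.0


def g2_to_cone_angle(g2):
    """Wobble-cone half-angle (degrees) for a given g2 in [0, 1].

    Closed-form inverse of ``cone_angle_to_g2``: cos(alpha) solves the
    quadratic c^2 + c - 2 g2 = 0.
    """
    g = np.asarray(g2, dtype=float)
    if np.any((g < 0) | (g > 1)):
        raise ValueError("g2 must lie in [0, 1]")
    c = (-1.0 + np.sqrt(1.0 + 8.0 * g)) / 2.0
    out = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    return float(out) if np.isscalar(g2) else out


@dataclass
class OrientationSubset:
    """Wrap-aware angular selection (relative azimuth and polar bands)."""

    dphi_range: tuple[float, float] | None = None    # degrees, in [0, 180)
    theta_range: tuple[float, float] | None = None   # degrees

    def select(self, dphi, theta):
        ok = np.ones(np.shape(dphi), dtype=bool)
        if self.dphi_range is not None:
            lo, hi = (v % 180.0 for v in self.dphi_range)
            d = np.asarray(dphi) % 180.0
            ok &= (d >= lo) & (d <= hi) if lo <= hi else (d >= lo) | (d <= hi)
        if self.theta_range is not None:
            lo, hi = self.theta_range
            ok &= (np.asarray(theta) >= lo) & (np.asarray(theta) <= hi)
        return ok


class StrandAxis:
    """Smoothing-spline curve through strand localizations.

    The points are rotated into a frame where the strand's principal axis
    is horizontal, a smoothing spline is fitted and the densely sampled
    curve kept as a polyline with arc-length parameterization; tangents
    come from central finite differences on the curve.
    """

    def __init__(self, curve_xy: np.ndarray, rotation_deg: float):
        self.curve = curve_xy                   # (n, 2) nm, original frame
        self.rotation_deg = rotation_deg
        d = np.gradient(curve_xy, axis=0)
        self.tangent_deg = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
        seg = np.linalg.norm(np.diff(curve_xy, axis=0), axis=1)
        self.arc = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc[-1])

    def project(self, x, y):
        """Nearest-point projection of (x, y) onto the curve.

        Returns (arc position, signed perpendicular distance, local
        tangent angle in degrees).  Equidistant candidates are resolved to
        the smallest arc-length (first minimum).
        """
        pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
        d2 = ((pts[:, None, :] - self.curve[None, :, :]) ** 2).sum(-1)
        idx = np.argmin(d2, axis=1)             # first minimum = smallest arc
        t = np.radians(self.tangent_deg[idx])
        rel = pts - self.curve[idx]
        dist = -rel[:, 0] * np.sin(t) + rel[:, 1] * np.cos(t)
        out = (self.arc[idx], dist, self.tangent_deg[idx])
        if np.isscalar(x):
            return out[0][0], out[1][0], out[2][0]
        return out


def fit_strand_axis(x, y, smoothing: float = 0.1, n_samples: int = 2000
                    ) -> StrandAxis:
    """Fit a smoothing-spline axis to strand localizations.

    ``smoothing`` follows the common smoothing-spline convention that
    interpolates at 1 and tends to the least-squares line at 0, with the
    curvature penalty weighted by lambda = (1 - p)/p evaluated with
    coordinates in micrometers (the scale at which the conventional
    default p = 0.1 produces a smoothing length of a few hundred nm for
    typical strand data).  Strands are fitted in their principal-axis
    frame, so moderately curved or diagonal strands are handled; closed
    or strongly folded shapes are not supported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("need >= 10 localizations to fit a strand axis")
    if not 0.0 < smoothing <= 1.0:
        raise ValueError("smoothing parameter must lie in (0, 1]")
    center = np.array([x.mean(), y.mean()])
    xy = np.column_stack([x, y]) - center
    # principal axis via SVD; rotate it onto +x
    _, _, vt = np.linalg.svd(xy, full_matrices=False)
    ang = np.arctan2(vt[0, 1], vt[0, 0])
    rot = np.array([[np.cos(-ang), -np.sin(-ang)],
                    [np.sin(-ang), np.cos(-ang)]])
    uv = xy @ rot.T
    order = np.argsort(uv[:, 0])
    u, v = uv[order, 0] / 1000.0, uv[order, 1] / 1000.0   # nm -> um
    u, uniq = np.unique(u, return_index=True)
    v = v[uniq]
    lam = (1.0 - smoothing) / smoothing
    spl = make_smoothing_spline(u, v, lam=lam)
    ug = np.linspace(u[0], u[-1], n_samples)
    curve_uv = np.column_stack([ug, spl(ug)]) * 1000.0    # um -> nm
    curve = curve_uv @ rot + center
    return StrandAxis(curve, np.degrees(ang))


def relative_azimuth(phi_deg, x, y, axis: StrandAxis):
    """Dipole azimuth relative to the local strand direction.

    Returns ``(dphi, dist)``: the azimuth difference wrapped into
    [0, 180) per the dipole hemisphere convention, and the signed
    perpendicular distance from the axis (which feeds line-width and
    fine-drift analyses).
    """
    _, dist, tangent = axis.project(x, y)
    dphi = (np.asarray(phi_deg, dtype=float) - tangent) % 180.0
    if np.isscalar(phi_deg) and np.ndim(dphi):
        return float(dphi), float(dist)
    return dphi, dist


def circular_median_mad(dphi, period: float = 180.0):
    """Median and MAD of angles living on a circle of given period.

    The sample is unwrapped around its circular mean before computing the
    ordinary median and median absolute deviation.
    """
    a = np.asarray(dphi, dtype=float) * 2.0 * np.pi / period
    mean = np.arctan2(np.sin(a).mean(), np.cos(a).mean())
    un = (np.asarray(dphi) - mean * period / (2 * np.pi)
          + period / 2) % period - period / 2
    med = np.median(un) + mean * period / (2 * np.pi)
    mad = np.median(np.abs(un - np.median(un)))
    return float(med % period), float(mad)


def periodicity_autocorrelation(arc_positions,
                                bin_width: float = 6.5,
                                min_peaks: int = 3,
                                prominence_mads: float = 2.0):
    """Autocorrelation of localization density along the strand axis.

    Localizations (arc-length positions, typically an orientation subset)
    are counted in ``bin_width`` bins; the mean-subtracted counts are
    autocorrelated and normalized to 1 at lag zero.  A periodicity is
    reported when at least ``min_peaks`` near-equidistant local maxima
    stand out of the lag-domain noise (prominence above
    ``prominence_mads`` times the MAD of the autocorrelation tail).

    Returns a dict with ``lag_nm``, ``autocorrelation``, ``period_nm``
    (NaN if none found) and ``reliable``.
    """
    s = np.asarray(arc_positions, dtype=float)
    if s.size < 10:
        raise ValueError("too few localizations for autocorrelation")
    edges = np.arange(s.min(), s.max() + bin_width, bin_width)
    counts, _ = np.histogram(s, bins=edges)
    c = counts - counts.mean()
    ac = np.correlate(c, c, mode="full")[len(c) - 1:]
    if ac[0] <= 0:
        raise ValueError("degenerate (constant) density profile")
    ac = ac / ac[0]
    lags = np.arange(ac.size) * bin_width
    noise = np.median(np.abs(ac[1:] - np.median(ac[1:])))
    peaks, props = find_peaks(ac[1:], prominence=prominence_mads * noise)
    peaks = peaks + 1
    period = np.nan
    reliable = False
    if len(peaks) >= min_peaks:
        spacing = np.diff(lags[peaks])
        med = np.median(spacing)
        # accept only a near-equidistant comb
        if np.all(np.abs(spacing - med) <= max(2 * bin_width, 0.2 * med)):
            period = float(np.median(spacing))
            reliable = lags[peaks[-1]] >= 3 * period
        elif len(peaks) >= min_peaks:
            # fall back to the first-peak harmonic comb if spacings are
            # contaminated by a stray maximum
            cand = lags[peaks[0]]
            harmonics = lags[peaks] / cand
            if np.all(np.abs(harmonics - np.round(harmonics)) < 0.25):
                period = float(cand)
                reliable = lags[peaks[-1]] >= 3 * period
    return {"lag_nm": lags, "autocorrelation": ac,
            "period_nm": period, "reliable": bool(reliable),
            "peak_lags_nm": lags[peaks]}


def g2_histogram_peak(g2_values, bandwidth: float | None = None):
    """Mode of the g2 distribution via kernel density, with cone angle.

    Returns ``(g2_peak, alpha_deg)``.
    """
    g = np.asarray(g2_values, dtype=float)
    if g.size < 100:
        raise ValueError("need >= 100 localizations for a stable g2 peak")
    kde = gaussian_kde(g, bw_method=bandwidth)
    grid = np.linspace(0.0, 1.0, 1001)
    peak = float(grid[np.argmax(kde(grid))])
    return peak, g2_to_cone_angle(peak)
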