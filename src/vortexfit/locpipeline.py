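"""Frame-level localization pipeline.

Camera frames (ADU) are gain/offset-converted to photons, candidate
emitters are detected by thresholding at the background plus a constant
(around 10 photons), 15x15-pixel ROIs are cut around the local centroids
and fitted with the vectorial PSF model, and the accepted localizations
are linked across consecutive frames and optionally corrected for fine
drift using straight DNA strands as fiducials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .aberration_map import AberrationMap
from .estimator import FitOptions, fit_mle, initial_estimate
from .optics_model import OpticalConfig, PARAM_NAMES, build_pupil

__all__ = [
    "CameraModel",
    "Track",
    "photon_convert",
    "detect_candidates",
    "extract_roi",
    "process_frame",
    "process_stack",
    "link_localizations",
    "fine_drift",
    "LOCALIZATION_COLUMNS",
]

LOCALIZATION_COLUMNS = (
    ["frame", "x_nm", "y_nm", "z_nm", "photons", "background",
     "phi_deg", "theta_deg", "g2"]
    + [f"crlb_{p}" for p in PARAM_NAMES]
    + ["chi2", "n_iterations", "field_x_px", "field_y_px", "rejected_reason"]
)


@dataclass
class CameraModel:
    gain: float = 2.0     # ADU / photon
    offset: float = 100.0  # ADU

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("camera gain must be positive")


def photon_convert(adu_image: np.ndarray, gain: float, offset: float
                   ) -> np.ndarray:
    """(ADU - offset)/gain, clamped at zero."""
    if gain <= 0:
        raise ValueError("camera gain must be positive")
    return np.clip((np.asarray(adu_image, dtype=float) - offset) / gain,
                   0.0, None)


def detect_candidates(frame: np.ndarray,
                      background_estimate: float | None = None,
                      threshold_offset: float = 10.0,
                      min_pixels: int = 2,
                      merge_radius_px: float = 7.0
                      ) -> list[tuple[float, float]]:
    """Candidate emitter centers (x_px, y_px) by intensity thresholding.

    Pixels above ``background + threshold_offset`` are grouped into
    connected components; each component of at least ``min_pixels`` pixels
    yields one candidate at its intensity-weighted local centroid (more
    robust than the brightest pixel for donut-shaped spots).  Overlapping
    emitters both produce candidates; confounded fits are left to the
    chi-squared filter downstream.
    """
    frame = np.asarray(frame, dtype=float)
    if background_estimate is None:
        background_estimate = float(np.median(frame))
    mask = frame > background_estimate + threshold_offset
    labels, n = ndimage.label(mask)
    cands = []
    for i in range(1, n + 1):
        sel = labels == i
        if sel.sum() < min_pixels:
            continue
        w = np.where(sel, frame - background_estimate, 0.0)
        cy, cx = ndimage.center_of_mass(w)
        cands.append([float(cx), float(cy), float(w.sum())])
    # The donut-shaped PSF can break one emitter into several components
    # (central spot + ring fragments); merge candidates closer than the
    # merge radius, weighting by component mass.
    cands.sort(key=lambda c: -c[2])
    out: list[list[float]] = []
    for cx, cy, m in cands:
        for o in out:
            if np.hypot(o[0] - cx, o[1] - cy) < merge_radius_px:
                tot = o[2] + m
                o[0] = (o[0] * o[2] + cx * m) / tot
                o[1] = (o[1] * o[2] + cy * m) / tot
                o[2] = tot
                break
        else:
            out.append([cx, cy, m])
    return [(c[0], c[1]) for c in out]


def extract_roi(frame: np.ndarray, center: tuple[float, float],
                roi_size: int):
    """Crop a square ROI around an (x, y) pixel center; None near edges."""
    half = roi_size // 2
    cx, cy = int(round(center[0])), int(round(center[1]))
    h, w = frame.shape
    if not (half <= cx < w - half and half <= cy < h - half):
        return None, None
    roi = frame[cy - half:cy + half + 1, cx - half:cx + half + 1]
    return roi, (cx, cy)


def process_frame(frame: np.ndarray,
                  frame_index: int,
                  config: OpticalConfig,
                  aberration_map: AberrationMap | None = None,
                  fit_options: FitOptions | None = None,
                  threshold_offset: float = 10.0,
                  _pupil_cache: dict | None = None) -> list[dict]:
    """Detect and fit all candidates of one photon frame."""
    rows = []
    bg = float(np.median(frame))
    for cx_f, cy_f in detect_candidates(frame, bg, threshold_offset):
        roi, center = extract_roi(frame, (cx_f, cy_f), config.roi_size)
        if roi is None:
            continue
        cx, cy = center
        if aberration_map is not None:
            zc = aberration_map.evaluate((cx, cy))
            pupil = build_pupil(config, zc)
        else:
            if _pupil_cache is not None:
                pupil = _pupil_cache.setdefault(
                    "p", build_pupil(config, None))
            else:
                pupil = build_pupil(config, None)
        res = fit_mle(roi, config=config, pupil=pupil, options=fit_options)
        t = res.theta_hat
        row = {
            "frame": frame_index,
            "x_nm": t.x + cx * config.pixel_size,
            "y_nm": t.y + cy * config.pixel_size,
            "z_nm": t.z, "photons": t.n_photons, "background": t.background,
            "phi_deg": t.phi, "theta_deg": t.theta, "g2": t.g2,
            "chi2": res.chi2, "n_iterations": res.n_iterations,
            "field_x_px": cx, "field_y_px": cy,
            "rejected_reason": res.rejected_reason,
        }
        for p, c in zip(PARAM_NAMES, res.crlb):
            row[f"crlb_{p}"] = c
        rows.append(row)
    return rows


def process_stack(frames,
                  config: OpticalConfig,
                  aberration_map: AberrationMap | None = None,
                  camera: CameraModel | None = None,
                  fit_options: FitOptions | None = None,
                  threshold_offset: float = 10.0,
                  coarse_drift: pd.DataFrame | None = None) -> pd.DataFrame:
    """Localization table for a frame stack.

    ``frames`` may be ADU (with ``camera``) or already in photons.
    ``coarse_drift`` is an externally produced per-frame (dx_nm, dy_nm)
    table (e.g. from redundant cross-correlation) subtracted from the
    reported positions.  Rejected fits are kept in the table with their
    rejection reason so that filter accounting is auditable.
    """
    cache: dict = {}
    rows = []
    for t, frame in enumerate(frames):
        img = (photon_convert(frame, camera.gain, camera.offset)
               if camera is not None else np.asarray(frame, dtype=float))
        rows.extend(process_frame(img, t, config, aberration_map,
                                  fit_options, threshold_offset,
                                  _pupil_cache=cache))
    table = pd.DataFrame(rows, columns=LOCALIZATION_COLUMNS)
    if coarse_drift is not None and len(table):
        d = coarse_drift.set_index("frame")
        table["x_nm"] -= d["dx_nm"].reindex(table["frame"]).fillna(0).values
        table["y_nm"] -= d["dy_nm"].reindex(table["frame"]).fillna(0).values
    return table


@dataclass
class Track:
    """Linked localizations of one emitter over consecutive frames."""

    indices: list[int]
    merged: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.indices)


def _angdiff(a, b):
    """Hemisphere-aware azimuth difference in degrees."""
    d = (a - b) % 180.0
    return min(d, 180.0 - d)


_LINK_PARAMS = [("x_nm", "crlb_x"), ("y_nm", "crlb_y"), ("z_nm", "crlb_z"),
                ("phi_deg", "crlb_phi"), ("theta_deg", "crlb_theta")]


def _linkable(a, b, factor=3.0):
    """Position and orientation all within ``factor`` x the larger CRLB."""
    for col, ccol in _LINK_PARAMS:
        tol = factor * max(a[ccol], b[ccol])
        if not np.isfinite(tol):
            continue
        diff = (_angdiff(a[col], b[col]) if col == "phi_deg"
                else abs(a[col] - b[col]))
        if diff >= tol:
            return False
    return True


def link_localizations(table: pd.DataFrame, factor: float = 3.0
                       ) -> list[Track]:
    """Greedy frame-to-frame linking of accepted localizations.

    Subsequent-frame localizations are linked when every position and
    orientation difference is below ``factor`` times the larger of the two
    uncertainties (azimuth differences wrap on the hemisphere).  Merged
    estimates are inverse-variance weighted means; merged photons are
    summed over the on-time.
    """
    acc = table[table["rejected_reason"] == "none"].sort_values("frame")
    open_tracks: list[list[int]] = []
    done: list[list[int]] = []
    for idx, row in acc.iterrows():
        t = int(row["frame"])
        attached = False
        for tr in open_tracks:
            prev = acc.loc[tr[-1]]
            if int(prev["frame"]) == t - 1 and _linkable(prev, row, factor):
                tr.append(idx)
                attached = True
                break
        if not attached:
            open_tracks.append([idx])
        # close stale tracks
        still = []
        for tr in open_tracks:
            if int(acc.loc[tr[-1]]["frame"]) >= t - 1:
                still.append(tr)
            else:
                done.append(tr)
        open_tracks = still
    done.extend(open_tracks)

    tracks = []
    for tr in done:
        sub = acc.loc[tr]
        merged = {"frames": sub["frame"].tolist(),
                  "n_photons": float(sub["photons"].sum())}
        for col, ccol in _LINK_PARAMS + [("g2", "crlb_g2")]:
            w = 1.0 / np.clip(sub[ccol].values, 1e-9, np.inf) ** 2
            w = np.where(np.isfinite(w), w, 0.0)
            if w.sum() == 0:
                w = np.ones(len(sub))
            merged[col] = float(np.average(sub[col].values, weights=w))
            merged[f"sigma_{col}"] = float(1.0 / np.sqrt(w.sum()))
        tracks.append(Track(indices=list(tr), merged=merged))
    return tracks


def fine_drift(residuals: list[pd.DataFrame],
               normals_deg: list[float],
               n_frames: int,
               frame_bin: int = 1) -> pd.DataFrame:
    """Fine drift trajectory from strand-fit residuals.

    ``residuals[i]`` holds columns ``frame``, ``dr_nm`` (signed
    perpendicular deviation from strand i's axis) and optionally
    ``weight``; ``normals_deg[i]`` is the direction of strand i's normal.
    Per frame bin, the perpendicular deviations of all strands are solved
    for a common (dx, dy) by weighted least squares:

        dr_i = dx * cos(n_i) + dy * sin(n_i)

    At least two distinct strand orientations are required to constrain
    both axes.
    """
    if len(residuals) < 2:
        raise ValueError("need >= 2 strands to constrain both drift axes")
    span = np.ptp([n % 180.0 for n in normals_deg])
    if span < 5.0:
        import warnings
        warnings.warn("strand normals nearly parallel; drift is poorly "
                      "constrained perpendicular to them")
    rows = []
    for start in range(0, n_frames, frame_bin):
        stop = start + frame_bin
        a, b, w = [], [], []
        for res, ndeg in zip(residuals, normals_deg):
            sel = res[(res["frame"] >= start) & (res["frame"] < stop)]
            if not len(sel):
                continue
            wt = sel["weight"].values if "weight" in sel else np.ones(len(sel))
            nr = np.radians(ndeg)
            for dr, wi in zip(sel["dr_nm"].values, wt):
                a.append([np.cos(nr), np.sin(nr)])
                b.append(dr)
                w.append(wi)
        if len(a) >= 2:
            a = np.asarray(a); b = np.asarray(b); w = np.asarray(w)
            sol, *_ = np.linalg.lstsq(a * w[:, None], b * w, rcond=None)
            dx, dy = sol
        else:
            dx = dy = np.nan
        for t in range(start, min(stop, n_frames)):
            rows.append({"frame": t, "dx_nm": dx, "dy_nm": dy})
    out = pd.DataFrame(rows)
    out[["dx_nm", "dy_nm"]] = out[["dx_nm", "dy_nm"]].ffill().bfill()
    return out
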