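"""Pipeline tests: photon conversion, candidate detection, stack
processing, linking and fine drift."""

import numpy as np
import pandas as pd
import pytest

from vortexfit.locpipeline import (
    CameraModel,
    detect_candidates,
    fine_drift,
    link_localizations,
    photon_convert,
    process_stack,
)
from vortexfit.optics_model import EmitterParams, OpticalConfig, image_model
from vortexfit.synthdata import make_movie


class TestPhotonConvert:
    def test_offset_only_gives_zero(self):
        adu = np.full((8, 8), 100.0)
        assert np.all(photon_convert(adu, 2.0, 100.0) == 0.0)

    def test_arithmetic(self):
        assert photon_convert(np.array([[120.0]]), 2.0, 100.0)[0, 0] == 10.0

    def test_clamps_below_offset(self):
        assert np.all(photon_convert(np.full((4, 4), 50.0), 2.0, 100.0)
                      == 0.0)

    def test_bad_gain(self):
        with pytest.raises(ValueError):
            photon_convert(np.zeros((2, 2)), 0.0, 0.0)
        with pytest.raises(ValueError):
            CameraModel(gain=-1.0)

    def test_digitize_roundtrip(self, rng):
        photons = rng.poisson(30.0, (16, 16)).astype(float)
        adu = np.round(photons * 2.3 + 100.0)
        back = photon_convert(adu, 2.3, 100.0)
        assert np.max(np.abs(back - photons)) < 0.5 / 2.3 + 1e-9


class TestDetectCandidates:
    def test_blank_frame(self, rng):
        frame = rng.poisson(10.0, (64, 64)).astype(float)
        assert detect_candidates(frame, 10.0, 10.0) == []

    def test_single_spot_found_near_truth(self, config, pupil, rng):
        mu = np.full((40, 40), 10.0)
        spot = image_model(EmitterParams(phi=40, theta=70, g2=0.75,
                                         background=0.0), config,
                           pupil=pupil).mu
        mu[12:27, 18:33] += spot
        hits = 0
        for _ in range(20):
            cands = detect_candidates(rng.poisson(mu).astype(float), 10.0)
            if len(cands) == 1 and abs(cands[0][0] - 25) <= 1 \
                    and abs(cands[0][1] - 19) <= 1:
                hits += 1
        assert hits >= 19

    def test_two_separated_spots(self, config, pupil, rng):
        mu = np.full((60, 60), 10.0)
        spot = image_model(EmitterParams(phi=40, theta=70, g2=0.75,
                                         background=0.0), config,
                           pupil=pupil).mu
        mu[5:20, 5:20] += spot
        mu[35:50, 35:50] += spot
        cands = detect_candidates(rng.poisson(mu).astype(float), 10.0)
        assert len(cands) == 2


class TestProcessStack:
    def test_empty_movie(self, config):
        table = process_stack(np.random.default_rng(0).poisson(
            10.0, (3, 40, 40)).astype(float), config)
        assert len(table) == 0

    def test_end_to_end_recall_and_accounting(self, config, rng):
        layout = [
            {"x_px": 12.0, "y_px": 14.0, "phi": 40.0, "theta": 75.0},
            {"x_px": 34.0, "y_px": 30.0, "phi": 120.0, "theta": 60.0},
        ]
        stack, truth = make_movie(layout, 5, config, seed=7,
                                  frame_shape=(48, 48))
        table = process_stack(stack, config)
        acc = table[table["rejected_reason"] == "none"]
        # recall: each emitter refound in (nearly) every frame
        assert len(acc) >= 0.9 * len(truth)
        # filter accounting: every fitted ROI lands in exactly one bucket
        reasons = table["rejected_reason"].value_counts()
        assert reasons.sum() == len(table)
        # positions match ground truth within a few CRLB
        for _, row in acc.iterrows():
            tr = truth[(truth.frame == row.frame)]
            d = np.hypot(tr.x_nm - row.x_nm, tr.y_nm - row.y_nm).min()
            assert d < 30.0

    def test_determinism(self, config):
        layout = [{"x_px": 10.0, "y_px": 10.0, "phi": 30.0, "theta": 80.0}]
        stack, _ = make_movie(layout, 2, config, seed=3,
                              frame_shape=(24, 24))
        t1 = process_stack(stack, config)
        t2 = process_stack(stack, config)
        pd.testing.assert_frame_equal(t1, t2)


def loc_row(frame, x=1000.0, y=2000.0, z=0.0, phi=90.0, theta=90.0,
            sx=5.0, sphi=5.0):
    return {
        "frame": frame, "x_nm": x, "y_nm": y, "z_nm": z,
        "photons": 4000.0, "background": 10.0,
        "phi_deg": phi, "theta_deg": theta, "g2": 0.75,
        "crlb_x": sx, "crlb_y": sx, "crlb_z": 25.0,
        "crlb_N": 200.0, "crlb_b": 0.4,
        "crlb_phi": sphi, "crlb_theta": 3.0, "crlb_g2": 0.07,
        "chi2": 1.0, "n_iterations": 8,
        "field_x_px": 10, "field_y_px": 10, "rejected_reason": "none",
    }


class TestLinking:
    def test_repeat_localization_links(self):
        table = pd.DataFrame([loc_row(0), loc_row(1)])
        tracks = link_localizations(table)
        assert len(tracks) == 1 and len(tracks[0]) == 2

    def test_violating_distance_not_linked(self):
        table = pd.DataFrame([loc_row(0), loc_row(1, x=1000.0 + 4 * 5.0)])
        tracks = link_localizations(table)
        assert len(tracks) == 2

    def test_angle_difference_wraps_on_hemisphere(self):
        # 178 vs 2 deg is a 4-deg azimuth difference, linkable at 3*5 deg
        table = pd.DataFrame([loc_row(0, phi=178.0), loc_row(1, phi=2.0)])
        assert len(link_localizations(table)) == 1

    def test_chain_merges_with_sqrt_n_precision(self, rng):
        rows = [loc_row(t, x=1000.0 + rng.normal(0, 2.0)) for t in range(5)]
        tracks = link_localizations(pd.DataFrame(rows))
        assert len(tracks) == 1 and len(tracks[0]) == 5
        merged = tracks[0].merged
        # inverse-variance weighted mean of 5 equal-precision points
        assert merged["sigma_x_nm"] == pytest.approx(5.0 / np.sqrt(5))
        assert merged["n_photons"] == pytest.approx(5 * 4000.0)

    def test_three_sigma_rule_never_violated_on_output(self, rng):
        rows = []
        for t in range(20):
            rows.append(loc_row(t, x=1000 + rng.normal(0, 6.0),
                                phi=90 + rng.normal(0, 6.0)))
        tracks = link_localizations(pd.DataFrame(rows))
        table = pd.DataFrame(rows)
        for tr in tracks:
            sub = table.loc[tr.indices]
            for a, b in zip(tr.indices[:-1], tr.indices[1:]):
                assert abs(table.loc[a, "x_nm"] - table.loc[b, "x_nm"]) \
                    < 3 * max(table.loc[a, "crlb_x"], table.loc[b, "crlb_x"])


class TestFineDrift:
    @staticmethod
    def _residuals(drift_xy, normals, n_frames, noise, rng):
        out = []
        for ndeg in normals:
            nr = np.radians(ndeg)
            rows = []
            for t in range(n_frames):
                dr = (drift_xy[t, 0] * np.cos(nr)
                      + drift_xy[t, 1] * np.sin(nr))
                for _ in range(6):
                    rows.append({"frame": t,
                                 "dr_nm": dr + rng.normal(0, noise)})
            out.append(pd.DataFrame(rows))
        return out

    def test_zero_residuals_zero_trajectory(self, rng):
        n = 20
        res = self._residuals(np.zeros((n, 2)), [0.0, 90.0], n, 0.0, rng)
        traj = fine_drift(res, [0.0, 90.0], n)
        assert np.allclose(traj[["dx_nm", "dy_nm"]].values, 0.0, atol=1e-9)

    def test_sinusoidal_drift_recovered(self, rng):
        n = 60
        t = np.arange(n)
        drift = np.column_stack([10.0 * np.sin(2 * np.pi * t / 30),
                                 10.0 * np.cos(2 * np.pi * t / 45)])
        res = self._residuals(drift, [0.0, 90.0, 45.0], n, 3.0, rng)
        traj = fine_drift(res, [0.0, 90.0, 45.0], n)
        err = traj[["dx_nm", "dy_nm"]].values - drift
        assert np.sqrt(np.mean(err ** 2)) < 1.5

    def test_correction_reduces_spread(self, rng):
        n = 40
        t = np.arange(n)
        drift = np.column_stack([8.0 * np.sin(2 * np.pi * t / 20),
                                 np.zeros(n)])
        res = self._residuals(drift, [0.0, 90.0], n, 3.0, rng)
        traj = fine_drift(res, [0.0, 90.0], n)
        raw = res[0]["dr_nm"].values
        corr = raw - traj.set_index("frame").loc[
            res[0]["frame"].values, "dx_nm"].values
        assert corr.std() < 0.7 * raw.std()

    def test_parallel_strands_unconstrained(self, rng):
        n = 10
        res = self._residuals(np.zeros((n, 2)), [0.0, 1.0], n, 1.0, rng)
        with pytest.warns(UserWarning):
            fine_drift(res, [0.0, 1.0], n)

    def test_single_strand_rejected(self, rng):
        n = 5
        res = self._residuals(np.zeros((n, 2)), [0.0], n, 1.0, rng)
        with pytest.raises(ValueError):
            fine_drift(res, [0.0], n)
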