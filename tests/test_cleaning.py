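"""Temporal preprocessing and QC: volume discard, FD, scrubbing, nuisance
regression, band-pass, and cohort inclusion rules."""

import numpy as np
import pandas as pd
import pytest

from connmed import (
    SubjectTimeSeries,
    bandpass,
    build_scrub_regressors,
    clean_subject,
    discard_initial,
    expand_friston24,
    framewise_displacement,
    generate_motion,
    qc_filter,
    regress_confounds,
)
from oracles import pinv_residuals


def _ts(data, tr=2.0, sid="s1"):
    data = np.asarray(data, dtype=float)
    names = tuple(f"R{i}" for i in range(data.shape[1]))
    return SubjectTimeSeries(sid, data, tr, names)


class TestDiscardInitial:
    def test_default_drops_five(self, rng):
        ts = _ts(rng.standard_normal((240, 9)))
        assert discard_initial(ts).data.shape == (235, 9)

    def test_zero_discard_is_identity(self, rng):
        ts = _ts(rng.standard_normal((20, 3)))
        assert np.array_equal(discard_initial(ts, 0).data, ts.data)

    def test_rows_retained_verbatim(self, rng):
        data = rng.standard_normal((10, 3))
        out = discard_initial(_ts(data), 5)
        assert np.array_equal(out.data, data[5:])

    def test_cannot_discard_everything(self, rng):
        with pytest.raises(ValueError):
            discard_initial(_ts(rng.standard_normal((5, 2))), 5)


class TestFramewiseDisplacement:
    def test_constant_motion_is_zero(self):
        fd = framewise_displacement(np.ones((30, 6)))
        assert np.allclose(fd, 0.0)

    def test_single_translation_step(self):
        m = np.zeros((20, 6))
        m[10:, 0] = 1.0  # +1 mm step at volume 10
        fd = framewise_displacement(m)
        assert fd[10] == pytest.approx(1.0)
        assert fd[0] == 0.0
        assert np.count_nonzero(fd) == 1

    def test_rotation_arc_length_on_50mm_sphere(self):
        m = np.zeros((10, 6))
        m[5:, 3] = 0.01  # 0.01 rad step
        fd = framewise_displacement(m, rotation_radius_mm=50)
        assert fd[5] == pytest.approx(0.5)

    def test_non_finite_motion_names_volume(self):
        m = np.zeros((10, 6))
        m[4, 2] = np.nan
        with pytest.raises(ValueError, match="volume 4"):
            framewise_displacement(m)


class TestScrubRegressors:
    def test_quiet_run_gives_empty_matrix(self):
        spikes = build_scrub_regressors(np.full(20, 0.1))
        assert spikes.shape == (20, 0)

    def test_single_exceedance_flags_window(self):
        fd = np.zeros(20)
        fd[10] = 0.6
        spikes = build_scrub_regressors(fd)
        assert spikes.shape == (20, 4)
        flagged = sorted(np.flatnonzero(spikes.sum(axis=1)))
        assert flagged == [9, 10, 11, 12]
        assert np.all(spikes.sum(axis=0) == 1.0)  # unit impulses

    def test_overlapping_windows_deduplicated(self):
        fd = np.zeros(20)
        fd[[3, 5]] = 0.7
        spikes = build_scrub_regressors(fd)
        flagged = set(np.flatnonzero(spikes.sum(axis=1)))
        # union oracle: {2,3,4,5} from t=3 and {4,5,6,7} from t=5
        assert flagged == {2, 3, 4, 5, 6, 7}
        assert spikes.shape[1] == 6

    def test_window_clipped_at_run_edges(self):
        fd = np.zeros(5)
        fd[0] = 0.9
        fd[4] = 0.9
        spikes = build_scrub_regressors(fd)
        assert set(np.flatnonzero(spikes.sum(axis=1))) == {0, 1, 2, 3, 4}


class TestFriston24:
    def test_zero_motion_all_zero(self):
        assert np.allclose(expand_friston24(np.zeros((10, 6))), 0.0)

    def test_constant_motion_blocks(self):
        out = expand_friston24(np.full((10, 6), 3.0))
        assert np.allclose(out[:, :6], 3.0)     # raw
        assert np.allclose(out[:, 6:12], 0.0)   # derivative
        assert np.allclose(out[:, 12:18], 9.0)  # square
        assert np.allclose(out[:, 18:], 0.0)    # derivative square

    def test_ramp_derivative(self):
        m = np.zeros((10, 6))
        m[:, 1] = np.arange(10)
        out = expand_friston24(m)
        assert np.allclose(out[1:, 7], 1.0)
        assert out[0, 7] == 0.0


class TestRegressConfounds:
    def test_no_confounders_demeans(self, rng):
        ts = _ts(rng.standard_normal((50, 4)) + 10.0)
        out = regress_confounds(ts, None)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10

    def test_exact_confound_removed(self, rng):
        conf = rng.standard_normal((60, 1))
        data = np.hstack([conf, rng.standard_normal((60, 2))])
        out = regress_confounds(_ts(data), conf)
        assert np.abs(out.data[:, 0]).max() < 1e-10

    def test_matches_pseudoinverse_oracle(self, rng):
        data = rng.standard_normal((100, 5))
        conf = rng.standard_normal((100, 3))
        out = regress_confounds(_ts(data), conf)
        expected = pinv_residuals(data, conf)
        assert np.abs(out.data - expected).max() < 1e-10

    def test_residuals_orthogonal_to_confounders(self, rng):
        data = rng.standard_normal((80, 4))
        conf = rng.standard_normal((80, 6))
        out = regress_confounds(_ts(data), conf)
        inner = conf.T @ out.data
        scale = np.linalg.norm(conf) * np.linalg.norm(out.data)
        assert np.abs(inner).max() < 1e-8 * scale

    def test_too_many_confounders_rejected(self, rng):
        data = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="nuisance"):
            regress_confounds(_ts(data), rng.standard_normal((10, 12)))


class TestBandpass:
    def _sine(self, freq_hz, n=235, tr=2.0):
        t = np.arange(n) * tr
        return np.sin(2 * np.pi * freq_hz * t)

    def _amplitude(self, x):
        return np.sqrt(2.0 * np.mean(np.square(x[40:-40])))

    def test_passband_sinusoid_preserved(self):
        x = self._sine(0.05)
        out = bandpass(_ts(x[:, None]))
        assert self._amplitude(out.data[:, 0]) == pytest.approx(
            self._amplitude(x), rel=0.10
        )

    def test_stopband_sinusoid_attenuated(self):
        x = self._sine(0.2)
        out = bandpass(_ts(x[:, None]))
        assert self._amplitude(out.data[:, 0]) <= 0.10 * self._amplitude(x)

    def test_dc_removed(self):
        out = bandpass(_ts(np.full((235, 2), 7.0)))
        assert np.abs(out.data).max() < 1e-6

    def test_band_above_nyquist_rejected(self):
        ts = _ts(np.random.default_rng(0).standard_normal((100, 1)), tr=2.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(ts, 0.01, 0.3)


class TestQCFilter:
    def _frame(self, **overrides):
        row = {
            "subject_id": "s1",
            "max_abs_translation_mm": 0.5,
            "max_abs_rotation_deg": 0.5,
            "mean_fd_mm": 0.1,
            "moca": 26,
            "gds": 2,
        }
        row.update(overrides)
        return pd.DataFrame([row])

    def test_low_moca_excluded(self):
        included, reports = qc_filter(self._frame(moca=21))
        assert included == []
        assert reports[0].reasons == ("cognitive-screen",)

    def test_high_mean_fd_excluded_under_conjunction(self):
        included, reports = qc_filter(self._frame(mean_fd_mm=0.25))
        assert included == []
        assert "head-motion" in reports[0].reasons

    def test_high_mean_fd_passes_under_disjunction(self):
        included, _ = qc_filter(
            self._frame(mean_fd_mm=0.25), motion_rule="disjunction"
        )
        assert included == ["s1"]

    def test_boundary_values_included(self):
        frame = self._frame(
            moca=22, gds=7, max_abs_translation_mm=2.0,
            max_abs_rotation_deg=2.0, mean_fd_mm=0.2,
        )
        included, reports = qc_filter(frame)
        assert included == ["s1"]
        assert reports[0].included and reports[0].reasons == ()

    def test_missing_fields_excluded_with_reason(self):
        included, reports = qc_filter(self._frame(moca=np.nan))
        assert included == []
        assert reports[0].reasons == ("missing-data",)


class TestCleanSubject:
    def test_full_chain_shapes_and_order(self, rng):
        data = rng.standard_normal((240, 6))
        ts = _ts(data)
        conf = generate_motion(240, 0.05, seed=4)
        cleaned, info = clean_subject(ts, conf)
        assert cleaned.data.shape == (235, 6)
        assert info["fd"].shape == (235,)
        assert info["n_regressors"] >= 27  # tissue(3) + friston24

    def test_correlation_estimates_unbiased_after_cleaning(self):
        # residualisation + band-pass on independent white noise must not
        # bias the correlation matrix: mean off-diagonal r near 0
        means = []
        for seed in range(100):
            gen = np.random.default_rng(seed)
            ts = _ts(gen.standard_normal((240, 5)))
            conf = generate_motion(240, 0.02, seed=seed + 1000)
            cleaned, _ = clean_subject(ts, conf)
            r = np.corrcoef(cleaned.data, rowvar=False)
            means.append(r[~np.eye(5, dtype=bool)].mean())
        assert abs(np.mean(means)) < 0.02
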