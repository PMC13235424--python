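"""Color traces, end-point detection, rate fitting, and offline correlation."""

import numpy as np
import pytest
from sklearn.metrics import mutual_info_score

from chromatrace import colorspace as cs
from chromatrace.kinetics import (
    ColorTrace,
    OfflineSeries,
    align_offline,
    build_trace,
    detect_onset,
    detect_plateau,
    fit_rate,
    mutual_information,
    resample_trace,
    trace_to_frame,
)

from conftest import make_frames


def synthetic_trace(t, delta_e, roi_name="synthetic"):
    """ColorTrace with a prescribed dE series (color coordinates unused by the
    detectors and fitters under test)."""
    n = len(t)
    zeros3 = np.zeros((n, 3))
    return ColorTrace(
        roi_name=roi_name,
        t=np.asarray(t, dtype=float),
        rgb=zeros3,
        hsv=zeros3,
        lab=zeros3,
        delta_e=np.asarray(delta_e, dtype=float),
        rgb_sum=np.zeros(n),
    )


class TestBuildTrace:
    def test_constant_video_gives_zero_delta_e(self, full_roi):
        frames = make_frames([(120, 80, 40)] * 5)
        trace = build_trace(frames, full_roi)
        assert np.allclose(trace.delta_e, 0.0)
        assert np.allclose(trace.rgb, (120, 80, 40))

    def test_two_frame_video_gives_lab_distance(self, full_roi):
        c0, c1 = (200, 50, 50), (50, 50, 200)
        frames = make_frames([c0, c1])
        trace = build_trace(frames, full_roi)
        expected = cs.delta_e_1976(cs.rgb_to_lab(c0), cs.rgb_to_lab(c1))
        assert trace.delta_e[0] == 0.0
        assert trace.delta_e[1] == pytest.approx(expected, rel=1e-12)

    def test_exponential_transition_matches_brute_force(self, full_roi):
        t = np.arange(40) / 2.0
        f = 1.0 - np.exp(-0.1 * t)
        start, end = np.array([240.0, 220, 60]), np.array([40.0, 30, 120])
        colors = start + f[:, None] * (end - start)
        trace = build_trace(make_frames(colors, fps=2.0), full_roi)
        brute = [
            cs.delta_e_1976(cs.rgb_to_lab(c), cs.rgb_to_lab(colors[0])) for c in colors
        ]
        assert np.allclose(trace.delta_e, brute, atol=1e-9)

    def test_reference_index_parameter(self, full_roi):
        frames = make_frames([(10, 10, 10), (100, 100, 100), (200, 200, 200)])
        trace = build_trace(frames, full_roi, reference_index=1)
        assert trace.delta_e[1] == 0.0
        assert trace.delta_e[0] > 0 and trace.delta_e[2] > 0

    def test_time_offset_invariance(self, full_roi):
        colors = [(10, 10, 10), (60, 60, 60), (110, 110, 110)]
        base = build_trace(make_frames(colors), full_roi)
        shifted_frames = make_frames(colors)
        for f in shifted_frames:
            f.t += 1000.0
        shifted = build_trace(shifted_frames, full_roi)
        assert np.allclose(base.delta_e, shifted.delta_e)

    def test_requires_two_frames(self, full_roi):
        with pytest.raises(ValueError):
            build_trace(make_frames([(0, 0, 0)]), full_roi)


class TestResampleTrace:
    def test_identity_and_length(self, full_roi):
        colors = np.linspace((0, 0, 0), (250, 250, 250), 100)
        trace = build_trace(make_frames(colors), full_roi)
        assert resample_trace(trace, 1) is trace
        thinned = resample_trace(trace, 10)
        assert len(thinned) == 10
        assert thinned.delta_e[thinned.reference_index] == 0.0

    def test_transient_spike_vanishes_at_low_rate(self, full_roi):
        """A 2-sample transient between retained indices is invisible after
        10-fold thinning — the frame-rate adequacy demonstration."""
        colors = np.full((100, 3), 100.0)
        colors[41:43] = (250.0, 20.0, 20.0)
        trace = build_trace(make_frames(colors), full_roi)
        assert trace.delta_e.max() > 50
        thinned = resample_trace(trace, 10)
        assert np.allclose(thinned.delta_e, 0.0)

    def test_rejects_bad_factor(self, full_roi):
        trace = build_trace(make_frames([(0, 0, 0), (9, 9, 9)]), full_roi)
        with pytest.raises(ValueError):
            resample_trace(trace, 0)


class TestDetectPlateau:
    def test_first_order_trace_matches_closed_form(self):
        """dE = A(1-exp(-kt)) has rate A*k*exp(-kt); the eps-crossing is
        t = ln(A k / eps)/k = 78.24 s for A=50, k=0.05, eps=0.05."""
        t = np.arange(0, 300, 1.0)
        trace = synthetic_trace(t, 50.0 * (1 - np.exp(-0.05 * t)))
        window = 5
        t_star = detect_plateau(trace, window=window, eps=0.05, min_excursion=5)
        analytic = np.log(50.0 * 0.05 / 0.05) / 0.05
        assert t_star == pytest.approx(analytic, abs=2 * window)

    def test_linear_ramp_never_plateaus(self):
        t = np.arange(0, 100, 1.0)
        trace = synthetic_trace(t, 1.0 * t)
        assert detect_plateau(trace, window=5, eps=0.05) is None

    def test_constant_trace_guarded_by_min_excursion(self):
        t = np.arange(0, 100, 1.0)
        trace = synthetic_trace(t, np.zeros_like(t))
        assert detect_plateau(trace, window=5, eps=0.05) is None

    def test_survives_resampling(self):
        """10-fold thinning moves the plateau estimate by at most one retained
        sample spacing on a smooth trace."""
        t = np.arange(0, 300, 0.5)
        full = synthetic_trace(t, 50.0 * (1 - np.exp(-0.05 * t)))
        thinned = resample_trace(full, 10)
        t_full = detect_plateau(full, window=10, eps=0.05, min_excursion=5)
        t_thin = detect_plateau(thinned, window=2, eps=0.05, min_excursion=5)
        spacing = thinned.t[1] - thinned.t[0]
        assert abs(t_full - t_thin) <= spacing + 1e-9

    def test_window_longer_than_trace_rejected(self):
        trace = synthetic_trace(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError):
            detect_plateau(trace, window=10, eps=0.05)


class TestDetectOnset:
    def test_delayed_rise(self):
        t = np.arange(0, 100, 1.0)
        de = np.where(t < 30, 0.0, (t - 30) * 1.0)
        trace = synthetic_trace(t, de)
        onset = detect_onset(trace, window=5, eps=0.1)
        assert onset == pytest.approx(30.0, abs=5.0)

    def test_constant_trace_has_no_onset(self):
        trace = synthetic_trace(np.arange(50.0), np.zeros(50))
        assert detect_onset(trace, window=5, eps=0.1) is None

    def test_rising_from_start(self):
        t = np.arange(0, 50, 1.0)
        trace = synthetic_trace(t, 2.0 * t)
        assert detect_onset(trace, window=5, eps=0.1) == pytest.approx(0.0, abs=3.0)


class TestFitRate:
    def test_noiseless_first_order_recovery(self):
        t = np.linspace(0, 300, 600)
        trace = synthetic_trace(t, 42.0 * (1 - np.exp(-0.05 * t)))
        s = fit_rate(trace, "first_order")
        assert s.converged
        assert s.k == pytest.approx(0.05, rel=1e-6)
        assert s.amplitude == pytest.approx(42.0, rel=1e-6)

    def test_noiseless_second_order_recovery(self):
        t = np.linspace(0, 300, 600)
        trace = synthetic_trace(t, 42.0 * (0.05 * t) / (1 + 0.05 * t))
        s = fit_rate(trace, "second_order")
        assert s.converged
        assert s.k == pytest.approx(0.05, rel=1e-6)

    def test_noisy_recovery_within_10pct(self, rng):
        t = np.linspace(0, 300, 600)
        de = 50.0 * (1 - np.exp(-0.05 * t)) + rng.normal(0, 1.0, t.shape)
        s = fit_rate(synthetic_trace(t, de), "first_order")
        assert s.k == pytest.approx(0.05, rel=0.10)

    def test_model_mismatch_has_larger_rss(self):
        t = np.linspace(0, 300, 600)
        trace = synthetic_trace(t, 42.0 * (0.05 * t) / (1 + 0.05 * t))
        good = fit_rate(trace, "second_order")
        bad = fit_rate(trace, "first_order")
        assert bad.rss > good.rss

    def test_parameter_recovery_distribution(self, rng):
        """Over 50 noisy replicates, median |k_hat/k - 1| < 5% and the 90th
        percentile < 15%."""
        t = np.linspace(0, 300, 600)
        errs = []
        for _ in range(50):
            de = 50.0 * (1 - np.exp(-0.05 * t)) + rng.normal(0, 1.0, t.shape)
            s = fit_rate(synthetic_trace(t, de), "first_order")
            errs.append(abs(s.k / 0.05 - 1.0))
        assert np.median(errs) < 0.05
        assert np.quantile(errs, 0.9) < 0.15

    def test_degenerate_trace_rejected(self):
        trace = synthetic_trace(np.arange(20.0), np.zeros(20))
        with pytest.raises(ValueError):
            fit_rate(trace)


class TestMutualInformation:
    def test_independent_samples_near_zero(self, rng):
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        assert mutual_information(x, y, bins=8) < 0.05

    def test_correlated_gaussian_matches_closed_form(self, rng):
        rho = 0.9
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=10_000)
        mi = mutual_information(xy[:, 0], xy[:, 1], bins=16)
        closed = -0.5 * np.log(1 - rho**2)
        assert mi == pytest.approx(closed, rel=0.15)

    def test_identity_gives_binned_entropy(self, rng):
        x = rng.normal(size=1000)
        counts, _ = np.histogram(x, bins=16)
        p = counts / counts.sum()
        entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert mutual_information(x, x, bins=16) == pytest.approx(entropy, rel=1e-9)

    def test_matches_sklearn_contingency_estimator(self, rng):
        """Same plug-in estimate as sklearn's mutual_info_score on the binned data."""
        x, y = rng.normal(size=500), rng.normal(size=500)
        bins = 8
        # clip merges the closed top edge into the last bin, matching histogram2d
        xb = np.minimum(np.digitize(x, np.histogram_bin_edges(x, bins)), bins)
        yb = np.minimum(np.digitize(y, np.histogram_bin_edges(y, bins)), bins)
        assert mutual_information(x, y, bins=bins) == pytest.approx(
            mutual_info_score(xb, yb), abs=1e-9
        )

    def test_invariant_under_affine_rescaling(self, rng):
        x, y = rng.normal(size=2000), rng.normal(size=2000)
        assert mutual_information(x, y, bins=12) == pytest.approx(
            mutual_information(2 * x + 1, y, bins=12), abs=1e-12
        )

    def test_nonnegative_and_input_checks(self, rng):
        x = rng.normal(size=100)
        assert mutual_information(x, rng.normal(size=100), bins=4) >= 0
        with pytest.raises(ValueError):
            mutual_information(x, x[:50])
        with pytest.raises(ValueError):
            mutual_information(x[:10], x[:10])


class TestAlignOffline:
    def test_exact_time_match(self):
        t = np.arange(0, 10, 1.0)
        trace = synthetic_trace(t, t * 2.0)
        offline = OfflineSeries(t=[2.0, 5.0, 7.0], value=[0.2, 0.5, 0.7])
        de, vals = align_offline(trace, offline)
        assert np.allclose(de, [4.0, 10.0, 14.0])
        assert np.allclose(vals, [0.2, 0.5, 0.7])

    def test_tie_breaks_to_earlier_sample(self):
        trace = synthetic_trace([0.0, 2.0], [0.0, 8.0])
        de, _ = align_offline(trace, OfflineSeries(t=[1.0], value=[0.5]))
        assert de[0] == 0.0

    def test_out_of_span_dropped_with_warning(self):
        trace = synthetic_trace(np.arange(5.0), np.arange(5.0))
        with pytest.warns(UserWarning, match="dropped"):
            de, vals = align_offline(
                trace, OfflineSeries(t=[1.0, 99.0], value=[1.0, 2.0])
            )
        assert len(de) == 1

    def test_monotone_conversion_strongly_linear(self, full_roi):
        """A conversion curve sampled sparsely against its own dE trace
        correlates almost perfectly."""
        t = np.arange(0, 120, 0.5)
        f = 1.0 - np.exp(-0.05 * t)
        start, end = np.array([250.0, 240, 60]), np.array([60.0, 40, 40])
        colors = start + f[:, None] * (end - start)
        trace = build_trace(make_frames(colors, fps=2.0), full_roi)
        offline_t = np.arange(5.0, 115.0, 10.0)
        offline = OfflineSeries(t=offline_t, value=1.0 - np.exp(-0.05 * offline_t))
        de, conv = align_offline(trace, offline)
        r = np.corrcoef(de, conv)[0, 1]
        assert r**2 > 0.95

    def test_offline_series_validation(self):
        with pytest.raises(ValueError):
            OfflineSeries(t=[1.0, 1.0], value=[0.0, 0.0])
        with pytest.raises(ValueError):
            OfflineSeries(t=[0.0, 1.0], value=[0.0, np.inf])


def test_trace_export_schema(full_roi):
    frames = make_frames([(0, 0, 0), (100, 100, 100), (200, 200, 200)])
    df = trace_to_frame(build_trace(frames, full_roi))
    assert list(df.columns) == [
        "frame_index", "t_seconds", "roi", "R", "G", "B",
        "H", "S", "V", "L", "a", "b", "delta_e", "rgb_sum",
    ]
    assert len(df) == 3
    assert (df["roi"] == "full").all()
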