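import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import cumulative_trapezoid

from adtnorm import ValidationError, arcsinh_transform
from adtnorm.landmark_detection import (
    DensityCurve,
    Landmark,
    LandmarkSet,
    apply_positive_peak_prior,
    compute_emd_matrix,
    detect_peaks,
    detect_valleys,
    drop_spurious_zero_peak,
    estimate_density,
    flag_outlier_positive_peaks,
    impute_outlier_valleys,
    make_grid,
    merge_low_peaks,
    scaled_mad_flags,
    select_bandwidth,
)


def analytic_curve(grid, modes, sds, weights, bandwidth=0.0):
    """Mixture-of-normals density, optionally convolved with a Gaussian
    kernel of the given bandwidth (closed form)."""
    d = np.zeros_like(grid)
    for m, s, w in zip(modes, sds, weights):
        se = np.sqrt(s ** 2 + bandwidth ** 2)
        d += w * np.exp(-0.5 * ((grid - m) / se) ** 2) / (se * np.sqrt(2 * np.pi))
    return DensityCurve(grid, d / np.trapezoid(d, grid), max(bandwidth, 1e-6),
                        1000)


class TestArcsinh:
    def test_zero_maps_to_zero(self):
        assert arcsinh_transform(np.array([0.0]))[0] == 0.0

    def test_closed_form(self):
        out = arcsinh_transform(np.array([5.0]), cofactor=5.0)[0]
        assert out == pytest.approx(np.log(1 + np.sqrt(2)), abs=1e-12)
        assert out == pytest.approx(0.881374, abs=1e-6)

    def test_strictly_increasing(self, rng):
        x = np.sort(rng.integers(0, 1000, 100)).astype(float)
        y = arcsinh_transform(np.unique(x))
        assert (np.diff(y) > 0).all()

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            arcsinh_transform(np.array([np.nan]))


class TestEstimateDensity:
    def test_matches_analytic_convolution(self, rng):
        vals = rng.normal(2.0, 0.2, 5000)
        grid = make_grid(0.0, 4.0, 512)
        curve = estimate_density(vals, 0.1, grid)
        truth = analytic_curve(grid, [2.0], [0.2], [1.0], bandwidth=0.1)
        mode = grid[np.argmax(curve.density)]
        assert abs(mode - 2.0) < 0.1
        assert np.abs(curve.density - truth.density).max() < 0.12

    def test_integrates_to_one(self, rng):
        vals = rng.normal(3.0, 0.5, 500)
        curve = estimate_density(vals, 0.2, make_grid(0.0, 6.0, 512))
        assert 0.99 <= curve.integral() <= 1.01

    def test_degenerate_cluster(self):
        curve = estimate_density(np.full(50, 2.5), 0.3, make_grid(0, 5, 512))
        peaks = detect_peaks(curve)
        assert len(peaks) == 1
        assert peaks[0].location == pytest.approx(2.5, abs=0.01)

    def test_multiplicity_invariance(self, rng):
        vals = rng.normal(2.0, 0.4, 200)
        grid = make_grid(0, 4, 256)
        a = estimate_density(vals, 0.2, grid)
        b = estimate_density(np.repeat(vals, 2), 0.2, grid)
        np.testing.assert_allclose(a.density, b.density, atol=1e-12)

    def test_bad_bandwidth(self):
        with pytest.raises(ValidationError):
            estimate_density(np.array([1.0, 2.0]), 0.0, make_grid(0, 3, 64))


class TestDetectPeaks:
    def test_bimodal_analytic(self):
        grid = make_grid(0.0, 6.0, 512)
        curve = analytic_curve(grid, [1.0, 4.0], [0.2, 0.3], [0.5, 0.5])
        peaks = detect_peaks(curve)
        step = grid[1] - grid[0]
        assert len(peaks) == 2
        assert abs(peaks[0].location - 1.0) <= step
        assert abs(peaks[1].location - 4.0) <= step

    def test_monotone_decreasing_boundary_mode(self):
        grid = make_grid(0.0, 5.0, 128)
        curve = DensityCurve(grid, np.exp(-grid), 0.1, 100)
        peaks = detect_peaks(curve)
        assert len(peaks) == 1
        assert peaks[0].location == grid[0]

    def test_plateau_leftmost(self):
        grid = make_grid(0.0, 1.0, 11)
        d = np.array([0.1, 0.2, 0.5, 0.5, 0.5, 0.2, 0.1, 0.1, 0.1, 0.1, 0.05])
        curve = DensityCurve(grid, d, 0.1, 100)
        peaks = detect_peaks(curve)
        assert len(peaks) == 1
        assert peaks[0].location == pytest.approx(grid[2])

    def test_min_height_filters(self):
        grid = make_grid(0.0, 6.0, 512)
        curve = analytic_curve(grid, [1.0, 4.0], [0.2, 0.3], [0.999, 0.001])
        assert len(detect_peaks(curve, min_height_frac=0.05)) == 1


class TestDetectValleys:
    def test_bimodal_valley_is_minimum(self):
        grid = make_grid(0.0, 6.0, 512)
        curve = analytic_curve(grid, [1.0, 4.0], [0.2, 0.3], [0.5, 0.5])
        peaks = detect_peaks(curve)
        valleys = detect_valleys(curve, peaks)
        assert len(valleys) == 1
        # brute-force oracle: argmin between the modes
        sel = (grid > 1.0) & (grid < 4.0)
        assert valleys[0].location == pytest.approx(
            grid[sel][np.argmin(curve.density[sel])], abs=1e-12)

    def test_single_peak_slope_valley_right_of_peak(self, rng):
        vals = np.abs(rng.normal(0, 0.8, 3000))
        curve = estimate_density(vals, 0.2, make_grid(0, 4, 512))
        peaks = detect_peaks(curve)
        valleys = detect_valleys(curve, peaks)
        assert len(valleys) == 1
        assert valleys[0].location > peaks[0].location
        assert valleys[0].provenance == "slope-derived"

    def test_three_peaks_two_valleys_interleaved(self):
        grid = make_grid(0.0, 8.0, 512)
        curve = analytic_curve(grid, [1, 4, 7], [0.3, 0.3, 0.3],
                               [1 / 3, 1 / 3, 1 / 3])
        peaks = detect_peaks(curve)
        valleys = detect_valleys(curve, peaks)
        assert len(peaks) == 3 and len(valleys) == 2
        LandmarkSet(peaks, valleys).validate()


class TestSelectBandwidth:
    def test_wide_rung_wins_when_resolving(self, rng):
        vals = np.concatenate([rng.normal(1, 0.2, 800), rng.normal(5, 0.3, 800)])
        grid = make_grid(0, 7, 512)
        bw, curve, n = select_bandwidth(vals, (0.5, 0.25, 0.1), grid)
        assert bw == 0.5
        assert n >= 2

    def test_unimodal_falls_to_narrowest(self, rng):
        vals = rng.normal(2.0, 0.25, 1500)
        bw, curve, n = select_bandwidth(vals, (0.5, 0.25, 0.1),
                                        make_grid(0, 4, 512))
        assert bw == 0.1

    def test_trimodal_with_prior(self, rng):
        vals = np.concatenate([rng.normal(1, 0.2, 600), rng.normal(2.6, 0.2, 600),
                               rng.normal(4.2, 0.2, 600)])
        grid = make_grid(0, 6, 512)
        bw, curve, n = select_bandwidth(vals, (0.5, 0.25, 0.1), grid,
                                        peak_count_prior=3)
        assert n >= 3
        # oracle: brute-force peak count at the chosen rung
        assert len(detect_peaks(estimate_density(vals, bw, grid))) == n


class TestCleanupRules:
    def test_merge_low_peaks_keeps_tallest(self):
        lm = LandmarkSet(
            peaks=[Landmark(0.1, 0.8), Landmark(0.4, 1.2), Landmark(3.0, 1.0)],
            valleys=[Landmark(0.25, 0.5), Landmark(1.5, 0.1)])
        out = merge_low_peaks(lm, 0.5)
        assert [p.location for p in out.peaks] == [0.4, 3.0]
        assert [v.location for v in out.valleys] == [1.5]
        assert out.peaks[0].provenance == "merged"

    def test_merge_identity_when_nothing_below(self):
        lm = LandmarkSet(peaks=[Landmark(1.0, 1.0), Landmark(3.0, 1.0)],
                         valleys=[Landmark(2.0, 0.1)])
        assert merge_low_peaks(lm, 0.5) is lm

    def test_merge_all_below(self):
        lm = LandmarkSet(peaks=[Landmark(0.1, 0.3), Landmark(0.3, 0.9)],
                         valleys=[Landmark(0.2, 0.1)])
        out = merge_low_peaks(lm, 0.5)
        assert len(out.peaks) == 1 and not out.valleys
        assert out.peaks[0].location == 0.3

    def test_drop_spurious_minor_zero_peak(self):
        grid = make_grid(0, 2, 128)
        curve = DensityCurve(grid, np.ones_like(grid), 0.1, 100)
        lm = LandmarkSet(peaks=[Landmark(0.05, 0.1), Landmark(0.9, 1.0)],
                         valleys=[Landmark(0.5, 0.05)])
        out = drop_spurious_zero_peak(lm, curve, 0.5)
        assert [p.location for p in out.peaks] == [0.9]

    def test_tallest_leftmost_kept(self):
        grid = make_grid(0, 2, 128)
        curve = DensityCurve(grid, np.ones_like(grid), 0.1, 100)
        lm = LandmarkSet(peaks=[Landmark(0.05, 1.0), Landmark(0.9, 0.5)],
                         valleys=[Landmark(0.5, 0.05)])
        out = drop_spurious_zero_peak(lm, curve, 0.5)
        assert len(out.peaks) == 2

    def test_sole_peak_never_deleted(self):
        grid = make_grid(0, 2, 128)
        curve = DensityCurve(grid, np.ones_like(grid), 0.1, 100)
        lm = LandmarkSet(peaks=[Landmark(0.05, 0.01)], valleys=[])
        assert len(drop_spurious_zero_peak(lm, curve, 0.5).peaks) == 1

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.05, 5.0), min_size=1, max_size=6, unique=True),
           st.floats(0.1, 2.0))
    def test_interleaving_after_cleanup(self, locs, thres):
        locs = sorted(locs)
        peaks = [Landmark(l, 0.5 + 0.1 * i) for i, l in enumerate(locs)]
        valleys = [Landmark((a + b) / 2, 0.05)
                   for a, b in zip(locs, locs[1:])]
        lm = LandmarkSet(peaks, valleys)
        out = merge_low_peaks(lm, thres)
        out.validate()
        grid = make_grid(0, 6, 64)
        curve = DensityCurve(grid, np.ones_like(grid), 0.1, 10)
        drop_spurious_zero_peak(out, curve, thres).validate()


class TestPositivePeakPrior:
    def _curve(self):
        grid = make_grid(0.0, 6.0, 512)
        return analytic_curve(grid, [3.2], [0.4], [1.0])

    def test_single_peak_labeled_positive(self):
        lm = LandmarkSet(peaks=[Landmark(3.2, 1.0)], valleys=[])
        out = apply_positive_peak_prior(lm, True, self._curve())
        assert out.positive_only
        assert out.peaks[0].provenance == "prior-override"
        if out.valleys:
            assert out.valleys[0].location < out.peaks[0].location

    def test_without_prior_stays_negative(self):
        lm = LandmarkSet(peaks=[Landmark(3.2, 1.0)], valleys=[])
        out = apply_positive_peak_prior(lm, False, self._curve())
        assert not out.positive_only

    def test_two_peaks_with_prior_warns(self):
        lm = LandmarkSet(peaks=[Landmark(1.0, 1.0), Landmark(3.0, 1.0)],
                         valleys=[Landmark(2.0, 0.1)])
        with pytest.warns(UserWarning, match="rightmost"):
            out = apply_positive_peak_prior(lm, True, self._curve())
        assert not out.positive_only


def mad_oracle(values, multiplier):
    """Literal transcription: |x - median| / (1.4826 * median(|x - median|))."""
    import statistics

    vals = [v for v in values if np.isfinite(v)]
    flags = [False] * len(values)
    if len(vals) < 3:
        return flags
    med = statistics.median(vals)
    mad = 1.4826 * statistics.median([abs(v - med) for v in vals])
    for i, v in enumerate(values):
        if not np.isfinite(v):
            continue
        if mad == 0:
            flags[i] = v != med
        else:
            flags[i] = abs(v - med) / mad > multiplier
    return flags


class TestMADFlags:
    def test_hand_computed_example(self):
        flags = flag_outlier_positive_peaks([0.9, 1.0, 1.1, 5.0], 3.0)
        assert flags.tolist() == [False, False, False, True]
        # hand computation: median 1.05, scaled MAD 1.4826*0.10 = 0.14826
        score = abs(5.0 - 1.05) / (1.4826 * 0.10)
        assert score == pytest.approx(26.64, abs=0.01)

    def test_all_equal_none_flagged(self):
        assert not flag_outlier_positive_peaks([2.0, 2.0, 2.0, 2.0], 3.0).any()

    def test_two_values_no_support(self):
        assert not flag_outlier_positive_peaks([1.0, 99.0], 3.0).any()

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=12),
           st.floats(0.5, 5.0))
    def test_matches_brute_force_oracle(self, values, multiplier):
        got = scaled_mad_flags(values, multiplier).tolist()
        assert got == mad_oracle(values, multiplier)


def emd_oracle(curve_a, curve_b):
    """Independent CDF-area computation via scipy.cumulative_trapezoid."""
    g = curve_a.grid
    ca = np.concatenate([[0.0], cumulative_trapezoid(curve_a.density, g)])
    cb = np.concatenate([[0.0], cumulative_trapezoid(curve_b.density, g)])
    ca, cb = ca / ca[-1], cb / cb[-1]
    return np.trapezoid(np.abs(ca - cb), g)


class TestEMD:
    def test_identical_curves_zero(self, rng):
        grid = make_grid(0, 5, 256)
        c = estimate_density(rng.normal(2, 0.5, 300), 0.2, grid)
        mat = compute_emd_matrix({"a": c, "b": c})
        assert mat.distances[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_point_masses_distance_one(self):
        grid = np.linspace(-1.0, 2.0, 3001)
        a = estimate_density(np.array([0.0, 0.0]), 0.005, grid)
        b = estimate_density(np.array([1.0, 1.0]), 0.005, grid)
        mat = compute_emd_matrix({"a": a, "b": b})
        assert mat.distances[0, 1] == pytest.approx(1.0, abs=0.02)

    def test_symmetry_and_zero_diagonal(self, rng):
        grid = make_grid(0, 5, 128)
        curves = {f"b{i}": estimate_density(rng.normal(1 + i, 0.4, 200), 0.3, grid)
                  for i in range(4)}
        mat = compute_emd_matrix(curves)
        np.testing.assert_allclose(mat.distances, mat.distances.T)
        np.testing.assert_allclose(np.diag(mat.distances), 0)

    def test_matches_cdf_area_oracle(self, rng):
        grid = make_grid(0, 6, 300)
        for _ in range(30):
            w = rng.random((2, 300)) + 1e-3
            a = DensityCurve(grid, w[0] / np.trapezoid(w[0], grid), 0.1, 10)
            b = DensityCurve(grid, w[1] / np.trapezoid(w[1], grid), 0.1, 10)
            mat = compute_emd_matrix({"a": a, "b": b})
            assert mat.distances[0, 1] == pytest.approx(
                emd_oracle(a, b), abs=1e-8)

    def test_grid_mismatch_errors(self, rng):
        a = estimate_density(rng.normal(1, 0.3, 100), 0.2, make_grid(0, 5, 128))
        b = estimate_density(rng.normal(1, 0.3, 100), 0.2, make_grid(0, 4, 128))
        with pytest.raises(ValidationError):
            compute_emd_matrix({"a": a, "b": b})


class TestValleyImputation:
    def _emd(self, rng, locs):
        grid = make_grid(0, 8, 128)
        curves = {f"b{i}": estimate_density(rng.normal(loc, 0.4, 200), 0.3, grid)
                  for i, loc in enumerate(locs)}
        return compute_emd_matrix(curves)

    def test_flagged_valley_imputed_from_neighbors(self, rng):
        emd = self._emd(rng, [2.0, 2.1, 2.05, 6.0])
        valleys = np.array([[2.0], [2.1], [2.05], [6.0]])
        out, mask = impute_outlier_valleys(valleys, emd, 3.0, k_neighbors=2)
        assert mask[3, 0]
        # nearest clean neighbors of the outlier batch hold valleys ~2.0-2.1
        assert 2.0 <= out[3, 0] <= 2.1

    def test_no_flags_identity(self, rng):
        emd = self._emd(rng, [2.0, 2.1, 2.05])
        valleys = np.array([[2.0], [2.1], [2.05]])
        out, mask = impute_outlier_valleys(valleys, emd, 3.0)
        np.testing.assert_array_equal(out, valleys)
        assert not mask.any()

    def test_two_batches_no_imputation(self, rng):
        emd = self._emd(rng, [2.0, 6.0])
        out, mask = impute_outlier_valleys(np.array([[2.0], [6.0]]), emd, 3.0)
        assert not mask.any()
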