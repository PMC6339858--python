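"""Curve-length profiles and dimension fitting against independent oracles."""

import numpy as np
import pytest

from scalefd import (
    CurveLengthProfile,
    DegenerateSignalError,
    Epoch,
    InputError,
    InsufficientScalesError,
    ScaleTooLargeError,
    band_to_scales,
    curve_length_profile,
    default_band_table,
    epoch_length_diagnostics,
    fit_dimension,
    gen_fbm,
    scale_specific_dimension,
    sliding_dimension_curve,
)


def naive_profile(x, ks):
    """Literal nested-loop transcription of the curve-length definition
    (1-based indexing, offsets m = 1..k, offsets without increments skipped)."""
    n = len(x)
    out = {}
    for k in ks:
        lms = []
        for m in range(1, k + 1):
            n_m = (n - m) // k
            if n_m < 1:
                continue
            s = sum(
                abs(x[m + i * k - 1] - x[m + (i - 1) * k - 1])
                for i in range(1, n_m + 1)
            )
            lms.append(s * (n - 1) / (n_m * k * k))
        out[k] = np.mean(lms)
    return out


class TestCurveLengthProfile:
    def test_constant_series_has_zero_lengths(self):
        ep = Epoch(np.full(100, 3.7), fs=200.0)
        prof = curve_length_profile(ep, [2, 3, 4, 5])
        assert np.all(prof.mean_lengths == 0.0)
        with pytest.raises(DegenerateSignalError):
            fit_dimension(prof, 2, 5)

    def test_linear_ramp_lengths_scale_as_inverse_k(self, ramp_epoch):
        prof = curve_length_profile(ramp_epoch, range(2, 40))
        # increments of c*t at stride k are c*k, so <L(k)> * k is constant
        prod = prof.mean_lengths * prof.k_values
        assert np.allclose(prod, prod[0], rtol=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_transcription(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(16, 65))
        x = rng.normal(size=n)
        ks = [k for k in (2, 3, 5, 7) if k < n]
        prof = curve_length_profile(Epoch(x, fs=100.0), ks)
        expected = naive_profile(x, ks)
        for k, got in zip(prof.k_values, prof.mean_lengths):
            assert got == pytest.approx(expected[k], rel=1e-10)

    def test_mean_is_average_of_offsets(self, rng):
        ep = Epoch(rng.normal(size=200), fs=100.0)
        prof = curve_length_profile(ep, [3, 7, 120])
        for mean, per in zip(prof.mean_lengths, prof.per_offset_lengths):
            assert mean == pytest.approx(np.nanmean(per), rel=1e-12)
        # k = 120 > N/2: offsets beyond N-k have no increments and are excluded
        assert prof.n_excluded_offsets[-1] == 120 - (200 - 120)

    def test_scale_too_large(self, rng):
        ep = Epoch(rng.normal(size=50), fs=100.0)
        with pytest.raises(ScaleTooLargeError):
            curve_length_profile(ep, [10, 50])

    def test_non_finite_samples_rejected(self):
        with pytest.raises(InputError):
            Epoch(np.array([1.0, np.nan, 2.0]), fs=100.0)


class TestFitDimension:
    def test_exact_power_law_recovered_to_machine_precision(self):
        ks = np.arange(2, 120)
        prof = CurveLengthProfile(
            ks, ks.astype(float) ** -1.5, tuple(np.array([l]) for l in ks ** -1.5)
        )
        for k_min, k_max in ((2, 119), (25, 100), (3, 25)):
            est = fit_dimension(prof, k_min, k_max)
            assert est.dimension == pytest.approx(1.5, abs=1e-12)
            assert est.r_squared == pytest.approx(1.0, abs=1e-12)
            assert est.n_points == k_max - k_min + 1

    def test_ramp_dimension_is_one(self, ramp_epoch):
        prof = curve_length_profile(ramp_epoch, range(2, 50))
        est = fit_dimension(prof, 2, 49)
        assert est.dimension == pytest.approx(1.0, abs=1e-3)

    def test_white_noise_dimension_is_two(self):
        ds = []
        for seed in range(3):
            x = np.random.default_rng(seed).standard_normal(10_000)
            prof = curve_length_profile(Epoch(x, fs=200.0), range(3, 134))
            ds.append(fit_dimension(prof, 3, 133).dimension)
        assert np.mean(ds) == pytest.approx(2.0, abs=0.1)

    def test_missing_scale_raises_instead_of_interpolating(self, rng):
        ep = Epoch(rng.normal(size=500), fs=100.0)
        prof = curve_length_profile(ep, [3, 4, 6, 7])  # k=5 missing
        with pytest.raises(InsufficientScalesError):
            fit_dimension(prof, 3, 7)

    def test_fewer_than_three_scales_raises(self, rng):
        ep = Epoch(rng.normal(size=500), fs=100.0)
        prof = curve_length_profile(ep, [3, 4])
        with pytest.raises(InsufficientScalesError):
            fit_dimension(prof, 3, 4)

    @pytest.mark.parametrize("a,b", [(0.5, 0.0), (-3.0, 10.0), (100.0, -7.5)])
    def test_amplitude_and_offset_invariance(self, a, b):
        ep = gen_fbm(2000, 0.5, seed=11)
        scaled = Epoch(a * ep.samples + b, ep.fs)
        band = band_to_scales(200.0, 2.0, 8.0)
        d0 = scale_specific_dimension(ep, band)
        d1 = scale_specific_dimension(scaled, band)
        assert d1.dimension == pytest.approx(d0.dimension, abs=1e-9)
        assert d1.r_squared == pytest.approx(d0.r_squared, abs=1e-9)


class TestScaleSpecific:
    def test_window_restriction_matches_manual_composition(self):
        ep = gen_fbm(3000, 0.4, seed=5)
        band = band_to_scales(200.0, 2.0, 8.0)
        est = scale_specific_dimension(ep, band)
        prof = curve_length_profile(ep, range(25, 101))
        assert est.dimension == fit_dimension(prof, 25, 100).dimension

    def test_distinct_windows_differ_on_composite_signal(self):
        # fBm plus a strong oscillation: fractality is scale-dependent
        ep = gen_fbm(10_000, 0.5, seed=21)
        t = np.arange(len(ep)) / ep.fs
        comp = Epoch(ep.samples + 5.0 * np.sin(2 * np.pi * 10.0 * t), ep.fs)
        d_slow = scale_specific_dimension(comp, band_to_scales(200.0, 2.0, 8.0))
        d_fast = scale_specific_dimension(comp, band_to_scales(200.0, 13.0, 60.0))
        assert abs(d_slow.dimension - d_fast.dimension) > 0.05


class TestSlidingCurve:
    def test_constant_for_exact_scale_free_signal(self, ramp_epoch):
        for width in (2, 5, 10, 20):
            curve = sliding_dimension_curve(ramp_epoch, width, range(2, 30, 4))
            ds = [e.dimension for _, e in curve]
            assert np.allclose(ds, 1.0, atol=1e-6)

    def test_matches_direct_window_fits(self):
        ep = gen_fbm(3000, 0.3, seed=2)
        curve = dict(sliding_dimension_curve(ep, 10, [25, 50]))
        for k_min in (25, 50):
            band = band_to_scales(200.0, 200.0 / (k_min + 10), 200.0 / k_min)
            direct = curve_length_profile(ep, range(k_min, k_min + 11))
            want = fit_dimension(direct, k_min, k_min + 10).dimension
            assert curve[k_min].dimension == pytest.approx(want, rel=1e-12)

    def test_narrow_windows_are_noisier_than_wide(self):
        """Dimension-vs-k_min curves smooth out once the window spans >= 10
        scales, mirroring the minimum-width rule."""
        var2, var20 = [], []
        for seed in range(10):
            x = np.random.default_rng(seed).standard_normal(4000)
            ep = Epoch(x, fs=200.0)
            for width, acc in ((2, var2), (20, var20)):
                curve = sliding_dimension_curve(ep, width, range(10, 41, 3))
                acc.append(np.var([e.dimension for _, e in curve]))
        assert np.mean(var2) > np.mean(var20)


class TestEpochLengthDiagnostics:
    def test_full_length_single_segment_matches_direct(self):
        ep = gen_fbm(10_000, 0.5, seed=3)
        bands = default_band_table(200.0)
        table = epoch_length_diagnostics(ep, [50.0], bands)
        assert (table["n_segments"] == 1).all()
        for band in bands:
            want = scale_specific_dimension(ep, band).dimension
            got = table.loc[table["band"] == band.label, "D"].iloc[0]
            assert got == pytest.approx(want, rel=1e-12)

    def test_too_short_segment_gets_missing_marker(self):
        ep = gen_fbm(1000, 0.5, seed=4)  # 5 s at 200 Hz
        wide = band_to_scales(200.0, 0.15, 8.0)  # k_max = 1333 >= segment
        table = epoch_length_diagnostics(ep, [5.0], [wide])
        assert np.isnan(table["D"]).all()
        assert (table["n_segments"] == 0).all()

    def test_leading_prefix_uses_first_window(self):
        ep = gen_fbm(10_000, 0.5, seed=6)
        band = band_to_scales(200.0, 13.0, 60.0)
        table = epoch_length_diagnostics(ep, [10.0], [band], mode="leading-prefix")
        first = Epoch(ep.samples[:2000], ep.fs)
        want = scale_specific_dimension(first, band).dimension
        assert table["D"].iloc[0] == pytest.approx(want, rel=1e-12)

    def test_estimates_converge_with_epoch_length(self):
        """Shortened leading evaluation windows drift further from the
        full-epoch estimate than long ones."""
        band = band_to_scales(200.0, 2.0, 8.0)
        gap_short, gap_long = [], []
        for seed in range(12):
            ep = gen_fbm(10_000, 0.3, seed=seed)
            tab = epoch_length_diagnostics(
                ep, [10.0, 30.0, 50.0], [band], mode="leading-prefix"
            )
            d10, d30, d50 = tab["D"].to_numpy()
            gap_short.append(abs(d10 - d50))
            gap_long.append(abs(d30 - d50))
        assert np.mean(gap_long) < np.mean(gap_short)
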