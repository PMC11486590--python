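import dataclasses

import numpy as np
import pytest
from scipy.special import erf

from spongiometry import (
    AverageProfile,
    GrowthPlateBoundary,
    LandmarkError,
    MorphometryConfig,
    average_profiles,
    control_phantom_spec,
    extract_line_profiles,
    fit_monoexponential,
    generate_phantom,
    interpolate_map,
    locate_landmarks,
    measure_femoral_head,
)
from spongiometry.morphometry import LineProfileSet, sigma_clipped_mean
from spongiometry.relaxometry import RelaxationMap


def constant_map(value=80.0, h=80, w=80, spacing=0.17):
    shape = (h, w)
    return RelaxationMap(
        values=np.full(shape, value),
        s0=np.full(shape, 100.0),
        rsq=np.ones(shape),
        pixel_spacing=spacing,
        contrast_label="T2",
    )


def horizontal_boundary(length=10.2, y=1.7, x0=1.0, n=25):
    xs = np.linspace(x0, x0 + length, n)
    return GrowthPlateBoundary(
        points=np.column_stack([xs, np.full(n, y)]), distal_hint=(0.0, 1.0)
    )


def gaussian_mixture(d):
    return (
        90.0
        - 30.0 * np.exp(-((d - 1.5) ** 2) / (2 * 0.4**2))
        + 20.0 * np.exp(-((d - 3.0) ** 2) / (2 * 0.6**2))
    )


def gaussian_mixture_oracle():
    """Fine-grid (1e-4 mm) numerical landmark oracle on the analytic profile."""
    d = np.arange(0.0, 10.0, 1e-4)
    v = gaussian_mixture(d)
    i_min = int(np.argmin(v))
    i_max = i_min + int(np.argmax(v[i_min:]))
    d2 = np.gradient(np.gradient(v, d), d)
    sgn = np.sign(d2)
    crossings = d[np.where(sgn[:-1] * sgn[1:] < 0)[0]]
    ps_d, ss_d = d[i_min], d[i_max]
    left = crossings[crossings < ps_d].max()
    mid = crossings[crossings > ps_d].min()
    return {
        "ps_depth": ps_d,
        "ss_depth": ss_d,
        "ps_value": v[i_min],
        "ss_value": v[i_max],
        "ps_thickness": mid - left,
        "ss_thickness": 2 * (ss_d - mid),
    }


class TestBoundaryValidation:
    def test_too_few_points(self):
        with pytest.raises(ValueError, match="3"):
            GrowthPlateBoundary(points=[[0, 0], [1, 0]], distal_hint=(0, 1))

    def test_duplicate_consecutive_points(self):
        with pytest.raises(ValueError, match="distinct"):
            GrowthPlateBoundary(points=[[0, 0], [0, 0], [1, 0]], distal_hint=(0, 1))

    def test_self_intersection(self):
        pts = [[0, 0], [2, 0], [1, 1], [1, -1]]
        with pytest.raises(ValueError, match="intersect"):
            GrowthPlateBoundary(points=pts, distal_hint=(0, 1))

    def test_hint_normalized(self):
        b = GrowthPlateBoundary(points=[[0, 0], [1, 0], [2, 0]], distal_hint=(0, 5))
        np.testing.assert_allclose(b.distal_hint, [0, 1])


class TestExtractLineProfiles:
    def test_straight_boundary_60_lines_vertical(self):
        rmap = constant_map()
        pset = extract_line_profiles(rmap, horizontal_boundary(length=10.2))
        assert pset.n_lines == 60
        # vertical lines: all profiles sample straight down, so origins keep x
        np.testing.assert_allclose(np.diff(pset.line_origins[:, 1]), 0, atol=1e-12)

    def test_constant_field_profiles_constant(self):
        rmap = constant_map(value=73.5)
        pset = extract_line_profiles(rmap, horizontal_boundary())
        np.testing.assert_allclose(pset.profiles, 73.5, atol=1e-9)

    def test_depth_grid(self):
        pset = extract_line_profiles(constant_map(), horizontal_boundary())
        assert pset.depths[0] == 0.0
        assert pset.depths[-1] <= 10.0
        assert pset.depths[-1] >= 9.5
        np.testing.assert_allclose(np.diff(pset.depths), 0.17)

    def test_boundary_outside_map_errors(self):
        rmap = constant_map(h=20, w=20)
        bad = horizontal_boundary(y=-5.0)
        with pytest.raises(ValueError, match="outside"):
            extract_line_profiles(rmap, bad)

    def test_too_few_lines_errors(self):
        rmap = constant_map()
        short = horizontal_boundary(length=0.6, n=4)
        with pytest.raises(ValueError, match="degenerate"):
            extract_line_profiles(rmap, short)

    def test_truncation_flagged(self):
        rmap = constant_map(h=40, w=80)  # only 6.8 mm tall
        pset = extract_line_profiles(rmap, horizontal_boundary(y=1.0))
        assert pset.truncated.all()
        assert np.isnan(pset.profiles[:, -1]).all()
        assert np.isfinite(pset.profiles[:, 0]).all()

    def test_arc_boundary_matches_radial_oracle(self):
        spec = control_phantom_spec(
            snr=np.inf,
            contrasts=("T2",),
            geometry="arc_bands",
            image_shape=(40, 44),
            transition_sigma_mm=0.45,
        )
        series_by, truth = generate_phantom(spec)
        rmap = interpolate_map(fit_monoexponential(series_by["T2"]), 3)
        pset = extract_line_profiles(rmap, truth.boundary)
        bt = spec.band_T_ms["T2"]
        bw = spec.band_widths_mm
        edges = np.concatenate(
            [[0.0], np.cumsum([bw[b] for b in ("growth_plate", "primary_spongiosa", "secondary_spongiosa")])]
        )
        ts = [bt[b] for b in ("epiphysis", "growth_plate", "primary_spongiosa",
                              "secondary_spongiosa", "mature_metaphysis")]
        sig = spec.transition_sigma_mm
        oracle = np.full_like(pset.depths, ts[0])
        for e, (t0, t1) in zip(edges, zip(ts[:-1], ts[1:])):
            oracle = oracle + (t1 - t0) * 0.5 * (1 + erf((pset.depths - e) / (sig * np.sqrt(2))))
        full = pset.profiles[np.isfinite(pset.profiles).all(axis=1)]
        assert len(full) >= 10
        rel_rms = np.sqrt(np.mean((full - oracle) ** 2, axis=1)) / oracle.mean()
        assert rel_rms.max() < 0.02


class TestAverageProfiles:
    def _pset(self, profiles):
        profiles = np.asarray(profiles, dtype=float)
        n, d = profiles.shape
        depths = np.arange(d) * 0.17
        return LineProfileSet(
            depths=depths,
            profiles=profiles,
            line_origins=np.zeros((n, 2)),
            truncated=np.zeros(n, bool),
        )

    def test_identical_profiles_identity(self):
        prof = np.tile(np.linspace(50, 90, 20), (15, 1))
        avg = average_profiles(self._pset(prof))
        np.testing.assert_allclose(avg.values, prof[0])
        assert (avg.n_contributing == 15).all()

    def test_single_gross_outlier_removed(self):
        prof = np.full((100, 12), 50.0)
        prof[0] = 500.0
        avg = average_profiles(self._pset(prof), MorphometryConfig(clip_sigma=3.0))
        np.testing.assert_allclose(avg.values, 50.0)
        assert (avg.n_contributing == 99).all()

    def test_clipped_mean_within_3se_of_truth(self):
        rng = np.random.default_rng(11)
        true_mean, true_sd, n = 80.0, 6.0, 80
        prof = rng.normal(true_mean, true_sd, size=(n, 30))
        avg = average_profiles(self._pset(prof))
        se = true_sd / np.sqrt(n)
        assert np.all(np.abs(avg.values - true_mean) < 3 * se)

    def test_sparse_depth_nan_with_warning(self):
        prof = np.full((12, 8), 60.0)
        prof[2:, 5] = np.nan  # only 2 contributors at depth 5
        with pytest.warns(UserWarning, match="contributing"):
            avg = average_profiles(self._pset(prof))
        assert np.isnan(avg.values[5])
        assert np.isfinite(avg.values[[0, 1, 2, 3, 4, 6, 7]]).all()

    def test_sigma_clipped_mean_zero_spread_column(self):
        mean, n = sigma_clipped_mean(np.full((20, 4), 7.0))
        np.testing.assert_allclose(mean, 7.0)
        assert (n == 20).all()


class TestLocateLandmarks:
    def _profile(self, values, step=0.17):
        depths = np.arange(len(values)) * step
        return AverageProfile(
            depths=depths, values=np.asarray(values, float), n_contributing=np.full(len(values), 80)
        )

    def test_gaussian_mixture_against_fine_grid_oracle(self):
        d = np.arange(0.0, 10.0 + 1e-9, 0.17)
        res = locate_landmarks(self._profile(gaussian_mixture(d)))
        oracle = gaussian_mixture_oracle()
        # depths to within one sample step; thicknesses allow smoothing bias
        assert res.ps_depth == pytest.approx(oracle["ps_depth"], abs=0.17)
        assert res.ss_depth == pytest.approx(oracle["ss_depth"], abs=0.17)
        assert res.ps_thickness == pytest.approx(oracle["ps_thickness"], abs=0.17 + 0.1)
        assert res.ss_thickness == pytest.approx(oracle["ss_thickness"], abs=0.17 + 0.1)
        assert res.ps_value < res.ss_value
        # Gaussian-dip inflection width ~ 2 sigma = 0.8 mm
        assert res.ps_thickness == pytest.approx(0.8, abs=0.3)

    def test_monotone_profile_raises(self):
        d = np.arange(0.0, 10.0, 0.17)
        with pytest.raises(LandmarkError, match="primary spongiosa"):
            locate_landmarks(self._profile(100.0 - 5.0 * d))

    def test_constant_profile_raises(self):
        with pytest.raises(LandmarkError):
            locate_landmarks(self._profile(np.full(60, 42.0)))

    def test_no_maximum_after_minimum_raises(self):
        d = np.arange(0.0, 10.0, 0.17)
        v = 50.0 + (d - 4.0) ** 2  # single minimum, no later max
        with pytest.raises(LandmarkError, match="secondary"):
            locate_landmarks(self._profile(v))

    def test_mm_window_beyond_profile_raises(self):
        d = np.arange(0.0, 6.0, 0.17)  # short profile
        v = gaussian_mixture(d)
        with pytest.raises(ValueError, match="profile_length"):
            locate_landmarks(self._profile(v))

    def test_nonfinite_profile_rejected(self):
        d = np.arange(0.0, 10.0, 0.17)
        v = gaussian_mixture(d)
        v[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            locate_landmarks(self._profile(v))

    def test_total_is_exact_sum(self):
        d = np.arange(0.0, 10.0 + 1e-9, 0.17)
        res = locate_landmarks(self._profile(gaussian_mixture(d)))
        assert res.total_thickness == res.ps_thickness + res.ss_thickness

    def test_control_phantom_ordering(self, control_phantom_t2, long_profile_config):
        rmap, truth = control_phantom_t2
        res = measure_femoral_head(rmap, truth.boundary, long_profile_config)
        assert 0 < res.ps_depth < res.ss_depth
        assert res.ps_value < res.mm_value < res.ss_value


class TestMeasureFemoralHead:
    def test_phantom_thickness_recovery(self, control_phantom_t2, long_profile_config):
        rmap, truth = control_phantom_t2
        res = measure_femoral_head(rmap, truth.boundary, long_profile_config)
        assert res.ss_thickness == pytest.approx(truth.true_ss_thickness, rel=0.15)

    def test_interpolation_consistency(self, long_profile_config):
        spec = control_phantom_spec(
            snr=np.inf, contrasts=("T2",), image_shape=(34, 36), transition_sigma_mm=0.45
        )
        series_by, truth = generate_phantom(spec)
        fitted = fit_monoexponential(series_by["T2"])
        r1 = measure_femoral_head(interpolate_map(fitted, 1), truth.boundary, long_profile_config)
        r3 = measure_femoral_head(interpolate_map(fitted, 3), truth.boundary, long_profile_config)
        assert abs(r1.ps_depth - r3.ps_depth) < 0.52
        assert abs(r1.ss_depth - r3.ss_depth) < 0.52

    def test_constant_map_landmark_error(self):
        with pytest.raises(LandmarkError):
            measure_femoral_head(constant_map(), horizontal_boundary())

    def test_provenance_attached(self, control_phantom_t2, long_profile_config):
        rmap, truth = control_phantom_t2
        res = measure_femoral_head(rmap, truth.boundary, long_profile_config)
        assert res.provenance["n_lines"] >= 10
        assert len(res.provenance["config_hash"]) == 12


def _profile_map_and_boundary(h=80, w=90, spacing=0.17, y0=1.7):
    """Map whose value depends only on distance below the line y = y0."""
    rows = np.arange(h) * spacing
    depth = np.clip(rows - y0, -y0, None)
    col = gaussian_mixture(np.abs(depth))
    values = np.tile(col[:, np.newaxis], (1, w))
    rmap = RelaxationMap(
        values=values,
        s0=np.full((h, w), 100.0),
        rsq=np.ones((h, w)),
        pixel_spacing=spacing,
        contrast_label="T2",
    )
    xs = np.linspace(1.2, (w - 1) * spacing - 1.2, 40)
    boundary = GrowthPlateBoundary(
        points=np.column_stack([xs, np.full_like(xs, y0)]), distal_hint=(0.0, 1.0)
    )
    return rmap, boundary


class TestEquivarianceAndRobustness:
    def test_rigid_transform_equivariance(self):
        rmap, boundary = _profile_map_and_boundary()
        res = measure_femoral_head(rmap, boundary)
        # transpose = reflection about the diagonal; swap x/y everywhere
        rmap_t = RelaxationMap(
            values=rmap.values.T,
            s0=rmap.s0.T,
            rsq=rmap.rsq.T,
            pixel_spacing=rmap.pixel_spacing,
            contrast_label="T2",
        )
        boundary_t = GrowthPlateBoundary(
            points=boundary.points[:, ::-1], distal_hint=boundary.distal_hint[::-1]
        )
        res_t = measure_femoral_head(rmap_t, boundary_t)
        for name in ("ps_depth", "ss_depth", "ps_value", "ss_value",
                     "mm_value", "ps_thickness", "ss_thickness"):
            assert getattr(res_t, name) == pytest.approx(getattr(res, name), abs=1e-6)

    def test_translation_equivariance(self):
        rmap, boundary = _profile_map_and_boundary()
        res = measure_femoral_head(rmap, boundary)
        k = 7  # pad by k pixels of NaN on top/left and shift boundary to match
        values = np.pad(rmap.values, ((k, 0), (k, 0)), constant_values=np.nan)
        rmap_p = RelaxationMap(
            values=values,
            s0=np.pad(rmap.s0, ((k, 0), (k, 0)), constant_values=np.nan),
            rsq=np.pad(rmap.rsq, ((k, 0), (k, 0)), constant_values=np.nan),
            pixel_spacing=rmap.pixel_spacing,
            contrast_label="T2",
        )
        shift = k * rmap.pixel_spacing
        boundary_p = GrowthPlateBoundary(
            points=boundary.points + shift, distal_hint=boundary.distal_hint
        )
        res_p = measure_femoral_head(rmap_p, boundary_p)
        assert res_p.ps_depth == pytest.approx(res.ps_depth, abs=1e-6)
        assert res_p.ss_thickness == pytest.approx(res.ss_thickness, abs=1e-6)

    def test_value_scale_equivariance(self):
        rmap, boundary = _profile_map_and_boundary()
        res = measure_femoral_head(rmap, boundary)
        c = 2.5
        rmap_c = dataclasses.replace(rmap, values=c * rmap.values)
        res_c = measure_femoral_head(rmap_c, boundary)
        assert res_c.ps_value == pytest.approx(c * res.ps_value, rel=1e-9)
        assert res_c.ss_value == pytest.approx(c * res.ss_value, rel=1e-9)
        assert res_c.mm_value == pytest.approx(c * res.mm_value, rel=1e-9)
        assert res_c.ps_depth == pytest.approx(res.ps_depth, abs=1e-9)
        assert res_c.ss_thickness == pytest.approx(res.ss_thickness, abs=1e-9)

    def test_outlier_lines_change_landmark_values_little(self):
        rmap, boundary = _profile_map_and_boundary()
        cfg = MorphometryConfig(clip_sigma=3.0)
        pset = extract_line_profiles(rmap, boundary, cfg)
        clean = locate_landmarks(average_profiles(pset, cfg), cfg)
        profiles = pset.profiles.copy()
        n_bad = max(1, int(0.05 * pset.n_lines))
        profiles[:n_bad] = 400.0  # gross outliers on 5% of lines
        dirty_set = LineProfileSet(
            depths=pset.depths,
            profiles=profiles,
            line_origins=pset.line_origins,
            truncated=pset.truncated,
        )
        dirty = locate_landmarks(average_profiles(dirty_set, cfg), cfg)
        assert dirty.ps_value == pytest.approx(clean.ps_value, rel=0.02)
        assert dirty.ss_value == pytest.approx(clean.ss_value, rel=0.02)
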