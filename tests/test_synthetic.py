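"""The scene generator: trajectories, band inversion, gaps, polygon structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricesits import features as ft
from ricesits.synthetic import (CLOUD_CODE, ConfigurationError, FlatParams,
                                PhenologyParams, SceneConfig, build_dataset,
                                default_b8_profile, inject_gaps,
                                invert_bands, simulate_trajectory)

DOYS = np.arange(152, 305, 5)


class TestTrajectories:
    def test_rice_curve_endpoints(self):
        p = PhenologyParams(noise_sd=0.0)
        tr = simulate_trajectory("rice", p, np.arange(150, 311), rng=None)
        ndvi = tr["ndvi"]
        doys = np.arange(150, 311)
        at = lambda d: ndvi[list(doys).index(d)]  # noqa: E731
        assert abs(at(p.transplant_doy) - p.ndvi_base) < 0.05
        assert ndvi.max() > p.ndvi_peak - 0.06
        assert at(300) < ndvi.max() - 0.05
        # LSWI: flooded at transplanting, dry by late ripening
        lswi = tr["lswi"]
        assert abs(lswi[list(doys).index(p.transplant_doy)]
                   - p.lswi_flood) < 0.05
        assert lswi[-1] < p.lswi_dry + 0.05

    def test_water_flat_nonpositive_ndvi(self):
        tr = simulate_trajectory("water", FlatParams(ndvi_level=-0.15,
                                                     lswi_level=0.6,
                                                     noise_sd=0.0), DOYS)
        assert np.all(tr["ndvi"] <= 0)
        assert np.ptp(tr["ndvi"]) < 1e-12

    def test_rice_tdvi_sign_by_stage(self):
        """Green-up yields positive index differences, senescence negative
        (checked numerically on the noiseless curve)."""
        p = PhenologyParams(noise_sd=0.0)
        grid = np.arange(150, 316)
        ndvi = simulate_trajectory("rice", p, grid)["ndvi"]
        diff = np.diff(ndvi)
        mid = (grid[:-1] + grid[1:]) / 2
        growth = (mid > p.growth_start + 5) & (mid < p.growth_start
                                               + 0.75 * p.growth_len)
        ripen = (mid > p.growth_end + 2) & (mid < p.ripen_end - 2)
        assert np.all(diff[growth] > 0)
        assert np.all(diff[ripen] < 0)

    def test_unknown_class_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_trajectory("swamp", FlatParams(), DOYS)
        with pytest.raises(ConfigurationError):
            simulate_trajectory("water", PhenologyParams(), DOYS)

    def test_param_invariants_enforced(self):
        with pytest.raises(ConfigurationError):
            PhenologyParams(transplant_len=5).validate()
        with pytest.raises(ConfigurationError):
            PhenologyParams(ndvi_peak=0.1, ndvi_base=0.2).validate()


class TestInvertBands:
    def test_zero_indices_symmetric(self):
        b2, b4, b8, b11 = invert_bands(0.0, 0.0, 0.4)
        assert b4 == pytest.approx(0.4) and b11 == pytest.approx(0.4)

    def test_direct_arithmetic(self):
        _, b4, _, _ = invert_bands(0.6, 0.0, 0.5)
        assert b4 == pytest.approx(0.125)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(-0.8, 0.9), st.floats(-0.8, 0.9),
           st.floats(0.05, 0.6))
    def test_round_trip(self, ndvi_v, lswi_v, b8_v):
        b2, b4, b8, b11 = invert_bands(ndvi_v, lswi_v, b8_v)
        if b4 <= 1.0 - 1e-9 and b11 <= 1.0 - 1e-9:  # no clipping occurred
            assert ft.ndvi(b8, b4) == pytest.approx(ndvi_v, abs=1e-9)
            assert ft.lswi(b8, b11) == pytest.approx(lswi_v, abs=1e-9)

    def test_singular_index_rejected(self):
        with pytest.raises(ValueError):
            invert_bands(-1.0, 0.0, 0.4)


class TestInjectGaps:
    def test_zero_rate_identity(self, rng):
        q = np.full((5, 20), 4, dtype=np.uint8)
        assert np.array_equal(inject_gaps(q, 0.0, rng), q)

    def test_binomial_mean_fraction(self):
        rng = np.random.default_rng(99)
        q = np.full((10_000, 30), 4, dtype=np.uint8)
        out = inject_gaps(q, 0.3, rng)
        frac = (out == CLOUD_CODE).mean()
        assert 0.29 <= frac <= 0.31

    def test_deterministic_given_seed(self):
        q = np.full((50, 12), 4, dtype=np.uint8)
        a = inject_gaps(q, 0.5, np.random.default_rng(3))
        b = inject_gaps(q, 0.5, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_at_least_one_clear_step(self):
        q = np.full((200, 5), 4, dtype=np.uint8)
        out = inject_gaps(q, 0.95, np.random.default_rng(0))
        assert np.all((out != CLOUD_CODE).sum(axis=1) >= 1)

    def test_rate_one_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            inject_gaps(np.full(5, 4), 1.0, rng)


class TestBuildDataset:
    def test_counts_and_polygon_ids(self):
        cfg = SceneConfig(classes=("rice", "water"), n_polygons_per_class=10,
                          points_per_polygon=3, patch_size=1, seed=0)
        ds = build_dataset(cfg)
        assert len(ds) == 60
        assert len(np.unique(ds.polygon_ids)) == 20
        assert np.array_equal(np.unique(ds.labels), [0, 1])
        assert np.all((ds.labels == 1) == (ds.class_names == "rice"))

    def test_same_seed_byte_identical(self):
        cfg = SceneConfig(n_polygons_per_class=4, points_per_polygon=2,
                          patch_size=1, seed=5)
        assert build_dataset(cfg).serialize_bytes() == \
            build_dataset(cfg).serialize_bytes()

    def test_reflectances_and_indices_bounded(self, tiny_scene):
        assert tiny_scene.bands.min() >= 0.0
        assert tiny_scene.bands.max() <= 1.0
        cb = tiny_scene.center_bands().astype(float)
        for idx in (ft.ndvi(cb[:, 2], cb[:, 1]), ft.lswi(cb[:, 2], cb[:, 3])):
            assert np.all(np.abs(idx) <= 1.0)

    def test_class_separability_noiseless(self):
        params = {
            "rice": PhenologyParams(noise_sd=0.0),
            "water": FlatParams(ndvi_level=-0.15, lswi_level=0.6,
                                noise_sd=0.0),
            "urban": FlatParams(ndvi_level=0.12, lswi_level=-0.05,
                                noise_sd=0.0),
        }
        cfg = SceneConfig(classes=("rice", "water", "urban"),
                          class_params=params, n_polygons_per_class=5,
                          points_per_polygon=2, patch_size=1, gap_rate=0.0,
                          seed=2)
        ds = build_dataset(cfg)
        cb = ds.center_bands().astype(float)
        ndvi = ft.ndvi(cb[:, 2], cb[:, 1])
        peak = (ds.doys >= 215) & (ds.doys <= 265)
        rice_peak = ndvi[ds.labels == 1][:, peak].mean()
        for cls in ("water", "urban"):
            other = ndvi[ds.class_names == cls][:, peak].mean()
            assert rice_peak - other > 0.3

    def test_polygon_points_correlated(self, tiny_scene):
        """Points in one polygon share a trajectory (same clean curve)."""
        pid = tiny_scene.polygon_ids[0]
        rows = np.flatnonzero(tiny_scene.polygon_ids == pid)
        assert len(rows) == 2
        assert np.array_equal(tiny_scene.true_ndvi[rows[0]],
                              tiny_scene.true_ndvi[rows[1]])

    def test_patch_structure(self):
        cfg = SceneConfig(classes=("rice", "urban"), n_polygons_per_class=2,
                          points_per_polygon=1, patch_size=3, seed=1)
        ds = build_dataset(cfg)
        s = ds[0]
        assert s.bands.shape == (3, 3, 4, len(ds.doys))
        # neighbours perturb the centre trajectory only slightly
        center = s.bands[1, 1]
        corner = s.bands[0, 0]
        assert np.abs(center - corner).max() < 0.06

    def test_zero_polygons_rejected(self):
        with pytest.raises(ConfigurationError):
            build_dataset(SceneConfig(n_polygons_per_class=0))

    def test_even_patch_rejected(self):
        with pytest.raises(ConfigurationError):
            SceneConfig(patch_size=4).validate()
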