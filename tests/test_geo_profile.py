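"""Dragnet scoring, bootstrap aggregation, masking and hotspot extraction."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from invasionscope.geo_profile import (
    EARTH_RADIUS_KM,
    BootstrapParams,
    DragnetParams,
    ElevationGrid,
    GeographicProfile,
    GridSpec,
    OccurrenceRecord,
    ValidationError,
    apply_elevation_mask,
    bootstrap_profile,
    dragnet_score,
    extract_source_areas,
    haversine_distance,
)
from invasionscope.synthetic_data import gen_occurrences

from conftest import brute_force_dragnet


class TestHaversine:
    def test_identity_and_closed_forms(self):
        assert haversine_distance(0, 0, 0, 0) == 0.0
        # one equatorial degree and a quarter meridian, closed form on the sphere
        assert haversine_distance(0, 0, 1, 0) == pytest.approx(
            EARTH_RADIUS_KM * math.pi / 180, rel=1e-12
        )
        assert haversine_distance(0, 0, 0, 90) == pytest.approx(
            EARTH_RADIUS_KM * math.pi / 2, rel=1e-12
        )

    @given(
        lon1=st.floats(-180, 180), lat1=st.floats(-90, 90),
        lon2=st.floats(-180, 180), lat2=st.floats(-90, 90),
    )
    def test_symmetric_and_nonnegative(self, lon1, lat1, lon2, lat2):
        d12 = haversine_distance(lon1, lat1, lon2, lat2)
        d21 = haversine_distance(lon2, lat2, lon1, lat1)
        assert d12 == pytest.approx(d21, abs=1e-9)
        assert d12 >= 0

    @pytest.mark.parametrize("bad", [(-181, 0), (181, 0), (0, 91), (0, -91)])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            haversine_distance(bad[0], bad[1], 0, 0)


class TestOccurrenceValidation:
    def test_elevation_below_lowest_land_rejected(self):
        with pytest.raises(ValidationError):
            OccurrenceRecord("x", 14.4, 40.7, -500.0)

    def test_bad_site_type_rejected(self):
        with pytest.raises(ValidationError):
            OccurrenceRecord("x", 14.4, 40.7, 10.0, site_type="airport")

    def test_duplicate_site_ids_rejected_by_model(self, small_grid):
        occ = [OccurrenceRecord("a", 14.41, 40.71, 0.0)] * 2
        with pytest.raises(ValidationError, match="duplicate"):
            GeographicProfile(occ, grid=small_grid)


class TestDragnetScore:
    def test_single_occurrence_peak_at_nearest_cell(self, small_grid):
        occ = [OccurrenceRecord("a", 14.412, 40.733, 0.0)]
        surf = dragnet_score(occ, small_grid, DragnetParams(normalize_by="none"))
        assert surf.argmax_cell() == small_grid.cell_of(14.412, 40.733)

    def test_monotone_decay_from_single_occurrence(self, small_grid):
        occ = [OccurrenceRecord("a", 14.425, 40.725, 0.0)]
        surf = dragnet_score(occ, small_grid, DragnetParams(normalize_by="none"))
        # score strictly decreasing in distance from the occurrence
        dists, scores = [], []
        for r in range(small_grid.n_rows):
            for c in range(small_grid.n_cols):
                lon, lat = small_grid.cell_center(r, c)
                dists.append(haversine_distance(lon, lat, 14.425, 40.725))
                scores.append(surf.scores[r, c])
        order = np.argsort(dists)
        assert np.all(np.diff(np.array(scores)[order]) < 0)

    def test_mirror_symmetry_about_central_meridian(self):
        grid = GridSpec(14.0, 14.5, 40.0, 40.5, 0.05)
        mid = 0.5 * (14.0 + 14.5)
        occ = [
            OccurrenceRecord("w", mid - 0.1, 40.25, 0.0),
            OccurrenceRecord("e", mid + 0.1, 40.25, 0.0),
        ]
        surf = dragnet_score(occ, grid)
        np.testing.assert_allclose(surf.scores, surf.scores[:, ::-1], rtol=1e-10)

    @pytest.mark.parametrize("shape", [(5, 5), (12, 7), (20, 20)])
    def test_matches_brute_force_oracle(self, shape, three_occurrences):
        nrows, ncols = shape
        grid = GridSpec(14.40, 14.40 + 0.01 * ncols, 40.70, 40.70 + 0.01 * nrows, 0.01)
        surf = dragnet_score(three_occurrences, grid)
        oracle = brute_force_dragnet(three_occurrences, grid)
        np.testing.assert_allclose(surf.scores, oracle, atol=1e-12, rtol=0)

    def test_permutation_invariance(self, small_grid, three_occurrences):
        a = dragnet_score(three_occurrences, small_grid).scores
        b = dragnet_score(three_occurrences[::-1], small_grid).scores
        np.testing.assert_array_equal(a, b)

    def test_empty_occurrences_error(self, small_grid):
        with pytest.raises(ValidationError):
            dragnet_score([], small_grid)

    def test_coincident_points_degenerate_normaliser(self, small_grid):
        occ = [
            OccurrenceRecord("a", 14.42, 40.72, 0.0),
            OccurrenceRecord("b", 14.42, 40.72, 0.0),
        ]
        with pytest.raises(ValidationError, match="degenerate"):
            dragnet_score(occ, small_grid)


class TestBootstrapProfile:
    def test_fraction_one_reproduces_deterministic_surface_exactly(
        self, small_grid, three_occurrences
    ):
        boot = BootstrapParams(n_replicates=7, fraction_low=1.0, fraction_high=1.0, seed=5)
        bagged = bootstrap_profile(three_occurrences, small_grid, boot=boot)
        full = dragnet_score(three_occurrences, small_grid).rescaled()
        np.testing.assert_array_equal(bagged.scores, full.scores)

    def test_seed_determinism(self, small_grid, three_occurrences):
        occ = three_occurrences + [OccurrenceRecord("d", 14.415, 40.735, 30.0)]
        b1 = bootstrap_profile(occ, small_grid, boot=BootstrapParams(seed=11)).scores
        b2 = bootstrap_profile(occ, small_grid, boot=BootstrapParams(seed=11)).scores
        b3 = bootstrap_profile(occ, small_grid, boot=BootstrapParams(seed=12)).scores
        np.testing.assert_array_equal(b1, b2)
        assert not np.array_equal(b1, b3)

    def test_too_few_occurrences_error(self, small_grid, three_occurrences):
        with pytest.raises(ValidationError):
            bootstrap_profile(three_occurrences[:2], small_grid)

    def test_scores_within_unit_interval(self, small_grid, three_occurrences):
        surf = bootstrap_profile(
            three_occurrences, small_grid, boot=BootstrapParams(n_replicates=10, seed=2)
        )
        assert surf.scores.min() >= 0.0 and surf.scores.max() <= 1.0

    def test_recovery_improves_with_sample_size(self):
        """Argmax distance to the true source decreases stochastically with n."""
        source = (14.43, 40.66)
        grid = GridSpec(14.2, 14.7, 40.45, 40.85, 0.01)
        boot = BootstrapParams(n_replicates=10)

        def mean_err(n, seeds):
            errs = []
            for s in seeds:
                occ = gen_occurrences(n, sources=[(*source, 1.0)], scale_km=5.0, seed=s)
                occ = [o for o in occ if grid.contains(o.longitude, o.latitude)]
                surf = bootstrap_profile(occ, grid, boot=boot)
                r, c = surf.argmax_cell()
                lon, lat = grid.cell_center(r, c)
                errs.append(haversine_distance(lon, lat, *source))
            return np.mean(errs)

        assert mean_err(200, range(4)) <= mean_err(10, range(4))


class TestElevationMask:
    def _surface(self, grid):
        occ = [
            OccurrenceRecord("a", 14.41, 40.71, 0.0),
            OccurrenceRecord("b", 14.44, 40.74, 0.0),
        ]
        return dragnet_score(occ, grid)

    def test_total_mask_and_empty_hotspots(self, small_grid):
        surf = self._surface(small_grid)
        dem = ElevationGrid(small_grid, np.full(small_grid.shape, 700.0))
        masked = apply_elevation_mask(surf, dem)
        assert masked.n_valid == 0
        assert extract_source_areas(masked) == []

    def test_noop_when_all_below_cap(self, small_grid):
        surf = self._surface(small_grid)
        dem = ElevationGrid(small_grid, np.full(small_grid.shape, 100.0))
        masked = apply_elevation_mask(surf, dem)
        assert masked.mask.all()
        np.testing.assert_array_equal(masked.scores, surf.scores)

    def test_boundary_inclusive_at_600(self, small_grid):
        surf = self._surface(small_grid)
        elev = np.full(small_grid.shape, 100.0)
        elev[0, 0] = 601.0
        elev[0, 1] = 600.0
        masked = apply_elevation_mask(surf, ElevationGrid(small_grid, elev))
        assert not masked.mask[0, 0]
        assert masked.mask[0, 1]
        assert masked.mask.sum() == masked.mask.size - 1

    def test_negative_elevation_masked(self, small_grid):
        surf = self._surface(small_grid)
        elev = np.full(small_grid.shape, 100.0)
        elev[2, 2] = -5.0
        masked = apply_elevation_mask(surf, ElevationGrid(small_grid, elev))
        assert not masked.mask[2, 2]

    def test_mask_count_matches_dem_band(self, small_grid):
        surf = self._surface(small_grid)
        rng = np.random.default_rng(0)
        elev = rng.uniform(-50, 900, size=small_grid.shape)
        masked = apply_elevation_mask(surf, ElevationGrid(small_grid, elev))
        outside = np.sum((elev < 0) | (elev > 600))
        assert masked.mask.size - masked.mask.sum() == outside

    def test_grid_mismatch_error(self, small_grid):
        surf = self._surface(small_grid)
        other = GridSpec(14.0, 14.05, 40.0, 40.05, 0.01)
        with pytest.raises(ValidationError, match="grid"):
            apply_elevation_mask(surf, ElevationGrid(other, np.zeros(other.shape)))


class TestSourceAreas:
    def test_single_dominant_peak(self, small_grid):
        scores = np.zeros(small_grid.shape)
        scores[2, 3] = 1.0
        surf_mask = np.ones(small_grid.shape, bool)
        from invasionscope.geo_profile import ScoreSurface

        areas = extract_source_areas(ScoreSurface(small_grid, scores, surf_mask))
        assert len(areas) == 1
        assert areas[0].rank == 1
        assert (2, 3) in areas[0].member_cells

    def test_tie_broken_lexicographically(self):
        from invasionscope.geo_profile import ScoreSurface

        grid = GridSpec(14.0, 14.9, 40.0, 40.9, 0.1)  # wide cells: peaks far apart
        scores = np.zeros(grid.shape)
        scores[1, 1] = scores[7, 7] = 1.0
        areas = extract_source_areas(
            ScoreSurface(grid, scores, np.ones(grid.shape, bool)),
            quantile_threshold=0.99,
            merge_radius_km=3.0,
        )
        assert len(areas) == 2
        assert areas[0].peak_score == areas[1].peak_score
        # equal peaks: rank 1 goes to the (row, col)-smaller peak
        assert grid.cell_of(areas[0].peak_lon, areas[0].peak_lat) == (1, 1)

    def test_nearby_peaks_merged(self):
        from invasionscope.geo_profile import ScoreSurface

        grid = GridSpec(14.0, 14.1, 40.0, 40.1, 0.01)  # ~0.85 km cells
        scores = np.zeros(grid.shape)
        scores[2, 2] = 1.0
        scores[2, 4] = 0.9  # ~1.7 km away, within the 3 km merge radius
        areas = extract_source_areas(
            ScoreSurface(grid, scores, np.ones(grid.shape, bool)), quantile_threshold=0.97
        )
        assert len(areas) == 1
        assert areas[0].peak_score == 1.0

    def test_three_source_simulation_recovers_all_peaks(self):
        sources = [(14.25, 40.55, 1.0), (14.55, 40.55, 0.7), (14.40, 40.80, 0.5)]
        grid = GridSpec(14.1, 14.7, 40.4, 40.95, 0.01)
        occ = gen_occurrences(120, sources=sources, scale_km=3.0, seed=7)
        occ = [o for o in occ if grid.contains(o.longitude, o.latitude)]
        # a sharper kernel separates the three modes before thresholding
        surf = bootstrap_profile(
            occ, grid, DragnetParams(decay_coefficient=3.0), BootstrapParams(seed=7)
        )
        areas = extract_source_areas(surf, quantile_threshold=0.90, merge_radius_km=3.0)
        assert len(areas) >= 3
        tol_km = 3 * grid.cell_size * 111.32  # three cell widths
        for slon, slat, _ in sources:
            d = min(
                haversine_distance(a.peak_lon, a.peak_lat, slon, slat) for a in areas
            )
            assert d <= tol_km


class TestModelResults:
    def test_fit_summary_and_peak(self, three_occurrences):
        model = GeographicProfile(three_occurrences, cell_size=0.01)
        res = model.fit(bootstrap=BootstrapParams(n_replicates=5, seed=1))
        text = res.summary()
        assert "Dragnet geographic profile" in text
        assert "bootstrap" in text
        lon, lat = res.peak()
        assert model.grid.contains(lon, lat)

    def test_from_dataframe_roundtrip(self, three_occurrences):
        import pandas as pd

        df = pd.DataFrame(
            {
                "site_id": [o.site_id for o in three_occurrences],
                "longitude": [o.longitude for o in three_occurrences],
                "latitude": [o.latitude for o in three_occurrences],
                "elevation_m": [o.elevation for o in three_occurrences],
                "site_type": [o.site_type for o in three_occurrences],
                "year": [o.year for o in three_occurrences],
                "infested": [o.infested for o in three_occurrences],
            }
        )
        model = GeographicProfile.from_dataframe(df, cell_size=0.01)
        assert len(model.occurrences) == 3

    def test_deterministic_fit_without_bootstrap(self, three_occurrences, small_grid):
        model = GeographicProfile(three_occurrences, grid=small_grid)
        res = model.fit(bootstrap=False)
        assert res.surface.provenance == "single-run"
        assert res.surface.scores.max() == 1.0
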