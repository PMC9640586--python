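"""Generator contracts: determinism, closed forms and parameter recovery."""

import numpy as np
import pytest

from invasionscope.geo_profile import GridSpec, haversine_distance
from invasionscope.haplotype_stats import collapse_haplotypes
from invasionscope.genetic_distances import p_distance
from invasionscope.synthetic_data import (
    SimulationConfig,
    gen_alignment,
    gen_dem,
    gen_fruit_records,
    gen_haplotype_samples,
    gen_occurrences,
    generate_bundle,
)

GRID = GridSpec(14.0, 14.5, 40.3, 40.9, 0.01)


class TestGenDem:
    def test_flat_surface_has_no_cells_above_cap(self):
        dem = gen_dem(GRID, base_elevation=100.0)
        assert np.all(dem.values == 100.0)
        assert np.sum(dem.values > 600.0) == 0

    def test_ridge_masked_fraction_matches_closed_form(self):
        base, amp, hw = 100.0, 900.0, 0.08
        ridge_lat = 40.6
        dem = gen_dem(
            GRID, base_elevation=base, ridge_amplitude=amp,
            ridge_lat=ridge_lat, ridge_halfwidth=hw,
        )
        # elev(lat) > 600 iff |lat - ridge_lat| < hw * (1 - (600-base)/amp)
        half_band = hw * (1 - (600.0 - base) / amp)
        expected_rows = sum(
            abs(GRID.cell_center(r, 0)[1] - ridge_lat) < half_band
            for r in range(GRID.n_rows)
        )
        observed_rows = np.sum((dem.values > 600.0).any(axis=1))
        assert abs(observed_rows - expected_rows) <= 1

    def test_seed_repeatability_with_noise(self):
        d1 = gen_dem(GRID, noise_sd=10.0, seed=3).values
        d2 = gen_dem(GRID, noise_sd=10.0, seed=3).values
        d3 = gen_dem(GRID, noise_sd=10.0, seed=4).values
        np.testing.assert_array_equal(d1, d2)
        assert not np.array_equal(d1, d3)


class TestGenOccurrences:
    SOURCE = (14.25, 40.6, 1.0)

    def test_zero_scale_places_points_at_source(self):
        occ = gen_occurrences(10, sources=[self.SOURCE], scale_km=1e-12, seed=0)
        for o in occ:
            assert haversine_distance(o.longitude, o.latitude, 14.25, 40.6) < 1e-6

    def test_mean_displacement_matches_kernel_mean(self):
        occ = gen_occurrences(2000, sources=[self.SOURCE], scale_km=5.0, seed=1)
        d = [haversine_distance(o.longitude, o.latitude, 14.25, 40.6) for o in occ]
        assert np.mean(d) == pytest.approx(5.0, rel=0.1)

    def test_elevation_cap_respected_via_resampling(self):
        dem = gen_dem(GRID, base_elevation=100.0, ridge_amplitude=900.0, ridge_lat=40.6)
        occ = gen_occurrences(
            80, sources=[self.SOURCE], scale_km=5.0, dem=dem, seed=2
        )
        assert len(occ) == 80  # resampling keeps n exact
        assert all(0 <= o.elevation <= 600.0 for o in occ)

    def test_determinism_and_unique_ids(self):
        a = gen_occurrences(25, sources=[self.SOURCE], seed=5)
        b = gen_occurrences(25, sources=[self.SOURCE], seed=5)
        assert [(o.longitude, o.latitude) for o in a] == [
            (o.longitude, o.latitude) for o in b
        ]
        assert len({o.site_id for o in a}) == 25

    def test_invalid_kernel(self):
        with pytest.raises(ValueError):
            gen_occurrences(5, kernel="levy")


class TestGenHaplotypes:
    def test_frequency_recovery_at_large_n(self):
        labels = gen_haplotype_samples((0.538, 0.462), n=10_000, seed=0)
        freq_a = labels.count("A") / len(labels)
        assert freq_a == pytest.approx(0.538, abs=0.015)

    def test_empty_and_determinism(self):
        assert gen_haplotype_samples(n=0, seed=1) == []
        assert gen_haplotype_samples(n=50, seed=7) == gen_haplotype_samples(n=50, seed=7)

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError):
            gen_haplotype_samples((0.6, 0.6), n=10)


class TestGenAlignment:
    def test_zero_divergence_gives_identical_sequences(self):
        aln = gen_alignment(
            length=120, groups={"a": 3, "b": 3},
            between_divergence=0.0, within_divergence=0.0, seed=0,
        )
        assert len({s.residues for s in aln}) == 1
        assert p_distance(aln[0], aln[-1]) == 0.0

    def test_haplotype_count_equals_variant_count(self):
        aln = gen_alignment(
            length=658, groups={"a": 10}, between_divergence=0.05,
            within_divergence=0.01, n_variants=2, seed=1,
        )
        assert len(collapse_haplotypes(aln)) == 2

    def test_between_group_divergence_hits_target(self):
        aln = gen_alignment(
            length=1448, groups={"a": 4, "b": 4},
            between_divergence=0.129, within_divergence=0.0062, seed=2,
        )
        cross = [
            p_distance(x, y)
            for x in aln if x.group == "a"
            for y in aln if y.group == "b"
        ]
        assert np.mean(cross) == pytest.approx(0.129, abs=0.01)

    def test_within_group_variant_distance(self):
        aln = gen_alignment(
            length=1000, groups={"a": 2}, between_divergence=0.1,
            within_divergence=0.01, n_variants=2, seed=3,
        )
        # two variants differ at 2 * round(0.01 * 1000 / 2) = 10 sites
        assert p_distance(aln[0], aln[1]) == pytest.approx(0.01, abs=0.001)

    def test_capacity_check(self):
        with pytest.raises(ValueError, match="sites"):
            gen_alignment(
                length=20, groups={f"g{i}": 1 for i in range(11)},
                between_divergence=0.25, within_divergence=0.0,
            )

    def test_determinism(self):
        a = gen_alignment(seed=9)
        b = gen_alignment(seed=9)
        assert [s.residues for s in a] == [s.residues for s in b]


class TestGenFruitRecords:
    def test_probability_zero_gives_all_clean(self):
        records = gen_fruit_records(
            category_probs={c: 0.0 for c in ("sorted", "unsorted", "discarded", "ground")},
            seed=0,
        )
        assert all(r.sap_beetle_count == 0 for r in records)

    def test_determinism(self):
        a = gen_fruit_records(seed=6)
        b = gen_fruit_records(seed=6)
        assert [(r.fruit_id, r.sap_beetle_count) for r in a] == [
            (r.fruit_id, r.sap_beetle_count) for r in b
        ]

    def test_infested_fruits_have_at_least_one_beetle(self):
        records = gen_fruit_records(seed=3)
        for r in records:
            if r.kernel_damaged:
                assert r.sap_beetle_count >= 1


class TestBundle:
    def test_end_to_end_bundle_feeds_every_stage(self):
        """A full synthetic bundle runs through profiling, masking, hotspot
        extraction, haplotype stats, distances and damage summaries."""
        from invasionscope import (
            GeographicProfile,
            BootstrapParams,
            collapse_haplotypes,
            group_distance_matrix,
            site_infestation_summary,
        )

        config = SimulationConfig(seed=123, n_occurrences=30)
        bundle = generate_bundle(config)
        res = GeographicProfile(bundle["occurrences"], grid=config.grid).fit(
            bootstrap=BootstrapParams(n_replicates=8, seed=123)
        )
        masked = res.apply_elevation_mask(bundle["dem"])
        assert masked.surface.n_valid > 0
        assert masked.source_areas()  # at least one candidate area
        table = collapse_haplotypes(
            [s for s in bundle["alignment"]]
        )
        assert table.total == len(bundle["alignment"])
        m = group_distance_matrix(bundle["alignment"], bootstrap_reps=20, seed=1)
        assert m.n_groups == 2
        s = site_infestation_summary(bundle["fruit_records"])
        assert s["n_sites"] == 20

    def test_bundle_deterministic(self):
        c = SimulationConfig(seed=77, n_occurrences=10)
        b1, b2 = generate_bundle(c), generate_bundle(c)
        np.testing.assert_array_equal(b1["dem"].values, b2["dem"].values)
        assert [o.longitude for o in b1["occurrences"]] == [
            o.longitude for o in b2["occurrences"]
        ]
        assert b1["haplotype_samples"] == b2["haplotype_samples"]
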