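import math

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from fractions import Fraction

from zooscankit.standardization import AllometricRegistry
from zooscankit.synthetic import (
    CommunityConfig,
    TaxonSpec,
    copepod_taxa,
    default_comau_community,
    expected_copepod_share,
    expected_counts,
    render_masks,
    sample_objects,
    synthetic_ctd_profile,
    with_dvm_amplitude,
    write_synthetic_ctd,
)


class TestDefaultCommunity:
    def test_standard_strata_and_taxon_count(self, community):
        assert community.strata == (0.0, 50.0, 100.0, 200.0, 300.0, 400.0, 450.0)
        assert len(community.taxa) >= 8

    def test_migrator_day_deep_night_shallow(self, community):
        mig = next(t for t in community.taxa if t.name == "Metridinidae")
        v_n = community.net_volumes()
        day_counts = np.asarray(mig.day_profile) * v_n
        night_counts = np.asarray(mig.night_profile) * v_n
        assert int(np.argmax(day_counts)) == 2  # 100-200 m
        assert int(np.argmax(night_counts)) == 0  # 0-50 m
        # roughly three quarters of the night population in the upper 50 m
        assert night_counts[0] / night_counts.sum() == pytest.approx(0.74, abs=0.03)

    def test_surface_and_deep_residents_present(self, community):
        cyclo = next(t for t in community.taxa if t.name == "Cyclopoida")
        assert int(np.argmax(cyclo.day_profile)) == 0
        mysid = next(t for t in community.taxa if t.name == "Mysida")
        v_n = community.net_volumes()
        deep = (np.asarray(mysid.day_profile) * v_n)[3:].sum()
        assert deep / (np.asarray(mysid.day_profile) * v_n).sum() > 0.8

    def test_copepod_share_in_observed_band(self, community):
        assert 0.64 <= expected_copepod_share(community) <= 0.81
        cops = set(copepod_taxa(community))
        for season in community.seasons:
            for diel in ("day", "night"):
                counts = expected_counts(community, season, diel)
                share = counts[counts.index.isin(cops)].sum() / counts.sum()
                assert 0.64 <= share <= 0.81


class TestSampleObjects:
    def test_zero_community_gives_empty_table(self):
        taxon = TaxonSpec(
            name="ghost",
            size_dist=(0.5, 0.3),
            ellipse_aspect=(0.4, 0.6),
            day_profile=(1e-12,) * 6,
            night_profile=(1e-12,) * 6,
            allometry_key="Copepoda",
        )
        cfg = CommunityConfig(taxa=(taxon,), junk_rate=0.0)
        objects, truth = sample_objects(cfg, "spring", "day", 1)
        assert objects.empty
        assert (truth.per_taxon["true_count"] == 0).all()

    def test_same_seed_identical_tables(self, community):
        a, _ = sample_objects(community, "summer", "night", 77)
        b, _ = sample_objects(community, "summer", "night", 77)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_labels_rejected(self, community):
        with pytest.raises(ValueError):
            sample_objects(community, "monsoon", "day", 1)
        with pytest.raises(ValueError):
            sample_objects(community, "spring", "dusk", 1)

    def test_thinning_unbiased_at_1_64(self):
        """Split 1/64 of an expected 6400-count net sample: the scaled
        count has mean 6400 (thinned mean 100) across seeds."""
        conc = 6400.0 / (math.pi * 0.35**2 * 50.0)
        taxon = TaxonSpec(
            name="Copepoda",
            size_dist=(0.5, 0.3),
            ellipse_aspect=(0.4, 0.6),
            day_profile=(conc, 0, 0, 0, 0, 0),
            night_profile=(conc, 0, 0, 0, 0, 0),
            allometry_key="Copepoda",
        )
        cfg = CommunityConfig(
            taxa=(taxon,),
            junk_rate=0.0,
            multi_object_rate=0.0,
            target_objects_per_scan=100,
        )
        thinned = []
        for seed in range(200):
            objects, truth = sample_objects(cfg, "spring", "day", seed)
            assert truth.samples["split_fraction"].iloc[0] == "1/64"
            thinned.append((objects["sample_id"] == "spring_day_000-050").sum())
        mean = np.mean(thinned)
        se = np.std(thinned, ddof=1) / np.sqrt(len(thinned))
        assert abs(mean - 100.0) <= 3 * se

    def test_areas_within_registry_range(self, community, registry):
        objects, _ = sample_objects(community, "spring", "night", 5)
        measured = objects[
            (objects["status"] == "validated") & objects["area_mm2"].notna()
        ]
        for taxon_cfg in community.taxa:
            lo, hi = registry.area_range(taxon_cfg.allometry_key)
            areas = measured.loc[measured["taxon"] == taxon_cfg.name, "area_mm2"]
            if len(areas):
                assert areas.min() >= lo and areas.max() <= hi

    def test_multi_object_rate_below_10pct(self, community):
        objects, _ = sample_objects(community, "spring", "day", 9)
        zoo = objects[objects["status"] == "validated"]
        assert zoo["multiple_flag"].mean() < 0.10
        assert zoo.loc[zoo["multiple_flag"], "area_mm2"].isna().all()

    def test_split_fractions_are_binary(self, community):
        _, truth = sample_objects(community, "spring", "day", 3)
        for s in truth.samples["split_fraction"]:
            frac = Fraction(s)
            assert frac.numerator == 1
            assert frac.denominator in {1, 2, 4, 8, 16, 32, 64}

    def test_dvm_amplitude_zero_equalizes_profiles(self, community):
        flat = with_dvm_amplitude(community, 0.0)
        for t in flat.taxa:
            assert t.night_profile == t.day_profile


class TestGroundTruth:
    def test_integrated_equals_stratum_weighted_sum(self, community):
        _, truth = sample_objects(community, "autumn", "day", 2)
        integ = truth.integrated_abundance(400.0)
        merged = truth.per_taxon.merge(truth.samples, on="sample_id")
        merged = merged[merged["stratum_bottom"] <= 400.0]
        manual = (
            merged["true_abundance_ind_m3"]
            * (merged["stratum_bottom"] - merged["stratum_top"])
        ).groupby(merged["taxon"]).sum()
        pd.testing.assert_series_equal(
            integ.sort_index(), manual.sort_index(), check_names=False
        )

    def test_truth_non_negative(self, community):
        _, truth = sample_objects(community, "winter", "night", 4)
        assert (truth.per_taxon["true_count"] >= 0).all()
        assert (truth.per_taxon["true_abundance_ind_m3"] >= 0).all()


class TestRenderMasks:
    def test_ellipse_pixel_area(self):
        objects = pd.DataFrame(
            {
                "object_id": ["o1"],
                "major_mm": [2.0],
                "minor_mm": [1.0],
            }
        )
        masks = render_masks(objects, pixel_scale=0.01)
        n_fg = masks["o1"].sum()
        assert n_fg == pytest.approx(math.pi * 100 * 50, rel=0.02)

    def test_circle_four_fold_symmetry(self):
        objects = pd.DataFrame(
            {"object_id": ["o1"], "major_mm": [1.0], "minor_mm": [1.0]}
        )
        mask = render_masks(objects, pixel_scale=0.01)["o1"]
        assert np.array_equal(mask, mask[::-1])
        assert np.array_equal(mask, mask[:, ::-1])
        assert mask.shape[0] == mask.shape[1]
        assert np.array_equal(mask, mask.T)

    def test_empty_table_empty_result(self):
        empty = pd.DataFrame(columns=["object_id", "major_mm", "minor_mm"])
        assert render_masks(empty) == {}

    def test_subpixel_axes_rejected(self):
        objects = pd.DataFrame(
            {"object_id": ["o1"], "major_mm": [0.01], "minor_mm": [0.005]}
        )
        with pytest.raises(ValueError):
            render_masks(objects, pixel_scale=0.01)


class TestSyntheticCtd:
    def test_spring_chlorophyll_peaks_above_25m(self):
        prof = synthetic_ctd_profile("spring", "day", seed=0)
        peak_depth = prof.loc[prof["chla_mg_m3"].idxmax(), "depth_m"]
        assert peak_depth < 25.0
        deep = prof[prof["depth_m"] > 25.0]["chla_mg_m3"]
        assert (deep < 1.8).all()

    def test_deep_temperature_stable_across_seasons(self):
        deep_means = []
        for season in ("spring", "summer", "autumn", "winter"):
            prof = synthetic_ctd_profile(season, "day", seed=0)
            deep_means.append(
                prof[prof["depth_m"] > 100.0]["temperature_C"].mean()
            )
        assert max(deep_means) - min(deep_means) < 1.0

    def test_deterministic_files(self, tmp_path):
        p1 = write_synthetic_ctd(tmp_path / "a", seed=5)
        p2 = write_synthetic_ctd(tmp_path / "b", seed=5)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()


class TestRecoveryConsistency:
    def test_scaled_counts_unbiased_for_every_split(self):
        """E[count/F] equals the Poisson mean regardless of split depth."""
        conc = 3200.0 / (math.pi * 0.35**2 * 50.0)
        taxon = TaxonSpec(
            name="Copepoda",
            size_dist=(0.5, 0.3),
            ellipse_aspect=(0.4, 0.6),
            day_profile=(conc, 0, 0, 0, 0, 0),
            night_profile=(conc, 0, 0, 0, 0, 0),
            allometry_key="Copepoda",
        )
        for target in (100, 400, 3200):  # forces different split depths
            cfg = CommunityConfig(
                taxa=(taxon,),
                junk_rate=0.0,
                multi_object_rate=0.0,
                target_objects_per_scan=target,
            )
            scaled = []
            for seed in range(150):
                objects, truth = sample_objects(cfg, "spring", "day", seed)
                f = float(Fraction(truth.samples["split_fraction"].iloc[0]))
                n = (objects["sample_id"] == "spring_day_000-050").sum()
                scaled.append(n / f)
            mean = np.mean(scaled)
            se = np.std(scaled, ddof=1) / np.sqrt(len(scaled))
            assert abs(mean - 3200.0) <= 3 * se
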