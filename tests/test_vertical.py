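import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from zooscankit import vertical as vt
from zooscankit.vertical import (
    DepthProfile,
    centroid_depth,
    chi_square_independence,
    depth_integrate,
    diel_cd_contrast,
    relative_composition,
    seasonal_diel_mean,
    simper,
)

STRATA6 = (0.0, 50.0, 100.0, 200.0, 300.0, 400.0, 450.0)
STRATA5 = (0.0, 50.0, 100.0, 200.0, 300.0, 400.0)


def _profile(values, strata=STRATA6, **kw):
    defaults = dict(taxon="t", season="spring", diel="day")
    defaults.update(kw)
    return DepthProfile(strata=strata, values=tuple(values), **defaults)


class TestDepthIntegrate:
    def test_uniform_concentration(self):
        prof = _profile([1.0] * 5, strata=STRATA5)
        assert depth_integrate(prof, 400.0) == pytest.approx(400.0)

    def test_worked_sum(self):
        prof = _profile([10, 2, 1, 1, 0.5], strata=STRATA5)
        assert depth_integrate(prof, 400.0) == pytest.approx(850.0)

    def test_deepest_stratum_dropped_whole(self):
        prof = _profile([1, 1, 1, 1, 1, 99])
        assert depth_integrate(prof, 400.0) == pytest.approx(400.0)

    def test_max_depth_inside_stratum_rejected(self):
        with pytest.raises(ValueError):
            depth_integrate(_profile([1] * 6), 375.0)

    @given(st.lists(st.floats(0, 100), min_size=6, max_size=6))
    @settings(max_examples=30, derandomize=True)
    def test_additive_over_taxa(self, values):
        """Integrating a community total equals summing per-taxon integrals."""
        a = _profile(values)
        b = _profile(values[::-1])
        total = _profile([x + y for x, y in zip(values, values[::-1])])
        assert depth_integrate(total) == pytest.approx(
            depth_integrate(a) + depth_integrate(b), rel=1e-12, abs=1e-12
        )


class TestCentroidDepth:
    def test_single_occupied_stratum(self):
        rec = centroid_depth(_profile([0, 0, 7, 0, 0, 0]))
        assert rec.cd_m == pytest.approx(150.0)

    def test_symmetric_extremes(self):
        rec = centroid_depth(_profile([5, 0, 0, 0, 0, 5]))
        assert rec.cd_m == pytest.approx(225.0)

    def test_weighted_mean(self):
        prof = _profile([10, 20, 30], strata=(0.0, 50.0, 100.0, 200.0))
        assert centroid_depth(prof).cd_m == pytest.approx(6250 / 60)

    def test_all_zero_flagged_undefined(self):
        rec = centroid_depth(_profile([0] * 6))
        assert not rec.defined and np.isnan(rec.cd_m)

    @given(
        st.lists(st.floats(0, 1000), min_size=6, max_size=6).filter(
            lambda v: sum(v) > 0
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_cd_bounded_by_mid_depths(self, values):
        rec = centroid_depth(_profile(values))
        assert 25.0 <= rec.cd_m <= 425.0


class TestChiSquare:
    def test_perfect_independence(self):
        stat, df, p = chi_square_independence([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_diagonal_table(self):
        # n(ad-bc)^2 / (r1 r2 c1 c2) = 40*(400)^2/20^4 = 40
        stat, df, _ = chi_square_independence([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)
        assert df == 1

    def test_df_formula_3x2(self):
        _, df, _ = chi_square_independence([[5, 6], [7, 8], [9, 10]])
        assert df == 2

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [5, 5]])


class TestDielContrast:
    def _records(self, day, night):
        taxa = [f"t{i}" for i in range(len(day))]
        return pd.DataFrame(
            {
                "taxon": taxa * 2,
                "diel": ["day"] * len(day) + ["night"] * len(night),
                "cd_m": list(day) + list(night),
            }
        )

    def test_identical_day_night_gives_zero(self):
        table, (stat, df, p) = diel_cd_contrast(
            self._records([150, 250, 75], [150, 250, 75])
        )
        assert stat == pytest.approx(0.0)
        assert df == 2

    def test_single_migrator_gives_positive_statistic(self):
        _, (stat, _, _) = diel_cd_contrast(
            self._records([150, 250, 75], [25, 250, 75])
        )
        assert stat > 0

    def test_unmatched_pairs_rejected(self):
        records = self._records([150, 250], [25, 250]).drop(index=[3])
        with pytest.raises(ValueError):
            diel_cd_contrast(records)


class TestSimper:
    def test_identical_samples_zero_dissimilarity(self):
        g = pd.DataFrame({"a": [1.0, 1.0], "b": [3.0, 3.0]})
        res = simper(g, g.copy())
        assert res.overall_dissimilarity == pytest.approx(0.0)
        assert (res.contributions["contribution"] == 0).all()

    def test_disjoint_single_pair(self):
        a = pd.DataFrame({"t1": [1.0], "t2": [0.0]})
        b = pd.DataFrame({"t1": [0.0], "t2": [1.0]})
        res = simper(a, b)
        assert res.overall_dissimilarity == pytest.approx(1.0)
        assert np.allclose(res.contributions["contribution"], [0.5, 0.5])

    @given(
        st.integers(2, 5),
        st.integers(2, 5),
        st.integers(2, 6),
        st.integers(0, 10_000),
    )
    @settings(max_examples=40, derandomize=True)
    def test_decomposition_identity(self, n_a, n_b, n_taxa, seed):
        """Σ per-taxon contributions equals the mean Bray–Curtis dissimilarity."""
        rng = np.random.default_rng(seed)
        cols = [f"t{i}" for i in range(n_taxa)]
        a = pd.DataFrame(rng.uniform(0.01, 10, (n_a, n_taxa)), columns=cols)
        b = pd.DataFrame(rng.uniform(0.01, 10, (n_b, n_taxa)), columns=cols)
        res = simper(a, b)
        bc = []
        for _, ra in a.iterrows():
            for _, rb in b.iterrows():
                bc.append(np.abs(ra - rb).sum() / (ra + rb).sum())
        assert res.overall_dissimilarity == pytest.approx(
            np.mean(bc), abs=1e-12
        )
        assert res.contributions["contribution"].sum() == pytest.approx(
            res.overall_dissimilarity, abs=1e-12
        )
        cum = res.contributions["cumulative_pct"].to_numpy()
        assert np.all(np.diff(cum) >= -1e-9)

    def test_cutoff_prefix_is_minimal(self):
        a = pd.DataFrame({"t1": [10.0], "t2": [1.0], "t3": [0.5]})
        b = pd.DataFrame({"t1": [0.0], "t2": [0.0], "t3": [0.0]})
        res = simper(a, b, cutoff=0.70)
        cum = res.contributions["cumulative_pct"]
        k = len(res.top_taxa)
        assert cum.iloc[k - 1] >= 70.0
        if k > 1:
            assert cum.iloc[k - 2] < 70.0

    def test_mismatched_taxa_or_empty_group_rejected(self):
        a = pd.DataFrame({"t1": [1.0]})
        with pytest.raises(ValueError):
            simper(a, pd.DataFrame({"t2": [1.0]}))
        with pytest.raises(ValueError):
            simper(a, pd.DataFrame(columns=["t1"]))


class TestRelativeComposition:
    def _conc(self, data):
        rows = []
        for sid, taxa in data.items():
            for taxon, ab in taxa.items():
                rows.append(
                    {
                        "sample_id": sid,
                        "taxon": taxon,
                        "abundance_ind_m3": ab,
                        "biovolume_mm3_m3": ab * 2,
                        "biomass_mg_m3": ab / 2,
                    }
                )
        return pd.DataFrame(rows)

    def test_single_taxon_is_100pct(self):
        out = relative_composition(self._conc({"s1": {"Copepoda": 5.0}}))
        assert out.loc["s1", "Copepoda"] == pytest.approx(100.0)

    def test_taxon_exactly_at_threshold_not_pooled(self):
        conc = self._conc({"s1": {"a": 97.0, "b": 3.0}})
        out = relative_composition(conc, pool_threshold=0.03)
        assert "b" in out.columns and "other" not in out.columns

    def test_rare_taxa_pooled_and_rows_sum_to_100(self):
        conc = self._conc(
            {"s1": {"a": 96.0, "b": 2.0, "c": 2.0}, "s2": {"a": 97.0, "b": 1.5, "c": 1.5}}
        )
        out = relative_composition(conc, pool_threshold=0.03)
        assert "other" in out.columns
        assert np.allclose(out.sum(axis=1), 100.0, atol=1e-9)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            relative_composition(self._conc({"s1": {"a": 1.0}}), metric="wetmass")


class TestSeasonalDielMean:
    @pytest.mark.parametrize(
        "day,night,expected",
        [
            (47894, 28198, 38046),
            (3108, 1216, 2162),
            (7.5, 7.5, 7.5),
        ],
    )
    def test_arithmetic_mean(self, day, night, expected):
        assert seasonal_diel_mean(day, night) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            seasonal_diel_mean(-1.0, 5.0)
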