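"""Vertical community structure: depth integration, centroid depths,
day/night contingency tests, SIMPER decomposition and composition summaries.

The centroid depth CD = Σ(p_k·z_k)/Σp_k (p_k: organisms in stratum k, z_k:
stratum mid-depth) condenses a vertical profile into one number; diel
vertical migration appears as a day-night CD offset.  SIMPER decomposes the
mean between-group Bray–Curtis dissimilarity into additive per-taxon
contributions, identifying which taxa drive day/night community differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DepthProfile:
    """Per-stratum values (abundance, biovolume or biomass) for one taxon
    and sampling event.  ``strata`` are the n+1 ordered boundaries (m)."""

    taxon: str
    season: str
    diel: str
    strata: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        bounds = np.asarray(self.strata, dtype=float)
        if np.any(np.diff(bounds) <= 0):
            raise ValueError("strata boundaries must be strictly increasing")
        vals = np.asarray(self.values, dtype=float)
        if len(vals) != len(bounds) - 1:
            raise ValueError("need one value per stratum")
        if np.any(vals < 0):
            raise ValueError("profile values must be non-negative")

    @property
    def mid_depths(self) -> np.ndarray:
        bounds = np.asarray(self.strata, dtype=float)
        return (bounds[:-1] + bounds[1:]) / 2.0

    @property
    def thickness(self) -> np.ndarray:
        return np.diff(np.asarray(self.strata, dtype=float))


@dataclass(frozen=True)
class CentroidDepthRecord:
    taxon: str
    season: str
    diel: str
    metric: str
    cd_m: float
    defined: bool = True


def depth_integrate(profile: DepthProfile, max_depth: float = 400.0) -> float:
    """Depth-integrated value (per m²) down to ``max_depth``.

    Σ value_k · thickness_k over strata lying fully above ``max_depth``;
    deeper strata are dropped whole (the deepest 50 m stratum of a 450 m
    design is excluded at the default 400 m), never pro-rated.
    ``max_depth`` must coincide with a stratum boundary.
    """
    bounds = np.asarray(profile.strata, dtype=float)
    if bounds[0] != 0:
        raise ValueError("strata must start at the surface (0 m)")
    if max_depth not in bounds:
        raise ValueError(
            f"max_depth {max_depth} m falls inside a stratum; boundaries are "
            f"{tuple(bounds)}"
        )
    keep = bounds[1:] <= max_depth
    vals = np.asarray(profile.values, dtype=float)
    return float((vals[keep] * profile.thickness[keep]).sum())


def centroid_depth(
    profile: DepthProfile, metric: str = "abundance"
) -> CentroidDepthRecord:
    """Weighted mean stratum mid-depth: CD = Σ(p_k·z_k)/Σp_k.

    An all-zero profile has no centroid; the record is returned flagged
    undefined with CD = NaN.
    """
    p = np.asarray(profile.values, dtype=float)
    total = p.sum()
    if total == 0:
        return CentroidDepthRecord(
            profile.taxon, profile.season, profile.diel, metric,
            float("nan"), defined=False,
        )
    cd = float((p * profile.mid_depths).sum() / total)
    return CentroidDepthRecord(
        profile.taxon, profile.season, profile.diel, metric, cd
    )


def chi_square_independence(
    table: np.ndarray,
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r×c table.

    No continuity correction; df = (r−1)(c−1).  Margins must be positive.
    Returns (statistic, df, p).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(table < 0):
        raise ValueError("cells must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero row or column margin")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def _default_cd_table(records: pd.DataFrame) -> np.ndarray:
    """Rows = taxa, columns = (day, night), cells = the CD values themselves.

    Treating centroid depths as the tabled quantities is statistically
    unconventional (they are not counts) but is the construction implied by
    pairing unreplicated day/night CDs in a contingency table.
    """
    pivot = records.pivot(index="taxon", columns="diel", values="cd_m")
    if not {"day", "night"} <= set(pivot.columns):
        raise ValueError("need both day and night records")
    pivot = pivot[["day", "night"]]
    if pivot.isna().any().any():
        raise ValueError("unmatched day/night pairs or undefined CDs present")
    return pivot.to_numpy()


def diel_cd_contrast(
    records: pd.DataFrame, table_builder=_default_cd_table
) -> tuple[np.ndarray, tuple[float, int, float]]:
    """Chi-square contrast of day vs night centroid depths across taxa.

    ``records`` needs columns ``taxon``, ``diel`` and ``cd_m`` with matched
    day/night rows for at least two taxa.  The contingency-table construction
    is pluggable; the default tabulates the CD values directly.
    Returns the table and the (statistic, df, p) triple.
    """
    n_taxa = records["taxon"].nunique()
    if n_taxa < 2:
        raise ValueError("need matched day/night CDs for at least two taxa")
    table = table_builder(records)
    return table, chi_square_independence(table)


@dataclass
class SimperResult:
    """Per-taxon decomposition of mean between-group Bray–Curtis dissimilarity.

    ``contributions`` is sorted descending with columns ``taxon``,
    ``contribution`` (additive share of the overall mean dissimilarity),
    ``contribution_pct`` and ``cumulative_pct``; ``top_taxa`` is the minimal
    prefix reaching the cumulative cutoff.
    """

    contributions: pd.DataFrame
    overall_dissimilarity: float
    cutoff: float
    top_taxa: list[str]


def simper(
    group_a: pd.DataFrame, group_b: pd.DataFrame, cutoff: float = 0.70
) -> SimperResult:
    """Similarity-percentage (SIMPER) analysis between two sample groups.

    Both groups are samples × taxa tables of non-negative values over the
    same taxon set.  For every between-group pair (j, k) the per-taxon
    contribution is |y_ij − y_ik| / Σ_i (y_ij + y_ik); contributions are
    averaged over all pairs, so they sum exactly to the mean Bray–Curtis
    dissimilarity.
    """
    if group_a.empty or group_b.empty:
        raise ValueError("both groups must contain at least one sample")
    if list(group_a.columns) != list(group_b.columns):
        raise ValueError("groups must share an identical taxon set")
    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("values must be non-negative")

    # pairwise |diff| and totals: (n_a, n_b, taxa)
    diff = np.abs(a[:, None, :] - b[None, :, :])
    denom = (a[:, None, :] + b[None, :, :]).sum(axis=2, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("a between-group pair has zero total; Bray–Curtis undefined")
    contrib = (diff / denom).mean(axis=(0, 1))

    order = np.argsort(-contrib, kind="stable")
    taxa = np.asarray(group_a.columns)[order]
    sorted_contrib = contrib[order]
    overall = float(contrib.sum())
    if overall > 0:
        pct = 100.0 * sorted_contrib / overall
    else:
        pct = np.zeros_like(sorted_contrib)
    cum = np.cumsum(pct)
    table = pd.DataFrame(
        {
            "taxon": taxa,
            "contribution": sorted_contrib,
            "contribution_pct": pct,
            "cumulative_pct": cum,
        }
    )
    if overall > 0:
        n_top = int(np.searchsorted(cum, 100.0 * cutoff - 1e-12) + 1)
        n_top = min(n_top, len(taxa))
    else:
        n_top = 0
    return SimperResult(
        contributions=table,
        overall_dissimilarity=overall,
        cutoff=cutoff,
        top_taxa=list(taxa[:n_top]),
    )


def relative_composition(
    conc: pd.DataFrame,
    metric: str = "abundance",
    pool_threshold: float = 0.03,
) -> pd.DataFrame:
    """Per-sample percentage composition with rare taxa pooled as "other".

    ``metric`` selects the column (abundance, biovolume or biomass).  A taxon
    is pooled when its share of the dataset-wide total is strictly below
    ``pool_threshold`` (a taxon at exactly the threshold is kept).  Each
    sample's percentages sum to 100.
    """
    col = {
        "abundance": "abundance_ind_m3",
        "biovolume": "biovolume_mm3_m3",
        "biomass": "biomass_mg_m3",
    }.get(metric)
    if col is None:
        raise ValueError(f"metric must be abundance|biovolume|biomass, got {metric!r}")
    wide = conc.pivot_table(
        index="sample_id", columns="taxon", values=col, aggfunc="sum", fill_value=0.0
    )
    totals = wide.to_numpy().sum()
    if totals <= 0:
        raise ValueError("all values are zero")
    share = wide.sum(axis=0) / totals
    rare = share.index[share < pool_threshold]
    if len(rare) > 0:
        pooled = wide[rare].sum(axis=1)
        wide = wide.drop(columns=rare)
        wide["other"] = wide.get("other", 0.0) + pooled
    sample_tot = wide.sum(axis=1)
    if (sample_tot == 0).any():
        bad = sample_tot.index[sample_tot == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    return 100.0 * wide.div(sample_tot, axis=0)


def seasonal_diel_mean(day_value: float, night_value: float) -> float:
    """Arithmetic day/night mean of an integrated quantity (unrounded)."""
    if day_value < 0 or night_value < 0:
        raise ValueError("integrated values must be non-negative")
    return (day_value + night_value) / 2.0


def round_half_even(value: float, ndigits: int = 0) -> float:
    """Display rounding (banker's) for tabulated seasonal means."""
    return float(np.round(value, ndigits))
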