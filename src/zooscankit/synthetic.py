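"""Synthetic fjord zooplankton communities with known ground truth.

Emulates the whole observation chain of a stratified-net / scanner study:
a multi-taxon community with taxon-specific lognormal body-size
distributions and stratum-resolved day/night abundance profiles is
"sampled" by a closing net (Poisson counts around profile × filtered
volume), subsampled with a binary plankton splitter (binomial thinning to
1, 1/2, …, 1/64), and emitted as an EcoTaxa-export-style object table with
a small fraction of multi-object vignettes and non-zooplankton objects.
Matching CTD casts (temperature, salinity, oxygen, pH, chlorophyll-a) are
generated per sampling event.

The Poisson-count / binomial-thinning model keeps recovery standard errors
available in closed form: a thinned count m ~ Poisson(λF), so the scaled-up
estimate m/F has variance λ/F.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .standardization import SampleMeta, net_sample_volume

SEASONS = ("spring", "summer", "autumn", "winter")
DIELS = ("day", "night")

#: Standard stratum boundaries (m) of the deep-fjord sampling design.
STANDARD_STRATA = (0.0, 50.0, 100.0, 200.0, 300.0, 400.0, 450.0)

#: Scan resolution: 2400 dpi = 25.4/2400 mm per pixel.
DEFAULT_PIXEL_SCALE = 25.4 / 2400.0

#: Body area (mm²) whose equivalent circular diameter equals the 0.3 mm
#: scanner detection limit; generated organisms are sized above it so that
#: the detection filter does not bias ground-truth recovery.
_DETECTION_AREA_MM2 = math.pi * 0.15**2

JUNK_LABELS = ("detritus", "feces", "fiber", "leg", "bubble", "other")

CTD_COLUMNS = (
    "depth_m",
    "temperature_C",
    "salinity_psu",
    "oxygen_umol_kg",
    "pH",
    "chla_mg_m3",
)


@dataclass(frozen=True)
class TaxonSpec:
    """One synthetic taxon: size distribution, shape, and vertical habits.

    ``size_dist`` holds (median area mm², lognormal sigma); ``ellipse_aspect``
    the (low, high) bounds of the uniform minor/major aspect-ratio draw;
    ``day_profile`` / ``night_profile`` the per-stratum concentrations
    (ind m⁻³) before the seasonal multiplier.
    """

    name: str
    size_dist: tuple[float, float]
    ellipse_aspect: tuple[float, float]
    day_profile: tuple[float, ...]
    night_profile: tuple[float, ...]
    seasonal_multiplier: dict[str, float] = field(default_factory=dict)
    allometry_key: str | None = None

    def __post_init__(self) -> None:
        lo, hi = self.ellipse_aspect
        if not (0 < lo <= hi <= 1):
            raise ValueError("aspect-ratio bounds must satisfy 0 < lo <= hi <= 1")
        for prof in (self.day_profile, self.night_profile):
            arr = np.asarray(prof, dtype=float)
            if np.any(arr < 0) or arr.sum() <= 0:
                raise ValueError("profiles must be non-negative with positive sum")
        if len(self.day_profile) != len(self.night_profile):
            raise ValueError("day and night profiles must have equal length")
        if any(m < 0 for m in self.seasonal_multiplier.values()):
            raise ValueError("seasonal multipliers must be >= 0")

    def multiplier(self, season: str) -> float:
        return self.seasonal_multiplier.get(season, 1.0)


@dataclass(frozen=True)
class CommunityConfig:
    """Full specification of a synthetic community and its sampling design."""

    taxa: tuple[TaxonSpec, ...]
    strata: tuple[float, ...] = STANDARD_STRATA
    seasons: tuple[str, ...] = SEASONS
    net_diameter: float = 0.7
    split_exponent_range: tuple[int, int] = (0, 6)
    target_objects_per_scan: int = 1000
    multi_object_rate: float = 0.05
    junk_rate: float = 0.08
    bad_focus_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        bounds = np.asarray(self.strata, dtype=float)
        if bounds[0] != 0 or np.any(np.diff(bounds) <= 0):
            raise ValueError("strata must increase strictly from 0")
        n_strata = len(bounds) - 1
        for t in self.taxa:
            if len(t.day_profile) != n_strata:
                raise ValueError(
                    f"taxon {t.name!r} profile length {len(t.day_profile)} "
                    f"!= number of strata {n_strata}"
                )
        k_lo, k_hi = self.split_exponent_range
        if not (0 <= k_lo <= k_hi <= 6):
            raise ValueError("split exponents must lie in 0..6")
        if not (0 <= self.multi_object_rate < 0.10):
            raise ValueError("multi_object_rate must be in [0, 0.10)")
        if not (0 <= self.junk_rate < 1):
            raise ValueError("junk_rate must be in [0, 1)")

    @property
    def n_strata(self) -> int:
        return len(self.strata) - 1

    @property
    def stratum_thickness(self) -> np.ndarray:
        return np.diff(np.asarray(self.strata, dtype=float))

    @property
    def stratum_mid_depths(self) -> np.ndarray:
        bounds = np.asarray(self.strata, dtype=float)
        return (bounds[:-1] + bounds[1:]) / 2.0

    def net_volumes(self) -> np.ndarray:
        """Filtered volume (m³) per stratum for a 100%-efficient haul."""
        return (
            math.pi * (self.net_diameter / 2.0) ** 2 * self.stratum_thickness
        )


@dataclass
class GroundTruth:
    """Model truth recorded alongside a generated sampling event.

    ``per_taxon`` has one row per sample (stratum) × taxon with the realized
    net count (``true_count``), the model concentration (``true_abundance``,
    ind m⁻³ — the Poisson mean divided by the filtered volume) and the mean
    generated individual volume.  ``samples`` carries the haul metadata
    including the split fraction applied to each scan.
    """

    samples: pd.DataFrame
    per_taxon: pd.DataFrame
    strata: tuple[float, ...]

    def integrated_abundance(self, max_depth: float = 400.0) -> pd.Series:
        """True depth-integrated abundance (ind m⁻²) per taxon.

        Sums concentration × stratum thickness over strata lying fully above
        ``max_depth``.
        """
        bounds = np.asarray(self.strata)
        merged = self.per_taxon.merge(
            self.samples[["sample_id", "stratum_top", "stratum_bottom"]],
            on="sample_id",
        )
        keep = merged["stratum_bottom"] <= max_depth
        merged = merged[keep]
        thickness = merged["stratum_bottom"] - merged["stratum_top"]
        return (
            (merged["true_abundance_ind_m3"] * thickness)
            .groupby(merged["taxon"])
            .sum()
        )

    def integrated_standard_error(self, max_depth: float = 400.0) -> pd.Series:
        """Closed-form SE of the pipeline's integrated-abundance estimate.

        Each stratum contributes variance λ_k / F_k scaled to areal units,
        where λ_k is the Poisson mean count and F_k the split fraction
        (thinned count ~ Poisson(λ_k F_k), estimate = count/F_k/V_N·t_k).
        """
        merged = self.per_taxon.merge(
            self.samples[
                [
                    "sample_id",
                    "stratum_top",
                    "stratum_bottom",
                    "split_fraction",
                    "net_volume_m3",
                ]
            ],
            on="sample_id",
        )
        merged = merged[merged["stratum_bottom"] <= max_depth].copy()
        thickness = merged["stratum_bottom"] - merged["stratum_top"]
        f = merged["split_fraction"].map(lambda s: float(Fraction(s)))
        v_n = merged["net_volume_m3"]
        lam = merged["true_abundance_ind_m3"] * v_n
        var = lam / f * (thickness / v_n) ** 2
        return np.sqrt(var.groupby(merged["taxon"]).sum())


def _lognorm_params(median: float, sigma: float) -> tuple[float, float]:
    return math.log(median), sigma


def _truncated_lognormal(
    rng: np.random.Generator, n: int, median: float, sigma: float,
    lo: float, hi: float,
) -> np.ndarray:
    """Draw body areas from a lognormal restricted to [lo, hi] (mm²)."""
    mu, s = _lognorm_params(median, sigma)
    a = stats.norm.cdf((math.log(lo) - mu) / s)
    b = stats.norm.cdf((math.log(hi) - mu) / s)
    u = rng.uniform(a, b, size=n)
    return np.exp(mu + s * stats.norm.ppf(u))


# --- default community -----------------------------------------------------

def _t(name, median, sigma, aspect, day, night, mult, key="Copepoda"):
    return TaxonSpec(
        name=name,
        size_dist=(median, sigma),
        ellipse_aspect=aspect,
        day_profile=tuple(day),
        night_profile=tuple(night),
        seasonal_multiplier=mult,
        allometry_key=key,
    )


def default_comau_community(seed: int = 0) -> CommunityConfig:
    """Default deep-fjord community emulating a copepod-dominated assemblage.

    Eleven taxa over the six standard strata (0-50-100-200-300-400-450 m):
    seven copepod groups jointly contributing roughly three quarters of the
    expected abundance, one strong diel migrator (Metridinidae-like: daytime
    maximum at 100–200 m, ~74% of the night population in the upper 50 m),
    small surface residents (Cyclopoida-like), and a deep-resident large
    taxon (mysids).  Abundance peaks in spring, as after a phytoplankton
    bloom; body-size distributions are unchanged across seasons.
    """
    cop_mult = {"spring": 1.6, "summer": 0.65, "autumn": 0.36, "winter": 0.44}
    taxa = (
        _t("Cyclopoida", 0.18, 0.35, (0.35, 0.60),
           (22, 6, 1.5, 0.8, 0.4, 0.3), (19, 7, 2.0, 0.8, 0.4, 0.3), cop_mult),
        _t("Harpacticoida", 0.16, 0.35, (0.30, 0.55),
           (18, 9, 6, 4.5, 4, 3), (16, 9, 6, 4.5, 4, 3), cop_mult),
        _t("Calanoida (<1.5 mm)", 0.25, 0.35, (0.35, 0.60),
           (16, 6, 2.5, 1.2, 0.6, 0.4), (15, 6, 3.0, 1.2, 0.6, 0.4), cop_mult),
        _t("Copepoda (nauplii)", 0.12, 0.25, (0.50, 0.75),
           (14, 3, 1.0, 0.4, 0.25, 0.2), (12, 3, 1.0, 0.4, 0.25, 0.2),
           {"spring": 2.0, "summer": 0.5, "autumn": 0.25, "winter": 0.65}),
        _t("Metridinidae", 0.70, 0.35, (0.30, 0.50),
           (2, 3, 12, 4, 1, 0.5), (32, 4, 2, 1, 0.5, 0.3),
           {"spring": 1.05, "summer": 0.95, "autumn": 0.8, "winter": 0.32}),
        _t("Calanidae", 1.10, 0.35, (0.30, 0.50),
           (1, 2, 6, 5, 1, 0.5), (12, 3, 3, 2, 1, 0.5),
           {"spring": 1.1, "summer": 0.65, "autumn": 0.48, "winter": 0.28}),
        _t("Euchaetidae", 1.60, 0.35, (0.28, 0.45),
           (0.3, 0.5, 2, 3, 2, 1), (4, 1, 2, 2, 1.5, 0.8),
           {"spring": 0.95, "summer": 0.55, "autumn": 0.4, "winter": 0.4}),
        _t("Chaetognatha", 1.80, 0.50, (0.08, 0.16),
           (4, 1, 1.5, 1, 0.5, 0.3), (5, 1, 1.5, 1, 0.5, 0.3),
           {"spring": 2.5, "summer": 2.0, "autumn": 1.0, "winter": 0.85},
           key="Chaetognatha"),
        _t("Cnidaria", 2.50, 0.60, (0.60, 0.90),
           (1.5, 0.5, 0.5, 0.8, 0.5, 0.3), (2, 0.5, 0.5, 0.6, 0.4, 0.3),
           {"spring": 2.0, "summer": 1.35, "autumn": 0.85, "winter": 2.2},
           key="Cnidaria"),
        _t("Mysida", 7.0, 0.45, (0.25, 0.40),
           (0.1, 0.15, 0.3, 1.2, 1.5, 1.0), (0.4, 0.25, 0.4, 1.0, 1.3, 0.9),
           {"spring": 1.7, "summer": 0.85, "autumn": 2.0, "winter": 1.7},
           key="Mysidacea"),
        _t("Appendicularia", 0.30, 0.40, (0.40, 0.70),
           (6, 2, 1, 0.5, 0.3, 0.2), (5, 2, 1, 0.5, 0.3, 0.2),
           {"spring": 3.0, "summer": 1.7, "autumn": 0.85, "winter": 1.0},
           key="Appendicularia"),
    )
    return CommunityConfig(taxa=taxa, seed=seed)


def copepod_taxa(config: CommunityConfig) -> list[str]:
    """Names of taxa sharing the Copepoda allometric coefficients."""
    return [t.name for t in config.taxa if t.allometry_key == "Copepoda"]


def expected_counts(
    config: CommunityConfig, season: str, diel: str
) -> pd.Series:
    """Expected whole-net counts per taxon for one sampling event.

    Σ_k profile_k · multiplier(season) · V_N,k over strata; this is the
    Poisson mean of the unthinned count.
    """
    _check_labels(config, season, diel)
    v_n = config.net_volumes()
    out = {}
    for t in config.taxa:
        prof = np.asarray(
            t.day_profile if diel == "day" else t.night_profile, dtype=float
        )
        out[t.name] = float((prof * t.multiplier(season) * v_n).sum())
    return pd.Series(out)


def expected_copepod_share(config: CommunityConfig) -> float:
    """Expected fraction of total abundance contributed by copepod taxa,
    pooled over all seasons and both diel phases."""
    cops = set(copepod_taxa(config))
    tot = 0.0
    cop = 0.0
    for season in config.seasons:
        for diel in DIELS:
            counts = expected_counts(config, season, diel)
            tot += counts.sum()
            cop += counts[counts.index.isin(cops)].sum()
    return cop / tot


def with_dvm_amplitude(
    config: CommunityConfig, amplitude: float
) -> CommunityConfig:
    """Scale the diel signal: night profile ← day + amplitude·(night − day).

    amplitude 1 leaves the community unchanged; 0 removes all diel vertical
    migration (night ≡ day), isolating sampling noise in day/night
    comparisons.
    """
    taxa = []
    for t in config.taxa:
        day = np.asarray(t.day_profile, dtype=float)
        night = np.asarray(t.night_profile, dtype=float)
        new_night = np.clip(day + amplitude * (night - day), 0.0, None)
        taxa.append(replace(t, night_profile=tuple(new_night)))
    return replace(config, taxa=tuple(taxa))


def _check_labels(config: CommunityConfig, season: str, diel: str) -> None:
    if season not in config.seasons:
        raise ValueError(f"unknown season {season!r}; expected {config.seasons}")
    if diel not in DIELS:
        raise ValueError(f"unknown diel phase {diel!r}; expected {DIELS}")


def _format_fraction(frac: Fraction) -> str:
    return "1" if frac.denominator == 1 else f"1/{frac.denominator}"


def _split_exponent(config: CommunityConfig, expected_total: float) -> int:
    """Binary splitting steps needed to keep a scan near the target load."""
    k_lo, k_hi = config.split_exponent_range
    if expected_total <= config.target_objects_per_scan:
        k = 0
    else:
        k = math.ceil(math.log2(expected_total / config.target_objects_per_scan))
    return int(np.clip(k, k_lo, k_hi))


def sample_objects(
    config: CommunityConfig, season: str, diel: str, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one sampling event (all strata) and emit the object table.

    Per stratum and taxon the net count is Poisson around
    profile × multiplier × V_N; the scanned subsample is a binomial thinning
    by the stratum's split fraction.  Each retained organism gets a body
    area from the taxon's truncated lognormal, an aspect ratio, the implied
    ellipse axes, and may be flagged as part of a multi-object vignette
    (axes unmeasurable → missing).  Junk objects (detritus etc.) are
    appended per the configured rate.  Identical seeds give identical
    output.
    """
    _check_labels(config, season, diel)
    rng = np.random.default_rng([int(seed) % (2**31), config.seed % (2**31)])
    bounds = np.asarray(config.strata, dtype=float)
    v_n = config.net_volumes()

    sample_rows = []
    truth_rows = []
    obj_rows = []

    for k in range(config.n_strata):
        top, bottom = bounds[k], bounds[k + 1]
        sample_id = f"{season}_{diel}_{int(top):03d}-{int(bottom):03d}"
        lam = np.array(
            [
                (t.day_profile if diel == "day" else t.night_profile)[k]
                * t.multiplier(season)
                * v_n[k]
                for t in config.taxa
            ]
        )
        split_k = _split_exponent(config, float(lam.sum()))
        frac = Fraction(1, 2**split_k)
        f = float(frac)
        sample_rows.append(
            {
                "sample_id": sample_id,
                "season": season,
                "diel": diel,
                "stratum_top": top,
                "stratum_bottom": bottom,
                "net_diameter": config.net_diameter,
                "net_volume_m3": v_n[k],
                "split_fraction": _format_fraction(frac),
            }
        )

        counter = 0
        for t, lam_t in zip(config.taxa, lam):
            true_count = int(rng.poisson(lam_t))
            thinned = int(rng.binomial(true_count, f)) if true_count else 0

            mean_vol = np.nan
            if thinned > 0:
                median, sigma = t.size_dist
                if t.allometry_key is not None:
                    from .standardization import AllometricRegistry

                    lo, hi = AllometricRegistry.default().area_range(
                        t.allometry_key
                    )
                    lo = max(lo, _DETECTION_AREA_MM2 * 1.002)
                else:
                    lo, hi = _DETECTION_AREA_MM2 * 1.002, 500.0
                areas = _truncated_lognormal(rng, thinned, median, sigma, lo, hi)
                aspects = rng.uniform(*t.ellipse_aspect, size=thinned)
                major = 2.0 * np.sqrt(areas / (math.pi * aspects))
                minor = aspects * major
                volumes = (4 / 3) * math.pi * (major / 2) * (minor / 2) ** 2
                mean_vol = float(volumes.mean())
                multi = rng.random(thinned) < config.multi_object_rate
                bad = rng.random(thinned) < config.bad_focus_rate
                for i in range(thinned):
                    status = "bad_focus" if bad[i] else "validated"
                    obj_rows.append(
                        {
                            "object_id": f"{sample_id}_obj{counter:05d}",
                            "sample_id": sample_id,
                            "taxon": t.name,
                            "area_mm2": np.nan if multi[i] else areas[i],
                            "major_mm": np.nan if multi[i] else major[i],
                            "minor_mm": np.nan if multi[i] else minor[i],
                            "split_fraction": _format_fraction(frac),
                            "status": status,
                            "multiple_flag": bool(multi[i]),
                        }
                    )
                    counter += 1

            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "taxon": t.name,
                    "true_count": true_count,
                    "true_abundance_ind_m3": lam_t / v_n[k],
                    "true_mean_volume_mm3": mean_vol,
                }
            )

        # non-zooplankton objects at the configured rate of the scan load
        n_real = counter
        if config.junk_rate > 0 and n_real > 0:
            n_junk = int(
                rng.poisson(n_real * config.junk_rate / (1 - config.junk_rate))
            )
            if n_junk:
                labels = rng.choice(JUNK_LABELS, size=n_junk)
                areas = np.exp(rng.normal(math.log(0.3), 0.8, size=n_junk))
                aspects = rng.uniform(0.2, 0.95, size=n_junk)
                major = 2.0 * np.sqrt(areas / (math.pi * aspects))
                for i in range(n_junk):
                    obj_rows.append(
                        {
                            "object_id": f"{sample_id}_obj{counter:05d}",
                            "sample_id": sample_id,
                            "taxon": str(labels[i]),
                            "area_mm2": areas[i],
                            "major_mm": major[i],
                            "minor_mm": aspects[i] * major[i],
                            "split_fraction": _format_fraction(frac),
                            "status": "junk_category",
                            "multiple_flag": False,
                        }
                    )
                    counter += 1

    columns = [
        "object_id",
        "sample_id",
        "taxon",
        "area_mm2",
        "major_mm",
        "minor_mm",
        "split_fraction",
        "status",
        "multiple_flag",
    ]
    objects = pd.DataFrame(obj_rows, columns=columns)
    truth = GroundTruth(
        samples=pd.DataFrame(sample_rows),
        per_taxon=pd.DataFrame(truth_rows),
        strata=tuple(config.strata),
    )
    return objects, truth


def sample_metadata(truth: GroundTruth) -> list[SampleMeta]:
    """Haul metadata objects for each sample of a generated event."""
    metas = []
    for _, row in truth.samples.iterrows():
        metas.append(
            SampleMeta(
                sample_id=row["sample_id"],
                season=row["season"],
                diel=row["diel"],
                stratum_top=float(row["stratum_top"]),
                stratum_bottom=float(row["stratum_bottom"]),
                net_diameter=float(row["net_diameter"]),
                split_fraction=Fraction(row["split_fraction"]),
            )
        )
    return metas


def render_masks(
    objects: pd.DataFrame,
    pixel_scale: float = DEFAULT_PIXEL_SCALE,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Rasterize each measured object as a filled-ellipse binary mask.

    Returns object_id → uint8 mask (axis-aligned ellipse with the object's
    axes at the given scale).  Objects whose axes are unmeasured
    (multi-object vignettes) are skipped; axes smaller than 2 px raise.
    """
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    from skimage.draw import ellipse as draw_ellipse

    masks: dict[str, np.ndarray] = {}
    for _, row in objects.iterrows():
        major, minor = row["major_mm"], row["minor_mm"]
        if pd.isna(major) or pd.isna(minor):
            continue
        a_px = major / (2.0 * pixel_scale)
        b_px = minor / (2.0 * pixel_scale)
        if 2 * b_px < 2 or 2 * a_px < 2:
            raise ValueError(
                f"object {row['object_id']}: axes below 2 px at scale "
                f"{pixel_scale} mm/px"
            )
        # odd-sized grid centred on a pixel keeps rasterized discs symmetric
        pad = 2
        h = 2 * (int(math.ceil(b_px)) + pad) + 1
        w = 2 * (int(math.ceil(a_px)) + pad) + 1
        mask = np.zeros((h, w), dtype=np.uint8)
        rr, cc = draw_ellipse(h // 2, w // 2, b_px, a_px, shape=mask.shape)
        mask[rr, cc] = 1
        masks[str(row["object_id"])] = mask
    return masks


# --- CTD -------------------------------------------------------------------

_CTD_SEASON_PARAMS = {
    # surface_T, deep_T, surf_salinity, surf_O2, chla_peak, peak_depth, width
    "spring": dict(t_surf=10.5, t_deep=11.3, s_surf=16.0, o2_surf=330.0,
                   chla_peak=30.0, chla_z=3.0, chla_w=6.0),
    "summer": dict(t_surf=16.7, t_deep=11.5, s_surf=20.0, o2_surf=260.0,
                   chla_peak=6.0, chla_z=8.0, chla_w=8.0),
    "autumn": dict(t_surf=12.0, t_deep=11.4, s_surf=24.0, o2_surf=230.0,
                   chla_peak=2.5, chla_z=10.0, chla_w=8.0),
    "winter": dict(t_surf=8.6, t_deep=11.35, s_surf=22.0, o2_surf=240.0,
                   chla_peak=2.5, chla_z=8.0, chla_w=7.0),
}


def synthetic_ctd_profile(
    season: str, diel: str = "day", seed: int = 0, max_depth: float = 450.0
) -> pd.DataFrame:
    """One synthetic CTD cast: variable surface layer over stable deep water.

    Surface temperature spans 8.6–16.7 °C across seasons while deep water
    stays near 11.4 °C; salinity rises from a brackish surface lens to a
    33-ish deep value; chlorophyll-a peaks in the upper 25 m with a strong
    spring maximum.  Deterministic per (season, diel, seed).
    """
    if season not in _CTD_SEASON_PARAMS:
        raise ValueError(f"unknown season {season!r}")
    p = _CTD_SEASON_PARAMS[season]
    si = list(_CTD_SEASON_PARAMS).index(season)
    di = DIELS.index(diel)
    rng = np.random.default_rng([int(seed) % (2**31), si, di])
    z = np.arange(1.0, max_depth + 1.0)

    temp = p["t_deep"] + (p["t_surf"] - p["t_deep"]) * np.exp(-z / 15.0)
    sal = 32.9 - (32.9 - p["s_surf"]) * np.exp(-z / 8.0)
    o2 = 180.0 + (p["o2_surf"] - 180.0) * np.exp(-z / 30.0)
    ph = 7.9 + 0.2 * np.exp(-z / 25.0)
    chla = p["chla_peak"] * np.exp(
        -((z - p["chla_z"]) ** 2) / (2 * p["chla_w"] ** 2)
    ) + 0.3 * np.exp(-z / 100.0)

    temp = temp + rng.normal(0, 0.02, z.size)
    sal = sal + rng.normal(0, 0.02, z.size)
    o2 = o2 + rng.normal(0, 1.0, z.size)
    ph = ph + rng.normal(0, 0.005, z.size)
    chla = np.clip(chla + rng.normal(0, 0.02, z.size), 0.0, None)

    return pd.DataFrame(
        {
            "depth_m": z,
            "temperature_C": temp,
            "salinity_psu": sal,
            "oxygen_umol_kg": o2,
            "pH": ph,
            "chla_mg_m3": chla,
        }
    )


def write_synthetic_ctd(
    out_dir: str | Path,
    seasons: tuple[str, ...] = SEASONS,
    diels: tuple[str, ...] = DIELS,
    seed: int = 0,
) -> dict[tuple[str, str], Path]:
    """Write one CTD CSV per sampling event; returns (season, diel) → path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for season in seasons:
        for diel in diels:
            prof = synthetic_ctd_profile(season, diel, seed=seed)
            path = out_dir / f"ctd_{season}_{diel}.csv"
            prof.to_csv(path, index=False, float_format="%.6f")
            paths[(season, diel)] = path
    return paths
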