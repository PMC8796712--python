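"""Standardization of counted and measured objects into concentrations.

Counts and per-object sums from a scanned subsample are scaled up by the
binary split fraction F, normalised by the volume of water filtered by the
net haul, and converted to three community currencies:

* abundance     (individuals m⁻³)  = (n / F) / V_N
* biovolume     (mm³ m⁻³)          = (ΣV / F) / V_N
* biomass       (mg dry mass m⁻³)  = (ΣDM / F) / V_N

Individual dry mass comes from the taxon-specific allometric regression
DM (µg) = a·A^b on scanned body area A (mm²); the µg→mg conversion sits
between the regression and the biomass formula.  Members of multi-object
vignettes are counted but cannot be measured; they contribute the mean
per-individual volume / dry mass of their taxon (same-sample mean, falling
back to a dataset-wide mean).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources

import numpy as np
import pandas as pd

ALLOWED_SPLIT_FRACTIONS = tuple(Fraction(1, 2**k) for k in range(7))

#: Object-table categories that are not zooplankton and are excluded from all
#: per-taxon metrics.
NON_TAXON_CATEGORIES = frozenset(
    {"detritus", "feces", "fiber", "leg", "bubble", "other"}
)

#: Label groups mapped onto the allometric registry's coefficient rows.  The
#: registry lists coarse groups; scan classifications are often finer (copepod
#: families, orders) and share their group's coefficients.
_REGISTRY_ALIASES = {
    "Copepoda": (
        "Copepoda (nauplii)",
        "Calanoida (<1.5 mm)",
        "Calanoida",
        "Calanidae",
        "Metridinidae",
        "Euchaetidae",
        "Cyclopoida",
        "Harpacticoida",
        "Oithonidae",
        "Oncaeidae",
        "Clausocalanidae",
        "copepodites",
    ),
    "Mysidacea": ("Mysida",),
    "Decapoda (zoea)": ("Decapoda", "Decapoda (larvae)"),
    "Gastropoda (larvae)": ("Gastropoda", "Mollusca (larvae)"),
    "Echinodermata": ("Echinodermata (larvae)",),
}


_DEFAULT_REGISTRY = None


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one closing-net haul stratum (one scanned sample)."""

    sample_id: str
    season: str
    diel: str
    stratum_top: float
    stratum_bottom: float
    net_diameter: float = 0.7
    filtration_efficiency: float = 1.0
    split_fraction: Fraction = Fraction(1)

    def __post_init__(self) -> None:
        if not (self.stratum_bottom > self.stratum_top >= 0):
            raise ValueError("require stratum_bottom > stratum_top >= 0")
        if self.net_diameter <= 0:
            raise ValueError("net_diameter must be positive")
        if not (0 < self.filtration_efficiency <= 1):
            raise ValueError("filtration_efficiency must be in (0, 1]")
        if Fraction(self.split_fraction) not in ALLOWED_SPLIT_FRACTIONS:
            raise ValueError(
                f"split_fraction must be 2^-k, k in 0..6; got {self.split_fraction}"
            )


class AllometricRegistry:
    """Taxon → (a, b, valid area range) for the dry-mass regression DM = a·A^b.

    ``a`` is in µg·mm^(−2b), ``b`` dimensionless, and the area range (mm²)
    delimits the body sizes over which each coefficient pair was calibrated.
    The default registry ships as a CSV with 23 organism categories; most use
    the generic crustacean-like pair (a = 43.38, b = 1.54), with specific
    pairs for Copepoda, Chaetognatha and the watery-bodied Cnidaria.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"taxon", "a", "b", "area_min_mm2", "area_max_mm2"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"registry table missing columns: {sorted(missing)}")
        if (table["a"] <= 0).any() or (table["b"] <= 0).any():
            raise ValueError("registry coefficients must be positive")
        self._table = table.set_index("taxon")
        self._alias = {}
        for key, names in _REGISTRY_ALIASES.items():
            if key in self._table.index:
                for name in names:
                    self._alias[name] = key

    @classmethod
    def default(cls) -> "AllometricRegistry":
        global _DEFAULT_REGISTRY
        if _DEFAULT_REGISTRY is None:
            path = resources.files("zooscankit.data").joinpath("allometry.csv")
            with resources.as_file(path) as p:
                _DEFAULT_REGISTRY = cls(pd.read_csv(p))
        return _DEFAULT_REGISTRY

    @property
    def table(self) -> pd.DataFrame:
        return self._table.reset_index()

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._table.index or taxon in self._alias

    def resolve(self, taxon: str) -> str:
        """Map an object-table label to its registry row name."""
        if taxon in self._table.index:
            return taxon
        if taxon in self._alias:
            return self._alias[taxon]
        raise KeyError(f"taxon {taxon!r} not in allometric registry")

    def coefficients(self, taxon: str) -> tuple[float, float]:
        row = self._table.loc[self.resolve(taxon)]
        return float(row["a"]), float(row["b"])

    def area_range(self, taxon: str) -> tuple[float, float]:
        row = self._table.loc[self.resolve(taxon)]
        return float(row["area_min_mm2"]), float(row["area_max_mm2"])


def net_sample_volume(meta: SampleMeta) -> float:
    """Volume of water (m³) filtered by a vertical haul over one stratum.

    V_N = π · (net diameter / 2)² · depth interval · filtration efficiency.
    Filtration efficiency defaults to the theoretical 1 (no flowmeter
    correction).
    """
    interval = meta.stratum_bottom - meta.stratum_top
    return (
        math.pi
        * (meta.net_diameter / 2.0) ** 2
        * interval
        * meta.filtration_efficiency
    )


def scale_by_split(value, split_fraction) -> float:
    """Scale a subsample count or sum up to the whole sample: value / F."""
    frac = Fraction(split_fraction)
    if frac not in ALLOWED_SPLIT_FRACTIONS:
        raise ValueError(f"split fraction must be 2^-k, k in 0..6; got {split_fraction}")
    return value / float(frac)


def dry_mass(
    taxon: str, area: float, registry: AllometricRegistry | None = None
) -> float:
    """Individual dry mass (µg) from body area (mm²): DM = a·A^b.

    Warns (without failing) when the area lies outside the calibrated range
    of the taxon's coefficients.
    """
    if registry is None:
        registry = AllometricRegistry.default()
    area_arr = np.asarray(area, dtype=float)
    if np.any(area_arr <= 0):
        raise ValueError("area must be positive")
    a, b = registry.coefficients(taxon)
    lo, hi = registry.area_range(taxon)
    if np.any((area_arr < lo) | (area_arr > hi)):
        warnings.warn(
            f"area outside the calibrated range [{lo}, {hi}] mm² for {taxon!r}",
            RuntimeWarning,
            stacklevel=2,
        )
    out = a * area_arr**b
    return float(out) if out.ndim == 0 else out


def concentrations(
    objects: pd.DataFrame,
    meta: SampleMeta,
    registry: AllometricRegistry | None = None,
    *,
    global_means: pd.DataFrame | None = None,
    include_bad_focus: bool = False,
) -> pd.DataFrame:
    """Per-taxon abundance, biovolume and biomass for one sample.

    Parameters
    ----------
    objects
        Object table rows for this sample, already passed through the
        detection-limit filter.  Needs columns ``taxon``, ``area_mm2``,
        ``major_mm``, ``minor_mm``, ``status``, ``multiple_flag``.
    meta
        Haul metadata; supplies the split fraction and net geometry.
    registry
        Allometric coefficients; defaults to the packaged registry.
    global_means
        Optional dataset-wide per-taxon means (columns ``mean_volume_mm3``,
        ``mean_dm_ug`` indexed by taxon) used as fallback when a taxon has
        only unmeasured (multi-vignette) objects in this sample.
    include_bad_focus
        If False (default), objects with status ``bad_focus`` are excluded
        from per-taxon metrics.

    Returns
    -------
    DataFrame with one row per taxon: ``sample_id, taxon, abundance_ind_m3,
    biovolume_mm3_m3, biomass_mg_m3, n_objects_measured,
    n_objects_substituted``.
    """
    if registry is None:
        registry = AllometricRegistry.default()
    v_n = net_sample_volume(meta)
    f = float(Fraction(meta.split_fraction))

    df = objects.copy()
    df = df[~df["taxon"].isin(NON_TAXON_CATEGORIES)]
    df = df[df["status"] != "junk_category"]
    if not include_bad_focus:
        df = df[df["status"] != "bad_focus"]

    if df.empty:
        return pd.DataFrame(
            columns=[
                "sample_id",
                "taxon",
                "abundance_ind_m3",
                "biovolume_mm3_m3",
                "biomass_mg_m3",
                "n_objects_measured",
                "n_objects_substituted",
            ]
        )

    major = df["major_mm"].to_numpy(dtype=float)
    minor = df["minor_mm"].to_numpy(dtype=float)
    area = df["area_mm2"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        df["_volume"] = (4.0 / 3.0) * np.pi * (major / 2.0) * (minor / 2.0) ** 2
    dm = np.full(len(df), np.nan)
    for taxon in df["taxon"].unique():
        sel = (df["taxon"] == taxon).to_numpy()
        a, b = registry.coefficients(taxon)
        with np.errstate(invalid="ignore"):
            dm[sel] = a * area[sel] ** b
    df["_dm_ug"] = dm

    measured = df["_volume"].notna() & df["_dm_ug"].notna()
    rows = []
    for taxon, grp in df.groupby("taxon", sort=True):
        m = grp[measured.loc[grp.index]]
        n_meas = len(m)
        n_sub = len(grp) - n_meas
        sum_v = m["_volume"].sum()
        sum_dm = m["_dm_ug"].sum()
        if n_sub > 0:
            if n_meas > 0:
                mean_v = m["_volume"].mean()
                mean_dm = m["_dm_ug"].mean()
            elif global_means is not None and taxon in global_means.index:
                mean_v = float(global_means.loc[taxon, "mean_volume_mm3"])
                mean_dm = float(global_means.loc[taxon, "mean_dm_ug"])
            else:
                raise ValueError(
                    f"taxon {taxon!r} has only unmeasured objects and no "
                    "mean volume/dry mass is available for substitution"
                )
            sum_v += n_sub * mean_v
            sum_dm += n_sub * mean_dm
        n = len(grp)
        rows.append(
            {
                "sample_id": meta.sample_id,
                "taxon": taxon,
                "abundance_ind_m3": (n / f) / v_n,
                "biovolume_mm3_m3": (sum_v / f) / v_n,
                "biomass_mg_m3": ((sum_dm / 1000.0) / f) / v_n,
                "n_objects_measured": n_meas,
                "n_objects_substituted": n_sub,
            }
        )
    return pd.DataFrame(rows)


def dataset_mean_sizes(
    objects: pd.DataFrame, registry: AllometricRegistry | None = None
) -> pd.DataFrame:
    """Dataset-wide per-taxon mean volume (mm³) and dry mass (µg).

    Used as the substitution fallback for samples where a taxon occurs only
    in multi-object vignettes.
    """
    if registry is None:
        registry = AllometricRegistry.default()
    df = objects[~objects["taxon"].isin(NON_TAXON_CATEGORIES)].copy()
    major = df["major_mm"].to_numpy(dtype=float)
    minor = df["minor_mm"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        df["_volume"] = (4.0 / 3.0) * np.pi * (major / 2.0) * (minor / 2.0) ** 2
    dm = np.full(len(df), np.nan)
    area = df["area_mm2"].to_numpy(dtype=float)
    for taxon in df["taxon"].unique():
        sel = (df["taxon"] == taxon).to_numpy()
        try:
            a, b = registry.coefficients(taxon)
        except KeyError:
            continue
        with np.errstate(invalid="ignore"):
            dm[sel] = a * area[sel] ** b
    df["_dm_ug"] = dm
    out = (
        df.dropna(subset=["_volume", "_dm_ug"])
        .groupby("taxon")[["_volume", "_dm_ug"]]
        .mean()
        .rename(columns={"_volume": "mean_volume_mm3", "_dm_ug": "mean_dm_ug"})
    )
    return out
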