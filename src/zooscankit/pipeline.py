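"""End-to-end orchestration: generate → measure → standardize → analyze.

These helpers wire the stage modules together for the common case of a
synthetic study (all seasons, day and night); the command-line interface is
a thin wrapper around them, and they are what the property-based tests run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import morphometrics, ordination, standardization, synthetic, vertical
from .io import RunConfig
from .standardization import AllometricRegistry
from .synthetic import CommunityConfig, DIELS, GroundTruth
from .vertical import DepthProfile


def _event_seed(base_seed: int, season_idx: int, diel_idx: int) -> int:
    return (base_seed * 64 + season_idx * 8 + diel_idx + 1) % (2**31)


@dataclass
class EventResult:
    """One sampling event after standardization."""

    season: str
    diel: str
    objects: pd.DataFrame
    truth: GroundTruth
    concentrations: pd.DataFrame
    n_below_detection: int


@dataclass
class StudyResult:
    """All events of a synthetic study plus the derived analyses."""

    events: list[EventResult]
    concentrations: pd.DataFrame
    integrated: pd.DataFrame
    centroid_depths: pd.DataFrame
    diel_tests: dict
    simper: dict
    rda: ordination.RDAResult | None = None
    rda_permutation: ordination.PermutationTestResult | None = None


def process_event(
    config: CommunityConfig,
    season: str,
    diel: str,
    seed: int,
    run: RunConfig | None = None,
    registry: AllometricRegistry | None = None,
) -> EventResult:
    """Generate one event and push it through measurement + standardization."""
    run = run or RunConfig()
    registry = registry or AllometricRegistry.default()
    objects, truth = synthetic.sample_objects(config, season, diel, seed)
    filtered, n_removed = morphometrics.apply_detection_limit(
        objects, measure=run.detection_measure
    )
    global_means = standardization.dataset_mean_sizes(filtered, registry)
    metas = synthetic.sample_metadata(truth)
    conc_parts = []
    for meta in metas:
        sub = filtered[filtered["sample_id"] == meta.sample_id]
        if sub.empty:
            continue
        conc_parts.append(
            standardization.concentrations(
                sub,
                meta,
                registry,
                global_means=global_means,
                include_bad_focus=run.include_bad_focus,
            )
        )
    conc = (
        pd.concat(conc_parts, ignore_index=True)
        if conc_parts
        else pd.DataFrame(
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
    )
    conc.insert(0, "season", season)
    conc.insert(1, "diel", diel)
    return EventResult(season, diel, objects, truth, conc, n_removed)


def event_profiles(
    event: EventResult, config: CommunityConfig, metric_col: str
) -> dict[str, DepthProfile]:
    """Per-taxon vertical profiles (one value per stratum) for one event."""
    strata = tuple(config.strata)
    bounds = np.asarray(strata)
    sample_order = event.truth.samples.set_index("sample_id")
    profiles = {}
    for taxon, grp in event.concentrations.groupby("taxon"):
        values = np.zeros(len(bounds) - 1)
        for _, row in grp.iterrows():
            top = sample_order.loc[row["sample_id"], "stratum_top"]
            k = int(np.searchsorted(bounds, top, side="left"))
            values[k] = row[metric_col]
        profiles[taxon] = DepthProfile(
            taxon=taxon,
            season=event.season,
            diel=event.diel,
            strata=strata,
            values=tuple(values),
        )
    return profiles


def run_study(
    config: CommunityConfig,
    run: RunConfig | None = None,
    seasons: tuple[str, ...] | None = None,
    with_rda: bool = True,
    n_perm: int | None = None,
) -> StudyResult:
    """Run the full analysis over all seasons and both diel phases."""
    run = run or RunConfig()
    seasons = seasons or config.seasons
    registry = AllometricRegistry.default()

    events: list[EventResult] = []
    for si, season in enumerate(seasons):
        for di, diel in enumerate(DIELS):
            seed = _event_seed(run.seed, si, di)
            events.append(process_event(config, season, diel, seed, run, registry))

    conc = pd.concat([e.concentrations for e in events], ignore_index=True)

    # depth-integrated values per event × taxon
    integ_rows = []
    cd_rows = []
    for e in events:
        for metric, col in (
            ("abundance", "abundance_ind_m3"),
            ("biovolume", "biovolume_mm3_m3"),
            ("biomass", "biomass_mg_m3"),
        ):
            profiles = event_profiles(e, config, col)
            for taxon, prof in profiles.items():
                if metric == "abundance":
                    integ_rows.append(
                        {
                            "season": e.season,
                            "diel": e.diel,
                            "taxon": taxon,
                            "integrated_ind_m2": vertical.depth_integrate(
                                prof, run.max_integration_depth
                            ),
                        }
                    )
                if metric in ("abundance", "biovolume"):
                    rec = vertical.centroid_depth(prof, metric)
                    cd_rows.append(
                        {
                            "season": e.season,
                            "diel": e.diel,
                            "taxon": taxon,
                            "metric": metric,
                            "cd_m": rec.cd_m,
                            "defined": rec.defined,
                        }
                    )
    integrated = pd.DataFrame(integ_rows)
    cds = pd.DataFrame(cd_rows)

    # per-season diel CD contrast (abundance CDs) and SIMPER on day vs night
    diel_tests = {}
    simper_results = {}
    for season in seasons:
        sub = cds[
            (cds["season"] == season)
            & (cds["metric"] == "abundance")
            & cds["defined"]
        ]
        counts = sub.groupby("taxon")["diel"].nunique()
        paired = counts.index[counts == 2]
        sub = sub[sub["taxon"].isin(paired)]
        if sub["taxon"].nunique() >= 2:
            table, test = vertical.diel_cd_contrast(
                sub[["taxon", "diel", "cd_m"]]
            )
            diel_tests[season] = {
                "table": table,
                "statistic": test[0],
                "df": test[1],
                "p": test[2],
            }
        season_conc = conc[conc["season"] == season]
        day = season_conc[season_conc["diel"] == "day"].pivot_table(
            index="sample_id", columns="taxon", values="abundance_ind_m3",
            aggfunc="sum", fill_value=0.0,
        )
        night = season_conc[season_conc["diel"] == "night"].pivot_table(
            index="sample_id", columns="taxon", values="abundance_ind_m3",
            aggfunc="sum", fill_value=0.0,
        )
        taxa = sorted(set(day.columns) | set(night.columns))
        day = day.reindex(columns=taxa, fill_value=0.0)
        night = night.reindex(columns=taxa, fill_value=0.0)
        if not day.empty and not night.empty:
            simper_results[season] = vertical.simper(
                day, night, cutoff=run.simper_cutoff
            )

    rda_result = None
    perm_result = None
    if with_rda:
        ctd = {
            (season, diel): synthetic.synthetic_ctd_profile(
                season, diel, seed=run.seed
            )
            for season in seasons
            for diel in DIELS
        }
        inp = ordination.prepare_matrices(
            conc,
            ctd,
            sample_events=pd.concat(
                [e.truth.samples for e in events], ignore_index=True
            )[["sample_id", "season", "diel", "stratum_top", "stratum_bottom"]],
            predictor_scope=run.predictor_scope,
            log_base=run.log_base,
        )
        rda_result = ordination.rda_fit(inp)
        perm_result = ordination.permutation_test(
            inp, n_perm=n_perm or run.n_permutations, seed=run.seed
        )

    return StudyResult(
        events=events,
        concentrations=conc,
        integrated=integrated,
        centroid_depths=cds,
        diel_tests=diel_tests,
        simper=simper_results,
        rda=rda_result,
        rda_permutation=perm_result,
    )
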