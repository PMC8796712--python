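"""Redundancy analysis (RDA) of taxon abundances on environmental variables.

RDA regresses a multivariate response Y (here log-transformed abundances,
column-centred) on a predictor matrix X (column-centred water-column means of
temperature, salinity, oxygen and log chlorophyll-a) and eigen-decomposes the
fitted values: the constrained variance fraction is trace(ŶᵀŶ)/trace(YᵀY),
the constrained axes are the principal components of Ŷ.  Significance is
assessed with a permutation test on the pseudo-F statistic

    F = (SS_constrained / q) / (SS_residual / (n − q − 1)),

permuting rows of Y (unrestricted), with the add-one p-value convention
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_PREDICTORS = ("temperature_C", "salinity_psu", "oxygen_umol_kg", "chla_mg_m3")


@dataclass
class OrdinationInput:
    """Centred response and predictor matrices plus sample annotations."""

    Y: pd.DataFrame
    X: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.Y) != len(self.X):
            raise ValueError("Y and X must have equal row counts")
        if self.Y.isna().any().any() or self.X.isna().any().any():
            raise ValueError("missing cells are not allowed")


@dataclass
class RDAResult:
    constrained_fraction: float
    axis_fractions: np.ndarray
    eigenvalues: np.ndarray
    site_scores: np.ndarray
    species_scores: np.ndarray
    biplot_scores: np.ndarray
    total_variance: float
    constrained_ss: float
    residual_ss: float
    rank_x: int


@dataclass
class PermutationTestResult:
    observed_f: float
    n_perm: int
    p_value: float
    seed: int


def prepare_matrices(
    conc: pd.DataFrame,
    ctd_profiles: dict,
    *,
    metric: str = "abundance",
    sample_events: pd.DataFrame | None = None,
    predictor_scope: str = "cast_mean",
    log_base: float = np.e,
) -> OrdinationInput:
    """Assemble response and predictor matrices from concentrations and CTD.

    ``conc`` is a tidy concentration table (``sample_id``, ``taxon`` and the
    metric columns); ``ctd_profiles`` maps (season, diel) → CTD DataFrame.
    ``sample_events`` maps sample_id → season, diel, stratum_top,
    stratum_bottom (required so each sample finds its cast); when omitted it
    is parsed from sample ids of the form ``season_diel_top-bottom``.

    The response is log(x+1)-transformed abundances (configurable base);
    predictors are whole-water-column means per cast (``cast_mean``) or
    per-stratum means (``stratum_mean``), with chlorophyll-a log(x+1)
    transformed.  Both matrices are column-centred.
    """
    col = {
        "abundance": "abundance_ind_m3",
        "biovolume": "biovolume_mm3_m3",
        "biomass": "biomass_mg_m3",
    }[metric]
    wide = conc.pivot_table(
        index="sample_id", columns="taxon", values=col, aggfunc="sum", fill_value=0.0
    )
    Y = np.log1p(wide) / np.log(log_base)

    if sample_events is None:
        parts = [sid.split("_") for sid in wide.index]
        if not all(len(p) == 3 for p in parts):
            raise ValueError("cannot parse sample ids; provide sample_events")
        sample_events = pd.DataFrame(
            {
                "sample_id": wide.index,
                "season": [p[0] for p in parts],
                "diel": [p[1] for p in parts],
                "stratum_top": [float(p[2].split("-")[0]) for p in parts],
                "stratum_bottom": [float(p[2].split("-")[1]) for p in parts],
            }
        )
    events = sample_events.set_index("sample_id").loc[wide.index]

    rows = []
    for sid, ev in events.iterrows():
        key = (ev["season"], ev["diel"])
        if key not in ctd_profiles:
            raise KeyError(f"missing CTD cast for sampling event {key}")
        prof = ctd_profiles[key]
        if predictor_scope == "cast_mean":
            sel = prof
        elif predictor_scope == "stratum_mean":
            sel = prof[
                (prof["depth_m"] >= ev["stratum_top"])
                & (prof["depth_m"] <= ev["stratum_bottom"])
            ]
        else:
            raise ValueError(f"unknown predictor_scope {predictor_scope!r}")
        means = sel[list(_PREDICTORS)].mean()
        rows.append(
            {
                "sample_id": sid,
                "temperature_C": means["temperature_C"],
                "salinity_psu": means["salinity_psu"],
                "oxygen_umol_kg": means["oxygen_umol_kg"],
                "log_chla": np.log1p(means["chla_mg_m3"]) / np.log(log_base),
            }
        )
    X = pd.DataFrame(rows).set_index("sample_id")

    # degenerate predictors carry no information and break the projection
    stds = X.std(axis=0, ddof=0)
    if (stds < 1e-12).any():
        bad = stds.index[stds < 1e-12].tolist()
        raise ValueError(f"constant/degenerate predictor column(s): {bad}")

    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    return OrdinationInput(Y=Yc, X=Xc, annotations=events.reset_index())


def rda_fit(inp: OrdinationInput) -> RDAResult:
    """Fit the redundancy analysis by least squares + eigendecomposition.

    Ŷ is the projection of (centred) Y onto the column space of (centred) X;
    the constrained axes are the right singular vectors of Ŷ, with axis
    variance fractions S_i²/trace(YᵀY).  Site scores are the constrained
    sample scores (linear-combination scores) U·S; species scores the
    response loadings V; biplot scores the correlations of predictors with
    the site scores.
    """
    Y = np.asarray(inp.Y, dtype=float)
    X = np.asarray(inp.X, dtype=float)
    n, p = Y.shape
    Y = Y - Y.mean(axis=0)
    X = X - X.mean(axis=0)
    q = np.linalg.matrix_rank(X)
    if q < X.shape[1]:
        raise np.linalg.LinAlgError(
            "predictor matrix is rank-deficient (collinear columns)"
        )
    if n < X.shape[1] + 2:
        raise ValueError("need at least predictors + 2 samples")

    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    Yhat = X @ coef
    total_ss = float((Y**2).sum())
    constrained_ss = float((Yhat**2).sum())
    residual_ss = float(((Y - Yhat) ** 2).sum())

    U, S, Vt = np.linalg.svd(Yhat, full_matrices=False)
    n_axes = min(q, p)
    U, S, Vt = U[:, :n_axes], S[:n_axes], Vt[:n_axes]
    eigenvalues = S**2 / (n - 1)
    axis_fractions = S**2 / total_ss if total_ss > 0 else np.zeros_like(S)

    site_scores = U * S
    species_scores = Vt.T
    # correlation of each predictor with each constrained axis
    biplot = np.zeros((X.shape[1], n_axes))
    for j in range(X.shape[1]):
        xj = X[:, j]
        for i in range(n_axes):
            si = site_scores[:, i]
            denom = xj.std() * si.std()
            biplot[j, i] = (
                np.mean((xj - xj.mean()) * (si - si.mean())) / denom
                if denom > 0
                else 0.0
            )

    return RDAResult(
        constrained_fraction=constrained_ss / total_ss if total_ss > 0 else 0.0,
        axis_fractions=axis_fractions,
        eigenvalues=eigenvalues,
        site_scores=site_scores,
        species_scores=species_scores,
        biplot_scores=biplot,
        total_variance=total_ss,
        constrained_ss=constrained_ss,
        residual_ss=residual_ss,
        rank_x=int(q),
    )


def pseudo_f(
    Y: np.ndarray, qr_q: np.ndarray, q_rank: int
) -> float:
    """Pseudo-F from a centred response and the thin-QR basis of X."""
    n = Y.shape[0]
    total = (Y**2).sum()
    fitted = (qr_q.T @ Y) ** 2
    ss_c = fitted.sum()
    ss_res = max(total - ss_c, 0.0)
    if ss_res == 0.0:  # noise-free response: F is unbounded
        return np.inf
    return (ss_c / q_rank) / (ss_res / (n - q_rank - 1))


def permutation_test(
    inp: OrdinationInput, n_perm: int = 10_000, seed: int = 0
) -> PermutationTestResult:
    """Permutation test of the constrained fraction via the pseudo-F statistic.

    Rows of Y are permuted without restriction; the p-value uses the add-one
    convention so it is never exactly 0.  Reproducible per seed.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    Y = np.asarray(inp.Y, dtype=float)
    X = np.asarray(inp.X, dtype=float)
    n = Y.shape[0]
    Y = Y - Y.mean(axis=0)
    X = X - X.mean(axis=0)
    q_rank = int(np.linalg.matrix_rank(X))
    if q_rank == 0 or n - q_rank - 1 <= 0:
        raise ValueError("sample size too small to permute")
    qr_q, _ = np.linalg.qr(X)
    qr_q = qr_q[:, :q_rank]

    f_obs = pseudo_f(Y, qr_q, q_rank)
    rng = np.random.default_rng(int(seed) % (2**31))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        # re-centring is unnecessary: permutation preserves column means
        if pseudo_f(Y[perm], qr_q, q_rank) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermutationTestResult(
        observed_f=float(f_obs), n_perm=n_perm, p_value=float(p), seed=seed
    )
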