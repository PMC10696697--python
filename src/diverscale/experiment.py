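"""Parameter sweeps and the statistical analysis of diversity continuity.

A quasi-random Sobol design covers the six-parameter biological space;
each draw runs one simulation, whose metrics are collected into a table.
Runs with too few extant species are filtered out, continuity columns
are added, and the analysis fits:

* per-facet simple regressions of species-level on population-level
  diversity (gamma and beta; everything log-transformed except species
  MPD),
* per-facet multiple regressions of continuity on the six biological
  parameters, reduced by bidirectional stepwise selection on AIC,
* Spearman rank correlations between continuity and clade properties
  with Bonferroni-multiplied p-values, and a scaled PCA of the clade
  properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import qmc
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .engine import SimulationParams, run_simulation
from .landscape import Landscape
from .metrics import FACETS, add_continuity_columns, compute_metrics_row

__all__ = [
    "PARAMETER_RANGES",
    "sobol_design",
    "run_ensemble_and_filter",
    "EnsembleResult",
    "stepwise_aic",
    "fit_continuity_models",
    "correlate_clade_properties",
    "AnalysisResult",
]

#: explored ranges of the six varied biological parameters
PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "initial_abundance": (0.11, 1.0),
    "thermal_optimum": (17.0, 31.4),
    "dispersal_scale": (100.0, 5000.0),
    "speciation_threshold": (12, 600),
    "mutation_sd": (0.01, 0.15),
    "niche_width": (0.02, 0.50),
}

PARAM_NAMES = tuple(PARAMETER_RANGES)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def sobol_design(
    n: int,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ``n`` parameter combinations from a scrambled Sobol sequence.

    Each column is scaled into its range; the speciation threshold is
    rounded to an integer count of timesteps.  Deterministic given
    ``seed``; inverted ranges raise ``ValueError``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(PARAMETER_RANGES if ranges is None else ranges)
    for name, (lo, hi) in ranges.items():
        if not lo < hi:
            raise ValueError(f"inverted range for {name}: ({lo}, {hi})")
    sampler = qmc.Sobol(d=len(ranges), scramble=True, seed=seed)
    u = sampler.random(n)
    lows = np.array([lo for lo, _ in ranges.values()])
    highs = np.array([hi for _, hi in ranges.values()])
    scaled = qmc.scale(u, lows, highs)
    df = pd.DataFrame(scaled, columns=list(ranges))
    if "speciation_threshold" in df:
        df["speciation_threshold"] = df["speciation_threshold"].round().astype(int)
    df.insert(0, "run_id", np.arange(n))
    return df


# ---------------------------------------------------------------------------
# ensemble execution
# ---------------------------------------------------------------------------

@dataclass
class EnsembleResult:
    metrics: pd.DataFrame  # retained runs, continuity columns included
    all_metrics: pd.DataFrame  # every successful run
    n_total: int
    n_retained: int
    failures: list[tuple[int, str]] = field(default_factory=list)


def retain_minimum_species(metrics: pd.DataFrame, min_species: int = 20) -> pd.DataFrame:
    """Keep rows with at least ``min_species`` extant species (boundary inclusive)."""
    if not len(metrics):
        return metrics
    return metrics[metrics["n_extant"] >= min_species].reset_index(drop=True)


def run_ensemble_and_filter(
    design: pd.DataFrame,
    landscape: Landscape,
    min_species: int = 20,
    n_steps: int | None = None,
    master_seed: int = 0,
) -> EnsembleResult:
    """Run every design row and keep runs with >= ``min_species`` extant.

    Per-run seeds are ``master_seed + run_id`` so the ensemble is
    reproducible and order-independent.  Individual run failures are
    recorded and excluded rather than fatal.
    """
    rows = []
    failures: list[tuple[int, str]] = []
    for rec in design.to_dict("records"):
        run_id = int(rec.get("run_id", len(rows)))
        params = SimulationParams(
            initial_abundance=float(rec["initial_abundance"]),
            thermal_optimum=float(rec["thermal_optimum"]),
            dispersal_scale=float(rec["dispersal_scale"]),
            speciation_threshold=int(rec["speciation_threshold"]),
            mutation_sd=float(rec["mutation_sd"]),
            niche_width=float(rec["niche_width"]),
            seed=master_seed + run_id,
        )
        try:
            result = run_simulation(landscape, params, n_steps=n_steps)
            rows.append(compute_metrics_row(result, sim_id=run_id))
        except Exception as exc:  # noqa: BLE001 - isolate per-run failures
            failures.append((run_id, repr(exc)))
    all_metrics = pd.DataFrame(rows)
    retained = retain_minimum_species(all_metrics, min_species)
    if len(retained):
        retained = add_continuity_columns(retained)
    return EnsembleResult(
        metrics=retained,
        all_metrics=all_metrics,
        n_total=len(design),
        n_retained=len(retained),
        failures=failures,
    )


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

def _ols(y: np.ndarray, X: pd.DataFrame) -> sm.regression.linear_model.RegressionResultsWrapper:
    return sm.OLS(y, sm.add_constant(X), missing="drop").fit()


def stepwise_aic(
    X: pd.DataFrame,
    y: np.ndarray,
    start_with_full: bool = True,
) -> list[str]:
    """Bidirectional greedy stepwise selection minimising AIC.

    Starting from the full (or empty) model, at each step the single
    term addition or removal that most lowers the AIC is applied, until
    no move improves it.  Returns the retained term names.
    """
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y) & np.isfinite(X.to_numpy(float)).all(axis=1)
    X, y = X.loc[ok], y[ok]
    terms = list(X.columns)
    current = list(terms) if start_with_full else []

    def aic_of(subset: Sequence[str]) -> float:
        if subset:
            return float(_ols(y, X[list(subset)]).aic)
        return float(sm.OLS(y, np.ones((y.size, 1))).fit().aic)

    best = aic_of(current)
    improved = True
    while improved:
        improved = False
        moves = []
        for t in current:
            moves.append([c for c in current if c != t])
        for t in terms:
            if t not in current:
                moves.append(current + [t])
        for cand in moves:
            a = aic_of(cand)
            if a < best - 1e-9:
                best, current, improved = a, list(cand), True
    return [t for t in terms if t in current]


@dataclass
class AnalysisResult:
    gamma_regressions: pd.DataFrame
    beta_regressions: pd.DataFrame
    multiple_regressions: dict[str, pd.DataFrame]
    model_stats: pd.DataFrame
    spearman: pd.DataFrame
    pca_loadings: pd.DataFrame
    pca_pct_variance: np.ndarray


def _simple_regression(df: pd.DataFrame, ycol: str, xcol: str, log_y: bool, log_x: bool) -> dict:
    y = df[ycol].to_numpy(float)
    x = df[xcol].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if log_y:
            y = np.where(y > 0, np.log(y), np.nan)
        if log_x:
            x = np.where(x > 0, np.log(x), np.nan)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return {"slope": np.nan, "t": np.nan, "p": np.nan, "n": int(ok.sum())}
    fit = _ols(y[ok], pd.DataFrame({xcol: x[ok]}))
    return {
        "slope": float(fit.params[xcol]),
        "t": float(fit.tvalues[xcol]),
        "p": float(fit.pvalues[xcol]),
        "n": int(ok.sum()),
    }


def fit_continuity_models(
    metrics: pd.DataFrame,
    predictors: Sequence[str] = PARAM_NAMES,
) -> AnalysisResult:
    """Level-vs-level regressions and stepwise continuity models.

    Gamma regressions relate species- to population-level diversity per
    facet; beta regressions do the same for bioregional beta values.
    All diversity measures are log-transformed except species MPD.  The
    multiple regressions predict each continuity facet from the
    biological parameters, reduced by bidirectional AIC stepwise
    selection; the full coefficient tables of the reduced models are
    returned together with adjusted R^2 and the F statistic.
    """
    if len(metrics) < 3:
        raise ValueError("need at least 3 retained simulations")
    gamma_rows, beta_rows = [], []
    for facet in FACETS:
        r = _simple_regression(
            metrics, f"species_{facet}", f"pop_{facet}",
            log_y=(facet != "mpd"), log_x=True,
        )
        gamma_rows.append({"facet": facet, **r})
        r = _simple_regression(
            metrics, f"beta_species_{facet}", f"beta_pop_{facet}",
            log_y=(facet != "mpd"), log_x=True,
        )
        beta_rows.append({"facet": facet, **r})

    X_full = metrics[list(predictors)].astype(float)
    multiple: dict[str, pd.DataFrame] = {}
    stats_rows = []
    for facet in FACETS:
        y = metrics[f"continuity_{facet}"].to_numpy(float)
        # standardise predictors so coefficients are comparable effect sizes
        Xz = (X_full - X_full.mean()) / X_full.std(ddof=0)
        if Xz.to_numpy().std(axis=0).min() == 0:
            raise ValueError("degenerate (constant) predictor column")
        kept = stepwise_aic(Xz, y)
        ok = np.isfinite(y)
        fit = _ols(y[ok], Xz.loc[ok, kept]) if kept else None
        if fit is not None:
            tab = pd.DataFrame(
                {
                    "coef": fit.params,
                    "se": fit.bse,
                    "t": fit.tvalues,
                    "p": fit.pvalues,
                }
            )
            stats_rows.append(
                {
                    "facet": facet,
                    "adj_r2": float(fit.rsquared_adj),
                    "F": float(fit.fvalue),
                    "p": float(fit.f_pvalue),
                    "n_terms": len(kept),
                }
            )
        else:  # pragma: no cover - every predictor dropped
            tab = pd.DataFrame(columns=["coef", "se", "t", "p"])
            stats_rows.append({"facet": facet, "adj_r2": np.nan, "F": np.nan, "p": np.nan, "n_terms": 0})
        multiple[facet] = tab

    return AnalysisResult(
        gamma_regressions=pd.DataFrame(gamma_rows),
        beta_regressions=pd.DataFrame(beta_rows),
        multiple_regressions=multiple,
        model_stats=pd.DataFrame(stats_rows),
        spearman=pd.DataFrame(),
        pca_loadings=pd.DataFrame(),
        pca_pct_variance=np.zeros(0),
    )


# ---------------------------------------------------------------------------
# correlations and PCA
# ---------------------------------------------------------------------------

DEFAULT_PROPERTIES = (
    "species_range",
    "turnover",
    "weighted_endemism",
    "diversification_rate",
    "thermal_evenness",
    "thermal_diversity",
    "competitive_evenness",
    "competitive_diversity",
)


def correlate_clade_properties(
    metrics: pd.DataFrame,
    continuity_cols: Sequence[str] | None = None,
    property_cols: Sequence[str] = DEFAULT_PROPERTIES,
) -> AnalysisResult:
    """Spearman correlations (Bonferroni-multiplied p) and a scaled PCA.

    Raw p-values are multiplied by the number of tests without capping
    at 1 (a capped column is reported alongside).  The PCA standardises
    the clade properties; loadings and percent variance per component
    are returned.  Pairs involving a constant column are reported as
    missing.
    """
    if len(metrics) < 3:
        raise ValueError("need at least 3 simulations")
    if continuity_cols is None:
        continuity_cols = [f"continuity_{f}" for f in FACETS]
    pairs = [(c, p) for c in continuity_cols for p in property_cols]
    m = len(pairs)
    rows = []
    for c, p in pairs:
        x = metrics[c].to_numpy(float)
        y = metrics[p].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.unique(x[ok]).size < 2 or np.unique(y[ok]).size < 2:
            rows.append({"continuity": c, "property": p, "rho": np.nan, "p_raw": np.nan,
                         "p_bonferroni": np.nan, "p_capped": np.nan, "n": int(ok.sum())})
            continue
        rho, praw = stats.spearmanr(x[ok], y[ok])
        rows.append(
            {
                "continuity": c,
                "property": p,
                "rho": float(rho),
                "p_raw": float(praw),
                "p_bonferroni": float(praw * m),
                "p_capped": float(min(praw * m, 1.0)),
                "n": int(ok.sum()),
            }
        )
    spearman = pd.DataFrame(rows)

    props = metrics[list(property_cols)].astype(float).dropna()
    if len(props) >= 3:
        Z = StandardScaler().fit_transform(props)
        pca = PCA()
        pca.fit(Z)
        loadings = pd.DataFrame(
            pca.components_.T,
            index=list(property_cols),
            columns=[f"PC{i + 1}" for i in range(pca.components_.shape[0])],
        )
        pct = pca.explained_variance_ratio_ * 100.0
    else:  # pragma: no cover - too few complete rows
        loadings = pd.DataFrame()
        pct = np.zeros(0)

    return AnalysisResult(
        gamma_regressions=pd.DataFrame(),
        beta_regressions=pd.DataFrame(),
        multiple_regressions={},
        model_stats=pd.DataFrame(),
        spearman=spearman,
        pca_loadings=loadings,
        pca_pct_variance=pct,
    )
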