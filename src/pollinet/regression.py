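"""Model-fitting stage: collinearity screening, the Poisson -> negative
binomial count-model ladder, bounded all-subsets AIC selection, Moran's I
residual diagnostics, and small meta-statistics on Delta-metrics.

Count responses (visits, richness) are fitted with Poisson GLMs and refitted
as negative binomial when the Pearson dispersion statistic signals
overdispersion; continuous responses (Shannon diversity, Delta-metrics) use
Gaussian linear models.  Model selection fits every predictor subset of
size 0..3 and ranks by AIC.  When residuals show significant spatial
autocorrelation the result is flagged for a generalised-least-squares refit
(the refit itself is outside this package's scope).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

DISPERSION_THRESHOLD = 1.5  # Pearson chi^2 / df above which NB replaces Poisson


# ------------------------------------------------------------ VIF screen

def vif_screen(
    X: pd.DataFrame, cutoff: float = 3.0
) -> tuple[list[str], list[tuple[str, float]]]:
    """Iteratively drop the highest-VIF predictor until all VIF <= cutoff.

    Returns (retained columns, dropped (name, VIF) in drop order).
    Perfectly collinear predictors (infinite VIF) are dropped first.
    """
    if X.shape[1] < 2:
        return list(X.columns), []
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    cols = list(X.columns)
    dropped: list[tuple[str, float]] = []
    while len(cols) >= 2:
        design = sm.add_constant(X[cols].to_numpy(dtype=float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vifs = np.array(
                [variance_inflation_factor(design, k + 1) for k in range(len(cols))]
            )
        vifs = np.where(np.isfinite(vifs), vifs, np.inf)
        worst = int(np.argmax(vifs))
        if vifs[worst] <= cutoff:
            break
        if np.isinf(vifs[worst]):
            warnings.warn(
                f"predictor {cols[worst]!r} is perfectly collinear; dropped",
                stacklevel=2,
            )
        dropped.append((cols[worst], float(vifs[worst])))
        cols.pop(worst)
    return cols, dropped


# ------------------------------------------------------------ model fits

@dataclass
class MoranResult:
    i: float
    expected: float
    variance: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class ModelResult:
    """One fitted model: family, coefficients and diagnostics."""

    response: str
    family: str  # poisson | negative_binomial | gaussian
    predictors: list[str]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    aic: float
    dispersion: float | None = None
    r2: float | None = None
    moran: MoranResult | None = None
    ranking: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def gls_recommended(self) -> bool:
        """True when residual spatial autocorrelation is significant."""
        return self.moran is not None and self.moran.significant


def _clean_design(X: pd.DataFrame) -> pd.DataFrame:
    const = [c for c in X.columns if np.std(X[c].to_numpy(dtype=float)) == 0]
    if const:
        warnings.warn(
            f"zero-variance predictors rejected before fit: {const}", stacklevel=3
        )
        X = X.drop(columns=const)
    return X


def fit_count_model(
    y,
    X: pd.DataFrame,
    response: str = "y",
    dispersion_threshold: float = DISPERSION_THRESHOLD,
) -> ModelResult:
    """Poisson GLM, escalated to negative binomial under overdispersion.

    The Poisson fit's Pearson chi^2 / df statistic decides: above the
    threshold the model is refitted as negative binomial with
    maximum-likelihood dispersion.  Pseudo-R^2 is 1 - deviance/null deviance.
    """
    y = np.asarray(y, dtype=float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("count response must be nonnegative integers")
    X = _clean_design(X)
    design = sm.add_constant(X.astype(float), has_constant="add")
    pois = sm.GLM(y, design, family=sm.families.Poisson()).fit()
    dispersion = float(pois.pearson_chi2 / pois.df_resid) if pois.df_resid > 0 else np.inf
    res, family = pois, "poisson"
    if dispersion > dispersion_threshold:
        from statsmodels.discrete.discrete_model import NegativeBinomial

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nb = NegativeBinomial(y, design).fit(
                start_params=np.r_[pois.params, 0.1], disp=0, maxiter=200
            )
        alpha = float(max(np.asarray(nb.params)[-1], 1e-8))
        glm_nb = sm.GLM(
            y, design, family=sm.families.NegativeBinomial(alpha=alpha)
        ).fit()
        res, family = glm_nb, "negative_binomial"
        # AIC must count the estimated dispersion parameter
        aic = float(glm_nb.aic + 2.0)
    else:
        aic = float(res.aic)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError(f"model for {response!r} did not converge cleanly")
    r2 = 1.0 - float(res.deviance / res.null_deviance) if res.null_deviance > 0 else np.nan
    return ModelResult(
        response=response,
        family=family,
        predictors=list(X.columns),
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        aic=aic,
        dispersion=dispersion,
        r2=r2,
    )


def fit_gaussian_model(y, X: pd.DataFrame, response: str = "y") -> ModelResult:
    """Ordinary linear model for continuous responses."""
    y = np.asarray(y, dtype=float)
    X = _clean_design(X)
    design = sm.add_constant(X.astype(float), has_constant="add")
    res = sm.OLS(y, design).fit()
    return ModelResult(
        response=response,
        family="gaussian",
        predictors=list(X.columns),
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        aic=float(res.aic),
        r2=float(res.rsquared),
    )


def subset_select_aic(
    y,
    X: pd.DataFrame,
    response: str = "y",
    family: str = "auto",
    max_terms: int = 3,
) -> ModelResult:
    """All-subsets AIC selection with at most ``max_terms`` predictors.

    Every subset of size 0..max_terms of the (already VIF-screened)
    candidates is fitted; the minimum-AIC model is returned with the full
    ranking table attached.  ``family='auto'`` treats integer responses as
    counts (Poisson/NB ladder, family fixed on the full candidate model so
    AICs are comparable) and everything else as Gaussian.
    """
    y = np.asarray(y, dtype=float)
    X = _clean_design(X)
    if family == "auto":
        is_count = (y >= 0).all() and np.allclose(y, np.round(y))
        family = "count" if is_count else "gaussian"
    if family == "count":
        full = fit_count_model(y, X, response=response)
        chosen = full.family

        def fit(sub: pd.DataFrame) -> ModelResult:
            if chosen == "poisson":
                return fit_count_model(y, sub, response=response, dispersion_threshold=np.inf)
            r = fit_count_model(y, sub, response=response, dispersion_threshold=-1.0)
            return r

    else:

        def fit(sub: pd.DataFrame) -> ModelResult:
            return fit_gaussian_model(y, sub, response=response)

    best: ModelResult | None = None
    rows = []
    for k in range(0, max_terms + 1):
        for combo in itertools.combinations(X.columns, k):
            sub = X[list(combo)]
            try:
                res = fit(sub)
            except Exception as exc:  # propagate per-subset failures as log rows
                rows.append({"predictors": combo, "aic": np.nan, "error": str(exc)})
                continue
            rows.append({"predictors": combo, "aic": res.aic, "error": ""})
            if best is None or res.aic < best.aic:
                best = res
    if best is None:
        raise RuntimeError("no candidate subset could be fitted")
    best.ranking = (
        pd.DataFrame(rows).sort_values("aic", na_position="last").reset_index(drop=True)
    )
    return best


# ------------------------------------------------------------- Moran's I

def inverse_distance_weights(coords: np.ndarray) -> np.ndarray:
    """Row-normalised inverse Euclidean distance weights, zero diagonal."""
    xy = np.asarray(coords, dtype=float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    if np.any((d == 0) & ~np.eye(len(xy), dtype=bool)):
        raise ValueError("coincident site coordinates")
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def morans_i(values, coords, weights: np.ndarray | None = None) -> MoranResult:
    """Moran's I with a normal-approximation test under the randomisation
    assumption.

    ``I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2`` with z the centred
    values; expectation under no autocorrelation is ``-1/(n-1)``.  The
    variance is the randomisation (permutation) variance, which includes the
    sample kurtosis and tracks the exact permutation distribution closely
    even at small n; the p-value is two-sided normal.
    """
    z = np.asarray(values, dtype=float)
    n = len(z)
    if n < 4:
        raise ValueError("Moran's I needs at least 4 observations")
    w = inverse_distance_weights(coords) if weights is None else np.asarray(weights, float)
    z = z - z.mean()
    s0 = w.sum()
    i_obs = (n / s0) * float(z @ w @ z) / float(z @ z)
    expected = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    b2 = n * (z**4).sum() / (z**2).sum() ** 2  # sample kurtosis
    var = (
        n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
        - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
    ) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - expected**2
    zscore = (i_obs - expected) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(zscore))
    return MoranResult(i=float(i_obs), expected=expected, variance=float(var), p=float(p))


def attach_moran(result: ModelResult, residuals, coords) -> ModelResult:
    result.moran = morans_i(residuals, coords)
    return result


# -------------------------------------------------------- meta statistics

def delta_meta(deltas) -> tuple[float, float]:
    """One-sample t-test of per-site Delta-metric values against zero."""
    x = np.asarray(deltas, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero variance; t statistic undefined")
    t, p = stats.ttest_1samp(x, 0.0)
    return float(t), float(p)


def resolution_compare(species_level, genus_level) -> dict[str, float]:
    """Compare a metric across taxonomic resolutions: Pearson correlation
    plus a paired t-test of the per-site values."""
    a = np.asarray(species_level, dtype=float)
    b = np.asarray(genus_level, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(a, ddof=1) == 0 or np.std(b, ddof=1) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p_r = stats.pearsonr(a, b)
    if np.std(a - b, ddof=1) == 0:
        t, p_t = (0.0, 1.0) if np.allclose(a, b) else (np.inf, 0.0)
    else:
        t, p_t = stats.ttest_rel(a, b)
    return {"r": float(r), "p_r": float(p_r), "t": float(t), "p_t": float(p_t)}
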