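"""Linear models of blood endpoints on exercise metrics, with
posterior-simulation confidence intervals.

Each endpoint is regressed (OLS, complete cases per endpoint) on four
covariates: the log-ratio-transformed proportion of low-intensity exercise,
capture duration (min), SST (°C) and total length (cm). Significance is
judged by 95% intervals from posterior simulation under the standard
noninformative prior for the normal linear model:

    σ²⁽ˢ⁾ ~ Scale-inv-χ²(n − k, s²)       (i.e. (n−k)·s² / χ²_{n−k})
    β⁽ˢ⁾ | σ²⁽ˢ⁾ ~ N(β̂, σ²⁽ˢ⁾ (XᵀX)⁻¹)

The 2.5/97.5 empirical percentiles of the draws form the interval; a term is
flagged significant iff the interval excludes zero. No multiple-testing
correction is applied (eight endpoints per species are tested separately);
see the methods note for the caveat.

Proportions are transformed with the logit, log(p/(1−p)) — the log-ratio of
low- versus not-low-intensity time, the natural choice when only p_low
enters the model. An additive-log-ratio variant log(p_low/p_high) is
available. Boundary proportions are clamped to [ε, 1−ε].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

DEFAULT_COVARIATES = ("logit_p_low", "capture_duration_min", "sst_c", "tl_cm")


def logratio_transform(p, eps: float = 1e-6,
                       n_seconds: Optional[int] = None,
                       mode: str = "logit", p_other=None):
    """Log-ratio transform of a proportion.

    mode="logit": log(p′/(1 − p′)); mode="alr": log(p′/p_other′). p is
    clamped to [ε, 1−ε] with ε = 1/(2·n_seconds) when the event length is
    known, else the ``eps`` default.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if n_seconds is not None:
        eps = 1.0 / (2.0 * n_seconds)
    pc = np.clip(p, eps, 1.0 - eps)
    if mode == "logit":
        out = np.log(pc / (1.0 - pc))
    elif mode == "alr":
        if p_other is None:
            raise ValueError("mode='alr' requires p_other (e.g. p_high)")
        po = np.clip(np.asarray(p_other, dtype=float), eps, 1.0 - eps)
        out = np.log(pc / po)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(out) if out.ndim == 0 else out


@dataclass
class ModelSpec:
    """One endpoint model: response ~ covariates, within one species."""

    response: str
    covariates: tuple = DEFAULT_COVARIATES
    species: Optional[str] = None


@dataclass
class ModelFit:
    """Fitted coefficients with posterior-simulation interval bounds."""

    response: str
    species: Optional[str]
    term_names: list
    params: np.ndarray
    sigma: float                 # residual sd, s
    df_resid: int
    n: int
    cov_unscaled: np.ndarray     # (XᵀX)⁻¹
    lower: Optional[np.ndarray] = None   # 2.5% bounds per term
    upper: Optional[np.ndarray] = None   # 97.5% bounds per term
    significant: Optional[np.ndarray] = None
    n_sims: int = 0


class PosteriorLinearModel(RegressorMixin, BaseEstimator):
    """OLS with posterior-simulation confidence intervals.

    Scikit-learn-style estimator: ``fit(X, y)`` with X of shape
    (n_samples, n_covariates); an intercept is always prepended.

    Parameters
    ----------
    n_sims : posterior draws used for the interval (default 1000).
    alpha : two-sided interval level complement (default 0.05 → 95% CI).
    random_state : seed for the posterior draws.

    Attributes
    ----------
    params_ : coefficient vector including the intercept (term order:
        intercept, then covariates as given).
    coef_, intercept_ : the sklearn view of the same fit.
    sigma_ : residual standard deviation s.
    conf_lower_, conf_upper_ : per-term empirical 2.5/97.5 percentile bounds.
    significant_ : per-term flag, True iff the interval excludes zero.
    """

    def __init__(self, n_sims: int = 1000, alpha: float = 0.05,
                 random_state: Optional[int] = None):
        self.n_sims = n_sims
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y, term_names: Optional[Sequence[str]] = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, p = X.shape
        k = p + 1
        if n < k + 2:
            raise ValueError(
                f"insufficient data: n={n} rows for {k} terms; need ≥ {k + 2}")
        names = ["intercept"] + (list(term_names) if term_names is not None
                                 else [f"x{i}" for i in range(p)])
        Xd = sm.add_constant(X, has_constant="add")
        rank = np.linalg.matrix_rank(Xd)
        if rank < k:
            dup = _collinear_terms(Xd, names)
            raise ValueError(f"design matrix is rank deficient (rank {rank} "
                             f"< {k}); collinear term(s): {dup}")
        res = sm.OLS(y, Xd).fit()
        self.term_names_ = names
        self.params_ = np.asarray(res.params, float)
        self.intercept_ = float(self.params_[0])
        self.coef_ = self.params_[1:].copy()
        self.df_resid_ = int(res.df_resid)
        self.sigma_ = float(np.sqrt(res.ssr / res.df_resid))
        self.cov_unscaled_ = np.asarray(res.normalized_cov_params, float)
        self.n_ = n
        if self.n_sims and self.n_sims > 0:
            lower, upper, _ = self._simulate(self.n_sims, self.random_state)
            self.conf_lower_, self.conf_upper_ = lower, upper
            self.significant_ = (lower > 0) | (upper < 0)
        else:
            self.conf_lower_ = self.conf_upper_ = self.significant_ = None
        return self

    def _simulate(self, n_sims, seed):
        fit = self._as_modelfit()
        draws = posterior_draws(fit, n_sims=n_sims, seed=seed)
        lower = np.percentile(draws, 2.5 if self.alpha == 0.05
                              else 100 * self.alpha / 2, axis=0)
        upper = np.percentile(draws, 97.5 if self.alpha == 0.05
                              else 100 * (1 - self.alpha / 2), axis=0)
        return lower, upper, draws

    def _as_modelfit(self) -> ModelFit:
        return ModelFit(response="", species=None,
                        term_names=list(self.term_names_),
                        params=self.params_, sigma=self.sigma_,
                        df_resid=self.df_resid_, n=self.n_,
                        cov_unscaled=self.cov_unscaled_)

    def posterior_samples(self, n_sims: Optional[int] = None,
                          random_state: Optional[int] = None) -> np.ndarray:
        """Draws of the coefficient vector, shape (n_sims, n_terms)."""
        return posterior_draws(self._as_modelfit(),
                               n_sims=n_sims or self.n_sims,
                               seed=(random_state if random_state is not None
                                     else self.random_state))

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_


def _collinear_terms(Xd: np.ndarray, names: Sequence[str]) -> list:
    """Name columns that add no rank — reported in rank-deficiency errors."""
    bad, kept = [], []
    for j in range(Xd.shape[1]):
        trial = Xd[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(names[j])
    return bad


def posterior_draws(fit: ModelFit, n_sims: int = 1000,
                    seed: Optional[int] = None) -> np.ndarray:
    """Noninformative-prior posterior simulation of (β, σ²); returns β draws.

    Variance: σ²⁽ˢ⁾ = df·s²/χ²_df. Coefficients: β⁽ˢ⁾ ~ N(β̂, σ²⁽ˢ⁾(XᵀX)⁻¹).
    """
    import warnings as _w
    if n_sims < 100:
        _w.warn(f"n_sims={n_sims} < 100 gives unstable interval bounds",
                stacklevel=2)
    rng = np.random.default_rng(seed)
    df = fit.df_resid
    chi2 = rng.chisquare(df, size=n_sims)
    sigma2 = df * fit.sigma ** 2 / chi2
    L = np.linalg.cholesky(fit.cov_unscaled)
    z = rng.standard_normal((n_sims, len(fit.params)))
    return fit.params + np.sqrt(sigma2)[:, None] * (z @ L.T)


def simulate_posterior(fit: ModelFit, n_sims: int = 1000,
                       seed: Optional[int] = None) -> ModelFit:
    """Attach 95% posterior-simulation bounds and significance flags."""
    draws = posterior_draws(fit, n_sims=n_sims, seed=seed)
    fit.lower = np.percentile(draws, 2.5, axis=0)
    fit.upper = np.percentile(draws, 97.5, axis=0)
    fit.significant = (fit.lower > 0) | (fit.upper < 0)
    fit.n_sims = n_sims
    return fit


def fit_linear_model(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Complete-case OLS for one endpoint within one species."""
    df = data
    if spec.species is not None and "species" in df.columns:
        df = df[df["species"] == spec.species]
    cols = [spec.response, *spec.covariates]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"data lacks column(s) {missing}")
    cc = df[cols].dropna()
    X = cc[list(spec.covariates)].to_numpy(float)
    y = cc[spec.response].to_numpy(float)
    n, p = X.shape
    k = p + 1
    if n < k + 2:
        raise ValueError(f"insufficient complete cases for {spec.response}: "
                         f"n={n}, need ≥ {k + 2}")
    # reuse the estimator's fitting/validation path; bounds attached later
    est = PosteriorLinearModel(n_sims=0)
    est.fit(X, y, term_names=list(spec.covariates))
    return ModelFit(response=spec.response, species=spec.species,
                    term_names=est.term_names_, params=est.params_,
                    sigma=est.sigma_, df_resid=est.df_resid_, n=est.n_,
                    cov_unscaled=est.cov_unscaled_)


def fit_endpoint_models(data: pd.DataFrame, responses: Sequence[str],
                        species: Optional[str] = None,
                        covariates: tuple = DEFAULT_COVARIATES,
                        n_sims: int = 1000,
                        seed: Optional[int] = None) -> list[ModelFit]:
    """Fit + posterior-simulate every endpoint; skips under-sampled ones."""
    fits = []
    for i, resp in enumerate(responses):
        spec = ModelSpec(response=resp, covariates=covariates,
                         species=species)
        try:
            fit = fit_linear_model(data, spec)
        except ValueError:
            continue
        sub_seed = None if seed is None else seed + i
        fits.append(simulate_posterior(fit, n_sims=n_sims, seed=sub_seed))
    return fits


def significance_table(fits: Sequence[ModelFit]) -> pd.DataFrame:
    """Per species × response × term: estimate, 2.5%, 97.5%, flag."""
    rows = []
    for f in fits:
        for j, term in enumerate(f.term_names):
            rows.append({
                "species": f.species,
                "response": f.response,
                "term": term,
                "estimate": f.params[j],
                "ci_2.5": None if f.lower is None else f.lower[j],
                "ci_97.5": None if f.upper is None else f.upper[j],
                "significant": (None if f.significant is None
                                else bool(f.significant[j])),
                "n": f.n,
            })
    return pd.DataFrame(rows, columns=["species", "response", "term",
                                       "estimate", "ci_2.5", "ci_97.5",
                                       "significant", "n"])


def render_significance_text(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of the significance table."""
    if table.empty:
        return "(no fitted models)\n"
    lines = []
    for (sp, resp), grp in table.groupby(["species", "response"],
                                         dropna=False, sort=False):
        n = int(grp["n"].iloc[0])
        sp_name = sp if isinstance(sp, str) and sp else "all"
        lines.append(f"{sp_name} / {resp} (n={n})")
        for _, r in grp.iterrows():
            star = " *" if r["significant"] else "  "
            lines.append(f"  {r['term']:<22s} {r['estimate']:>10.4f}  "
                         f"[{r['ci_2.5']:>10.4f}, {r['ci_97.5']:>10.4f}]{star}")
        lines.append("")
    lines.append("* 95% posterior-simulation interval excludes zero\n")
    return "\n".join(lines)
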