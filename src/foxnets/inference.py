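"""Regression models, contrasts, repeatability and worked derivations.

The inferential contract of the pipeline is permutation-based: observed
model coefficients are ranked against coefficients refitted on permuted
data, so the fitter only has to be *consistent* between observed and null
fits, not identical to any particular mixed-model package.  Gaussian and
Poisson fixed-effects fits use fast closed-form/IRLS paths (they are
refitted thousands of times inside permutation chains); mixed models are
delegated to statsmodels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

FAMILIES = {"gaussian", "poisson", "gamma", "lognormal", "hurdle-nb"}


@dataclass
class ModelSpec:
    """A model formula split into response, family and term lists."""

    response: str
    family: str
    fixed_effects: list
    random_effects: list = field(default_factory=list)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {sorted(FAMILIES)}")

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed_effects) if self.fixed_effects else "1"
        return f"{self.response} ~ {rhs}"

    def validate_columns(self, data: pd.DataFrame):
        cols = set(data.columns)
        import re

        refs = set()
        for term in [self.response, *self.fixed_effects, *self.random_effects]:
            for name in re.findall(r"[A-Za-z_][A-Za-z0-9_]*", term):
                if name not in {"C", "I", "np", "log", "log10", "center", "standardize"}:
                    refs.add(name)
        missing = refs - cols
        if missing:
            raise ValueError(f"model terms reference missing columns: {sorted(missing)}")


@dataclass
class FitResult:
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    loglik: float
    family: str
    formula: str
    nobs: int
    converged: bool = True
    scale: float = 1.0
    vc: dict = field(default_factory=dict)   # variance components (random effects)
    design_info: object | None = None

    def coef(self, name: str) -> float:
        return float(self.params[name])


# ---------------------------------------------------------------------------
# fast fixed-effects fitters
# ---------------------------------------------------------------------------

def _ols_fit(X: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n, p = X.shape
    sigma2 = float(resid @ resid) / n          # ML scale
    xtx_inv = np.linalg.pinv(X.T @ X)
    cov = xtx_inv * (resid @ resid) / max(n - p, 1)
    loglik = -0.5 * n * (np.log(2 * np.pi * max(sigma2, 1e-300)) + 1)
    return beta, cov, loglik, sigma2


def _poisson_irls(X: np.ndarray, y: np.ndarray, maxiter: int = 50, tol: float = 1e-9):
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-8))  # assumes an intercept column first
    ll_old = -np.inf
    converged = False
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        W = mu
        z = eta + (y - mu) / np.maximum(mu, 1e-12)
        XtW = X.T * W
        try:
            beta = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(XtW @ X, XtW @ z, rcond=None)[0]
        ll = float(y @ eta - mu.sum() - gammaln(y + 1).sum())
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1):
            converged = True
            break
        ll_old = ll
    eta = np.clip(X @ beta, -30, 30)
    mu = np.exp(eta)
    cov = np.linalg.pinv((X.T * mu) @ X)
    ll = float(y @ eta - mu.sum() - gammaln(y + 1).sum())
    return beta, cov, ll, converged


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit a model by maximum likelihood.

    Fixed-effects Gaussian and Poisson models use in-package closed-form /
    IRLS fits.  Random effects: Gaussian models go to statsmodels MixedLM
    (ML, crossed random intercepts via variance components); Poisson models
    to a Laplace-type approximation (statsmodels ``PoissonBayesMixedGLM``).
    Gamma-log models are fitted as fixed-effects GLMs; requesting random
    effects there falls back with a warning (the permutation ranking only
    needs a consistent fitter).
    """
    spec.validate_columns(data)
    if spec.family == "hurdle-nb":
        raise ValueError("use fit_hurdle_duration for hurdle models")
    work = data
    response = spec.response
    if spec.family == "lognormal":
        from .networks import strength_transform

        work = data.copy()
        work["_log_response"] = strength_transform(work[spec.response].to_numpy())
        response = "_log_response"
    rhs = " + ".join(spec.fixed_effects) if spec.fixed_effects else "1"
    formula = f"{response} ~ {rhs}"
    y, X = patsy.dmatrices(formula, work, return_type="dataframe")
    yv = y.to_numpy().ravel()
    Xv = X.to_numpy()
    names = list(X.columns)
    fam = "gaussian" if spec.family == "lognormal" else spec.family

    if not spec.random_effects:
        if fam == "gaussian":
            beta, cov, ll, scale = _ols_fit(Xv, yv)
            conv = True
        elif fam == "poisson":
            beta, cov, ll, conv = _poisson_irls(Xv, yv)
            scale = 1.0
        elif fam == "gamma":
            import statsmodels.api as sm

            res = sm.GLM(yv, Xv, family=sm.families.Gamma(sm.families.links.Log())).fit()
            beta, cov, ll = res.params, np.asarray(res.cov_params()), float(res.llf)
            scale, conv = float(res.scale), bool(res.converged)
        else:  # pragma: no cover
            raise ValueError(fam)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        return FitResult(pd.Series(beta, index=names), pd.Series(se, index=names),
                         pd.DataFrame(cov, index=names, columns=names),
                         loglik=ll, family=spec.family, formula=spec.formula,
                         nobs=len(yv), converged=conv, scale=scale,
                         design_info=X.design_info)

    return _fit_mixed(spec, work, response, formula, X.design_info)


def _fit_mixed(spec: ModelSpec, data: pd.DataFrame, response: str,
               formula: str, design_info) -> FitResult:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fam = "gaussian" if spec.family == "lognormal" else spec.family
    work = data.copy()
    work["_all"] = 1
    vcf = {re_: f"0 + C({re_.replace(':', '_x_')})" for re_ in spec.random_effects}
    for re_ in spec.random_effects:
        if ":" in re_:
            parts = re_.split(":")
            work[re_.replace(":", "_x_")] = work[parts[0]].astype(str)
            for extra in parts[1:]:
                work[re_.replace(":", "_x_")] += "|" + work[extra].astype(str)
    if fam == "gaussian":
        model = smf.mixedlm(formula, work, groups="_all", re_formula="0", vc_formula=vcf)
        res = _fit_mixedlm_robust(model, reml=False)
        names = list(res.fe_params.index)
        cov = pd.DataFrame(np.asarray(res.cov_params())[:len(names), :len(names)],
                           index=names, columns=names)
        vc = {k: float(v) for k, v in zip(vcf, np.atleast_1d(res.vcomp))}
        return FitResult(res.fe_params, res.bse_fe, cov, loglik=float(res.llf),
                         family=spec.family, formula=spec.formula, nobs=int(res.nobs),
                         converged=bool(res.converged), scale=float(res.scale),
                         vc=vc, design_info=design_info)
    if fam == "poisson":
        from statsmodels.genmod.bayes_mixed_glm import PoissonBayesMixedGLM

        vcf2 = {k.replace(":", "_x_"): v for k, v in vcf.items()}
        model = PoissonBayesMixedGLM.from_formula(formula, vcf2, work)
        res = model.fit_map()
        k = model.k_fep
        names = list(model.exog_names[:k]) if hasattr(model, "exog_names") else \
            [f"b{i}" for i in range(k)]
        params = pd.Series(res.fe_mean, index=names)
        se = pd.Series(res.fe_sd, index=names)
        cov = pd.DataFrame(np.diag(se.to_numpy() ** 2), index=names, columns=names)
        vc = {name: float(np.exp(2 * s)) for name, s in
              zip(vcf2, res.vcp_mean)}
        return FitResult(params, se, cov, loglik=float("nan"), family=spec.family,
                         formula=spec.formula, nobs=len(work), converged=True,
                         vc=vc, design_info=design_info)
    logger.warning("random effects unsupported for family %s; fitting fixed-effects GLM",
                   fam)
    reduced = ModelSpec(spec.response, spec.family, spec.fixed_effects, [])
    return fit_model(reduced, data)


# ---------------------------------------------------------------------------
# model simplification and contrasts
# ---------------------------------------------------------------------------

def _fit_mixedlm_robust(model, reml: bool):
    """Fit a MixedLM, falling back through optimizers on non-convergence.

    With few grouping levels lbfgs can stall at its starting values (which
    would silently report vc == scale), so retry before giving up.
    """
    res = None
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            with np.errstate(all="ignore"):
                res = model.fit(reml=reml, method=method, maxiter=500)
        except np.linalg.LinAlgError:
            continue
        if res.converged:
            return res
    if res is None:
        raise np.linalg.LinAlgError("mixed model fit failed with every optimizer")
    logger.warning("mixed model did not converge with any optimizer")
    return res


def _contains(term_a: str, term_b: str) -> bool:
    """True when interaction term_a contains all factors of term_b."""
    fa = set(term_a.split(":"))
    fb = set(term_b.split(":"))
    return fb < fa


def stepwise_reduce(spec: ModelSpec, data: pd.DataFrame, alpha: float = 0.05):
    """Stepwise simplification with deviance (likelihood-ratio) tests.

    Iteratively refits without each removable term (one whose factors do not
    appear in a retained higher-order interaction), and drops the term with
    the largest LRT P-value while it exceeds ``alpha``.  Stops at the
    intercept-only floor.  Returns ``(reduced_spec, history)``.
    """
    terms = list(spec.fixed_effects)
    history = []
    full = fit_model(ModelSpec(spec.response, spec.family, terms,
                               spec.random_effects), data)
    while terms:
        removable = [t for t in terms
                     if not any(_contains(other, t) for other in terms if other != t)]
        best = None
        for term in removable:
            reduced_terms = [t for t in terms if t != term]
            red = fit_model(ModelSpec(spec.response, spec.family, reduced_terms,
                                      spec.random_effects), data)
            lr = 2.0 * (full.loglik - red.loglik)
            df = len(full.params) - len(red.params)
            p = float(stats.chi2.sf(max(lr, 0.0), max(df, 1)))
            if best is None or p > best[2]:
                best = (term, red, p, df, lr)
        term, red, p, df, lr = best
        history.append({"dropped": term, "lr": lr, "df": df, "p": p,
                        "kept": p <= alpha})
        if p <= alpha:
            history[-1]["kept"] = True
            break
        terms = [t for t in terms if t != term]
        full = red
    return ModelSpec(spec.response, spec.family, terms, spec.random_effects), history


def sidak_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Sidak correction ``1 - (1 - p)^m`` (identity when m == 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = m if m is not None else p.size
    return 1.0 - (1.0 - p) ** m


def _cell_design(fit: FitResult, cells: pd.DataFrame) -> np.ndarray:
    return np.asarray(patsy.build_design_matrices([fit.design_info], cells)[0])


def tukey_contrasts(fit: FitResult, data: pd.DataFrame, factors: list,
                    covariate_values: dict | None = None) -> pd.DataFrame:
    """All pairwise cell contrasts of a categorical interaction, Sidak-adjusted.

    Builds the cell-mean grid over ``factors`` (other covariates fixed at
    ``covariate_values`` or their data means), forms every pairwise contrast
    within each family — levels of each factor compared within the cells of
    the remaining factors — and adjusts P-values per family with the Sidak
    correction.  Empty cells (absent from the data) are dropped and noted.
    """
    levels = {f: sorted(data[f].dropna().unique()) for f in factors}
    grid = pd.MultiIndex.from_product([levels[f] for f in factors],
                                      names=factors).to_frame(index=False)
    observed_cells = set(map(tuple, data[factors].drop_duplicates().to_numpy()))
    present = grid[[tuple(r) in observed_cells for r in grid.to_numpy()]].reset_index(drop=True)
    n_dropped = len(grid) - len(present)
    if n_dropped:
        logger.warning("%d empty cell(s) dropped from contrast grid", n_dropped)
    cov_vals = covariate_values or {}
    for col in data.columns:
        if col in factors or col == "_log_response":
            continue
        if col in cov_vals:
            present[col] = cov_vals[col]
        elif pd.api.types.is_numeric_dtype(data[col]):
            present[col] = float(data[col].mean())
        else:
            present[col] = data[col].mode().iloc[0]
    X = _cell_design(fit, present)
    beta = fit.params.to_numpy()
    cov = fit.cov_params.to_numpy()
    rows = []
    for vary in factors:
        others = [f for f in factors if f != vary]
        group_keys = present[others].apply(tuple, axis=1) if others else \
            pd.Series(["all"] * len(present))
        for key, idxs in present.groupby(group_keys).groups.items():
            idxs = list(idxs)
            fam_rows = []
            for ai in range(len(idxs)):
                for bi in range(ai + 1, len(idxs)):
                    i, j = idxs[ai], idxs[bi]
                    L = X[i] - X[j]
                    est = float(L @ beta)
                    se = float(np.sqrt(max(L @ cov @ L, 0.0)))
                    z = est / se if se > 0 else np.nan
                    p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
                    la = present.loc[i, vary]
                    lb = present.loc[j, vary]
                    fam_rows.append({"factor": vary, "within": str(key),
                                     "contrast": f"{la} - {lb}", "estimate": est,
                                     "se": se, "z": z, "p": p})
            m = len(fam_rows)
            for r in fam_rows:
                r["p_sidak"] = float(sidak_adjust([r["p"]], m)[0]) if np.isfinite(r["p"]) else np.nan
                rows.append(r)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hurdle model for encounter durations
# ---------------------------------------------------------------------------

@dataclass
class HurdleResult:
    zero_part: FitResult          # logistic: P(duration > 0)
    positive_part: FitResult | None  # zero-truncated negative binomial
    alpha: float | None           # NB dispersion
    degenerate: str | None        # "all_zero" | "all_positive" | None

    def predicted_mean(self, grid: pd.DataFrame) -> np.ndarray:
        """E[duration] = P(y > 0) * E[y | y > 0] at the grid covariates."""
        Xz = _cell_design(self.zero_part, grid)
        p_pos = 1.0 / (1.0 + np.exp(-(Xz @ self.zero_part.params.to_numpy())))
        if self.positive_part is None:
            return np.zeros(len(grid)) if self.degenerate == "all_zero" else p_pos * np.nan
        Xp = _cell_design(self.positive_part, grid)
        mu = np.exp(Xp @ self.positive_part.params.to_numpy())
        a = self.alpha
        p0 = (1.0 + a * mu) ** (-1.0 / a)
        return p_pos * mu / (1.0 - p0)


def fit_hurdle_duration(data: pd.DataFrame, response: str = "duration_s",
                        fixed_effects: list | None = None,
                        random_effect: str | None = "dyad") -> HurdleResult:
    """Two-part model for encounter durations in whole seconds.

    A logistic regression separates zero from positive durations; a
    zero-truncated negative binomial (log link) models positive lengths.
    With ``random_effect`` given, the zero part gets a Laplace-approximate
    random intercept; the positive part is fitted as a fixed-effects
    truncated NB (cluster structure noted, not modelled).  All-zero or
    all-positive data leave the corresponding part degenerate and flagged.
    """
    import statsmodels.api as sm
    from statsmodels.discrete.truncated_model import TruncatedLFNegativeBinomialP

    fixed_effects = fixed_effects or ["before_midnight * season"]
    y = data[response].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("durations must be whole seconds >= 0")
    work = data.copy()
    work["_positive"] = (y > 0).astype(int)
    rhs = " + ".join(fixed_effects)

    degenerate = None
    if work["_positive"].nunique() < 2:
        degenerate = "all_zero" if work["_positive"].iloc[0] == 0 else "all_positive"

    # --- zero part -------------------------------------------------------
    if degenerate:
        logger.warning("hurdle zero part degenerate (%s)", degenerate)
        yz, Xz = patsy.dmatrices(f"_positive ~ {rhs}", work, return_type="dataframe")
        names = list(Xz.columns)
        zero_part = FitResult(pd.Series(np.nan, index=names),
                              pd.Series(np.nan, index=names),
                              pd.DataFrame(np.nan, index=names, columns=names),
                              loglik=float("nan"), family="binomial",
                              formula=f"_positive ~ {rhs}", nobs=len(work),
                              converged=False, design_info=Xz.design_info)
    elif random_effect:
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        vcf = {random_effect: f"0 + C({random_effect})"}
        model = BinomialBayesMixedGLM.from_formula(f"_positive ~ {rhs}", vcf, work)
        res = model.fit_map()
        k = model.k_fep
        yz, Xz = patsy.dmatrices(f"_positive ~ {rhs}", work, return_type="dataframe")
        names = list(Xz.columns)[:k]
        zero_part = FitResult(pd.Series(res.fe_mean[:k], index=names),
                              pd.Series(res.fe_sd[:k], index=names),
                              pd.DataFrame(np.diag(res.fe_sd[:k] ** 2),
                                           index=names, columns=names),
                              loglik=float("nan"), family="binomial",
                              formula=f"_positive ~ {rhs}", nobs=len(work),
                              converged=True,
                              vc={random_effect: float(np.exp(2 * res.vcp_mean[0]))},
                              design_info=Xz.design_info)
    else:
        yz, Xz = patsy.dmatrices(f"_positive ~ {rhs}", work, return_type="dataframe")
        res = sm.GLM(yz, Xz, family=sm.families.Binomial()).fit()
        names = list(Xz.columns)
        zero_part = FitResult(pd.Series(np.asarray(res.params), index=names),
                              pd.Series(np.asarray(res.bse), index=names),
                              pd.DataFrame(np.asarray(res.cov_params()),
                                           index=names, columns=names),
                              loglik=float(res.llf), family="binomial",
                              formula=f"_positive ~ {rhs}", nobs=len(work),
                              converged=bool(res.converged),
                              design_info=Xz.design_info)

    # --- positive part ---------------------------------------------------
    pos = work[work["_positive"] == 1]
    if degenerate == "all_zero" or len(pos) < 3:
        return HurdleResult(zero_part, None, None, degenerate or "all_zero")
    yp, Xp = patsy.dmatrices(f"{response} ~ {rhs}", pos, return_type="dataframe")
    model = TruncatedLFNegativeBinomialP(yp.to_numpy().ravel(), Xp.to_numpy(),
                                         truncation=0)
    with np.errstate(all="ignore"):
        res = model.fit(method="bfgs", maxiter=500, disp=False)
    names = list(Xp.columns)
    params = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    positive = FitResult(pd.Series(params[:len(names)], index=names),
                         pd.Series(np.sqrt(np.clip(np.diag(cov)[:len(names)], 0, None)),
                                   index=names),
                         pd.DataFrame(cov[:len(names), :len(names)],
                                      index=names, columns=names),
                         loglik=float(res.llf), family="truncated-nb",
                         formula=f"{response} ~ {rhs}", nobs=len(pos),
                         converged=bool(res.mle_retvals.get("converged", True)),
                         design_info=Xp.design_info)
    alpha = float(params[-1])
    return HurdleResult(zero_part, positive, alpha, degenerate)


# ---------------------------------------------------------------------------
# predictions and worked derivations
# ---------------------------------------------------------------------------

_INV_LINKS = {"poisson": np.exp, "gamma": np.exp,
              "gaussian": lambda x: x, "lognormal": lambda x: x}


def predict_rates(fit: FitResult, grid: pd.DataFrame,
                  observed_range: tuple | None = None,
                  level: float = 0.95) -> pd.DataFrame:
    """Inverse-link predictions with CIs from the fixed-effect covariance.

    Random effects are set to zero.  ``observed_range`` (lo, hi) triggers an
    extrapolation warning when any numeric grid covariate leaves it.
    """
    X = _cell_design(fit, grid)
    beta = fit.params.to_numpy()
    cov = fit.cov_params.to_numpy()
    eta = X @ beta
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", X, cov, X), 0, None))
    zcrit = stats.norm.ppf(0.5 + level / 2)
    inv = _INV_LINKS["gaussian" if fit.family not in _INV_LINKS else fit.family]
    out = grid.copy()
    out["predicted"] = inv(eta)
    out["ci_low"] = inv(eta - zcrit * se)
    out["ci_high"] = inv(eta + zcrit * se)
    if observed_range is not None:
        lo, hi = observed_range
        numeric = out.select_dtypes("number")
        if ((numeric < lo) | (numeric > hi)).any().any():
            logger.warning("prediction grid extrapolates beyond the observed range")
    return out


def days_between_associations(rate: float) -> int:
    """Reciprocal of a daily association rate, rounded to whole days.

    E.g. 0.073 associations/day -> one association every 14 days.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    return int(np.round(1.0 / rate))


# ---------------------------------------------------------------------------
# repeatability
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    variance_individual: float
    variance_territory: float
    variance_residual: float
    icc: float
    repeatability: str    # low < 0.3 <= moderate <= 0.7 < high
    converged: bool = True


def icc_repeatability(data: pd.DataFrame, value_col: str,
                      individual_col: str = "fox",
                      territory_col: str = "territory") -> ICCResult:
    """Between-season repeatability of a network metric.

    Intercept-only mixed model with individual and territory random
    intercepts (REML); ICC is the share of total variance attributed to
    individual identity, classed low (< 0.3) / moderate / high (> 0.7).
    Data from all networks, including random-association ones, belong here.
    """
    import statsmodels.formula.api as smf

    work = data[[value_col, individual_col, territory_col]].dropna().copy()
    per_ind = work.groupby(individual_col).size()
    if per_ind.max() < 2:
        raise ValueError("ICC unidentifiable: single observation per individual")
    work["_all"] = 1
    vcf = {"individual": f"0 + C({individual_col})",
           "territory": f"0 + C({territory_col})"}
    model = smf.mixedlm(f"{value_col} ~ 1", work, groups="_all",
                        re_formula="0", vc_formula=vcf)
    res = _fit_mixedlm_robust(model, reml=True)
    var_ind, var_terr = (float(v) for v in np.atleast_1d(res.vcomp))
    var_resid = float(res.scale)
    total = var_ind + var_terr + var_resid
    icc = var_ind / total if total > 0 else float("nan")
    cls = "low" if icc < 0.3 else ("high" if icc > 0.7 else "moderate")
    return ICCResult(var_ind, var_terr, var_resid, icc, cls,
                     converged=bool(res.converged))


# ---------------------------------------------------------------------------
# auxiliary tests and diagnostics
# ---------------------------------------------------------------------------

def nonresident_sex_test(male_counts, female_counts) -> dict:
    """Paired Wilcoxon signed-rank test on per-territory male vs female counts.

    Returns the smaller signed-rank sum W, the exact-when-possible P value
    and the effect size r = Z / sqrt(n) from the normal approximation
    (negative when male counts exceed female counts).
    """
    m = np.asarray(male_counts, dtype=float)
    f = np.asarray(female_counts, dtype=float)
    d = m - f
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero: test undefined")
    res = stats.wilcoxon(m, f, zero_method="wilcox", alternative="two-sided",
                         method="auto")
    ranks = stats.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    t_minus = float(ranks[d < 0].sum())
    w = min(t_plus, t_minus)
    mean_w = n * (n + 1) / 4.0
    sd_w = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    # z from the smaller rank sum: consistent differences give negative z/r
    z = (w - mean_w) / sd_w if sd_w > 0 else float("nan")
    return {"W": w, "p": float(res.pvalue), "z": float(z),
            "r": float(z / np.sqrt(n)), "n": int(n)}


def collinearity_check(covariates: pd.DataFrame, vif_threshold: float = 5.0) -> dict:
    """Spearman rank correlations and variance inflation factors.

    VIF_j = 1 / (1 - R^2_j) from regressing covariate j on the others;
    constant covariates get an undefined (inf) VIF and a warning, as do
    VIFs above ``vif_threshold``.
    """
    cols = list(covariates.columns)
    if len(cols) < 2:
        raise ValueError("need at least two covariates")
    mat = covariates.to_numpy(dtype=float)
    rho, _ = stats.spearmanr(mat)
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = pd.DataFrame(rho, index=cols, columns=cols)
    vifs = {}
    for j, col in enumerate(cols):
        yj = mat[:, j]
        Xj = np.column_stack([np.ones(len(mat)), np.delete(mat, j, axis=1)])
        if np.var(yj) == 0:
            vifs[col] = float("inf")
            logger.warning("constant covariate %s: VIF undefined", col)
            continue
        beta, *_ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ beta
        r2 = 1.0 - resid @ resid / ((yj - yj.mean()) @ (yj - yj.mean()))
        vif = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
        vifs[col] = float(vif)
        if vif > vif_threshold:
            logger.warning("covariate %s has VIF %.2f > %.1f", col, vif, vif_threshold)
    return {"spearman": rho, "vif": vifs}


def dispersion_ratio(fit: FitResult, data: pd.DataFrame, response: str) -> float:
    """Pearson-residual dispersion diagnostic for Poisson fits (no hard threshold)."""
    X = _cell_design(fit, data)
    mu = np.exp(X @ fit.params.to_numpy())
    y = data[response].to_numpy(dtype=float)
    pearson = (y - mu) ** 2 / np.maximum(mu, 1e-12)
    return float(pearson.sum() / max(len(y) - len(fit.params), 1))
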