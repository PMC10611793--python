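"""Discharge location after acute-care TBI hospitalization.

Six destination categories — home (reference), home with support, long-term
care (LTC), complex continuing care (CCC), rehabilitation, other — modelled
with a baseline-category (multinomial) logit.  The optimizer is
Newton–Raphson with step-halving on the multinomial log-likelihood, which
also supports fixing an arbitrary single coefficient, the primitive behind
the profile-likelihood confidence intervals and the predictor
likelihood-ratio tests.  Supplementary binary logits contrast each
sublocation inside "other" against home.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.stats import chi2

from ._profile import glm_profile_ci
from .synthetic import DISCHARGE_CATEGORIES

logger = logging.getLogger(__name__)

DEFAULT_CONTROLS = ("age", "los", "adg_score", "rural", "income_quintile")


# ---------------------------------------------------------------------------
# core optimizer
# ---------------------------------------------------------------------------

class BaselineCategoryLogit:
    """Multinomial logit with a designated reference category.

    ``y`` holds category indices 0..K-1 with 0 the reference; ``X`` is the
    (n × p) design including an intercept column.  Parameters form a
    (K-1) × p matrix of log odds versus the reference.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray):
        self.y = np.asarray(y, dtype=int)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.k = int(self.y.max()) + 1
        if self.k < 2:
            raise ValueError("need at least two observed categories")
        # one-hot of non-reference outcomes, n × (K-1)
        self.Y = np.zeros((self.n, self.k - 1))
        nz = self.y > 0
        self.Y[np.flatnonzero(nz), self.y[nz] - 1] = 1.0

    def _probs(self, B: np.ndarray) -> np.ndarray:
        eta = self.X @ B.T                       # n × (K-1)
        m = np.maximum(0.0, eta.max(axis=1, keepdims=True))
        ex = np.exp(eta - m)
        denom = np.exp(-m) + ex.sum(axis=1, keepdims=True)
        return ex / denom                        # n × (K-1), non-reference

    def loglik(self, B: np.ndarray) -> float:
        P = self._probs(B)
        pref = 1.0 - P.sum(axis=1)
        pobs = np.where(self.y == 0, pref, P[np.arange(self.n),
                                             np.maximum(self.y - 1, 0)])
        return float(np.sum(np.log(np.clip(pobs, 1e-300, None))))

    def score(self, B: np.ndarray) -> np.ndarray:
        P = self._probs(B)
        return (self.Y - P).T @ self.X           # (K-1) × p

    def _hessian(self, B: np.ndarray) -> np.ndarray:
        """Negative Hessian (observed information), flattened to
        ((K-1)p) × ((K-1)p), category-major."""
        P = self._probs(B)
        k1, p = self.k - 1, self.p
        H = np.empty((k1, k1, p, p))
        for a in range(k1):
            for b in range(a, k1):
                w = P[:, a] * (1.0 - P[:, a]) if a == b else -P[:, a] * P[:, b]
                block = (self.X * w[:, None]).T @ self.X
                H[a, b] = block
                H[b, a] = block
        return H.transpose(0, 2, 1, 3).reshape(k1 * p, k1 * p)

    def fit(self, start: np.ndarray | None = None, fixed: dict | None = None,
            tol: float = 1e-8, maxiter: int = 100) -> tuple[np.ndarray, float]:
        """Maximize the log-likelihood; ``fixed`` maps flat parameter index
        (category-major: (k-1)*p + j) to a value held constant.  Returns
        (B, loglik)."""
        k1, p = self.k - 1, self.p
        B = np.zeros((k1, p)) if start is None else start.copy()
        fixed = fixed or {}
        flat_fix = np.array(sorted(fixed), dtype=int)
        for i in flat_fix:
            B.flat[i] = fixed[i]
        free = np.setdiff1d(np.arange(k1 * p), flat_fix)
        ll = self.loglik(B)
        for _ in range(maxiter):
            g = self.score(B).reshape(-1)[free]
            if np.abs(g).max() < tol:
                return B, ll
            info = self._hessian(B)[np.ix_(free, free)]
            try:
                step = np.linalg.solve(info, g)
            except np.linalg.LinAlgError:
                raise ValueError("singular information matrix; possible "
                                 "separation in the discharge model") from None
            # step-halving on the log-likelihood
            for _ in range(40):
                Bn = B.copy()
                Bn.reshape(-1)[free] += step
                lln = self.loglik(Bn)
                if lln >= ll - 1e-12:
                    break
                step *= 0.5
            else:
                raise ValueError("step-halving failed to improve the "
                                 "multinomial log-likelihood")
            B, ll = Bn, lln
            if np.abs(B).max() > 30:
                raise ValueError("separation in the discharge model "
                                 "(|coef| > 30)")
        g = np.abs(self.score(B).reshape(-1)[free]).max()
        if g < 1e-5:
            warnings.warn(f"multinomial fit stopped at score norm {g:.2g}")
            return B, ll
        raise ValueError(f"multinomial fit did not converge (score {g:.3g})")


# ---------------------------------------------------------------------------
# model surface
# ---------------------------------------------------------------------------

@dataclass
class MultinomialFit:
    """A fitted baseline-category logit for discharge location."""

    categories: list                # reference first
    covariates: list
    params: pd.DataFrame            # (K-1) × covariates, log odds vs home
    bse: pd.DataFrame               # Wald standard errors, same shape
    conf_int: dict                  # {(category, covariate): (lo, hi)} log-odds
    llf: float
    d: int
    n: int
    lrt: dict                       # {predictor: (stat, df, p)}
    predictors: tuple = ()

    def odds_ratios(self) -> pd.DataFrame:
        out = np.exp(self.params.copy())
        return out

    def predict_probs(self, x: np.ndarray) -> np.ndarray:
        """Category probabilities (reference first) for one covariate vector
        aligned to ``self.covariates``."""
        eta = self.params.to_numpy() @ np.asarray(x, dtype=float)
        e = np.exp(np.concatenate([[0.0], eta]))
        return e / e.sum()


def restrict_discharge_cohort(cohort: pd.DataFrame,
                              required=("adg_score", "los"),
                              ) -> tuple[pd.DataFrame, dict]:
    """Acute-care patients alive at discharge with a recorded discharge
    location and complete model covariates."""
    exclusions = {}
    kept = cohort
    m = kept["source"] == "acute"
    exclusions["not_acute_care"] = int((~m).sum())
    kept = kept[m]
    died_in_hospital = kept["death_day"].notna() & (
        kept["los"].isna() | (kept["death_day"] <= kept["los"]))
    exclusions["died_in_hospital"] = int(died_in_hospital.sum())
    kept = kept[~died_in_hospital]
    m = kept["discharge_location"].notna()
    exclusions["missing_discharge_location"] = int((~m).sum())
    kept = kept[m]
    for covar in required:
        m = kept[covar].notna()
        exclusions[f"missing_{covar}"] = int((~m).sum())
        kept = kept[m]
    for k, v in exclusions.items():
        logger.info("discharge cohort exclusion %s: %d", k, v)
    if len(kept) == 0:
        raise ValueError(f"empty discharge cohort; exclusions: {exclusions}")
    return kept.reset_index(drop=True), exclusions


def _design(cohort: pd.DataFrame, predictors, controls) -> pd.DataFrame:
    X = pd.DataFrame(index=cohort.index)
    X["const"] = 1.0
    for name in list(predictors) + list(controls):
        X[name] = cohort[name].astype(float)
    return X


def _profile_ci_multinomial(model: BaselineCategoryLogit, B: np.ndarray,
                            llf: float, flat_index: int, alpha: float = 0.05,
                            tol: float = 1e-6) -> tuple[float, float]:
    cut = llf - chi2.ppf(1.0 - alpha, 1) / 2.0
    bhat = B.flat[flat_index]
    info = model._hessian(B)
    try:
        se = float(np.sqrt(np.linalg.inv(info)[flat_index, flat_index]))
    except np.linalg.LinAlgError:
        se = 0.5
    if not np.isfinite(se) or se == 0.0:
        se = 0.5

    def excess(c):
        _, ll = model.fit(start=B, fixed={flat_index: c})
        return ll - cut

    bounds = []
    for direction in (-1.0, 1.0):
        step, far = 2.0 * se, None
        for _ in range(12):
            cand = bhat + direction * step
            try:
                if excess(cand) < 0:
                    far = cand
                    break
            except ValueError:
                far = None
                break
            step *= 2.0
        if far is None:
            bounds.append(direction * np.inf)
            continue
        a, b = (far, bhat) if direction < 0 else (bhat, far)
        bounds.append(float(brentq(excess, a, b, xtol=tol)))
    return bounds[0], bounds[1]


def fit_discharge_logit(cohort: pd.DataFrame, predictors=("sex",),
                        controls=DEFAULT_CONTROLS, reference: str = "home",
                        ci_method: str = "profile",
                        categories=DISCHARGE_CATEGORIES) -> MultinomialFit:
    """Maximum-likelihood baseline-category logit of discharge location.

    Unobserved categories are dropped with a warning (reducing the degrees
    of freedom); the reference category must be observed.  The LRT for each
    predictor compares against the refit without it (df = number of
    non-reference categories).  Profile CIs are computed for the predictor
    coefficients; Wald otherwise.
    """
    obs = set(cohort["discharge_location"].dropna().unique())
    if reference not in obs:
        raise ValueError(f"reference category {reference!r} not observed")
    cats = [reference] + [c for c in categories if c != reference and c in obs]
    dropped = [c for c in categories if c not in obs]
    if dropped:
        warnings.warn(f"unobserved discharge categories dropped: {dropped}")
    if len(cats) < 2:
        raise ValueError("need at least two observed discharge categories")
    cat_idx = {c: i for i, c in enumerate(cats)}
    y = cohort["discharge_location"].map(cat_idx).to_numpy(dtype=int)
    X = _design(cohort, predictors, controls)
    model = BaselineCategoryLogit(y, X.to_numpy())
    B, llf = model.fit()
    k1, p = len(cats) - 1, X.shape[1]

    params = pd.DataFrame(B, index=cats[1:], columns=X.columns)
    try:
        cov_all = np.linalg.inv(model._hessian(B))
        bse = pd.DataFrame(
            np.sqrt(np.diag(cov_all)).reshape(k1, p), index=cats[1:],
            columns=X.columns)
    except np.linalg.LinAlgError:
        bse = params * np.nan
    ci = {}
    if ci_method == "profile":
        for pred in predictors:
            j = list(X.columns).index(pred)
            for a, cat in enumerate(cats[1:]):
                ci[(cat, pred)] = _profile_ci_multinomial(model, B, llf,
                                                          a * p + j)
    elif ci_method == "wald":
        z = chi2.ppf(0.95, 1) ** 0.5
        for pred in predictors:
            for cat in cats[1:]:
                b, se = params.loc[cat, pred], bse.loc[cat, pred]
                ci[(cat, pred)] = (b - z * se, b + z * se)
    else:
        raise ValueError("ci_method must be 'profile' or 'wald'")

    lrt = {}
    for pred in predictors:
        Xr = X.drop(columns=[pred])
        _, ll0 = BaselineCategoryLogit(y, Xr.to_numpy()).fit()
        stat = max(0.0, 2.0 * (llf - ll0))
        lrt[pred] = (stat, k1, float(chi2.sf(stat, k1)))

    return MultinomialFit(categories=cats, covariates=list(X.columns),
                          params=params, bse=bse, conf_int=ci, llf=llf,
                          d=k1 * p, n=len(y), lrt=lrt,
                          predictors=tuple(predictors))


def other_subgroup_logits(cohort: pd.DataFrame, predictors=("gender_score",),
                          controls=DEFAULT_CONTROLS, min_events: int = 2,
                          ci_method: str = "profile") -> dict:
    """Binary logistic fits of each "other" sublocation versus home on the
    same covariates; rows per fit are the home rows plus that sublocation's
    rows.  Sublocations with fewer than ``min_events`` rows are skipped with
    a warning."""
    home = cohort[cohort["discharge_location"] == "home"]
    other = cohort[cohort["discharge_location"] == "other"]
    out = {}
    for sub, rows in other.groupby("other_sublocation"):
        if len(rows) < min_events:
            warnings.warn(f"sublocation {sub!r} skipped ({len(rows)} rows)")
            continue
        data = pd.concat([home, rows], ignore_index=True)
        y = (data["discharge_location"] == "other").to_numpy(dtype=float)
        X = _design(data, predictors, controls)
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        ci = res.conf_int()
        ci.columns = ["lower", "upper"]
        if ci_method == "profile":
            for pred in predictors:
                ci.loc[pred] = glm_profile_ci(y, X, pred,
                                              sm.families.Binomial())
        out[sub] = {"params": res.params, "conf_int": ci,
                    "odds_ratios": np.exp(res.params), "n": len(data),
                    "n_sublocation": len(rows), "llf": float(res.llf)}
    return out


def discharge_model_suite(cohort: pd.DataFrame,
                          score_column: str = "gender_score",
                          controls=DEFAULT_CONTROLS,
                          ci_method: str = "profile") -> dict:
    """The three discharge models on identical rows: sex only, gender score
    only, both (each plus shared controls)."""
    restricted, _ = restrict_discharge_cohort(cohort)
    work = restricted.rename(columns={score_column: "gender_score"}) \
        if score_column != "gender_score" else restricted
    fits = {
        "sex_only": fit_discharge_logit(work, ("sex",), controls,
                                        ci_method=ci_method),
        "gender_only": fit_discharge_logit(work, ("gender_score",), controls,
                                           ci_method=ci_method),
        "both": fit_discharge_logit(work, ("sex", "gender_score"), controls,
                                    ci_method=ci_method),
    }
    d1, d2, d3 = (fits[k].d for k in ("sex_only", "gender_only", "both"))
    k1 = len(fits["both"].categories) - 1
    assert d1 == d2 and d3 == d1 + k1
    if len({fits[k].n for k in fits}) != 1:
        raise ValueError("row-set mismatch across discharge models")
    return fits


def discharge_report(fits: dict) -> pd.DataFrame:
    """Table-style report: one odds-ratio block per non-reference category,
    plus the predictor LRTs."""
    rows = []

    def exp(v):  # wide CI bounds may overflow to inf; that is fine here
        with np.errstate(over="ignore"):
            return float(np.exp(np.float64(v)))

    for model, fit in fits.items():
        for pred in fit.predictors:
            row = {"model": model, "predictor": pred}
            for cat in fit.categories[1:]:
                lo, hi = fit.conf_int.get((cat, pred), (np.nan, np.nan))
                row[f"or_{cat}"] = exp(fit.params.loc[cat, pred])
                row[f"or_{cat}_lower"] = exp(lo)
                row[f"or_{cat}_upper"] = exp(hi)
            stat, df, p = fit.lrt[pred]
            row.update({"lrt": stat, "df": df, "p_value": p,
                        "ll": fit.llf, "d": fit.d, "n": fit.n})
            rows.append(row)
    return pd.DataFrame(rows)
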