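"""30-day excess mortality after severe TBI.

Deaths are modelled relative to the matched general-population death rate:
the cohort is expanded to person-period (one row per patient-day) form, the
log of (interval length × daily population rate, from the life table) enters
a log-link Poisson regression as an offset, and covariate effects are
therefore multiplicative on the standardized rate,

    log(rate) = baseline + log(daily population rate) + Xβ,

which is the piecewise-exponential survival model.  Day 0 deaths occupy a
single half-length interval, with the offset scaled accordingly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._profile import glm_profile_ci
from .synthetic import MECHANISMS, life_table_lookup

logger = logging.getLogger(__name__)

#: control covariates of the mortality models; "mechanism" expands to
#: indicator columns with falls as reference
DEFAULT_CONTROLS = ("age", "adg_score", "rural", "income_quintile", "mechanism")

SEVERITY_FROM_AIS = {1: "mild", 2: "mild", 3: "moderate", 4: "severe",
                     5: "severe", 6: "severe"}


def classify_severity(ais: int, mapping: dict | None = None) -> str:
    """TBI severity category from the 6-point AIS-based scale: mild (1–2),
    moderate (3), severe (>= 4).  The boundary assignment of 4 to severe is
    configurable via ``mapping``."""
    mapping = SEVERITY_FROM_AIS if mapping is None else mapping
    try:
        return mapping[int(ais)]
    except (KeyError, ValueError):
        return "unknown"


@dataclass
class MortalityFit:
    """A fitted excess-mortality Poisson model."""

    params: pd.Series
    conf_int: pd.DataFrame           # columns lower/upper, log-rate scale
    llf: float
    d: int                           # number of estimated coefficients
    n_patients: int
    n_events: int
    baseline: str
    ci_method: str = "profile"
    predictors: tuple = ()

    @property
    def rate_ratios(self) -> pd.DataFrame:
        with np.errstate(over="ignore"):  # wide CI bounds may hit inf
            out = pd.DataFrame({"rr": np.exp(self.params)})
            out["lower"] = np.exp(self.conf_int["lower"])
            out["upper"] = np.exp(self.conf_int["upper"])
        return out


def restrict_mortality_cohort(cohort: pd.DataFrame,
                              required=("adg_score",),
                              ) -> tuple[pd.DataFrame, dict]:
    """Severe cases with known 30-day survival status and complete model
    covariates.  Returns the restricted table and an exclusion breakdown;
    an empty result raises with that breakdown."""
    exclusions = {}
    kept = cohort
    m = kept["severity"] == "severe"
    exclusions["not_severe_or_unknown_severity"] = int((~m).sum())
    kept = kept[m]
    m = kept["survival_known"].astype(bool)
    exclusions["unknown_survival_status"] = int((~m).sum())
    kept = kept[m]
    for covar in required:
        m = kept[covar].notna()
        exclusions[f"missing_{covar}"] = int((~m).sum())
        kept = kept[m]
    for k, v in exclusions.items():
        logger.info("mortality cohort exclusion %s: %d", k, v)
    if len(kept) == 0:
        raise ValueError(f"empty mortality cohort; exclusions: {exclusions}")
    return kept.reset_index(drop=True), exclusions


def expand_person_period(cohort: pd.DataFrame, life_table: pd.DataFrame,
                         carry=("sex", "gender_score", "latent_score", "age",
                                "adg_score", "rural", "income_quintile",
                                "mechanism"),
                         ) -> pd.DataFrame:
    """Person-period expansion with life-table offsets.

    A death on day k (1 <= k <= 30) becomes k unit intervals with the event
    on the last; a censored patient becomes 30 unit intervals; a day-0 death
    becomes a single interval of length 0.5 with the event.  The offset is
    ``log(interval_length × annual_rate / 365)`` at the patient's (age, sex,
    event year)."""
    annual = life_table_lookup(life_table, cohort["age"], cohort["sex"],
                               cohort["event_year"])
    daily = annual / 365.0
    dd = cohort["death_day"].to_numpy(dtype=float)
    n_rows = np.where(np.isnan(dd), 30, np.where(dd == 0, 1, dd)).astype(int)
    idx = np.repeat(np.arange(len(cohort)), n_rows)
    day = np.concatenate([np.arange(1, k + 1) for k in n_rows])
    last = np.concatenate([np.r_[np.zeros(k - 1), 1.0] for k in n_rows])
    died = np.repeat(~np.isnan(dd), n_rows)
    day0 = np.repeat(np.nan_to_num(dd, nan=-1.0) == 0, n_rows)
    event = (last.astype(bool) & died).astype(int)
    interval = np.where(day0, 0.5, 1.0)
    day = np.where(day0, 0, day)

    pp = pd.DataFrame({
        "patient_id": cohort["patient_id"].to_numpy()[idx],
        "day": day,
        "event": event,
        "interval_length": interval,
        "log_offset": np.log(interval * daily[idx]),
    })
    for c in carry:
        if c in cohort.columns:
            pp[c] = cohort[c].to_numpy()[idx]
    return pp


def person_period_loglik(pp: pd.DataFrame, params: pd.Series, X: pd.DataFrame,
                         ) -> float:
    """Poisson log-likelihood of a person-period table at given coefficients
    (events are 0/1 so the factorial term vanishes)."""
    mu = np.exp(X.to_numpy() @ params.to_numpy() + pp["log_offset"].to_numpy())
    y = pp["event"].to_numpy()
    return float(np.sum(y * np.log(mu) - mu))


def build_design(pp: pd.DataFrame, predictors=(), controls=DEFAULT_CONTROLS,
                 baseline: str = "intercept") -> pd.DataFrame:
    """Design matrix for the Poisson fit.

    ``baseline`` is "intercept" (single constant) or "day-factor" (a
    constant plus one indicator per day beyond the first observed).
    Mechanism of injury expands to indicators with falls as reference;
    income quintile enters as a linear 1–5 term.
    """
    X = pd.DataFrame(index=pp.index)
    X["const"] = 1.0
    if baseline == "day-factor":
        days = sorted(pp["day"].unique())
        for dcat in days[1:]:
            X[f"day_{dcat}"] = (pp["day"] == dcat).astype(float)
    elif baseline != "intercept":
        raise ValueError("baseline must be 'intercept' or 'day-factor'")
    for p in predictors:
        X[p] = pp[p].astype(float)
    for c in controls:
        if c == "mechanism":
            for m in MECHANISMS[1:]:
                X[f"mechanism_{m}"] = (pp["mechanism"] == m).astype(float)
        else:
            X[c] = pp[c].astype(float)
    return X


def fit_excess_poisson(pp: pd.DataFrame, predictors=("sex",),
                       controls=DEFAULT_CONTROLS, baseline: str = "intercept",
                       ci_method: str = "profile", ci_targets=None,
                       alpha: float = 0.05) -> MortalityFit:
    """Fit the offset Poisson model and report rate ratios.

    Profile-likelihood CIs (default) are computed for ``ci_targets`` — the
    predictors of interest by default — and Wald CIs for the remaining
    coefficients; ``ci_method="wald"`` skips profiling entirely.
    """
    if pp["event"].sum() == 0:
        raise ValueError("no events in the person-period table")
    llf_shift = 0.0
    work = pp
    if baseline == "intercept":
        # Covariates are constant within patient, so the person-period
        # Poisson likelihood collapses to one row per patient (event count,
        # log total rate-weighted exposure); the event terms differ from the
        # row-level likelihood only by the parameter-free constant
        # sum over deaths of log(last interval / total person-time),
        # which is added back so the reported LL stays on the person-period
        # scale.  Fits, LRTs and profiles are unaffected.
        grp = pp.groupby("patient_id", sort=False)
        agg = grp.agg(event=("event", "sum"),
                      exposure=("log_offset", lambda s: np.exp(s).sum()),
                      total_time=("interval_length", "sum"),
                      last_interval=("interval_length", "last"))
        work = grp.head(1).set_index("patient_id").copy()
        work["event"] = agg["event"].to_numpy()
        work["log_offset"] = np.log(agg["exposure"].to_numpy())
        work = work.reset_index()
        died = agg["event"].to_numpy() > 0
        llf_shift = float(np.sum(np.log(agg["last_interval"].to_numpy()[died]
                                        / agg["total_time"].to_numpy()[died])))
    X = build_design(work, predictors, controls, baseline)
    y = work["event"].to_numpy(dtype=float)
    offset = work["log_offset"].to_numpy()
    res = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit(maxiter=200)
    if not np.all(np.isfinite(res.params)):
        raise ValueError(f"Poisson fit did not converge; score norm "
                         f"{np.abs(res.model.score(res.params)).max():.3g}")
    ci = res.conf_int(alpha=alpha)
    ci.columns = ["lower", "upper"]
    if ci_method == "profile":
        targets = list(predictors) if ci_targets is None else list(ci_targets)
        for name in targets:
            lo, hi = glm_profile_ci(y, X, name, sm.families.Poisson(),
                                    offset=offset, alpha=alpha)
            ci.loc[name] = [lo, hi]
    elif ci_method != "wald":
        raise ValueError("ci_method must be 'profile' or 'wald'")
    return MortalityFit(params=res.params, conf_int=ci,
                        llf=float(res.llf) + llf_shift,
                        d=X.shape[1], n_patients=pp["patient_id"].nunique(),
                        n_events=int(pp["event"].sum()), baseline=baseline,
                        ci_method=ci_method, predictors=tuple(predictors))


def mortality_model_suite(cohort: pd.DataFrame, life_table: pd.DataFrame,
                          score_column: str = "gender_score",
                          controls=DEFAULT_CONTROLS,
                          baseline: str = "intercept",
                          ci_method: str = "profile") -> dict:
    """The three mortality models on identical rows and offsets:
    Model 1 sex only, Model 2 gender score only, Model 3 both (each plus the
    shared controls)."""
    restricted, _ = restrict_mortality_cohort(cohort)
    if score_column not in restricted.columns:
        raise ValueError(f"cohort lacks a '{score_column}' column")
    work = restricted.rename(columns={score_column: "gender_score"}) \
        if score_column != "gender_score" else restricted
    pp = expand_person_period(work, life_table)
    fits = {
        "sex_only": fit_excess_poisson(pp, ("sex",), controls, baseline, ci_method),
        "gender_only": fit_excess_poisson(pp, ("gender_score",), controls,
                                          baseline, ci_method),
        "both": fit_excess_poisson(pp, ("sex", "gender_score"), controls,
                                   baseline, ci_method),
    }
    d1, d2, d3 = (fits[k].d for k in ("sex_only", "gender_only", "both"))
    assert d1 == d2 and d3 == d1 + 1
    if not ({fits[k].n_patients for k in fits} == {fits["both"].n_patients}):
        raise ValueError("row-set mismatch across mortality models")
    return fits


def mortality_summary(cohort: pd.DataFrame) -> dict:
    """Size, 30-day deaths and case-fatality percentage (one decimal) of a
    restricted mortality cohort."""
    n = len(cohort)
    deaths = int(cohort["death_day"].notna().sum())
    return {"n": n, "deaths": deaths,
            "percent_died": round(100.0 * deaths / n, 1) if n else float("nan")}


def mortality_report(fits: dict) -> pd.DataFrame:
    """Table-style report: one row per predictor per model with rate ratio,
    CI and the predictor's LRT against the model without it."""
    from .compare import likelihood_ratio_test

    rows = []
    ll = {k: f.llf for k, f in fits.items()}
    for model, fit in fits.items():
        for p in fit.predictors:
            rr = fit.rate_ratios.loc[p]
            if model == "both":
                reduced = "gender_only" if p == "sex" else "sex_only"
                stat, pval = likelihood_ratio_test(ll[reduced], ll["both"], 1)
            else:
                stat, pval = np.nan, np.nan
            rows.append({"model": model, "predictor": p, "rr": rr["rr"],
                         "ci_lower": rr["lower"], "ci_upper": rr["upper"],
                         "lrt": stat, "df": 1, "p_value": pval,
                         "ll": fit.llf, "d": fit.d, "n": fit.n_patients})
    return pd.DataFrame(rows)
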