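"""Derivation of the gender score from diagnostic-code indicators.

The score operationalizes "gender diagnosticity": the fitted probability that
a person is female given their recorded diagnostic codes.  Codes are first
screened one at a time with univariate logistic regressions of sex (female
= 1) on the code indicator; codes significant at the 5% level after
multiplicity correction (Benjamini–Hochberg by default, Bonferroni
selectable) in BOTH the training and the validation set enter a multivariate
logistic model fitted on the training set, whose predicted probabilities on
held-out patients are the gender scores (0 = "man-like", 1 = "woman-like").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .codes import CodeIndicatorMatrix

logger = logging.getLogger(__name__)

_MAX_ABS_COEF = 15.0  # larger fitted log-odds indicate (quasi-)separation


@dataclass
class GenderScoreModel:
    """Selected code set plus fitted logistic coefficients."""

    selected_codes: list
    intercept: float
    coefficients: np.ndarray  # aligned to selected_codes
    training_n: int


def univariate_screen(matrix: CodeIndicatorMatrix) -> pd.DataFrame:
    """One logistic fit of sex on each single code indicator.

    With a single binary covariate the logistic MLE is available in closed
    form from the 2×2 (carriage × sex) table: the slope is the log
    cross-product ratio and the intercept the log odds of female among
    non-carriers.  The p-value is the likelihood-ratio test of the slope
    against the intercept-only model (χ², 1 df).  Degenerate tables (a zero
    margin or a zero cell) are flagged non-converged, get ``p = NaN`` and
    are treated as non-significant downstream.

    Returns a frame with one row per code: ``code, n_carriers,
    odds_ratio_female, lrt, p_value, converged``.
    """
    n = len(matrix.patient_ids)
    fem = (matrix.sex == 1)
    nf, nm = int(fem.sum()), int((~fem).sum())
    rows = []
    for j, code in enumerate(matrix.code_labels):
        x = matrix.indicators[:, j].astype(bool)
        a = int((x & fem).sum())       # carriers, female
        b = int(x.sum()) - a           # carriers, male
        c, d = nf - a, nm - b          # non-carriers
        converged = min(a, b, c, d) > 0
        if converged:
            orf = (a * d) / (b * c)
            ll1 = (a * np.log(a / (a + b)) + b * np.log(b / (a + b))
                   + c * np.log(c / (c + d)) + d * np.log(d / (c + d)))
            p0 = nf / n
            ll0 = nf * np.log(p0) + nm * np.log(1 - p0)
            lrt = max(0.0, 2.0 * (ll1 - ll0))
            p = float(chi2.sf(lrt, 1))
        else:
            orf, lrt, p = np.nan, np.nan, np.nan
        rows.append((code, a + b, orf, lrt, p, converged))
    return pd.DataFrame(rows, columns=["code", "n_carriers",
                                       "odds_ratio_female", "lrt",
                                       "p_value", "converged"])


def adjust_pvalues(p_values, alpha: float = 0.05, method: str = "bh") -> np.ndarray:
    """Rejection flags at family level ``alpha``.

    ``method`` is ``"bh"`` (Benjamini–Hochberg step-up) or ``"bonferroni"``.
    Missing p-values (non-converged fits) are never rejected and do not
    count toward the family size.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    method = method.lower()
    if method not in ("bh", "bonferroni"):
        raise ValueError("method must be 'bh' or 'bonferroni'")
    p = np.asarray(p_values, dtype=float)
    out = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        sm_method = "fdr_bh" if method == "bh" else "bonferroni"
        out[ok] = multipletests(p[ok], alpha=alpha, method=sm_method)[0]
    return out


def select_codes(train_results: pd.DataFrame, validation_results: pd.DataFrame,
                 alpha: float = 0.05, method: str = "bh") -> list:
    """Codes significant after correction in BOTH screens, label-sorted.

    Selection is by significance only; opposite odds-ratio directions
    between the two sets are logged, not excluded.
    """
    if sorted(train_results["code"]) != sorted(validation_results["code"]):
        raise ValueError("train and validation screens cover different vocabularies")
    tr = train_results.set_index("code")
    va = validation_results.set_index("code").loc[tr.index]
    sig_t = adjust_pvalues(tr["p_value"].to_numpy(), alpha, method)
    sig_v = adjust_pvalues(va["p_value"].to_numpy(), alpha, method)
    both = tr.index.to_numpy()[sig_t & sig_v]
    selected = sorted(both)
    for c in selected:
        ot, ov = tr.loc[c, "odds_ratio_female"], va.loc[c, "odds_ratio_female"]
        if (ot - 1.0) * (ov - 1.0) < 0:
            logger.warning("code %s selected with discordant OR directions "
                           "(train %.3f, validation %.3f)", c, ot, ov)
    logger.info("selected %d of %d screened codes (alpha=%g, method=%s)",
                len(selected), len(tr), alpha, method)
    return selected


def fit_score_model(matrix: CodeIndicatorMatrix, selected_codes=None,
                    ) -> GenderScoreModel:
    """Multivariate logistic fit of sex on the selected code indicators
    (maximum likelihood, no regularization).

    Raises if no codes are selected or if the fit fails to converge or shows
    signs of separation — in that case revisit the code filters.
    """
    if selected_codes is None:
        selected_codes = list(matrix.code_labels)
    selected_codes = list(selected_codes)
    if len(selected_codes) == 0:
        raise ValueError("no selected codes: cannot fit a gender score model")
    if len(set(selected_codes)) != len(selected_codes):
        raise ValueError("duplicate selected codes")
    sub = matrix.restrict(selected_codes)
    X = pd.DataFrame(sub.indicators.astype(float), columns=selected_codes)
    X.insert(0, "const", 1.0)
    y = (sub.sex == 1).astype(float)
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as err:  # perfect separation can abort IRLS
        raise ValueError(
            f"gender score model failed to fit ({err}); review the code "
            "filters for separation") from None
    params = res.params.to_numpy()
    if not np.all(np.isfinite(params)) or np.abs(params).max() > _MAX_ABS_COEF:
        worst = X.columns[int(np.abs(params).argmax())]
        raise ValueError(
            f"gender score model shows separation (|coef| > {_MAX_ABS_COEF} "
            f"for {worst}); review the code filters")
    return GenderScoreModel(selected_codes=selected_codes,
                            intercept=float(params[0]),
                            coefficients=params[1:],
                            training_n=len(y))


def compute_scores(model: GenderScoreModel, matrix: CodeIndicatorMatrix) -> np.ndarray:
    """Inverse-logit of the fitted linear predictor; codes absent from
    ``matrix`` count as not carried.  Column order of ``matrix`` is
    irrelevant."""
    sub = matrix.restrict(model.selected_codes)
    eta = model.intercept + sub.indicators.astype(float) @ model.coefficients
    return expit(eta)


def summarize_scores(scores, sex, age, bin_width: float = 0.02) -> dict:
    """Distribution summaries by sex and by age decade.

    Returns ``{"by_sex": frame, "by_age_decade": frame, "histogram": frame}``
    with per-group quantiles (min, Q1, median, Q3, max) and histogram bin
    counts over [0, 1].  Groups with no members are simply absent.
    """
    scores = np.asarray(scores, dtype=float)
    sex = np.asarray(sex)
    age = np.asarray(age)
    if not (len(scores) == len(sex) == len(age)):
        raise ValueError("scores, sex and age must be aligned")
    df = pd.DataFrame({"score": scores, "sex": sex,
                       "decade": (age // 10) * 10})

    def q(g):
        return pd.Series({
            "n": len(g), "min": g.min(), "q1": g.quantile(0.25),
            "median": g.median(), "q3": g.quantile(0.75), "max": g.max(),
            "mean": g.mean(),
        })

    by_sex = df.groupby("sex")["score"].apply(q).unstack()
    by_dec = df.groupby("decade")["score"].apply(q).unstack()
    nbins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    hists = {}
    for s, g in df.groupby("sex"):
        hists[s], _ = np.histogram(g["score"], bins=edges)
    hist = pd.DataFrame(hists, index=pd.IntervalIndex.from_breaks(edges))
    return {"by_sex": by_sex, "by_age_decade": by_dec, "histogram": hist}
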