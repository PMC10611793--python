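"""Non-nested comparison of the sex-only and gender-score-only models.

The two single-effect models (Model 1: sex, Model 2: gender score, sharing
all control variables) are not nested in each other, but both nest inside
the full model (Model 3: both effects).  Two complementary readings:

* indirect — test each effect inside the full model with a likelihood-ratio
  test; one significant and the other not is evidence for the model keeping
  only the significant effect;
* direct — approximate the Bayes factor between the two single-effect
  models through their BIC difference.  Because the two models spend the
  same degrees of freedom, the BIC penalty cancels and

      ΔBIC₁₂ = LRT_S − LRT_G,      BF₁₂ ≈ exp{(LRT_S − LRT_G) / 2},

  where LRT_S and LRT_G are the full-model likelihood-ratio statistics for
  sex and gender score.  Evidence strength is read off the Kass–Raftery
  scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.stats import chi2

KASS_RAFTERY_BANDS = (
    (3.0, "not worth more than a mention"),
    (20.0, "positive"),
    (150.0, "strong"),
    (math.inf, "very strong"),
)


def likelihood_ratio_test(ll_reduced: float, ll_full: float,
                          df_diff: int) -> tuple[float, float]:
    """LRT statistic −2(LL_reduced − LL_full), clipped at 0, with its
    χ²(df_diff) upper-tail p-value."""
    if df_diff <= 0:
        raise ValueError("df_diff must be >= 1")
    if ll_full < ll_reduced - 1e-8:
        raise ValueError("full model log-likelihood below reduced model's")
    stat = max(0.0, -2.0 * (ll_reduced - ll_full))
    return stat, float(chi2.sf(stat, df_diff))


def delta_bic(ll_1: float, d_1: int, ll_2: float, d_2: int, n: float) -> float:
    """BIC difference favouring model 1: 2(LL₁ − LL₂) − (d₁ − d₂)·ln(n).
    The penalty term vanishes when the two models have equal degrees of
    freedom."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2.0 * (ll_1 - ll_2) - (d_1 - d_2) * math.log(n)


def bayes_factor_from_bic(delta_bic_12: float) -> float:
    """BF₁₂ ≈ exp(ΔBIC₁₂ / 2)."""
    if not math.isfinite(delta_bic_12):
        raise ValueError("delta BIC must be finite")
    try:
        return math.exp(delta_bic_12 / 2.0)
    except OverflowError:
        warnings.warn("Bayes factor overflow; returning inf")
        return math.inf


def bayes_factor_from_lrt(lrt_s: float, lrt_g: float) -> float:
    """BF₁₂ ≈ exp{(LRT_S − LRT_G)/2}; valid when the two single-effect
    models have equal degrees of freedom (the caller's responsibility)."""
    if lrt_s < 0 or lrt_g < 0:
        raise ValueError("LRT statistics must be non-negative")
    try:
        return math.exp((lrt_s - lrt_g) / 2.0)
    except OverflowError:
        warnings.warn("Bayes factor overflow; returning inf")
        return math.inf


def interpret_kass_raftery(bf: float) -> tuple[str, str]:
    """Kass–Raftery label for a Bayes factor.

    Returns ``(label, favored)`` with ``favored`` in {"model_1", "model_2",
    "equivocal"}; an input below 1 is inverted and attributed to model 2.
    Band boundaries (exactly 3, 20, 150) fall in the lower band.
    """
    if not bf > 0:
        raise ValueError("Bayes factor must be positive")
    favored = "equivocal" if bf == 1 else ("model_1" if bf > 1 else "model_2")
    mag = bf if bf >= 1 else 1.0 / bf
    for upper, label in KASS_RAFTERY_BANDS:
        if mag <= upper:
            return label, favored
    raise AssertionError("unreachable")


def format_bf(bf: float) -> float:
    """Report a Bayes factor at one significant figure above 10⁴ (matching
    the "4 × 10⁵" convention), full precision below."""
    if bf > 1e4 and math.isfinite(bf):
        exp = math.floor(math.log10(bf))
        return round(bf / 10 ** exp) * 10 ** exp
    return bf


@dataclass
class ComparisonResult:
    """Full-model effect tests plus the direct Bayes-factor comparison of
    the two single-effect models."""

    lrt_s: float
    lrt_g: float
    df_s: int
    df_g: int
    p_s: float
    p_g: float
    delta_bic_12: float
    bf_12: float
    n: float
    interpretation: str
    favored: str                 # "sex", "gender_score" or "equivocal"
    indirect_verdict: str

    @property
    def bf_21(self) -> float:
        return math.inf if self.bf_12 == 0 else 1.0 / self.bf_12

    def as_dict(self) -> dict:
        return {
            "lrt_sex": self.lrt_s, "lrt_gender": self.lrt_g,
            "df_sex": self.df_s, "df_gender": self.df_g,
            "p_sex": self.p_s, "p_gender": self.p_g,
            "delta_bic_12": self.delta_bic_12,
            "bf_sex_over_gender": format_bf(self.bf_12),
            "bf_gender_over_sex": format_bf(self.bf_21),
            "n": self.n, "interpretation": self.interpretation,
            "favored": self.favored, "indirect_verdict": self.indirect_verdict,
        }


def compare_sex_vs_gender(fit_sex, fit_gender, fit_both, n: float | None = None,
                          alpha: float = 0.05,
                          allow_unequal_df: bool = False) -> ComparisonResult:
    """Compare the sex-only and gender-only models through the full model.

    The fits must expose ``llf`` and ``d`` and share rows and controls.
    With equal single-model degrees of freedom the Bayes factor comes from
    the LRT shortcut; otherwise an explicit ``n`` is required (and
    ``allow_unequal_df=True``) to fall back on the raw BIC difference.
    """
    ll1, ll2, ll3 = fit_sex.llf, fit_gender.llf, fit_both.llf
    d1, d2, d3 = fit_sex.d, fit_gender.d, fit_both.d
    df_s = d3 - d2
    df_g = d3 - d1
    lrt_s, p_s = likelihood_ratio_test(ll2, ll3, df_s)
    lrt_g, p_g = likelihood_ratio_test(ll1, ll3, df_g)
    if d1 == d2:
        dbic = lrt_s - lrt_g
        bf12 = bayes_factor_from_lrt(lrt_s, lrt_g)
        n_used = float("nan") if n is None else n
    else:
        if not allow_unequal_df:
            raise ValueError("single-effect models have unequal degrees of "
                             "freedom; the LRT shortcut is invalid")
        if n is None:
            raise ValueError("explicit n required when degrees of freedom differ")
        dbic = delta_bic(ll1, d1, ll2, d2, n)
        bf12 = bayes_factor_from_bic(dbic)
        n_used = n
    label, fav = interpret_kass_raftery(bf12)
    favored = {"model_1": "sex", "model_2": "gender_score",
               "equivocal": "equivocal"}[fav]
    sig_s, sig_g = p_s < alpha, p_g < alpha
    if sig_s and not sig_g:
        indirect = "sex significant, gender score not: prefer sex-only model"
    elif sig_g and not sig_s:
        indirect = ("gender score significant, sex not: prefer "
                    "gender-score-only model")
    elif sig_s and sig_g:
        indirect = "both effects significant: no clear preference"
    else:
        indirect = "neither effect significant: equivocal"
    return ComparisonResult(lrt_s=lrt_s, lrt_g=lrt_g, df_s=df_s, df_g=df_g,
                            p_s=p_s, p_g=p_g, delta_bic_12=dbic, bf_12=bf12,
                            n=n_used, interpretation=label, favored=favored,
                            indirect_verdict=indirect)
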