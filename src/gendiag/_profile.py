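"""Profile-likelihood confidence intervals for log-link / logit GLMs.

A coefficient is profiled by fixing it at a candidate value c — its column
times c moves into the offset — refitting the remaining parameters, and
locating the two values where twice the log-likelihood drop from the full
fit equals the chi-square(1) quantile.  Root finding is bisection-based
(``brentq``) to a configurable tolerance on the coefficient scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.stats import chi2


def glm_profile_ci(y, X, name, family, offset=None, freq_weights=None,
                   alpha: float = 0.05, tol: float = 1e-6,
                   max_expand: int = 12) -> tuple[float, float]:
    """95% (by default) profile-likelihood CI for coefficient ``name``.

    ``X`` is a pandas DataFrame design matrix including the intercept.
    Returns ``(lower, upper)``; a bound that cannot be bracketed within
    ``max_expand`` doublings of the Wald radius comes back as ±inf with a
    warning (a sign of separation or an unbounded profile).
    """
    full = sm.GLM(y, X, family=family, offset=offset,
                  freq_weights=freq_weights).fit()
    bhat = float(full.params[name])
    se = float(full.bse[name])
    if not np.isfinite(se) or se == 0.0:
        se = 0.5
    cut = full.llf - chi2.ppf(1.0 - alpha, 1) / 2.0

    Xr = X.drop(columns=[name])
    xj = np.asarray(X[name], dtype=float)
    base = np.zeros(len(xj)) if offset is None else np.asarray(offset, dtype=float)
    warm = full.params.drop(name).to_numpy()

    def excess(c):
        fit = sm.GLM(y, Xr, family=family, offset=base + c * xj,
                     freq_weights=freq_weights).fit(start_params=warm,
                                                    maxiter=200)
        return fit.llf - cut

    bounds = []
    for direction in (-1.0, +1.0):
        step, lo_c = 2.0 * se, None
        for _ in range(max_expand):
            cand = bhat + direction * step
            if excess(cand) < 0.0:
                lo_c = cand
                break
            step *= 2.0
        if lo_c is None:
            warnings.warn(f"profile for {name} unbounded towards "
                          f"{'-' if direction < 0 else '+'}inf")
            bounds.append(direction * np.inf)
            continue
        a, b = (lo_c, bhat) if direction < 0 else (bhat, lo_c)
        bounds.append(float(brentq(excess, a, b, xtol=tol)))
    return bounds[0], bounds[1]
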