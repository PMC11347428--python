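"""Multivariable MR: direct effects of each exposure conditional on the others.

Both estimators are weighted least squares of the outcome effects on the
J x K matrix of exposure effects (weights se_out^-2): MV-IVW without an
intercept, MVMR-Egger with an intercept after orienting rows on a chosen
exposure.  SE inflation is multiplicative and floored at 1, mirroring the
univariable convention.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .sumstats import HarmonizedSet
from .uvmr import EstimationError, MrEstimate


class CollinearityError(EstimationError):
    pass


def _wls(x, y, w, df_resid):
    ws = np.sqrt(w)
    xw = x * ws[:, None]
    yw = y * ws
    xtx = xw.T @ xw
    if np.linalg.matrix_rank(xtx) < x.shape[1]:
        raise CollinearityError("rank-deficient exposure design")
    coef = np.linalg.solve(xtx, xw.T @ yw)
    resid = yw - xw @ coef
    rss = float(resid @ resid)
    sigma2 = max(rss / df_resid, 1.0) if df_resid > 0 else 1.0
    cov = sigma2 * np.linalg.inv(xtx)
    return coef, np.sqrt(np.diag(cov)), rss


def mvmr_ivw(h: HarmonizedSet) -> list:
    """MV-IVW: per-exposure direct effects by zero-intercept WLS.

    Requires K >= 2 exposures and J >= K+1 instruments (the union of each
    exposure's instruments, harmonized to the outcome).  With K = 1 this
    reduces exactly to univariable IVW.
    """
    j, k = h.b_exp.shape
    if j < k + 1:
        raise EstimationError(f"MV-IVW needs J >= K+1 (J={j}, K={k})")
    w = 1.0 / h.se_out ** 2
    coef, ses, rss = _wls(h.b_exp, h.b_out, w, j - k)
    q = rss  # weighted RSS of the no-intercept fit is the MVMR Q statistic
    out = []
    for idx in range(k):
        beta, se = float(coef[idx]), float(ses[idx])
        out.append(MrEstimate(
            method="mv_ivw", beta=beta, se=se,
            pval=float(2.0 * sps.norm.sf(abs(beta) / se)), n_snp=j,
            exposure=h.exposure_names[idx], outcome=h.outcome_name,
            extras={"Q": q, "Q_df": j - k,
                    "Q_p": float(sps.chi2.sf(q, j - k))},
        ))
    return out


def mvmr_egger(h: HarmonizedSet, orient_on: int = 0):
    """MVMR-Egger: WLS with intercept after orienting on one exposure.

    Every SNP's row (all exposure effects and the outcome effect) is
    sign-flipped so the ``orient_on`` exposure's effect is non-negative; the
    intercept is the pleiotropy diagnostic.  Returns ``(estimates,
    intercept_dict)``.
    """
    j, k = h.b_exp.shape
    if j < k + 2:
        raise EstimationError(f"MVMR-Egger needs J >= K+2 (J={j}, K={k})")
    flip = np.sign(h.b_exp[:, orient_on])
    flip[flip == 0] = 1.0
    x = np.column_stack([np.ones(j), h.b_exp * flip[:, None]])
    y = h.b_out * flip
    w = 1.0 / h.se_out ** 2
    coef, ses, rss = _wls(x, y, w, j - k - 1)
    df = j - k - 1
    intercept = {
        "egger_intercept": float(coef[0]),
        "egger_intercept_se": float(ses[0]),
        "egger_intercept_p": float(2.0 * sps.t.sf(abs(coef[0]) / ses[0], df)),
    }
    out = []
    for idx in range(k):
        beta, se = float(coef[idx + 1]), float(ses[idx + 1])
        out.append(MrEstimate(
            method="mvmr_egger", beta=beta, se=se,
            pval=float(2.0 * sps.t.sf(abs(beta) / se, df)), n_snp=j,
            exposure=h.exposure_names[idx], outcome=h.outcome_name,
            extras=dict(intercept, Q=rss, Q_df=df),
        ))
    return out, intercept
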