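"""Heterogeneity, pleiotropy, outlier, directionality and instrument-strength diagnostics.

Covers Cochran's Q, the MR-Egger intercept test, MR-PRESSO (global, outlier
and distortion tests by parametric simulation), radial-MR outlier detection,
Steiger directionality filtering and (conditional) F-statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .sumstats import HarmonizedSet
from .uvmr import ivw, mr_egger, _single_exposure


@dataclass
class SensitivityReport:
    q_stat: float = np.nan
    q_df: int = 0
    q_pval: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_se: float = np.nan
    egger_intercept_p: float = np.nan
    presso_global_p: float = np.nan
    presso_outlier_ids: list = field(default_factory=list)
    presso_distortion_p: float = np.nan
    radial_outlier_ids: list = field(default_factory=list)
    steiger_dropped_ids: list = field(default_factory=list)
    f_stat_mean: float = np.nan
    f_stat_min: float = np.nan
    conditional_f: dict = field(default_factory=dict)


def cochran_q(h: HarmonizedSet, theta: float | None = None):
    """Cochran's Q over per-SNP ratio estimates with first-order SEs.

    ``theta`` defaults to the fixed-effect IVW estimate.  Returns (Q, df, p)
    with p from the upper tail of chi-square on J-1 df.
    """
    bx, sx, by, sy = _single_exposure(h)
    keep = bx != 0
    bx, by, sy = bx[keep], by[keep], sy[keep]
    j = len(bx)
    if j < 2:
        raise ValueError("Cochran's Q needs at least 2 SNPs")
    if theta is None:
        theta = ivw(h, mode="fixed").beta
    ratios = by / bx
    sig2 = sy ** 2 / bx ** 2
    q = float(np.sum((ratios - theta) ** 2 / sig2))
    df = j - 1
    return q, df, float(sps.chi2.sf(q, df))


def egger_intercept_test(h: HarmonizedSet):
    """MR-Egger intercept with SE and two-sided t p-value (J-2 df).

    A non-zero intercept indicates average directional pleiotropy.
    """
    est = mr_egger(h)
    x = est.extras
    return x["egger_intercept"], x["egger_intercept_se"], x["egger_intercept_p"]


# ---------------------------------------------------------------------------
# MR-PRESSO


def _loo_ivw_theta(bx, by, w):
    """Leave-one-out fixed-effect IVW estimates, vectorized over SNPs."""
    sxy = np.sum(bx * by * w)
    sxx = np.sum(bx ** 2 * w)
    return (sxy - bx * by * w) / (sxx - bx ** 2 * w)


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, outlier_alpha: float = 0.05,
              seed: int = 0):
    """MR-PRESSO: pleiotropy residual sum and outlier test by parametric simulation.

    The observed statistic is the sum over SNPs of the inverse-variance
    weighted squared residual of ``b_out`` about the leave-one-out IVW
    prediction.  The null distribution is built from ``n_sim`` parametric
    draws ``b_exp' ~ N(b_exp, se_exp^2)``, ``b_out' ~ N(theta_(-j) b_exp,
    se_out^2)``.  Per-SNP outlier p-values are Bonferroni-adjusted against
    ``outlier_alpha``; when outliers are found a distortion test compares the
    outlier-corrected IVW estimate with the distribution obtained by removing
    random SNP subsets of the same size.

    Returns a dict with ``global_p``, ``outlier_ids``, ``distortion_p`` and
    ``corrected_estimate``.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    bx, sx, by, sy = _single_exposure(h)
    j = len(bx)
    if j < 4:
        raise ValueError("MR-PRESSO needs at least 4 SNPs")
    rng = np.random.default_rng(seed)
    w = 1.0 / sy ** 2

    theta_loo = _loo_ivw_theta(bx, by, w)
    resid_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(resid_obs.sum())

    # simulated null: (n_sim, J) draws
    bx_sim = rng.normal(bx, sx, size=(n_sim, j))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, j))
    sxy = np.sum(bx_sim * by_sim * w, axis=1, keepdims=True)
    sxx = np.sum(bx_sim ** 2 * w, axis=1, keepdims=True)
    theta_loo_sim = (sxy - bx_sim * by_sim * w) / (sxx - bx_sim ** 2 * w)
    resid_sim = w * (by_sim - theta_loo_sim * bx_sim) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_p = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))

    # per-SNP outlier test, Bonferroni across J
    p_snp = (np.sum(resid_sim >= resid_obs[None, :], axis=0) + 1) / (n_sim + 1)
    outlier_mask = p_snp * j < outlier_alpha
    outlier_ids = [str(s) for s in h.snp_ids[outlier_mask]]

    distortion_p = np.nan
    corrected = None
    if outlier_mask.any() and (~outlier_mask).sum() >= 2:
        kept = h.subset(~outlier_mask)
        corrected = ivw(kept, mode="fixed")
        theta_all = ivw(h, mode="fixed").beta
        obs_dist = (corrected.beta - theta_all) / abs(corrected.beta)
        n_out = int(outlier_mask.sum())
        sims = np.empty(n_sim)
        for s in range(n_sim):
            drop = rng.choice(j, size=n_out, replace=False)
            m = np.ones(j, bool)
            m[drop] = False
            th = np.sum(bx[m] * by[m] * w[m]) / np.sum(bx[m] ** 2 * w[m])
            sims[s] = (th - theta_all) / abs(th) if th != 0 else np.nan
        sims = sims[np.isfinite(sims)]
        distortion_p = float((np.sum(np.abs(sims) >= abs(obs_dist)) + 1)
                             / (len(sims) + 1))

    return {
        "global_p": global_p,
        "outlier_ids": outlier_ids,
        "distortion_p": distortion_p,
        "corrected_estimate": corrected,
        "rss_obs": rss_obs,
    }


# ---------------------------------------------------------------------------
# Radial MR


def radial_outliers(h: HarmonizedSet, alpha: float = 0.05):
    """Radial-transform IVW with per-SNP Q contributions.

    With first-order weights ``w_j = (b_exp/se_out)^2`` the radial coordinates
    are ``x_j = sqrt(w_j)``, ``y_j = ratio_j sqrt(w_j)``; the zero-intercept
    slope equals IVW and the per-SNP squared residuals decompose Cochran's Q
    exactly.  A SNP is an outlier when its Q_j exceeds the chi-square(1)
    critical value at ``alpha``.

    Returns ``(radial_estimate, outlier_ids, per_snp_q)``.
    """
    bx, sx, by, sy = _single_exposure(h)
    keep = bx != 0
    bx, by, sy = bx[keep], by[keep], sy[keep]
    ids = h.snp_ids[keep]
    w = (bx / sy) ** 2
    ratios = by / bx
    x = np.sqrt(w)
    y = ratios * np.sqrt(w)
    slope = float(np.sum(x * y) / np.sum(x * x))
    q_j = (y - slope * x) ** 2
    p_j = sps.chi2.sf(q_j, 1)
    outlier_ids = [str(s) for s in ids[p_j < alpha]]
    return slope, outlier_ids, q_j


# ---------------------------------------------------------------------------
# Steiger filtering


def steiger_filter(h: HarmonizedSet, n_exp: int, n_out: int, alpha: float = 0.05):
    """Drop SNPs that explain significantly more variance in the outcome.

    Variance explained per SNP is recovered from its F-statistic,
    ``r^2 = F / (F + n - 2)`` with ``F = (b/se)^2`` — usable even without
    allele frequencies.  A SNP is dropped when ``r^2_out > r^2_exp`` and the
    z-test on Fisher-transformed correlations (variance 1/(n-3) each) is
    significant at ``alpha``.

    Returns ``(kept HarmonizedSet, dropped_ids, direction_p)``.
    """
    bx, sx, by, sy = _single_exposure(h)
    f_x = (bx / sx) ** 2
    f_y = (by / sy) ** 2
    r2_x = f_x / (f_x + n_exp - 2)
    r2_y = f_y / (f_y + n_out - 2)
    zdiff = (np.arctanh(np.sqrt(r2_x)) - np.arctanh(np.sqrt(r2_y))) / np.sqrt(
        1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    p = 2.0 * sps.norm.sf(np.abs(zdiff))
    drop = (r2_y > r2_x) & (p < alpha)
    kept = h.subset(~drop) if (~drop).any() else None
    dropped_ids = [str(s) for s in h.snp_ids[drop]]
    return kept, dropped_ids, p


# ---------------------------------------------------------------------------
# Instrument strength


def instrument_strength(h: HarmonizedSet):
    """Per-SNP and mean F-statistics; conditional F per exposure when K >= 2.

    The conditional F for exposure k regresses its instrument effects on the
    other exposures' effects (weighted by se^-2, no intercept) and scales the
    weighted residual sum by 1/(J - K): a practical proxy for the
    Sanderson-Windmeijer conditional F.  F > 10 is the conventional adequacy
    bound.
    """
    f_snp = (h.b_exp / h.se_exp) ** 2  # (J, K)
    out = {
        "f_per_snp": f_snp,
        "f_mean": f_snp.mean(axis=0),
        "f_min": f_snp.min(axis=0),
        "conditional_f": {},
    }
    j, k = h.b_exp.shape
    if k >= 2:
        if j <= k:
            raise ValueError("conditional F needs J > K")
        for idx in range(k):
            others = [c for c in range(k) if c != idx]
            y = h.b_exp[:, idx]
            x = h.b_exp[:, others]
            w = 1.0 / h.se_exp[:, idx] ** 2
            ws = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(x * ws[:, None], y * ws, rcond=None)
            resid = y - x @ coef
            cond_f = float(np.sum(resid ** 2 * w) / (j - k))
            out["conditional_f"][h.exposure_names[idx]] = cond_f
    return out


def full_report(h: HarmonizedSet, n_exp: int | None = None, n_out: int | None = None,
                n_sim: int = 1000, seed: int = 0) -> SensitivityReport:
    """Run every applicable diagnostic and bundle the results."""
    rep = SensitivityReport()
    j = h.n_snp
    if h.n_exposure == 1:
        if j >= 2:
            rep.q_stat, rep.q_df, rep.q_pval = cochran_q(h)
        if j >= 3:
            (rep.egger_intercept, rep.egger_intercept_se,
             rep.egger_intercept_p) = egger_intercept_test(h)
            _, rep.radial_outlier_ids, _ = radial_outliers(h)
        if j >= 4:
            presso = mr_presso(h, n_sim=n_sim, seed=seed)
            rep.presso_global_p = presso["global_p"]
            rep.presso_outlier_ids = presso["outlier_ids"]
            rep.presso_distortion_p = presso["distortion_p"]
        if n_exp and n_out:
            _, rep.steiger_dropped_ids, _ = steiger_filter(h, n_exp, n_out)
    strength = instrument_strength(h)
    rep.f_stat_mean = float(strength["f_mean"][0])
    rep.f_stat_min = float(strength["f_min"][0])
    rep.conditional_f = strength["conditional_f"]
    return rep
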