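"""Univariable two-sample MR estimators.

All estimators consume a :class:`~medimr.sumstats.HarmonizedSet` with a single
exposure (K = 1) and return an :class:`MrEstimate` on the log-OR / SD scale.
Implemented methods: per-SNP Wald ratios, IVW (fixed and multiplicative random
effects), MR-Egger, weighted median (bootstrap SE), maximum likelihood
(profile), constrained ML with BIC model averaging (cML-MA), and a GSMR-style
estimator for clumped instruments with HEIDI-outlier removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .sumstats import HarmonizedSet


class EstimationError(RuntimeError):
    pass


class InsufficientInstrumentsError(EstimationError):
    """Raised when a method's instrument-count floor is not met."""


@dataclass
class MrEstimate:
    """A causal-effect estimate with 95% CI and method-specific diagnostics.

    ``beta`` is on the log-OR scale for binary outcomes and the SD scale for
    quantitative ones; ``or_value``/``or_ci`` are the exponentiated estimate
    (meaningful for binary outcomes only).
    """

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    exposure: str = ""
    outcome: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise EstimationError(f"{self.method}: non-positive SE")

    @property
    def ci_low(self) -> float:
        return self.beta - 1.96 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + 1.96 * self.se

    @property
    def or_value(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple:
        return (float(np.exp(self.ci_low)), float(np.exp(self.ci_high)))


def _single_exposure(h: HarmonizedSet):
    if h.n_exposure != 1:
        raise EstimationError("univariable method requires exactly one exposure")
    return h.b_exp[:, 0], h.se_exp[:, 0], h.b_out, h.se_out


def _normal_p(beta, se):
    return float(2.0 * sps.norm.sf(abs(beta) / se))


# ---------------------------------------------------------------------------
# Wald ratios


def wald_ratios(h: HarmonizedSet, second_order: bool = False):
    """Per-SNP ratio estimates b_out/b_exp with first-order SEs by default.

    Returns ``(ratios, ses, kept_ids, dropped_ids)``; SNPs with a zero
    exposure effect are dropped.  The second-order SE adds the exposure
    sampling term ``b_out^2 se_exp^2 / b_exp^4``.
    """
    bx, sx, by, sy = _single_exposure(h)
    keep = bx != 0
    bx, sx, by, sy = bx[keep], sx[keep], by[keep], sy[keep]
    ratios = by / bx
    var = sy ** 2 / bx ** 2
    if second_order:
        var = var + by ** 2 * sx ** 2 / bx ** 4
    return ratios, np.sqrt(var), h.snp_ids[keep], h.snp_ids[~keep]


# ---------------------------------------------------------------------------
# IVW


def cochran_q_ivw(bx, by, sy, theta):
    w = bx ** 2 / sy ** 2
    ratios = by / bx
    return float(np.sum(w * (ratios - theta) ** 2))


def ivw(h: HarmonizedSet, mode: str = "mre") -> MrEstimate:
    """Inverse-variance-weighted estimate: zero-intercept WLS of b_out on b_exp.

    ``mode='fixed'`` uses the analytic fixed-effect SE; ``mode='mre'``
    (default) inflates it by ``max(1, sqrt(Q / (J - 1)))`` — the
    multiplicative-random-effects model that is the dominant convention in
    two-sample MR tooling.
    """
    if mode not in ("fixed", "mre"):
        raise ValueError("mode must be 'fixed' or 'mre'")
    bx, sx, by, sy = _single_exposure(h)
    keep = bx != 0
    bx, sx, by, sy = bx[keep], sx[keep], by[keep], sy[keep]
    j = len(bx)
    if j == 0:
        raise EstimationError("no usable instruments")
    w = 1.0 / sy ** 2
    sxx = np.sum(bx ** 2 * w)
    if sxx == 0:
        raise EstimationError("all IVW weights are zero")
    theta = np.sum(bx * by * w) / sxx
    se = 1.0 / np.sqrt(sxx)
    q = cochran_q_ivw(bx, by, sy, theta) if j >= 2 else 0.0
    if mode == "mre" and j >= 2:
        se *= max(1.0, np.sqrt(q / (j - 1)))
    return MrEstimate(
        method=f"ivw_{'fe' if mode == 'fixed' else 'mre'}",
        beta=float(theta), se=float(se), pval=_normal_p(theta, se), n_snp=j,
        exposure=h.exposure_names[0], outcome=h.outcome_name,
        extras={"Q": q, "Q_df": max(j - 1, 0)},
    )


# ---------------------------------------------------------------------------
# MR-Egger


def _wls_with_intercept(x, y, w, df_resid):
    """Weighted least squares y = a + b x; SEs with multiplicative inflation
    floored at 1; returns (a, b, se_a, se_b, rss_w)."""
    design = np.column_stack([np.ones_like(x), x])
    ws = np.sqrt(w)
    xw = design * ws[:, None]
    yw = y * ws
    xtx = xw.T @ xw
    coef = np.linalg.solve(xtx, xw.T @ yw)
    resid = yw - xw @ coef
    rss = float(resid @ resid)
    sigma2 = max(rss / df_resid, 1.0)
    cov = sigma2 * np.linalg.inv(xtx)
    return coef[0], coef[1], np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1]), rss


def mr_egger(h: HarmonizedSet) -> MrEstimate:
    """MR-Egger: weighted regression with a free intercept.

    Rows are oriented so every exposure effect is non-negative; the intercept
    estimates average directional pleiotropy.  Inference uses t with J-2 df
    and multiplicative SE inflation floored at 1.
    """
    bx, sx, by, sy = _single_exposure(h)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 SNPs")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy ** 2
    a, b, se_a, se_b, rss = _wls_with_intercept(bx, by, w, j - 2)
    p_slope = float(2.0 * sps.t.sf(abs(b) / se_b, j - 2))
    p_int = float(2.0 * sps.t.sf(abs(a) / se_a, j - 2))
    return MrEstimate(
        method="egger", beta=float(b), se=float(se_b), pval=p_slope, n_snp=j,
        exposure=h.exposure_names[0], outcome=h.outcome_name,
        extras={"egger_intercept": float(a), "egger_intercept_se": float(se_a),
                "egger_intercept_p": p_int, "rss_w": rss},
    )


# ---------------------------------------------------------------------------
# Weighted median


def _weighted_median(values, weights):
    order = np.argsort(values)
    v = np.asarray(values, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    # percentile of the j-th sorted element: cumulative weight minus half its own
    p = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, p, v))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MrEstimate:
    """Weighted median of per-SNP ratios; SE from parametric bootstrap.

    Valid when at most half of the total weight comes from invalid
    instruments.  The SE is the standard deviation of the estimate over
    ``n_boot`` parametric resamples of (b_exp, b_out) from their sampling
    normals, so it is reproducible only for fixed ``seed``.
    """
    bx, sx, by, sy = _single_exposure(h)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError("weighted median needs at least 3 SNPs")
    ratios = by / bx
    w = bx ** 2 / sy ** 2  # first-order inverse-variance weights
    est = _weighted_median(ratios, w)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        ok = bxb != 0
        boots[b] = _weighted_median(byb[ok] / bxb[ok], bxb[ok] ** 2 / sy[ok] ** 2)
    se = float(np.std(boots, ddof=1))
    return MrEstimate(
        method="weighted_median", beta=est, se=se, pval=_normal_p(est, se), n_snp=j,
        exposure=h.exposure_names[0], outcome=h.outcome_name,
        extras={"n_boot": n_boot},
    )


# ---------------------------------------------------------------------------
# Maximum likelihood


def _profile_nll(theta, bx, sx, by, sy):
    # per-SNP true effect xi maximized out analytically; with known SEs the
    # profiled -logL is a pure weighted residual sum (no log-variance term)
    var = sy ** 2 + theta ** 2 * sx ** 2
    return 0.5 * np.sum((by - theta * bx) ** 2 / var)


def max_likelihood(h: HarmonizedSet) -> MrEstimate:
    """Bivariate-normal maximum likelihood over (theta, per-SNP true effects).

    The per-SNP true exposure effects are profiled out analytically, leaving a
    one-dimensional likelihood in theta; the SE comes from the observed
    information (numerical second derivative) of that profile.
    """
    bx, sx, by, sy = _single_exposure(h)
    j = len(bx)
    if j < 1:
        raise EstimationError("no instruments")
    start = ivw(h, mode="fixed").beta if j >= 2 else float(by[0] / bx[0])
    res = optimize.minimize_scalar(
        _profile_nll, args=(bx, sx, by, sy),
        bracket=(start - 1.0, start + 1.0), method="brent",
        options={"maxiter": 500},
    )
    if not res.success and not np.isfinite(res.x):
        raise EstimationError(f"ML failed to converge: {res}")
    theta = float(res.x)
    eps = 1e-5 * max(abs(theta), 1.0)
    d2 = (_profile_nll(theta + eps, bx, sx, by, sy)
          - 2 * _profile_nll(theta, bx, sx, by, sy)
          + _profile_nll(theta - eps, bx, sx, by, sy)) / eps ** 2
    if d2 <= 0:
        raise EstimationError("ML information non-positive at optimum")
    se = float(1.0 / np.sqrt(d2))
    return MrEstimate(
        method="maxlik", beta=theta, se=se, pval=_normal_p(theta, se), n_snp=j,
        exposure=h.exposure_names[0], outcome=h.outcome_name,
    )


# ---------------------------------------------------------------------------
# cML-MA


def _cml_fit_k(bx, sx, by, sy, k, theta0, max_iter=200):
    """Constrained ML with exactly k SNPs allowed a free pleiotropy term.

    Coordinate iteration: given theta, the k SNPs with the largest
    standardized residuals receive free r_j (contributing zero to the
    objective); theta is then re-estimated on the remaining SNPs by profile
    ML.  Returns (theta, se, invalid_index_set, nll, converged)."""
    j = len(bx)
    theta = theta0
    invalid = frozenset()
    visited = {}
    converged = True
    for _ in range(max_iter):
        t_resid = (by - theta * bx) ** 2 / (sy ** 2 + theta ** 2 * sx ** 2)
        new_invalid = frozenset(np.argsort(-t_resid)[:k].tolist()) if k > 0 else frozenset()
        if new_invalid == invalid and visited:
            break
        if new_invalid in visited:
            # oscillation: fall back to the best visited configuration
            converged = False
            invalid = min(visited, key=visited.get)
            break
        invalid = new_invalid
        valid = np.array([i for i in range(j) if i not in invalid], int)
        res = optimize.minimize_scalar(
            _profile_nll, args=(bx[valid], sx[valid], by[valid], sy[valid]),
            bracket=(theta - 1.0, theta + 1.0), method="brent")
        theta = float(res.x)
        visited[invalid] = _profile_nll(theta, bx[valid], sx[valid], by[valid], sy[valid])
    valid = np.array([i for i in range(j) if i not in invalid], int)
    res = optimize.minimize_scalar(
        _profile_nll, args=(bx[valid], sx[valid], by[valid], sy[valid]),
        bracket=(theta - 1.0, theta + 1.0), method="brent")
    theta = float(res.x)
    nll = _profile_nll(theta, bx[valid], sx[valid], by[valid], sy[valid])
    eps = 1e-5 * max(abs(theta), 1.0)
    d2 = (_profile_nll(theta + eps, bx[valid], sx[valid], by[valid], sy[valid])
          - 2 * nll
          + _profile_nll(theta - eps, bx[valid], sx[valid], by[valid], sy[valid])) / eps ** 2
    se = 1.0 / np.sqrt(d2) if d2 > 0 else np.inf
    return theta, se, invalid, float(nll), converged


def cml_ma(h: HarmonizedSet, max_invalid: int | None = None) -> MrEstimate:
    """Constrained maximum likelihood with BIC model averaging.

    Fits the constrained ML for every allowed count K of invalid instruments
    (0..max_invalid, default J-2), scores each by BIC(K) = 2 nll + K log J,
    and model-averages with weights proportional to exp(-BIC/2).  The MA
    variance combines within-model variance and between-model spread.  Does
    not rely on the InSIDE assumption.  (The data-perturbation variant is not
    implemented; averaging is over BIC only.)
    """
    bx, sx, by, sy = _single_exposure(h)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError("cML-MA needs at least 3 SNPs")
    if max_invalid is None:
        max_invalid = j - 2
    max_invalid = min(max_invalid, j - 2)

    theta0 = ivw(h, mode="fixed").beta
    thetas, ses, bics, invalid_sets, warns = [], [], [], [], []
    for k in range(max_invalid + 1):
        theta, se, invalid, nll, conv = _cml_fit_k(bx, sx, by, sy, k, theta0)
        thetas.append(theta)
        ses.append(se)
        bics.append(2.0 * nll + k * np.log(j))
        invalid_sets.append(sorted(invalid))
        if not conv:
            warns.append(k)

    thetas = np.array(thetas)
    ses = np.array(ses)
    bics = np.array(bics)
    wts = np.exp(-(bics - bics.min()) / 2.0)
    wts /= wts.sum()
    theta_ma = float(np.sum(wts * thetas))
    var_ma = float(np.sum(wts * (ses ** 2 + (thetas - theta_ma) ** 2)))
    se_ma = float(np.sqrt(var_ma))
    k_best = int(np.argmin(bics))
    return MrEstimate(
        method="cml_ma", beta=theta_ma, se=se_ma, pval=_normal_p(theta_ma, se_ma),
        n_snp=j, exposure=h.exposure_names[0], outcome=h.outcome_name,
        extras={"bic": bics.tolist(), "bic_weights": wts.tolist(),
                "k_best": k_best, "theta_by_k": thetas.tolist(),
                "invalid_best": invalid_sets[k_best],
                "oscillation_warnings": warns},
    )


# ---------------------------------------------------------------------------
# GSMR (clumped-instrument variant)


def gsmr_lite(h: HarmonizedSet, heidi_outlier_p: float = 0.01,
              min_snps: int = 10, max_iter: int = 20) -> MrEstimate:
    """GSMR-style estimate accounting for exposure sampling error, with
    HEIDI-outlier removal.

    Instruments are assumed LD-independent (already clumped).  Iterates
    between the weighted estimate with weights
    ``[(se_out^2 + theta^2 se_exp^2) / b_exp^2]^-1`` applied to the per-SNP
    ratios, and removal of SNPs whose standardized deviation from theta has
    p < ``heidi_outlier_p``.  At least ``min_snps`` instruments are required.
    """
    bx, sx, by, sy = _single_exposure(h)
    j = len(bx)
    if j < min_snps:
        raise InsufficientInstrumentsError(
            f"gsmr needs at least {min_snps} SNPs, got {j}")

    active = np.arange(j)
    removed = []
    theta = ivw(h, mode="fixed").beta
    for _ in range(max_iter):
        bxa, sxa, bya, sya = bx[active], sx[active], by[active], sy[active]
        ratios = bya / bxa
        for _ in range(50):  # inner re-weighting to a fixed point
            var_ratio = (sya ** 2 + theta ** 2 * sxa ** 2) / bxa ** 2
            w = 1.0 / var_ratio
            new_theta = float(np.sum(w * ratios) / np.sum(w))
            if abs(new_theta - theta) < 1e-12:
                theta = new_theta
                break
            theta = new_theta
        var_ratio = (sya ** 2 + theta ** 2 * sxa ** 2) / bxa ** 2
        z = (ratios - theta) / np.sqrt(var_ratio)
        pvals = 2.0 * sps.norm.sf(np.abs(z))
        worst = int(np.argmin(pvals))
        if pvals[worst] >= heidi_outlier_p:
            break
        removed.append(h.snp_ids[active[worst]])
        active = np.delete(active, worst)
        if len(active) < 3:
            break

    bxa, sxa, bya, sya = bx[active], sx[active], by[active], sy[active]
    var_ratio = (sya ** 2 + theta ** 2 * sxa ** 2) / bxa ** 2
    w = 1.0 / var_ratio
    se = float(1.0 / np.sqrt(np.sum(w)))
    return MrEstimate(
        method="gsmr", beta=float(theta), se=se, pval=_normal_p(theta, se),
        n_snp=int(len(active)),
        exposure=h.exposure_names[0], outcome=h.outcome_name,
        extras={"removed_snps": [str(s) for s in removed]},
    )


ALL_METHODS = {
    "ivw": ivw,
    "egger": mr_egger,
    "weighted_median": weighted_median,
    "maxlik": max_likelihood,
    "cml_ma": cml_ma,
    "gsmr": gsmr_lite,
}


def run_uvmr(h: HarmonizedSet, methods=("ivw", "egger", "weighted_median",
                                        "maxlik", "cml_ma", "gsmr"),
             seed: int = 0) -> dict:
    """Run a panel of univariable estimators; methods whose preconditions fail
    are recorded as unavailable rather than aborting the panel."""
    out = {}
    for name in methods:
        fn = ALL_METHODS[name]
        try:
            if name == "weighted_median":
                out[name] = fn(h, seed=seed)
            else:
                out[name] = fn(h)
        except (EstimationError, ValueError) as exc:
            out[name] = {"unavailable": str(exc)}
    return out
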