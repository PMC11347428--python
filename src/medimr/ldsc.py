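"""LD score regression: SNP heritability and cross-trait genetic correlation.

The slope of chi-square on LD score estimates heritability; the slope of the
z-score product for two traits estimates genetic covariance, with a free
intercept absorbing sample overlap.  Genetic correlation is
``rg = gencov / sqrt(h2_1 h2_2)``; standard errors come from a delete-one
block jackknife over contiguous SNP blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

DEFAULT_N_BLOCKS = 200


class DegenerateDesignError(ValueError):
    pass


@dataclass
class LdscResult:
    h2_1: float
    h2_1_se: float
    h2_2: float
    h2_2_se: float
    gencov: float
    rg: float
    rg_se: float
    p_rg: float
    intercept_1: float
    intercept_2: float
    gencov_intercept: float
    n_blocks: int
    flags: tuple = ()


def _wls_line(x, y, w):
    """Weighted straight-line fit; returns (intercept, slope)."""
    sw = np.sum(w)
    mx = np.sum(w * x) / sw
    my = np.sum(w * y) / sw
    sxx = np.sum(w * (x - mx) ** 2)
    if sxx <= 0:
        raise DegenerateDesignError("LD scores are constant; slope undefined")
    slope = np.sum(w * (x - mx) * (y - my)) / sxx
    return my - slope * mx, slope


def _block_bounds(m, n_blocks):
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(n_blocks)]


def _jackknife(values):
    """Delete-one jackknife SE from per-block leave-out estimates."""
    values = np.asarray(values, float)
    b = len(values)
    mean = values.mean()
    return float(np.sqrt((b - 1) / b * np.sum((values - mean) ** 2)))


def _h2_fit(z, ell, n, m_total, weights=None):
    chi2 = z ** 2
    if weights is None:
        # initial unweighted pass to set heteroskedasticity weights
        _, slope0 = _wls_line(ell, chi2, np.ones_like(ell))
        h2_0 = np.clip(slope0 * m_total / n, 0.0, 1.0)
        weights = 1.0 / (ell * (1.0 + n * h2_0 * ell / m_total) ** 2)
    intercept, slope = _wls_line(ell, chi2, weights)
    return intercept, slope * m_total / n, weights


def ldsc_h2(z, ld_scores, n, m_total=None, n_blocks: int = DEFAULT_N_BLOCKS):
    """SNP heritability by LD score regression with block-jackknife SEs.

    One weight update from an initial unweighted fit (single iteration);
    negative fitted h2 is returned as-is with a flag rather than truncated.

    Returns ``(h2, se, intercept, intercept_se)``.
    """
    z = np.asarray(z, float)
    ell = np.asarray(ld_scores, float)
    if len(z) != len(ell):
        raise ValueError("z and ld_scores must align")
    if n_blocks < 20:
        raise ValueError("need at least 20 jackknife blocks")
    m = len(z)
    if m_total is None:
        m_total = m
    intercept, h2, weights = _h2_fit(z, ell, n, m_total)

    h2_jk, int_jk = [], []
    for lo, hi in _block_bounds(m, n_blocks):
        mask = np.ones(m, bool)
        mask[lo:hi] = False
        i_b, s_b = _wls_line(ell[mask], z[mask] ** 2, weights[mask])
        h2_jk.append(s_b * m_total / n)
        int_jk.append(i_b)
    return float(h2), _jackknife(h2_jk), float(intercept), _jackknife(int_jk)


def ldsc_rg(z1, z2, ld_scores, n1, n2, m_total=None,
            n_blocks: int = DEFAULT_N_BLOCKS) -> LdscResult:
    """Cross-trait genetic correlation by LD score regression.

    The z-product slope on LD score estimates ``gencov sqrt(n1 n2)/M``; its
    free intercept absorbs shared samples.  The jackknife is applied to the
    full ratio ``rg = gencov / sqrt(h2_1 h2_2)`` (heritabilities re-fit per
    leave-out block), and the p-value is normal on rg/se.
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    ell = np.asarray(ld_scores, float)
    m = len(ell)
    if not (len(z1) == len(z2) == m):
        raise ValueError("aligned SNP sets required")
    if m_total is None:
        m_total = m

    int1, h2_1, w1 = _h2_fit(z1, ell, n1, m_total)
    int2, h2_2, w2 = _h2_fit(z2, ell, n2, m_total)
    flags = ()
    if h2_1 <= 0 or h2_2 <= 0:
        raise DegenerateDesignError(
            f"non-positive heritability (h2_1={h2_1:.4g}, h2_2={h2_2:.4g}); rg undefined")

    w_rg = np.sqrt(w1 * w2)
    zprod = z1 * z2
    int_g, slope_g = _wls_line(ell, zprod, w_rg)
    gencov = slope_g * m_total / np.sqrt(n1 * n2)
    rg = gencov / np.sqrt(h2_1 * h2_2)
    if abs(rg) > 1.25:
        flags = ("rg_out_of_range",)

    # jackknife over blocks, re-fitting all three regressions per leave-out
    rg_jk, h1_jk, h2_jk = [], [], []
    for lo, hi in _block_bounds(m, n_blocks):
        mask = np.ones(m, bool)
        mask[lo:hi] = False
        _, s1 = _wls_line(ell[mask], z1[mask] ** 2, w1[mask])
        _, s2 = _wls_line(ell[mask], z2[mask] ** 2, w2[mask])
        _, sg = _wls_line(ell[mask], zprod[mask], w_rg[mask])
        h1_b = s1 * m_total / n1
        h2_b = s2 * m_total / n2
        h1_jk.append(h1_b)
        h2_jk.append(h2_b)
        if h1_b > 0 and h2_b > 0:
            gc_b = sg * m_total / np.sqrt(n1 * n2)
            rg_jk.append(gc_b / np.sqrt(h1_b * h2_b))
    if len(rg_jk) < n_blocks // 2:
        raise DegenerateDesignError("too many jackknife blocks with h2 <= 0")
    rg_se = _jackknife(rg_jk)
    p_rg = float(2.0 * sps.norm.sf(abs(rg) / rg_se)) if rg_se > 0 else np.nan

    return LdscResult(
        h2_1=float(h2_1), h2_1_se=_jackknife(h1_jk),
        h2_2=float(h2_2), h2_2_se=_jackknife(h2_jk),
        gencov=float(gencov), rg=float(rg), rg_se=rg_se, p_rg=p_rg,
        intercept_1=float(int1), intercept_2=float(int2),
        gencov_intercept=float(int_g), n_blocks=n_blocks, flags=flags,
    )
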