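"""Summary-data-based MR of gene expression on disease, with the HEIDI test.

The SMR statistic instruments expression with the top cis-eQTL:

    beta_smr = b_gwas / b_eqtl
    T_smr    = z_gwas^2 z_eqtl^2 / (z_gwas^2 + z_eqtl^2)  ~  chi-square(1)

HEIDI then asks whether surrounding SNPs in LD with the top eQTL give the same
ratio: heterogeneity (small p) indicates linkage of two distinct causal
variants rather than a shared one, so p > 0.05 is the pass criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .synthgwas import Region

HEIDI_EQTL_P = 1.6e-3   # candidate-SNP eQTL significance bound
HEIDI_R2_MIN = 0.05     # LD window with the top eQTL
HEIDI_R2_MAX = 0.9
HEIDI_MAX_SNPS = 20
HEIDI_MIN_SNPS = 4      # "more than three SNPs" rule


@dataclass
class SmrResult:
    probe_id: str
    beta_smr: float
    se_smr: float
    p_smr: float
    p_heidi: float = np.nan
    n_heidi_snps: int = 0
    flags: list = field(default_factory=list)


def smr_test(z_eqtl: float, b_eqtl: float, z_gwas: float, b_gwas: float):
    """SMR Wald-type test at the top cis-eQTL.

    Returns ``(beta_smr, se_smr, p_smr)``; as z_eqtl -> inf the test reduces
    to the single-instrument GWAS Wald test.
    """
    if b_eqtl == 0:
        raise ValueError("eQTL effect is zero")
    beta_smr = b_gwas / b_eqtl
    denom = z_gwas ** 2 + z_eqtl ** 2
    if denom == 0:
        return beta_smr, np.inf, 1.0
    t_smr = z_gwas ** 2 * z_eqtl ** 2 / denom
    p_smr = float(sps.chi2.sf(t_smr, 1))
    se_smr = abs(beta_smr) / np.sqrt(t_smr) if t_smr > 0 else np.inf
    return float(beta_smr), float(se_smr), p_smr


def _nearest_psd(a: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((a + a.T) / 2.0)
    vals = np.clip(vals, 1e-10, None)
    return (vecs * vals) @ vecs.T


def heidi_test(region: Region, top_index: int | None = None,
               eqtl_p_threshold: float = HEIDI_EQTL_P,
               r2_window: tuple = (HEIDI_R2_MIN, HEIDI_R2_MAX),
               max_snps: int = HEIDI_MAX_SNPS):
    """HEIDI: heterogeneity in dependent instruments around the top eQTL.

    Trait 1 of ``region`` is the eQTL study, trait 2 the GWAS.  Candidate
    SNPs must pass the eQTL significance bound and sit in LD with the top SNP
    (r^2 within ``r2_window``); the ``max_snps`` most significant are used.
    The statistic is the sum of squared standardized differences
    ``d_i = beta_smr(i) - beta_smr(top)`` with a delta-method covariance that
    carries the LD-induced correlation of the marginal estimates; its null
    distribution is a weighted chi-square combination approximated by
    Satterthwaite moment matching on the eigenvalues of the correlation of d.

    Returns ``(p_heidi, n_snps_used, skip_reason)``; ``p_heidi`` is NaN when
    fewer than four candidates remain (the "more than three SNPs" rule).
    """
    if region.ld is None:
        raise ValueError("HEIDI requires an LD matrix")
    z_e, z_g = region.z1, region.z2
    b_e, b_g = region.beta1, region.beta2
    se_e, se_g = region.se1, region.se2
    if top_index is None:
        top_index = int(np.argmax(np.abs(z_e)))

    p_eqtl = 2.0 * sps.norm.sf(np.abs(z_e))
    r2 = region.ld[:, top_index] ** 2
    cand = np.where(
        (p_eqtl < eqtl_p_threshold)
        & (r2 >= r2_window[0]) & (r2 <= r2_window[1])
        & (np.arange(region.n_snp) != top_index)
        & (b_e != 0)
    )[0]
    if len(cand) > max_snps:
        order = np.argsort(p_eqtl[cand], kind="mergesort")
        cand = cand[order[:max_snps]]
    # canonical order so the test is invariant to input permutations
    cand = np.sort(cand)
    if len(cand) < HEIDI_MIN_SNPS:
        return np.nan, int(len(cand)), "fewer than four candidate SNPs"

    t = top_index
    beta_top = b_g[t] / b_e[t]
    d = b_g[cand] / b_e[cand] - beta_top

    # delta-method gradient of d_i in (b_g_i, b_e_i, b_g_t, b_e_t)
    m = len(cand)
    cov = np.empty((m, m))
    ld = region.ld
    for a_idx in range(m):
        i = cand[a_idx]
        for b_idx in range(a_idx, m):
            j = cand[b_idx]
            # Cov(b_g_i/b_e_i, b_g_j/b_e_j) terms, eQTL and GWAS independent
            c = (ld[i, j] * se_g[i] * se_g[j] / (b_e[i] * b_e[j])
                 + (b_g[i] * b_g[j] / (b_e[i] ** 2 * b_e[j] ** 2))
                 * ld[i, j] * se_e[i] * se_e[j])
            # minus cross terms with the top ratio
            c -= (ld[i, t] * se_g[i] * se_g[t] / (b_e[i] * b_e[t])
                  + (b_g[i] * b_g[t] / (b_e[i] ** 2 * b_e[t] ** 2))
                  * ld[i, t] * se_e[i] * se_e[t])
            c -= (ld[j, t] * se_g[j] * se_g[t] / (b_e[j] * b_e[t])
                  + (b_g[j] * b_g[t] / (b_e[j] ** 2 * b_e[t] ** 2))
                  * ld[j, t] * se_e[j] * se_e[t])
            # plus variance of the shared top ratio
            c += (se_g[t] ** 2 / b_e[t] ** 2
                  + b_g[t] ** 2 * se_e[t] ** 2 / b_e[t] ** 4)
            cov[a_idx, b_idx] = cov[b_idx, a_idx] = c

    var = np.diag(cov).copy()
    if np.any(var <= 0):
        cov = _nearest_psd(cov)
        var = np.diag(cov).copy()
    z_d = d / np.sqrt(var)
    stat = float(np.sum(z_d ** 2))

    corr = cov / np.sqrt(np.outer(var, var))
    evals = np.linalg.eigvalsh((corr + corr.T) / 2.0)
    evals = np.clip(evals, 0.0, None)
    s1, s2 = evals.sum(), np.sum(evals ** 2)
    if s2 <= 0:
        return np.nan, m, "degenerate covariance"
    scale = s2 / s1
    dof = s1 ** 2 / s2
    p = float(sps.chi2.sf(stat / scale, dof))
    return p, m, None


def run_smr(region: Region, probe_id: str = "probe",
            instrument_p: float = 5e-8) -> SmrResult:
    """SMR + HEIDI for one expression probe against one GWAS trait.

    Trait 1 of ``region`` is the eQTL study, trait 2 the GWAS.  The top eQTL
    must pass the instrument threshold.
    """
    top = int(np.argmax(np.abs(region.z1)))
    p_top = 2.0 * sps.norm.sf(abs(region.z1[top]))
    if p_top >= instrument_p:
        raise ValueError(
            f"top eQTL p = {p_top:.3g} fails the instrument threshold {instrument_p:g}")
    beta_smr, se_smr, p_smr = smr_test(
        region.z1[top], region.beta1[top], region.z2[top], region.beta2[top])
    res = SmrResult(probe_id=probe_id, beta_smr=beta_smr, se_smr=se_smr, p_smr=p_smr)
    if region.ld is not None:
        p_heidi, n_used, reason = heidi_test(region, top_index=top)
        res.p_heidi = p_heidi
        res.n_heidi_snps = n_used
        if reason:
            res.flags.append(f"heidi_skipped: {reason}")
    else:
        res.flags.append("heidi_skipped: no LD matrix")
    return res
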