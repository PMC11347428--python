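"""Bayesian colocalization of two traits in a genomic region.

Single-causal-variant-per-trait enumeration over five hypotheses:

* H0 — no causal variant for either trait in the region
* H1 / H2 — a causal variant for trait 1 / trait 2 only
* H3 — causal variants for both traits, at different SNPs
* H4 — one shared causal variant driving both traits

Evidence per SNP is the Wakefield approximate Bayes factor; hypothesis sums
are accumulated in log space so the computation is stable at |z| well beyond
GWAS scale.  PPH4 > 0.8 is conventionally read as strong colocalization
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .synthgwas import Region

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_BINARY = 0.2
PPH4_STRONG = 0.8


@dataclass
class ColocResult:
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    n_snps: int
    priors: tuple = (DEFAULT_P1, DEFAULT_P2, DEFAULT_P12)
    flags: tuple = ()

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])


def wakefield_abf(z, se, prior_sd: float) -> np.ndarray:
    """Log approximate Bayes factor for a single association.

    With shrinkage ``r = prior_sd^2 / (prior_sd^2 + se^2)``:
    ``log ABF = 0.5 [log(1 - r) + r z^2]``.  Tends to 0 as se -> inf (no
    information) and is negative at z = 0 (null variant penalized by the
    prior).
    """
    z = np.asarray(z, float)
    se = np.asarray(se, float)
    if np.any(se <= 0) or prior_sd <= 0:
        raise ValueError("se and prior_sd must be positive")
    r = prior_sd ** 2 / (prior_sd ** 2 + se ** 2)
    return 0.5 * (np.log1p(-r) + r * z ** 2)


def _prior_sd(trait_type: str) -> float:
    return PRIOR_SD_BINARY if trait_type == "binary" else PRIOR_SD_QUANTITATIVE


def coloc_posterior(region: Region, p1: float = DEFAULT_P1, p2: float = DEFAULT_P2,
                    p12: float = DEFAULT_P12, prior_sd1: float | None = None,
                    prior_sd2: float | None = None) -> ColocResult:
    """Posterior probabilities of H0..H4 for a two-trait region.

    Per-SNP log ABFs are combined into hypothesis sums (in log space):

        S1 = p1 sum_j BF1_j
        S2 = p2 sum_j BF2_j
        S3 = p1 p2 [ (sum BF1)(sum BF2) - sum BF1_j BF2_j ]
        S4 = p12 sum_j BF1_j BF2_j

    and normalized against S0 = 1.
    """
    if region.n_snp < 2:
        raise ValueError("colocalization needs at least 2 SNPs")
    sd1 = prior_sd1 if prior_sd1 is not None else _prior_sd(region.trait_types[0])
    sd2 = prior_sd2 if prior_sd2 is not None else _prior_sd(region.trait_types[1])

    labf1 = wakefield_abf(region.z1, region.se1, sd1)
    labf2 = wakefield_abf(region.z2, region.se2, sd2)

    l1 = logsumexp(labf1)
    l2 = logsumexp(labf2)
    lcross = logsumexp(labf1 + labf2)

    log_s0 = 0.0
    log_s1 = np.log(p1) + l1
    log_s2 = np.log(p2) + l2
    log_s4 = np.log(p12) + lcross
    # sum over i != j of BF1_i BF2_j = exp(l1 + l2) - exp(lcross)
    diff = lcross - (l1 + l2)
    flags = ()
    if diff >= 0:  # numerically everything concentrated on one SNP
        log_s3 = -np.inf
        flags = ("h3_degenerate",)
    else:
        log_s3 = np.log(p1) + np.log(p2) + l1 + l2 + np.log1p(-np.exp(diff))

    logs = np.array([log_s0, log_s1, log_s2, log_s3, log_s4])
    pp = np.exp(logs - logsumexp(logs))
    return ColocResult(*pp.tolist(), n_snps=region.n_snp,
                       priors=(p1, p2, p12), flags=flags)
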