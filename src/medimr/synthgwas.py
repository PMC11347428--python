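"""Synthetic GWAS summary statistics with the structure the analysis assumes.

Three generators cover the three downstream regimes:

* :func:`simulate_mediation_gwas` — clumped (LD-independent) instruments for a
  three-trait structural model exposure -> mediator -> outcome with optional
  (possibly directional, possibly InSIDE-violating) pleiotropy.  This is the
  two-sample MR / mediation test bed.
* :func:`simulate_region` — a cis region with AR(1) LD and zero, one or two
  causal variants, for colocalization and SMR/HEIDI.
* :func:`simulate_ldsc_pair` — genome-scale z-scores for two polygenic traits
  whose chi-square inflation tracks LD scores, for LD score regression.

All generators are pure functions of (scenario, seed): summary statistics are
simulated directly, never via individual-level genotypes, because every
consumer operates on summary data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SummaryStats, from_frame


class ScenarioError(ValueError):
    """Scenario parameters outside their valid range."""


# ---------------------------------------------------------------------------
# Mediation scenario


@dataclass
class MediationScenario:
    """Structural exposure -> mediator -> outcome model on instrument effects.

    Per instrument j with true exposure effect ``gamma_j ~ N(0, sigma_gamma^2)``:

    * mediator effect  ``theta_em * gamma_j``
    * outcome effect   ``theta_dir * gamma_j + theta_my * theta_em * gamma_j + alpha_j``

    where ``alpha_j`` is a direct (pleiotropic) path, zero for valid SNPs and
    ``N(pleio_mean, pleio_sd^2)`` with correlation ``inside_corr`` to gamma_j
    for invalid ones.  The mediator additionally carries its own instrument
    block of ``j_med`` SNPs with effects ``delta ~ N(0, sigma_delta^2)``, zero
    exposure effect and outcome effect ``theta_my * delta`` — without such
    SNPs the mediator->outcome step of two-step MR is unidentifiable.
    Defaults mimic a large-cohort two-sample design: a few hundred thousand
    samples per trait and instrument effects strong enough for mean
    F-statistics comfortably above 10.
    """

    j_snps: int = 100
    j_med: int = 100
    theta_em: float = 0.3
    theta_my: float = 0.5
    theta_dir: float = 0.35
    sigma_gamma: float = 0.02
    sigma_delta: float = 0.02
    prop_invalid: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    inside_corr: float = 0.0
    n_x: int = 300_000
    n_m: int = 300_000
    n_y: int = 300_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.j_snps < 3:
            raise ScenarioError("need at least 3 instruments")
        if not 0.0 <= self.prop_invalid <= 1.0:
            raise ScenarioError("prop_invalid must be in [0, 1]")
        if abs(self.inside_corr) > 1.0:
            raise ScenarioError("|inside_corr| must be <= 1")
        if min(self.n_x, self.n_m, self.n_y) < 2:
            raise ScenarioError("sample sizes must be >= 2")


def _snp_frame(beta, se, n, eaf):
    j = len(beta)
    return pd.DataFrame({
        "SNP": [f"rs{i + 1}" for i in range(j)],
        "CHR": [f"chr{i + 1}" for i in range(j)],  # LD-independent instruments
        "POS": np.full(j, 1_000_000),
        "EA": "A",
        "OA": "G",
        "EAF": eaf,
        "BETA": beta,
        "SE": se,
        "P": np.nan,  # recomputed by validation
        "N": n,
    })


def simulate_mediation_gwas(sc: MediationScenario):
    """Simulate (exposure, mediator, outcome) summary statistics plus the truth.

    Returns ``(exposure, mediator, outcome, truth)`` where ``truth`` is a dict
    with the structural effects, per-SNP true effects and the implied true
    proportion mediated (``None`` and flagged undefined when the total effect
    is zero).
    """
    rng = np.random.default_rng(sc.seed)
    j = sc.j_snps

    gamma = rng.normal(0.0, sc.sigma_gamma, j)
    invalid = rng.random(j) < sc.prop_invalid
    alpha = np.zeros(j)
    if invalid.any() and sc.pleio_sd > 0:
        eps = rng.normal(0.0, 1.0, j)
        std_gamma = gamma / sc.sigma_gamma if sc.sigma_gamma > 0 else np.zeros(j)
        corr_part = sc.inside_corr * std_gamma + np.sqrt(1 - sc.inside_corr ** 2) * eps
        alpha[invalid] = sc.pleio_mean + sc.pleio_sd * corr_part[invalid]
    elif invalid.any():
        alpha[invalid] = sc.pleio_mean

    # mediator-specific instrument block: zero exposure effect
    delta = rng.normal(0.0, sc.sigma_delta, sc.j_med)
    gamma = np.concatenate([gamma, np.zeros(sc.j_med)])
    alpha = np.concatenate([alpha, np.zeros(sc.j_med)])
    invalid = np.concatenate([invalid, np.zeros(sc.j_med, bool)])
    j = j + sc.j_med

    gamma_m = sc.theta_em * gamma
    gamma_m[sc.j_snps:] = delta
    gamma_y = sc.theta_dir * gamma + sc.theta_my * gamma_m + alpha

    # se = 1/sqrt(n); allele-frequency variation is absorbed into the constant.
    se_x = np.full(j, 1.0 / np.sqrt(sc.n_x))
    se_m = np.full(j, 1.0 / np.sqrt(sc.n_m))
    se_y = np.full(j, 1.0 / np.sqrt(sc.n_y))
    eaf = rng.uniform(0.05, 0.95, j)

    b_x = gamma + rng.normal(0.0, se_x)
    b_m = gamma_m + rng.normal(0.0, se_m)
    b_y = gamma_y + rng.normal(0.0, se_y)

    exposure = from_frame(_snp_frame(b_x, se_x, sc.n_x, eaf), "exposure")
    mediator = from_frame(_snp_frame(b_m, se_m, sc.n_m, eaf), "mediator")
    outcome = from_frame(_snp_frame(b_y, se_y, sc.n_y, eaf), "outcome",
                         trait_type="binary")

    total = sc.theta_dir + sc.theta_em * sc.theta_my
    indirect = sc.theta_em * sc.theta_my
    truth = {
        "gamma": gamma,
        "alpha": alpha,
        "invalid": invalid,
        "theta_em": sc.theta_em,
        "theta_my": sc.theta_my,
        "theta_dir": sc.theta_dir,
        "theta_total": total,
        "indirect": indirect,
        "proportion_mediated": (indirect / total) if total != 0 else None,
        "proportion_defined": total != 0,
    }
    return exposure, mediator, outcome, truth


# ---------------------------------------------------------------------------
# Regional scenario (coloc / SMR / HEIDI)


@dataclass
class RegionScenario:
    """A cis region with AR(1) LD and configurable causal architecture.

    ``causal_config`` places a causal variant of non-centrality ``lambda1``
    (z-score units) for trait 1 and/or ``lambda2`` for trait 2: ``shared``
    puts both at the same index, ``distinct`` at well-separated indices.
    """

    m_snps: int = 50
    ld_rho: float = 0.8
    causal_config: str = "shared"  # none | trait1_only | trait2_only | distinct | shared
    lambda1: float = 8.0
    lambda2: float = 8.0
    n1: int = 30_000
    n2: int = 30_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_snps < 5:
            raise ScenarioError("region needs at least 5 SNPs")
        if abs(self.ld_rho) >= 1:
            raise ScenarioError("|ld_rho| must be < 1")
        valid = {"none", "trait1_only", "trait2_only", "distinct", "shared"}
        if self.causal_config not in valid:
            raise ScenarioError(f"causal_config must be one of {sorted(valid)}")


@dataclass
class Region:
    """SNP set with LD matrix and per-trait marginal association statistics.

    The unit of colocalization, SMR/HEIDI and TWAS.  ``z1``/``z2`` are marginal
    z-scores; ``se1``/``se2`` per-SNP standard errors on the beta scale (so
    ``beta = z * se``).
    """

    snp_ids: np.ndarray
    z1: np.ndarray
    z2: np.ndarray
    ld: np.ndarray | None = None
    se1: np.ndarray | None = None
    se2: np.ndarray | None = None
    n1: int | None = None
    n2: int | None = None
    trait_types: tuple = ("quantitative", "quantitative")
    causal_index: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z1 = np.asarray(self.z1, float)
        self.z2 = np.asarray(self.z2, float)
        m = len(self.z1)
        if len(self.z2) != m or len(self.snp_ids) != m:
            raise ValueError("region vectors must have equal length")
        if self.ld is not None:
            self.ld = np.asarray(self.ld, float)
            if self.ld.shape != (m, m):
                raise ValueError("LD matrix shape mismatch")
            if not np.allclose(self.ld, self.ld.T, atol=1e-8):
                raise ValueError("LD matrix must be symmetric")
        if self.se1 is None:
            self.se1 = np.full(m, 1.0 / np.sqrt(self.n1) if self.n1 else 1.0)
        if self.se2 is None:
            self.se2 = np.full(m, 1.0 / np.sqrt(self.n2) if self.n2 else 1.0)
        self.se1 = np.asarray(self.se1, float)
        self.se2 = np.asarray(self.se2, float)

    @property
    def n_snp(self) -> int:
        return len(self.z1)

    @property
    def beta1(self) -> np.ndarray:
        return self.z1 * self.se1

    @property
    def beta2(self) -> np.ndarray:
        return self.z2 * self.se2


def ar1_ld(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_region(sc: RegionScenario) -> Region:
    """Draw marginal z-scores for two traits over an AR(1)-LD region.

    Marginal z for each trait is MVN(Sigma @ lam, Sigma) where ``lam`` carries
    the causal non-centrality at that trait's causal index.
    """
    rng = np.random.default_rng(sc.seed)
    m = sc.m_snps
    sigma = ar1_ld(m, sc.ld_rho)
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(m))

    lam1 = np.zeros(m)
    lam2 = np.zeros(m)
    mid = m // 2
    if sc.causal_config in ("trait1_only", "shared"):
        lam1[mid] = sc.lambda1
    if sc.causal_config in ("trait2_only", "shared"):
        lam2[mid] = sc.lambda2
    if sc.causal_config == "distinct":
        lam1[m // 4] = sc.lambda1
        lam2[(3 * m) // 4] = sc.lambda2

    z1 = sigma @ lam1 + chol @ rng.standard_normal(m)
    z2 = sigma @ lam2 + chol @ rng.standard_normal(m)
    return Region(
        snp_ids=np.array([f"rs{i + 1}" for i in range(m)]),
        z1=z1, z2=z2, ld=sigma,
        n1=sc.n1, n2=sc.n2,
        causal_index={"trait1": int(np.argmax(np.abs(lam1))) if lam1.any() else None,
                      "trait2": int(np.argmax(np.abs(lam2))) if lam2.any() else None},
    )


# ---------------------------------------------------------------------------
# Polygenic pair scenario (LDSC)


@dataclass
class PolygenicPairScenario:
    """Two polygenic traits whose z-score second moments follow LD scores."""

    m_snps: int = 50_000
    h2_1: float = 0.3
    h2_2: float = 0.3
    rg: float = 0.5
    n1: int = 50_000
    n2: int = 50_000
    n_overlap: int = 0
    rho_pheno: float = 0.0
    ld_scores: np.ndarray | None = None  # drawn if None
    seed: int = 0

    def __post_init__(self) -> None:
        for h2 in (self.h2_1, self.h2_2):
            if not 0.0 <= h2 <= 1.0:
                raise ScenarioError("h2 must be in [0, 1]")
        if abs(self.rg) > 1.0:
            raise ScenarioError("|rg| must be <= 1")


def simulate_ldsc_pair(sc: PolygenicPairScenario):
    """Simulate aligned z-score vectors for two traits plus their LD scores.

    Per SNP j the pair (z1_j, z2_j) is bivariate normal with

        Var(z1_j) = 1 + n1 h2_1 l_j / M,
        Cov       = sqrt(n1 n2) rg sqrt(h2_1 h2_2) l_j / M
                    + n_overlap rho_pheno / sqrt(n1 n2).

    Returns ``(z1, z2, ld_scores)``.
    """
    rng = np.random.default_rng(sc.seed)
    m = sc.m_snps
    if sc.ld_scores is None:
        # long-tailed LD scores, floor 1 (a SNP is in LD with itself)
        ell = 1.0 + rng.gamma(shape=2.0, scale=20.0, size=m)
    else:
        ell = np.asarray(sc.ld_scores, float)
        if np.any(ell < 1):
            raise ScenarioError("ld_scores must be >= 1")

    v1 = 1.0 + sc.n1 * sc.h2_1 * ell / m
    v2 = 1.0 + sc.n2 * sc.h2_2 * ell / m
    cov = (np.sqrt(sc.n1 * sc.n2) * sc.rg * np.sqrt(sc.h2_1 * sc.h2_2) * ell / m
           + sc.n_overlap * sc.rho_pheno / np.sqrt(sc.n1 * sc.n2))
    det = v1 * v2 - cov ** 2
    if np.any(det <= 0):
        raise ScenarioError("per-SNP covariance matrix not positive-definite")

    e1 = rng.standard_normal(m)
    e2 = rng.standard_normal(m)
    z1 = np.sqrt(v1) * e1
    # conditional construction keeps the draw exact per SNP
    z2 = (cov / np.sqrt(v1)) * e1 + np.sqrt(v2 - cov ** 2 / v1) * e2
    return z1, z2, ell


# ---------------------------------------------------------------------------
# Multi-mediator study (pipeline test bed)


def simulate_study(mediator_specs, j_exposure: int = 60, sigma_gamma: float = 0.02,
                   theta_dir: float = 0.2, n: int = 300_000, seed: int = 0):
    """Simulate a whole screening study: one exposure, several mediators, one outcome.

    Each entry of ``mediator_specs`` is a mapping with ``name`` and optionally
    ``theta_em`` (exposure->mediator), ``theta_my`` (mediator->outcome),
    ``j_own`` (the mediator's own instrument count), ``sigma_delta`` (their
    effect SD) and ``n`` (its GWAS sample size).  The exposure has
    ``j_exposure`` instruments with effects ``N(0, sigma_gamma^2)``; each
    mediator additionally has its own instrument block with effects
    ``N(0, sigma_delta^2)`` and zero exposure effect, and the outcome effect
    at every SNP is ``theta_dir * gamma + sum_m theta_my_m * (true mediator-m
    effect)`` plus sampling noise.  A weak-instrument mediator is produced by
    a small ``sigma_delta``.

    Returns ``(exposure, outcome, mediators_dict, truth)``.
    """
    rng = np.random.default_rng(seed)
    specs = [dict(name=s.get("name", f"mediator_{i + 1}"),
                  theta_em=s.get("theta_em", 0.3),
                  theta_my=s.get("theta_my", 0.5),
                  j_own=s.get("j_own", 40),
                  sigma_delta=s.get("sigma_delta", 0.02),
                  n=s.get("n", n))
             for i, s in enumerate(mediator_specs)]

    ids = [f"rsE{i + 1}" for i in range(j_exposure)]
    gamma = rng.normal(0.0, sigma_gamma, j_exposure)
    blocks = {}  # name -> (ids, delta)
    for s in specs:
        bids = [f"rs{s['name']}_{i + 1}" for i in range(s["j_own"])]
        blocks[s["name"]] = (bids, rng.normal(0.0, s["sigma_delta"], s["j_own"]))
        ids = ids + bids
    m_total = len(ids)

    exp_true = np.zeros(m_total)
    exp_true[:j_exposure] = gamma
    med_true = {}
    offset = j_exposure
    for s in specs:
        t = np.zeros(m_total)
        t[:j_exposure] = s["theta_em"] * gamma
        t[offset:offset + s["j_own"]] = blocks[s["name"]][1]
        med_true[s["name"]] = t
        offset += s["j_own"]
    out_true = theta_dir * exp_true + sum(
        s["theta_my"] * med_true[s["name"]] for s in specs)

    se = 1.0 / np.sqrt(n)
    eaf = rng.uniform(0.05, 0.95, m_total)

    def _table(true, nn, name, trait_type="quantitative"):
        se_v = np.full(m_total, 1.0 / np.sqrt(nn))
        beta = true + rng.normal(0.0, se_v)
        df = _snp_frame(beta, se_v, nn, eaf)
        df["SNP"] = ids
        return from_frame(df, name, trait_type=trait_type)

    exposure = _table(exp_true, n, "education")
    outcome = _table(out_true, n, "disease", trait_type="binary")
    mediators = {s["name"]: _table(med_true[s["name"]], s["n"], s["name"])
                 for s in specs}
    truth = {"gamma": gamma, "theta_dir": theta_dir, "specs": specs,
             "snp_ids": ids}
    return exposure, outcome, mediators, truth
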