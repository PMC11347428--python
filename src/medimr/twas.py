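"""Transcriptome-wide association from pre-trained expression weights.

Combines per-SNP expression weights w with GWAS z-scores under the local LD
structure:

    z_twas = (w' z) / sqrt(w' LD w)

Weight training (top1/blup/lasso/enet/bslmm) is out of scope: a GeneModel is
an input, typically from a FUSION-style weights file.  Gene-level significance
is controlled by Benjamini-Hochberg FDR, and shared susceptibility genes
across traits are reported by set intersection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

WEIGHT_MODELS = ("top1", "blup", "lasso", "enet", "bslmm")


@dataclass
class GeneModel:
    """Per-gene expression-weight vector from a pre-trained predictive model."""

    gene_id: str
    snp_ids: np.ndarray
    weights: np.ndarray
    model: str = "lasso"

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        self.weights = np.asarray(self.weights, float)
        if len(self.snp_ids) != len(self.weights):
            raise ValueError("snp_ids and weights must align")
        if not np.any(self.weights != 0):
            raise ValueError("gene model needs at least one nonzero weight")
        if self.model not in WEIGHT_MODELS:
            raise ValueError(f"unknown weight model {self.model!r}")


def read_gene_model(path, gene_id=None) -> GeneModel:
    """Read a per-gene tab-delimited weight file (snp, allele, weight, model)."""
    df = pd.read_csv(path, sep="\t")
    return GeneModel(
        gene_id=gene_id or str(path),
        snp_ids=df["snp"].to_numpy(),
        weights=df["weight"].to_numpy(float),
        model=str(df["model"].iloc[0]) if "model" in df else "lasso",
    )


def _nearest_psd(a: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((a + a.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T


def twas_zscore(model: GeneModel, z_gwas, ld):
    """Gene-level association z-score and two-sided normal p.

    ``z_gwas`` and ``ld`` must be aligned to ``model.snp_ids``.  The statistic
    is invariant to rescaling the weights.  A non-positive weight variance
    triggers a nearest-PSD repair of the LD matrix before failing.
    """
    z = np.asarray(z_gwas, float)
    ld = np.asarray(ld, float)
    w = model.weights
    if len(z) != len(w) or ld.shape != (len(w), len(w)):
        raise ValueError("weights, z-scores and LD must align")
    denom = float(w @ ld @ w)
    if denom <= 0:
        denom = float(w @ _nearest_psd(ld) @ w)
        if denom <= 0:
            raise ValueError("weight variance w' LD w is not positive")
    z_twas = float(w @ z) / np.sqrt(denom)
    return z_twas, float(2.0 * sps.norm.sf(abs(z_twas)))


def bh_fdr(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up: returns (monotone q-values, significant mask)."""
    pvals = np.asarray(pvals, float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return qvals, reject


def shared_genes(hits_by_trait: dict) -> dict:
    """Set-intersection report of FDR-significant genes across traits.

    ``hits_by_trait`` maps trait name -> iterable of significant gene ids;
    returns pairwise intersections plus the intersection across all traits.
    """
    traits = sorted(hits_by_trait)
    sets = {t: set(hits_by_trait[t]) for t in traits}
    out = {}
    for i, t1 in enumerate(traits):
        for t2 in traits[i + 1:]:
            out[f"{t1} & {t2}"] = sorted(sets[t1] & sets[t2])
    if len(traits) > 1:
        common = set.intersection(*sets.values())
        out["all"] = sorted(common)
    return out
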