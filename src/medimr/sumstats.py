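"""GWAS summary statistics: data model, I/O, allele harmonization, instrument selection.

The unit of all downstream estimation is the :class:`HarmonizedSet`: a table of
SNPs whose effect sizes for one or more exposures and a single outcome are all
expressed per copy of the same effect allele.  Binary-trait effects are carried
on the natural-log odds scale throughout; odds ratios appear only at formatting
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

# Canonical internal column dialect. Every reader maps onto these names and
# every writer emits them.
CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Field-standard instrument-selection defaults; the clumping parameters are
# deliberately config-exposed because published analyses rarely state them.
DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_KB = 10_000
DEFAULT_PALINDROME_EAF_LIMIT = 0.42


class SumstatsError(ValueError):
    """Base class for summary-statistics input problems."""


class FormatError(SumstatsError):
    """A mandatory column is missing or unreadable."""


class HarmonizationError(SumstatsError):
    """No SNPs survive cross-table alignment."""


class InstrumentError(SumstatsError):
    """No instruments survive selection (pipeline records 'excluded: no instruments')."""


@dataclass
class SummaryStats:
    """One trait's GWAS summary statistics.

    ``table`` uses the canonical dialect (see :data:`CANONICAL_COLUMNS`);
    ``beta`` is per effect-allele copy, log-OR for binary traits and SD units
    for quantitative ones.
    """

    trait_name: str
    table: pd.DataFrame
    trait_type: str = "quantitative"  # or "binary"
    unit_note: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.table["SNP"].duplicated().any():
            dup = self.table.loc[self.table["SNP"].duplicated(), "SNP"].iloc[0]
            raise SumstatsError(f"duplicate snp_id {dup!r} in {self.trait_name}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.table["SNP"])

    def write(self, path) -> None:
        """Write the table in the canonical tab-delimited dialect."""
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class HarmonizedSet:
    """Instruments aligned across K exposures and one outcome on a shared effect allele.

    Arrays are indexed ``[snp]`` or ``[snp, exposure]``.
    """

    exposure_names: list
    outcome_name: str
    snp_ids: np.ndarray
    b_exp: np.ndarray  # (J, K)
    se_exp: np.ndarray  # (J, K)
    b_out: np.ndarray  # (J,)
    se_out: np.ndarray  # (J,)
    eaf: np.ndarray  # (J,) NaN where missing
    palindromic: np.ndarray = field(default=None)
    flipped: np.ndarray = field(default=None)
    dropped: pd.DataFrame = field(default=None)  # SNP, dropped_reason
    outcome_type: str = "binary"

    def __post_init__(self) -> None:
        self.b_exp = np.atleast_2d(np.asarray(self.b_exp, float))
        if self.b_exp.shape[0] == 1 and len(self.snp_ids) != 1:
            self.b_exp = self.b_exp.T
        self.se_exp = np.asarray(self.se_exp, float).reshape(self.b_exp.shape)
        self.b_out = np.asarray(self.b_out, float).ravel()
        self.se_out = np.asarray(self.se_out, float).ravel()
        self.snp_ids = np.asarray(self.snp_ids)
        self.eaf = np.asarray(self.eaf, float).ravel() if self.eaf is not None else np.full(self.n_snp, np.nan)
        if self.palindromic is None:
            self.palindromic = np.zeros(self.n_snp, bool)
        if self.flipped is None:
            self.flipped = np.zeros(self.n_snp, bool)
        if self.dropped is None:
            self.dropped = pd.DataFrame(columns=["SNP", "dropped_reason"])
        if self.n_snp < 1:
            raise HarmonizationError("empty harmonized set")
        if not (np.all(self.se_exp > 0) and np.all(self.se_out > 0)):
            raise SumstatsError("non-positive SE in harmonized set")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposure(self) -> int:
        return self.b_exp.shape[1]

    def subset(self, mask) -> "HarmonizedSet":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = np.zeros(self.n_snp, bool)
            idx[mask] = True
            mask = idx
        return HarmonizedSet(
            exposure_names=list(self.exposure_names),
            outcome_name=self.outcome_name,
            snp_ids=self.snp_ids[mask],
            b_exp=self.b_exp[mask],
            se_exp=self.se_exp[mask],
            b_out=self.b_out[mask],
            se_out=self.se_out[mask],
            eaf=self.eaf[mask],
            palindromic=self.palindromic[mask],
            flipped=self.flipped[mask],
            dropped=self.dropped,
            outcome_type=self.outcome_type,
        )


# ---------------------------------------------------------------------------
# Reading


def read_sumstats(path, column_map=None, trait_name=None, trait_type="quantitative",
                  unit_note="", sep=None) -> SummaryStats:
    """Read a delimited summary-statistics file into the canonical dialect.

    ``column_map`` maps canonical names (``SNP``, ``EA``, ``BETA``, ...) to the
    source file's column names; canonical names already present need no entry.
    Rows violating basic invariants (se <= 0, p outside (0, 1], identical
    alleles) are dropped and counted in ``n_dropped``.  A missing P column is
    recomputed from a two-sided normal test of beta/se.
    """
    df = pd.read_csv(path, sep=sep if sep is not None else None, engine="python")
    if df.empty:
        raise SumstatsError(f"empty summary-statistics table: {path}")
    column_map = dict(column_map or {})
    rename = {src: canon for canon, src in column_map.items() if src in df.columns}
    df = df.rename(columns=rename)

    mandatory = ["SNP", "EA", "OA", "BETA", "SE"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s) {missing} in {path}")
    for c in CANONICAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df = df[CANONICAL_COLUMNS].copy()
    return _validate_frame(df, trait_name or str(path), trait_type, unit_note)


def from_frame(df: pd.DataFrame, trait_name: str, trait_type: str = "quantitative",
               unit_note: str = "") -> SummaryStats:
    """Build a validated SummaryStats from an in-memory canonical frame."""
    df = df.copy()
    for c in CANONICAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    return _validate_frame(df[CANONICAL_COLUMNS], trait_name, trait_type, unit_note)


def _validate_frame(df: pd.DataFrame, trait_name, trait_type, unit_note) -> SummaryStats:
    df["EA"] = df["EA"].astype(str).str.upper()
    df["OA"] = df["OA"].astype(str).str.upper()
    for c in ("BETA", "SE", "P", "EAF"):
        df[c] = pd.to_numeric(df[c], errors="coerce")

    ok = (
        df["SE"].gt(0)
        & df["BETA"].notna()
        & df["EA"].ne(df["OA"])
        & df["EA"].str.fullmatch(r"[ACGT]+")
        & df["OA"].str.fullmatch(r"[ACGT]+")
    )
    # P may be absent (recomputed below) but if present must be in (0, 1]
    has_p = df["P"].notna()
    ok &= ~has_p | (df["P"].gt(0) & df["P"].le(1))
    ok &= df["EAF"].isna() | (df["EAF"].gt(0) & df["EAF"].lt(1))

    n_dropped = int((~ok).sum())
    df = df.loc[ok].reset_index(drop=True)
    if df.empty:
        raise SumstatsError(f"no valid rows remain for {trait_name}")

    recompute = df["P"].isna()
    if recompute.any():
        z = df.loc[recompute, "BETA"] / df.loc[recompute, "SE"]
        df.loc[recompute, "P"] = 2.0 * sps.norm.sf(np.abs(z))
    return SummaryStats(trait_name=trait_name, table=df, trait_type=trait_type,
                        unit_note=unit_note, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Harmonization


def _is_palindromic(ea, oa):
    return _COMPLEMENT.get(ea) == oa


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, b) for b in allele)


def _align_row(ea_ref, oa_ref, ea, oa):
    """Return 'same', 'flip', or None (incompatible), resolving strand flips."""
    if (ea, oa) == (ea_ref, oa_ref):
        return "same"
    if (ea, oa) == (oa_ref, ea_ref):
        return "flip"
    cea, coa = _complement(ea), _complement(oa)
    if (cea, coa) == (ea_ref, oa_ref):
        return "same"
    if (cea, coa) == (oa_ref, ea_ref):
        return "flip"
    return None


def harmonize(exposures, outcome: SummaryStats,
              palindrome_eaf_limit: float = DEFAULT_PALINDROME_EAF_LIMIT) -> HarmonizedSet:
    """Align one or more exposures and an outcome onto a shared effect allele.

    The first exposure's alleles define the reference orientation.  Swapped
    alleles flip the sign of beta (and replace eaf by 1-eaf); strand flips are
    resolved by complementing before matching.  Palindromic (A/T, C/G) SNPs
    are retained only when both tables report an allele frequency clearly away
    from 0.5 (``min(eaf, 1-eaf) < palindrome_eaf_limit`` in both), with the
    orientation inferred from frequency; otherwise they are dropped with
    reason ``palindromic_ambiguous``.
    """
    if isinstance(exposures, SummaryStats):
        exposures = [exposures]
    if len(exposures) < 1:
        raise ValueError("need at least one exposure")

    tables = [e.table.set_index("SNP") for e in exposures]
    out_tab = outcome.table.set_index("SNP")
    common = tables[0].index
    for t in tables[1:]:
        common = common.intersection(t.index)
    common = common.intersection(out_tab.index)
    if len(common) == 0:
        raise HarmonizationError(
            f"no SNPs shared by {[e.trait_name for e in exposures]} and {outcome.trait_name}")

    K = len(exposures)
    rows = []
    dropped = []
    for snp in common:
        ref = tables[0].loc[snp]
        ea_ref, oa_ref = ref["EA"], ref["OA"]
        palin = _is_palindromic(ea_ref, oa_ref)

        b_exp = np.empty(K)
        se_exp = np.empty(K)
        flipped_any = False
        ok = True
        reason = None
        freq_pairs = []  # (eaf on reference orientation) per table, for palindrome logic

        for k, t in enumerate(tables):
            r = t.loc[snp]
            if palin:
                # orientation by frequency only
                b_exp[k], se_exp[k] = r["BETA"], r["SE"]
                freq_pairs.append(r["EAF"])
                continue
            action = _align_row(ea_ref, oa_ref, r["EA"], r["OA"])
            if action is None:
                ok, reason = False, "allele_mismatch"
                break
            sign = -1.0 if action == "flip" else 1.0
            flipped_any |= action == "flip"
            b_exp[k] = sign * r["BETA"]
            se_exp[k] = r["SE"]

        if ok:
            r = out_tab.loc[snp]
            if palin:
                b_out_raw, se_out, eaf_out = r["BETA"], r["SE"], r["EAF"]
            else:
                action = _align_row(ea_ref, oa_ref, r["EA"], r["OA"])
                if action is None:
                    ok, reason = False, "allele_mismatch"
                else:
                    sign = -1.0 if action == "flip" else 1.0
                    flipped_any |= action == "flip"
                    b_out, se_out = sign * r["BETA"], r["SE"]

        if ok and palin:
            freqs = freq_pairs + [eaf_out]
            if any(pd.isna(f) for f in freqs) or any(
                    min(f, 1 - f) >= palindrome_eaf_limit for f in freqs):
                ok, reason = False, "palindromic_ambiguous"
            else:
                # minor-allele concordance: if the effect allele is minor in the
                # reference table it must be minor everywhere; otherwise flip.
                ref_minor = freq_pairs[0] < 0.5
                signs = [1.0 if (f < 0.5) == ref_minor else -1.0 for f in freqs]
                b_exp = b_exp * signs[:K]
                flipped_any |= any(s < 0 for s in signs)
                b_out = signs[-1] * b_out_raw

        if not ok:
            dropped.append((snp, reason))
            continue

        eaf_ref = tables[0].loc[snp, "EAF"]
        rows.append((snp, b_exp.copy(), se_exp.copy(), b_out, se_out, eaf_ref,
                     palin, flipped_any))

    if not rows:
        raise HarmonizationError("no SNPs survived harmonization")

    snp_ids = np.array([r[0] for r in rows])
    return HarmonizedSet(
        exposure_names=[e.trait_name for e in exposures],
        outcome_name=outcome.trait_name,
        snp_ids=snp_ids,
        b_exp=np.vstack([r[1] for r in rows]),
        se_exp=np.vstack([r[2] for r in rows]),
        b_out=np.array([r[3] for r in rows]),
        se_out=np.array([r[4] for r in rows]),
        eaf=np.array([r[5] for r in rows], float),
        palindromic=np.array([r[6] for r in rows]),
        flipped=np.array([r[7] for r in rows]),
        dropped=pd.DataFrame(dropped, columns=["SNP", "dropped_reason"]),
        outcome_type=outcome.trait_type,
    )


# ---------------------------------------------------------------------------
# Instrument selection


def select_instruments(stats: SummaryStats, p_threshold: float = DEFAULT_P_THRESHOLD,
                       ld: pd.DataFrame | np.ndarray | None = None,
                       ld_snps=None,
                       clump_r2: float = DEFAULT_CLUMP_R2,
                       clump_kb: int = DEFAULT_CLUMP_KB) -> SummaryStats:
    """Keep genome-wide-significant SNPs and greedily clump them.

    SNPs are visited by ascending p-value; a SNP is discarded when it lies
    within ``clump_kb`` of an already-kept SNP on the same chromosome, or when
    ``ld`` is supplied and its r^2 with a kept SNP exceeds ``clump_r2``.
    """
    if len(stats) == 0:
        raise InstrumentError(f"empty table for {stats.trait_name}")
    df = stats.table
    sig = df[df["P"] < p_threshold]
    if sig.empty:
        raise InstrumentError(
            f"no instruments for {stats.trait_name} at p < {p_threshold:g}")

    ld_index = None
    if ld is not None:
        if isinstance(ld, pd.DataFrame):
            ld_index = {s: i for i, s in enumerate(ld.index)}
            ld = ld.to_numpy()
        elif ld_snps is not None:
            ld_index = {s: i for i, s in enumerate(ld_snps)}
        else:
            raise ValueError("plain-array ld requires ld_snps giving SNP order")

    # stable order: ascending p, then snp_id so row order never matters
    sig = sig.sort_values(["P", "SNP"], kind="mergesort")
    kept = []
    for _, row in sig.iterrows():
        ok = True
        for krow in kept:
            same_chr = (pd.notna(row["CHR"]) and pd.notna(krow["CHR"])
                        and str(row["CHR"]) == str(krow["CHR"]))
            if same_chr and pd.notna(row["POS"]) and pd.notna(krow["POS"]):
                if abs(float(row["POS"]) - float(krow["POS"])) <= clump_kb * 1000:
                    ok = False
                    break
            if ld_index is not None and row["SNP"] in ld_index and krow["SNP"] in ld_index:
                r = ld[ld_index[row["SNP"]], ld_index[krow["SNP"]]]
                if r * r > clump_r2:
                    ok = False
                    break
        if ok:
            kept.append(row)

    out = pd.DataFrame(kept).reset_index(drop=True)
    return SummaryStats(trait_name=stats.trait_name, table=out,
                        trait_type=stats.trait_type, unit_note=stats.unit_note)
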