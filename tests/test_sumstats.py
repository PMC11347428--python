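import io

import numpy as np
import pandas as pd
import pytest

from medimr import sumstats
from medimr.sumstats import (HarmonizationError, InstrumentError, from_frame,
                             harmonize, read_sumstats, select_instruments)


def _tsv(text):
    buf = io.StringIO(text.strip() + "\n")
    return buf


def _frame(rows):
    return pd.DataFrame(rows, columns=["SNP", "CHR", "POS", "EA", "OA", "EAF",
                                       "BETA", "SE", "P", "N"])


class TestReadSumstats:
    def test_well_formed_table_is_read_verbatim(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("SNP\tEA\tOA\tBETA\tSE\tP\n"
                     "rs1\tA\tG\t0.1\t0.02\t1e-8\n"
                     "rs2\tC\tT\t-0.2\t0.03\t1e-10\n"
                     "rs3\tG\tA\t0.05\t0.01\t0.4\n")
        ss = read_sumstats(p, trait_name="bmi")
        assert len(ss) == 3
        assert ss.n_dropped == 0
        assert list(ss.table["BETA"]) == [0.1, -0.2, 0.05]

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("SNP\tEA\tOA\tBETA\tSE\tP\n"
                     "rs1\tA\tG\t0.1\t0.0\t1e-8\n"   # se = 0
                     "rs2\tC\tC\t0.2\t0.03\t1e-10\n"  # identical alleles
                     "rs3\tG\tA\t0.05\t0.01\t0.4\n")
        ss = read_sumstats(p, trait_name="x")
        assert len(ss) == 1
        assert ss.n_dropped == 2

    def test_missing_pvalue_recomputed_from_z(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("SNP\tEA\tOA\tBETA\tSE\n"
                     "rs1\tA\tG\t0.0196\t0.01\n")  # z = 1.96
        ss = read_sumstats(p, trait_name="x")
        assert ss.table["P"].iloc[0] == pytest.approx(0.05, abs=1e-3)

    def test_column_map_renames_source_columns(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("rsid,a1,a2,b,stderr\nrs1,A,G,0.1,0.02\n")
        ss = read_sumstats(p, column_map={"SNP": "rsid", "EA": "a1", "OA": "a2",
                                          "BETA": "b", "SE": "stderr"})
        assert ss.table["SNP"].iloc[0] == "rs1"

    def test_missing_mandatory_column_names_it(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("SNP\tEA\tBETA\tSE\nrs1\tA\t0.1\t0.02\n")
        with pytest.raises(sumstats.FormatError, match="OA"):
            read_sumstats(p)


class TestHarmonize:
    def _pair(self, out_rows):
        exp = from_frame(_frame([
            ("rs1", "1", 100, "A", "G", 0.2, 0.10, 0.01, 1e-9, 1000),
            ("rs2", "1", 200, "C", "T", 0.3, -0.05, 0.01, 1e-9, 1000),
        ]), "exp")
        out = from_frame(_frame(out_rows), "out", trait_type="binary")
        return exp, out

    def test_same_alleles_pass_through_unchanged(self):
        exp, out = self._pair([
            ("rs1", "1", 100, "A", "G", 0.2, 0.20, 0.02, 1e-5, 500),
            ("rs2", "1", 200, "C", "T", 0.3, 0.10, 0.02, 1e-5, 500),
        ])
        h = harmonize([exp], out)
        assert np.allclose(h.b_out, [0.20, 0.10])
        assert not h.flipped.any()

    def test_swapped_alleles_flip_outcome_beta(self):
        exp, out = self._pair([
            ("rs1", "1", 100, "G", "A", 0.8, 0.20, 0.02, 1e-5, 500),
            ("rs2", "1", 200, "C", "T", 0.3, 0.10, 0.02, 1e-5, 500),
        ])
        h = harmonize([exp], out)
        assert h.b_out[list(h.snp_ids).index("rs1")] == pytest.approx(-0.20)

    def test_strand_flip_resolved_by_complementing(self):
        # outcome lists rs1 as T/C = complement of A/G: same orientation
        exp, out = self._pair([
            ("rs1", "1", 100, "T", "C", 0.2, 0.20, 0.02, 1e-5, 500),
            ("rs2", "1", 200, "C", "T", 0.3, 0.10, 0.02, 1e-5, 500),
        ])
        h = harmonize([exp], out)
        assert h.b_out[list(h.snp_ids).index("rs1")] == pytest.approx(0.20)

    def test_palindromic_near_half_frequency_dropped(self):
        exp = from_frame(_frame([
            ("rs1", "1", 100, "A", "T", 0.50, 0.10, 0.01, 1e-9, 1000),
            ("rs2", "1", 200, "C", "T", 0.30, 0.05, 0.01, 1e-9, 1000),
        ]), "exp")
        out = from_frame(_frame([
            ("rs1", "1", 100, "A", "T", 0.50, 0.20, 0.02, 1e-5, 500),
            ("rs2", "1", 200, "C", "T", 0.30, 0.10, 0.02, 1e-5, 500),
        ]), "out")
        h = harmonize([exp], out)
        assert list(h.snp_ids) == ["rs2"]
        assert "palindromic_ambiguous" in set(h.dropped["dropped_reason"])

    def test_palindromic_clear_frequency_kept_and_oriented(self):
        exp = from_frame(_frame([
            ("rs1", "1", 100, "A", "T", 0.10, 0.10, 0.01, 1e-9, 1000),
        ]), "exp")
        # outcome reports the same SNP with eaf 0.9: opposite orientation
        out = from_frame(_frame([
            ("rs1", "1", 100, "A", "T", 0.90, 0.20, 0.02, 1e-5, 500),
        ]), "out")
        h = harmonize([exp], out)
        assert h.b_out[0] == pytest.approx(-0.20)

    def test_no_shared_snps_raises(self):
        exp = from_frame(_frame([
            ("rs1", "1", 100, "A", "G", 0.2, 0.1, 0.01, 1e-9, 1000)]), "exp")
        out = from_frame(_frame([
            ("rs9", "1", 900, "A", "G", 0.2, 0.1, 0.01, 1e-9, 1000)]), "out")
        with pytest.raises(HarmonizationError):
            harmonize([exp], out)

    def test_idempotent_on_aligned_tables(self):
        exp, out = self._pair([
            ("rs1", "1", 100, "A", "G", 0.2, 0.20, 0.02, 1e-5, 500),
            ("rs2", "1", 200, "C", "T", 0.3, 0.10, 0.02, 1e-5, 500),
        ])
        h1 = harmonize([exp], out)
        # rebuild tables from the harmonized set and harmonize again
        exp2 = from_frame(_frame([
            (s, "1", 100, "A", "G", h1.eaf[i], h1.b_exp[i, 0], h1.se_exp[i, 0],
             1e-9, 1000)
            for i, s in enumerate(h1.snp_ids)]), "exp")
        out2 = from_frame(_frame([
            (s, "1", 100, "A", "G", h1.eaf[i], h1.b_out[i], h1.se_out[i],
             1e-5, 500)
            for i, s in enumerate(h1.snp_ids)]), "out")
        h2 = harmonize([exp2], out2)
        assert np.allclose(np.sort(h1.b_out), np.sort(h2.b_out))
        assert np.allclose(np.sort(h1.b_exp[:, 0]), np.sort(h2.b_exp[:, 0]))

    def test_flip_property_negated_swapped_outcome_identical(self):
        exp, out = self._pair([
            ("rs1", "1", 100, "A", "G", 0.2, 0.20, 0.02, 1e-5, 500),
            ("rs2", "1", 200, "C", "T", 0.3, 0.10, 0.02, 1e-5, 500),
        ])
        h1 = harmonize([exp], out)
        swapped = out.table.copy()
        swapped[["EA", "OA"]] = swapped[["OA", "EA"]].to_numpy()
        swapped["BETA"] = -swapped["BETA"]
        swapped["EAF"] = 1.0 - swapped["EAF"]
        out2 = from_frame(swapped, "out", trait_type="binary")
        h2 = harmonize([exp], out2)
        assert np.allclose(h1.b_out, h2.b_out)
        assert np.allclose(h1.b_exp, h2.b_exp)


class TestSelectInstruments:
    def _stats(self, rows):
        return from_frame(_frame(rows), "exp")

    def test_p_threshold_filters(self):
        ss = self._stats([
            (f"rs{i}", str(i), 1000, "A", "G", 0.2, 0.1, 0.01, p, 1000)
            for i, p in enumerate([1e-9, 1e-7, 1e-6, 1e-5, 0.01], start=1)
        ])
        kept = select_instruments(ss, p_threshold=5e-8)
        assert len(kept) == 1
        assert kept.table["SNP"].iloc[0] == "rs1"

    def test_distance_clump_keeps_smaller_p(self):
        ss = self._stats([
            ("rs1", "1", 1_000_000, "A", "G", 0.2, 0.1, 0.01, 1e-9, 1000),
            ("rs2", "1", 1_001_000, "A", "G", 0.2, 0.1, 0.01, 1e-8, 1000),
        ])
        kept = select_instruments(ss, clump_kb=10_000)
        assert list(kept.table["SNP"]) == ["rs1"]

    def test_independent_snps_all_kept_with_ld(self):
        ss = self._stats([
            ("rs1", "1", 1, "A", "G", 0.2, 0.1, 0.01, 1e-9, 1000),
            ("rs2", "2", 1, "A", "G", 0.2, 0.1, 0.01, 1e-9, 1000),
            ("rs3", "3", 1, "A", "G", 0.2, 0.1, 0.01, 1e-9, 1000),
        ])
        ld = pd.DataFrame(np.eye(3), index=["rs1", "rs2", "rs3"],
                          columns=["rs1", "rs2", "rs3"])
        kept = select_instruments(ss, ld=ld)
        assert len(kept) == 3

    def test_ld_clump_removes_correlated(self):
        ss = self._stats([
            ("rs1", "1", 1, "A", "G", 0.2, 0.1, 0.01, 1e-9, 1000),
            ("rs2", "2", 1, "A", "G", 0.2, 0.1, 0.01, 1e-8, 1000),
        ])
        ld = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]],
                          index=["rs1", "rs2"], columns=["rs1", "rs2"])
        kept = select_instruments(ss, ld=ld, clump_r2=0.001)
        assert list(kept.table["SNP"]) == ["rs1"]

    def test_row_order_invariance(self):
        rows = [
            (f"rs{i}", str(i), 1000 * i, "A", "G", 0.2, 0.1, 0.01, p, 1000)
            for i, p in enumerate([1e-9, 1e-12, 1e-10, 3e-8], start=1)
        ]
        a = select_instruments(self._stats(rows))
        b = select_instruments(self._stats(rows[::-1]))
        assert sorted(a.table["SNP"]) == sorted(b.table["SNP"])

    def test_no_instruments_is_named_error(self):
        ss = self._stats([
            ("rs1", "1", 1, "A", "G", 0.2, 0.1, 0.01, 0.5, 1000)])
        with pytest.raises(InstrumentError, match="no instruments"):
            select_instruments(ss)
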