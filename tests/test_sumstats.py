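"""Summary-statistics I/O, harmonization, clumping, instrument selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate.sumstats import (
    HarmonizedPairs,
    InsufficientInstrumentsError,
    LDTable,
    SumStats,
    clump,
    harmonize,
    per_snp_f,
    read_sumstats,
    select_instruments,
    swap_effect_allele,
    write_pairs,
    write_sumstats,
)

from conftest import make_sumstats, snp_row

HEADER = "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"


def write_tsv(path, rows):
    with open(path, "w") as fh:
        fh.write(HEADER)
        for r in rows:
            fh.write("\t".join(str(v) for v in r) + "\n")


class TestReadWrite:
    def test_well_formed_rows_parse_identically(self, tmp_path):
        rows = [("rs1", 1, 100, "A", "G", 0.2, 0.1, 0.02, 1e-9, 5000),
                ("rs2", 1, 200, "C", "T", 0.4, -0.05, 0.01, 0.03, 5000),
                ("rs3", 2, 300, "G", "A", 0.5, 0.0, 0.05, 1.0, 5000)]
        p = tmp_path / "s.tsv"
        write_tsv(p, rows)
        stats = read_sumstats(p)
        assert len(stats) == 3
        rec = stats.indexed().loc["rs2"]
        assert rec["beta"] == -0.05 and rec["se"] == 0.01 and rec["pval"] == 0.03
        assert stats.parse_report.n_dropped == 0

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        rows = [("rs1", 1, 100, "A", "G", 0.2, 0.1, 0.02, 1e-9, 5000),
                ("rs2", 1, 200, "C", "T", 0.4, 0.05, 0.0, 0.03, 5000),   # se = 0
                ("rs3", 1, 300, "G", "G", 0.4, 0.05, 0.01, 0.03, 5000),  # ea == oa
                ("rs4", 1, 400, "G", "A", 0.4, "NA", 0.01, 0.03, 5000)]  # missing beta
        p = tmp_path / "s.tsv"
        write_tsv(p, rows)
        stats = read_sumstats(p)
        assert len(stats) == 1
        assert stats.parse_report.n_dropped == 3
        assert stats.parse_report.drop_reasons["invalid-se"] == 1

    def test_zero_valid_rows_is_an_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text(HEADER)
        with pytest.raises(ValueError, match="zero valid rows"):
            read_sumstats(p)

    def test_missing_file_and_missing_column(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_sumstats(tmp_path / "nope.tsv")
        p = tmp_path / "nohead.tsv"
        p.write_text("SNP\tBETA\nrs1\t0.1\n")
        with pytest.raises(ValueError, match="absent from header"):
            read_sumstats(p)

    def test_column_map_renames_headers(self, tmp_path):
        p = tmp_path / "odd.tsv"
        p.write_text("marker\tCHR\tPOS\tEA\tOA\tEAF\teffect\tSE\tP\tN\n"
                     "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.02\t1e-9\t5000\n")
        stats = read_sumstats(p, column_map={"snp_id": "marker", "beta": "effect"})
        assert stats.snp_ids.tolist() == ["rs1"]

    def test_round_trip_is_content_identical(self, tmp_path):
        rows = [("rs1", 1, 100, "A", "G", 0.2, 0.123456789, 0.02, 1e-9, 5000),
                ("rs2", 2, 200, "C", "T", 0.4, -0.05, 0.01, 0.03, 6000)]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_tsv(p1, rows)
        stats = read_sumstats(p1)
        write_sumstats(stats, p2)
        again = read_sumstats(p2)
        pd.testing.assert_frame_equal(stats.table, again.table)

    def test_write_empty_collection_gives_header_only(self, tmp_path):
        empty = SumStats("none", make_sumstats([]).table)
        p = tmp_path / "empty.tsv"
        write_sumstats(empty, p)
        assert p.read_text().strip() == HEADER.strip()

    def test_write_pairs_round_trip_and_drop_report(self, tmp_path):
        pairs = HarmonizedPairs.from_arrays([0.1, 0.2], [0.01, 0.01],
                                            [0.05, 0.1], [0.02, 0.02])
        pairs.dropped = [("rs9", "allele-mismatch"), ("rs8", "palindromic-ambiguous")]
        p, d = tmp_path / "pairs.tsv", tmp_path / "dropped.tsv"
        write_pairs(pairs, p, dropped_path=d)
        back = pd.read_csv(p, sep="\t")
        pd.testing.assert_frame_equal(back, pairs.table)
        drops = pd.read_csv(d, sep="\t")
        assert len(drops) == 2 and set(drops["reason"]) == {
            "allele-mismatch", "palindromic-ambiguous"}

    def test_duplicate_snp_ids_rejected_by_container(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_sumstats([snp_row("rs1", 0.1, 0.01, 0.5),
                           snp_row("rs1", 0.2, 0.01, 0.5)])


class TestHarmonize:
    def exposure(self):
        return make_sumstats([snp_row("rs1", 0.1, 0.01, 1e-9, ea="A", oa="G")],
                             label="exp")

    @pytest.mark.parametrize("ea,oa,beta,expected_beta,reason", [
        ("A", "G", 0.05, 0.05, None),          # identical orientation
        ("G", "A", 0.05, -0.05, None),         # swapped alleles negate
        ("T", "C", 0.05, 0.05, None),          # strand complement of A/G
        ("C", "T", 0.05, -0.05, None),         # complement + swap
        ("A", "C", 0.05, None, "allele-mismatch"),
    ])
    def test_allele_alignment_cases(self, ea, oa, beta, expected_beta, reason):
        out = make_sumstats([snp_row("rs1", beta, 0.02, 0.01, ea=ea, oa=oa)],
                            label="out")
        pairs = harmonize(self.exposure(), out)
        if reason is None:
            assert len(pairs) == 1
            assert pairs.beta_outcome[0] == pytest.approx(expected_beta)
            assert pairs.beta_exposure[0] == pytest.approx(0.1)
        else:
            assert len(pairs) == 0
            assert pairs.dropped == [("rs1", reason)]

    def test_palindromic_at_maximal_ambiguity_dropped(self):
        exp = make_sumstats([snp_row("rs1", 0.1, 0.01, 1e-9, ea="A", oa="T",
                                     eaf=0.50)], label="exp")
        out = make_sumstats([snp_row("rs1", 0.05, 0.02, 0.01, ea="A", oa="T",
                                     eaf=0.50)], label="out")
        pairs = harmonize(exp, out)
        assert pairs.dropped == [("rs1", "palindromic-ambiguous")]

    def test_palindromic_aligned_by_frequency_when_unambiguous(self):
        exp = make_sumstats([snp_row("rs1", 0.1, 0.01, 1e-9, ea="A", oa="T",
                                     eaf=0.10)], label="exp")
        same_side = make_sumstats([snp_row("rs1", 0.05, 0.02, 0.01, ea="T",
                                           oa="A", eaf=0.12)], label="out")
        flipped = make_sumstats([snp_row("rs1", 0.05, 0.02, 0.01, ea="T",
                                         oa="A", eaf=0.88)], label="out")
        assert harmonize(exp, same_side).beta_outcome[0] == pytest.approx(0.05)
        assert harmonize(exp, flipped).beta_outcome[0] == pytest.approx(-0.05)

    def test_palindromic_missing_eaf_dropped(self):
        exp = make_sumstats([snp_row("rs1", 0.1, 0.01, 1e-9, ea="G", oa="C",
                                     eaf=0.1)], label="exp")
        out = make_sumstats([snp_row("rs1", 0.05, 0.02, 0.01, ea="G", oa="C",
                                     eaf=np.nan)], label="out")
        assert harmonize(exp, out).dropped == [("rs1", "palindromic-ambiguous")]

    def test_retained_plus_dropped_partition_intersection(self):
        exp = make_sumstats([
            snp_row("rs1", 0.1, 0.01, 1e-9, ea="A", oa="G"),
            snp_row("rs2", 0.1, 0.01, 1e-9, ea="A", oa="T", eaf=0.5),
            snp_row("rs3", 0.1, 0.01, 1e-9, ea="C", oa="T"),
            snp_row("rs4", 0.1, 0.01, 1e-9, ea="A", oa="G")], label="exp")
        out = make_sumstats([
            snp_row("rs1", 0.05, 0.02, 0.01, ea="G", oa="A"),
            snp_row("rs2", 0.05, 0.02, 0.01, ea="A", oa="T", eaf=0.5),
            snp_row("rs3", 0.05, 0.02, 0.01, ea="A", oa="C"),  # mismatch
            snp_row("rs9", 0.05, 0.02, 0.01)], label="out")
        pairs = harmonize(exp, out)
        assert len(pairs) + len(pairs.dropped) == 3  # rs4/rs9 not shared
        assert set(p for p, _ in pairs.dropped) == {"rs2", "rs3"}

    def test_empty_intersection_is_an_error(self):
        exp = make_sumstats([snp_row("rs1", 0.1, 0.01, 1e-9)], label="exp")
        out = make_sumstats([snp_row("rs2", 0.1, 0.01, 1e-9)], label="out")
        with pytest.raises(ValueError, match="empty SNP intersection"):
            harmonize(exp, out)

    def test_three_study_harmonization_aligns_mediator(self):
        exp = make_sumstats([snp_row("rs1", 0.1, 0.01, 1e-9, ea="A", oa="G")],
                            label="exp")
        out = make_sumstats([snp_row("rs1", 0.05, 0.02, 0.01, ea="A", oa="G")],
                            label="out")
        med = make_sumstats([snp_row("rs1", 0.03, 0.02, 0.01, ea="G", oa="A")],
                            label="med")
        pairs = harmonize(exp, out, mediator=med)
        assert pairs.has_mediator
        assert pairs.beta_mediator[0] == pytest.approx(-0.03)

    @settings(deadline=None, derandomize=True)
    @given(beta=st.floats(-1, 1, allow_nan=False),
           eaf=st.floats(0.01, 0.99))
    def test_allele_swap_is_an_involution(self, beta, eaf):
        b2, f2 = swap_effect_allele(*swap_effect_allele(beta, eaf))
        assert b2 == pytest.approx(beta) and f2 == pytest.approx(eaf)


class TestClump:
    def stats(self, pvals, positions=None, chroms=None, label="t"):
        positions = positions or [1000 * (i + 1) for i in range(len(pvals))]
        chroms = chroms or ["1"] * len(pvals)
        return make_sumstats(
            [snp_row(f"rs{i+1}", 0.1, 0.01, p, chrom=c, pos=pos)
             for i, (p, pos, c) in enumerate(zip(pvals, positions, chroms))],
            label=label)

    def test_independent_snps_all_retained(self):
        stats = self.stats([1e-10, 1e-9, 1e-8])
        assert clump(stats, LDTable(), 0.001, 10_000_000) == ["rs1", "rs2", "rs3"]

    def test_dominant_pair_keeps_smaller_p(self):
        stats = self.stats([1e-10, 1e-9])
        ld = LDTable({("rs1", "rs2"): 0.5})
        assert clump(stats, ld, 0.001, 10_000_000) == ["rs1"]

    def test_chained_ld_greedy_selection(self):
        # r2(1,2)=0.9, r2(2,3)=0.9, r2(1,3)=0: greedy keeps 1, prunes 2,
        # then keeps 3 and 4 (brute-force enumeration of the procedure)
        stats = self.stats([1e-12, 1e-11, 1e-10, 1e-9])
        ld = LDTable({("rs1", "rs2"): 0.9, ("rs2", "rs3"): 0.9})
        assert clump(stats, ld, 0.001, 10_000_000) == ["rs1", "rs3", "rs4"]

    def test_window_limits_pruning(self):
        # same LD but second SNP outside the window: both survive
        stats = self.stats([1e-10, 1e-9], positions=[1000, 20_000_000])
        ld = LDTable({("rs1", "rs2"): 0.9})
        assert clump(stats, ld, 0.001, 10_000_000) == ["rs1", "rs2"]
        # at exactly the window edge the neighbour is pruned
        stats2 = self.stats([1e-10, 1e-9], positions=[1000, 1000 + 10_000_000])
        assert clump(stats2, ld, 0.001, 10_000_000) == ["rs1"]

    def test_different_chromosomes_never_pruned(self):
        stats = self.stats([1e-10, 1e-9], positions=[1000, 2000],
                           chroms=["1", "2"])
        ld = LDTable({("rs1", "rs2"): 0.9})
        assert clump(stats, ld, 0.001, 10_000_000) == ["rs1", "rs2"]

    def test_empty_input_gives_empty_output(self):
        assert clump(make_sumstats([]), LDTable(), 0.001, 10_000_000) == []

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(perm_seed=st.integers(0, 10_000))
    def test_output_invariant_to_row_order(self, perm_seed):
        stats = self.stats([1e-12, 1e-11, 1e-10, 1e-9, 1e-8])
        ld = LDTable({("rs1", "rs2"): 0.9, ("rs3", "rs4"): 0.9,
                      ("rs2", "rs5"): 0.9})
        expected = clump(stats, ld, 0.001, 10_000_000)
        rng = np.random.default_rng(perm_seed)
        shuffled = SumStats("t", stats.table.sample(
            frac=1, random_state=int(rng.integers(1 << 31))))
        assert clump(shuffled, ld, 0.001, 10_000_000) == expected


class TestSelectInstruments:
    def stats(self, n_sig, n_weak=0, ea="A", oa="G"):
        rows = [snp_row(f"rs{i+1}", 0.1, 0.01, 1e-9, pos=1000 * (i + 1),
                        ea=ea, oa=oa) for i in range(n_sig)]
        rows += [snp_row(f"weak{i}", 0.01, 0.01, 0.5, pos=500_000 + i)
                 for i in range(n_weak)]
        return make_sumstats(rows)

    def test_insufficient_instruments_carries_count(self):
        with pytest.raises(InsufficientInstrumentsError) as exc:
            select_instruments(self.stats(9), LDTable())
        assert exc.value.n_available == 9

    def test_twelve_independent_significant_snps_selected(self):
        inst = select_instruments(self.stats(12, n_weak=5), LDTable())
        assert len(inst) == 12
        assert all(f == pytest.approx(100.0) for f in inst.per_snp_f.values())

    def test_indels_excluded_before_clumping(self):
        stats = self.stats(12)
        indel = make_sumstats([snp_row("indel1", 0.5, 0.01, 1e-30, ea="AT",
                                       oa="A", pos=999)])
        merged = SumStats("t", pd.concat([stats.table, indel.table],
                                         ignore_index=True))
        inst = select_instruments(merged, LDTable())
        assert "indel1" not in inst.snp_ids

    def test_no_op_filter_limit_returns_all_biallelic(self):
        stats = self.stats(12, n_weak=5)
        inst = select_instruments(stats, LDTable(), p_threshold=1.0,
                                  r2_threshold=1.0, min_variants=1)
        assert len(inst) == 17


class TestPerSnpF:
    @pytest.mark.parametrize("beta,se,expected", [
        (0.1, 0.02, 25.0), (0.0, 0.01, 0.0), (0.03, 0.01, 9.0)])
    def test_analytic_values(self, beta, se, expected):
        assert per_snp_f(beta, se) == pytest.approx(expected)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            per_snp_f(0.1, 0.0)
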