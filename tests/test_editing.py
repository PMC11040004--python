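"""T-stripped alignment, editing tables, ORF reconstruction, code-4 translation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kedit.editing import (
    align_read_tstripped,
    build_site_table,
    coverage_profile,
    find_longest_orf,
    is_edited,
    reconstruct_orf,
    translate_code4,
    tstrip,
)

dna = st.text(alphabet="ACGT", min_size=5, max_size=200).filter(
    lambda s: set(s) != {"T"}
)


class TestSiteTable:
    def test_example_decomposition(self):
        t = build_site_table("x", "ACTTGA")
        assert t.backbone == "ACGA"
        assert t.site_ucount == [0, 0, 2, 0, 0]
        assert t.site_coord_5p == [0, 1, 4, 5]

    def test_leading_ts_counted_in_first_site(self):
        assert build_site_table("x", "TTAC").site_ucount[0] == 2

    @given(dna)
    def test_rebuild_roundtrip(self, seq):
        t = build_site_table("x", seq)
        assert t.rebuild() == seq
        assert t.n_sites == len(t.backbone) + 1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_site_table("x", "TTTT")
        with pytest.raises(ValueError):
            build_site_table("x", "")


class TestReadAlignment:
    TABLE = build_site_table("ref", "ACTTGA")

    def test_deletion_counted(self):
        p = align_read_tstripped("r", "ACTGA", self.TABLE, min_read_len=4, try_revcomp=False)
        assert (p.obs_ucount, p.ref_ucount) == ([0, 1, 0], [0, 2, 0])
        assert (p.n_deletions, p.n_insertions, p.n_edited_sites) == (1, 0, 1)

    def test_insertions_counted(self):
        p = align_read_tstripped("r", "ACTTTTGA", self.TABLE, min_read_len=4, try_revcomp=False)
        assert p.obs_ucount[1] == 4 and p.n_insertions == 2

    def test_reverse_strand_read_maps(self):
        p = align_read_tstripped("r", "TCAAAGT", self.TABLE, min_read_len=4)
        assert p is not None and p.strand == "-"

    def test_unmappable_read_returns_none(self):
        t = build_site_table("ref", "ACGACGACGCCAGCAGGCAGCAA")
        assert align_read_tstripped("r", "TGTGTGTGTGTGTGTGTGTGTG", t) is None

    def test_indel_balance_invariant(self, small_sim):
        cfg, truth, reads = small_sim
        name = next(iter(truth.edited_mrnas))
        t = truth.site_table(name)
        for rid, seq, _ in reads["mrna"][:300]:
            p = align_read_tstripped(rid, seq, t)
            if p is None:
                continue
            obs_total = sum(p.obs_ucount)
            ref_total = sum(p.ref_ucount)
            assert p.n_insertions - p.n_deletions == obs_total - ref_total

    def test_planted_stage_patterns_recovered_exactly(self, small_sim):
        cfg, truth, reads = small_sim
        name = next(iter(truth.edited_mrnas))
        t = truth.site_table(name)
        e = truth.edited_ucounts[name]
        checked = 0
        for rid, seq, _ in reads["mrna"]:
            origin = truth.read_origins[rid]
            if origin.get("locus") != name or origin.get("stage") != 1.0:
                continue
            p = align_read_tstripped(rid, seq, t)
            if p is None:
                continue
            assert p.obs_ucount == e[p.first_site : p.last_site + 1]
            checked += 1
        assert checked > 10


class TestIsEdited:
    def make(self, n_edited):
        t = build_site_table("x", "ACGACGACGACG")
        obs = list(t.site_ucount[1:8])
        for i in range(n_edited):
            obs[i] += 1
        from kedit.editing import ReadEditingPattern

        return ReadEditingPattern("r", "x", "+", 1, 7, obs, t.site_ucount[1:8])

    def test_five_site_threshold_boundary(self):
        assert is_edited(self.make(5)) is True
        assert is_edited(self.make(4)) is False

    def test_pre_edited_read_not_edited(self):
        assert is_edited(self.make(0)) is False


class TestCoverage:
    def test_depth_sums_equal_covered_bases(self, small_sim):
        cfg, truth, reads = small_sim
        name = next(iter(truth.edited_mrnas))
        t = truth.site_table(name)
        pats = [
            p
            for rid, seq, _ in reads["mrna"]
            if truth.read_origins[rid].get("locus") == name
            for p in [align_read_tstripped(rid, seq, t)]
            if p is not None
        ]
        cov = coverage_profile({name: pats}, {name: t})
        # a read spanning interior sites [first, last] covers the backbone
        # bases first-1 .. last inclusive
        total_covered = sum(p.last_site - p.first_site + 2 for p in pats)
        assert int(cov[name]["depth"].sum()) == total_covered
        assert cov[name]["mapped_reads"] == len(pats)


class TestReconstruct:
    def test_majority_state_wins_in_toy_conflict(self):
        t = build_site_table("x", "ACGACGACG")
        from kedit.editing import ReadEditingPattern

        ref = t.site_ucount
        pats = []
        for i in range(7):  # majority: one inserted U at site 3
            obs = list(ref[1:8])
            obs[2] = 1
            pats.append(ReadEditingPattern(f"a{i}", "x", "+", 1, 7, obs, ref[1:8]))
        for i in range(3):  # minority: three Us
            obs = list(ref[1:8])
            obs[2] = 3
            pats.append(ReadEditingPattern(f"b{i}", "x", "+", 1, 7, obs, ref[1:8]))
        orf = reconstruct_orf(pats, t, expected_protein_len=1, min_orf_fraction=0)
        assert orf.consensus_ucount[3] == 1

    def test_no_reads_is_an_error(self):
        with pytest.raises(ValueError):
            reconstruct_orf([], build_site_table("x", "ACGT"))


class TestTranslate:
    @pytest.mark.parametrize(
        "seq,prot",
        [("TGA", "W"), ("TAA", "*"), ("ATGTGATAA", "MW*"), ("ATGNNN", "MX")],
    )
    def test_code4(self, seq, prot):
        assert translate_code4(seq) == prot

    def test_code4_against_codon_map_oracle(self, rng):
        # independent oracle: the standard code with the single UGA->Trp swap
        from Bio.Data.CodonTable import unambiguous_dna_by_id

        std = unambiguous_dna_by_id[1]
        for _ in range(30):
            codon = "".join(rng.choice(list("ACGT"), 3))
            got = translate_code4(codon)
            if codon == "TGA":
                assert got == "W"
            elif codon in std.stop_codons:
                assert got == "*"
            else:
                assert got == std.forward_table[codon]

    def test_longest_orf_finds_terminated_frame(self):
        assert find_longest_orf("ATGTGATAA") == (0, 9, "MW")
        # unterminated frame yields nothing
        assert find_longest_orf("ATGGCAGCA")[2] == ""
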