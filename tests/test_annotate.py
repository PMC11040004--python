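"""Minicircle annotation: motif scan, circularisation, inverted repeats,
class deduplication and re-orientation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kedit.annotate import (
    IUPAC,
    AmbiguousCircularizationError,
    CircularSeq,
    MotifHit,
    circle_identity,
    circularize_contig,
    classify_minicircles,
    find_inverted_repeats,
    reorient_minicircle,
    rescore_inverted_repeat,
    revcomp,
    scan_motif,
)

CSB3 = "GGGGTTGGTGTG"
CSB1 = "YYRYRYRRRRYYYYRYRYRR"


def naive_scan(seq, pattern, circular):
    """Per-position IUPAC set check (the oracle)."""
    s = seq + (seq[: len(pattern) - 1] if circular else "")
    sets = [IUPAC[c] for c in pattern.upper()]
    return [
        i
        for i in range(len(seq) if circular else len(seq) - len(pattern) + 1)
        if i + len(pattern) <= len(s)
        and all(s[i + j] in sets[j] for j in range(len(pattern)))
    ]


class TestScanMotif:
    def test_exact_hit_at_origin(self):
        seq = CircularSeq("x", "GGGGTTGGTGTGAA", circular=False)
        hits = scan_motif(seq, CSB3.lower(), "CSB3")
        assert [(h.start, h.strand) for h in hits] == [(0, "+")]

    def test_wrapped_hit_on_circular_sequence(self):
        rot = CSB3[5:] + "AA" + CSB3[:5]  # 12-mer spans the origin
        hits = scan_motif(CircularSeq("x", rot, True), CSB3, "CSB3")
        assert [h.start for h in hits] == [9]
        linear = scan_motif(CircularSeq("x", rot, False), CSB3, "CSB3")
        assert linear == []

    def test_invalid_symbol_named(self):
        with pytest.raises(ValueError, match="'J'"):
            scan_motif(CircularSeq("x", "ACGT", False), "AJT")

    def test_minus_strand_hit_reported_on_forward_coordinates(self):
        seq = "AAAA" + revcomp(CSB3) + "CCCC"
        hits = scan_motif(CircularSeq("x", seq, False), CSB3, "CSB3", both_strands=True)
        assert [(h.start, h.strand) for h in hits] == [(4, "-")]

    @given(st.integers(0, 2**31 - 1))
    def test_degenerate_pattern_matches_iupac_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # random flank with an embedded y/r expansion half the time
        seq = "".join(rng.choice(list("ACGT"), 60))
        if rng.random() < 0.5:
            exp = "".join(
                str(rng.choice(list(IUPAC[c]))) for c in CSB1
            )
            pos = int(rng.integers(0, 40))
            seq = seq[:pos] + exp + seq[pos + len(exp):]
        circular = bool(rng.random() < 0.5)
        c = CircularSeq("x", seq, circular)
        got = [h.start for h in scan_motif(c, CSB1)]
        assert got == naive_scan(seq, CSB1, circular)


class TestCircularize:
    def test_terminal_repeat_collapsed(self, rng):
        core = "".join(rng.choice(list("ACGT"), 60))
        rep = "ACGTACGT"
        contig = rep + core + rep
        out = circularize_contig(contig, k_min=8)
        assert out.circular and len(out) == len(contig) - 8

    def test_no_repeat_returns_flagged_linear(self, rng):
        s = "".join(rng.choice(list("ACGT"), 50))
        out = circularize_contig("AC" + s + "GT", k_min=8)
        assert not out.circular and len(out.seq) == 54

    def test_homopolymer_is_ambiguous(self):
        with pytest.raises(AmbiguousCircularizationError):
            circularize_contig("AAAAAA", k_min=2)


class TestInvertedRepeats:
    def plant(self, rng, arm_len, sep, mutate=0, mut_pos=None):
        arm = "".join(rng.choice(list("ACGT"), arm_len))
        spacer = "".join(rng.choice(list("ACGT"), sep))
        arm2 = list(revcomp(arm))
        for k in range(mutate):
            i = mut_pos if mut_pos is not None else int(rng.integers(0, len(arm2)))
            arm2[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[arm2[i]]
        flank = lambda n: "".join(rng.choice(list("ACGT"), n))
        return flank(10) + arm + spacer + "".join(arm2) + flank(10)

    def test_threshold_boundary_10bp_vs_9bp(self, rng):
        # perfect 10 bp arms score 40 (reported); 9 bp score 36 (absent);
        # poly(A) context prevents chance extensions past the planted arms
        for arm_len, expected in [(10, True), (9, False)]:
            found = 0
            for _ in range(5):
                arm = "".join(rng.choice(list("ACGT"), arm_len))
                s = "A" * 10 + arm + "A" * 12 + revcomp(arm) + "A" * 10
                irs = find_inverted_repeats(s, threshold=40)
                found += any(ir.score >= 40 for ir in irs)
            assert found == (5 if expected else 0)

    def test_one_central_mismatch_12bp_arms_score_40(self, rng):
        # 11 matches and 1 interior mismatch: 11*4 - 4 = 40, at the
        # threshold (an end mismatch would trim to a pure shorter arm)
        hits = 0
        for _ in range(6):
            arm = "".join(rng.choice(list("ACGT"), 12))
            arm2 = list(revcomp(arm))
            arm2[6] = {"A": "C", "C": "A", "G": "T", "T": "G"}[arm2[6]]
            # poly(A) flanks cannot extend the alignment (A:A never pairs)
            s = "A" * 10 + arm + "A" * 15 + "".join(arm2) + "A" * 10
            irs = find_inverted_repeats(s, threshold=40)
            hits += any(ir.score == 40 and ir.mismatches == 1 for ir in irs)
        assert hits == 6

    def test_random_sequence_empty(self, rng):
        for _ in range(10):
            s = "".join(rng.choice(list("ACGT"), 30))
            assert find_inverted_repeats(s, threshold=40) == []

    def test_reported_score_reproduced_by_rescoring(self, rng):
        for _ in range(8):
            s = self.plant(rng, 14, 20, mutate=int(rng.integers(0, 2)))
            for ir in find_inverted_repeats(s, threshold=40):
                assert rescore_inverted_repeat(s, ir) == ir.score
                assert ir.arm2_start >= ir.arm1_end  # non-overlapping arms

    def test_ungapped_arm_oracle_one_sided(self, rng):
        """Every ungapped arm pair scoring >= threshold is found with at
        least that score."""
        for _ in range(6):
            s = self.plant(rng, 12, 14, mutate=int(rng.integers(0, 2)))
            # oracle: exhaustive ungapped arm enumeration
            best = 0
            n = len(s)
            for a1 in range(n):
                for L in range(4, 20):
                    if a1 + L > n:
                        break
                    arm1 = s[a1 : a1 + L]
                    rc = revcomp(arm1)
                    start = a1 + L
                    p = s.find(rc, start)
                    while p >= 0:
                        best = max(best, 4 * L)
                        p = s.find(rc, p + 1)
            irs = find_inverted_repeats(s, threshold=40)
            if best >= 40:
                assert irs and max(ir.score for ir in irs) >= best


class TestClassify:
    def test_rotation_and_strand_invariance(self, rng):
        s = "".join(rng.choice(list("ACGT"), 120))
        a = CircularSeq("a", s)
        b = CircularSeq("b", s[50:] + s[:50])
        c = CircularSeq("c", revcomp(s[30:] + s[:30]))
        classes = classify_minicircles([a, b, c], 0.97)
        assert len(classes) == 1 and sorted(sum(classes.values(), [])) == ["a", "b", "c"]

    def test_identity_threshold_boundary(self, rng):
        s = list("".join(rng.choice(list("ACGT"), 100)))
        for n_diffs, n_classes in [(3, 1), (4, 2)]:
            t = list(s)
            for i in range(n_diffs):
                pos = 50 + i  # clustered away from the anchor seeds
                t[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[t[pos]]
            classes = classify_minicircles(
                [CircularSeq("a", "".join(s)), CircularSeq("b", "".join(t))], 0.97
            )
            assert len(classes) == n_classes

    def test_partition_property(self, rng):
        circles = [
            CircularSeq(f"c{i}", "".join(rng.choice(list("ACGT"), 100)))
            for i in range(8)
        ]
        classes = classify_minicircles(circles, 0.97)
        members = sorted(sum(classes.values(), []))
        assert members == sorted(c.id for c in circles)


class TestReorient:
    def circle(self, rng, L=2000):
        return CircularSeq("m", "".join(rng.choice(list("ACGT"), L)))

    def test_forced_rotation(self, rng):
        c = self.circle(rng)
        hits = [MotifHit("CSB3", 500, 12, "+", CSB3)]
        out, offset, flipped = reorient_minicircle(c, hits, gene_start=700)
        assert offset == 500 and not flipped
        assert out.seq == c.seq[500:] + c.seq[:500]

    def test_nearest_csb_chosen(self, rng):
        c = self.circle(rng)
        hits = [MotifHit("CSB3", 100, 12, "+", CSB3), MotifHit("CSB3", 750, 12, "+", CSB3)]
        out, offset, _ = reorient_minicircle(c, hits, gene_start=900)
        assert offset == 750  # distance 150 beats 800

    def test_tie_breaks_to_lower_coordinate(self, rng):
        c = self.circle(rng)
        hits = [MotifHit("CSB3", 100, 12, "+", CSB3), MotifHit("CSB3", 500, 12, "+", CSB3)]
        out, offset, _ = reorient_minicircle(c, hits, gene_start=300)
        assert offset == 100

    def test_reorientation_is_idempotent(self, rng):
        c = self.circle(rng)
        hits = [MotifHit("CSB3", 500, 12, "+", CSB3)]
        once, off1, _ = reorient_minicircle(c, hits, gene_start=700)
        hits2 = [MotifHit("CSB3", 0, 12, "+", CSB3)]
        twice, off2, _ = reorient_minicircle(once, hits2, gene_start=200)
        assert off2 == 0 and twice.seq == once.seq

    def test_missing_annotation_raises(self, rng):
        with pytest.raises(ValueError):
            reorient_minicircle(self.circle(rng), [], gene_start=100)
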