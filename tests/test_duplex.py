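"""Duplex aligner: pair classification, thresholds, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kedit.duplex import (
    CANONICAL,
    GU,
    MM,
    RELAXED,
    WC,
    DuplexParams,
    GuideRNA,
    align_duplex,
    align_grna_set,
    classify_pair,
    render_duplex,
    rescore,
)

COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def revcomp_rna(s):
    return "".join(COMP[b] for b in reversed(s))


def naive_align(gseq, mseq, p):
    """Independent brute force: every ungapped antiparallel window, direct
    threshold checks, then the same greedy best-score non-redundancy prune."""
    g = gseq.upper().replace("T", "U")
    m = mseq.upper().replace("T", "U")
    sc_of = {WC: p.score_wc, GU: p.score_gu, MM: p.score_mm}
    wins = []
    for s in range(len(m)):
        for e in range(s + p.min_length, len(m) + 1):
            L = e - s
            for gs in range(0, len(g) - L + 1):
                ge = gs + L
                pairs = [classify_pair(m[s + k], g[ge - 1 - k]) for k in range(L)]
                if pairs.count(MM) > p.max_mismatch:
                    continue
                if pairs.count(GU) > p.max_gu:
                    continue
                score = sum(sc_of[c] for c in pairs)
                if score < p.min_score:
                    continue
                if any(c != WC for c in pairs[L - p.min_anchor :]):
                    continue
                if L < p.seed_length:
                    continue
                if (
                    max(
                        sum(sc_of[c] for c in pairs[i : i + p.seed_length])
                        for i in range(L - p.seed_length + 1)
                    )
                    < p.seed_score
                ):
                    continue
                wins.append(
                    (s, e, gs, ge, "".join(pairs), score, pairs.count(GU), pairs.count(MM))
                )
    kept = []
    for w in sorted(wins, key=lambda w: (-w[5], w[0], -(w[1] - w[0]))):
        if all(
            w[1] <= k[0] or w[0] >= k[1] or w[3] <= k[2] or w[2] >= k[3]
            for k in kept
        ):
            kept.append(w)
    return sorted(kept)


def as_tuples(alns):
    return sorted(
        (a.mrna_start, a.mrna_end, a.grna_start, a.grna_end, a.pair_string, a.score, a.n_gu, a.n_mm)
        for a in alns
    )


class TestClassifyPair:
    @pytest.mark.parametrize(
        "m,g,cls",
        [
            ("G", "C", WC), ("C", "G", WC), ("A", "U", WC), ("U", "A", WC),
            ("G", "U", GU), ("U", "G", GU),
            ("A", "G", MM), ("A", "A", MM), ("C", "U", MM), ("G", "G", MM),
        ],
    )
    def test_classes(self, m, g, cls):
        assert classify_pair(m, g) == cls

    def test_non_rna_base_rejected(self):
        with pytest.raises(ValueError, match="T"):
            classify_pair("T", "A")


class TestAlignDuplex:
    def test_perfect_complement_scores_two_per_pair(self, rng):
        m = "".join(rng.choice(list("ACGU"), 21))
        g = revcomp_rna(m)
        (aln,) = align_duplex(g, m, RELAXED)
        assert (aln.length, aln.score, aln.n_mm, aln.n_gu) == (21, 42, 0, 0)
        assert aln.pair_string == WC * 21

    def test_gu_cap_boundary(self):
        # 17 G:U pairs pass the relaxed cap, 18 fail; WC tail keeps the
        # score and anchor valid in both cases
        for n_gu, expect in [(17, 1), (18, 0)]:
            m = "G" * n_gu + "A" * 30
            g = revcomp_rna(m).replace("C", "U", n_gu)  # gRNA U opposite mRNA G
            alns = align_duplex(g, m, RELAXED)
            alns = [a for a in alns if a.n_gu == n_gu]
            assert len(alns) == expect

    def test_anchor_boundary(self, rng):
        # a wobble within the two mRNA-3'-terminal pairs breaks the anchor
        m = "".join(rng.choice(list("ACGU"), 30))
        g = list(revcomp_rna(m))
        alns_ok = align_duplex("".join(g), m, RELAXED)
        assert alns_ok and alns_ok[0].mrna_end == 30
        # make the final mRNA pair a wobble: mRNA 3' base pairs gRNA 5' base
        m2 = m[:-1] + ("G" if g[0] == "U" else "U" if g[0] == "G" else "C")
        alns = align_duplex("".join(g), m2, RELAXED)
        assert all(a.pair_string[-RELAXED.min_anchor :] == WC * RELAXED.min_anchor for a in alns)

    def test_short_mrna_yields_empty(self):
        assert align_duplex("ACGU" * 10, "ACGU" * 4, RELAXED) == []

    @pytest.mark.parametrize("preset", [RELAXED, CANONICAL])
    def test_oracle_equivalence_random_and_planted(self, preset, rng):
        mismatches = 0
        for case in range(60):
            m = "".join(rng.choice(list("ACGU"), int(rng.integers(40, 110))))
            if case % 2 == 0:
                a = int(rng.integers(0, len(m) - 32))
                g = list(revcomp_rna(m[a : a + 30]))
                for _ in range(int(rng.integers(0, 3))):
                    i = int(rng.integers(0, len(g)))
                    g[i] = str(rng.choice(list("ACGU")))
                g = "".join(g)
            else:
                g = "".join(rng.choice(list("ACGU"), int(rng.integers(25, 36))))
            if as_tuples(align_duplex(g, m, preset)) != naive_align(g, m, preset):
                mismatches += 1
        assert mismatches == 0

    def test_score_additivity(self, rng):
        for _ in range(20):
            m = "".join(rng.choice(list("ACGU"), 80))
            a = int(rng.integers(0, 50))
            g = revcomp_rna(m[a : a + 28])
            for aln in align_duplex(g, m, RELAXED):
                assert aln.score == rescore(aln, RELAXED)
                assert aln.n_gu == aln.pair_string.count(GU)
                assert aln.n_mm == aln.pair_string.count(MM)
                assert aln.length == len(aln.pair_string)

    def test_set_alignment_matches_per_grna_calls(self, rng):
        m = "".join(rng.choice(list("ACGU"), 150))
        grnas = []
        for i in range(4):
            a = int(rng.integers(0, 110))
            grnas.append(GuideRNA(f"g{i}", "src", "-", 0, 0, revcomp_rna(m[a : a + 30])))
        single = []
        for g in grnas:
            single.extend(align_duplex(g, m, RELAXED))
        batched = align_grna_set(grnas, m, RELAXED)
        key = lambda a: (a.grna_id, a.mrna_start, a.mrna_end, a.score)
        assert sorted(map(key, batched)) == sorted(map(key, single))


class TestRender:
    def test_all_wc_pair_line(self):
        m = "ACGUACGUACGUACGUACGUA"
        g = revcomp_rna(m)
        (aln,) = align_duplex(g, m, RELAXED)
        block = render_duplex(aln, m, g)
        lines = block.splitlines()
        assert lines[1] == WC * 21
        assert lines[0] == m
        assert lines[2] == g[::-1]  # gRNA printed 3'->5'

    def test_pair_line_matches_classification(self, rng):
        m = "".join(rng.choice(list("ACGU"), 40))
        g = list(revcomp_rna(m))
        g[10] = "A" if g[10] != "A" else "C"
        alns = align_duplex("".join(g), m, RELAXED)
        for aln in alns:
            lines = render_duplex(aln, m, "".join(g)).splitlines()
            for col, cls in enumerate(aln.pair_string):
                mb = lines[0][col].upper()
                gb = lines[2][col]
                assert classify_pair(mb, gb) == cls

    def test_inserted_us_lowercased(self):
        m = "ACGUUACGUACGUACGUACGUACG"
        g = revcomp_rna(m)
        (aln,) = align_duplex(g, m, RELAXED)
        block = render_duplex(aln, m, g, inserted={3, 4})
        assert block.splitlines()[0][3:5] == "uu"
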