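"""Synthetic-kDNA generator: planted structure, determinism, read libraries."""

import filecmp
from pathlib import Path

import numpy as np
import pytest

from kedit.editing import align_read_tstripped
from kedit.simulate import (
    InfeasibleTilingError,
    SimConfig,
    _tile_domain,
    simulate_kdna,
    simulate_reads,
)
from tests.conftest import SMALL


class TestStructure:
    def test_default_counts_match_study_conditions(self, rng):
        cfg = SimConfig(seed=5)
        truth = simulate_kdna(cfg)
        assert len(truth.minicircles) == 41
        assert sum(len(m.genes) for m in truth.minicircles) == 42
        sizes = sorted(len(m.seq) for m in truth.minicircles)
        assert sizes[0] == 601
        assert all(1920 <= s <= 2019 for s in sizes[1:])
        assert sum(1 for g in truth.grnas.values() if g.source == "maxicircle") == 3
        assert max(len(m.genes) for m in truth.minicircles) == 2

    def test_no_editing_limit(self):
        cfg = SimConfig(seed=3, edited_fraction_of_sites=0.0, **{
            k: v for k, v in SMALL.items() if k != "coverage"
        })
        truth = simulate_kdna(cfg)
        for name, edited in truth.edited_mrnas.items():
            assert edited == truth.pre_edited[name]

    def test_infeasible_tiling_raises(self):
        with pytest.raises(InfeasibleTilingError):
            _tile_domain(0, 1000, 3, (40, 50), 4)
        with pytest.raises(InfeasibleTilingError):
            SimConfig(seed=0, n_minicircles=10)  # 42 gRNAs cannot fit

    def test_planted_grnas_are_perfect_complements(self, small_sim):
        cfg, truth, _ = small_sim
        from kedit.duplex import classify_pair, WC

        for gid, (name, a, b) in truth.grna_targets.items():
            g = truth.grnas[gid].seq
            window = truth.edited_mrnas[name][a:b].replace("T", "U")
            assert len(g) == b - a
            assert all(
                classify_pair(window[k], g[len(g) - 1 - k]) == WC
                for k in range(len(g))
            )

    def test_minicircle_architecture(self, small_sim):
        cfg, truth, _ = small_sim
        for mc in truth.minicircles:
            # two head-to-tail conserved regions with CSB1 and CSB3 each
            assert len(mc.csb1) == 2 and len(mc.csb3) == 2
            for p in mc.csb1:
                assert mc.seq[p : p + len(cfg.csb1)] == cfg.csb1
            for p in mc.csb3:
                assert mc.seq[p : p + len(cfg.csb3)] == cfg.csb3
            for g in mc.genes:
                assert 0 <= g.start < g.end <= len(mc.seq)
                assert g.strand == "-"


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(seed=9, **SMALL)
        for d in ("a", "b"):
            truth = simulate_kdna(cfg, tmp_path / d)
            simulate_reads(truth, cfg, tmp_path / d)
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files
        for f in files:
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_different_seeds_differ(self):
        t1 = simulate_kdna(SimConfig(seed=1, **SMALL))
        t2 = simulate_kdna(SimConfig(seed=2, **SMALL))
        assert t1.maxicircle != t2.maxicircle


class TestReads:
    def test_coverage_zero_yields_empty_valid_libraries(self):
        cfg = SimConfig(
            seed=4,
            coverage=0.0,
            kdna_coverage=0.0,
            smallrna_reads_per_grna=0,
            **{k: v for k, v in SMALL.items() if k not in ("coverage", "smallrna_reads_per_grna")},
        )
        truth = simulate_kdna(cfg)
        reads = simulate_reads(truth, cfg)
        assert all(v == [] for v in reads.values())

    def test_mean_depth_matches_requested_coverage(self, small_sim):
        cfg, truth, reads = small_sim
        name = next(iter(truth.gene_mrnas))
        tlen = len(truth.gene_mrnas[name])
        bases = sum(
            len(seq)
            for rid, seq, _ in reads["mrna"]
            if truth.read_origins[rid]["locus"] == name
        )
        depth = bases / tlen
        # n reads is ceil(cov*len/rl); terminal fragments are shorter
        assert 0.7 * cfg.coverage < depth < 1.25 * cfg.coverage

    def test_unedited_gene_reads_carry_no_edits_at_zero_error(self, small_sim):
        cfg, truth, reads = small_sim
        assert cfg.error_rate == 0.0
        name = next(iter(truth.gene_mrnas))
        table = truth.site_table(name)
        n = 0
        for rid, seq, _ in reads["mrna"]:
            if truth.read_origins[rid]["locus"] != name:
                continue
            p = align_read_tstripped(rid, seq, table)
            if p is not None:
                assert p.n_edited_sites == 0
                n += 1
        assert n > 10

    def test_fully_edited_stage_reads_match_edited_mrna(self):
        cfg = SimConfig(
            seed=8,
            editing_stage_distribution=((1.0, 1.0),),
            **SMALL,
        )
        truth = simulate_kdna(cfg)
        reads = simulate_reads(truth, cfg)
        name = next(iter(truth.edited_mrnas))
        table = truth.site_table(name)
        e = truth.edited_ucounts[name]
        n = 0
        for rid, seq, _ in reads["mrna"]:
            if truth.read_origins[rid]["locus"] != name:
                continue
            p = align_read_tstripped(rid, seq, table)
            if p is None:
                continue
            assert p.obs_ucount == e[p.first_site : p.last_site + 1]
            n += 1
        assert n > 10

    def test_degenerate_tail_and_no_adapter_reads_equal_grna(self):
        cfg = SimConfig(
            seed=8,
            tail_len_distribution=((0, 1.0),),
            adapter_seq="",
            **SMALL,
        )
        truth = simulate_kdna(cfg)
        reads = simulate_reads(truth, cfg)
        by_id = {rid: seq for rid, seq, _ in reads["smallrna_r1"]}
        for rid, origin in truth.read_origins.items():
            if "grna" not in origin:
                continue
            g = truth.grnas[origin["grna"]].seq.replace("U", "T")
            got = by_id[rid]
            assert got[: min(len(g), len(got))] == g[: min(len(g), len(got))]

    def test_grna_reads_strip_and_merge_back_to_planted_sequence(self, small_sim):
        cfg, truth, reads = small_sim
        from kedit.discovery import preprocess_small_reads, strip_tails

        inserts = dict(
            preprocess_small_reads(reads["smallrna_r1"], reads["smallrna_r2"], cfg.adapter_seq)
        )
        n = 0
        for rid, origin in truth.read_origins.items():
            if "grna" not in origin or rid not in inserts:
                continue
            g = truth.grnas[origin["grna"]].seq.replace("U", "T")
            got = strip_tails(inserts[rid])
            # tail stripping cannot distinguish a genuine gRNA-terminal T/A
            # run from the added tail, so the result is a near-full prefix
            assert g.startswith(got) and len(got) >= len(g) - 4
            n += 1
        assert n > 50
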