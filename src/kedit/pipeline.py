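"""End-to-end orchestration: simulate -> annotate -> call gRNAs -> map/edit ->
reconstruct -> cascade -> attribute, with a JSON run manifest.

The pipeline operates in memory on a planted ground truth (or on sequences
loaded from FASTA/FASTQ via the CLI), writes per-stage outputs under the run
directory when one is given, and records every stage's parameters as a
stable hash so that re-running an identical configuration provably reproduces
the same analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from .annotate import (
    CircularSeq,
    classify_minicircles,
    find_inverted_repeats,
    reorient_minicircle,
    scan_motif,
)
from .cascade import build_cascade, cascade_coverage_stats, filter_alignments
from .discovery import (
    annotate_grna_genes,
    call_expressed_grnas,
    preprocess_small_reads,
)
from .duplex import CANONICAL, RELAXED, DuplexParams, GuideRNA, align_duplex
from .editing import (
    align_read_tstripped,
    coverage_profile,
    reconstruct_orf,
    tstrip,
)
from .noncognate import attribute_editing, extract_hyperedited_reads
from .simulate import GroundTruth, SimConfig, simulate_kdna, simulate_reads


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    out_dir: Optional[str] = None
    sim: Dict = field(default_factory=dict)
    csb3: str = "GGGGTTGGTGTG"
    csb1: str = "YYRYRYRRRRYYYYRYRYRR"
    gram: Optional[str] = None
    discovery_preset: str = "canonical"
    attribution_preset: str = "relaxed"
    identity_threshold: float = 0.97
    min_edited_sites: int = 5
    min_indels: int = 10
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def duplex_params(self, preset: str) -> DuplexParams:
        if preset == "canonical":
            return CANONICAL
        if preset == "relaxed":
            return RELAXED
        raise ValueError(f"unknown preset: {preset}")


def _params_hash(obj) -> str:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def map_reads_to_tables(reads, tables, max_backbone_mm: int = 1):
    """Assign each read to its unique best cryptogene placement.

    Reads with no placement, or tied best placements across loci, are left
    unassigned.  Returns ({locus: [patterns]}, {read id: oriented sequence},
    n_unassigned).
    """
    patterns = defaultdict(list)
    oriented = {}
    unassigned = 0
    from .annotate import revcomp

    for rid, seq, _q in reads:
        best, tie = None, False
        for name, table in tables.items():
            p = align_read_tstripped(rid, seq, table, max_backbone_mm)
            if p is not None:
                if best is None or p.n_backbone_mm < best.n_backbone_mm:
                    best, tie = p, False
                elif p.n_backbone_mm == best.n_backbone_mm:
                    tie = True
        if best is None or tie:
            unassigned += 1
        else:
            patterns[best.cryptogene_id].append(best)
            oriented[rid] = seq if best.strand == "+" else revcomp(seq)
    return patterns, oriented, unassigned


def edited_domain_bounds(table, consensus_ucount) -> Optional[Tuple[int, int]]:
    """Bounds of the edited region on the edited sequence (half-open)."""
    pos = 0
    lo = hi = None
    for i in range(table.n_sites):
        u = consensus_ucount[i]
        if u != table.site_ucount[i]:
            if lo is None:
                lo = pos
            hi = pos + u + 1
        pos += u
        if i < len(table.backbone):
            pos += 1
    if lo is None:
        return None
    return lo, min(hi, pos)


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the full simulated-kDNA analysis; returns the run manifest.

    Stage order: simulate, annotate, call_grnas, map_edit, reconstruct,
    cascade, attribute.  A stage failure halts the run; the manifest then
    carries the failing stage and the stages already completed.
    """
    # configuration errors surface before any stage runs
    config.duplex_params(config.discovery_preset)
    config.duplex_params(config.attribution_preset)
    sim_check = SimConfig(seed=config.seed, **config.sim)

    manifest = {"stages": [], "seed": config.seed}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    state: Dict = {}

    def stage(name, params, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:  # halt with stage context, keep partials
            manifest["stages"].append(
                {"name": name, "status": "failed", "error": str(exc)}
            )
            if out_dir:
                (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise StageFailure(name, exc) from exc
        manifest["stages"].append(
            {
                "name": name,
                "status": "ok",
                "params_hash": _params_hash(params),
                "seconds": round(time.time() - t0, 3),
            }
        )
        return result

    # 1 -- simulate
    sim_cfg = SimConfig(seed=config.seed, **config.sim)
    truth = stage("simulate", sim_cfg, lambda: simulate_kdna(sim_cfg, out_dir))
    reads = stage(
        "simulate",
        sim_cfg,
        lambda: simulate_reads(truth, sim_cfg, out_dir),
    )
    manifest["stages"].pop()  # the two simulate calls are one logical stage
    state["truth"], state["reads"] = truth, reads

    circles = [CircularSeq(m.id, m.seq) for m in truth.minicircles]
    maxi = CircularSeq("maxicircle", truth.maxicircle, circular=True)

    # 2 -- structural annotation of minicircles
    def do_annotate():
        motifs = {}
        irs = {}
        gram = config.gram or truth.config.gram
        for c in circles:
            motifs[c.id] = {
                "CSB3": scan_motif(c, config.csb3, "CSB3"),
                "CSB1": scan_motif(c, config.csb1, "CSB1"),
                "GRAM": scan_motif(c, gram, "GRAM"),
            }
            irs[c.id] = find_inverted_repeats(c)
        classes = classify_minicircles(circles, config.identity_threshold)
        return {"motifs": motifs, "inverted_repeats": irs, "classes": classes}

    ann = stage(
        "annotate",
        {"csb3": config.csb3, "csb1": config.csb1, "identity": config.identity_threshold},
        do_annotate,
    )
    state["annotation"] = ann

    # 3 -- gRNA discovery: alignment-based plus expression-based refinement
    params = config.duplex_params(config.discovery_preset)
    locus_regions = {
        "maxicircle": [(l.start, l.end) for l in truth.loci if l.kind != "grna"]
    }

    def do_call_grnas():
        aln_genes, empty = annotate_grna_genes(
            circles, maxi, truth.edited_mrnas, params, exclude_regions=locus_regions
        )
        inserts = preprocess_small_reads(
            reads["smallrna_r1"], reads["smallrna_r2"], sim_cfg.adapter_seq
        )
        expr_genes, clusters = call_expressed_grnas(
            inserts, circles, maxi, identity=config.identity_threshold
        )
        # expression-refined boundaries win over alignment-derived ones
        genes = {(g.source_id, g.start, g.end, g.strand): g for g in expr_genes}
        return {
            "alignment_genes": aln_genes,
            "expression_genes": expr_genes,
            "genes": list(genes.values()),
            "clusters": clusters,
            "circles_without_alignment": empty,
        }

    disc = stage("call_grnas", dataclasses.asdict(params), do_call_grnas)
    state["discovery"] = disc

    # 4 -- T-stripped read mapping
    tables = {
        l.name: truth.site_table(l.name) for l in truth.loci if l.kind != "grna"
    }

    def do_map():
        patterns, oriented, unassigned = map_reads_to_tables(reads["mrna"], tables)
        cov = coverage_profile(patterns, tables, config.min_edited_sites)
        return {"patterns": patterns, "oriented": oriented, "unassigned": unassigned, "coverage": cov}

    mapped = stage("map_edit", {"max_backbone_mm": 1}, do_map)
    state["mapping"] = mapped

    # 5 -- edited ORF reconstruction
    def do_reconstruct():
        orfs = {}
        for name, table in tables.items():
            pats = mapped["patterns"].get(name, [])
            if not pats or truth.kind_of(name) == "unedited":
                continue
            orfs[name] = reconstruct_orf(
                pats, table, expected_protein_len=truth.expected_protein_len.get(name)
            )
        return orfs

    orfs = stage("reconstruct", {"min_orf_fraction": 0.85}, do_reconstruct)
    state["orfs"] = orfs

    # 6 -- cascade reconstruction for pan-edited mRNAs
    def do_cascade():
        genes = disc["genes"]
        grna_objs: List[GuideRNA] = []
        boundaries = {}
        sources = {c.id: c.seq for c in circles}
        sources["maxicircle"] = maxi.seq
        from .annotate import revcomp

        for g in genes:
            seg = sources[g.source_id][g.start : g.end]
            seq = (revcomp(seg) if g.strand == "-" else seg).replace("T", "U")
            gid = f"{g.source_id}:{g.start}-{g.end}({g.strand})"
            grna_objs.append(
                GuideRNA(gid, g.source_id, g.strand, g.start, g.end, seq)
            )
            boundaries[gid] = (g.start, g.end)
        cascades = {}
        for name, orf in orfs.items():
            if orf.status != "ok":
                continue
            mrna = orf.edited_seq
            from .duplex import align_grna_set

            alns = align_grna_set(grna_objs, mrna, params, mrna_id=name)
            filt = filter_alignments(
                alns, boundaries, {g.id: g for g in grna_objs}
            )
            if not filt:
                continue
            domain = edited_domain_bounds(tables[name], orf.consensus_ucount)
            cmap = build_cascade(filt, name, domain)
            stats = cascade_coverage_stats(cmap)
            cascades[name] = {"map": cmap, "stats": stats, "alignments": filt}
        return {"cascades": cascades, "grnas": grna_objs}

    casc = stage("cascade", {"preset": config.discovery_preset}, do_cascade)
    state["cascade"] = casc

    # 7 -- non-cognate attribution on hyper-edited reads
    rel = config.duplex_params(config.attribution_preset)

    def do_attribute():
        results = {}
        for name, table in tables.items():
            if truth.kind_of(name) != "stochastic":
                continue
            pats = mapped["patterns"].get(name, [])
            hyper = extract_hyperedited_reads(pats, config.min_indels)
            pat_by_id = {p.read_id: p for p in hyper}
            rds = [
                (p.read_id, mapped["oriented"][p.read_id]) for p in hyper
            ]
            results[name] = attribute_editing(
                rds, table, pat_by_id, casc["grnas"], rel
            )
        return results

    attr = stage("attribute", dataclasses.asdict(rel), do_attribute)
    state["attribution"] = attr

    manifest["params_hash"] = _params_hash(
        {
            "sim": dataclasses.asdict(sim_cfg),
            "discovery": dataclasses.asdict(params),
            "attribution": dataclasses.asdict(rel),
            "identity": config.identity_threshold,
        }
    )
    if out_dir:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    state["manifest"] = manifest
    return state
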