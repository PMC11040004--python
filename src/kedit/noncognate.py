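"""Attribution of editing events to non-cognate gRNA guiding.

Transcripts whose own gRNAs are absent can still accumulate U-indels through
transient, non-cognate pairing with gRNAs of other transcripts.  This module
extracts heavily edited reads (>= 10 U insertions plus deletions), aligns the
complete gRNA set against each read under relaxed duplex thresholds, and asks
per edited site whether some passing alignment both spans the site (with its
flanking backbone bases) and pairs every U of the site without a mismatch --
i.e. the gRNA's guiding nucleotides (A or G opposite U) prescribe exactly the
observed U count.  It also compares alignment-feature distributions (length,
G:U pairs, mismatches) between cognate and non-cognate alignment groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .coding import rank_sum_test
from .duplex import MM, RELAXED, DuplexParams, GuideRNA, align_grna_set
from .editing import EditingSiteTable, ReadEditingPattern


@dataclass
class AttributionResult:
    cryptogene_id: str
    n_reads: int
    n_events_total: int
    n_events_explained: int
    per_alignment_features: List[Tuple[int, int, int]]  # (length, n_gu, n_mm)

    @property
    def pct_explained(self) -> float:
        if self.n_events_total == 0:
            return 0.0
        return 100.0 * self.n_events_explained / self.n_events_total


def extract_hyperedited_reads(
    patterns: Sequence[ReadEditingPattern], min_indels: int = 10
) -> List[ReadEditingPattern]:
    """Reads carrying at least ``min_indels`` U insertions + deletions."""
    return [p for p in patterns if p.n_insertions + p.n_deletions >= min_indels]


def _read_site_layout(read_seq: str, pattern: ReadEditingPattern):
    """Map each interior site of an aligned read to its U-run coordinates.

    Returns {site: (run_start, run_end, flank5, flank3)} in read coordinates,
    where flank5/flank3 are the backbone base positions bounding the run.
    Works on the read in its mapped orientation.
    """
    backbone_pos = [i for i, b in enumerate(read_seq.upper()) if b not in "TU"]
    layout = {}
    for k in range(1, len(backbone_pos)):
        site = pattern.first_site + (k - 1)
        flank5 = backbone_pos[k - 1]
        flank3 = backbone_pos[k]
        layout[site] = (flank5 + 1, flank3, flank5, flank3)
    return layout


def attribute_editing(
    reads: Sequence[Tuple[str, str]],
    table: EditingSiteTable,
    patterns: Dict[str, ReadEditingPattern],
    grnas: Sequence[GuideRNA],
    params: DuplexParams = RELAXED,
) -> AttributionResult:
    """Attribute edited sites of hyper-edited reads to gRNA guiding.

    ``reads`` are (id, sequence) pairs in mapped (+) orientation; ``patterns``
    their T-stripped alignments to ``table``.  A site is explained when at
    least one passing gRNA:read duplex covers its U run together with both
    flanking backbone bases, with no mismatch at any position of the run
    (existential semantics over alignments).
    """
    total = explained = 0
    n_reads = 0
    features: List[Tuple[int, int, int]] = []
    for rid, seq in reads:
        pat = patterns.get(rid)
        if pat is None:
            continue
        n_reads += 1
        layout = _read_site_layout(seq, pat)
        edited = pat.edited_sites
        if not edited:
            continue
        alns = align_grna_set(grnas, seq, params, mrna_id=rid)
        features.extend((a.length, a.n_gu, a.n_mm) for a in alns)
        for site in edited:
            total += 1
            run_lo, run_hi, f5, f3 = layout[site]
            for a in alns:
                if a.mrna_start <= f5 and a.mrna_end > f3:
                    pairs = a.pair_string[f5 - a.mrna_start : f3 - a.mrna_start + 1]
                    if MM not in pairs:
                        explained += 1
                        break
    return AttributionResult(
        cryptogene_id=table.cryptogene_id,
        n_reads=n_reads,
        n_events_total=total,
        n_events_explained=explained,
        per_alignment_features=features,
    )


def compare_alignment_features(
    group_a: Sequence[Tuple[int, int, int]],
    group_b: Sequence[Tuple[int, int, int]],
) -> Dict[str, Dict[str, float]]:
    """Two-sided rank-sum comparison of (length, n_gu, n_mm) distributions."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    out = {}
    for idx, name in enumerate(("length", "n_gu", "n_mm")):
        a = [f[idx] for f in group_a]
        b = [f[idx] for f in group_b]
        out[name] = rank_sum_test(a, b)
    return out
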