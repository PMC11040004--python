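"""Editing-cascade reconstruction and coverage statistics.

Pan-edited transcripts are edited by an ordered succession of gRNAs acting
3'->5': each gRNA anchors on sequence created (or left intact) by its
predecessor, so the cascade order is recoverable from the 3'->5' tiling of
gRNA:mRNA alignments.  Alignments are first screened with three filters --
gene-boundary containment, no run of three or more adjacent mismatches, and
a mismatch/length ratio of at most 1/8 -- then chained greedily from the
3'-most alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .duplex import MM, DuplexAlignment, GuideRNA


@dataclass
class CascadeStep:
    grna_id: str
    mrna_start: int
    mrna_end: int
    overlap_with_predecessor: int  # nt; 0 means adjacent but not overlapping
    score: int


@dataclass
class CascadeMap:
    mrna_id: str
    steps: List[CascadeStep]
    gaps: List[Tuple[int, int]]  # uncovered [start, end); zero-length = adjacency
    redundancy_profile: np.ndarray
    domain: Tuple[int, int]

    @property
    def ordered_grnas(self) -> List[str]:
        return [s.grna_id for s in self.steps]


def filter_alignments(
    alns: Sequence[DuplexAlignment],
    gene_boundaries: Optional[Dict[str, Tuple[int, int]]] = None,
    grnas: Optional[Dict[str, GuideRNA]] = None,
    max_adjacent_mm: int = 3,
    max_mm_ratio: float = 1.0 / 8.0,
) -> List[DuplexAlignment]:
    """Apply the three cascade filters to gRNA:mRNA alignments.

    (i) alignments using source loci outside the refined gRNA gene
    boundaries are discarded (requires ``gene_boundaries`` keyed by gRNA id
    and ``grnas`` for the gene coordinates); (ii) alignments containing
    ``max_adjacent_mm`` (three) or more consecutive mismatches are
    discarded -- G:U pairs interrupt a mismatch run; (iii) alignments with
    mismatch/length ratio strictly above 1/8 are discarded (a ratio of
    exactly 1/8 is retained).  The filters commute.
    """
    out = []
    for aln in alns:
        if gene_boundaries is not None and aln.grna_id in gene_boundaries:
            lo, hi = gene_boundaries[aln.grna_id]
            g = grnas[aln.grna_id] if grnas else None
            if g is not None and g.gene_start >= 0:
                # positions of the used gRNA stretch on the source molecule
                if g.strand == "-":
                    used_lo = g.gene_end - aln.grna_end
                    used_hi = g.gene_end - aln.grna_start
                else:
                    used_lo = g.gene_start + aln.grna_start
                    used_hi = g.gene_start + aln.grna_end
                if used_lo < lo or used_hi > hi:
                    continue
        if max_adjacent_mm <= aln.length and MM * max_adjacent_mm in aln.pair_string:
            continue
        if aln.n_mm / aln.length > max_mm_ratio + 1e-12:
            continue
        out.append(aln)
    return out


def build_cascade(
    alns: Sequence[DuplexAlignment],
    mrna_id: str,
    domain: Optional[Tuple[int, int]] = None,
) -> CascadeMap:
    """Chain filtered alignments into a 3'->5' cascade.

    Starting from the alignment with the 3'-most end, each successor must
    begin 5' of the current frontier; among candidates the one reaching
    furthest 3'-ward (largest end) is chosen, ties broken by score.
    Overlaps with the predecessor are recorded as anchor overlaps; uncovered
    stretches (including zero-length "adjacent but not overlapping" joints)
    are recorded as gaps.  The redundancy profile counts covering
    alignments per position over all filtered alignments.
    """
    if not alns:
        raise ValueError("no alignments to chain")
    pool = list(alns)
    if domain is None:
        domain = (min(a.mrna_start for a in pool), max(a.mrna_end for a in pool))
    current = max(pool, key=lambda a: (a.mrna_end, a.score))
    steps = [CascadeStep(current.grna_id, current.mrna_start, current.mrna_end, -1, current.score)]
    used = {id(current)}
    gaps: List[Tuple[int, int]] = []
    frontier = current.mrna_start
    while True:
        cands = [a for a in pool if id(a) not in used and a.mrna_start < frontier]
        if not cands:
            break
        nxt = max(cands, key=lambda a: (a.mrna_end, a.score))
        if nxt.mrna_end > frontier:
            overlap = nxt.mrna_end - frontier
        else:
            # a zero-length gap records an "adjacent but not overlapping" joint
            gaps.append((nxt.mrna_end, frontier))
            overlap = 0
        steps.append(
            CascadeStep(nxt.grna_id, nxt.mrna_start, nxt.mrna_end, overlap, nxt.score)
        )
        used.add(id(nxt))
        frontier = nxt.mrna_start
    redundancy = np.zeros(domain[1] - domain[0], dtype=np.int32)
    for a in alns:
        lo = max(a.mrna_start, domain[0]) - domain[0]
        hi = min(a.mrna_end, domain[1]) - domain[0]
        if hi > lo:
            redundancy[lo:hi] += 1
    return CascadeMap(mrna_id, steps, gaps, redundancy, domain)


def cascade_coverage_stats(
    cmap: CascadeMap, all_grna_ids: Optional[Sequence[str]] = None
) -> Dict[str, object]:
    """Summarise a cascade: redundancy, gaps and unassigned gRNAs."""
    prof = cmap.redundancy_profile
    assigned = set(cmap.ordered_grnas)
    unassigned = (
        sorted(set(all_grna_ids) - assigned) if all_grna_ids is not None else []
    )
    real_gaps = [g for g in cmap.gaps if g[1] > g[0]]
    return {
        "mean_redundancy": float(prof.mean()) if len(prof) else 0.0,
        "max_redundancy": int(prof.max()) if len(prof) else 0,
        "n_gaps": len(real_gaps),
        "gap_total_length": int(sum(g[1] - g[0] for g in real_gaps)),
        "n_adjacent_joints": sum(1 for g in cmap.gaps if g[1] == g[0]),
        "n_steps": len(cmap.steps),
        "unassigned_grnas": unassigned,
        "n_unassigned": len(unassigned),
    }
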