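"""T-stripped alignment and U-indel editing analysis.

U-indel editing inserts and deletes uridines without touching the other three
bases, so a cryptogene and every editing intermediate of its transcript share
the same non-T "backbone".  Stripping Ts from both read and reference turns
editing-tolerant mapping into plain substring search, after which the per-site
U counts (number of Ts immediately 5' of each backbone base) carry the whole
editing signal.

Editing sites are indexed 0..n_backbone along the genomic 5'->3' axis; the
editing cascade progresses 3'->5', so site ``n`` (the terminal, 3'-most site)
is edited first.  Helpers expose the 3'->5' numbering used for reporting.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq

from .annotate import revcomp


@dataclass
class EditingSiteTable:
    """Backbone and reference U-counts of a cryptogene.

    ``site_ucount[i]`` is the number of Ts preceding backbone base ``i`` in
    the reference; the final entry counts trailing Ts (the terminal site).
    Reinserting the counts before each backbone base reconstructs the
    reference exactly.
    """

    cryptogene_id: str
    backbone: str
    site_ucount: List[int]
    site_coord_5p: List[int]

    @property
    def n_sites(self) -> int:
        return len(self.backbone) + 1

    def rebuild(self, ucounts: Optional[Sequence[int]] = None) -> str:
        """Sequence obtained by inserting ``ucounts`` Ts before each base."""
        u = self.site_ucount if ucounts is None else list(ucounts)
        if len(u) != self.n_sites:
            raise ValueError("ucount vector length must equal n_sites")
        parts = []
        for i, b in enumerate(self.backbone):
            parts.append("T" * u[i])
            parts.append(b)
        parts.append("T" * u[-1])
        return "".join(parts)


def tstrip(seq: str) -> Tuple[str, List[int]]:
    """Split a sequence into its non-T backbone and per-site T counts."""
    backbone = []
    counts = [0]
    for b in seq.upper():
        if b == "T" or b == "U":
            counts[-1] += 1
        else:
            backbone.append(b)
            counts.append(0)
    return "".join(backbone), counts


def build_site_table(cryptogene_id: str, seq: str) -> EditingSiteTable:
    """Decompose a cryptogene sequence into an :class:`EditingSiteTable`."""
    s = str(seq).upper()
    if not s:
        raise ValueError(f"{cryptogene_id}: empty sequence")
    backbone, counts = tstrip(s)
    if not backbone:
        raise ValueError(f"{cryptogene_id}: sequence contains only T")
    coords = []
    pos = 0
    for i, u in enumerate(counts[:-1]):
        pos += u
        coords.append(pos)
        pos += 1
    return EditingSiteTable(cryptogene_id, backbone, counts, coords)


@dataclass
class ReadEditingPattern:
    """Observed per-site U counts of one read against a cryptogene.

    ``first_site``/``last_site`` delimit (inclusive) the *interior* sites
    fully contained in the read; the two flanking partial sites are excluded
    from all edit statistics because read truncation censors their U runs.
    Sites are genomic (5'->3') indices; ``span_3p5p`` reports the same span
    in cascade (3'->5') numbering.
    """

    read_id: str
    cryptogene_id: str
    strand: str
    first_site: int
    last_site: int
    obs_ucount: List[int]  # counts for sites first_site..last_site
    ref_ucount: List[int]
    n_backbone_mm: int = 0

    @property
    def n_insertions(self) -> int:
        return sum(max(o - r, 0) for o, r in zip(self.obs_ucount, self.ref_ucount))

    @property
    def n_deletions(self) -> int:
        return sum(max(r - o, 0) for o, r in zip(self.obs_ucount, self.ref_ucount))

    @property
    def n_edited_sites(self) -> int:
        return sum(o != r for o, r in zip(self.obs_ucount, self.ref_ucount))

    @property
    def edited_sites(self) -> List[int]:
        return [
            self.first_site + i
            for i, (o, r) in enumerate(zip(self.obs_ucount, self.ref_ucount))
            if o != r
        ]

    def span_3p5p(self, n_sites: int) -> Tuple[int, int]:
        return (n_sites - 1 - self.last_site, n_sites - 1 - self.first_site)


def _find_backbone(
    read_bb: str, ref_bb: str, max_mm: int
) -> List[Tuple[int, int]]:
    """All (offset, mismatches) placements of read_bb in ref_bb with <= max_mm.

    Pigeonhole seeding: any placement with at most ``max_mm`` substitutions
    contains an exact occurrence of one of ``max_mm + 1`` read segments, so
    exact substring search (C speed) locates every candidate before a full
    verification.
    """
    k, n = len(read_bb), len(ref_bb)
    if k > n or k == 0:
        return []
    parts = max_mm + 1
    seg = k // parts
    if seg < 4:  # tiny reads: direct scan
        offsets = range(n - k + 1)
    else:
        cand = set()
        for p in range(parts):
            lo = p * seg
            piece = read_bb[lo : lo + seg] if p < parts - 1 else read_bb[lo:]
            start = 0
            while True:
                hit = ref_bb.find(piece, start)
                if hit < 0:
                    break
                off = hit - lo
                if 0 <= off <= n - k:
                    cand.add(off)
                start = hit + 1
        offsets = sorted(cand)
    out = []
    for off in offsets:
        window = ref_bb[off : off + k]
        mm = sum(a != b for a, b in zip(window, read_bb))
        if mm <= max_mm:
            out.append((off, mm))
    return out


def align_read_tstripped(
    read_id: str,
    read_seq: str,
    table: EditingSiteTable,
    max_backbone_mm: int = 1,
    min_read_len: int = 20,
    try_revcomp: bool = True,
) -> Optional[ReadEditingPattern]:
    """Place a read on a cryptogene by its T-stripped backbone.

    The read's backbone must occur in the reference backbone with at most
    ``max_backbone_mm`` substitutions, as a unique best hit (both strands are
    tried when ``try_revcomp``).  Reads shorter than ``min_read_len``, reads
    without a hit, and reads with tied best hits return ``None``.
    """
    seq = str(read_seq).upper().replace("U", "T")
    if len(seq) < min_read_len:
        return None
    cands = []
    for strand, s in (("+", seq), ("-", revcomp(seq))) if try_revcomp else (
        ("+", seq),
    ):
        bb, counts = tstrip(s)
        if len(bb) < 2:
            continue
        for off, mm in _find_backbone(bb, table.backbone, max_backbone_mm):
            cands.append((mm, strand, off, counts, len(bb)))
    if not cands:
        return None
    cands.sort(key=lambda c: c[0])
    if len(cands) > 1 and cands[0][0] == cands[1][0]:
        return None  # ambiguous placement
    mm, strand, off, counts, k = cands[0]
    # interior sites: between consecutive matched backbone bases
    first, last = off + 1, off + k - 1
    obs = counts[1:k]  # read site i+1 <-> reference site off+1+i
    ref = table.site_ucount[first : last + 1]
    return ReadEditingPattern(
        read_id=read_id,
        cryptogene_id=table.cryptogene_id,
        strand=strand,
        first_site=first,
        last_site=last,
        obs_ucount=list(obs),
        ref_ucount=list(ref),
        n_backbone_mm=mm,
    )


def is_edited(pattern: ReadEditingPattern, min_sites: int = 5) -> bool:
    """A read counts as edited when it differs at >= ``min_sites`` sites."""
    return pattern.n_edited_sites >= min_sites


def coverage_profile(
    patterns_by_gene: Dict[str, List[ReadEditingPattern]],
    tables: Dict[str, EditingSiteTable],
    min_sites: int = 5,
):
    """Per-gene mapped/edited read counts and per-backbone-base depth."""
    out = {}
    for gene, pats in patterns_by_gene.items():
        table = tables[gene]
        depth = np.zeros(len(table.backbone), dtype=np.int64)
        edited = 0
        for p in pats:
            depth[p.first_site - 1 : p.last_site + 1] += 1
            if is_edited(p, min_sites):
                edited += 1
        out[gene] = {
            "mapped_reads": len(pats),
            "edited_reads": edited,
            "depth": depth,
        }
    return out


@dataclass
class EditedORF:
    """Result of consensus edited-sequence and ORF reconstruction."""

    cryptogene_id: str
    edited_seq: str
    consensus_ucount: List[int]
    status: str  # "ok" or "failed"
    orf_start: int = -1
    orf_stop: int = -1
    protein: str = ""
    support: int = 0
    stop_codon: str = ""


_CODE4_STOPS = {"TAA", "TAG"}


def translate_code4(seq: str, frame: int = 0) -> str:
    """Translate DNA/RNA under NCBI table 4 (UGA -> Trp; UAA/UAG -> stop).

    Ambiguous or non-ACGTU bases translate to ``X``; stops render as ``*``.
    """
    s = str(seq).upper().replace("U", "T")[frame:]
    s = s[: len(s) - len(s) % 3]
    if not s:
        return ""
    out = []
    for i in range(0, len(s), 3):
        codon = s[i : i + 3]
        if set(codon) <= set("ACGT"):
            out.append(str(Seq(codon).translate(table=4)))
        else:
            out.append("X")
    return "".join(out)


def find_longest_orf(seq: str) -> Tuple[int, int, str]:
    """Longest reading frame terminated by UAA/UAG under code 4.

    Scans all three forward frames; an ORF is a maximal stop-free codon run
    that ends at a UAA or UAG stop codon.  Returns (orf_start, orf_end,
    protein) with nucleotide coordinates covering the codons and the stop;
    (-1, -1, "") if no terminated ORF exists.
    """
    s = str(seq).upper().replace("U", "T")
    best = (-1, -1, "")
    for frame in range(3):
        start = frame
        i = frame
        while i + 3 <= len(s):
            codon = s[i : i + 3]
            if codon in _CODE4_STOPS:
                if i > start:
                    prot = translate_code4(s[start:i])
                    if "X" not in prot and len(prot) > len(best[2]):
                        best = (start, i + 3, prot)
                start = i + 3
            i += 3
    return best


def reconstruct_orf(
    patterns: Sequence[ReadEditingPattern],
    table: EditingSiteTable,
    expected_protein_len: Optional[int] = None,
    min_orf_fraction: float = 0.85,
) -> EditedORF:
    """Consensus editing path and ORF call for one cryptogene.

    Builds a graph whose nodes are (site, observed U count) states and whose
    edges connect states co-observed at adjacent sites within a read,
    weighted by read support.  Starting from the majority state of the
    3'-most covered site, the path maximising the minimum edge support
    (bottleneck objective; ties by total support, then fewer edits) is
    selected, uncovered sites fall back to their reference counts, and the
    resulting sequence is scanned for a code-4 ORF terminated by UAA/UAG.
    The reconstruction fails when the best terminated ORF is shorter than
    ``min_orf_fraction`` of the expected protein length.
    """
    if not patterns:
        raise ValueError(f"{table.cryptogene_id}: no aligned reads")
    n = table.n_sites
    states: Dict[int, Counter] = defaultdict(Counter)
    edges: Dict[int, Counter] = defaultdict(Counter)  # site s: (u_s, u_{s+1})
    for p in patterns:
        for i, u in enumerate(p.obs_ucount):
            states[p.first_site + i][u] += 1
        for i in range(len(p.obs_ucount) - 1):
            edges[p.first_site + i][(p.obs_ucount[i], p.obs_ucount[i + 1])] += 1

    covered = sorted(states)
    smin, smax = covered[0], covered[-1]

    def majority(site: int) -> int:
        ref = table.site_ucount[site]
        return min(
            states[site].items(),
            key=lambda kv: (-kv[1], abs(kv[0] - ref), kv[0]),
        )[0]

    # dynamic programme 3' -> 5': value = (bottleneck, total support, -edits),
    # maximised lexicographically; seeded at the majority state of the
    # 3'-most covered site
    INF = float("inf")
    seed = majority(smax)
    value: Dict[int, Tuple] = {seed: (INF, 0, -(seed != table.site_ucount[smax]))}
    choice: Dict[int, Dict[int, int]] = {}  # site -> {u: successor u'}
    for s in range(smax - 1, smin - 1, -1):
        nxt_value = value
        value = {}
        choice[s] = {}
        for (u, nxt), w in edges[s].items():
            if nxt not in nxt_value:
                continue
            vb, vt, ve = nxt_value[nxt]
            cand = (min(vb, w), vt + w, ve - (u != table.site_ucount[s]))
            if u not in value or cand > value[u]:
                value[u] = cand
                choice[s][u] = nxt
        if not value:  # chain break: restart from the local majority state
            u = majority(s) if s in states else table.site_ucount[s]
            value = {u: (0, 0, 0)}
            choice[s][u] = None

    consensus = list(table.site_ucount)
    cur = max(value, key=lambda u: value[u])
    bottleneck = value[cur][0]
    consensus[smin] = cur
    for s in range(smin, smax):
        cur = choice[s].get(cur)
        if cur is None:
            cur = majority(s + 1) if s + 1 in states else table.site_ucount[s + 1]
        consensus[s + 1] = cur
    if bottleneck == INF:  # single-site coverage
        bottleneck = states[smax][seed]

    edited = table.rebuild(consensus)
    orf_start, orf_end, prot = find_longest_orf(edited)
    expected = expected_protein_len or (len(edited) // 3 - 1)
    status = "ok" if len(prot) >= min_orf_fraction * expected else "failed"
    return EditedORF(
        cryptogene_id=table.cryptogene_id,
        edited_seq=edited,
        consensus_ucount=consensus,
        status=status,
        orf_start=orf_start,
        orf_stop=orf_end,
        protein=prot,
        support=int(bottleneck or 0),
        stop_codon=edited[orf_end - 3 : orf_end] if orf_end > 0 else "",
    )
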