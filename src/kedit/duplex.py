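"""Antiparallel gRNA:mRNA duplex alignment.

Guide RNAs direct U-indel editing by base pairing with their target mRNA in
antiparallel orientation (gRNA 5' end opposite the mRNA 3' end).  Pairing uses
both Watson-Crick pairs and G:U wobbles; isolated mismatches are tolerated.
The aligner enumerates ungapped duplex windows between the two RNAs and keeps
those passing a set of thresholds: a nucleation seed window, minimum length and
total score, caps on G:U pairs and mismatches, and a run of contiguous
Watson-Crick pairs ("anchor") at the mRNA-3' end of the duplex -- the region a
gRNA must clamp onto before it can guide editing 5' of it.

Pair classes follow the standard rendering convention: ``|`` Watson-Crick,
``:`` G:U wobble, ``#`` any other apposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

WC = "|"
GU = ":"
MM = "#"

_BASES = "ACGU"
_CODE = {b: i for i, b in enumerate(_BASES)}

# pair-class lookup: 0 = WC, 1 = GU, 2 = MM (rows mRNA, cols gRNA);
# code 4 is an internal block separator that pairs nothing
_PAIR_CLASS = np.full((5, 5), 2, dtype=np.int8)
for _m, _g in [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]:
    _PAIR_CLASS[_CODE[_m], _CODE[_g]] = 0
for _m, _g in [("G", "U"), ("U", "G")]:
    _PAIR_CLASS[_CODE[_m], _CODE[_g]] = 1

_CLASS_CHAR = np.array([WC, GU, MM])


def classify_pair(mrna_base: str, grna_base: str) -> str:
    """Classify a single mRNA:gRNA base apposition.

    Returns ``"|"`` for Watson-Crick pairs (A:U, U:A, G:C, C:G), ``":"`` for
    G:U wobbles (G:U, U:G) and ``"#"`` for any other combination.  Bases must
    be RNA (``A``, ``C``, ``G``, ``U``).
    """
    try:
        m = _CODE[mrna_base.upper()]
        g = _CODE[grna_base.upper()]
    except KeyError as exc:
        raise ValueError(f"non-RNA base: {exc.args[0]!r}") from None
    return _CLASS_CHAR[_PAIR_CLASS[m, g]]


@dataclass(frozen=True)
class DuplexParams:
    """Thresholds and per-pair scores for duplex discovery.

    ``min_anchor`` counts contiguous Watson-Crick pairs required at the
    mRNA-3' end of the duplex (the gRNA 5' anchor region).
    """

    seed_score: int = 24
    seed_length: int = 16
    min_length: int = 25
    min_score: int = 35
    max_gu: int = 12
    max_mismatch: int = 2
    min_anchor: int = 4
    score_wc: int = 2
    score_gu: int = 1
    score_mm: int = -1

    def __post_init__(self):
        if self.min_anchor > self.min_length:
            raise ValueError("min_anchor must not exceed min_length")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


#: Default (strict) discovery preset used for gRNA gene annotation.
CANONICAL = DuplexParams()

#: Relaxed preset used when attributing editing in hyper-edited reads.
RELAXED = DuplexParams(
    seed_score=20,
    seed_length=16,
    min_length=21,
    min_score=25,
    max_gu=17,
    max_mismatch=4,
    min_anchor=2,
)

PRESETS = {"canonical": CANONICAL, "relaxed": RELAXED}


@dataclass
class DuplexAlignment:
    """One ungapped antiparallel duplex between a gRNA and an mRNA.

    Coordinates are 0-based half-open on the respective 5'->3' sequences.
    ``pair_string`` lists the pair class per mRNA position (ascending); the
    gRNA runs antiparallel, i.e. mRNA position ``mrna_start + k`` pairs with
    gRNA position ``grna_end - 1 - k``.
    """

    grna_id: str
    mrna_id: str
    mrna_start: int
    mrna_end: int
    grna_start: int
    grna_end: int
    pair_string: str
    score: int
    n_gu: int
    n_mm: int

    @property
    def length(self) -> int:
        return self.mrna_end - self.mrna_start


@dataclass
class GuideRNA:
    """An (expressed or predicted) guide RNA and its genomic source locus."""

    id: str
    source: str
    strand: str
    gene_start: int
    gene_end: int
    seq: str  # RNA sense, 5'->3'

    def __len__(self) -> int:
        return len(self.seq)


def _rna_codes(seq: str) -> np.ndarray:
    s = seq.upper().replace("T", "U")
    try:
        return np.array([_CODE[b] for b in s], dtype=np.int8)
    except KeyError:
        bad = sorted(set(s) - set(_BASES))
        raise ValueError(f"non-RNA base(s) in sequence: {bad}")


def align_duplex(
    grna,
    mrna,
    params: DuplexParams = CANONICAL,
    grna_id: str = "gRNA",
    mrna_id: str = "mRNA",
) -> List[DuplexAlignment]:
    """Find antiparallel gRNA:mRNA duplexes passing ``params``.

    ``grna`` may be a :class:`GuideRNA` or a plain RNA-sense string (``T`` is
    accepted and read as ``U``).  All threshold-passing ungapped windows are
    enumerated; windows describing the same pairing locus are pruned to the
    best-scoring one (ties broken leftmost on the mRNA, then longest).
    An mRNA shorter than ``min_length`` yields an empty list.
    """
    if isinstance(grna, GuideRNA):
        grna_id = grna.id
        gseq = grna.seq
    else:
        gseq = str(grna)
    mseq = str(mrna)
    if len(mseq) < params.min_length or len(gseq) < params.min_length:
        return []
    raw = _align_core(
        _rna_codes(mseq), _rna_codes(gseq), params, grna_id, mrna_id
    )
    return prune_overlaps(raw)


def _align_core(
    am: np.ndarray,
    ag: np.ndarray,
    params: DuplexParams,
    grna_id: str,
    mrna_id: str,
) -> List[DuplexAlignment]:
    """Enumerate all threshold-passing ungapped duplex windows (no pruning)."""
    nm, ng = len(am), len(ag)
    if nm < params.min_length or ng < params.min_length:
        return []

    # anti-diagonal (constant d = i + j) geometry, built as a zero-copy
    # sheared view: row d, column i holds the gRNA code paired with mRNA
    # position i on diagonal d
    # anti-diagonal geometry as a zero-copy positive-stride view: row d,
    # column t holds the gRNA code paired with mRNA position i = nm - 1 - t
    # on diagonal d (the mRNA axis is flipped so all strides stay positive)
    W = nm + ng - 1
    pad = np.full(nm - 1, 4, dtype=np.int8)  # sentinel: pairs nothing
    agp = np.concatenate([pad, ag, pad])
    sw = np.lib.stride_tricks.sliding_window_view(agp, nm)[:W]
    comp_am = np.array([3, 2, 1, 0, 6], dtype=np.int8)[am]  # A<->U, C<->G
    wob_am = np.full(nm, 5, dtype=np.int8)
    wob_am[am == 2] = 3  # mRNA G wobbles gRNA U
    wob_am[am == 3] = 2  # mRNA U wobbles gRNA G
    comp_r = comp_am[::-1].copy()
    wob_r = wob_am[::-1].copy()
    wc = sw == comp_r[None, :]
    gu = sw == wob_r[None, :]

    # candidate cells: every passing window must contain a seed window of
    # seed_length with score >= seed_score, so sliding seed scores along the
    # anti-diagonals (rows of the sheared frame) give a complete filter
    sl = params.seed_length
    if nm < sl:
        return []
    score_mat = wc.view(np.int8) * np.int8(params.score_wc - params.score_mm)
    score_mat += gu.view(np.int8) * np.int8(params.score_gu - params.score_mm)
    score_mat += np.int8(params.score_mm)
    acc = np.int16 if nm < 2**13 else np.int32  # cumulative score headroom
    cs = np.cumsum(score_mat, axis=1, dtype=acc)
    seed_mat = cs[:, sl - 1 :].copy()
    seed_mat[:, 1:] -= cs[:, : nm - sl]
    dd, tt = np.nonzero(seed_mat >= params.seed_score)  # row-major sorted
    if len(tt) == 0:
        return []
    # collapse consecutive seed hits on a diagonal into one candidate group
    new_run = np.ones(len(tt), dtype=bool)
    new_run[1:] = (dd[1:] != dd[:-1]) | (tt[1:] != tt[:-1] + 1)
    group_start = np.flatnonzero(new_run)
    group_end = np.append(group_start[1:], len(tt)) - 1

    def _cls_at(i: int, d: int) -> int:
        return _PAIR_CLASS[am[i], ag[d - i]] if 0 <= d - i < ng else 2

    score_of = np.array([params.score_wc, params.score_gu, params.score_mm])
    results = {}
    for gs_, ge_ in zip(group_start, group_end):
        d = int(dd[gs_])
        lo = max(0, d - ng + 1)  # smallest mRNA index on this diagonal
        hi = min(nm - 1, d)
        dn = hi - lo + 1
        if dn < params.min_length:
            continue
        # group rows tt[gs_]..tt[ge_] cover mRNA window
        # [nm - sl - tt[ge_], nm - tt[gs_]) on this diagonal
        rs = (nm - sl - int(tt[ge_])) - lo  # seed-region start, diagonal-local
        re_ = (nm - int(tt[gs_])) - lo      # end, half-open
        rs = min(max(rs, 0), dn)
        re_ = min(max(re_, 0), dn)
        if re_ <= rs:
            continue
        # expand to the window-feasible region: at most max_mismatch extra
        # mismatches on either side
        a_min, mm_left = rs, 0
        while a_min > 0 and mm_left <= params.max_mismatch:
            if _cls_at(lo + a_min - 1, d) == 2:
                mm_left += 1
                if mm_left > params.max_mismatch:
                    break
            a_min -= 1
        b_max, mm_right = re_, 0
        while b_max < dn and mm_right <= params.max_mismatch:
            if _cls_at(lo + b_max, d) == 2:
                mm_right += 1
                if mm_right > params.max_mismatch:
                    break
            b_max += 1
        if b_max - a_min < params.min_length:
            continue
        c = np.array(
            [_cls_at(i, d) for i in range(lo + a_min, lo + b_max)], dtype=np.int8
        )
        # cheap upper bound: all matches scoring as Watson-Crick
        if 2 * int((c < 2).sum()) < params.min_score:
            continue
        n = len(c)
        sc = score_of[c]
        ps = np.concatenate([[0], np.cumsum(sc)])
        pmm = np.concatenate([[0], np.cumsum(c == 2)])
        pgu = np.concatenate([[0], np.cumsum(c == 1)])
        wc_run = np.zeros(n, dtype=np.int32)
        r = 0
        for k in range(n):
            r = r + 1 if c[k] == 0 else 0
            wc_run[k] = r
        seed = ps[sl:] - ps[:-sl] if n >= sl else np.empty(0)
        for a in range(0, n - params.min_length + 1):
            excess = pmm[a] + params.max_mismatch
            bmax = n if excess >= pmm[n] else int(np.searchsorted(pmm, excess, "right")) - 1
            for b in range(a + params.min_length, bmax + 1):
                if ps[b] - ps[a] < params.min_score:
                    continue
                if pgu[b] - pgu[a] > params.max_gu:
                    continue
                if wc_run[b - 1] < params.min_anchor:
                    continue
                if b - a < sl or seed[a : b - sl + 1].max() < params.seed_score:
                    continue
                ms, me = lo + a_min + a, lo + a_min + b
                key = (ms, me, d)
                if key in results:
                    continue
                results[key] = DuplexAlignment(
                    grna_id=grna_id,
                    mrna_id=mrna_id,
                    mrna_start=int(ms),
                    mrna_end=int(me),
                    grna_start=int(d - (me - 1)),
                    grna_end=int(d - ms + 1),
                    pair_string="".join(_CLASS_CHAR[c[a:b]]),
                    score=int(ps[b] - ps[a]),
                    n_gu=int(pgu[b] - pgu[a]),
                    n_mm=int(pmm[b] - pmm[a]),
                )

    return list(results.values())


_SENTINEL = 4


def _concat_blocks(seqs: List[str], gap: int):
    """Concatenate code arrays separated by ``gap`` sentinel codes."""
    codes = [_rna_codes(s) for s in seqs]
    sep = np.full(gap, _SENTINEL, dtype=np.int8)
    parts = []
    starts = []
    pos = 0
    for i, c in enumerate(codes):
        if i:
            parts.append(sep)
            pos += gap
        starts.append(pos)
        parts.append(c)
        pos += len(c)
    return np.concatenate(parts), starts, [len(c) for c in codes]


def align_grna_set(
    grnas: Sequence[GuideRNA],
    mrna,
    params: DuplexParams = CANONICAL,
    mrna_id: str = "mRNA",
) -> List[DuplexAlignment]:
    """Align many gRNAs against one mRNA in a single pass.

    Equivalent to concatenating the per-gRNA ``align_duplex`` results: the
    gRNAs are joined with non-pairing separators longer than the mismatch
    budget, so no window can bridge two gRNAs.
    """
    grnas = [g for g in grnas if len(g.seq) >= params.min_length]
    if not grnas:
        return []
    mseq = str(mrna)
    if len(mseq) < params.min_length:
        return []
    ag, starts, lens = _concat_blocks([g.seq for g in grnas], params.max_mismatch + 1)
    raw = prune_overlaps(_align_core(_rna_codes(mseq), ag, params, "set", mrna_id))
    out = []
    for aln in raw:
        bi = int(np.searchsorted(starts, aln.grna_start, "right")) - 1
        if aln.grna_start < starts[bi] or aln.grna_end > starts[bi] + lens[bi]:
            continue  # touches a separator: a trimmed variant also exists
        aln.grna_id = grnas[bi].id
        aln.grna_start -= starts[bi]
        aln.grna_end -= starts[bi]
        out.append(aln)
    return out


def align_mrna_set(
    grna,
    mrnas: Dict[str, str],
    params: DuplexParams = CANONICAL,
    grna_id: str = "gRNA",
) -> List[DuplexAlignment]:
    """Align one (long) RNA against many mRNAs in a single pass."""
    if isinstance(grna, GuideRNA):
        grna_id, gseq = grna.id, grna.seq
    else:
        gseq = str(grna)
    items = [(k, v) for k, v in mrnas.items() if len(v) >= params.min_length]
    if not items or len(gseq) < params.min_length:
        return []
    am, starts, lens = _concat_blocks([v for _, v in items], params.max_mismatch + 1)
    raw = prune_overlaps(_align_core(am, _rna_codes(gseq), params, grna_id, "set"))
    out = []
    for aln in raw:
        bi = int(np.searchsorted(starts, aln.mrna_start, "right")) - 1
        if aln.mrna_start < starts[bi] or aln.mrna_end > starts[bi] + lens[bi]:
            continue
        aln.mrna_id = items[bi][0]
        aln.mrna_start -= starts[bi]
        aln.mrna_end -= starts[bi]
        out.append(aln)
    return out


def prune_overlaps(alns: List[DuplexAlignment]) -> List[DuplexAlignment]:
    """Greedy best-score selection of non-redundant duplexes.

    Two duplexes compete when they overlap on both the mRNA and the gRNA
    (i.e. they describe the same pairing locus); the best-scoring one wins,
    ties broken leftmost on the mRNA, then longest.  Duplexes from distinct
    gRNA loci may legitimately share mRNA positions (cascade anchor
    overlaps) and are all kept.
    """
    kept: List[DuplexAlignment] = []
    for aln in sorted(alns, key=lambda a: (-a.score, a.mrna_start, -a.length)):
        if all(
            aln.mrna_end <= k.mrna_start
            or aln.mrna_start >= k.mrna_end
            or aln.grna_end <= k.grna_start
            or aln.grna_start >= k.grna_end
            for k in kept
        ):
            kept.append(aln)
    kept.sort(key=lambda a: a.mrna_start)
    return kept


def rescore(aln: DuplexAlignment, params: DuplexParams = CANONICAL) -> int:
    """Recompute the additive score of an alignment from its pair string."""
    return sum(
        {WC: params.score_wc, GU: params.score_gu, MM: params.score_mm}[c]
        for c in aln.pair_string
    )


def render_duplex(
    aln: DuplexAlignment,
    mrna: str,
    grna,
    inserted: Optional[set] = None,
    deleted: Optional[set] = None,
    flank: int = 0,
) -> str:
    """Render an alignment as a three-line text block.

    Line 1: mRNA 5'->3' (inserted U positions lowercase ``u``); line 2: pair
    classes ``|``/``:``/``#``; line 3: the gRNA written 3'->5' so that paired
    bases sit in the same column.  ``deleted`` positions (mRNA coordinates of
    backbone bases 3' of a site where Us were removed) are annotated with a
    ``T`` marker line when given.
    """
    gseq = grna.seq if isinstance(grna, GuideRNA) else str(grna)
    gseq = gseq.upper().replace("T", "U")
    mseq = str(mrna).upper().replace("T", "U")
    s, e = aln.mrna_start, aln.mrna_end
    lo = max(0, s - flank)
    hi = min(len(mseq), e + flank)

    def mchar(i: int) -> str:
        b = mseq[i]
        if inserted and i in inserted and b == "U":
            return "u"
        return b

    mline = "".join(mchar(i) for i in range(lo, hi))
    pline = " " * (s - lo) + aln.pair_string + " " * (hi - e)
    gline = (
        " " * (s - lo)
        + gseq[aln.grna_start : aln.grna_end][::-1]
        + " " * (hi - e)
    )
    lines = [mline, pline, gline]
    if deleted:
        dline = "".join("T" if i in deleted else " " for i in range(lo, hi))
        lines.insert(0, dline)
    return "\n".join(lines)
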