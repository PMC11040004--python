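"""Structural annotation of minicircles and the maxicircle.

Kinetoplastid minicircles carry short conserved sequence blocks (CSBs) -- the
universal 12-mer CSB3 ``ggggttggtgtg`` and the degenerate palindromic CSB1 --
plus inverted repeats and one or two guide-RNA genes.  This module provides
IUPAC motif scanning on circular sequences, contig circularisation via
terminal direct repeats, einverted-style inverted-repeat detection, class
deduplication of near-identical circles, and the conventional re-orientation
of a minicircle so that it starts at the CSB block nearest its gRNA gene.

Coordinates are 0-based half-open throughout; GFF3 output converts to the
1-based closed convention of the format.
"""

from __future__ import annotations

import re as _re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = str.maketrans("ACGTN", "TGCAN")
_IUPAC_COMP = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def revcomp_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC degenerate pattern."""
    return pattern.upper().translate(_IUPAC_COMP)[::-1]


@dataclass
class CircularSeq:
    """A DNA sequence that may be circular."""

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self):
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.id}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    def rotate(self, offset: int) -> "CircularSeq":
        """Return the circle rotated so old position ``offset`` becomes 0."""
        if not self.circular:
            raise ValueError("cannot rotate a linear sequence")
        off = offset % len(self.seq)
        return CircularSeq(self.id, self.seq[off:] + self.seq[:off], True)


@dataclass
class MotifHit:
    motif_name: str
    start: int  # 0-based, leftmost footprint base on the forward strand
    length: int
    strand: str
    pattern: str


@dataclass
class InvertedRepeat:
    arm1_start: int
    arm1_end: int
    arm2_start: int
    arm2_end: int
    score: int
    mismatches: int
    gaps: int


def _validate_pattern(pattern: str) -> None:
    for sym in pattern.upper():
        if sym not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol: {sym!r}")


_SCAN_RE_CACHE: Dict[str, "_re.Pattern"] = {}


def _scan_linear(seq: str, pattern: str) -> List[int]:
    p = pattern.upper()
    rx = _SCAN_RE_CACHE.get(p)
    if rx is None:
        body = "".join(
            IUPAC[s] if len(IUPAC[s]) == 1 else "[" + IUPAC[s] + "]" for s in p
        )
        rx = _re.compile("(?=" + body + ")")  # lookahead: overlapping hits
        _SCAN_RE_CACHE[p] = rx
    return [m.start() for m in rx.finditer(seq)]


def scan_motif(
    seq: CircularSeq,
    pattern: str,
    motif_name: str = "motif",
    both_strands: bool = False,
) -> List[MotifHit]:
    """All positions where the IUPAC ``pattern`` matches the sequence.

    On circular sequences, hits wrapping the origin are reported with their
    forward-strand start position (which may exceed ``len(seq) - len(pattern)``).
    Minus-strand hits are found by scanning the reverse-complemented pattern
    and are reported with the leftmost forward-strand coordinate of their
    footprint.  Matching is exact over the IUPAC code sets.
    """
    _validate_pattern(pattern)
    k = len(pattern)
    L = len(seq.seq)
    if k > L:
        return []
    s = seq.seq + (seq.seq[: k - 1] if seq.circular else "")
    hits = [
        MotifHit(motif_name, i, k, "+", pattern.upper())
        for i in _scan_linear(s, pattern)
        if i < L
    ]
    if both_strands:
        rc = revcomp_pattern(pattern)
        hits += [
            MotifHit(motif_name, i, k, "-", pattern.upper())
            for i in _scan_linear(s, rc)
            if i < L
        ]
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


class AmbiguousCircularizationError(ValueError):
    pass


def circularize_contig(
    contig, k_min: int = 20, contig_id: str = "contig"
) -> CircularSeq:
    """Collapse a terminal exact direct repeat to circularise a contig.

    If the longest ``k`` with ``contig[:k] == contig[-k:]`` satisfies
    ``k >= k_min``, one repeat copy is removed and a circular sequence
    returned; otherwise the contig is returned unchanged with
    ``circular=False``.  A terminal repeat longer than half the contig is
    ambiguous (the true origin of the duplication cannot be placed) and
    raises :class:`AmbiguousCircularizationError`.
    """
    if isinstance(contig, CircularSeq):
        contig_id, contig = contig.id, contig.seq
    s = str(contig).upper()
    L = len(s)
    k_best = 0
    for k in range(L - 1, 0, -1):
        if s[:k] == s[-k:]:
            k_best = k
            break
    if 2 * k_best > L:
        raise AmbiguousCircularizationError(
            f"{contig_id}: terminal repeat of {k_best} bp exceeds half the "
            f"contig ({L} bp)"
        )
    if k_best >= k_min:
        return CircularSeq(contig_id, s[:-k_best], circular=True)
    return CircularSeq(contig_id, s, circular=False)


def _sw_self_revcomp(
    seq: str, match: int, mismatch: int, gap: int, d_lo: int = 2, d_hi: Optional[int] = None
):
    """Smith-Waterman of ``seq`` against its own reverse complement.

    Wavefront (anti-diagonal) dynamic programming in a skewed matrix so every
    update is a pure numpy slice (linear gap penalty, local alignment with
    floor 0).  Only anti-diagonals ``d = i + j`` in [d_lo, d_hi] are filled;
    restricting the band bounds the separation between the two arms.
    """
    code = np.frombuffer(seq.encode(), dtype=np.uint8)
    rc = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
    n = len(code)
    if d_hi is None:
        d_hi = 2 * n
    d_lo = max(2, d_lo)
    d_hi = min(2 * n, d_hi)
    # W[i, d] == H[i, d - i]; H is (n+1) x (n+1)
    W = np.zeros((n + 1, d_hi + 1), dtype=np.int32)
    for d in range(d_lo, d_hi + 1):
        lo = max(1, d - n)
        hi = min(n, d - 1)
        if lo > hi:
            continue
        i = np.arange(lo, hi + 1)
        sub = np.where(code[i - 1] == rc[d - i - 1], match, mismatch)
        diag = W[lo - 1 : hi, d - 2] + sub
        up = W[lo - 1 : hi, d - 1] + gap
        left = W[lo : hi + 1, d - 1] + gap
        W[lo : hi + 1, d] = np.maximum(0, np.maximum(diag, np.maximum(up, left)))
    return W, code, rc


def find_inverted_repeats(
    seq,
    match: int = 4,
    mismatch: int = -4,
    gap: int = -14,
    threshold: int = 40,
    max_reports: int = 25,
    max_separation: Optional[int] = 300,
) -> List[InvertedRepeat]:
    """Detect inverted repeats by local self-vs-reverse-complement alignment.

    einverted-style scoring: ``match`` (+4), ``mismatch`` (-4) and a linear
    ``gap`` penalty (-14 per gapped position); alignments scoring at least
    ``threshold`` are reported with 0-based half-open arm coordinates, the
    second arm lying strictly 3' of (and not overlapping) the first.
    ``max_separation`` bounds the loop between the arms (pass ``None`` for an
    unrestricted search); arms themselves may span up to 400 bp within the
    band.
    """
    s = seq.seq if isinstance(seq, CircularSeq) else str(seq).upper()
    n = len(s)
    if n < 2:
        return []
    if max_separation is None:
        d_lo, d_hi = 2, 2 * n
    else:
        # arm separation = n - d at the alignment end; the path only
        # increases d, by at most 2 per aligned arm position
        d_lo, d_hi = n - max_separation - 800, n
    W, code, rc = _sw_self_revcomp(s, match, mismatch, gap, d_lo, d_hi)

    # candidate end cells, best first
    ii, dd = np.nonzero(W >= threshold)
    order = np.argsort(-W[ii, dd], kind="stable")
    reported: List[InvertedRepeat] = []
    used = np.zeros(n, dtype=bool)
    for idx in order:
        if len(reported) >= max_reports:
            break
        i, d = int(ii[idx]), int(dd[idx])
        j = d - i
        if j < 1 or j > n:
            continue
        score = int(W[i, d])
        # traceback
        ci, cj = i, j
        mism = gaps = 0
        while ci > 0 and cj > 0 and W[ci, ci + cj] > 0:
            h = W[ci, ci + cj]
            sub = match if code[ci - 1] == rc[cj - 1] else mismatch
            if ci > 0 and cj > 0 and h == W[ci - 1, ci + cj - 2] + sub:
                if sub == mismatch:
                    mism += 1
                ci, cj = ci - 1, cj - 1
            elif ci > 0 and h == W[ci - 1, ci + cj - 1] + gap:
                gaps += 1
                ci -= 1
            elif cj > 0 and h == W[ci, ci + cj - 1] + gap:
                gaps += 1
                cj -= 1
            else:  # pragma: no cover - defensive
                break
        a1s, a1e = ci, i          # arm1 on forward strand
        a2s, a2e = n - j, n - cj  # arm2 mapped back from the reverse strand
        if a2s < a1e:  # keep arm1 < arm2, non-overlapping
            continue
        if used[a1s:a1e].any() or used[a2s:a2e].any():
            continue
        used[a1s:a1e] = True
        used[a2s:a2e] = True
        reported.append(
            InvertedRepeat(a1s, a1e, a2s, a2e, score, mism, gaps)
        )
    reported.sort(key=lambda r: r.arm1_start)
    return reported


def rescore_inverted_repeat(
    seq, ir: InvertedRepeat, match: int = 4, mismatch: int = -4, gap: int = -14
) -> int:
    """Re-derive an IR's score from its arm coordinates (global on the arms)."""
    s = seq.seq if isinstance(seq, CircularSeq) else str(seq).upper()
    a = s[ir.arm1_start : ir.arm1_end]
    b = revcomp(s[ir.arm2_start : ir.arm2_end])
    la, lb = len(a), len(b)
    NEG = -(10**9)
    H = np.full((la + 1, lb + 1), NEG, dtype=np.int64)
    H[0, 0] = 0
    for i in range(la + 1):
        for j in range(lb + 1):
            if i and j:
                sub = match if a[i - 1] == b[j - 1] else mismatch
                H[i, j] = max(H[i, j], H[i - 1, j - 1] + sub)
            if i:
                H[i, j] = max(H[i, j], H[i - 1, j] + gap)
            if j:
                H[i, j] = max(H[i, j], H[i, j - 1] + gap)
    return int(H[la, lb])


# ---------------------------------------------------------------------------
# minicircle class deduplication and orientation


def _best_rotation_identity(a: str, b: str, seed_len: int = 15) -> float:
    """Identity between two circles under rotation (one strand of b).

    Anchors rotations of ``b`` at exact occurrences of short seeds taken from
    ``a`` and scores a rotation by Hamming identity over the shorter length,
    normalised by the longer.  Near-identical circles (the clustering regime)
    always share exact seeds.
    """
    la, lb = len(a), len(b)
    if min(la, lb) < seed_len:
        return 0.0
    bb = b + b
    best = 0.0
    span = min(la, lb)
    denom = max(la, lb)
    for off in (0, la // 3, 2 * la // 3):
        seed = a[off : off + seed_len]
        start = 0
        while True:
            p = bb.find(seed, start)
            if p < 0 or p >= lb:
                break
            rot = (p - off) % lb
            rb = bb[rot : rot + span]
            matches = sum(x == y for x, y in zip(a[:span], rb))
            best = max(best, matches / denom)
            start = p + 1
    return best


def circle_identity(a: CircularSeq, b: CircularSeq) -> float:
    """Rotation- and strand-invariant identity between two circles."""
    fwd = _best_rotation_identity(a.seq, b.seq)
    rev = _best_rotation_identity(a.seq, revcomp(b.seq))
    return max(fwd, rev)


def classify_minicircles(
    circles: Sequence[CircularSeq], identity_threshold: float = 0.97
) -> Dict[str, List[str]]:
    """Greedy deduplication of circles into sequence classes.

    Circles are processed longest first (ties by id); each joins the first
    existing class whose representative it matches at or above the identity
    threshold (rotation- and strand-invariant), else founds a new class.
    Returns {representative id: [member ids]}; deterministic given the input.
    """
    order = sorted(circles, key=lambda c: (-len(c), c.id))
    reps: List[CircularSeq] = []
    classes: Dict[str, List[str]] = {}
    for c in order:
        for rep in reps:
            if circle_identity(rep, c) >= identity_threshold:
                classes[rep.id].append(c.id)
                break
        else:
            reps.append(c)
            classes[c.id] = [c.id]
    return classes


def reorient_minicircle(
    circle: CircularSeq,
    csb_hits: Sequence[MotifHit],
    gene_start: int,
    gene_strand: str = "-",
) -> Tuple[CircularSeq, int, bool]:
    """Rotate (and flip) a minicircle to its conventional origin.

    The circle is rotated so the CSB hit with the smallest circular distance
    to the functional gRNA gene sits at position 0 (ties broken by the lower
    coordinate).  If the gRNA gene lies on the same strand as the CSBs, the
    circle is flipped so that the gene ends up on the opposite strand, the
    standard minicircle architecture.  Returns (reoriented circle, rotation
    offset applied, flipped).
    """
    if not csb_hits:
        raise ValueError(f"{circle.id}: no CSB hit to orient by")
    if gene_start is None:
        raise ValueError(f"{circle.id}: no gRNA gene to orient by")
    L = len(circle)

    def circ_dist(a: int, b: int) -> int:
        d = (b - a) % L
        return min(d, L - d)

    best = min(csb_hits, key=lambda h: (circ_dist(h.start, gene_start), h.start))
    flipped = best.strand == gene_strand
    if flipped:
        flipped_seq = CircularSeq(circle.id, revcomp(circle.seq), True)
        start = (L - (best.start + best.length)) % L
        return flipped_seq.rotate(start), start, True
    return circle.rotate(best.start), best.start, False


# ---------------------------------------------------------------------------
# GFF3 / TSV output


def gff3_lines(source_id: str, features) -> List[str]:
    """Serialise (type, start, end, strand, attrs) tuples to GFF3 rows.

    Input coordinates are 0-based half-open and converted to the 1-based
    closed convention here.
    """
    rows = []
    for ftype, start, end, strand, attrs in features:
        attr_s = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
        rows.append(
            "\t".join(
                [
                    source_id,
                    "kedit",
                    ftype,
                    str(start + 1),
                    str(end),
                    ".",
                    strand,
                    ".",
                    attr_s,
                ]
            )
        )
    return rows
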