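"""Guide-RNA gene annotation and expression calling.

Two independent routes identify gRNA genes: alignment of minicircle and
maxicircle sequences against fully edited mRNAs (a gRNA gene is a locus whose
minus-strand transcript can form a passing duplex with an edited mRNA), and
small-RNA sequencing of the gRNA population itself (adapter trimming, pair
merging, 3' tail removal, 97%-identity clustering, consensus, and validation
by mapping the consensus back to a source molecule).  Expression-derived
boundaries take precedence over alignment-derived ones.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .annotate import CircularSeq, revcomp
from .duplex import (
    CANONICAL,
    DuplexAlignment,
    DuplexParams,
    GuideRNA,
    align_duplex,
    align_mrna_set,
)


@dataclass
class GuideGene:
    """A gRNA gene locus on a minicircle or the maxicircle."""

    source_id: str
    start: int
    end: int
    strand: str
    supporting_alignment: Optional[DuplexAlignment] = None
    mrna_id: Optional[str] = None
    expression_support: int = 0
    boundaries_refined: bool = False

    @property
    def seq_on(self):
        return (self.start, self.end)


@dataclass
class SmallRNACluster:
    members: List[str]
    consensus: str
    size: int
    source_id: Optional[str] = None
    start: int = -1
    end: int = -1
    strand: str = "."
    validated: bool = False


def _minus_transcript(seq: str) -> str:
    """RNA-sense transcript of the minus strand of a DNA segment."""
    return revcomp(seq).replace("T", "U")


def annotate_grna_genes(
    circles: Sequence[CircularSeq],
    maxicircle: Optional[CircularSeq],
    edited_mrnas: Dict[str, str],
    params: DuplexParams = CANONICAL,
    exclude_regions: Optional[Dict[str, List[Tuple[int, int]]]] = None,
) -> Tuple[List[GuideGene], List[str]]:
    """Predict gRNA genes by source:mRNA duplex alignment.

    Both strands of every circle and of the maxicircle are aligned (as
    RNA-sense transcripts) against every edited mRNA; each passing duplex is
    emitted as a :class:`GuideGene` at the corresponding source locus, and
    overlapping loci on the same source/strand are merged.  On the
    maxicircle, ``exclude_regions`` (typically the annotated gene and
    cryptogene intervals, whose minus strands are trivially complementary to
    their own transcripts) suppresses self-antisense calls.  Returns
    (genes, ids of circles with no alignment to any edited mRNA).
    """
    exclude_regions = exclude_regions or {}
    sources = [(c.id, c.seq) for c in circles]
    if maxicircle is not None:
        sources.append((maxicircle.id, maxicircle.seq))
    genes: List[GuideGene] = []
    empty: List[str] = []
    for sid, seq in sources:
        found_here: List[GuideGene] = []
        L = len(seq)
        for strand in ("+", "-"):
            transcript = seq.replace("T", "U") if strand == "+" else _minus_transcript(seq)
            alns = [
                aln
                for mid, mrna in edited_mrnas.items()
                for aln in align_duplex(
                    transcript, mrna, params, grna_id=sid, mrna_id=mid
                )
            ]
            for aln in alns:
                if strand == "+":
                    s, e = aln.grna_start, aln.grna_end
                else:  # transcript position i is source position L-1-i
                    s, e = L - aln.grna_end, L - aln.grna_start
                if any(
                    s < xe and e > xs
                    for xs, xe in exclude_regions.get(sid, [])
                ):
                    continue
                found_here.append(
                    GuideGene(
                        source_id=sid,
                        start=s,
                        end=e,
                        strand=strand,
                        supporting_alignment=aln,
                        mrna_id=aln.mrna_id,
                    )
                )
        merged = _merge_loci(found_here)
        genes.extend(merged)
        if not merged and maxicircle is not None and sid != maxicircle.id:
            empty.append(sid)
        elif not merged and maxicircle is None:
            empty.append(sid)
    return genes, empty


def _merge_loci(genes: List[GuideGene]) -> List[GuideGene]:
    """Merge overlapping loci on the same source and strand, keeping the
    best-scoring supporting alignment and the union interval."""
    out: List[GuideGene] = []
    for g in sorted(genes, key=lambda x: (x.strand, x.start)):
        last = out[-1] if out else None
        if (
            last is not None
            and last.strand == g.strand
            and g.start < last.end
        ):
            last.end = max(last.end, g.end)
            last.start = min(last.start, g.start)
            if (
                g.supporting_alignment is not None
                and last.supporting_alignment is not None
                and g.supporting_alignment.score > last.supporting_alignment.score
            ):
                last.supporting_alignment = g.supporting_alignment
                last.mrna_id = g.mrna_id
        else:
            out.append(g)
    out.sort(key=lambda x: (x.start, x.strand))
    return out


# ---------------------------------------------------------------------------
# small-RNA preprocessing


class FastqFormatError(ValueError):
    pass


def parse_fastq(path_or_lines) -> List[Tuple[str, str, str]]:
    """Minimal strict FASTQ reader returning (id, seq, qual) triples."""
    if isinstance(path_or_lines, (str,)) or hasattr(path_or_lines, "read"):
        fh = open(path_or_lines) if isinstance(path_or_lines, str) else path_or_lines
        lines = [l.rstrip("\n") for l in fh]
        if isinstance(path_or_lines, str):
            fh.close()
    else:
        lines = [l.rstrip("\n") for l in path_or_lines]
    lines = [l for l in lines if l != ""]
    if len(lines) % 4:
        raise FastqFormatError(
            f"truncated FASTQ: record {len(lines) // 4 + 1} incomplete"
        )
    out = []
    for i in range(0, len(lines), 4):
        rec = i // 4 + 1
        if not lines[i].startswith("@"):
            raise FastqFormatError(f"record {rec}: header does not start with @")
        if lines[i + 2][:1] != "+":
            raise FastqFormatError(f"record {rec}: separator line missing")
        if len(lines[i + 1]) != len(lines[i + 3]):
            raise FastqFormatError(f"record {rec}: sequence/quality length mismatch")
        out.append((lines[i][1:].split()[0], lines[i + 1].upper(), lines[i + 3]))
    return out


def trim_adapter(seq: str, adapter: str, min_terminal: int = 8) -> str:
    """Remove an adapter and everything 3' of it.

    An exact internal occurrence truncates the read at its start; otherwise
    a terminal prefix of the adapter of at least ``min_terminal`` nt matching
    the read's 3' end is clipped.
    """
    if not adapter:
        return seq
    p = seq.find(adapter)
    if p >= 0:
        return seq[:p]
    for k in range(min(len(adapter), len(seq)) - 1, min_terminal - 1, -1):
        if seq.endswith(adapter[:k]):
            return seq[: len(seq) - k]
    return seq


def merge_pair(
    r1: Tuple[str, str], r2: Tuple[str, str], min_identity: float = 0.9
) -> Optional[str]:
    """Merge a completely overlapping read pair into one insert sequence.

    The reverse complement of read 2 must fully contain, or be contained in,
    read 1 at its best offset with at least ``min_identity`` matches;
    disagreeing positions resolve to the base with the higher quality score.
    Returns the merged insert, or None when the pair does not fully overlap.
    """
    s1, q1 = r1
    s2, q2 = r2
    rc2 = revcomp(s2)
    rq2 = q2[::-1]
    short, long_ = (s1, rc2) if len(s1) <= len(rc2) else (rc2, s1)
    best = None
    for off in range(len(long_) - len(short) + 1):
        matches = sum(a == b for a, b in zip(short, long_[off : off + len(short)]))
        if best is None or matches > best[1]:
            best = (off, matches)
    if best is None or best[1] < min_identity * len(short):
        return None
    off = best[0]
    if len(s1) <= len(rc2):
        a, qa, b, qb, boff = s1, q1, rc2, rq2, off
        merged = []
        for i, base in enumerate(a):
            other = b[boff + i]
            if base == other:
                merged.append(base)
            else:
                merged.append(base if qa[i] >= qb[boff + i] else other)
        return "".join(merged)
    merged = []
    for i, base in enumerate(rc2):
        other = s1[off + i]
        if base == other:
            merged.append(base)
        else:
            merged.append(base if rq2[i] >= q1[off + i] else other)
    return "".join(merged)


def preprocess_small_reads(
    reads1: Sequence[Tuple[str, str, str]],
    reads2: Sequence[Tuple[str, str, str]],
    adapter: str,
    min_len: int = 15,
) -> List[Tuple[str, str]]:
    """Adapter-trim, length-filter and merge a paired small-RNA library.

    Reads shorter than ``min_len`` after trimming are dropped; pairs whose
    trimmed mates fully overlap are merged into single insert sequences.
    Unmerged pairs are discarded (inserts longer than the read length cannot
    be gRNAs).  Returns (read id, insert sequence) pairs.
    """
    by_id2 = {rid: (s, q) for rid, s, q in reads2}
    out = []
    for rid, s1, q1 in reads1:
        t1 = trim_adapter(s1, adapter)
        if len(t1) < min_len:
            continue
        mate = by_id2.get(rid)
        if mate is None:
            continue
        t2 = trim_adapter(mate[0], adapter)
        if len(t2) < min_len:
            continue
        merged = merge_pair((t1, q1[: len(t1)]), (t2, mate[1][: len(t2)]))
        if merged is not None and len(merged) >= min_len:
            out.append((rid, merged))
    return out


_TAIL_RE_CACHE: Dict[int, "re.Pattern"] = {}


def strip_tails(seq: str, min_tail: int = 3) -> str:
    """Remove one trailing 3' poly(T) or poly(A) run of >= ``min_tail`` nt."""
    pat = _TAIL_RE_CACHE.get(min_tail)
    if pat is None:
        pat = re.compile("(T{%d,}|A{%d,})$" % (min_tail, min_tail))
        _TAIL_RE_CACHE[min_tail] = pat
    return pat.sub("", seq)


# ---------------------------------------------------------------------------
# clustering and expression calling


def _best_offset_identity(a: str, b: str) -> Tuple[float, int]:
    """Identity of the best ungapped offset alignment of the shorter sequence
    inside the longer (matches / shorter length), and the offset of ``b``
    relative to ``a`` (may be negative)."""
    if len(b) <= len(a):
        short, long_, sign = b, a, 1
    else:
        short, long_, sign = a, b, -1
    best = (0.0, 0)
    for off in range(len(long_) - len(short) + 1):
        m = sum(x == y for x, y in zip(short, long_[off : off + len(short)]))
        ident = m / len(short)
        if ident > best[0]:
            best = (ident, off)
    return best[0], sign * best[1]


def cluster_reads(
    inserts: Sequence[Tuple[str, str]], identity: float = 0.97
) -> List[SmallRNACluster]:
    """Greedy length-sorted clustering at an identity threshold.

    The longest sequence founds the first cluster; every read joins the
    first cluster whose representative it matches at >= ``identity`` (best
    ungapped offset, matches / shorter length), else founds a new cluster.
    Consensus is the per-column majority over members aligned at their best
    offsets (ties to the representative's base).
    """
    order = sorted(inserts, key=lambda r: (-len(r[1]), r[0]))
    reps: List[str] = []
    members: List[List[Tuple[str, str, int]]] = []  # (id, seq, offset in rep)
    for rid, seq in order:
        placed = False
        for ci, rep in enumerate(reps):
            ident, rel = _best_offset_identity(rep, seq)
            if ident >= identity:
                members[ci].append((rid, seq, max(rel, 0)))
                placed = True
                break
        if not placed:
            reps.append(seq)
            members.append([(rid, seq, 0)])
    clusters = []
    for rep, mem in zip(reps, members):
        cols = [Counter() for _ in rep]
        for rid, seq, off in mem:
            for i, b in enumerate(seq):
                if 0 <= off + i < len(rep):
                    cols[off + i][b] += 1
        consensus = "".join(
            max(c.items(), key=lambda kv: (kv[1], kv[0] == rep[i]))[0] if c else rep[i]
            for i, c in enumerate(cols)
        )
        clusters.append(
            SmallRNACluster(
                members=[m[0] for m in mem], consensus=consensus, size=len(mem)
            )
        )
    return clusters


def map_consensus(
    consensus: str,
    sources: Dict[str, Tuple[str, bool]],
    seed_len: int = 18,
    max_mm: int = 1,
) -> Optional[Tuple[str, int, int, str]]:
    """Exact-seed map of a consensus to a source molecule.

    A consensus gRNA maps when a ``seed_len`` exact prefix seed locates it
    (either strand; circular sources are searched across the origin) and the
    full-length placement has at most ``max_mm`` mismatches.  Returns
    (source id, start, end, strand) on the forward strand, or None.
    """
    k = min(seed_len, len(consensus))
    for sid, (seq, circular) in sources.items():
        L = len(seq)
        search = seq + (seq[: len(consensus) - 1] if circular else "")
        for strand in ("+", "-"):
            probe = consensus if strand == "+" else revcomp(consensus)
            seed = probe[:k]
            start = 0
            while True:
                p = search.find(seed, start)
                if p < 0 or p >= L:
                    break
                window = search[p : p + len(probe)]
                if len(window) == len(probe):
                    mm = sum(a != b for a, b in zip(window, probe))
                    if mm <= max_mm:
                        return sid, p, p + len(probe), strand
                start = p + 1
    return None


def call_expressed_grnas(
    inserts: Sequence[Tuple[str, str]],
    circles: Sequence[CircularSeq],
    maxicircle: Optional[CircularSeq],
    identity: float = 0.97,
    min_tail: int = 3,
    min_cluster_size: int = 2,
) -> Tuple[List[GuideGene], List[SmallRNACluster]]:
    """Call expressed gRNAs from merged small-RNA inserts.

    Tail-stripped inserts are clustered at the identity threshold; cluster
    consensus sequences are validated by mapping back to a minicircle or the
    maxicircle, which also fixes the gene boundaries (the consensus of the
    member termini).  Returns (refined GuideGenes, all clusters); clusters
    that fail validation are reported as orphans via ``validated=False``.
    """
    stripped = [(rid, strip_tails(seq, min_tail)) for rid, seq in inserts]
    stripped = [x for x in stripped if x[1]]
    clusters = cluster_reads(stripped, identity)
    sources = {c.id: (c.seq, c.circular) for c in circles}
    if maxicircle is not None:
        sources[maxicircle.id] = (maxicircle.seq, maxicircle.circular)
    genes: List[GuideGene] = []
    for cl in clusters:
        hit = map_consensus(cl.consensus, sources)
        if hit is None or cl.size < min_cluster_size:
            continue
        sid, start, end, strand = hit
        cl.source_id, cl.start, cl.end, cl.strand = sid, start, end, strand
        cl.validated = True
        # gene is on the strand the gRNA is transcribed from: a '+' mapping
        # of the consensus means the plus strand carries the gRNA sequence
        gene_strand = "+" if strand == "+" else "-"
        genes.append(
            GuideGene(
                source_id=sid,
                start=start,
                end=end,
                strand=gene_strand,
                expression_support=cl.size,
                boundaries_refined=True,
            )
        )
    return genes, clusters
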