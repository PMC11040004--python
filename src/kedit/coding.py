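"""Codon-level analyses under the protistan mitochondrial code (table 4).

Covers synonymous codon incidence across a set of mitochondrial CDS,
UAA/UAG stop-codon usage (UGA is tryptophan, never stop, under code 4),
comparison of recoded (read-through) stop-codon usage against the likely
predecessor codons, and the N-terminus-anchored mitochondrial targeting
signal pattern scan.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from scipy import stats

from .editing import translate_code4

CODE4_STOPS = ("TAA", "TAG")

#: likely evolutionary predecessors of the recoded (read-through) codons:
#: TAA/TAG read as Glu (predecessors GAA/GAG), TGA read as Trp (TGG)
PREDECESSORS = {"TAA": ("GAA", "GAG"), "TAG": ("GAA", "GAG"), "TGA": ("TGG",)}


class InternalStopError(ValueError):
    pass


def _codons(cds: str) -> List[str]:
    s = str(cds).upper().replace("U", "T")
    if len(s) % 3:
        raise ValueError(f"CDS length {len(s)} not divisible by 3")
    return [s[i : i + 3] for i in range(0, len(s), 3)]


@dataclass
class CodonTable:
    """Codon counts and within-amino-acid synonymous incidences."""

    per_gene_counts: Dict[str, Counter]
    counts: Counter
    incidence: Dict[str, float]  # codon -> count / synonymous family total
    aa_of: Dict[str, str]
    stop_codon: Dict[str, Optional[str]]


def codon_incidence(cds_by_gene: Dict[str, str]) -> CodonTable:
    """Count codons over a CDS set and normalise within amino-acid families.

    Each CDS is translated under code 4; an internal stop raises
    :class:`InternalStopError` naming the gene and codon position.  The
    terminal stop codon, when present, is recorded separately and excluded
    from the incidence counts.
    """
    per_gene: Dict[str, Counter] = {}
    stop_codon: Dict[str, Optional[str]] = {}
    total: Counter = Counter()
    aa_of: Dict[str, str] = {}
    for gene, cds in cds_by_gene.items():
        codons = _codons(cds)
        stop = None
        if codons and codons[-1] in CODE4_STOPS:
            stop = codons[-1]
            codons = codons[:-1]
        cnt: Counter = Counter()
        for i, codon in enumerate(codons):
            if codon in CODE4_STOPS:
                raise InternalStopError(
                    f"{gene}: internal stop codon {codon} at codon {i}"
                )
            aa = translate_code4(codon)
            aa_of[codon] = aa
            cnt[codon] += 1
        per_gene[gene] = cnt
        stop_codon[gene] = stop
        total.update(cnt)
    family: Counter = Counter()
    for codon, n in total.items():
        family[aa_of[codon]] += n
    incidence = {c: n / family[aa_of[c]] for c, n in total.items()}
    return CodonTable(per_gene, total, incidence, aa_of, stop_codon)


def incidence_per_1000(table: CodonTable) -> Dict[str, float]:
    """Alternative normalisation: codon count per 1000 codons."""
    n = sum(table.counts.values())
    return {c: 1000 * v / n for c, v in table.counts.items()}


def stop_usage(cds_by_gene: Dict[str, str]) -> Dict[str, object]:
    """Tally UAA vs UAG terminal stops; anything else is flagged.

    Under code 4, TGA encodes tryptophan, so a TGA-terminal CDS counts as
    lacking a stop codon.
    """
    counts = Counter({"TAA": 0, "TAG": 0})
    flagged = []
    for gene, cds in cds_by_gene.items():
        codons = _codons(cds)
        if codons and codons[-1] in CODE4_STOPS:
            counts[codons[-1]] += 1
        else:
            flagged.append(gene)
    return {"UAA": counts["TAA"], "UAG": counts["TAG"], "flagged": flagged}


def readthrough_usage(
    cds_by_gene: Dict[str, str],
    group_of: Dict[str, str],
) -> Dict[str, object]:
    """Recoded-codon usage vs predecessor codons, compared between groups.

    For nuclear CDS in which TAA/TAG are sense (Glu) and TGA is sense (Trp),
    computes per gene and per recoded codon the proportion
    ``p = recoded / (recoded + predecessors)`` and compares the per-gene
    proportions between the two gene groups with a two-sided rank-sum test.
    """
    groups = sorted(set(group_of.values()))
    if not cds_by_gene or any(
        g not in set(group_of.values()) for g in groups
    ):
        raise ValueError("empty input")
    per_gene: Dict[str, Dict[str, float]] = {}
    for gene, cds in cds_by_gene.items():
        cnt = Counter(_codons(cds)[:-1])  # exclude the terminal stop
        props = {}
        for codon, preds in PREDECESSORS.items():
            rec = cnt[codon]
            pred = sum(cnt[p] for p in preds)
            props[codon] = rec / (rec + pred) if rec + pred else 0.0
        per_gene[gene] = props
    tests = {}
    if len(groups) == 2:
        ga = [g for g in per_gene if group_of[g] == groups[0]]
        gb = [g for g in per_gene if group_of[g] == groups[1]]
        if not ga or not gb:
            raise ValueError("empty group")
        for codon in PREDECESSORS:
            a = [per_gene[g][codon] for g in ga]
            b = [per_gene[g][codon] for g in gb]
            tests[codon] = rank_sum_test(a, b)
    return {"per_gene": per_gene, "tests": tests, "groups": groups}


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> Dict[str, float]:
    """Two-sided Mann-Whitney rank-sum comparison of two samples.

    Exact p-value for small tie-free samples (both n <= 12), normal
    approximation with continuity correction otherwise.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    import numpy as np

    ties = len(set(a) | set(b)) < len(a) + len(b)
    method = "exact" if (len(a) <= 12 and len(b) <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "median_a": med_a,
        "median_b": med_b,
        "direction": "a>b" if med_a > med_b else ("a<b" if med_a < med_b else "="),
    }


# ---------------------------------------------------------------------------
# targeting-signal scan


@dataclass
class SignalHit:
    protein_id: str
    start: int  # always 0: the pattern is N-terminus anchored
    end: int
    matched: str


#: N-terminal mitochondrial targeting signal: Met, a basic/bulky residue,
#: an optional spacer, a basic/hydroxylated residue, a 1-10 residue spacer,
#: then S/T/R/K.
TARGETING_SIGNAL = ("M", "RHKFL", (0, 1), "RKHST", (1, 10), "STRK")


def targeting_scan_one(protein: str) -> Optional[SignalHit]:
    """Shortest N-terminus-anchored match of the targeting-signal pattern.

    Spacer lengths are tried in order of increasing total match length, so
    the first hit is the shortest possible match.
    """
    p = str(protein).upper()
    m, set1, (s1lo, s1hi), set2, (s2lo, s2hi), set3 = TARGETING_SIGNAL
    combos = sorted(
        ((l1, l2) for l1 in range(s1lo, s1hi + 1) for l2 in range(s2lo, s2hi + 1)),
        key=lambda c: (c[0] + c[1], c[0]),
    )
    for l1, l2 in combos:
        end = 1 + 1 + l1 + 1 + l2 + 1
        if len(p) < end:
            continue
        if (
            p[0] == m
            and p[1] in set1
            and p[2 + l1] in set2
            and p[3 + l1 + l2] in set3
        ):
            return SignalHit("", 0, end, p[:end])
    return None


def targeting_scan(proteins: Dict[str, str]) -> List[SignalHit]:
    """Scan a protein set for the N-terminal targeting-signal pattern."""
    hits = []
    for pid, seq in proteins.items():
        h = targeting_scan_one(seq)
        if h is not None:
            h.protein_id = pid
            hits.append(h)
    return hits
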