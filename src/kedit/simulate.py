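"""Ground-truthed synthetic kinetoplast genomes, transcriptomes and reads.

The generator plants a complete, internally consistent kinetoplast system:

* a maxicircle carrying unedited genes, pan-edited and minimally edited
  cryptogenes (each with a known fully edited mRNA and per-site U counts),
  cryptogenes whose guide RNAs have been lost (edited only stochastically),
  and a few maxicircle-encoded gRNA loci for the minimally edited domains;
* minicircles of the canonical dimeric architecture -- two head-to-tail
  conserved regions (CSB1 + CSB3) at opposite poles, an inverted repeat, and
  one or two gRNA genes with an adjacent GRAM motif on the strand opposite
  the CSBs -- including one distinctly short minicircle class;
* gRNA cascades tiling each pan-edited domain 3'->5' with a configurable
  anchor overlap and redundancy, plus unassigned "orphan" gRNAs;
* read libraries: mRNA-seq reads drawn from staged editing intermediates
  (edited 3' of a per-read breakpoint, pre-edited 5' of it), paired
  small-RNA reads of the gRNAs with 3' U/A tails and sequencing adapters,
  and genomic kDNA fragments.

Everything is deterministic given the seed, and the returned
:class:`GroundTruth` carries the planted state needed for recovery tests.
Sequencing noise is substitution-only so that the U-indel ground truth stays
unambiguous.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .annotate import revcomp
from .duplex import GuideRNA
from .editing import EditingSiteTable, build_site_table, find_longest_orf

DNA = "ACGT"
_COMP_RNA = {"A": "U", "C": "G", "G": "C", "U": "A"}
_RNA2DNA_COMP = {"A": "T", "C": "G", "G": "C", "U": "A"}

SENSE_CODONS = [
    a + b + c
    for a in DNA
    for b in DNA
    for c in DNA
    if a + b + c not in ("TAA", "TAG")
]

_UNEDITED_NAMES = ["ND1", "ND2", "ND4", "ND5", "COI", "RPS3"]
_PAN_NAMES = ["RPS12", "COIII", "A6"]
_MINIMAL_NAMES = ["COII", "CYb"]
_STOCHASTIC_NAMES = ["ND3", "ND8", "ND9", "G3", "G4"]


class InfeasibleTilingError(ValueError):
    """Raised when gRNA lengths cannot tile a domain with the requested overlap."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic kinetoplast genome.

    Defaults emulate the characterised system: 41 minicircle classes (40 of
    1920-2019 bp plus one 601 bp class), 42 minicircle gRNA genes (one class
    carrying two), two of them orphans, three maxicircle gRNA loci serving
    the minimally edited cryptogenes, three pan-edited cascades and five
    cryptogenes whose gRNAs are absent.
    """

    seed: int = 0
    # minicircle architecture
    n_minicircles: Optional[int] = 41
    minicircle_len_range: Tuple[int, int] = (1920, 2019)
    n_small_minicircles: int = 1
    small_minicircle_len: int = 601
    grnas_per_minicircle: int = 1
    n_double_grna_minicircles: int = 1
    n_orphan_grnas: int = 2
    csb1: str = "CTACACGAGACTCTACGTGA"  # concrete yyryryrrrryyyyryryrr
    csb3: str = "GGGGTTGGTGTG"
    gram: str = "TTAGGCAGTAAC"
    ir_arm_len: int = 20
    # maxicircle content
    pan_cascade_sizes: Tuple[int, ...] = (14, 13, 13)
    minimal_cascade_sizes: Tuple[int, ...] = (2, 1)
    n_stochastic_cryptogenes: int = 5
    n_unedited_genes: int = 6
    unedited_gene_codons: int = 145
    stochastic_backbone_len: int = 260
    n_pads_per_stochastic: int = 3
    edited_fraction_of_sites: float = 0.35
    grna_len_range: Tuple[int, int] = (40, 50)
    anchor_overlap: int = 4
    redundancy: float = 1.0
    maxicircle_spacer_range: Tuple[int, int] = (60, 100)
    # read libraries
    read_len: int = 120
    coverage: float = 30.0
    error_rate: float = 0.0
    editing_stage_distribution: Tuple[Tuple[float, float], ...] = (
        (1.0, 0.70),
        (0.5, 0.10),
        (0.0, 0.20),
    )
    tail_len_distribution: Tuple[Tuple[int, float], ...] = (
        (3, 0.25),
        (5, 0.25),
        (8, 0.25),
        (12, 0.25),
    )
    adapter_seq: str = "AGATCGGAAGAGC"
    smallrna_reads_per_grna: int = 30
    kdna_coverage: float = 3.0

    def __post_init__(self):
        for name in (
            "n_small_minicircles",
            "n_double_grna_minicircles",
            "n_orphan_grnas",
            "n_stochastic_cryptogenes",
            "n_unedited_genes",
            "smallrna_reads_per_grna",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.minicircle_len_range[0] <= 0 or self.small_minicircle_len <= 0:
            raise ValueError("minicircle lengths must be positive")
        for dist in (self.editing_stage_distribution, self.tail_len_distribution):
            total = sum(p for _, p in dist)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("distribution probabilities must sum to 1")
        if not 0.0 <= self.edited_fraction_of_sites <= 1.0:
            raise ValueError("edited_fraction_of_sites must be a fraction")
        if self.grnas_per_minicircle not in (1, 2):
            raise ValueError("grnas_per_minicircle must be 1 or 2")
        if self.n_minicircles is not None:
            self.resolved_n_minicircles()  # fails fast on slot bookkeeping

    @property
    def n_cascade_grnas(self) -> int:
        extra = sum(
            int(round((self.redundancy - 1.0) * k)) for k in self.pan_cascade_sizes
        )
        return sum(self.pan_cascade_sizes) + max(0, extra)

    def _slots(self, n_circles: int) -> int:
        per = self.grnas_per_minicircle
        n_cascade_circles = n_circles - self.n_orphan_grnas
        if per == 1:
            return n_cascade_circles + self.n_double_grna_minicircles
        return 2 * n_cascade_circles

    def resolved_n_minicircles(self) -> int:
        """Number of minicircles implied by the gRNA bookkeeping."""
        per = self.grnas_per_minicircle
        needed = self.n_cascade_grnas
        if per == 1:
            n = needed - self.n_double_grna_minicircles + self.n_orphan_grnas
        else:
            n = math.ceil(needed / 2) + self.n_orphan_grnas
        if self.n_minicircles is None:
            return n
        ok = (
            self._slots(self.n_minicircles) == needed
            if self.grnas_per_minicircle == 1
            else self._slots(self.n_minicircles) >= needed
        )
        if not ok:
            raise InfeasibleTilingError(
                f"{self.n_minicircles} minicircles provide "
                f"{self._slots(self.n_minicircles)} cascade gRNA slots but "
                f"{needed} cascade gRNAs are planted"
            )
        return self.n_minicircles


@dataclass
class PlantedGene:
    grna_id: str
    start: int
    end: int
    strand: str


@dataclass
class MinicircleTruth:
    id: str
    seq: str
    csb1: List[int]
    csb3: List[int]
    gram: List[int]
    ir: Optional[Tuple[int, int, int, int]]
    genes: List[PlantedGene]


@dataclass
class PadTruth:
    """A planted non-cognate gRNA landing site on a stochastic cryptogene."""

    grna_id: str
    first_site: int
    last_site: int
    guided_ucount: Dict[int, int]  # site -> threaded U count


@dataclass
class Locus:
    name: str
    kind: str  # unedited | pan | minimal | stochastic | grna
    start: int
    end: int
    strand: str


@dataclass
class GroundTruth:
    config: SimConfig
    maxicircle: str = ""
    loci: List[Locus] = field(default_factory=list)
    minicircles: List[MinicircleTruth] = field(default_factory=list)
    edited_mrnas: Dict[str, str] = field(default_factory=dict)
    gene_mrnas: Dict[str, str] = field(default_factory=dict)
    pre_edited: Dict[str, str] = field(default_factory=dict)
    edited_ucounts: Dict[str, List[int]] = field(default_factory=dict)
    expected_protein_len: Dict[str, int] = field(default_factory=dict)
    grnas: Dict[str, GuideRNA] = field(default_factory=dict)
    grna_targets: Dict[str, Tuple[str, int, int]] = field(default_factory=dict)
    cascades: Dict[str, List[str]] = field(default_factory=dict)
    pads: Dict[str, List[PadTruth]] = field(default_factory=dict)
    read_origins: Dict[str, dict] = field(default_factory=dict)

    def site_table(self, name: str) -> EditingSiteTable:
        seq = self.pre_edited.get(name) or self.gene_mrnas[name]
        return build_site_table(name, seq)

    def kind_of(self, name: str) -> str:
        for loc in self.loci:
            if loc.name == name:
                return loc.kind
        raise KeyError(name)


# ---------------------------------------------------------------------------
# sequence construction helpers


def _random_seq(rng, n: int) -> str:
    return "".join(np.array(list(DNA))[rng.integers(0, 4, n)])


def _random_cds(rng, n_codons: int, stop: str) -> str:
    body = "".join(
        SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)
    )
    return "ATG" + body + stop


def _mm_flank_base(mrna_base_dna: str, rng) -> str:
    """Minicircle plus-strand base whose minus-strand transcript cannot pair
    the given mRNA base (neither Watson-Crick nor G:U)."""
    x = mrna_base_dna.upper().replace("T", "U")
    forbidden = {_COMP_RNA[x]}
    if x == "G":
        forbidden.add("U")
    if x == "U":
        forbidden.add("G")
    allowed = [g for g in "ACGU" if g not in forbidden]
    g = allowed[int(rng.integers(0, len(allowed)))]
    return _RNA2DNA_COMP[g]


def _tile_domain(
    cs: int, ce: int, k: int, len_range: Tuple[int, int], overlap: int
) -> List[Tuple[int, int]]:
    """Split [cs, ce) into k windows with exact ``overlap`` between
    neighbours, 3'-most first.  Raises when lengths leave the allowed range."""
    if k < 1:
        raise InfeasibleTilingError("cascade must contain at least one gRNA")
    total = (ce - cs) + (k - 1) * overlap
    base, rem = divmod(total, k)
    lengths = [base + (1 if i < rem else 0) for i in range(k)]
    lo, hi = len_range
    if any(l < lo or l > hi for l in lengths) or any(l <= overlap for l in lengths):
        raise InfeasibleTilingError(
            f"domain of {ce - cs} nt cannot be tiled by {k} gRNAs of "
            f"{lo}-{hi} nt with {overlap} nt anchor overlap"
        )
    windows = []
    end = ce
    for l in lengths:
        windows.append((end - l, end))
        end = (end - l) + overlap
    assert windows[-1][0] == cs
    return windows


def _grna_from_window(mrna_dna: str, a: int, b: int) -> str:
    """RNA-sense gRNA perfectly Watson-Crick complementary to mRNA[a:b]."""
    return revcomp(mrna_dna[a:b]).replace("T", "U")


F5 = 16  # unedited 5' flank of an edited mRNA (nt)
F3 = 16  # unedited 3' flank
ANCHOR3 = 12  # never-edited 3' run used by the first gRNA's anchor


def _build_edited_cryptogene(
    rng, name: str, cascade_k: int, cfg: SimConfig, stop: str = "TAA",
    minimal: bool = False,
):
    """Fully edited mRNA, pre-edited cryptogene and gRNA tiling windows."""
    lmean = sum(cfg.grna_len_range) // 2
    D = cascade_k * (lmean - cfg.anchor_overlap) + cfg.anchor_overlap
    if minimal:
        n_codons = max(120, (D + 2 * F5) // 3 + 40)
    else:
        n_codons = (D + F5 + F3 - 12 - 13 - 6) // 3 + 1
    for _ in range(40):
        leader = _random_seq(rng, 13)
        trailer = _random_seq(rng, 12)
        edited = leader + _random_cds(rng, n_codons, stop) + trailer
        L = len(edited)
        if minimal:
            dom_lo, dom_hi = L - F3 - D + ANCHOR3, L - F3
        else:
            dom_lo, dom_hi = F5, L - F3
        table = build_site_table(name, edited)
        e = list(table.site_ucount)
        g = list(e)
        n_edit = 0
        for i in range(1, table.n_sites - 1):
            coord = table.site_coord_5p[i]
            if not dom_lo <= coord < dom_hi:
                continue
            if rng.random() >= cfg.edited_fraction_of_sites:
                continue
            if e[i] > 0 and rng.random() < 0.85:
                g[i] = max(0, e[i] - int(rng.integers(1, 4)))  # insertion site
            else:
                g[i] = e[i] + int(rng.integers(1, 4))  # deletion site
            if g[i] != e[i]:
                n_edit += 1
        pre = table.rebuild(g)
        if cfg.edited_fraction_of_sites == 0 or n_edit > 0 or minimal:
            ce = L - F3 + ANCHOR3
            csd = dom_lo if minimal else F5
            windows = _tile_domain(
                csd if minimal else F5, ce, cascade_k, cfg.grna_len_range,
                cfg.anchor_overlap,
            )
            prot_len = len(find_longest_orf(edited)[2])
            return edited, pre, e, windows, prot_len
    raise InfeasibleTilingError(f"{name}: could not plant edited sites")


def _build_stochastic_cryptogene(rng, name: str, cfg: SimConfig, grna_pool):
    """Cryptogene without gRNAs: backbone with reference U counts plus
    planted non-cognate gRNA landing pads, and no open reading frame."""
    nb = cfg.stochastic_backbone_len
    for _ in range(60):
        backbone = "".join("ACG"[i] for i in rng.integers(0, 3, nb))
        ucount = [int(u) for u in rng.choice([0, 1, 2, 3], nb + 1, p=[0.55, 0.25, 0.15, 0.05])]
        pads: List[PadTruth] = []
        n_pads = min(cfg.n_pads_per_stochastic, len(grna_pool))
        if n_pads > 0:
            anchors = np.linspace(30, nb - 60, n_pads).astype(int)
            chosen = rng.choice(len(grna_pool), n_pads, replace=False)
            for anchor, gi in zip(anchors, chosen):
                grna = grna_pool[int(gi)]
                frag, threaded = _pad_from_grna(rng, grna.seq)
                m = len(frag)
                lo = int(anchor)
                backbone = backbone[:lo] + frag + backbone[lo + m:]
                # the duplex prescribes counts at every interior pad site,
                # including zeros (guided deletions where the reference has Us)
                guided = {lo + j: threaded.get(j, 0) for j in range(1, m)}
                pads.append(
                    PadTruth(
                        grna_id=grna.id,
                        first_site=lo + 1,
                        last_site=lo + m - 1,
                        guided_ucount=guided,
                    )
                )
        table = EditingSiteTable(name, backbone, ucount, [])
        pre = table.rebuild()
        expected = len(pre) // 3 - 1
        if len(find_longest_orf(pre)[2]) < 0.6 * expected:
            return pre, pads, expected
    raise InfeasibleTilingError(f"{name}: could not build ORF-less cryptogene")


def _pad_from_grna(rng, grna_rna: str) -> Tuple[str, Dict[int, int]]:
    """Backbone fragment + threaded U counts such that the gRNA forms a full
    all-WC/GU duplex with the fragment once edited to those counts.

    Walking the gRNA 5'->3' corresponds to walking the mRNA 3'->5'.  Each
    gRNA base either pairs a backbone base (which is emitted: G pairs C, U
    pairs A or wobbles with G, C pairs G) or guides a U insertion (A always,
    G when chosen as a wobble guide).  U prescriptions falling outside the
    emitted fragment (before the first or after the last backbone pair, whose
    flanking backbone base the duplex would not cover) are discarded.  The
    first three gRNA bases avoid wobble choices so the duplex ends in clean
    Watson-Crick pairs at its mRNA-3' anchor.

    Returns (fragment 5'->3', {fragment index j (1..m-1): Us preceding
    fragment base j}).
    """
    frag_rev: List[str] = []        # backbone bases in emission (3'->5') order
    pend_by_rev_idx: Dict[int, int] = {}
    for k, c in enumerate(grna_rna):
        anchor = k < 3
        if c == "A":  # pairs only U: always a guided insertion
            if frag_rev:
                i = len(frag_rev) - 1
                pend_by_rev_idx[i] = pend_by_rev_idx.get(i, 0) + 1
        elif c == "G":
            if not anchor and rng.random() < 0.25 and frag_rev:
                i = len(frag_rev) - 1  # G:U wobble-guided U
                pend_by_rev_idx[i] = pend_by_rev_idx.get(i, 0) + 1
            else:
                frag_rev.append("C")
        elif c == "U":
            frag_rev.append("A" if (anchor or rng.random() < 0.8) else "G")
        else:  # C pairs G
            frag_rev.append("G")
    m = len(frag_rev)
    frag = "".join(reversed(frag_rev))
    # Us attributed to emission index i precede fragment base j = m - 1 - i;
    # j == 0 would need a flanking base outside the duplex, so it is dropped
    counts = {
        m - 1 - i: n for i, n in pend_by_rev_idx.items() if m - 1 - i >= 1
    }
    return frag, counts


# ---------------------------------------------------------------------------
# the generator


def simulate_kdna(config: SimConfig, out_dir=None) -> GroundTruth:
    """Plant a maxicircle, minicircle repertoire, gRNA cascades and edited
    mRNAs; deterministic given ``config.seed``.

    When ``out_dir`` is given, writes ``maxicircle.fasta``,
    ``minicircles.fasta``, ``edited_mrnas.fasta``, ``pre_edited.fasta``,
    ``features.gff3`` and ``ground_truth.json`` there.
    """
    rng = np.random.default_rng(config.seed)
    n_minicircles = config.resolved_n_minicircles()
    truth = GroundTruth(config=config)

    # --- transcripts and cascades -------------------------------------
    pan_names = (_PAN_NAMES + [f"PAN{i}" for i in range(len(_PAN_NAMES), 99)])[
        : len(config.pan_cascade_sizes)
    ]
    minimal_names = (_MINIMAL_NAMES + [f"MIN{i}" for i in range(99)])[
        : len(config.minimal_cascade_sizes)
    ]
    sto_names = (_STOCHASTIC_NAMES + [f"STO{i}" for i in range(99)])[
        : config.n_stochastic_cryptogenes
    ]
    unedited_names = (_UNEDITED_NAMES + [f"GEN{i}" for i in range(99)])[
        : config.n_unedited_genes
    ]

    # terminal stop assignment over the translatable mRNAs; for the default
    # eleven-gene set this yields the canonical 8 UAA : 3 UAG split
    translatable = unedited_names + pan_names + minimal_names
    stop_of = {
        name: ("TAG" if i % 4 == 1 else "TAA")
        for i, name in enumerate(translatable)
    }

    gene_seqs: Dict[str, str] = {}
    for name in unedited_names:
        gene_seqs[name] = _random_cds(
            rng, config.unedited_gene_codons, stop_of[name]
        )

    cascade_windows: Dict[str, List[Tuple[int, int]]] = {}
    for name, k in list(zip(pan_names, config.pan_cascade_sizes)) + list(
        zip(minimal_names, config.minimal_cascade_sizes)
    ):
        minimal = name in minimal_names
        edited, pre, e_counts, windows, prot_len = _build_edited_cryptogene(
            rng, name, k, config, stop=stop_of[name], minimal=minimal
        )
        truth.edited_mrnas[name] = edited
        truth.pre_edited[name] = pre
        truth.edited_ucounts[name] = e_counts
        truth.expected_protein_len[name] = prot_len
        cascade_windows[name] = windows

    # --- guide RNAs ----------------------------------------------------
    grna_serial = 0

    def new_grna(target: Optional[str], a: int, b: int, orphan=False) -> GuideRNA:
        nonlocal grna_serial
        grna_serial += 1
        gid = f"g{grna_serial:03d}"
        if orphan:
            seq = _random_seq(rng, int(rng.integers(*config.grna_len_range))).replace(
                "T", "U"
            )
        else:
            seq = _grna_from_window(truth.edited_mrnas[target], a, b)
        g = GuideRNA(id=gid, source="", strand="-", gene_start=-1, gene_end=-1, seq=seq)
        truth.grnas[gid] = g
        if not orphan:
            truth.grna_targets[gid] = (target, a, b)
        return g

    minicircle_grnas: List[GuideRNA] = []
    for name in pan_names:
        ids = []
        for (a, b) in cascade_windows[name]:
            g = new_grna(name, a, b)
            ids.append(g.id)
            minicircle_grnas.append(g)
        truth.cascades[name] = ids
        n_extra = int(round((config.redundancy - 1.0) * len(ids)))
        dom_lo = cascade_windows[name][-1][0]
        dom_hi = cascade_windows[name][0][1]
        for _ in range(max(0, n_extra)):
            l = int(rng.integers(*config.grna_len_range))
            a = int(rng.integers(dom_lo, dom_hi - l + 1))
            g = new_grna(name, a, a + l)
            minicircle_grnas.append(g)
    maxicircle_grnas: List[GuideRNA] = []
    for name in minimal_names:
        ids = []
        for (a, b) in cascade_windows[name]:
            g = new_grna(name, a, b)
            ids.append(g.id)
            maxicircle_grnas.append(g)
        truth.cascades[name] = ids
    orphans = [new_grna(None, 0, 0, orphan=True) for _ in range(config.n_orphan_grnas)]

    # --- stochastic cryptogenes (gRNAs lost) ---------------------------
    pool = minicircle_grnas
    for name in sto_names:
        pre, pads, expected = _build_stochastic_cryptogene(rng, name, config, pool)
        truth.pre_edited[name] = pre
        truth.pads[name] = pads
        truth.expected_protein_len[name] = expected

    # --- maxicircle assembly -------------------------------------------
    order = (
        [(n, "unedited") for n in unedited_names]
        + [(n, "pan") for n in pan_names]
        + [(n, "minimal") for n in minimal_names]
        + [(n, "stochastic") for n in sto_names]
    )
    parts: List[str] = []
    pos = 0
    spacer_lo, spacer_hi = config.maxicircle_spacer_range
    pending_maxi = list(maxicircle_grnas)
    for name, kind in order:
        spacer = _random_seq(rng, int(rng.integers(spacer_lo, spacer_hi + 1)))
        if pending_maxi:
            g = pending_maxi.pop(0)
            spacer = _plant_gene_in_segment(rng, spacer, g, truth, pad=6)
        parts.append(spacer)
        pos += len(spacer)
        seq = gene_seqs.get(name, truth.pre_edited.get(name))
        truth.loci.append(Locus(name, kind, pos, pos + len(seq), "+"))
        parts.append(seq)
        pos += len(seq)
    parts.append(_random_seq(rng, int(rng.integers(spacer_lo, spacer_hi + 1))))
    truth.maxicircle = "".join(parts)
    _resolve_planted_coords(truth, "maxicircle", truth.maxicircle, maxicircle_grnas)
    for name in unedited_names:
        truth.gene_mrnas[name] = gene_seqs[name]
        truth.expected_protein_len[name] = len(find_longest_orf(gene_seqs[name])[2])

    # --- minicircles ---------------------------------------------------
    mc_grna_assignment = _assign_grnas_to_circles(
        rng, [g.id for g in minicircle_grnas], [g.id for g in orphans],
        n_minicircles, config,
    )
    for i, gene_ids in enumerate(mc_grna_assignment):
        small = _is_small_circle(i, len(mc_grna_assignment), config)
        mc = _build_minicircle(rng, f"mc{i + 1:02d}", gene_ids, truth, config, small)
        truth.minicircles.append(mc)

    if out_dir is not None:
        write_truth_files(truth, out_dir)
    return truth


def _plant_gene_in_segment(rng, segment: str, g: GuideRNA, truth, pad: int) -> str:
    """Embed a gRNA gene (minus strand) into a segment, with three forced
    non-pairing flank bases on each side; the gene position is resolved to
    global coordinates later by exact search."""
    gene_plus = revcomp(g.seq.replace("U", "T"))
    target = truth.grna_targets.get(g.id)
    left = right = ""
    if target is not None:
        name, a, b = target
        mrna = truth.edited_mrnas[name]
        # gRNA 5' end corresponds to the plus-strand segment end; extensions
        # there pair mRNA bases 3' of the window, and vice versa
        right = "".join(_mm_flank_base(mrna[b + t], rng) for t in range(3))
        left = "".join(_mm_flank_base(mrna[a - 1 - t], rng) for t in range(3))[::-1]
    insert = left + gene_plus + right
    if len(segment) < len(insert) + 2 * pad:
        segment = segment + _random_seq(rng, len(insert) + 2 * pad - len(segment))
    lo = pad
    return segment[:lo] + insert + segment[lo + len(insert):]


def _resolve_planted_coords(truth, source_id, source_seq, grnas):
    for g in grnas:
        gene_plus = revcomp(g.seq.replace("U", "T"))
        start = source_seq.find(gene_plus)
        if start < 0:  # pragma: no cover - construction guarantees presence
            raise RuntimeError(f"planted gene {g.id} not found on {source_id}")
        g.source = source_id
        g.gene_start = start
        g.gene_end = start + len(gene_plus)
        g.strand = "-"
        truth.loci.append(Locus(g.id, "grna", g.gene_start, g.gene_end, "-"))


def _assign_grnas_to_circles(rng, cascade_ids, orphan_ids, n_circles, cfg):
    """Distribute gRNA ids over minicircles; orphans occupy the last circles,
    double-gene circles come from the cascade pool."""
    per = cfg.grnas_per_minicircle
    n_orphan_circles = len(orphan_ids)
    n_cascade_circles = n_circles - n_orphan_circles
    ids = list(cascade_ids)
    rng.shuffle(ids)
    assignment: List[List[str]] = []
    double_idx = set()
    if per == 1 and cfg.n_double_grna_minicircles:
        want = min(cfg.n_double_grna_minicircles, n_cascade_circles)
        base = min(13, n_cascade_circles - 1)
        idx = base
        while len(double_idx) < want:
            double_idx.add(idx % n_cascade_circles)
            idx += 1
    it = iter(ids)
    for i in range(n_cascade_circles):
        take = per + (1 if i in double_idx and per == 1 else 0)
        circle = []
        for _ in range(take):
            nxt = next(it, None)
            if nxt is not None:
                circle.append(nxt)
        assignment.append(circle)
    for oid in orphan_ids:
        assignment.append([oid])
    return assignment


def _is_small_circle(i: int, n: int, cfg: SimConfig) -> bool:
    if cfg.n_small_minicircles <= 0:
        return False
    smalls = set()
    base = min(33, n - 1)
    j = base
    while len(smalls) < min(cfg.n_small_minicircles, n):
        smalls.add(j % n)
        j += 1
    return i in smalls


def _build_minicircle(rng, mc_id, gene_ids, truth, cfg, small) -> MinicircleTruth:
    L = (
        cfg.small_minicircle_len
        if small
        else int(rng.integers(cfg.minicircle_len_range[0], cfg.minicircle_len_range[1] + 1))
    )
    seq = _random_seq(rng, L)

    def put(s, pos, frag):
        return s[:pos] + frag + s[pos + len(frag):]

    csb1_pos = [10, L // 2 + 10]
    csb3_pos = [40, L // 2 + 40]
    for p in csb1_pos:
        seq = put(seq, p, cfg.csb1)
    for p in csb3_pos:
        seq = put(seq, p, cfg.csb3)
    ir = None
    if not small:
        arm = _random_seq(rng, cfg.ir_arm_len)
        a1 = (3 * L) // 4
        a2 = a1 + cfg.ir_arm_len + 40
        seq = put(seq, a1, arm)
        seq = put(seq, a2, revcomp(arm))
        ir = (a1, a1 + cfg.ir_arm_len, a2, a2 + cfg.ir_arm_len)

    gene_centers = [L // 4] + ([2 * L // 3] if len(gene_ids) > 1 else [])
    genes: List[PlantedGene] = []
    gram_pos: List[int] = []
    for gid, center in zip(gene_ids, gene_centers):
        g = truth.grnas[gid]
        gene_plus = revcomp(g.seq.replace("U", "T"))
        target = truth.grna_targets.get(gid)
        left = right = ""
        if target is not None:
            name, a, b = target
            mrna = truth.edited_mrnas[name]
            right = "".join(_mm_flank_base(mrna[b + t], rng) for t in range(3))
            left = "".join(_mm_flank_base(mrna[a - 1 - t], rng) for t in range(3))[::-1]
        insert = left + gene_plus + right
        start = center - len(insert) // 2
        seq = put(seq, start, insert)
        gs = start + len(left)
        ge = gs + len(gene_plus)
        g.source = mc_id
        g.gene_start, g.gene_end, g.strand = gs, ge, "-"
        genes.append(PlantedGene(gid, gs, ge, "-"))
        if not small:
            gp = gs - len(cfg.gram) - 12
            seq = put(seq, gp, cfg.gram)
            gram_pos.append(gp)
    return MinicircleTruth(mc_id, seq, csb1_pos, csb3_pos, gram_pos, ir, genes)


# ---------------------------------------------------------------------------
# read simulation


def _apply_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = [b for b in DNA if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def _staged_sequence(truth: GroundTruth, name: str, progress: float) -> str:
    """Editing intermediate: edited at sites 3' of the breakpoint, pre-edited
    5' of it (the cascade's 3'->5' progression)."""
    table = truth.site_table(name)
    e = truth.edited_ucounts[name]
    g = table.site_ucount
    n = table.n_sites
    breakpoint_site = int(round((1.0 - progress) * n))
    mixed = [e[i] if i >= breakpoint_site else g[i] for i in range(n)]
    return table.rebuild(mixed)


def simulate_reads(truth: GroundTruth, config: SimConfig, out_dir=None):
    """Sample the read libraries from a planted ground truth.

    Returns ``{"mrna": [...], "smallrna_r1": [...], "smallrna_r2": [...],
    "kdna": [...]}`` with (id, sequence, quality) triples, and records each
    read's origin in ``truth.read_origins``.  Coverage 0 yields empty, valid
    libraries.
    """
    rng = np.random.default_rng(config.seed + 1)
    rl = config.read_len
    stages = [p for p, _ in config.editing_stage_distribution]
    stage_p = [w for _, w in config.editing_stage_distribution]
    out = {"mrna": [], "smallrna_r1": [], "smallrna_r2": [], "kdna": []}

    # (a) mRNA reads at staged editing intermediates
    serial = 0
    for loc in truth.loci:
        if loc.kind == "grna":
            continue
        if loc.kind in ("unedited",):
            variants = {0: truth.gene_mrnas[loc.name]}
        elif loc.kind in ("pan", "minimal"):
            variants = {
                i: _staged_sequence(truth, loc.name, stages[i])
                for i in range(len(stages))
            }
        else:  # stochastic: per-read random U-indel patterns
            variants = None
        tlen = len(truth.pre_edited.get(loc.name, truth.gene_mrnas.get(loc.name, "")))
        n_reads = int(math.ceil(config.coverage * tlen / rl)) if tlen else 0
        table = truth.site_table(loc.name) if variants is None else None
        for _ in range(n_reads):
            if variants is None:
                seq, meta = _stochastic_read_template(rng, table), {"stage": "random"}
            elif len(variants) == 1:
                seq, meta = variants[0], {"stage": None}
            else:
                si = int(rng.choice(len(stages), p=stage_p))
                seq, meta = variants[si], {"stage": stages[si]}
            if len(seq) <= rl:
                start, frag = 0, seq
            else:
                # end-inclusive fragment starts: transcript termini are
                # covered at full depth (shorter terminal fragments), as in
                # fragmented sequencing libraries
                min_frag = 40
                start = int(rng.integers(-(rl - min_frag), len(seq) - min_frag + 1))
                start = max(start, 0)
                frag = seq[start : start + rl]
            serial += 1
            rid = f"mrna.{loc.name}.{serial}"
            out["mrna"].append((rid, _apply_errors(rng, frag, config.error_rate), "I" * len(frag)))
            truth.read_origins[rid] = {"locus": loc.name, "start": start, **meta}

    # (b) paired small-RNA reads of the gRNAs
    tail_lens = [l for l, _ in config.tail_len_distribution]
    tail_p = [w for _, w in config.tail_len_distribution]
    for gid, g in truth.grnas.items():
        for j in range(config.smallrna_reads_per_grna):
            tl = int(rng.choice(len(tail_lens), p=tail_p))
            tlen = tail_lens[tl]
            tbase = "T" if rng.random() < 0.65 else "A"
            insert = g.seq.replace("U", "T") + tbase * tlen
            r1 = (insert + config.adapter_seq + _random_seq(rng, rl))[:rl]
            r2 = (revcomp(insert) + config.adapter_seq + _random_seq(rng, rl))[:rl]
            rid = f"srna.{gid}.{j + 1}"
            out["smallrna_r1"].append(
                (rid, _apply_errors(rng, r1, config.error_rate), "I" * len(r1))
            )
            out["smallrna_r2"].append(
                (rid, _apply_errors(rng, r2, config.error_rate), "I" * len(r2))
            )
            truth.read_origins[rid] = {"grna": gid, "tail": tbase * tlen}

    # (c) genomic kDNA fragments
    serial = 0
    sources = [("maxicircle", truth.maxicircle, False)] + [
        (mc.id, mc.seq, True) for mc in truth.minicircles
    ]
    for name, seq, circular in sources:
        n_reads = int(math.ceil(config.kdna_coverage * len(seq) / rl))
        doubled = seq + seq if circular else seq
        for _ in range(n_reads):
            hi = len(seq) if circular else max(1, len(seq) - rl + 1)
            start = int(rng.integers(0, hi))
            frag = doubled[start : start + rl]
            serial += 1
            rid = f"kdna.{name}.{serial}"
            out["kdna"].append((rid, _apply_errors(rng, frag, config.error_rate), "I" * len(frag)))
            truth.read_origins[rid] = {"source": name, "start": start}

    if out_dir is not None:
        write_read_files(out, out_dir)
    return out


def _stochastic_read_template(rng, table: EditingSiteTable) -> str:
    """A transcript copy carrying random, gRNA-free U-indels."""
    counts = list(table.site_ucount)
    n = table.n_sites
    k = int(rng.integers(8, 26))
    sites = rng.choice(np.arange(3, n - 3), size=min(k, n - 6), replace=False)
    for s in sites:
        s = int(s)
        delta = int(rng.integers(1, 4))
        if counts[s] == 0 or rng.random() < 0.6:
            counts[s] += delta
        else:
            counts[s] = max(0, counts[s] - delta)
    return table.rebuild(counts)


def simulate_misguided_reads(
    truth: GroundTruth,
    config: SimConfig,
    cryptogene_id: str,
    n_reads: int = 60,
    guided_fraction: float = 0.8,
    seed: Optional[int] = None,
):
    """Reads whose editing is part non-cognate-guided, part random.

    Each read carries the full threaded editing pattern of one planted
    landing pad (sites guided by a known gRNA of another transcript) plus
    enough additional random-count edited sites to make guided sites a
    ``guided_fraction`` share of its edited sites.  Returns
    ``(reads, labels)`` where labels maps read id to its guided and random
    site sets (the brute-force attribution ground truth).
    """
    rng = np.random.default_rng(config.seed + 7 if seed is None else seed)
    table = truth.site_table(cryptogene_id)
    pads = truth.pads[cryptogene_id]
    if not pads:
        raise ValueError(f"{cryptogene_id}: no landing pads planted")
    ref = table.site_ucount
    pad_sites = set()
    for p in pads:
        pad_sites.update(range(p.first_site - 2, p.last_site + 3))
    reads, labels = [], {}
    for j in range(n_reads):
        pad = pads[int(rng.integers(0, len(pads)))]
        counts = list(ref)
        for s, u in pad.guided_ucount.items():
            counts[s] = u
        guided = sorted(s for s, u in pad.guided_ucount.items() if u != ref[s])
        n_rand = int(round(len(guided) * (1.0 - guided_fraction) / guided_fraction))
        lo = max(3, pad.first_site - 45)
        hi = min(table.n_sites - 3, pad.last_site + 45)
        candidates = [s for s in range(lo, hi) if s not in pad_sites]
        rng.shuffle(candidates)
        randoms = []
        for s in candidates:
            if len(randoms) >= n_rand:
                break
            delta = int(rng.integers(1, 4))
            counts[s] = counts[s] + delta if (counts[s] == 0 or rng.random() < 0.6) else max(0, counts[s] - delta)
            if counts[s] != ref[s]:
                randoms.append(s)
        span_lo = min([pad.first_site] + randoms) - 2
        span_hi = max([pad.last_site] + randoms) + 2
        seq = table.rebuild(counts)
        frag = _slice_by_sites(table, counts, span_lo, span_hi, seq)
        rid = f"mis.{cryptogene_id}.{j + 1}"
        reads.append((rid, frag, "I" * len(frag)))
        labels[rid] = {"guided": set(guided), "random": set(randoms)}
    return reads, labels


def _slice_by_sites(table, counts, site_lo, site_hi, rebuilt) -> str:
    """Slice a rebuilt sequence so it spans backbone bases
    ``site_lo - 1 .. site_hi`` (clamped), with sites interior to the read."""
    pos = 0
    starts = []
    for i, b in enumerate(table.backbone):
        pos += counts[i]
        starts.append(pos)
        pos += 1
    lo_bb = max(0, site_lo - 1)
    hi_bb = min(len(table.backbone) - 1, site_hi)
    return rebuilt[starts[lo_bb] : starts[hi_bb] + 1]


# ---------------------------------------------------------------------------
# file output


def write_fasta(path, records):
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fastq(path, reads):
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_truth_files(truth: GroundTruth, out_dir):
    from .annotate import gff3_lines

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "maxicircle.fasta", [("maxicircle", truth.maxicircle)])
    write_fasta(out / "minicircles.fasta", [(m.id, m.seq) for m in truth.minicircles])
    write_fasta(out / "edited_mrnas.fasta", sorted(truth.edited_mrnas.items()))
    write_fasta(out / "pre_edited.fasta", sorted(truth.pre_edited.items()))
    write_fasta(
        out / "grnas.fasta", [(g.id, g.seq.replace("U", "T")) for g in truth.grnas.values()]
    )
    rows = []
    for loc in truth.loci:
        ftype = "gRNA_gene" if loc.kind == "grna" else "gene"
        rows += gff3_lines(
            "maxicircle",
            [(ftype, loc.start, loc.end, loc.strand, {"ID": loc.name, "kind": loc.kind})],
        )
    for mc in truth.minicircles:
        feats = []
        for p in mc.csb1:
            feats.append(("CSB1", p, p + len(truth.config.csb1), "+", {"ID": f"{mc.id}.csb1.{p}"}))
        for p in mc.csb3:
            feats.append(("CSB3", p, p + len(truth.config.csb3), "+", {"ID": f"{mc.id}.csb3.{p}"}))
        for p in mc.gram:
            feats.append(("GRAM", p, p + len(truth.config.gram), "+", {"ID": f"{mc.id}.gram.{p}"}))
        if mc.ir:
            feats.append(("inverted_repeat", mc.ir[0], mc.ir[3], "+", {"ID": f"{mc.id}.ir"}))
        for g in mc.genes:
            feats.append(("gRNA_gene", g.start, g.end, g.strand, {"ID": g.grna_id}))
        rows += gff3_lines(mc.id, feats)
    (out / "features.gff3").write_text("##gff-version 3\n" + "\n".join(rows) + "\n")
    summary = {
        "seed": truth.config.seed,
        "n_minicircles": len(truth.minicircles),
        "grnas": {
            gid: {
                "source": g.source,
                "start": g.gene_start,
                "end": g.gene_end,
                "strand": g.strand,
                "target": truth.grna_targets.get(gid),
            }
            for gid, g in truth.grnas.items()
        },
        "cascades": truth.cascades,
        "expected_protein_len": truth.expected_protein_len,
        "loci": [[l.name, l.kind, l.start, l.end, l.strand] for l in truth.loci],
    }
    (out / "ground_truth.json").write_text(json.dumps(summary, indent=1, sort_keys=True))


def write_read_files(reads, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fastq(out / "mrna.fastq", reads["mrna"])
    write_fastq(out / "smallrna_R1.fastq", reads["smallrna_r1"])
    write_fastq(out / "smallrna_R2.fastq", reads["smallrna_r2"])
    write_fastq(out / "kdna.fastq", reads["kdna"])
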