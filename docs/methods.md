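# Methods

`kedit` implements the computational workflow for characterising a
trypanosomatid kinetoplast (mitochondrial) genome and its U-indel-edited
transcriptome, together with a ground-truthed simulator that plants every
structure the downstream analyses are supposed to recover.  This note
documents the models, the parameter choices and their rationale, the
numerical details, and the limits of what the simulation-based validation
shows.

## The biological model

Kinetoplastid mitochondria encode many proteins as *cryptogenes*: loci whose
transcripts only acquire an open reading frame after uridines (U) are
inserted and deleted at specific sites.  Editing is directed by short guide
RNAs (gRNAs), mostly encoded on minicircles, that base pair with the mRNA in
antiparallel orientation using Watson-Crick and G:U wobble pairs.  Because a
gRNA's 5' "anchor" must pair with sequence 3' of the sites it edits, and that
sequence is itself the product of the preceding gRNA, editing progresses
3'->5' as an ordered cascade.  Stripping Ts from read and reference makes
mapping invariant to editing state: the non-T backbone is conserved, and the
per-site U counts carry the entire editing signal.

## Module-by-module summary

### Duplex alignment (`kedit.duplex`)

Ungapped antiparallel windows between an RNA pair are classified per position
as Watson-Crick (`|`), G:U wobble (`:`) or mismatch (`#`).  A window is
reported when it satisfies, simultaneously: a nucleation seed (a
`seed_length` sub-window scoring at least `seed_score`), minimum length and
total score, caps on wobbles and mismatches, and `min_anchor` contiguous
Watson-Crick pairs at the mRNA-3' end of the duplex.  Windows describing the
same pairing locus (overlapping on both molecules) are pruned to the best
scoring one, ties resolved leftmost on the mRNA and then longest.  Two
presets exist:

| parameter    | canonical | relaxed |
|--------------|-----------|---------|
| seed_score   | 24        | 20      |
| seed_length  | 16        | 16      |
| min_length   | 25        | 21      |
| min_score    | 35        | 25      |
| max_gu       | 12        | 17      |
| max_mismatch | 2         | 4       |
| min_anchor   | 4         | 2       |

The relaxed set is the published configuration for scoring potential guiding
in hyper-edited reads; the canonical set is this package's stricter default
for gene discovery.  Per-pair scores are WC = +2, GU = +1, MM = -1, chosen
for self-consistency with those thresholds (a minimal 21-nt all-WC duplex
scores 42; a 16-nt seed of WC pairs scores 32) and exposed as parameters.
The reference tools' internal per-pair scores are not published, so this
scheme is an interpretation; all threshold semantics are boundary-exact and
tested one unit above and below.

Implementation: candidate windows are found by sliding the seed score along
anti-diagonals of the pairing matrix (a zero-copy strided view).  Because
every passing window must contain a passing seed window, the filter is
complete, and enumeration around candidates applies the remaining
constraints exactly.  The engine is validated against a brute-force
enumeration of all windows on hundreds of random and half-planted cases.

### Structural annotation (`kedit.annotate`)

* Motif scanning is exact over IUPAC code sets (no fuzzy matching), on both
  strands, across the origin of circular molecules.  CSB3 is the universal
  dodecamer `GGGGTTGGTGTG`; CSB1 the degenerate palindrome
  `YYRYRYRRRRYYYYRYRYRR`; the GRAM (gRNA-associated motif) has no published
  text consensus and is accepted only as a user-supplied pattern.
* Contig circularisation collapses a terminal exact direct repeat of at
  least 20 bp (`k_min`, configurable; chosen as far above chance for ~2 kb
  circles — no published value exists).  A repeat longer than half the
  contig is ambiguous and is reported as an error.
* Inverted repeats use a local self-versus-reverse-complement alignment
  with einverted-style scores: match +4, gap -14 (linear), threshold 40 as
  published, and mismatch -4 (unpublished; configurable).  The search is
  banded: arm separations up to 300 bp by default (`max_separation=None`
  removes the band).  Every report is validated by rescoring the arm pair.
* Minicircle class deduplication is greedy, longest first, under rotation-
  and strand-invariant identity (seed-anchored rotation followed by Hamming
  identity over the shorter length, normalised by the longer).  The default
  threshold 0.97 mirrors the small-RNA clustering threshold since no value
  is published for DNA classes.
* Re-orientation rotates a minicircle so the CSB block nearest its
  functional gRNA gene (circular distance; ties to the lower coordinate)
  sits at position 0, flipping the strand if needed so the gene lies
  opposite the CSBs.

### gRNA discovery (`kedit.discovery`)

Alignment-based annotation transcribes both strands of each minicircle and
of the maxicircle and aligns them against the fully edited mRNAs with the
canonical preset; passing loci are emitted as gene candidates and
overlapping loci merged.  On the maxicircle, the annotated gene/cryptogene
intervals are excluded: a locus's own minus strand is trivially
complementary to its unedited transcript regions and would otherwise be
called as a spurious "gRNA gene" at every locus.

Expression-based calling processes a paired small-RNA library: adapter
removal (exact internal occurrence, or a terminal adapter prefix of at
least 8 nt), a 15-nt minimum length, merging of completely overlapping
pairs (quality-weighted consensus), removal of one trailing 3' poly(U) or
poly(A) run of >= 3 nt (`min_tail`; a composite tail, e.g. U then A, is
removed only once — a documented limitation), greedy length-sorted
clustering at 97% identity (matches / shorter length at the best ungapped
offset — a CD-HIT-like short-read regime), per-column majority consensus,
and validation by mapping the consensus back to a source molecule (18-nt
exact seed, at most one mismatch overall).  Where alignment- and
expression-derived boundaries disagree, expression wins.

### Editing analysis (`kedit.editing`)

The editing-site table decomposes a cryptogene into its non-T backbone and
per-site reference U counts (site *i* = Us immediately 5' of backbone base
*i*, plus a terminal site); rebuilding is exact by construction.  Reads are
placed by locating their T-stripped backbone in the reference backbone
(pigeonhole-seeded exact search, at most one substitution by default, both
strands, unique best placement required; ties leave the read unassigned).
The two partial flanking sites of each read are censored from all edit
statistics.  A read counts as edited at >= 5 edited sites; hyper-edited
reads carry >= 10 U insertions plus deletions.

ORF reconstruction builds a graph over (site, observed U count) states with
edges between states co-observed at adjacent sites, weighted by read
support.  Seeded at the majority state of the 3'-most covered site, the
maximum-bottleneck path (ties: total support, then fewer edits relative to
the reference) defines the consensus U-count vector; uncovered sites keep
reference counts.  The rebuilt sequence is scanned in all three frames for
the longest stop-free codon run terminated by UAA or UAG under NCBI
translation table 4 (UGA = tryptophan).  Reconstruction fails when the best
terminated ORF is shorter than 85% of the expected protein length
(`min_orf_fraction`), reproducing the "failed to reconstruct" outcome for
transcripts edited only stochastically.  The bottleneck objective is an
interpretation (the reference implementation's objective is unpublished)
and is stated as such.

### Cascades (`kedit.cascade`)

Alignments are screened with the three published filters: (i) alignments
using source loci outside the refined gene boundaries are discarded;
(ii) alignments with three or more adjacent mismatches are discarded, where
G:U pairs interrupt a mismatch run (consistent with the rendering notation
that separates `:` from `#`); (iii) alignments with mismatch/length ratio
strictly above 1/8 are discarded.  The filters commute.  Chaining starts
from the 3'-most alignment; each successor must begin 5' of the frontier,
preferring the candidate reaching furthest 3'-ward (ties by score).
Overlaps with the predecessor are anchor overlaps; zero-length joints are
flagged "adjacent but not overlapping"; the redundancy profile counts
covering alignments per position over the edited domain (taken from the
reconstructed ORF's edited region).

### Non-cognate attribution (`kedit.noncognate`)

Each hyper-edited read is aligned against the complete gRNA set under the
relaxed preset.  An edited site is *explained* if at least one passing
duplex covers its U run together with both flanking backbone bases with no
mismatch at any of those positions — i.e. the guiding nucleotides (A or G
opposite U) prescribe exactly the observed count.  Semantics are
existential over alignments, and "editing events" are counted as sites, not
individual Us (a per-U mode would be a one-line change where the site
weight becomes `|obs - ref|`).  Group comparisons of alignment features
(length, G:U count, mismatches) use a two-sided Mann-Whitney rank-sum test,
exact for tie-free samples of at most 12, normal approximation with
continuity correction otherwise; the original analysis does not name its
test.

### Codon analyses (`kedit.coding`)

Codon incidence is the within-amino-acid synonymous fraction (an
alternative per-1000-codons normalisation is provided, as the figure-level
definition is not printed).  Stop usage tallies UAA versus UAG terminal
codons; TGA is tryptophan under code 4 and a TGA-terminal CDS is flagged as
stop-less.  Read-through codon usage compares each recoded codon against
its likely predecessors (TAA, TAG vs GAA/GAG; TGA vs TGG) as the proportion
recoded/(recoded + predecessor) per gene, with a rank-sum comparison
between gene groups.  The targeting-signal scan applies the anchored
pattern M-[RHKFL]-x(0,1)-[RKHST]-x(1,10)-[STRK], reporting the shortest
match by trying spacer lengths in order of increasing total length; it is
tested against exhaustive expansion of all 20 fixed-length variants.

## The simulator (`kedit.simulate`)

`simulate_kdna` plants, deterministically per seed:

* 41 minicircle classes (40 of 1920-2019 bp, one of 601 bp), each with two
  head-to-tail conserved regions (CSB1 + CSB3) at opposite poles, an
  inverted repeat (absent from the short class), and one gRNA gene on the
  strand opposite the CSBs with a GRAM motif planted 12 nt upstream; one
  class carries two genes, so 42 minicircle gRNA genes in total, two of
  them orphans with no mRNA target;
* a maxicircle with six unedited genes, three pan-edited cryptogenes whose
  cascades hold 14 + 13 + 13 = 40 gRNAs, two minimally edited cryptogenes
  served by three maxicircle-encoded gRNA loci, and five cryptogenes whose
  gRNAs are absent ("complex-I-like");
* fully edited mRNAs built as valid code-4 ORFs, with 35% of editing sites
  inside the edited domain carrying a U-indel difference from the
  pre-edited form; terminal stop codons are assigned so the default eleven
  translatable mRNAs use UAA eight times and UAG three times;
* cascades tiled 3'->5' with gRNAs of 40-50 nt and a 4-nt anchor overlap;
  planted gRNAs are perfect Watson-Crick complements of their mRNA window,
  and each gene is flanked on the source by three bases chosen to pair
  nothing, so the best duplex window coincides exactly with the planted
  gene (this is what makes coordinate-exact recovery a meaningful test);
* on each gRNA-less cryptogene, three "landing pads": backbone stretches
  compatible with a non-cognate gRNA such that threading that gRNA
  (pairing backbone bases, inserting Us opposite its A/G positions)
  produces an exactly-known guided editing pattern.

`simulate_reads` samples (a) mRNA fragments from staged editing
intermediates — a read is fully edited 3' of a breakpoint and pre-edited 5'
of it, matching the anchor-dependent cascade model; the default stage mix
is 70% fully edited, 10% half edited, 20% pre-edited, reflecting the
dominance of mature transcripts in poly(A)-selected libraries and giving
the mature form a clear per-site majority; (b) paired small-RNA reads of
every gRNA with 3' U or A tails (3-12 nt) and a sequencing adapter;
(c) genomic kDNA fragments.  Fragment starts are end-inclusive so
transcript termini are covered at full depth, as in fragmented libraries.
Sequencing noise is substitution-only, keeping the U-indel ground truth
unambiguous.  Reads from gRNA-less cryptogenes carry per-read random
U-indel patterns (8-25 sites, counts perturbed by 1-3), which is what makes
their consensus reconstruction fail while canonical cryptogenes still
reconstruct.

`simulate_misguided_reads` generates hyper-edited reads whose editing is a
planted mixture: the full guided pattern of one landing pad plus enough
random-count edited sites elsewhere to bring the guided share to a target
fraction (default 80%), with exact per-read ground-truth site labels.

### What the simulation does and does not show

The generator reproduces the *statistical structure* the analyses assume:
conserved motifs at fixed architectural positions, perfectly complementary
gRNA genes, strictly 3'->5' staged intermediates, clean adapter/tail
structure, substitution-only noise, and uniform coverage.  Passing the
round-trip tests therefore demonstrates that the algorithms invert the
generative model exactly at these scales — it does not demonstrate
robustness to assembly artefacts, indel sequencing errors, branched or
alternative editing pathways, expression heterogeneity between minicircle
classes, or base-composition biases of real kDNA, none of which are
modelled.  Tail stripping is intrinsically blind to a genuine gRNA-terminal
U run followed by a U tail; the consensus over reads with mixed tail types
resolves this in practice, but single-read boundaries can be short by the
length of that run.

## Problem sizes and numerical choices

The default study conditions (41 minicircles, ~9 kb maxicircle, ~2,000 mRNA
reads, ~1,350 small-RNA read pairs) run the full pipeline in roughly ten
seconds; the validation suite repeats the round trip over twenty seeds and
the acceptance script over three.  Determinism: one `numpy` generator
seeded from the configuration drives the genome build, and a second
(seed + 1) the read sampling; identical configurations produce
byte-identical output files.  Coordinates are 0-based half-open everywhere
internally; GFF3 output converts to 1-based closed.  Editing sites are
reported with genomic 5'->3' indices, with the 3'->5' cascade numbering
available as a conversion, since cascades progress 3'->5'.

## Known limitations

* Gapped duplexes are not modelled (guiding is represented as ungapped
  base pairing; U-indel differences live in the editing layer, not the
  duplex), and there is no thermodynamic duplex model.
* The inverted-repeat search reports up to 25 non-overlapping alignments
  and, with the default band, misses arm pairs separated by more than
  300 bp.
* `classify_minicircles` assumes near-identical circles share exact 15-mers
  (three seed positions are tried); classes diverged uniformly beyond ~7%
  at every seed would not be anchored, which is irrelevant at the 0.97
  threshold.
* The rank-sum exact p-value is only used for small tie-free samples;
  tied data fall back to the corrected normal approximation.
* Attribution treats a site covered by any conforming duplex as explained;
  no attempt is made to decide which gRNA acted when several could.
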