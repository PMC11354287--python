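# Methods

`plastevo` analyzes the structural evolution of plastid genomes
(plastomes): circular molecules with the canonical quadripartite layout
LSC + IRa + SSC + IRb, where the two inverted-repeat copies (IRa, IRb) are
reverse complements of each other. The package covers five analyses —
quadripartite detection and structural typing, dispersed-repeat landscapes,
long-read quantification of rare repeat-mediated recombination,
region-stratified substitution rates, and phylogenetic trait statistics —
plus a synthetic-data generator that realizes the statistical structure
those analyses assume, so the whole pipeline is testable end to end on a
desk machine.

## Coordinate and molecule conventions

All coordinates are 0-based half-open on the forward strand of the
published (linearized) origin; GFF3 I/O converts at the boundary. Circular
genomes are stored linearized; operations needing wraparound use the
doubled sequence and reduce positions modulo the length. Synthetic
molecules place the LSC start at position 0. N bases are excluded from
every GC numerator and denominator. Plastid coding sequences use the
bacterial/plastid genetic code (NCBI table 11).

## Synthetic-data generator

The generator is first-class, tested code, not a fixture. It emulates:

* **Quadripartite construction.** Region lengths default to LSC 14,000 bp,
  IR 6,500 bp, SSC 6,500 bp (~33.5 kb total) — roughly one-fifth of a real
  ~150-kb plastome, preserving the rank order and the LSC ≥ SSC
  constraint. GC equilibria default to LSC 0.36, IR 0.43, SSC 0.32,
  reproducing the IR-rich / SSC-poor contrast. An ordered marker-gene map
  places rps19 at the LSC/IRa border, the tRNAs trnR-ACG and trnN-GUU at
  the IRa/SSC border, ndhF at the SSC start, and the nine variably-located
  genes (ndhD, psaC, ndhE, ndhG, ndhI, ndhA, ndhH, rps15, ycf1) at the SSC
  end adjacent to IRb, mirroring the canonical gene neighborhood. CDS
  stand-ins are stop-free random codon strings at plausible (shortened)
  lengths.
* **Structural events.** An IR expansion re-labels the SSC-terminal block
  of named genes as IR and inserts its reverse complement at the IRa–SSC
  junction, so both IR copies carry the genes and the molecule grows by
  the block length — exactly how real boundary shifts duplicate genes.
  Inversions inside IRa are mirrored into IRb, so IRa/IRb identity is an
  invariant after every event. The bundled recipes produce the three
  structural types used throughout: type I (canonical), type II (five-gene
  expansion + nested large and ycf1-only inversions), type III (nine-gene
  expansion + ndhB..trnR-ACG inversion). A junction-shift event emulates
  the modest border-gene displacements behind minor types (e.g. rps19
  straddling J(LSC-IRa)).
* **Sequence evolution.** HKY85 with configurable transition bias
  (default κ = 2) and per-region GC equilibrium; per-site rate = branch
  length × region multiplier (single-copy vs IR). LSC, IRa and SSC evolve
  independently and each tip is reassembled with IRb = revcomp(IRa):
  perfect concerted evolution, the idealization of IR copy-correction
  (biased gene conversion). All randomness flows from one numpy generator.
* **Long reads.** HiFi-like: substitution errors only (default 0),
  lognormal lengths (default mean 12 kb, σ = 0.25) capped at the molecule
  length. Reads are drawn from an isomer mixture: the main configuration,
  the SSC-flipped (flip-flop) isomer at weight 0.5 — the two major isomers
  are equimolar in vivo — and recombinant isomers, each defined by one
  annotated inverted repeat pair, at weights capped at 0.05 (substoichiometric).
  The `exact_counts` mode pins totals exactly: non-recombinant reads are
  full-circle molecules (so each one overlaps every junction locus, making
  the requested total the per-junction denominator), and each recombinant
  read is a window centred on its novel junction.

**Boundary sharpness.** Exact junction recovery by the detector is only
well-defined if the bases flanking each junction do not happen to extend
the IR match; the generator enforces this by mutating at most two
single-copy spacer bases after assembly. Real plastomes offer no such
guarantee — on real data the detected boundaries are maximal-identity
boundaries, which may differ from annotation by a few bases.

**Observability of isomer origin.** A flip-flop read that does not span an
entire IR copy plus unique anchors in both single-copy regions is an exact
reverse-complement substring of the main isomer; no mapper can distinguish
it. The truth table therefore records both the isomer of origin and the
*expected observable class* of each read, and classifier accuracy is
asserted against the latter. With ~6.5–9.6 kb synthetic IRs and 12-kb
reads a useful fraction of flip reads is informative; with real ~25-kb IRs
the informative fraction is smaller — a genuine property of the assay, not
of the implementation.

What the generator does **not** emulate: indel and structural read errors,
chimeric library artifacts, nuclear-plastid transfers, rate heterogeneity
along branches, and selection on codons (CDS stand-ins are neutral).
Passing tests therefore demonstrate algorithmic correctness under the
stated model, not robustness to every artifact of real sequencing data.

## Quadripartite detection and typing

The detector seeds exact k-mers (k = 25) of the doubled forward sequence
against the doubled reverse complement, groups hits by circular diagonal,
extends through isolated mismatches (a mismatch is crossed only if ≥19 of
the next 20 bases match), and keeps the longest disjoint inverted arc pair
with length ≥ `min_ir_len` (default 1,000 bp — far below real ~24-kb IRs
but above dispersed-repeat scale) and identity ≥ `min_identity` (default
0.99). Doubling makes detection rotation invariant; a genome without a
qualifying pair returns "no IR" rather than erroring. The longer
single-copy arc is LSC; on ties, the arc holding rbcL (else more genes).

Typing uses the signed order of ndhB, ycf1 and trnR-ACG inside IRa,
read from the LSC-side junction with strands compared to the canonical
layout: canonical order and strand → type I (with or without expansion);
ndhB inverted with ycf1 first → type II; ndhB inverted with trnR-ACG
first → type III; anything else is reported unclassifiable with its
evidence. Minor types come from which border gene straddles an IR
junction (rps19 → a, ndhF → b, ycf1 → c); the measured offsets are always
reported and the a/b/c mapping is a configurable rule, since real minor
types are defined only qualitatively.

Gene-order inversions between two genomes are found on signed
permutations of shared genes with one IR copy dropped. For genes
duplicated in only one genome the copy choice is ambiguous; each
contiguous run of such genes is resolved to the choice (IRa-side or
IRb-side) minimizing gene-order breakpoints, IRa side on ties. This
parsimony rule makes an IR expansion look like what it is — a
translocation, not an inversion — at the cost that an inversion nested
entirely inside the translocated block (the ycf1-only event of type II)
is absorbed into the ambiguity and not separately resolvable from gene
order alone. Breakpoints are reported as inter-anchor intervals, never
single coordinates, because anchor-level resolution is all gene-order
data supports.

## Dispersed repeats

Gapless seed-and-extend self-comparison (seed k = 7, echoing a word size
of 7; match +2, mismatch −3; X-drop 12) with the IRb region masked, both
orientations, minimum length 30 bp (the threshold used for
recombination-competent repeats) and minimum identity 0.90; a score floor
(default 40) stands in for an e-value cutoff. At `min_identity = 1`
extension is exact and the output provably equals the set of maximal
exact matches, which the test suite verifies against an exhaustive
all-diagonals oracle on 5-kb instances. Tandem-like self-overlapping
pairs are excluded (tandem repeats are out of scope). Counts are
reported per pair and lengths both per pair (binned: ≤200, 201–500,
501–1,000, >1,000 bp) and as the merged footprint, because both
summaries are in common use and conflating them is a classic error.

## Long-read recombination

The internal mapper indexes 31-mers of the doubled reference and chains
exact anchors by (strand, diagonal) — valid because HiFi-like errors are
substitutions, which never shift the diagonal. Segments are extended at
their ends through scattered mismatches, filtered greedily by new read
coverage, and trimmed to be non-overlapping on the read (overlaps across
a repeat copy are cut at the midpoint, which is also where crossover
position is genuinely ambiguous). External split alignments are accepted
as a documented TSV.

Classification: one collinear segment → concordant; every breakpoint
inside IR homology with a strand change → flip-flop (the IR is exactly
the homology through which the two major isomers interconvert); exactly
two flanks joining through a cataloged dispersed repeat pair (endpoints
within ±80 bp of the two copies) → recombinant with that junction id;
otherwise ambiguous. Because the catalog is built with one IR copy
masked, the IR itself is never a "repeat pair" and flip-flop reads cannot
be called recombinant.

Only reads with ≥98% of their length aligned are counted (full-length
rule, which on real data suppresses nuclear-plastid transfer fragments).
Per-junction frequency is 100·s/n rounded half-up to two decimals; the
denominator n counts full-length reads whose alignment covers either
repeat copy plus 1 kb on both flanks (plus the supporting reads), which
is why junction totals differ within one read set.

## Substitution rates

Loci are stratified as CSC (single-copy in all taxa), CIR (IR in all
taxa) or VSR (variable), with a gene counting as single-copy in a taxon
when fewer than 40 nt lie inside the IR; loci under 150 bp after
excluding gapped columns are dropped. Estimation is distance-based:
Nei–Gojobori (1986) with Jukes–Cantor correction for dS/dN (synonymous
sites averaged over the pair, pathway-averaged differences, stop-codon
pathways excluded unless all are blocked; p ≥ 3/4 flagged as saturated
nan, with a 1e-9 tolerance against float ties), and closed-form JC69 /
K80 / GTR nucleotide distances (GTR via −tr(Π log(Π⁻¹F)) on the
symmetrized divergence matrix). Branch lengths on the fixed topology come
from non-negative least squares over the tip-pair path equations
(negative solutions are impossible by construction; residual norm
reported). Clade rates are mean root-to-tip cumulative branch lengths
(mean rather than median; configurable), and translocation effects are
ratios of those clade means against the CSC concatenation. Note the
root-adjacent edge split is not identifiable from distances alone; ratios
are unaffected because numerator and denominator are fitted on the same
topology with proportional signal.

## Composition

GC by codon position over CDS sets, RSCU (observed count over the mean of
the synonymous family, stop codons excluded, unused families reported
missing — family sums equal the family size by construction), and the GC
change of a locus between a clade where it sits in the IR and one where
it is single-copy (positive = GC rose upon translocation).

## Statistics

Wilcoxon rank-sum with exact permutation enumeration up to a combined
n of 20 (ties handled by mid-ranks) and a tie/continuity-corrected normal
approximation beyond; Bonferroni adjustment with the family size
configurable, since family boundaries are an analysis choice. OLS with
adjusted R². PGLS under Brownian motion with C the shared root-path
length matrix and the textbook GLS estimator — on a star phylogeny this
reduces to OLS exactly, which is tested to machine precision. Blomberg's
K uses the GLS phylogenetic mean, the C-corrected MSE and the Brownian
expectation (tr C − n/(1ᵀC⁻¹1))/(n−1); its permutation p-value is the
fraction of tip-shuffles with K at least the observed value. K and the
PGLS coefficients are pinned against R reference implementations
(phytools/picante, and the explicit GLS solve with ape's vcv) on a frozen
fixture. K values far above 1 (as real clade-structured plastome traits
produce) arise here only from deliberately clade-clustered synthetic
traits; reproducing any particular published K requires the real tree and
traits.

## Problem sizes and determinism

Default test-scale runs use ~33–38 kb genomes, 10-kb concatenations with
12 taxa, hundreds to ~1,500 reads, and ≤999 permutations; the full test
suite runs in a few minutes on one CPU. Every stochastic component takes
an explicit seed; the pipeline writes a manifest of parameter hashes and
output checksums, reruns reproduce identical checksums, and a corrupted
intermediate is regenerated on rerun.

## Known limitations

Gene-order inversion detection cannot resolve events nested inside
IR-translocated blocks (see above). The repeat finder's extension is
greedy and can over- or under-shoot fuzzy repeat boundaries by a few
bases at identity < 1. The mapper assumes substitution-only errors; indels
would break diagonal chaining and require banded alignment. The GTR
distance is undefined (nan) near saturation. Minor-type letters are a
convention over measured offsets, not a biological invariant.
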