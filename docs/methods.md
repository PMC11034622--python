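# Methods

## Scope and model

`mitocompare` analyzes annotated circular insect mitochondrial genomes:
the 37-gene inventory (13 protein-coding genes, 22 tRNAs, 2 rRNAs) plus a
control region. Its core is a gene-order rearrangement analysis for
crickets (Gryllidea), surrounded by the standard sequence-level
characterizations (composition and strand skews, codon usage, a
Nei–Gojobori selection/numt screen) and phylogenomic matrix preparation.
A deterministic simulator generates annotated genomes so every statistic
is exercisable without downloads.

## Gene orders and conventions

A gene order is the cyclic sequence of (gene, strand) pairs read in the
ascending-coordinate direction of the deposited strand, control region
excluded. Two conventions are fixed deliberately:

* **Reading direction.** Literature descriptions of the rRNA block are
  direction-ambiguous ("12S-trnV-16S" and "16S-trnV-12S" describe the
  same cycle read opposite ways). All comparisons here use the
  ascending-coordinate direction; under it the typical insect rRNA block
  is `16S(−), trnV(−), 12S(−)` and the derived (transposed) block is
  `16S(−), 12S(−), trnV(−)`, with trnV adjacent to the control region.
* **No reflection equivalence.** Flipping the whole molecule swaps light
  and heavy strands, which carry real biological signal (strand-grouped
  composition), so a reflected order is a different order.

The shipped `insect_typical` reference is the pancrustacean ancestral
arrangement with the field-standard strand assignments (trnQ, trnC, trnY,
trnF, ND5, trnH, ND4, ND4L, trnP, ND1, trnL1, 16S, trnV, 12S on the minus
strand).

## Rearrangement statistics

A gene is *rearranged* relative to a benchmark when, after restricting
both cycles to their shared genes, its unordered pair of flanking gene
names differs from the benchmark's, or its strand differs. This is a
per-gene neighborhood criterion in the spirit of rearrangement-frequency
web services, not a breakpoint or DCJ distance; it is deliberately simple
enough to verify by exhaustive enumeration (the test suite does exactly
that). Genes absent from a genome are skipped, never counted as
rearranged, so partial genomes contribute only to the genes they carry.

* **RF(g)** = 100 × (genomes with g rearranged) / (genomes containing g),
  *truncated* to two decimals. Truncation (not rounding) is the
  convention under which 30/38 prints as 78.94.
* **RS** of a genome = Σ over genes of w_pos·[position changed] +
  w_strand·[strand changed], default weights (1, 1).

### Arrangement types

Gryllidea arrangements are classified by two diagnostic blocks: whether
the trnN–trnS1–trnE trio is locally inverted (to trnE(−)-trnS1(−)-trnN(−)),
and whether the rRNA block is typical or trnV-transposed:

| type | trio inverted | rRNA block |
|------|---------------|------------|
| I    | no            | typical    |
| II   | yes           | typical    |
| III  | yes           | transposed |
| IVG  | no            | transposed |

An order whose diagnostic evidence matches a type but whose remaining
genes deviate from that type's full arrangement is reported NOVEL, with
the evidence attached. Under the fixed reading direction, Type I is
cyclically identical to the typical insect order (its usual description
as "16S-trnV-12S" is the opposite-direction reading); the classifier
therefore labels the typical arrangement itself Type I, and the REF label
is reserved for benchmarks in reports.

### Benchmarks and the type-score ordering

Against `insect_typical` with weights (1, 1) the type scores are I = 0,
II = 7 (4 position + 3 strand changes from the inversion), IVG = 4 (the
trnV transposition) and III = 11 (both events). Because Type III's
changes strictly contain Type II's, *no* additive weighting under this
benchmark can rank II above III. The II > III > I > IVG ordering reported
for these arrangements by rearrangement web services arises from a
benchmark whose rRNA block differs from the typical insect order and
which is not published. The package therefore ships a second, documented
benchmark, `trnv_shifted` (typical order with trnV moved next to the
control region) — the minimal arrangement consistent with that ordering:
under it the scores are II = 11 > III = 7 > I = 4 > IVG = 0. The ordering
is asserted as a regression under `trnv_shifted`; score *magnitudes* are
a property of the unpublished benchmark convention and are nowhere
pinned. RF values that depend on the unpublished benchmark (e.g. a 16S
frequency of 100) are likewise out of scope; the reproducible quantities
are those derivable from the four type definitions alone.

## Composition statistics

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C), computed over unambiguous
bases only (Ns excluded from all denominators, so AT% + GC% = 100). A
zero denominator yields skew 0 with a degenerate flag — short tRNA slices
can legitimately lack G+C, and raising there would make whole-table
generation fragile. Whole-genome rows use the deposited strand (control
region included by default, excludable); per-gene rows use each gene's
sense strand, the only convention that reproduces the published sign
pattern in which minus-strand genes show positive GC-skew against a
negative genome-wide skew. Pooled tRNA rows concatenate sense-strand tRNA
sequences grouped by deposited-strand orientation (plus = L, minus = H).
Reports print percentages to 1 decimal and skews to 3; full precision is
kept internally.

Start/stop codons are read from the sense strand and reported verbatim;
starts outside {ATN, TTG, GTG} are flagged unusual, never corrected —
upstream annotation choices are reported as-is. A CDS length ≢ 0 (mod 3)
yields the trailing T/TA as an incomplete stop, flagged.

## Codon usage and selection screen

The genetic code defaults to translation table 5 (invertebrate
mitochondrial: AGA/AGG = Ser, ATA = Met, TGA = Trp; stops TAA/TAG; 62
sense codons). Synonymous families follow the tRNA families — leucine
split into CUN/UUR, serine into AGN/UCN — so RSCU and amino-acid
frequencies are reported per split family. (Published figures sometimes
label AGA under arginine; table 5 places it in the serine AGN family, and
the code, not the figure label, governs here.) RSCU(c) = count(c) /
(family total / family size); families with zero usage report 0. Codons
containing N and stop codons are excluded; codons are DNA internally, RNA
(U) in display output.

The numt screen translates a CDS and reports codon indices of internal
TAA/TAG — the working signature of a nuclear mitochondrial pseudogene or
frameshift.

dN/dS is the original Nei–Gojobori (1986) pathway method: per-codon
synonymous site fractions with stop-creating changes counted
nonsynonymous; differences averaged with equal weight over substitution
pathways, stop-crossing pathways excluded (all pathways used if every one
is blocked); proportions corrected with Jukes–Cantor
d = −(3/4)·ln(1 − 4p/3), raising a distinct error at p ≥ 3/4 rather than
returning NaN. Gapped or ambiguous codon columns are deleted pairwise-
completely. The codon-based Z-test uses Z = (dN − dS)/SE with SE from a
seeded bootstrap over codon columns (default 1000 replicates; replicates
whose resample saturates the correction are discarded); alternatives:
neutral (two-sided), positive (dN > dS), purifying (dN < dS). The
variance estimator is a package choice — the test's naming convention in
the literature does not fix one; the bootstrap was chosen over the
analytic variance for robustness at short gene lengths.

## Phylogenomic matrix preparation

Alignment, model selection and tree inference are external tools; the
package imports per-gene alignments (FASTA), applies codon-position
masks, concatenates in a fixed gene order (ATP6, ATP8, COI, COII, COIII,
CYTB, ND1…ND6, ND4L — a package convention affecting only charset
coordinates), gap-fills missing taxon×gene blocks, and exports relaxed
PHYLIP plus RAxML or NEXUS-sets partition files. The `gryllidea11`
preset encodes the eleven-partition scheme (ND5+ND4 and ATP8+ND6 merged)
with codon sites 1+2 retained for ATP6, COII, COIII, ND1, ND3 and ND6 —
the downstream encoding of a substitution-saturation assessment that is
itself external. By default masks are applied physically (site-3 columns
removed), so exported charsets are contiguous and tile the matrix
exactly; step syntax (`a-b\3`) is emitted only for schemes left unmasked.

## Synthetic genomes

The generator emulates an annotated cricket mitogenome, not a sequencing
experiment:

* **Layout** — genes in the requested arrangement (REF/I/II/III/IVG or a
  custom order), control region appended after the last listed gene
  (between 12S and trnI in the typical rotation), 0–5 bp random spacers.
* **Lengths** — uniform per-gene ranges: ATP8 162–171, ND5 1725–1734,
  12S 627–785, 16S 1193–1375, tRNAs 48–71, control region 500–2000 bp;
  the other PCG ranges are package defaults typical of published cricket
  records (e.g. COI 1530–1545, CYTB 1134–1143). PCG lengths snap to the
  reading frame, including 3k+1/3k+2 for incomplete stops.
* **Composition** — bases i.i.d. with probabilities solved from target
  AT% (default 72), AT-skew (0.04) and GC-skew (−0.33), the observed
  cricket whole-genome values; the control region is AT-enriched
  (default 85%). Asymmetry is modeled as a property of the deposited
  strand: minus-strand genes are sampled from the mirrored distribution,
  which yields the realistic pattern of positive sense-strand GC-skew
  for minus-strand genes. Infeasible targets (a base probability hitting
  0 with coding constraints) raise a spec error.
* **Coding constraints** — PCGs begin with the configured start (default
  ATG; ND1 defaults to TTG, the conserved cricket usage), end with the
  configured stop (TAA default; TAG and incomplete T/TA supported), and
  the body is rejection-sampled to exclude internal TAA/TAG.
* **Cohorts** — per-type counts, default 7 I / 23 II / 7 III / 1 IVG
  (the published census of complete Gryllidea mitogenomes by
  arrangement type); per-genome seeds are spawned from the cohort seed,
  and identical specs serialize to byte-identical GenBank.

What passing tests on synthetic data do **not** show: the generator has
no codon-usage bias beyond base composition, no tRNA secondary structure,
no among-site rate variation and no phylogenetic signal, so agreement on
synthetic cohorts validates the *statistics and their conventions*, not
inferences about real sequence evolution.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally, 1-based inclusive in
  GenBank I/O; origin-wrapping features keep `end > L` with a wrap flag.
* Unknown or ambiguous gene labels (e.g. `tRNA-Ser` without a codon
  family) are hard errors — misnamed genes silently corrupt gene-order
  statistics. Duplicated genes are rejected with a distinct error;
  missing genes are tolerated and flagged wherever a statistic can skip
  them.
* Cyclic-order comparison requires identical gene sets; fewer than 3
  shared genes is an explicit incomparability error (a neighbor context
  needs 3 genes).
* Canonical rotation anchors at trnI, falling back to the
  lexicographically smallest gene; ties cannot occur (names unique).

## Problem sizes

Default test and analysis scale: 38-genome cohorts (~15 kb each), 200
random orders for the oracle equivalence check, 80 genomes for
construction recovery, all 62×62 codon pairs for the substitution-count
enumeration, 1000 bootstrap replicates per Z-test. These sizes keep every
result exact or statistically stable at fixed seeds.
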