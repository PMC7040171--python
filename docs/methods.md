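# Methods

## The screening model

SARPs (*Streptomyces* Antibiotic Regulatory Protein family) are
actinomycete transcriptional activators with an N-terminal winged
helix-turn-helix (HTH) DNA-binding domain and a C-terminal bacterial
transcriptional activation domain (BTAD).  They are usually encoded inside
the biosynthetic gene cluster (BGC) they activate and bind direct heptamer
repeats — consensus 5'-GTCAGSS-3' for PapR2-like SARPs, S = G or C —
separated by 4-bp spacers, typically overlapping the −35 promoter element
of their target genes.  Because different SARPs recognize similar sites, a
well-characterized SARP expressed in a foreign strain can substitute for a
cluster's native activator and switch on an otherwise silent BGC.

`sarpscout` implements the desk half of that strategy as a screen over an
annotated genome:

1. **Motif scan** — every window of both strands is scored against the
   consensus by fractional identity; hits are filtered to intergenic
   intervals, where functional promoter-proximal sites are expected.
2. **SARP inventory** — proteins with profile hits against the four
   canonical Pfam domains (PF00486 HTH, PF03704 BTAD, PF00931 NB-ARC,
   PF13424 TPR_12) are classified by architecture: `small` (HTH+BTAD only),
   `large` (HTH+BTAD plus NB-ARC and/or TPR), `btad_only`, `hth_only`, or
   `incomplete`.
3. **Cluster annotation** — per BGC region: cluster-situated SARP gene
   count, best global-alignment similarity of those SARPs to the reference
   activator, and intergenic motif hits inside the region.
4. **Gating and ranking** — a cluster is a candidate for SARP-driven
   activation iff it (a) contains a SARP gene, (b) whose product exceeds the
   reference-similarity gate (strictly > 55% by default), and (c) carries a
   qualifying intergenic motif.  Survivors are ranked by best motif
   identity, then best reference similarity, then cluster id.

## Motif scoring

Identity of a site to the consensus is (matching scored positions) /
(scored positions).  A base matching the IUPAC-allowed set scores 1 — a G
or C at an S position is a *full* match, which is what makes a "100%
identical" hit to a degenerate consensus meaningful.  An `N` in the scanned
sequence matches nothing (soft-masked input is upper-cased on read; other
ambiguity codes are normalized to N by default).

Two array-scoring conventions are supported:

* default (genome scanning): single heptamer, spacers never scored;
  threshold 6/7 ≈ 0.857 (at most one mismatch).  The threshold is a
  configurable package default — a single-mismatch allowance keeps the
  expected chance-hit load per genome manageable while still catching
  slightly degenerate functional sites.
* `TRI_HEPTAMER_ARRAY` preset: three repeats with two 4-bp spacers scored
  as automatic matches, 29 scored positions in total.  Under this
  convention one heptamer mismatch gives 28/29 = 96.55% and ten give
  19/29 = 65.52%, matching how array identities are conventionally quoted
  over the full repeat-plus-spacer footprint.

The scanner is vectorized (per-position lookup tables over an encoded
sequence); a scalar `score_site` path exists for single sites and serves as
the enumeration oracle in the test suite.  Hits are reported in plus-strand
coordinates, sorted by (start, strand, identity desc); overlapping hits are
all reported — no greedy masking, since downstream association and gating
only ask about presence and best identity.

## Coordinates, intergenic regions and promoter windows

All internal coordinates are 0-based half-open; user-facing reports print
1-based inclusive spans.  "Intergenic" means not covered by any CDS on
either strand; the complement is computed over merged CDS footprints and
includes the stretches flanking the first and last CDS.  Compound (joined)
CDS locations are flattened to their outer span with a warning — spliced
bacterial CDS are rare and the screen only needs footprints.

A promoter window extends upstream of a gene's translational start on the
gene's own strand — default 350 bp, clipped at the nearest neighboring CDS
boundary and truncated at replicon edges.  The default conservatively
covers the 182–230 bp upstream fragments in which PapR2-type binding has
been demonstrated experimentally, while bounding the search space; the
genome-wide motif filter uses intergenic intervals rather than fixed
windows because how far upstream a hit may sit and still be "promoter" is
not a settled quantity.

## Architecture decision table

Classification is a total function of the set of canonical roles hit:

| HTH | BTAD | NB-ARC or TPR | class |
|-----|------|---------------|------------|
| ✓   | ✓    | –             | small      |
| ✓   | ✓    | ✓             | large      |
| –   | ✓    | any           | btad_only  |
| ✓   | –    | any           | hth_only   |
| –   | –    | any           | incomplete |

Proteins hitting only NB-ARC/TPR are `incomplete`: without a DNA-binding or
activation domain there is nothing SARP-like to score.  PF93704 is accepted
as an alias of the BTAD accession PF03704 (a typo that circulates in the
literature); accessions are normalized by stripping version suffixes, and
the normalization is idempotent.  The per-domain e-value cutoff defaults to
1e-5; the four-profile membership rule is presence-based, so any cutoff
that separates genuine domain hits from noise gives the same classes.

For genome-level prevalence, a genome is SARP-positive if it encodes at
least one protein classified small/large/btad_only/hth_only — i.e. at
least one canonical role including HTH or BTAD, excluding profile hits
that lack both (such hits outside Actinobacteria are typically not true
SARPs).

## Percentages and the similarity rule

All printed percentages use round-half-up to the nearest integer
(`floor(x + 0.5)`); this single convention reproduces every published
census ratio the test suite checks (611/625→98, 115/276→42, 79/1236→6,
38/39→97, 3289/6525→50, 1080/6525→17, 330/1080→31, 184/822→22).

Two genes are "similar" iff alignment e-value < 1e-5 AND identity > 30%
AND coverage of the shorter sequence > 25% — all strict, following the
ClusterBlast convention.  Known-cluster similarity is the rounded percent
of the known cluster's genes with at least one similar query gene; one
query gene may support several reference genes.  The rule consumes
precomputed pairwise hit tables from any aligner; this package does not
re-run BLAST.

## Reference-protein similarity

`pairwise_similarity` is a global (end-gap-penalized) Needleman–Wunsch
alignment, BLOSUM62, gap open 10 / extend 0.5, via Biopython's
`PairwiseAligner`.  Identity = identical columns / alignment columns;
similarity = columns with a positive substitution score (identities
included) / alignment columns; gap columns count only in the denominator.
Global alignment is chosen for determinism on full-length regulator
comparisons; BLASTP-style local percentages for the same pair can differ,
so published local-alignment values are not reproduction targets.  The
>55% similarity gate is applied to `similarity_percent` and is strictly
`>` (configurable to `≥`).

An independent hand-written affine-gap DP in the test suite cross-checks
the aligner's scores; the identity/similarity bookkeeping is checked
against hand-computed toy alignments.

## The synthetic-data generator

`fixtures.simulate_genome` emulates the screen's inputs with known truth:
a single replicon of BGC-like clusters (default 3 clusters × 4 genes of
600 bp separated by 250 bp gaps), i.i.d. background at a stated GC
fraction, consensus motifs planted mid-gap at chosen mismatch loads and
strands, and SARP genes with matching domain-hit rows and protein
sequences at chosen similarity to a generated 250-aa reference.  One
`numpy.random.default_rng(seed)` stream drives every choice, so
regeneration is byte-identical.

Two constructions make the truth exact rather than approximate:

* planted mismatches mutate to bases *outside* the IUPAC-allowed set, so a
  site planted with k mismatches scans at exactly (7−k)/7;
* intergenic gaps are rejection-sampled until free of chance windows at
  ≤1 mismatch on either strand, so within clusters the planted motifs are
  the complete intergenic hit set at the default threshold.
* reference-similarity targets are met by substituting the required number
  of residues with non-positive-scoring replacements; at moderate loads
  (≥ ~50% target) the optimal global alignment stays gapless and the
  realized similarity is exact, while at heavy loads (40% target) gapped
  realignments can shift it by a point or two — the demo gates tolerate
  this.

The default background GC of 0.5 makes the analytic chance-hit rate of the
consensus exactly 4/4⁷ per strand-position (two 2-fold degenerate
positions), which the statistical tests rely on.  What the generator does
**not** emulate: the ~70% GC of real actinomycete genomes (which raises
the S-position match rate and hence the background hit load), codon
structure, operons, or phylogenetically realistic SARP sequences.  Passing
tests therefore demonstrate correctness of the machinery, not expected hit
yields on real *Streptomyces* assemblies.

The standard demo (`fixtures.demo_screen`) plants one cluster that passes
every gate (small SARP at 60% similarity + perfect intergenic motif), one
that fails the similarity gate (40%) and one that fails the motif gate (no
motif), so exactly one candidate must emerge.

## Problem sizes and numerical choices

The acceptance script and test suite run in seconds on one CPU: the
scanner-vs-enumeration check uses 200 random sequences of length ≤ 500;
planted-motif recovery uses 5 genomes × 3 motifs per mismatch load
k ∈ {0,1,2}; the background-rate measurement scans 520 kb on both strands
(≈1.04 million strand-positions, 3σ binomial tolerance).  Threshold
comparisons subtract 1e-9 before comparing identities so that exact
rational thresholds (6/7) are not lost to float rounding.  Ties in hit
ordering break by (start, strand '+' first, identity descending); report
TSVs use fixed float formats so identical inputs give byte-identical
output.

## Known limitations

* No PWM/information-content scoring and no p-value calibration of hits;
  identity to a hard consensus is the model, as in pattern-scan practice.
* Motif hits are not required to sit a fixed distance from a −10/−35
  element; intergenic location is the only positional filter.
* Known-cluster similarity depends entirely on the supplied pairwise hit
  table (aligner, database and version), so published per-cluster
  percentages are not reproduction targets.
* Whether a candidate motif must sit in the *same* cluster as the SARP
  gene is genuinely ambiguous in practice; both behaviours are available
  via `require_cluster_situated_sarp`, and the default (required) follows
  the strategy's strain-prioritization wording.
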