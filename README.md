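# sarpscout

SARP-guided genome mining for actinomycetes: find *Streptomyces* Antibiotic
Regulatory Protein (SARP) genes and SARP binding motifs in and around
biosynthetic gene clusters (BGCs), and rank clusters as candidates for
SARP-driven activation of silent antibiotic pathways.

## Who this is for

Natural-product and regulation labs that want to shortlist which silent
BGCs in a sequenced strain are most likely to switch on when a
well-characterized SARP activator (e.g. PapR2) is expressed in that strain
— before committing to cloning and fermentation work.

## The model

PapR2-type SARPs bind direct heptamer repeats with consensus

```
5'-G T C A G S S-3'      (S = G or C), repeats separated by 4-bp spacers
```

usually overlapping the −35 element of the target promoter.  A site is
scored by fractional identity to the consensus (a G/C at an S position is a
full match; spacers are unscored by default).  SARP proteins are recognized
by four Pfam domains — PF00486 (Trans_reg_C, the winged HTH), PF03704
(BTAD), PF00931 (NB-ARC), PF13424 (TPR_12) — and classified as `small`
(HTH+BTAD), `large` (+NB-ARC/TPR), `btad_only`, `hth_only` or `incomplete`.
A cluster is a candidate for activation iff

1. it contains a cluster-situated SARP gene,
2. that SARP's global-alignment similarity to the reference activator is
   strictly greater than 55%, and
3. a consensus motif (identity ≥ 6/7 by default) lies in an intergenic
   interval of the cluster.

Candidates are ranked by best motif identity, then best reference
similarity.  Two genes are "similar" for known-cluster comparisons iff
e-value < 10⁻⁵, identity > 30% and shortest-sequence coverage > 25%
(strict, ClusterBlast convention); all percentages round half-up.

See `docs/methods.md` for the full account.

## Worked example

Generate the built-in demo screen (a 3-cluster synthetic genome with one
activatable cluster planted) and run the full pipeline:

```
sarp-scout simulate --preset demo --seed 42 --outdir fixtures/
sarp-scout scan --genome fixtures/genome.gbk --regions fixtures/regions.bed \
    --domains fixtures/domains.tsv --reference fixtures/reference.faa \
    --proteins fixtures/proteins.faa
```

which prints:

```
rank	cluster_id	verdict	best_motif_identity	best_sarp_similarity	failed_gates
1	region_1	candidate	1.0000	60.0	.
2	region_2	rejected	1.0000	40.9	sarp_similar
3	region_3	rejected	0.0000	60.0	has_promoter_motif
```

region_1 carries a small SARP at 60% similarity to the reference and a
perfect intergenic `GTCAGCC` site, so it passes all three gates; region_2's
SARP is too divergent (40.9% ≤ 55%); region_3 has a similar SARP but no
motif in its intergenic intervals.  The same pipeline is available in
Python:

```python
from sarpscout import run_screen
result = run_screen("genome.gbk", "regions.bed", "domains.tsv",
                    "reference.faa", "proteins.faa")
print(result.report)
```

Library highlights: `motif.scan` (both-strand degenerate-consensus
scanning), `motif.find_repeat_arrays` (heptamer–spacer arrays),
`seqio.extract_intergenic` / `seqio.promoter_window`,
`sarpfind.classify_architecture` / `sarpfind.census` /
`sarpfind.pairwise_similarity`, `bgclink.gene_similar` /
`bgclink.cluster_similarity` / `bgclink.associate`, and
`fixtures.simulate_genome` for ground-truthed synthetic screens.

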