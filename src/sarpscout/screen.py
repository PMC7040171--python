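"""End-to-end SARP-guided screen: files in, ranked candidate report out."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from . import bgclink, motif, prioritize, sarpfind, seqio
from .bgclink import ClusterAnnotation, SarpGene
from .prioritize import CandidateScore, PrioritizationThresholds
from .sarpfind import SARP_POSITIVE_CLASSES


@dataclass
class ScreenResult:
    annotations: list[ClusterAnnotation]
    candidates: list[CandidateScore]
    report: str
    strain_prioritized: bool


def run_screen(
    genome_path: str | Path,
    regions_path: str | Path,
    domains_path: str | Path,
    reference_path: str | Path | None = None,
    proteins_path: str | Path | None = None,
    model: motif.MotifModel | None = None,
    thresholds: PrioritizationThresholds | None = None,
    min_intergenic_length: int = 1,
    regions_format: str | None = None,
    genome_format: str = "genbank",
    gff_fasta: str | Path | None = None,
) -> ScreenResult:
    """Run the full screen over one annotated genome.

    Pipeline: read genome -> scan both strands for the consensus -> extract
    intergenic regions -> load BGC regions -> classify SARP architectures
    from the domain table -> align candidate SARPs to the reference protein
    -> associate everything per cluster -> gate and rank.
    """
    model = model or motif.MotifModel()
    thresholds = thresholds or PrioritizationThresholds()
    if regions_format is None:
        regions_format = "bed" if str(regions_path).endswith(".bed") else "antismash-genbank"

    records = seqio.read_genome(genome_path, format=genome_format, fasta=gff_fasta)
    regions = bgclink.load_regions(regions_path, format=regions_format)

    hits: list[motif.MotifHit] = []
    intergenic: list[seqio.IntergenicRegion] = []
    for rec in records:
        hits.extend(motif.scan(rec.sequence, model, strands="both", record_id=rec.record_id))
        intergenic.extend(seqio.extract_intergenic(rec, min_length=min_intergenic_length))

    domain_hits = sarpfind.parse_domain_hits(domains_path)
    by_protein: dict[str, list] = {}
    for h in domain_hits:
        by_protein.setdefault(h.protein_id, []).append(h)

    gene_index = {
        f.gene_id: (rec.record_id, f)
        for rec in records
        for f in rec.cds_features()
    }
    sarp_genes: list[SarpGene] = []
    for pid, phits in by_protein.items():
        arch = sarpfind.classify_architecture(phits)
        if arch not in SARP_POSITIVE_CLASSES:
            continue
        if pid not in gene_index:
            raise ValueError(f"domain-hit protein {pid!r} has no CDS in the genome")
        record_id, feat = gene_index[pid]
        sarp_genes.append(SarpGene(pid, record_id, feat.start, feat.end, arch))

    similarities: dict[str, sarpfind.SimilarityResult] = {}
    if reference_path is not None and proteins_path is not None:
        reference = next(SeqIO.parse(str(reference_path), "fasta"))
        proteins = {r.id: str(r.seq) for r in SeqIO.parse(str(proteins_path), "fasta")}
        for g in sarp_genes:
            seq = proteins.get(g.gene_id)
            if seq:
                similarities[g.gene_id] = sarpfind.pairwise_similarity(
                    seq, str(reference.seq), query_id=g.gene_id, target_id=reference.id
                )

    annotations = bgclink.associate(regions, intergenic, hits, sarp_genes, similarities)
    candidates = prioritize.gate_candidates(annotations, thresholds)
    report = prioritize.report_tsv(candidates)
    return ScreenResult(
        annotations=annotations,
        candidates=candidates,
        report=report,
        strain_prioritized=prioritize.strain_prioritized(candidates),
    )
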