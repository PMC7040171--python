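"""Synthetic genomes, domain tables and census populations with known truth.

The simulator emulates the inputs of a SARP-guided screen: a replicon with
non-overlapping CDS features organized into BGC-like clusters, consensus
motifs planted into intergenic gaps at controlled mismatch loads and
strands, SARP genes with matching domain-hit rows and protein sequences at
controlled similarity to a reference activator, and census populations with
exact per-group architecture counts.  Everything derives from one integer
seed through a single numpy Generator stream, so regeneration is
byte-identical.

Planted motif identity is exact by construction: mismatch positions are
mutated to bases *outside* the IUPAC-allowed set, so a site planted with k
mismatches scans at exactly (7-k)/7.  Intergenic gaps are rejection-sampled
to be free of chance near-consensus windows (at most one mismatch, either
strand), so within clusters the planted truth is the complete intergenic
hit set at the default scan threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bgclink import ClusterRegion, SarpGene
from .motif import DEFAULT_CONSENSUS, MotifModel, iupac_matcher, scan
from .sarpfind import Architecture, DomainHit, ProteinRecord
from .seqio import GeneFeature, GenomeRecord, write_genome_genbank
from .utils import revcomp

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Domain-hit rows emitted per architecture (profile, evalue, ali_from, ali_to).
_ARCHITECTURE_PROFILES: dict[Architecture, list[tuple[str, float, int, int]]] = {
    Architecture.SMALL: [("PF00486.27", 1e-30, 5, 70), ("PF03704.16", 1e-25, 80, 240)],
    Architecture.LARGE: [
        ("PF00486.27", 1e-30, 5, 70),
        ("PF03704.16", 1e-25, 80, 240),
        ("PF00931.22", 1e-15, 260, 500),
        ("PF13424.6", 1e-10, 520, 600),
    ],
    Architecture.BTAD_ONLY: [("PF03704.16", 1e-25, 80, 240)],
    Architecture.HTH_ONLY: [("PF00486.27", 1e-30, 5, 70)],
    Architecture.INCOMPLETE: [],
}


@dataclass(frozen=True)
class PlantedMotif:
    record_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    cluster_index: int

    @property
    def expected_identity(self) -> float:
        return (7 - self.mismatches) / 7


@dataclass(frozen=True)
class PlantedSarp:
    gene_id: str
    cluster_index: int
    architecture: Architecture
    similarity_target: float


@dataclass
class TruthTable:
    """Ground truth for one simulated screen, plus the in-memory objects."""

    seed: int
    motifs: list[PlantedMotif]
    sarps: list[PlantedSarp]
    clusters: list[ClusterRegion]
    genome: GenomeRecord
    domain_hits: list[DomainHit]
    proteins: dict[str, str]  # gene_id -> amino-acid sequence (SARP genes only)
    reference_protein: str
    sarp_genes: list[SarpGene] = field(default_factory=list)


def random_background(length: int, gc_fraction: float = 0.5, rng=None, seed=None) -> str:
    """I.i.d. DNA background at the stated GC fraction."""
    if rng is None:
        rng = np.random.default_rng(seed)
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    bases = rng.choice(np.array(list("ACGT")), size=length, p=[at, gc, gc, at])
    return "".join(bases)


def _motif_free_gap(length: int, gc_fraction: float, rng, model: MotifModel) -> str:
    """A background gap with no window at <=1 mismatch on either strand."""
    probe = MotifModel(consensus=model.consensus, min_identity=6.0 / 7.0)
    for _ in range(500):
        gap = random_background(length, gc_fraction, rng=rng)
        if not scan(gap, probe, strands="both"):
            return gap
    raise RuntimeError(f"could not draw a motif-free gap of length {length}")


def _realize_consensus(rng, consensus: str = DEFAULT_CONSENSUS) -> str:
    """One concrete instance of the consensus (degenerate positions drawn)."""
    return "".join(sorted(allowed)[rng.integers(len(allowed))] for allowed in iupac_matcher(consensus))


def _plant_mismatches(site: str, k: int, rng, consensus: str = DEFAULT_CONSENSUS) -> str:
    """Mutate k positions to bases outside the IUPAC-allowed set."""
    allowed_sets = iupac_matcher(consensus)
    positions = rng.choice(len(site), size=k, replace=False)
    site_l = list(site)
    for p in positions:
        outside = sorted(set("ACGT") - allowed_sets[p])
        site_l[p] = outside[rng.integers(len(outside))]
    return "".join(site_l)


def _mutated_protein(reference: str, similarity_target: float, rng) -> str:
    """Copy of the reference with enough non-positive-scoring substitutions
    that gapless global alignment gives exactly the target similarity."""
    from Bio.Align import substitution_matrices

    sub = substitution_matrices.load("BLOSUM62")
    L = len(reference)
    k = round((1 - similarity_target / 100.0) * L)
    positions = rng.choice(L, size=k, replace=False)
    seq = list(reference)
    for p in positions:
        orig = seq[p]
        bad = [aa for aa in _AMINO_ACIDS if aa != orig and sub[orig][aa] <= 0]
        seq[p] = bad[rng.integers(len(bad))]
    return "".join(seq)


_PRODUCT_CYCLE = ["nrps", "t2pks", "terpene", "other"]


def simulate_genome(
    n_clusters: int = 3,
    genes_per_cluster: int = 4,
    gc_fraction: float = 0.5,
    planted_motifs: list[tuple[int, int, str]] | None = None,
    planted_sarps: list[tuple[int, Architecture]] | None = None,
    seed: int = 0,
    sarp_similarities: list[float] | None = None,
    gene_length: int = 600,
    gap_length: int = 250,
    outdir: str | Path | None = None,
) -> TruthTable:
    """Simulate one replicon of BGC-like clusters with planted ground truth.

    planted_motifs: (cluster index, mismatch count 0..7, strand) — each motif
    is written into the next free intergenic gap of its cluster.
    planted_sarps: (cluster index, Architecture) — each turns the next free
    gene of its cluster into a SARP gene with matching domain-hit rows and a
    protein sequence at the paired ``sarp_similarities`` target (default 60%)
    to the generated reference protein.

    If ``outdir`` is given, writes genome.gbk, regions.bed, domains.tsv,
    proteins.faa and reference.faa exactly as the seqio/bgclink/sarpfind
    readers consume them.  Returns the TruthTable either way.
    """
    planted_motifs = planted_motifs or []
    planted_sarps = planted_sarps or []
    if sarp_similarities is None:
        sarp_similarities = [60.0] * len(planted_sarps)
    if len(sarp_similarities) != len(planted_sarps):
        raise ValueError("sarp_similarities must pair with planted_sarps")
    for ci, k, strand in planted_motifs:
        if not (0 <= ci < n_clusters):
            raise ValueError(f"planted motif cluster index {ci} out of range")
        if not (0 <= k <= 7):
            raise ValueError("mismatch count must be in 0..7")
        if strand not in "+-":
            raise ValueError("motif strand must be '+' or '-'")
    for ci, _arch in planted_sarps:
        if not (0 <= ci < n_clusters):
            raise ValueError(f"planted SARP cluster index {ci} out of range")
    if genes_per_cluster < 2:
        raise ValueError("need at least 2 genes per cluster (motifs go between genes)")
    n_gaps = genes_per_cluster - 1
    per_cluster_motifs: dict[int, list[tuple[int, str]]] = {}
    for ci, k, strand in planted_motifs:
        per_cluster_motifs.setdefault(ci, []).append((k, strand))
        if len(per_cluster_motifs[ci]) > n_gaps:
            raise ValueError(f"cluster {ci}: more motifs than intergenic gaps")

    rng = np.random.default_rng(seed)
    record_id = "contig1"
    scrub_model = MotifModel()
    span = scrub_model.site_span

    chunks: list[str] = []
    features: list[GeneFeature] = []
    clusters: list[ClusterRegion] = []
    motifs: list[PlantedMotif] = []
    pos = 0

    def emit(seq: str) -> None:
        nonlocal pos
        chunks.append(seq)
        pos += len(seq)

    emit(_motif_free_gap(300, gc_fraction, rng, scrub_model))
    for ci in range(n_clusters):
        cluster_start = pos
        motif_queue = list(per_cluster_motifs.get(ci, []))
        gene_ids = []
        for gi in range(genes_per_cluster):
            gene_id = f"c{ci}g{gi}"
            strand = "+" if rng.random() < 0.75 else "-"
            gene_seq = random_background(gene_length, gc_fraction, rng=rng)
            features.append(
                GeneFeature(gene_id, pos, pos + gene_length, strand, "CDS",
                            product="hypothetical protein")
            )
            gene_ids.append(gene_id)
            emit(gene_seq)
            if gi < genes_per_cluster - 1:
                gap = _motif_free_gap(gap_length, gc_fraction, rng, scrub_model)
                if motif_queue:
                    if gap_length < span:
                        raise ValueError(
                            f"motif span {span} exceeds intergenic gap length {gap_length}"
                        )
                    k, mstrand = motif_queue.pop(0)
                    site = _plant_mismatches(_realize_consensus(rng), k, rng)
                    planted = site if mstrand == "+" else revcomp(site)
                    at = (gap_length - span) // 2
                    gap = gap[:at] + planted + gap[at + span:]
                    motifs.append(
                        PlantedMotif(record_id, pos + at, pos + at + span, mstrand, k, ci)
                    )
                emit(gap)
        clusters.append(
            ClusterRegion(
                cluster_id=f"region_{ci + 1}",
                record_id=record_id,
                start=cluster_start,
                end=pos,
                product_type=_PRODUCT_CYCLE[ci % len(_PRODUCT_CYCLE)],
                genes=gene_ids,
            )
        )
        emit(_motif_free_gap(400, gc_fraction, rng, scrub_model))

    genome = GenomeRecord(
        record_id=record_id,
        sequence="".join(chunks),
        features=features,
        source_taxon="Streptomyces simulatus",
    )

    reference = "".join(
        _AMINO_ACIDS[i] for i in rng.integers(len(_AMINO_ACIDS), size=250)
    )
    domain_hits: list[DomainHit] = []
    proteins: dict[str, str] = {}
    sarps: list[PlantedSarp] = []
    sarp_genes: list[SarpGene] = []
    used_genes: dict[int, int] = {}
    for (ci, arch), target in zip(planted_sarps, sarp_similarities):
        gi = used_genes.get(ci, 0)
        if gi >= genes_per_cluster:
            raise ValueError(f"cluster {ci}: more SARPs than genes")
        used_genes[ci] = gi + 1
        gene_id = f"c{ci}g{gi}"
        for profile, ev, a, b in _ARCHITECTURE_PROFILES[arch]:
            domain_hits.append(DomainHit(gene_id, profile.split(".")[0], ev, a, b))
        proteins[gene_id] = _mutated_protein(reference, target, rng)
        sarps.append(PlantedSarp(gene_id, ci, arch, target))
        feat = genome.get_gene(gene_id)
        sarp_genes.append(SarpGene(gene_id, record_id, feat.start, feat.end, arch))

    truth = TruthTable(
        seed=seed,
        motifs=motifs,
        sarps=sarps,
        clusters=clusters,
        genome=genome,
        domain_hits=domain_hits,
        proteins=proteins,
        reference_protein=reference,
        sarp_genes=sarp_genes,
    )
    if outdir is not None:
        write_fixture_files(truth, outdir)
    return truth


def write_fixture_files(truth: TruthTable, outdir: str | Path) -> dict[str, Path]:
    """Write the simulated screen inputs as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.gbk",
        "regions": outdir / "regions.bed",
        "domains": outdir / "domains.tsv",
        "proteins": outdir / "proteins.faa",
        "reference": outdir / "reference.faa",
    }
    write_genome_genbank([truth.genome], paths["genome"])
    paths["regions"].write_text(
        "".join(
            f"{c.record_id}\t{c.start}\t{c.end}\t{c.product_type}\n"
            for c in truth.clusters
        )
    )
    paths["domains"].write_text(
        "".join(
            f"{h.protein_id}\t{h.profile_id}\t{h.evalue}\t{h.ali_from}\t{h.ali_to}\n"
            for h in truth.domain_hits
        )
    )
    paths["proteins"].write_text(
        "".join(f">{pid}\n{seq}\n" for pid, seq in sorted(truth.proteins.items()))
    )
    paths["reference"].write_text(f">reference_sarp\n{truth.reference_protein}\n")
    return paths


def demo_screen(seed: int = 42, outdir: str | Path | None = None) -> TruthTable:
    """The standard 3-cluster demo: exactly one prioritizable candidate.

    Cluster 0: small SARP at 60% similarity to the reference plus a perfect
    intergenic motif (passes all gates).  Cluster 1: small SARP at 40%
    similarity plus a perfect motif (fails the >55% similarity gate).
    Cluster 2: small SARP at 60% similarity but no motif (fails the
    promoter-motif gate).
    """
    return simulate_genome(
        n_clusters=3,
        genes_per_cluster=4,
        planted_motifs=[(0, 0, "+"), (1, 0, "+")],
        planted_sarps=[
            (0, Architecture.SMALL),
            (1, Architecture.SMALL),
            (2, Architecture.SMALL),
        ],
        sarp_similarities=[60.0, 40.0, 60.0],
        seed=seed,
        outdir=outdir,
    )


def simulate_census(
    spec: dict[str, dict[Architecture, int]],
    group_field: str = "taxon_order",
) -> list[ProteinRecord]:
    """Emit exactly the specified number of proteins per (group, class).

    Each protein carries synthetic domain hits consistent with its class via
    ``assign_architectures``; the architecture field is set accordingly.
    """
    from .sarpfind import assign_architectures

    proteins: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    for group in sorted(spec):
        for arch in Architecture:
            n = spec[group].get(arch, 0)
            if n < 0:
                raise ValueError(f"negative count for {group}/{arch.value}")
            for i in range(n):
                pid = f"{group}_{arch.value}_{i}"
                p = ProteinRecord(protein_id=pid)
                setattr(p, group_field, group)
                proteins.append(p)
                for profile, ev, a, b in _ARCHITECTURE_PROFILES[arch]:
                    hits.append(DomainHit(pid, profile.split(".")[0], ev, a, b))
    return assign_architectures(proteins, hits)


def simulate_genome_flags(spec: dict[str, tuple[int, int]]):
    """Per-genome SARP-positive flags: {genus: (positives, total)} -> DataFrame."""
    import pandas as pd

    rows = []
    for genus in sorted(spec):
        positives, total = spec[genus]
        if not (0 <= positives <= total):
            raise ValueError(f"{genus}: positives must be within [0, total]")
        rows.extend(
            {"genus": genus, "sarp_positive": i < positives} for i in range(total)
        )
    return pd.DataFrame(rows, columns=["genus", "sarp_positive"])
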