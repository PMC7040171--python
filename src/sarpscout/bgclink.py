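"""BGC region loading, known-cluster similarity, and cluster annotation.

Regions come from antiSMASH-style GenBank files (region/cluster features
with product qualifiers) or BED intervals.  The known-cluster similarity
rule follows the ClusterBlast convention: two genes are similar if their
alignment has e-value < 1e-5, identity > 30% and coverage of the shorter
sequence > 25% (all strict); a query cluster's similarity to a known
cluster is the rounded percentage of the known cluster's genes with at
least one similar counterpart.  ``associate`` assembles per-cluster
annotation rows — cluster-situated SARP gene count, best similarity to the
reference SARP, and motif hits restricted to intergenic positions — in the
shape of a screening summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .motif import MotifHit
from .sarpfind import Architecture, SimilarityResult
from .seqio import IntergenicRegion
from .utils import percent


@dataclass
class ClusterRegion:
    """A BGC interval on a replicon (0-based half-open)."""

    cluster_id: str
    record_id: str
    start: int
    end: int
    product_type: str = "unknown"
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"region {self.cluster_id!r}: invalid interval [{self.start}, {self.end})"
            )

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end

    def overlaps(self, start: int, end: int) -> bool:
        return start < self.end and self.start < end


@dataclass(frozen=True)
class GenePairHit:
    """One aligned query/reference gene pair (coverage on the shorter gene)."""

    query_gene: str
    ref_gene: str
    evalue: float
    identity_percent: float
    coverage_percent_shortest: float


@dataclass(frozen=True)
class SimilarityRule:
    """Strict thresholds for calling two genes similar."""

    evalue_max: float = 1e-5
    identity_min_percent: float = 30.0
    coverage_min_percent: float = 25.0

    def __post_init__(self) -> None:
        if self.evalue_max <= 0 or self.identity_min_percent <= 0 or self.coverage_min_percent <= 0:
            raise ValueError("all similarity-rule thresholds must be positive")


@dataclass
class SarpGene:
    """A classified SARP gene with its genomic span."""

    gene_id: str
    record_id: str
    start: int
    end: int
    architecture: Architecture


@dataclass
class ClusterAnnotation:
    """One screening-summary row for a BGC."""

    cluster_id: str
    product_type: str
    known_cluster_similarity_percent: int | None
    sarp_gene_count: int
    sarp_gene_ids: list[str]
    best_papr2_identity: float | None
    best_papr2_similarity: float | None
    motif_hits: list[MotifHit]
    partial_overlap_flag: bool = False
    region: ClusterRegion | None = None


def load_regions(path: str | Path, format: str = "antismash-genbank") -> list[ClusterRegion]:
    """Load BGC regions from an antiSMASH GenBank or a BED file.

    antiSMASH files mark each BGC with a ``region`` (v5+) or ``cluster``
    feature carrying a ``product`` qualifier; BED lines use the name field
    (column 4) as the product type.
    """
    path = Path(path)
    if format == "bed":
        regions = []
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"BED line {i + 1}: fewer than 3 columns")
            name = cols[3] if len(cols) > 3 else "unknown"
            regions.append(
                ClusterRegion(
                    cluster_id=f"region_{len(regions) + 1}",
                    record_id=cols[0],
                    start=int(cols[1]),
                    end=int(cols[2]),
                    product_type=name,
                )
            )
        return regions
    if format == "antismash-genbank":
        regions = []
        for rec in SeqIO.parse(str(path), "genbank"):
            for feat in rec.features:
                if feat.type not in ("region", "cluster"):
                    continue
                if feat.location is None:
                    raise ValueError(f"region feature without coordinates in {rec.id}")
                product = ";".join(feat.qualifiers.get("product", ["unknown"]))
                number = feat.qualifiers.get("region_number", [str(len(regions) + 1)])[0]
                regions.append(
                    ClusterRegion(
                        cluster_id=f"region_{number}",
                        record_id=rec.id or rec.name,
                        start=int(feat.location.start),
                        end=int(feat.location.end),
                        product_type=product,
                    )
                )
        return regions
    raise ValueError(f"unknown region format {format!r}")


def gene_similar(hit: GenePairHit, rule: SimilarityRule = SimilarityRule()) -> bool:
    """True iff the pair passes all three strict thresholds."""
    return (
        hit.evalue < rule.evalue_max
        and hit.identity_percent > rule.identity_min_percent
        and hit.coverage_percent_shortest > rule.coverage_min_percent
    )


def cluster_similarity(
    ref_genes: Sequence[str],
    hits: Iterable[GenePairHit],
    rule: SimilarityRule = SimilarityRule(),
) -> int:
    """Percent of known-cluster genes with at least one similar query gene.

    100 when every reference gene is recovered; round-half-up otherwise.
    One query gene may support multiple reference genes.
    """
    if not ref_genes:
        raise ValueError("cluster_similarity requires a nonempty reference gene list")
    found = {h.ref_gene for h in hits if h.ref_gene in set(ref_genes) and gene_similar(h, rule)}
    return percent(len(found), len(ref_genes))


def associate(
    regions: Sequence[ClusterRegion],
    intergenic: Sequence[IntergenicRegion],
    motif_hits: Sequence[MotifHit],
    sarp_genes: Sequence[SarpGene],
    similarities: Mapping[str, SimilarityResult] | None = None,
    known_cluster_similarity: Mapping[str, int] | None = None,
) -> list[ClusterAnnotation]:
    """Build one annotation row per BGC region.

    Counts SARP genes whose span lies inside the region (partial overlaps
    are counted but flagged), attaches the best reference-protein similarity
    among them, and attaches motif hits that fall inside the region AND
    inside an intergenic interval.  ``similarities`` maps SARP gene_id ->
    SimilarityResult against the reference SARP; ``known_cluster_similarity``
    maps cluster_id -> percent.  Inputs must refer to the same assembly:
    record ids present in hits/genes but absent from all regions' records
    are reported, since that almost always means mismatched inputs.
    """
    similarities = similarities or {}
    known_cluster_similarity = known_cluster_similarity or {}
    region_records = {r.record_id for r in regions}
    offenders = sorted(
        {g.record_id for g in sarp_genes if g.record_id not in region_records}
        | {h.record_id for h in motif_hits if h.record_id not in region_records}
        | {ig.record_id for ig in intergenic if ig.record_id not in region_records}
    )
    if regions and offenders:
        raise ValueError(
            f"record ids not present in any region's assembly: {offenders}"
        )

    ig_by_record: dict[str, list[IntergenicRegion]] = {}
    for ig in intergenic:
        ig_by_record.setdefault(ig.record_id, []).append(ig)

    annotations = []
    for region in regions:
        inside, partial = [], False
        for g in sarp_genes:
            if g.record_id != region.record_id:
                continue
            if region.contains(g.start, g.end):
                inside.append(g)
            elif region.overlaps(g.start, g.end):
                inside.append(g)
                partial = True
        best_sim = None
        for g in inside:
            s = similarities.get(g.gene_id)
            if s is not None and (
                best_sim is None or s.similarity_percent > best_sim.similarity_percent
            ):
                best_sim = s
        hits_in = [
            h
            for h in motif_hits
            if h.record_id == region.record_id
            and region.contains(h.start, h.end)
            and any(ig.contains(h.start, h.end) for ig in ig_by_record.get(h.record_id, []))
        ]
        annotations.append(
            ClusterAnnotation(
                cluster_id=region.cluster_id,
                product_type=region.product_type,
                known_cluster_similarity_percent=known_cluster_similarity.get(region.cluster_id),
                sarp_gene_count=len(inside),
                sarp_gene_ids=[g.gene_id for g in inside],
                best_papr2_identity=best_sim.identity_percent if best_sim else None,
                best_papr2_similarity=best_sim.similarity_percent if best_sim else None,
                motif_hits=hits_in,
                partial_overlap_flag=partial,
                region=region,
            )
        )
    return annotations


def annotations_to_tsv(annotations: Sequence[ClusterAnnotation]) -> str:
    """Screening-summary TSV (fixed column order, deterministic formatting)."""
    header = (
        "cluster_id\tproduct_type\tknown_cluster_similarity_percent\tlocalization"
        "\tsarp_gene_count\tpapr2_identity_percent\tpapr2_similarity_percent"
        "\tmotif_present\tmotif_count\tbest_motif_identity\n"
    )
    rows = []
    for a in annotations:
        loc = (
            f"{a.region.record_id}:{a.region.start + 1}-{a.region.end}"
            if a.region
            else "."
        )
        best_motif = max((h.identity for h in a.motif_hits), default=None)
        rows.append(
            "\t".join(
                [
                    a.cluster_id,
                    a.product_type,
                    "." if a.known_cluster_similarity_percent is None
                    else str(a.known_cluster_similarity_percent),
                    loc,
                    str(a.sarp_gene_count),
                    "." if a.best_papr2_identity is None else f"{a.best_papr2_identity:.1f}",
                    "." if a.best_papr2_similarity is None else f"{a.best_papr2_similarity:.1f}",
                    "+" if a.motif_hits else "-",
                    str(len(a.motif_hits)),
                    "." if best_motif is None else f"{best_motif:.4f}",
                ]
            )
        )
    return header + "\n".join(rows) + ("\n" if rows else "")
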