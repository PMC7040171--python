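"""Annotated-genome IO plus intergenic-region and promoter-window extraction.

Coordinates are 0-based half-open throughout the library; user-facing exports
(reports, BED name fields) follow each format's own convention.  A gene's
"promoter window" is the stretch immediately upstream of its translational
start on its own strand, optionally clipped at the nearest neighboring CDS.
Intergenic regions are the maximal intervals not covered by any CDS on either
strand, including the stretches before the first and after the last CDS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .utils import normalize_dna, revcomp


@dataclass
class GeneFeature:
    """A strand-aware gene interval on a replicon (0-based half-open)."""

    gene_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    kind: str = "CDS"
    product: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.gene_id!r}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A replicon sequence with its ordered CDS features."""

    record_id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    source_taxon: str | None = None

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.gene_id!r} end {f.end} exceeds record "
                    f"{self.record_id!r} length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def cds_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "CDS"]

    def get_gene(self, gene_id: str) -> GeneFeature:
        for f in self.features:
            if f.gene_id == gene_id:
                return f
        raise KeyError(f"gene {gene_id!r} not found in record {self.record_id!r}")


@dataclass
class IntergenicRegion:
    """A maximal interval not covered by any CDS."""

    record_id: str
    start: int
    end: int
    sequence: str
    flank_left_gene: str | None = None
    flank_right_gene: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


@dataclass
class PromoterWindow:
    """Upstream window of a gene, oriented 5'->3' relative to the gene.

    start/end are plus-strand coordinates; ``sequence`` is reverse-complemented
    for minus-strand genes so it always reads toward the gene start.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    window_length: int
    sequence: str


def _feature_id(feat, index: int) -> str:
    for key in ("locus_tag", "gene", "protein_id", "ID", "Name"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return f"cds_{index}"


def read_genome(
    path: str | Path,
    format: str = "genbank",
    fasta: str | Path | None = None,
    ambiguity: str = "normalize",
) -> list[GenomeRecord]:
    """Read an annotated genome into GenomeRecord objects.

    Parameters
    ----------
    path : file path
        GenBank flat file, or GFF3 file when ``format="gff3+fasta"``.
    format : {"genbank", "gff3+fasta"}
    fasta : path, required for gff3+fasta
        FASTA with the contig sequences named in the GFF3.
    ambiguity : {"normalize", "strict"}
        Ambiguity codes other than N are replaced by N, or rejected.

    Every CDS feature becomes a GeneFeature; compound (joined) locations are
    flattened to their outer span with a warning.  Sequences are upper-cased.
    """
    path = Path(path)
    if format == "genbank":
        return _read_genbank(path, ambiguity)
    if format in ("gff3+fasta", "gff3"):
        if fasta is None:
            raise ValueError("format 'gff3+fasta' requires the fasta= argument")
        return _read_gff3(path, Path(fasta), ambiguity)
    raise ValueError(f"unknown genome format {format!r}")


def _read_genbank(path: Path, ambiguity: str) -> list[GenomeRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        features = []
        for i, feat in enumerate(rec.features):
            if feat.type != "CDS":
                continue
            loc = feat.location
            if loc is None:
                raise ValueError(f"CDS feature #{i} in {rec.id} has no coordinates")
            if len(getattr(loc, "parts", [loc])) > 1:
                warnings.warn(
                    f"CDS {_feature_id(feat, i)!r}: compound location flattened to span"
                )
            product = feat.qualifiers.get("product", [None])[0]
            features.append(
                GeneFeature(
                    gene_id=_feature_id(feat, i),
                    start=int(loc.start),
                    end=int(loc.end),
                    strand="-" if loc.strand == -1 else "+",
                    kind="CDS",
                    product=product,
                )
            )
        taxon = rec.annotations.get("organism")
        records.append(
            GenomeRecord(
                record_id=rec.id or rec.name,
                sequence=normalize_dna(str(rec.seq), ambiguity),
                features=features,
                source_taxon=taxon,
            )
        )
    if not records:
        raise ValueError(f"no records parsed from {path}")
    return records


def _read_gff3(gff_path: Path, fasta_path: Path, ambiguity: str) -> list[GenomeRecord]:
    import gffutils

    seqs = {
        rec.id: normalize_dna(str(rec.seq), ambiguity)
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features_by_seq: dict[str, list[GeneFeature]] = {sid: [] for sid in seqs}
    for i, feat in enumerate(db.features_of_type("CDS", order_by="start")):
        if feat.seqid not in seqs:
            raise ValueError(f"GFF3 feature on unknown contig {feat.seqid!r}")
        gene_id = feat.attributes.get("ID", feat.attributes.get("Name", [f"cds_{i}"]))[0]
        start, end = feat.start - 1, feat.end  # GFF3 is 1-based inclusive
        if end > len(seqs[feat.seqid]):
            raise ValueError(
                f"feature {gene_id!r} end {end} exceeds contig {feat.seqid!r} "
                f"length {len(seqs[feat.seqid])}"
            )
        product = feat.attributes.get("product", [None])[0]
        features_by_seq[feat.seqid].append(
            GeneFeature(
                gene_id=gene_id,
                start=start,
                end=end,
                strand="-" if feat.strand == "-" else "+",
                kind="CDS",
                product=product,
            )
        )
    return [
        GenomeRecord(record_id=sid, sequence=seq, features=features_by_seq[sid])
        for sid, seq in seqs.items()
    ]


def extract_intergenic(record: GenomeRecord, min_length: int = 1) -> list[IntergenicRegion]:
    """Maximal intervals of a replicon not covered by any CDS.

    Regions before the first and after the last CDS are included; a record
    with no CDS yields one region spanning the whole replicon.  Only regions
    of length >= min_length are returned.
    """
    cds = record.cds_features()
    regions: list[tuple[int, int, str | None, str | None]] = []
    if not cds:
        regions.append((0, record.length, None, None))
    else:
        # merge overlapping CDS footprints, remembering flanking gene ids
        merged: list[list] = []  # [start, end, first_gene, last_gene]
        for f in cds:
            if merged and f.start <= merged[-1][1]:
                if f.end > merged[-1][1]:
                    merged[-1][1] = f.end
                    merged[-1][3] = f.gene_id
            else:
                merged.append([f.start, f.end, f.gene_id, f.gene_id])
        if merged[0][0] > 0:
            regions.append((0, merged[0][0], None, merged[0][2]))
        for left, right in zip(merged, merged[1:]):
            if right[0] > left[1]:
                regions.append((left[1], right[0], left[3], right[2]))
        if merged[-1][1] < record.length:
            regions.append((merged[-1][1], record.length, merged[-1][3], None))
    return [
        IntergenicRegion(
            record_id=record.record_id,
            start=s,
            end=e,
            sequence=record.sequence[s:e],
            flank_left_gene=lg,
            flank_right_gene=rg,
        )
        for s, e, lg, rg in regions
        if e - s >= min_length
    ]


def promoter_window(
    record: GenomeRecord,
    gene_id: str,
    window_length: int = 350,
    clip_at_neighbor: bool = True,
) -> PromoterWindow:
    """The upstream window of a gene on its own strand.

    For a plus-strand gene at [s, e) the window is [max(0, s-W), s); for a
    minus-strand gene at [s, e) it is [e, min(L, e+W)) with the sequence
    reverse-complemented.  With ``clip_at_neighbor`` the window additionally
    stops at the nearest boundary of any other CDS, so it never reaches into
    a neighboring gene.  Windows are truncated (never padded) at replicon
    edges; the result can be empty if the neighbor abuts the gene.
    """
    gene = record.get_gene(gene_id)
    L = record.length
    if gene.strand == "+":
        lo, hi = max(0, gene.start - window_length), gene.start
        if clip_at_neighbor:
            for f in record.cds_features():
                if f.gene_id == gene.gene_id:
                    continue
                if lo < f.end <= hi:
                    lo = f.end
        seq = record.sequence[lo:hi]
    else:
        lo, hi = gene.end, min(L, gene.end + window_length)
        if clip_at_neighbor:
            for f in record.cds_features():
                if f.gene_id == gene.gene_id:
                    continue
                if lo <= f.start < hi:
                    hi = f.start
        seq = revcomp(record.sequence[lo:hi])
    return PromoterWindow(
        gene_id=gene_id,
        start=lo,
        end=hi,
        strand=gene.strand,
        window_length=window_length,
        sequence=seq,
    )


def intergenic_to_bed(regions: Iterable[IntergenicRegion]) -> str:
    """BED6 text for intergenic regions (name = flanking gene pair)."""
    lines = []
    for r in regions:
        name = f"{r.flank_left_gene or 'START'}|{r.flank_right_gene or 'END'}"
        lines.append(f"{r.record_id}\t{r.start}\t{r.end}\t{name}\t0\t.")
    return "\n".join(lines) + ("\n" if lines else "")


def write_genome_genbank(records: Sequence[GenomeRecord], path: str | Path) -> None:
    """Write GenomeRecords back to a GenBank flat file (round-trip support)."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    out = []
    for rec in records:
        sr = SeqRecord(
            Seq(rec.sequence),
            id=rec.record_id,
            name=rec.record_id[:16],
            description="",
            annotations={"molecule_type": "DNA"},
        )
        if rec.source_taxon:
            sr.annotations["organism"] = rec.source_taxon
        for f in rec.features:
            qualifiers = {"locus_tag": [f.gene_id]}
            if f.product:
                qualifiers["product"] = [f.product]
            sr.features.append(
                SeqFeature(
                    FeatureLocation(f.start, f.end, strand=-1 if f.strand == "-" else 1),
                    type=f.kind,
                    qualifiers=qualifiers,
                )
            )
        out.append(sr)
    SeqIO.write(out, str(path), "genbank")
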