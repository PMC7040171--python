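"""SARP regulator identification, architecture classification and census.

A SARP (Streptomyces Antibiotic Regulatory Protein) carries an N-terminal
winged helix-turn-helix DNA-binding domain (Pfam Trans_reg_C, PF00486) and a
C-terminal bacterial transcriptional activation domain (BTAD, PF03704).
"Small" SARPs contain only these two; "large" SARPs additionally carry an
NB-ARC NTPase-like domain (PF00931) and/or tetratricopeptide repeats
(TPR_12, PF13424).  This module consumes profile-search hit tables (hmmscan
domtblout or a simplified TSV), assigns each protein an architecture class,
aggregates counts into census tables with integer percentages, and computes
global-alignment identity/similarity of candidate SARPs to a reference
protein such as PapR2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .utils import percent

logger = logging.getLogger(__name__)

#: Canonical Pfam profile -> domain role map.  PF93704 is accepted as a
#: widely-circulated typo alias of the BTAD accession PF03704.
DEFAULT_PROFILE_ROLES: dict[str, str] = {
    "PF00486": "HTH",
    "PF03704": "BTAD",
    "PF93704": "BTAD",
    "PF00931": "NB-ARC",
    "PF13424": "TPR",
}


class Architecture(str, Enum):
    """SARP domain-architecture class (a total function of domain roles).

    small     : HTH and BTAD present, neither NB-ARC nor TPR
    large     : HTH and BTAD present, plus NB-ARC and/or TPR
    btad_only : BTAD present without HTH (putative divergent subfamily)
    hth_only  : HTH present without BTAD
    incomplete: neither HTH nor BTAD (including NB-ARC/TPR-only hits)
    """

    SMALL = "small"
    LARGE = "large"
    BTAD_ONLY = "btad_only"
    HTH_ONLY = "hth_only"
    INCOMPLETE = "incomplete"


#: Architectures counted as SARP-positive for genome prevalence: at least one
#: of the four canonical roles including a DNA-binding or activation domain.
SARP_POSITIVE_CLASSES = frozenset(
    {Architecture.SMALL, Architecture.LARGE, Architecture.BTAD_ONLY, Architecture.HTH_ONLY}
)


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    profile_id: str
    evalue: float
    ali_from: int
    ali_to: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.protein_id}/{self.profile_id}")
        if self.ali_from > self.ali_to:
            raise ValueError(
                f"ali_from > ali_to for {self.protein_id}/{self.profile_id}"
            )


@dataclass
class ProteinRecord:
    protein_id: str
    sequence: str = ""
    taxon_order: str | None = None
    taxon_genus: str | None = None
    cluster_type: str | None = None
    genome_id: str | None = None
    architecture: Architecture | None = None


@dataclass(frozen=True)
class SimilarityResult:
    query_id: str
    target_id: str
    identity_percent: float
    similarity_percent: float
    alignment_length: int


def normalize_accession(profile_id: str) -> str:
    """Strip a Pfam version suffix: 'PF00486.27' -> 'PF00486'."""
    return profile_id.split(".", 1)[0]


def parse_domain_hits(
    path: str | Path,
    evalue_cutoff: float = 1e-5,
    format: str = "auto",
) -> list[DomainHit]:
    """Parse a per-domain hit table into DomainHit objects.

    Supports the hmmscan ``--domtblout`` layout (whitespace-delimited, '#'
    comments, per-domain i-E-value in column 13) and a simplified 5-column
    TSV (protein_id, profile_id, evalue, ali_from, ali_to).  Hits with
    e-value above the cutoff are dropped; profile accessions are normalized
    by stripping version suffixes.  Malformed rows are skipped with a logged
    warning and counted on the returned list's ``.skipped`` attribute-free
    log line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if format == "auto":
        body = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
        format = "tsv" if body and len(body[0].split("\t")) == 5 else "domtbl"
    hits: list[DomainHit] = []
    skipped = 0
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            if format == "tsv":
                protein_id, profile_id, ev, a, b = line.split("\t")
                hit = DomainHit(
                    protein_id=protein_id,
                    profile_id=normalize_accession(profile_id),
                    evalue=float(ev),
                    ali_from=int(a),
                    ali_to=int(b),
                )
            else:  # hmmscan domtblout: target=profile, query=protein
                f = line.split()
                profile_acc = f[1] if f[1] != "-" else f[0]
                hit = DomainHit(
                    protein_id=f[3],
                    profile_id=normalize_accession(profile_acc),
                    evalue=float(f[12]),  # per-domain independent E-value
                    ali_from=int(f[17]),
                    ali_to=int(f[18]),
                    score=float(f[13]),
                )
        except (ValueError, IndexError) as exc:
            skipped += 1
            logger.warning("skipping malformed row %d of %s: %s", lineno, path, exc)
            continue
        if hit.evalue <= evalue_cutoff:
            hits.append(hit)
    if skipped:
        logger.warning("%d malformed rows skipped in %s", skipped, path)
    return hits


def classify_architecture(
    hits_for_one_protein: Iterable[DomainHit],
    canonical_map: Mapping[str, str] = DEFAULT_PROFILE_ROLES,
) -> Architecture:
    """Assign the SARP architecture class from one protein's domain hits.

    Total and deterministic over all subsets of the four canonical roles;
    profiles not in the canonical map are ignored.
    """
    roles = {
        canonical_map[normalize_accession(h.profile_id)]
        for h in hits_for_one_protein
        if normalize_accession(h.profile_id) in canonical_map
    }
    hth, btad = "HTH" in roles, "BTAD" in roles
    extra = "NB-ARC" in roles or "TPR" in roles
    if hth and btad:
        return Architecture.LARGE if extra else Architecture.SMALL
    if btad:
        return Architecture.BTAD_ONLY
    if hth:
        return Architecture.HTH_ONLY
    return Architecture.INCOMPLETE


def assign_architectures(
    proteins: Sequence[ProteinRecord],
    hits: Iterable[DomainHit],
    canonical_map: Mapping[str, str] = DEFAULT_PROFILE_ROLES,
) -> list[ProteinRecord]:
    """Classify every protein in place from a pooled hit table."""
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    for p in proteins:
        p.architecture = classify_architecture(by_protein.get(p.protein_id, []), canonical_map)
    return list(proteins)


_GROUP_FIELDS = {"order": "taxon_order", "genus": "taxon_genus", "cluster_type": "cluster_type"}


def census(
    proteins: Sequence[ProteinRecord],
    group_by: str = "order",
    denominator: str = "proteins",
) -> pd.DataFrame:
    """Aggregate classified proteins into a census table.

    One row per grouping value (taxonomic order, genus, or BGC product
    class; missing keys fall into an "unknown" bucket) with per-architecture
    counts, a row total, and integer percentages (round-half-up) of the row
    total.  A ``percent_of_all`` column gives each group's share of the full
    dataset.  With ``denominator="genomes"`` rows count genomes instead,
    a genome being positive if at least one of its proteins is
    SARP-classified (small/large/btad_only/hth_only).
    """
    if group_by not in _GROUP_FIELDS:
        raise ValueError(f"group_by must be one of {sorted(_GROUP_FIELDS)}")
    if denominator not in ("proteins", "genomes"):
        raise ValueError("denominator must be 'proteins' or 'genomes'")
    attr = _GROUP_FIELDS[group_by]
    classes = [a.value for a in Architecture]

    if denominator == "genomes":
        rows: dict[str, dict[str, set]] = {}
        for p in proteins:
            if p.genome_id is None:
                raise ValueError(f"protein {p.protein_id} lacks genome_id")
            group = getattr(p, attr) or "unknown"
            d = rows.setdefault(group, {"all": set(), "positive": set()})
            d["all"].add(p.genome_id)
            if p.architecture in SARP_POSITIVE_CLASSES:
                d["positive"].add(p.genome_id)
        df = pd.DataFrame(
            {
                "total": {g: len(d["all"]) for g, d in rows.items()},
                "sarp_positive": {g: len(d["positive"]) for g, d in rows.items()},
            }
        ).sort_index()
        df["percent_positive"] = [
            percent(pos, tot) if tot else 0
            for pos, tot in zip(df["sarp_positive"], df["total"])
        ]
        df.index.name = group_by
        return df

    counts: dict[str, dict[str, int]] = {}
    for p in proteins:
        if p.architecture is None:
            raise ValueError(f"protein {p.protein_id} has no assigned architecture")
        group = getattr(p, attr) or "unknown"
        row = counts.setdefault(group, {c: 0 for c in classes})
        row[p.architecture.value] += 1
    df = pd.DataFrame.from_dict(counts, orient="index").reindex(columns=classes).fillna(0)
    df = df.astype(int).sort_index()
    df["total"] = df[classes].sum(axis=1)
    grand_total = int(df["total"].sum())
    for c in classes:
        df[f"percent_{c}"] = [
            percent(n, tot) if tot else 0 for n, tot in zip(df[c], df["total"])
        ]
    df["percent_of_all"] = [
        percent(tot, grand_total) if grand_total else 0 for tot in df["total"]
    ]
    df.index.name = group_by
    return df


def genome_prevalence(genome_table: pd.DataFrame) -> pd.Series:
    """Per-genus integer percent of SARP-positive genomes.

    ``genome_table`` has one row per genome with columns ``genus`` and
    ``sarp_positive`` (boolean).  Genera with zero genomes are excluded
    with a warning.
    """
    for col in ("genus", "sarp_positive"):
        if col not in genome_table.columns:
            raise ValueError(f"genome_table lacks required column {col!r}")
    out = {}
    for genus, grp in genome_table.groupby("genus"):
        total = len(grp)
        if total == 0:  # defensive; groupby never yields empty groups
            logger.warning("genus %s has zero genomes; excluded", genus)
            continue
        out[genus] = percent(int(grp["sarp_positive"].sum()), total)
    return pd.Series(out, name="percent_sarp_positive").sort_index()


def pairwise_similarity(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    query_id: str = "query",
    target_id: str = "target",
) -> SimilarityResult:
    """Global-alignment percent identity and similarity of two proteins.

    Needleman-Wunsch with affine gaps and end gaps penalized, BLOSUM62 by
    default.  identity = identical columns / alignment columns; similarity =
    columns whose substitution score is positive (identities included) /
    alignment columns.  Gap columns count only in the denominator.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if not a or not b:
        raise ValueError("pairwise_similarity requires two nonempty sequences")
    a, b = a.upper(), b.upper()
    sub = substitution_matrices.load(matrix)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = sub
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    ncol = len(row_a)
    ident = similar = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-" or cb == "-":
            continue
        if ca == cb:
            ident += 1
            similar += 1
        elif sub[ca][cb] > 0:
            similar += 1
    return SimilarityResult(
        query_id=query_id,
        target_id=target_id,
        identity_percent=100.0 * ident / ncol,
        similarity_percent=100.0 * similar / ncol,
        alignment_length=ncol,
    )


def census_to_tsv(df: pd.DataFrame) -> str:
    """Serialize a census table as TSV (one row per group)."""
    return df.to_csv(sep="\t")
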