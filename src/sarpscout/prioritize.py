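"""Gate and rank BGCs as candidates for SARP-driven activation.

The screening strategy prioritizes clusters that (a) contain at least one
cluster-situated SARP gene, (b) whose best SARP shows high similarity to
the reference activator (strictly greater than 55% amino-acid similarity by
default), and (c) that carry a consensus motif within an intergenic
(promoter-candidate) interval of the cluster.  The strategy itself defines
no total order among survivors, so the ranking key used here — best motif
identity, then best reference similarity, then cluster id — is this
package's own deterministic convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .bgclink import ClusterAnnotation
from .motif import DEFAULT_MIN_IDENTITY


@dataclass(frozen=True)
class PrioritizationThresholds:
    similarity_gate_percent: float = 55.0
    similarity_gate_strict: bool = True  # ">" per the strategy wording; False for ">="
    require_motif_in_promoter: bool = True
    require_cluster_situated_sarp: bool = True
    min_motif_identity: float = DEFAULT_MIN_IDENTITY

    def __post_init__(self) -> None:
        if not (0 < self.similarity_gate_percent <= 100):
            raise ValueError("similarity_gate_percent must be in (0, 100]")


@dataclass
class CandidateScore:
    cluster_id: str
    gates_passed: dict[str, bool]
    best_motif_identity: float
    best_sarp_similarity: float
    verdict: str = field(init=False)

    def __post_init__(self) -> None:
        self.verdict = "candidate" if all(self.gates_passed.values()) else "rejected"

    @property
    def rank_key(self) -> tuple:
        return (-self.best_motif_identity, -self.best_sarp_similarity, self.cluster_id)

    def failed_gates(self) -> list[str]:
        return [name for name, ok in self.gates_passed.items() if not ok]


def gate_candidates(
    annotations: Sequence[ClusterAnnotation],
    thresholds: PrioritizationThresholds = PrioritizationThresholds(),
) -> list[CandidateScore]:
    """Evaluate the activation gates for every cluster annotation.

    Gates (each can be disabled on the thresholds object):
      has_sarp           — at least one cluster-situated SARP gene
      sarp_similar       — best reference similarity above the gate
      has_promoter_motif — at least one intergenic motif hit at or above
                           the motif identity threshold
    A cluster is a candidate iff all enabled gates pass.
    """
    t = thresholds
    scores = []
    for a in annotations:
        gates: dict[str, bool] = {}
        if t.require_cluster_situated_sarp:
            gates["has_sarp"] = a.sarp_gene_count >= 1
        sim = a.best_papr2_similarity
        if t.similarity_gate_strict:
            gates["sarp_similar"] = sim is not None and sim > t.similarity_gate_percent
        else:
            gates["sarp_similar"] = sim is not None and sim >= t.similarity_gate_percent
        qualifying = [h for h in a.motif_hits if h.identity >= t.min_motif_identity - 1e-9]
        if t.require_motif_in_promoter:
            gates["has_promoter_motif"] = len(qualifying) >= 1
        scores.append(
            CandidateScore(
                cluster_id=a.cluster_id,
                gates_passed=gates,
                best_motif_identity=max((h.identity for h in qualifying), default=0.0),
                best_sarp_similarity=sim if sim is not None else 0.0,
            )
        )
    return scores


def rank(candidates: Sequence[CandidateScore]) -> list[CandidateScore]:
    """Candidates first (by rank key), then rejected clusters, deterministically."""
    passed = sorted((c for c in candidates if c.verdict == "candidate"), key=lambda c: c.rank_key)
    failed = sorted((c for c in candidates if c.verdict == "rejected"), key=lambda c: c.rank_key)
    return passed + failed


def strain_prioritized(candidates: Sequence[CandidateScore]) -> bool:
    """Strain-level roll-up: the genome is prioritized if any cluster passes."""
    return any(c.verdict == "candidate" for c in candidates)


def report_tsv(candidates: Sequence[CandidateScore]) -> str:
    """Ranked report as TSV with fixed columns and float formatting.

    Byte-identical for identical inputs; rejected clusters follow candidates
    with their failed gates listed.
    """
    header = (
        "rank\tcluster_id\tverdict\tbest_motif_identity\tbest_sarp_similarity"
        "\tfailed_gates\n"
    )
    rows = []
    for i, c in enumerate(rank(candidates), 1):
        rows.append(
            f"{i}\t{c.cluster_id}\t{c.verdict}\t{c.best_motif_identity:.4f}"
            f"\t{c.best_sarp_similarity:.1f}\t{','.join(c.failed_gates()) or '.'}"
        )
    return header + "\n".join(rows) + ("\n" if rows else "")
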