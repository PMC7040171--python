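"""Degenerate-consensus motif scanning for SARP binding sites.

SARPs of the PapR2 type recognize a degenerate heptamer, consensus
5'-GTCAGSS-3' (S = G or C), which in natural promoters occurs as direct
repeats separated by 4-bp spacers, typically overlapping the -35 element.
This module scores every window of a sequence against such a consensus on
one or both strands and reports hits above an identity threshold; tandem
heptamer-spacer arrays are recovered either by scanning with a multi-repeat
model or by chaining single-heptamer hits at the expected spacing.

Scoring is plain fractional identity to the consensus: a base matching the
IUPAC-allowed set at its position scores 1, anything else 0.  A G or C at an
S position is a full match — degenerate positions are satisfied, not
penalized.  An N in the scanned sequence never matches any consensus
position.  Spacer positions are excluded from the identity denominator
unless ``score_spacers`` is set, in which case they always count as matches
(there is no consensus to violate); that mode reproduces reported array
identities computed over all repeat-plus-spacer positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .utils import revcomp

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: PapR2-type SARP binding-site consensus heptamer.
DEFAULT_CONSENSUS = "GTCAGSS"

#: Default scan threshold: at most one mismatch in the heptamer.
DEFAULT_MIN_IDENTITY = 6.0 / 7.0

_EPS = 1e-9


def iupac_matcher(consensus: str) -> list[frozenset[str]]:
    """Per-position allowed-base sets for an IUPAC consensus string.

    Raises ValueError naming the offending position for invalid codes.
    N in a *site* matches nothing, but N in the consensus allows all bases.
    """
    if not consensus:
        raise ValueError("consensus must be nonempty")
    sets = []
    for i, code in enumerate(consensus.upper()):
        try:
            sets.append(IUPAC_CODES[code])
        except KeyError:
            raise ValueError(
                f"invalid IUPAC code {code!r} at consensus position {i}"
            ) from None
    return sets


@dataclass(frozen=True)
class MotifModel:
    """A heptamer consensus with optional direct-repeat geometry.

    repeat_count=1 scans for single heptamers; repeat_count=r with
    spacer_length=s scans for r tandem copies separated by s unconstrained
    bases, total span r*len(consensus) + (r-1)*s.
    """

    consensus: str = DEFAULT_CONSENSUS
    repeat_count: int = 1
    spacer_length: int = 4
    score_spacers: bool = False
    min_identity: float = DEFAULT_MIN_IDENTITY

    def __post_init__(self) -> None:
        iupac_matcher(self.consensus)  # validates
        if self.repeat_count < 1:
            raise ValueError("repeat_count must be >= 1")
        if self.spacer_length < 0:
            raise ValueError("spacer_length must be >= 0")
        if not (0.0 <= self.min_identity <= 1.0):
            raise ValueError("min_identity must be in [0, 1]")

    @property
    def heptamer_length(self) -> int:
        return len(self.consensus)

    @property
    def site_span(self) -> int:
        h, r, s = self.heptamer_length, self.repeat_count, self.spacer_length
        return r * h + (r - 1) * s

    def positions(self) -> list[tuple[int, frozenset[str] | None]]:
        """(offset, allowed set) for every site position; None marks a spacer."""
        allowed = iupac_matcher(self.consensus)
        out: list[tuple[int, frozenset[str] | None]] = []
        off = 0
        for rep in range(self.repeat_count):
            for a in allowed:
                out.append((off, a))
                off += 1
            if rep < self.repeat_count - 1:
                for _ in range(self.spacer_length):
                    out.append((off, None))
                    off += 1
        return out

    def scored_position_count(self) -> int:
        if self.score_spacers:
            return self.site_span
        return self.repeat_count * self.heptamer_length


#: Preset matching the tri-heptamer array geometry with spacers scored:
#: 3 repeats x 7 positions + 2 spacers x 4 = 29 scored positions, so one
#: heptamer mismatch gives 28/29 = 96.55% and ten give 19/29 = 65.52%.
TRI_HEPTAMER_ARRAY = MotifModel(
    consensus=DEFAULT_CONSENSUS,
    repeat_count=3,
    spacer_length=4,
    score_spacers=True,
    min_identity=0.0,
)


@dataclass(frozen=True)
class MotifHit:
    """A scored motif occurrence, in plus-strand coordinates.

    site_sequence is given 5'->3' on the hit strand.
    """

    record_id: str
    start: int
    end: int
    strand: str
    identity: float
    site_sequence: str
    repeat_count_matched: int = 1


def score_site(site: str, model: MotifModel) -> float:
    """Identity of one site to the model consensus.

    identity = matching scored positions / total scored positions.  Spacer
    positions count (as automatic matches, unless the site base is N) only
    when model.score_spacers is set.
    """
    site = site.upper()
    if len(site) != model.site_span:
        raise ValueError(
            f"site length {len(site)} does not match model span {model.site_span}"
        )
    matches = 0
    scored = 0
    for off, allowed in model.positions():
        base = site[off]
        if allowed is None:
            if not model.score_spacers:
                continue
            scored += 1
            if base != "N":
                matches += 1
        else:
            scored += 1
            if base in allowed:  # N is never in an allowed set
                matches += 1
    return matches / scored


_BASE_TO_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_TO_CODE[ord(_b)] = _i
_BASE_TO_CODE[ord("N")] = 4


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    return _BASE_TO_CODE[arr]


def _scan_one_strand(codes: np.ndarray, model: MotifModel) -> np.ndarray:
    """Identity of every window on one strand (vectorized)."""
    span = model.site_span
    n_win = codes.size - span + 1
    if n_win <= 0:
        return np.empty(0)
    matches = np.zeros(n_win, dtype=np.int32)
    scored = 0
    for off, allowed in model.positions():
        window_bases = codes[off : off + n_win]
        if allowed is None:
            if not model.score_spacers:
                continue
            scored += 1
            matches += window_bases != 4  # any real base satisfies a spacer
        else:
            scored += 1
            mask = np.zeros(5, dtype=bool)
            for b in allowed:
                mask[_BASE_TO_CODE[ord(b)]] = True
            matches += mask[window_bases]
    return matches / scored


def scan(
    sequence: str,
    model: MotifModel | None = None,
    strands: str = "both",
    record_id: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """Scan a sequence for motif sites at identity >= model.min_identity.

    Every window of the model span on each requested strand is scored.
    Minus-strand hits are reported in plus-strand coordinates with the site
    sequence given on the hit strand.  Hits are sorted by (start, strand '+'
    before '-', identity descending).  ``offset`` shifts reported coordinates
    (for scanning a slice of a larger replicon).
    """
    if model is None:
        model = MotifModel()
    if strands not in ("+", "-", "both"):
        raise ValueError("strands must be '+', '-' or 'both'")
    sequence = sequence.upper()
    span = model.site_span
    L = len(sequence)
    hits: list[MotifHit] = []
    threshold = model.min_identity - _EPS

    if strands in ("+", "both") and L >= span:
        ident = _scan_one_strand(_encode(sequence), model)
        for pos in np.nonzero(ident >= threshold)[0]:
            p = int(pos)
            hits.append(
                MotifHit(
                    record_id=record_id,
                    start=offset + p,
                    end=offset + p + span,
                    strand="+",
                    identity=float(ident[p]),
                    site_sequence=sequence[p : p + span],
                    repeat_count_matched=model.repeat_count,
                )
            )
    if strands in ("-", "both") and L >= span:
        rc = revcomp(sequence)
        ident = _scan_one_strand(_encode(rc), model)
        for pos in np.nonzero(ident >= threshold)[0]:
            p = int(pos)
            start = L - p - span  # map back to plus-strand coordinates
            hits.append(
                MotifHit(
                    record_id=record_id,
                    start=offset + start,
                    end=offset + start + span,
                    strand="-",
                    identity=float(ident[p]),
                    site_sequence=rc[p : p + span],
                    repeat_count_matched=model.repeat_count,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand, -h.identity))
    return hits


@dataclass
class RepeatArray:
    """A maximal run of same-strand heptamer hits at repeat spacing."""

    hits: list[MotifHit]
    start: int = field(init=False)
    end: int = field(init=False)
    strand: str = field(init=False)
    combined_identity: float = field(init=False)

    def __post_init__(self) -> None:
        self.start = self.hits[0].start
        self.end = self.hits[-1].end
        self.strand = self.hits[0].strand
        self.combined_identity = sum(h.identity for h in self.hits) / len(self.hits)

    def __len__(self) -> int:
        return len(self.hits)


def find_repeat_arrays(
    hits: Sequence[MotifHit],
    spacer_length: int = 4,
    tolerance: int = 0,
    heptamer_length: int = 7,
) -> list[RepeatArray]:
    """Chain single-heptamer hits into direct-repeat arrays.

    Consecutive same-strand hits whose start-to-start distance is
    heptamer_length + spacer_length +/- tolerance are grouped into one
    maximal run; singleton hits become arrays of one.  Hits must come from
    one record; strands are chained independently.
    """
    records = {h.record_id for h in hits}
    if len(records) > 1:
        raise ValueError(f"hits span multiple records: {sorted(records)}")
    period = heptamer_length + spacer_length
    arrays: list[RepeatArray] = []
    for strand in ("+", "-"):
        run: list[MotifHit] = []
        for h in sorted((h for h in hits if h.strand == strand), key=lambda h: h.start):
            if run and abs(h.start - run[-1].start - period) <= tolerance:
                run.append(h)
            else:
                if run:
                    arrays.append(RepeatArray(run))
                run = [h]
        if run:
            arrays.append(RepeatArray(run))
    arrays.sort(key=lambda a: (a.start, a.strand))
    return arrays


def hits_to_bed(hits: Iterable[MotifHit]) -> str:
    """BED6 text for motif hits (score = round(identity*1000))."""
    lines = [
        f"{h.record_id}\t{h.start}\t{h.end}\t{h.site_sequence}"
        f"\t{round(h.identity * 1000)}\t{h.strand}"
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def hits_to_tsv(hits: Iterable[MotifHit]) -> str:
    """TSV text for motif hits with site sequences and identities."""
    header = "record_id\tstart\tend\tstrand\tidentity\tsite_sequence\n"
    rows = [
        f"{h.record_id}\t{h.start}\t{h.end}\t{h.strand}"
        f"\t{h.identity:.4f}\t{h.site_sequence}"
        for h in hits
    ]
    return header + "\n".join(rows) + ("\n" if rows else "")


def load_motif_config(path) -> MotifModel:
    """Load a MotifModel from a plain-text key=value config file."""
    kwargs: dict = {}
    casts = {
        "consensus": str,
        "repeat_count": int,
        "spacer_length": int,
        "score_spacers": lambda v: v.lower() in ("1", "true", "yes"),
        "min_identity": float,
    }
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in casts:
                raise ValueError(f"unknown motif config key {key!r}")
            kwargs[key] = casts[key](value.strip())
    return MotifModel(**kwargs)
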