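"""Consensus prophage-region calling.

Candidate regions come from an external detector (a primary dsDNA score in
[0, 1], optional host-flank "contamination" intervals, and a boolean
secondary-confirmation flag from a second detector).  Retention follows a
two-tier consensus rule applied after host-flank trimming and a minimum
length filter:

* ``primary_score >= hi`` (default 0.9): retained as ``high_confidence``;
* ``lo <= primary_score < hi`` (default [0.5, 0.9)): retained only if the
  secondary detector confirmed the region (``secondary_confirmed``).

The stage order is fixed: score screen at ``lo`` -> flank trimming ->
length filter -> consensus.  Each stage's survivor count is recorded in
:class:`StageCounts` so the bookkeeping identity
``n_total == n_high + n_confirmed`` can be checked on every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

__all__ = [
    "CandidateRegion",
    "ProphageRegion",
    "StageCounts",
    "screen_primary",
    "trim_host_flanks",
    "filter_length",
    "apply_consensus",
    "composition_percent",
    "merge_intervals",
    "call_regions",
]

#: retention tiers
HIGH_CONFIDENCE = "high_confidence"
SECONDARY_CONFIRMED = "secondary_confirmed"


@dataclass(frozen=True)
class CandidateRegion:
    """A detector-proposed genomic interval (0-based, half-open)."""

    genome_id: str
    start: int
    end: int
    primary_score: float
    contamination: tuple[tuple[int, int], ...] = ()
    secondary_confirmed: bool = False
    external_intact: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.primary_score <= 1.0):
            raise ValueError(f"primary_score must be in [0, 1], got {self.primary_score}")
        if self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ProphageRegion:
    """A retained prophage region after trimming, filtering and consensus."""

    region_id: str
    genome_id: str
    start: int
    end: int
    tier: str
    primary_score: float
    external_intact: bool = False
    sequence: str | None = field(default=None, repr=False, compare=False)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class StageCounts:
    """Survivor counts after each pipeline stage."""

    n_input: int = 0
    n_screened: int = 0
    n_trimmed: int = 0
    n_length_ok: int = 0
    n_high: int = 0
    n_confirmed: int = 0

    @property
    def n_total(self) -> int:
        return self.n_high + self.n_confirmed

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_screened": self.n_screened,
            "n_trimmed": self.n_trimmed,
            "n_length_ok": self.n_length_ok,
            "n_high": self.n_high,
            "n_confirmed": self.n_confirmed,
            "n_total": self.n_total,
        }


def screen_primary(
    candidates: Sequence[CandidateRegion], lo: float = 0.5
) -> list[CandidateRegion]:
    """Keep candidates whose primary score reaches ``lo`` (inclusive).

    Order-preserving; a score of exactly ``lo`` is retained.
    """
    return [c for c in candidates if c.primary_score >= lo]


def trim_host_flanks(candidate: CandidateRegion) -> CandidateRegion:
    """Subtract host-flank contamination intervals from a candidate.

    Contamination intervals must abut the region's current start or end
    (they are flanks); an interval strictly interior to the region raises
    ``ValueError``.  Trimming that consumes the whole region yields a
    zero-length interval, which the length filter drops downstream.
    """
    start, end = candidate.start, candidate.end
    # Sort so left flanks are consumed before right ones regardless of input order.
    pending = sorted(candidate.contamination)
    for cs, ce in pending:
        if cs < candidate.start or ce > candidate.end:
            raise ValueError(
                f"contamination [{cs}, {ce}) outside region "
                f"[{candidate.start}, {candidate.end})"
            )
    for cs, ce in pending:
        if start >= end:
            break  # already empty
        if cs <= start:
            start = max(start, ce)
        elif ce >= end:
            end = min(end, cs)
        else:
            raise ValueError(
                f"contamination [{cs}, {ce}) is interior to [{start}, {end}); "
                "only flanks are trimmable"
            )
    if start > end:
        start = end
    return replace(candidate, start=start, end=end, contamination=())


def filter_length(
    candidates: Sequence[CandidateRegion], min_len: int = 5000
) -> list[CandidateRegion]:
    """Keep candidates at least ``min_len`` bp long (inclusive threshold)."""
    return [c for c in candidates if c.length >= min_len]


def apply_consensus(
    candidates: Sequence[CandidateRegion],
    hi: float = 0.9,
    lo: float = 0.5,
    counts: StageCounts | None = None,
) -> list[ProphageRegion]:
    """Apply the two-tier retention rule to screened, trimmed candidates.

    Retained iff ``primary_score >= hi`` (tier ``high_confidence``) or
    ``lo <= primary_score < hi`` with the secondary-confirmation flag set
    (tier ``secondary_confirmed``).
    """
    regions: list[ProphageRegion] = []
    for cand in candidates:
        if cand.primary_score >= hi:
            tier = HIGH_CONFIDENCE
        elif cand.primary_score >= lo and cand.secondary_confirmed:
            tier = SECONDARY_CONFIRMED
        else:
            continue
        regions.append(
            ProphageRegion(
                region_id=f"{cand.genome_id}|{cand.start}-{cand.end}",
                genome_id=cand.genome_id,
                start=cand.start,
                end=cand.end,
                tier=tier,
                primary_score=cand.primary_score,
                external_intact=cand.external_intact,
            )
        )
    if counts is not None:
        counts.n_high = sum(r.tier == HIGH_CONFIDENCE for r in regions)
        counts.n_confirmed = sum(r.tier == SECONDARY_CONFIRMED for r in regions)
    return regions


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def composition_percent(
    genome_length: int, intervals: Sequence[tuple[int, int]]
) -> float:
    """Percent of the genome covered by (merged) prophage intervals.

    Overlapping regions are merged before summation so the result never
    exceeds 100.
    """
    if genome_length <= 0:
        raise ValueError(f"genome_length must be positive, got {genome_length}")
    covered = sum(e - s for s, e in merge_intervals(intervals))
    return 100.0 * covered / genome_length


def call_regions(
    candidates: Sequence[CandidateRegion],
    genomes: dict[str, str] | None = None,
    min_len: int = 5000,
    hi: float = 0.9,
    lo: float = 0.5,
) -> tuple[list[ProphageRegion], StageCounts]:
    """Run the full calling pipeline: screen -> trim -> length filter -> consensus.

    If ``genomes`` (id -> sequence) is given, each retained region carries
    its extracted sequence.
    """
    counts = StageCounts(n_input=len(candidates))
    screened = screen_primary(candidates, lo=lo)
    counts.n_screened = len(screened)
    trimmed = [trim_host_flanks(c) for c in screened]
    trimmed = [c for c in trimmed if c.length > 0]
    counts.n_trimmed = len(trimmed)
    long_enough = filter_length(trimmed, min_len=min_len)
    counts.n_length_ok = len(long_enough)
    regions = apply_consensus(long_enough, hi=hi, lo=lo, counts=counts)
    if genomes is not None:
        regions = [
            replace(r, sequence=genomes[r.genome_id][r.start : r.end]) for r in regions
        ]
    return regions, counts
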