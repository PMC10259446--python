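"""ANI-based dereplication of prophage regions into populations.

Two prophage regions belong to the same *population* when their average
nucleotide identity (ANI) exceeds 95% over at least 85% of the shorter
sequence — the standard viral population boundary.  ANI here is
fragment-based: the shorter sequence is partitioned into non-overlapping
~1 kb fragments, each fragment is mapped to the longer sequence by
seed-and-extend (exact k-mer seeds vote for a diagonal; the best diagonal
is scored by gapless comparison, both orientations tried), and fragments
whose best identity falls below 70% count as unaligned.  ANI is the
length-weighted mean identity of the aligned fragments; the aligned
fraction is the share of the shorter sequence's bases in aligned
fragments.

Gapless extension is exact under a substitution-only divergence model and
a close approximation for real prophages at the >=95% identity scale that
matters for the population cutoff.  Populations are single-linkage
connected components of the qualifying-pair graph — deterministic and
insertion-order independent.  Representative selection keeps, for every
host species present in a population, that species' longest member (the
multi-host rule: a population spanning two host species keeps one
representative per species).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "ANIResult",
    "PhagePopulation",
    "DereplicationSummary",
    "pairwise_ani",
    "compute_ani_matrix",
    "cluster_populations",
    "select_representatives",
    "dereplicate",
]

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i

_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _revcomp(seq: str) -> str:
    return seq.encode().translate(_COMPLEMENT)[::-1].decode()


def _kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all overlapping k-mers (2-bit packed)."""
    if len(enc) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(enc, k).astype(np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return win @ powers


@dataclass(frozen=True)
class ANIResult:
    """Pairwise ANI between two regions (symmetric in the pair)."""

    id_a: str
    id_b: str
    ani: float  # percent, length-weighted over aligned fragments
    aligned_fraction: float  # percent of the shorter sequence aligned

    def involves(self, region_id: str) -> bool:
        return region_id in (self.id_a, self.id_b)


@dataclass
class PhagePopulation:
    population_id: str
    members: list[str]
    representatives: list[str]

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


@dataclass
class DereplicationSummary:
    n_regions: int
    n_singletons: int
    n_populations: int  # multi-member populations
    n_representatives: int


class _FragmentIndex:
    """k-mer position index of one target sequence."""

    def __init__(self, seq: str, k: int):
        self.k = k
        self.length = len(seq)
        codes = _kmer_codes(_encode(seq), k)
        order = np.argsort(codes, kind="stable")
        sorted_codes = codes[order]
        self._codes = sorted_codes
        self._positions = order
        self.enc = _encode(seq)

    def positions(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return self._positions[lo:hi]


def _best_fragment_identity(
    frag_enc: np.ndarray,
    index: _FragmentIndex,
    k: int,
    max_diagonals: int,
) -> float:
    """Best gapless identity of a fragment against the indexed target."""
    codes = _kmer_codes(frag_enc, k)
    votes: Counter[int] = Counter()
    for i, code in enumerate(codes.tolist()):
        for pos in index.positions(code).tolist():
            votes[pos - i] += 1
    if not votes:
        return 0.0
    flen = len(frag_enc)
    best = 0.0
    # ties broken by smaller offset for determinism
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[:max_diagonals]
    for off, _count in ranked:
        t0 = max(off, 0)
        t1 = min(off + flen, index.length)
        if t1 <= t0:
            continue
        f0 = t0 - off
        matches = int((frag_enc[f0 : f0 + (t1 - t0)] == index.enc[t0:t1]).sum())
        ident = matches / flen  # overhang counts as mismatch
        if ident > best:
            best = ident
    return best


def _fragment_bounds(length: int, fragment_size: int) -> list[tuple[int, int]]:
    """Partition [0, length) into floor(length/fragment_size) near-equal
    non-overlapping fragments covering every base (so the aligned fraction
    of a self-comparison is exactly 100%)."""
    n = max(1, length // fragment_size)
    edges = np.linspace(0, length, n + 1).astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n)]


def pairwise_ani(
    seq_a: str,
    seq_b: str,
    id_a: str = "a",
    id_b: str = "b",
    fragment_size: int = 1000,
    min_fragment_identity: float = 0.70,
    k: int = 13,
    max_diagonals: int = 8,
    min_length: int = 5000,
) -> ANIResult:
    """Fragment-based ANI between two sequences.

    The shorter sequence is fragmented (equal lengths: the sequence of the
    lexicographically smaller id), each fragment is aligned gaplessly at
    its best seeded diagonal in either orientation, and fragments under
    ``min_fragment_identity`` count as unaligned.  Deterministic and
    symmetric in the pair.
    """
    if len(seq_a) < min_length or len(seq_b) < min_length:
        raise ValueError(f"sequences must be >= {min_length} bp")
    # canonical orientation of the comparison: shorter is fragmented
    if (len(seq_a), id_a) <= (len(seq_b), id_b):
        short, long_ = seq_a, seq_b
    else:
        short, long_ = seq_b, seq_a
    fwd = _FragmentIndex(long_, k)
    rev = _FragmentIndex(_revcomp(long_), k)
    short_enc = _encode(short)
    aligned_bases = 0
    weighted = 0.0
    for s, e in _fragment_bounds(len(short), fragment_size):
        frag = short_enc[s:e]
        ident = _best_fragment_identity(frag, fwd, k, max_diagonals)
        if ident < 1.0:
            ident = max(ident, _best_fragment_identity(frag, rev, k, max_diagonals))
        if ident >= min_fragment_identity:
            aligned_bases += len(frag)
            weighted += ident * len(frag)
    if aligned_bases:
        ani = 100.0 * weighted / aligned_bases
    else:
        ani = 0.0
    af = 100.0 * aligned_bases / len(short)
    return ANIResult(id_a=id_a, id_b=id_b, ani=ani, aligned_fraction=af)


def compute_ani_matrix(
    regions: Mapping[str, str],
    prescreen_k: int = 16,
    prescreen_min_shared: int = 30,
    **ani_kwargs,
) -> list[ANIResult]:
    """All-vs-all ANI over a region set, with a shared-k-mer prescreen.

    Pairs sharing fewer than ``prescreen_min_shared`` canonical 16-mers are
    skipped (reported with ani = 0, aligned_fraction = 0): unrelated
    sequences share essentially none, while pairs anywhere near the 95%
    population cutoff share thousands.
    """
    ids = sorted(regions)
    ksets: dict[str, set[int]] = {}
    for rid in ids:
        fwd = _kmer_codes(_encode(regions[rid]), prescreen_k)
        rev = _kmer_codes(_encode(_revcomp(regions[rid])), prescreen_k)
        # canonical k-mer = min(code, code of the reverse complement)
        ksets[rid] = set(np.minimum(fwd, rev[::-1]).tolist())
    out: list[ANIResult] = []
    for i, ra in enumerate(ids):
        for rb in ids[i + 1 :]:
            shared = len(ksets[ra] & ksets[rb])
            if shared < prescreen_min_shared:
                out.append(ANIResult(ra, rb, 0.0, 0.0))
                continue
            out.append(
                pairwise_ani(regions[ra], regions[rb], id_a=ra, id_b=rb, **ani_kwargs)
            )
    return out


def cluster_populations(
    region_ids: Sequence[str],
    ani_results: Sequence[ANIResult],
    ani_min: float = 95.0,
    af_min: float = 85.0,
) -> list[PhagePopulation]:
    """Single-linkage populations: connected components of the graph with
    an edge for every pair with ani > ``ani_min`` (strict) and
    aligned_fraction >= ``af_min``.  Populations are ordered by smallest
    member id; representatives are left empty here."""
    g = nx.Graph()
    g.add_nodes_from(region_ids)
    for r in ani_results:
        if r.ani > ani_min and r.aligned_fraction >= af_min:
            g.add_edge(r.id_a, r.id_b)
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    return [
        PhagePopulation(population_id=f"pop{i:03d}", members=c, representatives=[])
        for i, c in enumerate(comps)
    ]


def select_representatives(
    population: PhagePopulation,
    host_map: Mapping[str, str],
    lengths: Mapping[str, int],
) -> list[str]:
    """One representative per host species present in the population: that
    species' longest member, ties broken by lexicographically smallest id."""
    by_species: dict[str, list[str]] = {}
    for m in population.members:
        if m not in host_map:
            raise KeyError(f"no host species for region {m}")
        by_species.setdefault(host_map[m], []).append(m)
    reps = []
    for sp in sorted(by_species):
        members = by_species[sp]
        reps.append(min(members, key=lambda m: (-lengths[m], m)))
    return sorted(reps)


def dereplicate(
    regions: Mapping[str, str],
    host_map: Mapping[str, str],
    ani_min: float = 95.0,
    af_min: float = 85.0,
    **ani_kwargs,
) -> tuple[list[PhagePopulation], list[ANIResult], DereplicationSummary]:
    """Full dereplication: all-vs-all ANI, clustering, representatives."""
    results = compute_ani_matrix(regions, **ani_kwargs)
    populations = cluster_populations(sorted(regions), results, ani_min, af_min)
    lengths = {rid: len(seq) for rid, seq in regions.items()}
    for pop in populations:
        pop.representatives = select_representatives(pop, host_map, lengths)
    n_singletons = sum(p.is_singleton for p in populations)
    summary = DereplicationSummary(
        n_regions=len(regions),
        n_singletons=n_singletons,
        n_populations=len(populations) - n_singletons,
        n_representatives=sum(len(p.representatives) for p in populations),
    )
    return populations, results, summary
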