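"""Independent oracles used by the test suite.

These deliberately take a different computational route than the package:

* a full dynamic-programming Smith-Waterman (numba-jitted) for fragment
  identities, against the package's seed-and-extend gapless ANI;
* a literal transcription of the Meng-Rosenthal-Rubin z formula;
* an exhaustive permutation oracle for the Kruskal-Wallis p-value built on
  scipy's own H statistic.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from numba import njit
from scipy import stats as sps

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i

_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def _enc(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.encode().translate(_COMPLEMENT)[::-1].decode()


@njit(cache=True)
def _sw_matches(a, b, match, mismatch, gap):  # pragma: no cover - jitted
    """Smith-Waterman best local score and the match count on its path."""
    n, m = len(a), len(b)
    h = np.zeros((n + 1, m + 1), dtype=np.int32)
    mat = np.zeros((n + 1, m + 1), dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = h[i - 1, j - 1] + s
            up = h[i - 1, j] + gap
            left = h[i, j - 1] + gap
            v = diag
            mv = mat[i - 1, j - 1] + (1 if a[i - 1] == b[j - 1] else 0)
            if up > v:
                v = up
                mv = mat[i - 1, j]
            if left > v:
                v = left
                mv = mat[i, j - 1]
            if v < 0:
                v = 0
                mv = 0
            h[i, j] = v
            mat[i, j] = mv
            if v > best:
                best = v
                bi, bj = i, j
    return best, mat[bi, bj]


def sw_fragment_identity(
    fragment: str, target: str, match: int = 2, mismatch: int = -2, gap: int = -4
) -> float:
    """Identity of the fragment's best local DP alignment against the
    target, expressed over the full fragment length (unaligned fragment
    bases count as mismatches), maximized over both orientations."""
    fa = _enc(fragment)
    best = 0
    for t in (target, revcomp(target)):
        _, matches = _sw_matches(fa, _enc(t), match, mismatch, gap)
        best = max(best, matches)
    return best / len(fragment)


def dp_ani(seq_a: str, seq_b: str, fragment_size: int = 1000,
           min_fragment_identity: float = 0.70) -> tuple[float, float]:
    """Fragment ANI with every fragment scored by full DP (the oracle
    counterpart of ``prophage_census.dereplication.pairwise_ani``)."""
    short, long_ = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
    n = max(1, len(short) // fragment_size)
    edges = np.linspace(0, len(short), n + 1).astype(int)
    aligned = 0
    weighted = 0.0
    for i in range(n):
        frag = short[edges[i]:edges[i + 1]]
        ident = sw_fragment_identity(frag, long_)
        if ident >= min_fragment_identity:
            aligned += len(frag)
            weighted += ident * len(frag)
    ani = 100.0 * weighted / aligned if aligned else 0.0
    return ani, 100.0 * aligned / len(short)


def meng_z_reference(r1: float, r2: float, r_yy: float, n: int) -> float:
    """Literal transcription of the published z formula for comparing two
    overlapping dependent correlations."""
    rbar_sq = (r1 * r1 + r2 * r2) / 2.0
    f = (1.0 - r_yy) / (2.0 * (1.0 - rbar_sq))
    if f > 1.0:
        f = 1.0
    h = (1.0 - f * rbar_sq) / (1.0 - rbar_sq)
    z1 = 0.5 * math.log((1.0 + r1) / (1.0 - r1))
    z2 = 0.5 * math.log((1.0 + r2) / (1.0 - r2))
    return (z1 - z2) * math.sqrt((n - 3.0) / (2.0 * (1.0 - r_yy) * h))


def kruskal_exact_p(groups) -> float:
    """Exhaustive permutation p-value for Kruskal-Wallis, using scipy's H
    on every distinct relabelling of the pooled observations."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    sizes = [len(g) for g in groups]
    h_obs = sps.kruskal(*groups).statistic
    count = total = 0
    for perm in itertools.permutations(range(len(pooled))):
        vals = pooled[list(perm)]
        start = 0
        gs = []
        for s in sizes:
            gs.append(vals[start:start + s])
            start += s
        h = sps.kruskal(*gs).statistic
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return count / total
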