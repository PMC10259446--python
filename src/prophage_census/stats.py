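"""Lysogen survey statistics.

Per-genome prophage counts and composition, per-species summaries
(median with sample SD — an unusual but conventional pairing in survey
tables — plus min and max), Kruskal-Wallis tests across host species,
Spearman correlations of genome size with prophage count and with
prophage composition, and the Meng-Rosenthal-Rubin z test comparing those
two overlapping correlations (they share the genome-size variable).

The Meng z statistic for correlations r1 = r(x, y1) and r2 = r(x, y2)
with r_yy = r(y1, y2) over N cases:

    rbar2 = (r1^2 + r2^2) / 2
    f     = min(1, (1 - r_yy) / (2 (1 - rbar2)))        (capped at 1)
    h     = (1 - f * rbar2) / (1 - rbar2)
    z     = (atanh r1 - atanh r2) * sqrt((N - 3) / (2 (1 - r_yy) h))

with a two-sided normal p-value and a normal-theory confidence interval
on the Fisher-z difference atanh(r1) - atanh(r2).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calling import ProphageRegion, composition_percent
from .intactness import IntactCall

__all__ = [
    "SpeciesSummary",
    "CorrelationComparison",
    "SurveyResult",
    "summarize_species",
    "kruskal_wallis",
    "spearman",
    "meng_z",
    "build_survey_table",
    "run_survey",
    "SURVEY_METRICS",
]

SURVEY_METRICS = (
    "n_prophages",
    "n_intact",
    "composition_pct",
    "intact_composition_pct",
)


# ---------------------------------------------------------------------------
# species summaries
# ---------------------------------------------------------------------------


def summarize_species(
    survey: pd.DataFrame, metrics: Sequence[str] = SURVEY_METRICS
) -> pd.DataFrame:
    """Per-species median, sample SD (n-1 denominator), min and max.

    A species with a single genome has no sample SD; it is reported as 0.0
    and flagged by ``sd_defined = False``.
    """
    rows = []
    for species, grp in survey.groupby("species", sort=True):
        row: dict[str, object] = {"species": species, "n_genomes": len(grp)}
        row["sd_defined"] = len(grp) > 1
        for m in metrics:
            vals = grp[m].to_numpy(dtype=float)
            row[f"{m}_median"] = float(np.median(vals))
            row[f"{m}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            row[f"{m}_min"] = float(vals.min())
            row[f"{m}_max"] = float(vals.max())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def _kw_h(groups: Sequence[np.ndarray]) -> float:
    """Kruskal-Wallis H with midranks and tie correction."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie == 0.0:  # every observation identical
        return 0.0
    return h / tie


def kruskal_wallis(
    groups: Sequence[Sequence[float]], method: str = "asymptotic"
) -> tuple[float, float]:
    """Kruskal-Wallis test across >= 2 groups.

    ``method="asymptotic"`` takes p from the chi-square distribution with
    k-1 degrees of freedom; ``method="exact"`` enumerates every partition
    of the pooled observations into groups of the observed sizes (only
    feasible for tiny N).  All observations identical gives H = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    n = sum(len(a) for a in arrs)
    if n < 3:
        raise ValueError("need >= 3 observations in total")
    h = _kw_h(arrs)
    if np.unique(np.concatenate(arrs)).size == 1:
        return 0.0, 1.0
    if method == "asymptotic":
        p = float(sps.chi2.sf(h, len(arrs) - 1))
    elif method == "exact":
        if n > 10:
            raise ValueError("exact method only supported for N <= 10")
        pooled = np.concatenate(arrs)
        sizes = [len(a) for a in arrs]
        count = 0
        total = 0
        for perm in _partitions(n, sizes):
            hp = _kw_h([pooled[list(ix)] for ix in perm])
            total += 1
            if hp >= h - 1e-12:
                count += 1
        p = count / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(h), p


def _partitions(n: int, sizes: Sequence[int]):
    """All ways to split indices 0..n-1 into ordered groups of the given sizes."""
    def rec(remaining: tuple[int, ...], sizes: Sequence[int]):
        if not sizes:
            yield ()
            return
        for combo in itertools.combinations(remaining, sizes[0]):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in rec(rest, sizes[1:]):
                yield (combo,) + tail

    yield from rec(tuple(range(n)), sizes)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on midranks) with its p-value.

    Zero rank variance in either variable is degenerate and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with >= 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("zero rank variance: correlation undefined")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Meng-Rosenthal-Rubin comparison of overlapping correlations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationComparison:
    r1: float
    r2: float
    r_yy: float
    n: int
    z: float
    p: float
    ci_low: float  # CI on the Fisher-z difference atanh(r1) - atanh(r2)
    ci_high: float
    ci_scale: str = "fisher_z_difference"
    alpha: float = 0.05


def meng_z(r1: float, r2: float, r_yy: float, n: int, alpha: float = 0.05) -> CorrelationComparison:
    """Compare two overlapping dependent correlations (shared predictor).

    ``r1`` and ``r2`` are the correlations of the shared variable with
    each of two outcomes; ``r_yy`` is the correlation between the
    outcomes.  ``f`` is capped at 1 as the original derivation instructs.
    Antisymmetric: swapping r1 and r2 negates z exactly.
    """
    if n < 4:
        raise ValueError("need N >= 4")
    if not (-1.0 < r1 < 1.0 and -1.0 < r2 < 1.0):
        raise ValueError("r1 and r2 must be in (-1, 1)")
    if r_yy >= 1.0:
        if r1 != r2:
            raise ValueError("r_yy = 1 with r1 != r2: degenerate denominator")
        r_yy = 1.0
    rbar2 = (r1**2 + r2**2) / 2.0
    f = min(1.0, (1.0 - r_yy) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    dz = math.atanh(r1) - math.atanh(r2)
    if r1 == r2:
        z = 0.0
        se = float("nan") if r_yy == 1.0 else math.sqrt(2.0 * (1.0 - r_yy) * h / (n - 3))
    else:
        se = math.sqrt(2.0 * (1.0 - r_yy) * h / (n - 3))
        z = dz / se
    p = 2.0 * sps.norm.sf(abs(z))
    if math.isnan(se):
        lo = hi = dz
    else:
        crit = sps.norm.ppf(1.0 - alpha / 2.0)
        lo, hi = dz - crit * se, dz + crit * se
    return CorrelationComparison(
        r1=r1, r2=r2, r_yy=r_yy, n=n, z=float(z), p=float(p),
        ci_low=float(lo), ci_high=float(hi), alpha=alpha,
    )


# ---------------------------------------------------------------------------
# survey orchestration
# ---------------------------------------------------------------------------


@dataclass
class SurveyResult:
    per_genome: pd.DataFrame
    per_species: pd.DataFrame
    tests: dict = field(default_factory=dict)


def build_survey_table(
    genome_lengths: Mapping[str, int],
    hosts: Mapping[str, str],
    regions: Sequence[ProphageRegion],
    intact_calls: Mapping[str, IntactCall],
) -> pd.DataFrame:
    """Per-genome survey rows: counts and composition, total and intact.

    Every genome appears, including lysogen-free ones (count 0); intact
    composition uses only regions classified intact.
    """
    by_genome: dict[str, list[ProphageRegion]] = {g: [] for g in genome_lengths}
    for r in regions:
        by_genome[r.genome_id].append(r)
    rows = []
    for gid in sorted(genome_lengths):
        regs = by_genome[gid]
        glen = genome_lengths[gid]
        intact_regs = [r for r in regs if intact_calls[r.region_id].intact]
        rows.append(
            {
                "genome_id": gid,
                "species": hosts[gid],
                "genome_length": glen,
                "n_prophages": len(regs),
                "n_intact": len(intact_regs),
                "composition_pct": composition_percent(
                    glen, [(r.start, r.end) for r in regs]
                ),
                "intact_composition_pct": composition_percent(
                    glen, [(r.start, r.end) for r in intact_regs]
                ),
            }
        )
    return pd.DataFrame(rows)


def run_survey(
    genome_lengths: Mapping[str, int],
    hosts: Mapping[str, str],
    regions: Sequence[ProphageRegion],
    intact_calls: Mapping[str, IntactCall],
) -> SurveyResult:
    """Full survey: per-genome table, species summaries, and tests.

    With fewer than two species the group tests are skipped with a
    warning; the correlations still require non-degenerate inputs and are
    reported as None when undefined (e.g. no prophages anywhere).
    """
    per_genome = build_survey_table(genome_lengths, hosts, regions, intact_calls)
    per_species = summarize_species(per_genome)
    tests: dict = {}
    species_groups = [
        grp for _, grp in per_genome.groupby("species", sort=True)
    ]
    if len(species_groups) < 2:
        warnings.warn("fewer than 2 species: Kruskal-Wallis tests skipped")
        tests["kruskal_counts"] = None
        tests["kruskal_composition"] = None
    else:
        for key, col in (
            ("kruskal_counts", "n_prophages"),
            ("kruskal_composition", "composition_pct"),
        ):
            h, p = kruskal_wallis([g[col].to_numpy() for g in species_groups])
            tests[key] = {"H": h, "p": p}
    size = per_genome["genome_length"].to_numpy(dtype=float)
    count = per_genome["n_prophages"].to_numpy(dtype=float)
    comp = per_genome["composition_pct"].to_numpy(dtype=float)
    try:
        r1, p1 = spearman(size, count)
        r2, p2 = spearman(size, comp)
        r_yy, _ = spearman(count, comp)
        tests["spearman_size_count"] = {"rho": r1, "p": p1}
        tests["spearman_size_composition"] = {"rho": r2, "p": p2}
        tests["spearman_count_composition"] = {"rho": r_yy}
        cmp_ = meng_z(r1, r2, r_yy, n=len(per_genome))
        tests["meng"] = {
            "z": cmp_.z,
            "p": cmp_.p,
            "ci_low": cmp_.ci_low,
            "ci_high": cmp_.ci_high,
            "ci_scale": cmp_.ci_scale,
        }
    except ValueError as err:
        warnings.warn(f"correlation comparison skipped: {err}")
        tests.setdefault("spearman_size_count", None)
        tests.setdefault("spearman_size_composition", None)
        tests.setdefault("spearman_count_composition", None)
        tests["meng"] = None
    return SurveyResult(per_genome=per_genome, per_species=per_species, tests=tests)
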