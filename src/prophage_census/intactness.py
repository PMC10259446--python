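"""Prophage intactness classification.

A prophage region is predicted intact if either

* an external detector already flagged it intact, or
* it encodes at least three *different* phage hallmark (cornerstone) genes
  — structural/packaging genes diagnostic of a functional phage — and
  additionally encodes an integrase and/or a transposase.

Multiple copies of the same hallmark category count once.  The hallmark
vocabulary is configurable; the default covers the canonical structural
program of tailed dsDNA phages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "GeneAnnotation",
    "IntactCall",
    "DEFAULT_HALLMARKS",
    "count_distinct_hallmarks",
    "classify_intact",
]

#: Default hallmark (cornerstone) gene vocabulary.  The exact list used by
#: published surveys is not standardized; this one is configurable and the
#: classification is only as good as the vocabulary supplied.
DEFAULT_HALLMARKS: frozenset[str] = frozenset(
    {
        "terminase large subunit",
        "portal protein",
        "major capsid protein",
        "capsid maturation protease",
        "major tail protein",
        "tail tape measure protein",
        "baseplate protein",
    }
)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene of a prophage region with its functional evidence."""

    gene_id: str
    region_id: str | None = None
    hallmark_category: str | None = None
    is_integrase: bool = False
    is_transposase: bool = False
    phrog_category: str | None = None
    phrog_evalue: float | None = None
    cog_letters: str = ""
    description: str = ""
    bitscore: float | None = None

    def __post_init__(self) -> None:
        if self.phrog_evalue is not None and self.phrog_evalue < 0:
            raise ValueError("e-value must be non-negative")


@dataclass(frozen=True)
class IntactCall:
    intact: bool
    evidence: str  # "external" | "hallmark_rule" | "none"
    n_hallmarks: int


def count_distinct_hallmarks(
    genes: Iterable[GeneAnnotation],
    vocabulary: frozenset[str] | set[str] = DEFAULT_HALLMARKS,
) -> int:
    """Number of distinct hallmark categories among a region's genes."""
    seen = {
        g.hallmark_category
        for g in genes
        if g.hallmark_category is not None and g.hallmark_category in vocabulary
    }
    return len(seen)


def classify_intact(
    genes: Sequence[GeneAnnotation],
    external_intact_flag: bool = False,
    vocabulary: frozenset[str] | set[str] = DEFAULT_HALLMARKS,
    min_hallmarks: int = 3,
) -> IntactCall:
    """Classify a region as intact via the external flag or the hallmark rule.

    ``intact`` iff the external flag is set, or the region encodes
    ``min_hallmarks`` or more distinct hallmark genes *and* at least one
    integrase or transposase.
    """
    n_hallmarks = count_distinct_hallmarks(genes, vocabulary)
    if external_intact_flag:
        return IntactCall(True, "external", n_hallmarks)
    has_mobilizer = any(g.is_integrase or g.is_transposase for g in genes)
    if n_hallmarks >= min_hallmarks and has_mobilizer:
        return IntactCall(True, "hallmark_rule", n_hallmarks)
    return IntactCall(False, "none", n_hallmarks)
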