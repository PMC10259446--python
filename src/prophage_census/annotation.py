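"""Functional category resolution and per-species frequency tables.

Each prophage gene is resolved to exactly one functional category with a
PHROG-then-COG precedence:

1. the PHROG category, if the PHROG hit has e-value below 1e-6 and the
   category is informative (not "other"/"unknown function");
2. otherwise the best COG hit with bitscore above 30: if its description
   contains any phage-associated keyword the gene becomes
   "Phage-associated"; if the hit spans multiple COG letters it collapses
   to "S" (function unknown); else the single COG letter;
3. otherwise "S".

Keyword matching is case-insensitive substring by default ("viral" also
matches inside "antiviral" — a known false-positive mode of the rule); an
optional word-boundary mode is available.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intactness import GeneAnnotation

__all__ = [
    "FunctionCall",
    "DEFAULT_KEYWORDS",
    "resolve_function",
    "category_frequency_table",
]

#: Keywords whose presence in a COG/EggNOG description reclassifies the
#: gene as phage-associated.
DEFAULT_KEYWORDS: tuple[str, ...] = (
    "phage",
    "baseplate",
    "capsid",
    "integrase",
    "tail",
    "tape",
    "lysozyme",
    "portal",
    "holin",
    "n-acetylmuramoyl-l-alanine amidase",
    "transposase",
    "virus",
    "viral",
)

PHAGE_ASSOCIATED = "Phage-associated"
UNKNOWN = "S"
_UNINFORMATIVE_PHROG = {"other", "unknown function"}


@dataclass(frozen=True)
class FunctionCall:
    gene_id: str
    source: str  # "phrog" | "cog" | "none"
    category: str


def _matches_keyword(
    description: str, keywords: Sequence[str], word_boundary: bool
) -> bool:
    text = description.lower()
    if not word_boundary:
        return any(k in text for k in keywords)
    return any(
        re.search(rf"(?<![a-z0-9]){re.escape(k)}(?![a-z0-9])", text) for k in keywords
    )


def resolve_function(
    gene: GeneAnnotation,
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
    phrog_evalue_max: float = 1e-6,
    cog_bitscore_min: float = 30.0,
    word_boundary: bool = False,
) -> FunctionCall:
    """Resolve one gene to its functional category (see module docstring)."""
    phrog = (gene.phrog_category or "").strip()
    if (
        phrog
        and gene.phrog_evalue is not None
        and gene.phrog_evalue < phrog_evalue_max
        and phrog.lower() not in _UNINFORMATIVE_PHROG
    ):
        return FunctionCall(gene.gene_id, "phrog", phrog)
    letters = (gene.cog_letters or "").strip()
    if letters and gene.bitscore is not None and gene.bitscore > cog_bitscore_min:
        if _matches_keyword(gene.description, keywords, word_boundary):
            return FunctionCall(gene.gene_id, "cog", PHAGE_ASSOCIATED)
        if len(letters) > 1:
            return FunctionCall(gene.gene_id, "cog", UNKNOWN)
        return FunctionCall(gene.gene_id, "cog", letters)
    return FunctionCall(gene.gene_id, "none", UNKNOWN)


def category_frequency_table(
    function_calls: Iterable[FunctionCall],
    gene_to_species: Mapping[str, str],
) -> pd.DataFrame:
    """Per-host-species counts and percents of functional categories.

    The percent denominator is the total number of prophage genes of that
    species, so percents sum to 100 per species.  Species with no genes
    are simply absent (no division by zero).
    """
    rows = [
        (gene_to_species[fc.gene_id], fc.category) for fc in function_calls
    ]
    if not rows:
        return pd.DataFrame(columns=["species", "category", "count", "percent"])
    df = pd.DataFrame(rows, columns=["species", "category"])
    counts = (
        df.groupby(["species", "category"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby("species")["count"].transform("sum")
    counts["percent"] = 100.0 * counts["count"] / totals
    return counts
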