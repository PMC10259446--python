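"""Synthetic lysogen benchmark generator.

Builds multi-species sets of bacterial genomes with *planted* prophages and
a ground-truth manifest, emulating the statistical structure of a real
prophage survey: several host species with different per-genome prophage
count distributions, prophage families whose members diverge by per-site
substitution at rate ``mu``, detector evidence tables whose scores span the
primary/secondary confirmation band, decoy candidate regions, and a
reference proteome set placed at controlled amino-acid identity from the
planted families.

The evolution model is substitution-only (no indels), so gene coordinates
carry through exactly and every downstream identity assertion has a
closed form: two members of a family with rate ``mu`` have expected
pairwise nucleotide identity ``(1-mu)^2 + mu^2/3`` (each lineage diverges
independently from the ancestor; a fraction ``mu^2`` of sites mutate in
both lineages and one third of those coincide).

Coordinates are 0-based half-open throughout; GFF3 emission converts to
1-based inclusive.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSpec",
    "SpeciesSpec",
    "PhageSpec",
    "DetectorNoise",
    "RefSpec",
    "SimConfig",
    "GenomeRecord",
    "PlantedGene",
    "PlantedRegion",
    "ProphageFamily",
    "PhageMember",
    "TruthManifest",
    "SimResult",
    "generate_host_genome",
    "generate_prophage_family",
    "derive_reference_protein",
    "mutate_nucleotides",
    "mutate_protein",
    "random_protein",
    "plant_prophages",
    "emit_detector_evidence",
    "generate_reference_set",
    "simulate",
    "default_config",
    "intact_layout",
    "cryptic_layout",
]

NUCLEOTIDES = np.array(list("ACGT"))
AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSpec:
    """One gene of a phage layout, with the annotation evidence it will carry."""

    label: str
    protein_length: int = 200
    hallmark: str | None = None
    integrase: bool = False
    transposase: bool = False
    phrog_category: str | None = None
    phrog_evalue: float | None = None
    cog_letters: str = ""
    description: str = ""
    bitscore: float | None = None


@dataclass(frozen=True)
class SpeciesSpec:
    """One host species: genome backbone parameters and planted counts."""

    name: str
    n_genomes: int
    genome_length: int
    gc: float
    prophage_counts: tuple[int, ...]
    family_pool: tuple[int, ...] = ()  # family indices this species draws from

    def __post_init__(self) -> None:
        if len(self.prophage_counts) != self.n_genomes:
            raise ValueError(
                f"{self.name}: prophage_counts must have one entry per genome"
            )
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("gc must be in [0, 1]")


@dataclass(frozen=True)
class PhageSpec:
    """Prophage family parameters."""

    n_families: int = 4
    length_range: tuple[int, int] = (12_000, 18_000)
    mu: float = 0.02
    layouts: tuple[tuple[GeneSpec, ...], ...] = ()  # one per family (cycled)

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 0.3):
            raise ValueError("mu must be in [0, 0.3]")


@dataclass(frozen=True)
class DetectorNoise:
    """Detector evidence noise model."""

    band_fraction: float = 0.3  # true regions scored in [0.5, 0.9)
    confirm_prob: float = 1.0  # P(secondary confirmation | band)
    decoys_per_genome: int = 5
    flank_prob: float = 0.5  # P(host flank appended per side)
    flank_len_range: tuple[int, int] = (500, 2000)

    def __post_init__(self) -> None:
        for p in (self.band_fraction, self.confirm_prob, self.flank_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class RefSpec:
    """One reference proteome derived from a planted family.

    ``target_aai`` is the intended mean per-protein amino-acid identity (in
    percent) between the reference's derived proteins and the source
    family's ancestor proteins; ``target_fraction`` is the fraction of the
    family's proteins that are derived at all (the rest are replaced by
    random protein sequence, emulating unrelated gene content).
    """

    label: str
    source_family: int
    target_aai: float
    target_fraction: float
    genus: str = ""
    family: str = ""
    klass: str = ""  # taxonomic class, e.g. "Caudoviricetes"
    unclassified: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_aai <= 100.0):
            raise ValueError("target_aai must be in [0, 100]")
        if not (0.0 <= self.target_fraction <= 1.0):
            raise ValueError("target_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    seed: int
    species: tuple[SpeciesSpec, ...]
    phages: PhageSpec
    noise: DetectorNoise
    references: tuple[RefSpec, ...]

    def __post_init__(self) -> None:
        max_phage = self.phages.length_range[1]
        for sp in self.species:
            if sp.genome_length <= max_phage:
                raise ValueError(
                    f"{sp.name}: genome_length must exceed max prophage length"
                )


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------


@dataclass
class GenomeRecord:
    genome_id: str
    species: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    label: str
    start: int  # genome coordinates, 0-based half-open
    end: int
    hallmark: str | None
    is_integrase: bool
    is_transposase: bool
    phrog_category: str | None
    phrog_evalue: float | None
    cog_letters: str
    description: str
    bitscore: float | None
    protein: str


@dataclass(frozen=True)
class PlantedRegion:
    genome_id: str
    start: int
    end: int
    family_id: str
    member_index: int
    genes: tuple[PlantedGene, ...]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PhageMember:
    sequence: str
    proteins: tuple[str, ...]  # one per layout gene


@dataclass
class ProphageFamily:
    family_id: str
    ancestor: str
    layout: tuple[GeneSpec, ...]
    gene_coords: tuple[tuple[int, int], ...]  # relative to phage start
    ancestor_proteins: tuple[str, ...]
    members: list[PhageMember]
    mu: float


@dataclass
class TruthManifest:
    """Ground truth for one simulated survey."""

    regions: list[PlantedRegion]
    genomes: dict[str, dict]  # genome_id -> {species, length, planted_composition_pct}
    references: dict[str, dict]  # ref label -> taxonomy + source family

    def to_json(self) -> str:
        payload = {
            "regions": [asdict(r) for r in self.regions],
            "genomes": self.genomes,
            "references": self.references,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        payload = json.loads(text)
        regions = [
            PlantedRegion(
                genome_id=r["genome_id"],
                start=r["start"],
                end=r["end"],
                family_id=r["family_id"],
                member_index=r["member_index"],
                genes=tuple(PlantedGene(**g) for g in r["genes"]),
            )
            for r in payload["regions"]
        ]
        return cls(regions, payload["genomes"], payload["references"])


@dataclass
class SimResult:
    config: SimConfig
    genomes: dict[str, GenomeRecord]
    hosts: dict[str, str]  # genome_id -> species
    families: dict[str, ProphageFamily]
    manifest: TruthManifest
    evidence: pd.DataFrame
    genes: pd.DataFrame
    references: dict[str, list[tuple[str, str]]]  # label -> [(protein_id, seq)]
    ref_taxonomy: pd.DataFrame


# ---------------------------------------------------------------------------
# default gene layouts
# ---------------------------------------------------------------------------


def intact_layout() -> tuple[GeneSpec, ...]:
    """Gene layout of a (predicted-)intact prophage: three distinct hallmark
    genes plus an integrase, with a handful of cargo genes exercising every
    branch of the functional-annotation precedence."""
    return (
        GeneSpec(
            "terminase",
            protein_length=220,
            hallmark="terminase large subunit",
            phrog_category="head and packaging",
            phrog_evalue=1e-30,
            description="terminase large subunit",
        ),
        GeneSpec(
            "portal",
            protein_length=180,
            hallmark="portal protein",
            phrog_category="head and packaging",
            phrog_evalue=1e-25,
            description="portal protein",
        ),
        GeneSpec(
            "capsid",
            protein_length=200,
            hallmark="major capsid protein",
            phrog_category="head and packaging",
            phrog_evalue=1e-40,
            description="major capsid protein",
        ),
        GeneSpec(
            "integrase",
            protein_length=190,
            integrase=True,
            phrog_category="integration and excision",
            phrog_evalue=1e-20,
            description="integrase",
        ),
        GeneSpec(
            "regulator",
            protein_length=120,
            phrog_category="unknown function",
            phrog_evalue=1e-8,
            cog_letters="K",
            description="transcriptional regulator",
            bitscore=55.0,
        ),
        GeneSpec(
            "tail_fiber",
            protein_length=150,
            cog_letters="S",
            description="phage tail fiber protein",
            bitscore=80.0,
        ),
        GeneSpec(
            "sugar_kinase",
            protein_length=160,
            cog_letters="G",
            description="glycerate kinase family protein",
            bitscore=48.0,
        ),
        GeneSpec("orphan", protein_length=100),
    )


def cryptic_layout() -> tuple[GeneSpec, ...]:
    """Layout of a degraded prophage: only two hallmark genes, no
    integrase/transposase — fails the intactness rule."""
    return (
        GeneSpec(
            "terminase",
            protein_length=220,
            hallmark="terminase large subunit",
            phrog_category="head and packaging",
            phrog_evalue=1e-30,
            description="terminase large subunit",
        ),
        GeneSpec(
            "capsid",
            protein_length=200,
            hallmark="major capsid protein",
            phrog_category="head and packaging",
            phrog_evalue=1e-40,
            description="major capsid protein",
        ),
        GeneSpec(
            "dual_cog",
            protein_length=140,
            cog_letters="EG",
            description="amidotransferase domain protein",
            bitscore=50.0,
        ),
        GeneSpec("orphan", protein_length=100),
    )


# ---------------------------------------------------------------------------
# sequence primitives
# ---------------------------------------------------------------------------


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_host_genome(
    length: int, gc: float, seed: int | np.random.Generator
) -> str:
    """Random host backbone sequence with the requested GC fraction."""
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    rng = _as_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(NUCLEOTIDES[idx])


def mutate_nucleotides(
    seq: str, mu: float, rng: np.random.Generator
) -> str:
    """Per-site substitution at rate ``mu``; substituted sites change to a
    uniformly chosen different base."""
    if mu == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < mu
    n_hit = int(hit.sum())
    if n_hit:
        # offset 1..3 in the ACGT cycle guarantees a different base
        codes = np.searchsorted(np.frombuffer(b"ACGT", dtype="S1"), arr[hit])
        codes = (codes + rng.integers(1, 4, size=n_hit)) % 4
        arr[hit] = np.frombuffer(b"ACGT", dtype="S1")[codes]
    return arr.tobytes().decode()


def mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site amino-acid substitution; substituted sites become a
    uniformly chosen *different* residue, so realized identity ~ 1-rate."""
    if rate == 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    n_hit = int(hit.sum())
    if n_hit:
        cur = np.searchsorted(AMINO_ACIDS, arr[hit])
        new = (cur + rng.integers(1, len(AMINO_ACIDS), size=n_hit)) % len(AMINO_ACIDS)
        arr[hit] = AMINO_ACIDS[new]
    return "".join(arr)


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS), size=length)])


def derive_reference_protein(
    seq: str,
    target_identity: float,
    rng: np.random.Generator,
    motif_len: int = 24,
) -> str:
    """Derive a reference protein at a controlled mean identity.

    Distant homologs remain detectable by local alignment because they
    retain conserved motifs, so the derivation keeps the first
    ``motif_len`` residues verbatim and concentrates the divergence in
    the remainder, choosing the remainder's substitution rate so the
    whole-protein identity hits ``target_identity`` (a fraction in
    [0, 1]).  Targets below ``motif_len / len(seq)`` are unreachable and
    floor at the motif fraction.  Targets at or above 0.95 use uniform
    substitution (no motif needed for detectability).
    """
    if target_identity >= 0.95:
        return mutate_protein(seq, 1.0 - target_identity, rng)
    m = min(motif_len, len(seq))
    rest_len = len(seq) - m
    if rest_len == 0:
        return seq
    rest_identity = (target_identity * len(seq) - m) / rest_len
    rest_identity = min(1.0, max(0.0, rest_identity))
    return seq[:m] + mutate_protein(seq[m:], 1.0 - rest_identity, rng)


# ---------------------------------------------------------------------------
# family generation and planting
# ---------------------------------------------------------------------------


def generate_prophage_family(
    ancestor_length: int,
    n_members: int,
    mu: float,
    layout: Sequence[GeneSpec],
    seed: int | np.random.Generator,
    family_id: str = "fam0",
    gc: float = 0.5,
) -> ProphageFamily:
    """Generate a prophage family: a random ancestor and ``n_members``
    substitution-diverged members with shared gene coordinates.

    Genes are laid head-to-tail from position 100 with 50 bp spacers; each
    gene occupies ``3 * protein_length`` bp.  Member proteins diverge from
    the ancestor proteins at the same per-site rate ``mu``.
    """
    if ancestor_length < 5000:
        raise ValueError("ancestor_length must be >= 5000")
    rng = _as_rng(seed)
    coords: list[tuple[int, int]] = []
    pos = 100
    for gs in layout:
        end = pos + 3 * gs.protein_length
        coords.append((pos, end))
        pos = end + 50
    if coords and coords[-1][1] > ancestor_length:
        raise ValueError(
            f"layout needs {coords[-1][1]} bp but ancestor is {ancestor_length} bp"
        )
    ancestor = generate_host_genome(ancestor_length, gc, rng)
    ancestor_proteins = tuple(
        random_protein(gs.protein_length, rng) for gs in layout
    )
    members = []
    for _ in range(n_members):
        members.append(
            PhageMember(
                sequence=mutate_nucleotides(ancestor, mu, rng),
                proteins=tuple(
                    mutate_protein(p, mu, rng) for p in ancestor_proteins
                ),
            )
        )
    return ProphageFamily(
        family_id=family_id,
        ancestor=ancestor,
        layout=tuple(layout),
        gene_coords=tuple(coords),
        ancestor_proteins=ancestor_proteins,
        members=members,
        mu=mu,
    )


@dataclass(frozen=True)
class PhageInsert:
    """One phage to plant: a member of a family."""

    family: ProphageFamily
    member_index: int

    @property
    def member(self) -> PhageMember:
        return self.family.members[self.member_index]


def plant_prophages(
    genome: GenomeRecord,
    phages: Sequence[PhageInsert],
    seed: int | np.random.Generator,
    max_retries: int = 100,
    gene_counter: list[int] | None = None,
) -> tuple[GenomeRecord, list[PlantedRegion]]:
    """Insert phages at uniformly drawn, non-overlapping backbone positions.

    The output genome length equals the input length plus the total phage
    length; truth coordinates (region and genes) are exact in the output
    genome.  Raises if distinct insertion points cannot be drawn within
    ``max_retries`` attempts.
    """
    rng = _as_rng(seed)
    total = sum(len(p.member.sequence) for p in phages)
    if total >= 0.4 * len(genome.sequence):
        raise ValueError("total phage length must stay below 40% of genome length")
    if not phages:
        return genome, []
    backbone = genome.sequence
    for _ in range(max_retries):
        points = rng.integers(0, len(backbone) + 1, size=len(phages))
        if len(set(points.tolist())) == len(phages):
            break
    else:
        raise RuntimeError("cannot place phages without overlap after retries")
    order = np.argsort(points, kind="stable")
    pieces: list[str] = []
    regions: list[PlantedRegion] = []
    prev = 0
    offset = 0
    counter = gene_counter if gene_counter is not None else [0]
    for idx in order:
        ins = phages[idx]
        point = int(points[idx])
        pieces.append(backbone[prev:point])
        start = point + offset
        seq = ins.member.sequence
        pieces.append(seq)
        genes = []
        for gi, ((gs, (g0, g1)), prot) in enumerate(
            zip(
                zip(ins.family.layout, ins.family.gene_coords),
                ins.member.proteins,
            )
        ):
            genes.append(
                PlantedGene(
                    gene_id=f"gene{counter[0]:05d}",
                    label=gs.label,
                    start=start + g0,
                    end=start + g1,
                    hallmark=gs.hallmark,
                    is_integrase=gs.integrase,
                    is_transposase=gs.transposase,
                    phrog_category=gs.phrog_category,
                    phrog_evalue=gs.phrog_evalue,
                    cog_letters=gs.cog_letters,
                    description=gs.description,
                    bitscore=gs.bitscore,
                    protein=prot,
                )
            )
            counter[0] += 1
        regions.append(
            PlantedRegion(
                genome_id=genome.genome_id,
                start=start,
                end=start + len(seq),
                family_id=ins.family.family_id,
                member_index=ins.member_index,
                genes=tuple(genes),
            )
        )
        offset += len(seq)
        prev = point
    pieces.append(backbone[prev:])
    new_seq = "".join(pieces)
    assert len(new_seq) == len(backbone) + total
    out = GenomeRecord(genome.genome_id, genome.species, new_seq)
    regions.sort(key=lambda r: r.start)
    return out, regions


# ---------------------------------------------------------------------------
# detector evidence
# ---------------------------------------------------------------------------

EVIDENCE_COLUMNS = [
    "genome_id",
    "start",
    "end",
    "primary_score",
    "contamination",
    "secondary_confirmed",
    "external_intact_flag",
]


def format_intervals(intervals: Sequence[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in intervals)


def parse_intervals(text: str) -> tuple[tuple[int, int], ...]:
    if not text or text != text:  # NaN-safe
        return ()
    out = []
    for part in str(text).split(";"):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def emit_detector_evidence(
    manifest: TruthManifest,
    noise: DetectorNoise,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Detector candidate table for a truth manifest.

    Every true region appears with a primary score >= 0.5: with probability
    ``band_fraction`` the score falls in the confirmation band [0.5, 0.9)
    and the secondary flag is set with probability ``confirm_prob``;
    otherwise the score is >= 0.9.  Host flanks are appended around true
    intervals (recorded as contamination sub-intervals, so trimming
    recovers the exact truth coordinates).  Decoys are either low-score
    intervals (< 0.5) or short high-score intervals (< 5 kb), so neither
    survives consensus calling.
    """
    rng = _as_rng(seed)
    rows = []
    regions_by_genome: dict[str, list[PlantedRegion]] = {}
    for r in manifest.regions:
        regions_by_genome.setdefault(r.genome_id, []).append(r)
    for genome_id in sorted(manifest.genomes):
        glen = manifest.genomes[genome_id]["length"]
        truths = regions_by_genome.get(genome_id, [])
        occupied = [(r.start, r.end) for r in truths]
        for r in truths:
            in_band = rng.random() < noise.band_fraction
            if in_band:
                score = float(rng.uniform(0.55, 0.89))
                confirmed = bool(rng.random() < noise.confirm_prob)
            else:
                score = float(rng.uniform(0.90, 0.995))
                confirmed = False
            start, end = r.start, r.end
            contamination: list[tuple[int, int]] = []
            if rng.random() < noise.flank_prob:
                f = int(rng.integers(*noise.flank_len_range))
                if r.start - f >= 0:
                    start = r.start - f
                    contamination.append((start, r.start))
            if rng.random() < noise.flank_prob:
                f = int(rng.integers(*noise.flank_len_range))
                if r.end + f <= glen:
                    end = r.end + f
                    contamination.append((r.end, end))
            rows.append(
                (
                    genome_id,
                    start,
                    end,
                    round(score, 4),
                    format_intervals(contamination),
                    confirmed,
                    False,
                )
            )
        for _ in range(noise.decoys_per_genome):
            short = rng.random() < 0.5
            length = int(rng.integers(2000, 4999) if short else rng.integers(6000, 12000))
            placed = False
            for _attempt in range(50):
                s = int(rng.integers(0, max(1, glen - length)))
                e = s + length
                if all(e <= ts or s >= te for ts, te in occupied):
                    placed = True
                    break
            if not placed:
                continue
            score = float(rng.uniform(0.90, 0.99)) if short else float(rng.uniform(0.05, 0.45))
            rows.append((genome_id, s, e, round(score, 4), "", False, False))
    return pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)


# ---------------------------------------------------------------------------
# reference proteomes
# ---------------------------------------------------------------------------


def generate_reference_set(
    families: dict[str, ProphageFamily],
    reference_spec: Sequence[RefSpec],
    seed: int | np.random.Generator,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Reference proteomes at controlled AAI from the planted families.

    For each spec entry, ``round(target_fraction * n)`` of the source
    family's ancestor proteins are derived by per-site amino-acid
    substitution at rate ``1 - target_aai/100``; the remainder are replaced
    by random protein sequence of the same length.  Returns the proteomes
    and a taxonomy table (reference_id, genus, family, class, unclassified).
    """
    rng = _as_rng(seed)
    proteomes: dict[str, list[tuple[str, str]]] = {}
    tax_rows = []
    for spec in reference_spec:
        fam_key = f"fam{spec.source_family}"
        fam = families.get(fam_key)
        if fam is None:
            fam = families[str(spec.source_family)]
        if not fam.ancestor_proteins:
            raise ValueError(f"family {fam.family_id} has no proteins")
        n = len(fam.ancestor_proteins)
        n_derived = round(spec.target_fraction * n)
        target = spec.target_aai / 100.0
        prots = []
        for i, p in enumerate(fam.ancestor_proteins):
            if i < n_derived:
                prots.append(
                    (f"{spec.label}|p{i:03d}", derive_reference_protein(p, target, rng))
                )
            else:
                prots.append((f"{spec.label}|p{i:03d}", random_protein(len(p), rng)))
        proteomes[spec.label] = prots
        tax_rows.append(
            (
                spec.label,
                "" if spec.unclassified else spec.genus,
                "" if spec.unclassified else spec.family,
                "" if spec.unclassified else spec.klass,
                spec.unclassified,
            )
        )
    taxonomy = pd.DataFrame(
        tax_rows, columns=["reference_id", "genus", "family", "class", "unclassified"]
    )
    return proteomes, taxonomy


# ---------------------------------------------------------------------------
# whole-survey simulation
# ---------------------------------------------------------------------------


def default_config(seed: int = 0) -> SimConfig:
    """The default synthetic survey: 3 species x 5 genomes with planted
    per-species prophage count medians {3, 1, 0}.

    Genome backbones (160-240 kb) are scaled down ~10x from real bacterial
    genomes to keep the full pipeline fast; larger genomes add no tested
    behaviour because every operation is linear in backbone length.
    Species with more prophages get larger genomes, emulating the positive
    genome-size/prophage-count association seen in real lysogen surveys.
    Families 0-2 carry an intact gene layout (3 hallmarks + integrase);
    family 3 is cryptic (2 hallmarks, no integrase).
    """
    layouts = (intact_layout(), intact_layout(), intact_layout(), cryptic_layout())
    species = (
        SpeciesSpec(
            "Snodgrassella alvi", 5, 240_000, 0.42, (3, 3, 3, 4, 2), family_pool=(0, 3)
        ),
        SpeciesSpec(
            "Gilliamella apicola", 5, 200_000, 0.35, (1, 1, 1, 0, 2), family_pool=(1,)
        ),
        SpeciesSpec(
            "Bifidobacterium asteroides",
            5,
            160_000,
            0.60,
            (0, 0, 0, 0, 1),
            family_pool=(2,),
        ),
    )
    references = (
        RefSpec(
            "REF_genus",
            source_family=0,
            target_aai=85.0,
            target_fraction=0.95,
            genus="Fernvirus",
            family="Peduoviridae",
            klass="Caudoviricetes",
        ),
        RefSpec(
            "REF_family",
            source_family=1,
            target_aai=55.0,
            target_fraction=0.60,
            genus="",
            family="Peduoviridae",
            klass="Caudoviricetes",
        ),
        RefSpec(
            "REF_class",
            source_family=2,
            target_aai=15.0,
            target_fraction=0.30,
            genus="",
            family="",
            klass="Caudoviricetes",
        ),
        RefSpec(
            "REF_unclassified",
            source_family=3,
            target_aai=15.0,
            target_fraction=0.30,
            unclassified=True,
        ),
    )
    return SimConfig(
        seed=seed,
        species=species,
        phages=PhageSpec(n_families=4, layouts=layouts),
        noise=DetectorNoise(),
        references=references,
    )


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator for one configuration.

    Deterministic: identical configs (including seed) give byte-identical
    outputs, manifest included.
    """
    rng = np.random.default_rng(config.seed)
    # 1. demand per family, so each family has exactly as many members as plantings
    demand = [0] * config.phages.n_families
    species_assignments: list[list[list[int]]] = []  # per species, per genome, family ids
    for sp in config.species:
        pool = sp.family_pool or tuple(range(config.phages.n_families))
        per_genome = []
        for count in sp.prophage_counts:
            fams = [int(pool[int(rng.integers(0, len(pool)))]) for _ in range(count)]
            for f in fams:
                demand[f] += 1
            per_genome.append(fams)
        species_assignments.append(per_genome)
    # 2. families
    layouts = config.phages.layouts or (intact_layout(),)
    families: dict[str, ProphageFamily] = {}
    for f in range(config.phages.n_families):
        length = int(rng.integers(*config.phages.length_range))
        families[f"fam{f}"] = generate_prophage_family(
            ancestor_length=length,
            n_members=max(demand[f], 1),
            mu=config.phages.mu,
            layout=layouts[f % len(layouts)],
            seed=rng,
            family_id=f"fam{f}",
        )
    # 3. genomes with planted phages
    genomes: dict[str, GenomeRecord] = {}
    hosts: dict[str, str] = {}
    all_regions: list[PlantedRegion] = []
    genome_meta: dict[str, dict] = {}
    member_cursor = {k: 0 for k in families}
    gene_counter = [0]
    for si, sp in enumerate(config.species):
        abbrev = sp.name.split()[0][0] + sp.name.split()[-1][:4]
        for gi in range(sp.n_genomes):
            genome_id = f"{abbrev}_{gi:02d}"
            backbone = GenomeRecord(
                genome_id, sp.name, generate_host_genome(sp.genome_length, sp.gc, rng)
            )
            inserts = []
            for f in species_assignments[si][gi]:
                key = f"fam{f}"
                inserts.append(PhageInsert(families[key], member_cursor[key]))
                member_cursor[key] += 1
            genome, regions = plant_prophages(
                backbone, inserts, rng, gene_counter=gene_counter
            )
            genomes[genome_id] = genome
            hosts[genome_id] = sp.name
            all_regions.extend(regions)
            planted = sum(r.length for r in regions)
            genome_meta[genome_id] = {
                "species": sp.name,
                "length": genome.length,
                "planted_composition_pct": 100.0 * planted / genome.length,
            }
    ref_meta = {
        spec.label: {
            "genus": spec.genus,
            "family": spec.family,
            "class": spec.klass,
            "unclassified": spec.unclassified,
            "source_family": f"fam{spec.source_family}",
            "target_aai": spec.target_aai,
            "target_fraction": spec.target_fraction,
        }
        for spec in config.references
    }
    manifest = TruthManifest(all_regions, genome_meta, ref_meta)
    # 4. detector evidence + references
    evidence = emit_detector_evidence(manifest, config.noise, rng)
    proteomes, taxonomy = generate_reference_set(families, config.references, rng)
    genes = genes_table(manifest)
    return SimResult(
        config=config,
        genomes=genomes,
        hosts=hosts,
        families=families,
        manifest=manifest,
        evidence=evidence,
        genes=genes,
        references=proteomes,
        ref_taxonomy=taxonomy,
    )


GENE_COLUMNS = [
    "gene_id",
    "genome_id",
    "start",
    "end",
    "label",
    "hallmark_category",
    "is_integrase",
    "is_transposase",
    "phrog_category",
    "phrog_evalue",
    "cog_letters",
    "description",
    "bitscore",
    "protein",
]


def genes_table(manifest: TruthManifest) -> pd.DataFrame:
    """Flatten planted genes into the per-gene annotation table."""
    rows = []
    for r in manifest.regions:
        for g in r.genes:
            rows.append(
                (
                    g.gene_id,
                    r.genome_id,
                    g.start,
                    g.end,
                    g.label,
                    g.hallmark or "",
                    g.is_integrase,
                    g.is_transposase,
                    g.phrog_category or "",
                    g.phrog_evalue if g.phrog_evalue is not None else np.nan,
                    g.cog_letters,
                    g.description,
                    g.bitscore if g.bitscore is not None else np.nan,
                    g.protein,
                )
            )
    return pd.DataFrame(rows, columns=GENE_COLUMNS)
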