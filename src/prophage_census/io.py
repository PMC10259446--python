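"""File readers/writers for the pipeline's plain-text formats.

FASTA goes through Biopython; everything tabular is TSV via pandas;
manifests and test results are JSON with sorted keys so that identical
runs produce byte-identical output trees.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import CandidateRegion, ProphageRegion
from .simulate import (
    DetectorNoise,
    PhageSpec,
    RefSpec,
    SimConfig,
    SimResult,
    SpeciesSpec,
    cryptic_layout,
    default_config,
    intact_layout,
    parse_intervals,
)

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "candidates_from_evidence",
    "write_json",
    "write_sim_outputs",
    "regions_to_frame",
    "config_from_json",
]


def write_fasta(records: Mapping[str, str], path: Path | str) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: Path | str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: pd.DataFrame, path: Path | str) -> None:
    """Emit planted genes as GFF3 CDS features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g.gene_id};product={g.description or g.label}"
            fh.write(
                f"{g.genome_id}\tsim\tCDS\t{g.start + 1}\t{g.end}\t.\t+\t0\t{attrs}\n"
            )


def candidates_from_evidence(evidence: pd.DataFrame) -> list[CandidateRegion]:
    """Detector evidence rows -> CandidateRegion objects."""
    out = []
    for _, row in evidence.iterrows():
        out.append(
            CandidateRegion(
                genome_id=str(row["genome_id"]),
                start=int(row["start"]),
                end=int(row["end"]),
                primary_score=float(row["primary_score"]),
                contamination=parse_intervals(row.get("contamination", "")),
                secondary_confirmed=bool(row["secondary_confirmed"]),
                external_intact=bool(row["external_intact_flag"]),
            )
        )
    return out


def write_json(obj, path: Path | str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def regions_to_frame(regions: Sequence[ProphageRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "genome_id": r.genome_id,
                "start": r.start,
                "end": r.end,
                "length": r.length,
                "tier": r.tier,
                "primary_score": r.primary_score,
            }
            for r in regions
        ],
        columns=[
            "region_id",
            "genome_id",
            "start",
            "end",
            "length",
            "tier",
            "primary_score",
        ],
    )


def write_sim_outputs(sim: SimResult, outdir: Path | str) -> None:
    """Write the generator's external files into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(
        {gid: rec.sequence for gid, rec in sorted(sim.genomes.items())},
        outdir / "genomes.fasta",
    )
    write_gff3(sim.genes, outdir / "genes.gff3")
    sim.genes.drop(columns=["protein"]).to_csv(
        outdir / "gene_annotations.tsv", sep="\t", index=False
    )
    proteins = {
        row.gene_id: row.protein for row in sim.genes.itertuples() if row.protein
    }
    write_fasta(proteins, outdir / "proteins.faa")
    sim.evidence.to_csv(outdir / "detector_evidence.tsv", sep="\t", index=False)
    ref_records = {
        pid: seq for label in sorted(sim.references) for pid, seq in sim.references[label]
    }
    write_fasta(ref_records, outdir / "references.faa")
    sim.ref_taxonomy.to_csv(outdir / "reference_taxonomy.tsv", sep="\t", index=False)
    with open(outdir / "truth_manifest.json", "w") as fh:
        fh.write(sim.manifest.to_json())
        fh.write("\n")
    pd.DataFrame(
        sorted(sim.hosts.items()), columns=["genome_id", "species"]
    ).to_csv(outdir / "hosts.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# simulation config from JSON
# ---------------------------------------------------------------------------

_LAYOUTS = {"intact": intact_layout, "cryptic": cryptic_layout}


def config_from_json(source: Path | str | dict, seed: int | None = None) -> SimConfig:
    """Build a SimConfig from a JSON file or dict.

    Any omitted section falls back to the default scenario.  Layouts are
    named ("intact" / "cryptic").  ``seed`` overrides the config's seed.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = json.load(fh)
    else:
        cfg = dict(source)
    base = default_config(seed=cfg.get("seed", 0))
    species = base.species
    if "species" in cfg:
        species = tuple(
            SpeciesSpec(
                name=s["name"],
                n_genomes=s["n_genomes"],
                genome_length=s["genome_length"],
                gc=s.get("gc", 0.5),
                prophage_counts=tuple(s["prophage_counts"]),
                family_pool=tuple(s.get("family_pool", ())),
            )
            for s in cfg["species"]
        )
    phages = base.phages
    if "phages" in cfg:
        p = cfg["phages"]
        layouts = tuple(
            _LAYOUTS[name]() for name in p.get("layouts", ["intact"])
        )
        phages = PhageSpec(
            n_families=p.get("n_families", base.phages.n_families),
            length_range=tuple(p.get("length_range", base.phages.length_range)),
            mu=p.get("mu", base.phages.mu),
            layouts=layouts,
        )
    noise = base.noise
    if "noise" in cfg:
        d = cfg["noise"]
        noise = DetectorNoise(
            band_fraction=d.get("band_fraction", base.noise.band_fraction),
            confirm_prob=d.get("confirm_prob", base.noise.confirm_prob),
            decoys_per_genome=d.get("decoys_per_genome", base.noise.decoys_per_genome),
            flank_prob=d.get("flank_prob", base.noise.flank_prob),
            flank_len_range=tuple(
                d.get("flank_len_range", base.noise.flank_len_range)
            ),
        )
    references = base.references
    if "references" in cfg:
        references = tuple(
            RefSpec(
                label=r["label"],
                source_family=r["source_family"],
                target_aai=r["target_aai"],
                target_fraction=r["target_fraction"],
                genus=r.get("genus", ""),
                family=r.get("family", ""),
                klass=r.get("class", ""),
                unclassified=r.get("unclassified", False),
            )
            for r in cfg["references"]
        )
    return SimConfig(
        seed=seed if seed is not None else cfg.get("seed", 0),
        species=species,
        phages=phages,
        noise=noise,
        references=references,
    )
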