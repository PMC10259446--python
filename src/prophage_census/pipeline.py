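"""End-to-end pipeline: simulate -> call -> intact -> derep -> classify ->
annotate -> survey, with a manifest of intermediate counts.

``run_all`` is deterministic: the same config (including seed) produces a
byte-identical output tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io as pio
from .annotation import FunctionCall, category_frequency_table, resolve_function
from .calling import ProphageRegion, StageCounts, call_regions
from .dereplication import ANIResult, DereplicationSummary, PhagePopulation, dereplicate
from .intactness import GeneAnnotation, IntactCall, classify_intact
from .simulate import SimConfig, SimResult, simulate
from .stats import SurveyResult, run_survey
from .taxonomy import AAIResult, TaxonomyCall, classify_all, host_specificity

__all__ = ["PipelineResult", "assign_genes_to_regions", "run_all"]


@dataclass
class PipelineResult:
    sim: SimResult
    regions: list[ProphageRegion]
    counts: StageCounts
    region_genes: dict[str, list[GeneAnnotation]]
    intact: dict[str, IntactCall]
    populations: list[PhagePopulation]
    ani_results: list[ANIResult]
    derep: DereplicationSummary
    taxonomy: list[TaxonomyCall]
    aai_results: list[AAIResult]
    host_spec: dict
    functions: list[FunctionCall]
    category_frequencies: pd.DataFrame
    survey: SurveyResult

    def manifest(self) -> dict:
        m = dict(self.counts.as_dict())
        m.update(
            {
                "n_genomes": len(self.sim.genomes),
                "n_singletons": self.derep.n_singletons,
                "n_populations": self.derep.n_populations,
                "n_representatives": self.derep.n_representatives,
            }
        )
        return m


def assign_genes_to_regions(
    genes: pd.DataFrame, regions: Sequence[ProphageRegion]
) -> dict[str, list[GeneAnnotation]]:
    """Attach each gene to the called region that contains it.

    A gene belongs to a region when its interval lies within the region's
    interval on the same genome.  Genes outside every region are dropped
    (they belong to candidates that did not survive calling).
    """
    by_genome: dict[str, list[ProphageRegion]] = {}
    for r in regions:
        by_genome.setdefault(r.genome_id, []).append(r)
    out: dict[str, list[GeneAnnotation]] = {r.region_id: [] for r in regions}
    for row in genes.itertuples():
        for r in by_genome.get(row.genome_id, ()):
            if row.start >= r.start and row.end <= r.end:
                out[r.region_id].append(
                    GeneAnnotation(
                        gene_id=row.gene_id,
                        region_id=r.region_id,
                        hallmark_category=row.hallmark_category or None,
                        is_integrase=bool(row.is_integrase),
                        is_transposase=bool(row.is_transposase),
                        phrog_category=row.phrog_category or None,
                        phrog_evalue=(
                            None if pd.isna(row.phrog_evalue) else float(row.phrog_evalue)
                        ),
                        cog_letters=row.cog_letters or "",
                        description=row.description or "",
                        bitscore=None if pd.isna(row.bitscore) else float(row.bitscore),
                    )
                )
                break
    return out


def _region_proteins(
    genes: pd.DataFrame, region: ProphageRegion
) -> list[str]:
    sel = genes[
        (genes.genome_id == region.genome_id)
        & (genes.start >= region.start)
        & (genes.end <= region.end)
    ].sort_values("start")
    return [p for p in sel.protein.tolist() if p]


def run_all(
    config: SimConfig,
    outdir: Path | str | None = None,
    min_len: int = 5000,
    hi: float = 0.9,
    lo: float = 0.5,
) -> PipelineResult:
    """Run every stage on one simulated survey; optionally write outputs."""
    sim = simulate(config)
    genome_seqs = {gid: rec.sequence for gid, rec in sim.genomes.items()}
    candidates = pio.candidates_from_evidence(sim.evidence)
    regions, counts = call_regions(
        candidates, genomes=genome_seqs, min_len=min_len, hi=hi, lo=lo
    )
    regions.sort(key=lambda r: r.region_id)

    region_genes = assign_genes_to_regions(sim.genes, regions)
    intact = {
        r.region_id: classify_intact(region_genes[r.region_id], r.external_intact)
        for r in regions
    }

    region_seqs = {r.region_id: r.sequence for r in regions}
    region_hosts = {r.region_id: sim.hosts[r.genome_id] for r in regions}
    populations, ani_results, derep = dereplicate(region_seqs, region_hosts)

    rep_ids = sorted(rid for p in populations for rid in p.representatives)
    query_proteomes = {
        rid: _region_proteins(sim.genes, next(r for r in regions if r.region_id == rid))
        for rid in rep_ids
    }
    query_proteomes = {q: p for q, p in query_proteomes.items() if p}
    ref_proteomes = {
        label: [seq for _, seq in prots] for label, prots in sim.references.items()
    }
    taxonomy, aai_results = classify_all(
        query_proteomes, ref_proteomes, sim.ref_taxonomy
    )
    multi_pops = {
        p.population_id: p.members for p in populations if not p.is_singleton
    }
    host_spec = host_specificity(multi_pops, region_hosts)

    functions = [
        resolve_function(g) for regs in sorted(region_genes) for g in region_genes[regs]
    ]
    gene_species = {
        g.gene_id: sim.hosts[rid.split("|")[0]]
        for rid, genes_ in region_genes.items()
        for g in genes_
    }
    freq = category_frequency_table(functions, gene_species)

    genome_lengths = {gid: rec.length for gid, rec in sim.genomes.items()}
    survey = run_survey(genome_lengths, sim.hosts, regions, intact)

    result = PipelineResult(
        sim=sim,
        regions=regions,
        counts=counts,
        region_genes=region_genes,
        intact=intact,
        populations=populations,
        ani_results=ani_results,
        derep=derep,
        taxonomy=taxonomy,
        aai_results=aai_results,
        host_spec=host_spec,
        functions=functions,
        category_frequencies=freq,
        survey=survey,
    )
    if outdir is not None:
        write_pipeline_outputs(result, outdir)
    return result


def write_pipeline_outputs(result: PipelineResult, outdir: Path | str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_sim_outputs(result.sim, outdir)
    pio.regions_to_frame(result.regions).to_csv(
        outdir / "regions.tsv", sep="\t", index=False
    )
    pio.write_fasta(
        {r.region_id: r.sequence for r in result.regions}, outdir / "regions.fasta"
    )
    pd.DataFrame(
        [
            {
                "region_id": rid,
                "intact": call.intact,
                "evidence": call.evidence,
                "n_hallmarks": call.n_hallmarks,
            }
            for rid, call in sorted(result.intact.items())
        ]
    ).to_csv(outdir / "intactness.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "id_a": a.id_a,
                "id_b": a.id_b,
                "ani": round(a.ani, 4),
                "aligned_fraction": round(a.aligned_fraction, 4),
            }
            for a in result.ani_results
        ]
    ).to_csv(outdir / "ani_pairs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "population_id": p.population_id,
                "member": m,
                "is_representative": m in p.representatives,
            }
            for p in result.populations
            for m in p.members
        ]
    ).to_csv(outdir / "populations.tsv", sep="\t", index=False)
    region_seqs = {r.region_id: r.sequence for r in result.regions}
    rep_ids = sorted(rid for p in result.populations for rid in p.representatives)
    pio.write_fasta(
        {rid: region_seqs[rid] for rid in rep_ids}, outdir / "representatives.fasta"
    )
    pd.DataFrame(
        [
            {
                "query": t.query_id,
                "rank": t.rank,
                "label": t.label or "",
                "aai": round(t.support.aai, 4) if t.support else "",
                "fraction_matched": (
                    round(t.support.fraction_matched, 4) if t.support else ""
                ),
            }
            for t in result.taxonomy
        ]
    ).to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
    pio.write_json(result.host_spec, outdir / "host_specificity.json")
    pd.DataFrame(
        [
            {"gene_id": f.gene_id, "source": f.source, "category": f.category}
            for f in result.functions
        ]
    ).to_csv(outdir / "functions.tsv", sep="\t", index=False)
    result.category_frequencies.to_csv(
        outdir / "category_frequencies.tsv", sep="\t", index=False
    )
    result.survey.per_genome.to_csv(
        outdir / "survey_per_genome.tsv", sep="\t", index=False
    )
    result.survey.per_species.to_csv(
        outdir / "survey_summary.tsv", sep="\t", index=False
    )
    pio.write_json(result.survey.tests, outdir / "tests.json")
    pio.write_json(result.manifest(), outdir / "manifest.json")
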