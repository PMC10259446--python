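# Methods

`prophage_census` implements a prophage survey over bacterial genome
assemblies as a chain of small, separately testable stages, together with a
synthetic-genome generator that plants prophages with exact ground truth.
This note records the models, the defaults and why they were chosen, and
what a green test does and does not establish.

## Consensus region calling

Candidate regions arrive from external detectors as intervals with a
primary dsDNA-phage score in [0, 1], optional host-flank "contamination"
sub-intervals, and a boolean confirmation flag from a secondary detector.
The calling pipeline is a fixed stage order:

1. **Primary screen** — keep candidates with score ≥ 0.5 (inclusive).
2. **Flank trimming** — subtract contamination intervals. Only flanks are
   trimmable: an interval strictly interior to a region raises an error,
   because interior host sequence would imply the candidate is two regions,
   not one. Trimming that consumes the whole region leaves a zero-length
   interval that the next stage drops.
3. **Length filter** — keep regions ≥ 5 kb (inclusive). This is the path by
   which highly degraded prophage relics leave the analysis.
4. **Two-tier consensus** — retain if score ≥ 0.9 (*high confidence*), or if
   score is in [0.5, 0.9) **and** the secondary detector confirmed
   (*secondary confirmed*). The band is half-open at 0.9 to avoid double
   counting; the boundary choice is configurable (`hi`, `lo`).

Survivor counts per stage are recorded (`StageCounts`), and the identity
`n_total = n_high + n_confirmed` holds by construction on every run.

**Prophage composition** is the percentage of a genome covered by retained
regions. Overlapping regions are merged before summation, so composition
can never exceed 100% even on pathological inputs. The denominator is the
total assembly length.

## Intactness

A region is predicted intact when an external detector flagged it intact,
or when it encodes ≥ 3 *distinct* phage hallmark (cornerstone) genes and at
least one integrase or transposase. Copies of the same hallmark category
count once. The default hallmark vocabulary is {terminase large subunit,
portal protein, major capsid protein, capsid maturation protease, major
tail protein, tail tape measure protein, baseplate protein}; published
cornerstone lists differ slightly, so the vocabulary is a parameter and
results that depend on it are approximate by construction. Integrase and
transposase are taken from annotation flags, not re-detected from sequence.
The rule is monotone: adding a gene can only create intactness, never
destroy it.

## ANI dereplication

Two regions belong to one *population* when ANI > 95% over ≥ 85% of the
shorter sequence (strict on identity — "above 95%" — inclusive on
coverage; both are configurable since the coverage boundary is genuinely
ambiguous in common usage).

The ANI estimator is fragment-based seed-and-extend:

- the shorter sequence is partitioned into `floor(len/1000)` near-equal,
  non-overlapping fragments covering every base (1000–1999 bp each). Exact
  1000-bp fragments would strand a remainder and make a self-comparison
  report < 100% aligned fraction; the near-equal partition keeps
  `ani(x, x) = (100, 100)` exact.
- each fragment's 13-mers vote for diagonals against an index of the longer
  sequence; the best diagonals (up to 8) are scored by gapless comparison,
  in both orientations, and the best identity wins. Fragment bases that
  overhang the target count as mismatches.
- fragments with best identity < 70% are unaligned; ANI is the
  length-weighted mean identity of aligned fragments, aligned fraction is
  their share of the shorter sequence.

Gapless extension is exact under the generator's substitution-only model
and a close approximation near the 95% cutoff that decides population
membership; the test suite checks agreement with a full Smith-Waterman
oracle to < 0.5 percentage points. At 13 bp, seeds are dense enough to find
the true diagonal down to ~70% identity — below the fragment floor, so a
missed seed cannot change a qualifying pair. An all-vs-all prescreen skips
pairs sharing < 30 canonical 16-mers (unrelated sequences share ~0; pairs
near the cutoff share thousands).

Populations are single-linkage connected components of the qualifying-pair
graph — deterministic and input-order independent, unlike centroid-greedy
dereplication. Representatives: for each host species present in a
population, that species' longest member (ties: lexicographically smallest
id), so a population spanning two species keeps two representatives. The
representative count therefore equals singletons + Σ per-cluster host
species counts.

## AAI taxonomy

Each query proteome is compared to each reference proteome: every query
protein takes its best local alignment (BLOSUM62, affine gaps −11/−1) over
the reference's proteins; hits with raw score < 70 are discarded. The
floor is the significance analog of a BLASTp E-value cutoff of 10⁻³:
empirically, best local scores between unrelated proteins of 100–300
residues stay below ~60, while any conserved ~20-residue motif scores well
above 90, so acceptance is effectively deterministic. AAI is the mean
identity of accepted best hits; the matched fraction uses the **query**
protein count as denominator (the prophage is the classification target).

Rank cascade against the top hit (highest AAI, then higher fraction, then
reference id): genus if AAI > 70 and fraction ≥ 85; family if AAI ≥ 30 and
fraction ≥ 50; otherwise class *Caudoviricetes* when the reference belongs
to that class; otherwise unclassified (also when the top reference is
itself unclassified, or no reference produced an accepted hit). Genus is
strict, family inclusive, matching the usual phrasing of these thresholds.
The cascade is monotone: raising AAI or fraction never demotes a rank.

One known behaviour: at very low homology the accepted local alignments
cover only the conserved cores, so the reported AAI of a class-rank call
can be high while the matched fraction is low — the fraction gate, not the
identity, is what separates family from class in that regime.

`host_specificity` summarizes any clustering (populations here, gene-
sharing subclusters in general): the number of clusters spanning more than
one host species and the host-exclusive fraction.

## Functional categories

Precedence: (1) the PHROG category when its e-value < 10⁻⁶ and the
category is informative (not "other"/"unknown function"); (2) otherwise
the best COG hit with bitscore > 30 — reclassified to "Phage-associated"
if the description contains any of 13 keywords (phage, baseplate, capsid,
integrase, tail, tape, lysozyme, portal, holin, N-Acetylmuramoyl-L-alanine
amidase, transposase, virus, viral), collapsed to "S" if the hit spans
multiple COG letters, else the single letter; (3) otherwise "S". Keyword
matching is case-insensitive substring by default — so "viral" matches
inside "antiviral", a deliberate reproduction of the rule as commonly
applied, with an optional word-boundary mode for the stricter reading. A
gene that passes the PHROG gate is never keyword-reclassified. Frequency
tables count categories per host species with the species' total prophage
gene count as denominator, so percents partition to 100.

## Survey statistics

Per-species summaries report **median with sample SD** (n−1 denominator) —
an unusual pairing, kept because it is the convention of the survey tables
this mirrors — plus min and max; a single-genome species reports SD 0 with
`sd_defined = False`.

Kruskal-Wallis uses midranks with tie correction; the default p-value is
asymptotic (χ², k−1 df). Because the χ² approximation is poor at tiny N, an
exact mode enumerates every partition of the pooled observations into the
observed group sizes (N ≤ 10); the exact p is validated against an
independent permutation oracle. All-identical observations give H = 0,
p = 1. Spearman is Pearson on midranks (scipy); zero rank variance raises.

The two genome-size correlations (size vs prophage count, size vs
composition) share a variable, so they are compared with the
Meng-Rosenthal-Rubin z test:

    rbar² = (r1² + r2²)/2
    f     = min(1, (1 − r_yy) / (2(1 − rbar²)))      (capped at 1)
    h     = (1 − f·rbar²)/(1 − rbar²)
    z     = (atanh r1 − atanh r2) · sqrt((N − 3)/(2(1 − r_yy)h))

with a two-sided normal p. The confidence interval is normal-theory on the
Fisher-z difference `atanh(r1) − atanh(r2)` and is labelled as such
(`ci_scale`), since several interval constructions circulate for this
test. `r_yy = 1` with `r1 ≠ r2` is rejected (degenerate denominator).

## The synthetic generator

The generator emulates a multi-species lysogen survey, not any particular
dataset: host species with fixed per-genome planted prophage counts,
prophage *families* (populations) whose members diverge from a random
ancestor by per-site substitution at rate μ, detector evidence with a
confirmation band and decoys, and reference proteomes at controlled AAI.

**Evolution model.** Substitution-only, no indels: gene coordinates carry
through exactly and every identity assertion is closed-form — two members
of a family have expected identity `(1−μ)² + μ²/3`. Gene protein sequences
evolve in amino-acid space at the same per-site rate (this avoids reading-
frame and stop-codon bookkeeping that no downstream stage tests;
nucleotide and protein divergence are therefore independent draws, not a
translation of one another). One genome is one contig; fragmentated
assemblies add no tested behaviour. Coordinates are 0-based half-open
internally; GFF3 output converts to 1-based inclusive.

**Default scenario** (`default_config`): 3 species × 5 genomes with
planted per-genome counts (3,3,3,4,2), (1,1,1,0,2), (0,0,0,0,1) — species
medians {3, 1, 0}. Backbones are 240/200/160 kb — scaled ~10× down from
real bacterial genomes to keep the full pipeline around seconds; every
stage is linear in backbone length, so nothing tested depends on the
scale. Larger-genome species get more prophages, emulating the positive
genome-size/lysogeny association real surveys report. Four families
(12–18 kb, μ = 0.02): three carry an intact layout (terminase, portal,
major capsid + integrase + cargo), one is cryptic (2 hallmarks, no
integrase); families are private to one species, so populations are
host-exclusive by construction. Detector noise: 30% of true regions score
in the [0.5, 0.9) band with confirmation probability 1 (both retention
tiers are exercised, nothing true is lost), 5 decoys per genome (half
low-score, half short-but-high-score — exercising both rejection paths;
the per-genome decoy count is a free parameter, as real detector
false-positive rates vary widely), host flanks appended with probability
0.5 per side (500–2000 bp, recorded as contamination so trimming recovers
truth exactly).

**Reference derivation.** A reference proteome derives `round(fraction·n)`
of a source family's ancestor proteins and replaces the rest with random
sequence. Uniform substitution to a target identity of ~15% produces
proteins statistically indistinguishable from random under local alignment
(best scores overlap the random-score distribution), which would make
low-AAI references undetectable — unlike real distant homologs, which are
found precisely because they retain conserved motifs. Derived proteins
therefore keep their first 24 residues verbatim and concentrate the
divergence in the remainder, calibrated so whole-protein identity hits the
target (targets below `24/len` floor at the motif fraction; targets ≥ 95%
use uniform substitution). This is what makes the rank cascade
deterministic at planted AAI {85, 55, 15}.

**What a green test establishes.** Exact recovery of planted truth at the
default noise level, correct threshold and boundary semantics, agreement
of ANI/AAI with dynamic-programming oracles, and statistical machinery
matching closed forms and independent transcriptions. What it does not:
realistic phage gene content, insertion-site (att) biology, indel/
rearrangement divergence, degraded-prophage mimicry (degradation is
represented only by the < 5 kb filter path), detector miscalibration, or
fragmented assemblies. Real-data behaviour of the upstream detectors is
out of scope by design — their outputs are inputs here.

## Numerical and determinism notes

- All randomness flows from one `numpy` Generator seeded by the config;
  identical configs give byte-identical output trees (file writers use
  sorted keys and fixed orderings).
- Ties: ANI fragment diagonals by smaller offset; representative selection
  by length then id; AAI top hit by AAI, fraction, then reference id;
  population ordering by smallest member id; COG hits arrive pre-reduced
  (one row per gene), with ties resolved upstream by bitscore then
  lexicographic order.
- Degenerate inputs: zero-length trimmed regions drop silently at the
  length filter; empty query proteomes and sub-5 kb ANI inputs raise;
  single-species surveys skip group tests with a warning rather than
  failing.
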