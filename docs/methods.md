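# Methods

## The annotation model

A reference database is a set of gene families, each belonging to one of
ten phosphorus metabolic processes (two-component systems, transporters,
organic phosphoester hydrolysis, pyruvate metabolism, pentose phosphate
pathway, phosphotransferase systems, oxidative phosphorylation, phosphonate
and phosphinate metabolism, purine and pyrimidine metabolism, plus a
catch-all), backed by two record classes:

* **representatives** carry a family label; a best hit to one annotates the
  query with that family;
* **homologues** are decoy sequences related to, but distinct from, the
  target families; a best hit to one rejects the query outright.

Annotation is strictly *single-label best-hit*: the query's highest-bitscore
hit (ties broken by identity, then subject id) is the only evidence
considered. It must pass three inclusive gates — identity ≥ 30.0 %, aligned
length ≥ 25 aa, e-value ≤ 10⁻⁵ — and its subject must be a representative.
A homologue best hit is a terminal veto even when the second-best hit is a
passing representative; this is deliberate, because the decoys exist
precisely to absorb queries that resemble a target family without belonging
to it. Every rejection is recorded with its reason (`no_hit`,
`failed_filter`, `homologue_hit`), so downstream reports can distinguish
absence from veto.

Two filter presets matter in practice: the default 30 %/25 aa/10⁻⁵ setting
for metagenomic ORFs, and a 70 % identity preset for annotating whole
genomes, where the permissive cutoff demonstrably overestimates family
counts.

## Alignment and identity

"Global identity" is identical columns divided by *all* columns of the
optimal end-to-end alignment, terminal gaps included — the strictest
reproducible reading, matching the USEARCH-style definition. Scoring is
BLOSUM62 with gap open 11 / extend 1 (a gap of length k costs 11 + (k−1)).
The dialect question of whether terminal gaps should be excluded from the
denominator is acknowledged; the inclusive definition was chosen and is used
consistently everywhere (clustering, recruitment thresholds, dereplication),
so thresholds are comparable across stages. Identity is made symmetric by
canonicalizing the argument order before aligning, which pins down one
alignment among co-optimal ones.

The internal search engine scores each query against every record with
local (Smith–Waterman) alignment under the same scoring, and converts raw
scores via the standard gapped-BLOSUM62 Karlin–Altschul constants
(λ = 0.267, K = 0.041), with database length the sum of record lengths.
These e-values are approximate by construction — only the ≤ 10⁻⁵ gate
matters downstream — and the engine exists so that every pipeline and test
runs with no external binary. For production-scale searches the external
backend consumes 12-column tabular hits from DIAMOND-class tools and applies
the identical e-value gate and best-hit tie-breaking, so results are
interchangeable at the annotation level (not at the level of exact bitscores,
which heuristic tools compute differently).

## Database construction

Construction is staged, and each stage re-validates the structural
invariants (unique ids, every representative's family declared, every
family non-empty):

1. **Candidate extraction.** Keyword rules (family → keyword/alias list)
   claim annotated candidates by token-wise, case-insensitive match against
   gene names and descriptions. Records matching multiple families are
   excluded as ambiguous and logged — ambiguity is evidence of an unreliable
   label, not a tie to break.
2. **Core clustering** at 30 % global identity, greedy centroid style:
   sequences processed longest-first (ties by id, so the result is
   deterministic), each joining the first centroid within threshold.
   "Nearest-neighbour clustering" is not a fully specified procedure in the
   field; greedy centroid clustering with label inheritance is the
   implementation choice here. Cluster label logic is conservative:
   monochromatic clusters become representatives (unlabelled members inherit
   the label); label-mixed clusters demote wholesale to homologues; clusters
   with no curated member at all also become homologues, i.e. unlabelled
   sequences may join families but never found them.
3. **Orthology expansion** at 30 %: a source record joins the family of its
   best representative when its label agrees or is absent, becomes a
   homologue when its label conflicts, and is discarded below threshold.
4. **Compaction** at 95 % for named families whose representative sets are
   highly redundant; only centroids are kept, family count unchanged.
5. **Bulk merge** at a strict 80 % — the same recruitment rule, tightened
   because very large sources at a permissive cutoff would flood the
   database with marginal recruits.
6. **Dereplication** at 100 % throughout: an exact duplicate never enters
   twice.

In place of interactive manual curation, every assignment lands in a
machine-readable review report (id, cluster, outcome) stored with the
database and written as `review.tsv` by the CLI.

## Abundance

Family abundance in a sample is read coverage per gigabase:

    coverage = Σ_orfs (N × l / L) / S

with N reads mapped to the ORF, L the ORF length in nucleotides, l the
per-sample read length in bases, and S the sample's sequencing size in Gb.
S is interpreted as total sequenced bases / 10⁹ (not bytes). Read length is
a per-sample constant (the Illumina paired-end assumption); variable-length
data must be pre-averaged by the caller. The statistic is linear in N and l
and inversely proportional to L and S, and the tests assert those scaling
laws exactly.

## Validation designs

**Simulated gene sets.** Queries carry truth labels (target family or
negative). The confusion matrix yields accuracy, PPV, specificity,
sensitivity and NPV; zero-denominator metrics are reported as missing, never
as 0. Scoring is *binary* (target vs non-target) by default, matching truth
defined at the gene-set level; a *family* level is provided in which a
target annotated to the wrong family counts as a false positive, so PPV
penalizes cross-family confusion. The threshold sweep evaluates every cell
of a dense identity × hit-length grid (defaults 0.2–99.9 % by 0.1 → 998
points; 2–99 aa by 1 → 98 points). It is computed by binning each query
once by its best hit and taking 2-D suffix sums, which is provably equal to
naive per-cell recomputation (and tested cell-by-cell against it). Along the
identity axis TP+FP can only shrink, so sensitivity is non-increasing and
specificity non-decreasing — asserted as invariants on every synthetic run.

**Mock genomes.** A genome's proteome is annotated and the number of
distinct predicted families is divided by the number of families its own
annotation (GFF) declares, matched through the same keyword rules used for
candidate extraction. The ratio classifies the genome as overestimated
(> 1), exact (= 1) or underestimated (< 1); classification uses exact
rational comparison of the integer counts, since ratios of small integers
need no tolerance. Summaries report class counts, min/max/mean and the
sample (n−1) standard deviation.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not real protein evolution. Sequences are uniform over the 20 amino acids;
family members derive from a common ancestor by i.i.d. substitutions
(substitution-only by default, so identities are analytically controllable:
two sequences at divergences d₁, d₂ from the ancestor match at a position
with probability (1−d₁)(1−d₂) + d₁d₂/19; an indel-rate knob exists and
defaults to 0). Decoys diverge from the family ancestor at a higher rate,
placing them between members and background; negatives are independent
random sequences at ~5–10 % background identity. All generators are pure
functions of a seeded spec: per-artefact rng streams are derived from
(seed, artefact, index), so regenerating any piece in isolation is
deterministic.

Default design: 10 families × 8 members of 300 aa, within-family divergence
0.15 (members ≈ 72 % identical to each other), decoy divergence 0.45
(≈ 50 % identity to members), one decoy per family, 50 negatives. These
sizes keep a full pipeline run — database, search, annotation, scoring,
mock community — at desk scale (tens of seconds on one CPU) while leaving
the three identity strata (member / decoy / background) separated by wide
margins. What passing tests on this design demonstrates is the *logic* of
the method — decoy veto, filter semantics, sweep arithmetic, detection-ratio
classification; it does not demonstrate performance on real protein
families, where divergence is structured, homology is not i.i.d., and the
member/decoy identity strata overlap. On real data the quantitative metrics
depend on database curation quality, which is out of scope here.

## Numerical choices and degenerate inputs

* Thresholds are all inclusive (≥ for identity and length, ≤ for e-value).
* Clustering and best-hit selection are fully tie-broken (length then id;
  bitscore then identity then subject id), so every pipeline output is
  deterministic for fixed inputs.
* Empty sequences, empty query sets, empty truth sets, zero annotated family
  counts and duplicate ids are rejected with named errors rather than
  propagated as empty results.
* Terminal stop codons (`*`) are stripped on FASTA input; internal stops are
  rejected.
* The coverage inversion solves N = coverage·S·L/l and refuses targets not
  representable with integer N, reporting the nearest achievable value.

## Known limitations

* The internal search engine is O(queries × records) exact alignment; it is
  meant for correctness and desk-scale validation, not for metagenome-scale
  search — that is what the external backend is for.
* Karlin–Altschul e-values use fixed published constants rather than
  sequence-composition-adjusted ones; e-values near the 10⁻⁵ gate can
  therefore differ from BLAST's for unusual compositions.
* Keyword matching of GFF attributes is a proxy for how a genome's own
  annotation names families; synonyms absent from the rule lists count
  against the detection ratio.
* Nucleotide input, six-frame translation, read mapping and ORF prediction
  are out of scope; queries arrive as protein FASTA and mapping counts as
  TSV.
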