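# Methods

## Model

The package formalizes annotation transfer between *homologous variants*:
missense substitutions in different proteins that map to the same column of
a family multiple sequence alignment. Its working assumptions are

1. curated seed alignments define residue equivalence — a variant is only
   analyzable where its position falls inside an aligned domain segment;
2. for proteins under autosomal-dominant (AD) inheritance with an
   established pathogenic missense burden ("pathogenic proteins"), the
   molecular consequence of a substitution and the clinical phenotype are
   directly coupled;
3. substitutions with identical or physicochemically similar residues
   (strictly positive BLOSUM score) at equivalent positions tend to share
   their consequence.

Everything else — dataset filters, pair categories, directional scoring,
the two-stage verdict — is bookkeeping around these assumptions.

### Coordinates and identity

Residue positions and alignment columns are 1-based; segment spans follow
the `name/start-end` convention (inclusive). `.` and `-` are
interchangeable gap characters; lowercase insert-state residues are
uppercased. Pairwise identity between two segments is the fraction of
*co-aligned* columns (both non-gap) with equal residues; one-sided gaps are
excluded from the denominator. This is the least biased reading of
"identity in the aligned domain": alignment-length or mean-sequence-length
denominators would punish segments for each other's gaps. Both
alternatives remain available through the `denominator` parameter of
`pairwise_identity`. Identity stratification uses a strict inequality
(`> 0.30` for the high-confidence stratum), so a pair at exactly the
threshold is excluded; `select_mode(..., inclusive=True)` flips that.

### Dataset construction

Pathogenic variants: ClinVar-style records with significance pathogenic /
likely-pathogenic (merged), non-somatic. "Non-somatic" is implemented as
`origin != somatic`, i.e. records of unknown origin are retained.
Uncertain, conflicting or benign significances are dropped — the
non-pathogenic set is sourced from population data, not from benign labels.
Non-pathogenic variants: gnomAD-style records with allele frequency
≥ 1e-6 (the floor *keeps* a variant at exactly the threshold). Both sets
are restricted to pathogenic proteins (AD and ≥3 distinct pathogenic
missense variants, counted on the raw label-mapped ClinVar input, before
any cross-set discard), deduplicated on (protein, position, ref, alt), and
any key claimed pathogenic but also observed in the population set is
discarded from *both* sides: such variants are plausibly benign
ascertainment artifacts, and the population set is large enough to afford
the loss.

### Pair enumeration and scoring

All unordered pairs of mapped variants from distinct proteins at one
column are emitted when both the reference and the alternate residues are
at least BLOSUM-similar (identity implies similarity because the BLOSUM
diagonal is positive); the four category modes are then pure flag filters,
which is what makes the strict counts nest inside every similar category.
A variant whose stated reference residue contradicts the alignment residue
at its mapped column is skipped and reported — in real data this is
isoform drift, and accepting it silently would corrupt the column map.
When overlapping families place the same two variants at more than one
column, the occurrence with the highest pair identity is kept, preventing
double counting in the metrics. Pairs between two domain copies within a
single protein are excluded by default (`allow_intra_protein=False`);
intra-protein paralogy is a different phenomenon from the cross-protein
transfer being measured.

Scoring is directional: each unordered pair is evaluated twice, once with
each member as the annotated truth and its partner as the transferred
prediction. A concordant P-P pair yields 2 TP, an N-N pair 2 TN, and a
discordant N-P pair exactly 1 FN + 1 FP. Under this expansion pair-level
accuracy and directional accuracy coincide algebraically, and the metric
formulas (Se, Sp, Acc, MCC) applied to the published clinical-scale class
counts reproduce all published two-decimal values — the property the
acceptance suite checks. Any metric with a zero denominator is reported as
undefined (`None`), never as 0. Display rounding is half-up to two
decimals; machine outputs carry full precision.

### Prediction policy

Evidence for a query is every annotated variant in another protein at the
query's column whose reference and alternate are at least similar, tiered
`strict` (both identical) vs `similar`. Aggregation, where the underlying
study is silent, is the package's own policy: strict evidence, when
present, fully overrides similar evidence; within the deciding tier the
majority label wins; ties break toward the label carried at the highest
pair identity; an exact tie (count and identity) is `conflicting`, which
propagates to a clinical `no_evidence`. The rationale mirrors the
reliability ordering observed in the concordance analysis — strict matches
first, closer homologs more trustworthy. The policy is deliberately
concentrated in one function (`predictor._aggregate`).

The clinical mapping: damaging + pathogenic protein → `disease_causing`;
any determinate call on a known non-pathogenic protein →
`non_disease_causing`; unknown gene context → `not_applicable` (never
disease-causing, since monogenic status is a precondition). The optional
evidence filter `min_identity` (preset 0.30) can only remove evidence, so
it can never promote a call to disease-causing.

`expand_predictions` inverts the direction: one annotated variant is
projected onto every other segment carrying a residue at its column —
strict tier: the identical substitution where the column residue equals
the annotated reference; similar tier: every BLOSUM-similar alternate
where the reference residues are similar. Pathogenic labels are projected
only into pathogenic-flagged proteins; non-pathogenic labels everywhere
(a damaging change outside an AD gene is still not disease-causing).

## Synthetic benchmark

The generator grows each family star-wise from an unobserved root: every
member substitutes a fixed number of positions, so that *pairwise* member
identity hits the target. With per-member substitution fraction s, two
members agree on a co-aligned column with probability (1−s)² + q·s², where
q = 0.2226 is the exact probability that two independent substitutions of
one root residue coincide under the substitution sampler (with probability
0.7 a substitution lands uniformly on a BLOSUM62-positive partner of the
current residue, otherwise uniformly on any other residue — the bias keeps
"similar" pair categories populated the way real families populate them).
The quadratic is inverted for s; realized identities are verified
post-generation against a ±0.05 tolerance (for domains ≥100 columns), and
a violating draw is regenerated under a spawned sub-seed (a spec that
keeps failing after 60 attempts is declared infeasible). One consequence
of the sampler: target identities below ≈0.19 are unreachable, because
even unrelated sequences agree at rate q. Gaps are placed independently
per member at the requested rate; segments embed at random offsets inside
longer synthetic proteins so that `seg_start > 1` is exercised.

Variants are planted one pair per column at columns where two distinct
proteins carry similar-or-identical residues, so every planted pair is
recoverable by enumeration and the set of enumerated pairs equals the
planted truth table exactly. The anchor's label is pathogenic with
probability `pathogenic_fraction`; the partner copies it with probability
ρ (`concordance_rate`). Pathogenic variants are emitted as ClinVar-style
rows (germline), non-pathogenic ones as gnomAD-style rows with allele
frequencies uniform in `af_range` (default 1e-5..1e-2, safely above the
default frequency floor). Planting exactly two variants per column keeps
the measured concordance an unbiased binomial estimate of ρ; planting more
would create partner–partner pairs whose concordance is ρ² + (1−ρ)².

All randomness flows from one integer seed through
`numpy.random.SeedSequence.spawn`, so stages are independently
reproducible and regeneration retries are deterministic.

What the benchmark emulates: column-equivalent substitutions with a known
label-agreement rate, identity-stratified families, AD/AR gene context,
and the full TSV/Stockholm round trip. What it does not: phylogenetic tree
structure, site-rate heterogeneity, indel evolution, isoform drift,
realistic allele-frequency spectra, or annotation noise correlated with
gene ascertainment. Passing the recovery experiments therefore shows the
pipeline's bookkeeping is faithful — not that real clinical concordance
equals the planted rates.

### Experiment sizes

The recovery experiments use 14 families × 8 proteins × 220 columns with
150 planted pairs each (~2100 pairs) for the 0.95 experiment, and
10 high-identity (~0.65) families at ρ = 0.98 plus 4 distant (~0.23)
families at ρ = 0.90 (1200 + 400 pairs) for the stratified experiment;
at these sizes three binomial standard errors are ≈0.014 and ≈0.012, tight
enough to separate the planted rates, and the whole acceptance script
completes in seconds.

## Known limitations

* Variant identity is protein-level (protein_id, position, ref, alt);
  transcript/isoform mapping is assumed done upstream.
* The aggregation policy is one defensible choice among several; it is
  configurable only by editing a single function, not via flags.
* `conflicting` evidence yields clinical `no_evidence` even when the gene
  context alone would force `non_disease_causing`.
* The substitution-matrix surface is BLOSUM45/62/80 only.
* Stockholm writing emits single-block records; `.` gaps are read but
  serialized as `-` (the two are semantically identical here), so byte-level
  round-trip is guaranteed only for writer-produced files; structural
  round-trip is guaranteed always.
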