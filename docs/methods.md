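# Methods

## Quantification model

A 4-plex reporter experiment measures, per peptide spectrum, four peak
areas: channel 114 (pooled healthy control) and channels 115–117 (three
patients of one batch). The pipeline is strictly ordered — isotope
correction → peptide ratios → protein rollup → within-batch normalization →
per-protein test → calling — and is invariant to input row order and to any
common scaling of all four channels of a spectrum.

**Isotope correction.** Isobaric tags leak a few percent of signal into
neighbouring mass channels. Writing the observed areas as a = M·x with a
4×4 purity matrix M (rows = observed channel, columns = true channel,
columns summing to 1), the true areas are recovered by solving the linear
system. The default M is the identity: correction factors come from vendor
reagent certificates, which vary by lot, so users supply a matrix file when
they have one. Negative solutions (noise near the detection floor) are
clipped to 0 with a warning; matrices with condition number above 1e8 are
rejected.

**Ratios and rollup.** Peptide relative abundance is `A_c / A_114`;
spectra with a zero reference area are excluded (logged), not fatal.
Protein ratios are arithmetic means of peptide ratios per (protein, batch),
the convention of standard iTRAQ processing software; the peptide count is
the number of distinct peptide ids supporting the protein.

**Normalization.** Each channel's ratios are divided by the batch-wide
*median* of that channel across all proteins, so small differences in
protein loading cancel and the post-normalization per-channel median is
exactly 1. The median (rather than mean) is used because planted or real
regulated tails would otherwise drag the centre; the statistic is
configurable (`median`/`mean`). Normalization is idempotent to 1e-12.

**Differential test.** The control enters every ratio as the denominator,
so its "values" are identically 1 and a two-sample test is degenerate; the
test is therefore a two-sided one-sample t-test of log₂ ratios against 0
across all patients (a patient = one batch × case-channel combination;
10 × 3 = 30 by default). Proteins with fewer than two ratios or zero
log-ratio variance are recorded as not testable and never called.

**Calling.** A protein is a DEP iff mean ratio > 1.2 or < 0.8, p < 0.05,
≥ 2 distinct peptides, unused score > 2, and consensus fraction > 25/30.
All fold/score/consensus comparisons are strict, matching the defining
inequalities; peptide count is ≥ (a count, not a measured value). The
consensus rule is operationalized as the fraction of patients whose
individual ratio lies on the same side of 1.0 as the protein's mean — the
natural reading of "patients sharing the protein's profile"; output is
sorted by |log₂ mean ratio| descending.

## Fingerprint screening

Fingerprints are plain binary vectors; similarity is the Tanimoto
coefficient of the on-bit sets. No chemistry toolkit is needed because the
screen consumes only the score. Two all-zero fingerprints are defined to
have similarity 0 (empty union) with a warning. The keep rule is *strictly*
greater than 0.8: compounds scoring below 0.8 are explicitly redundant and
the boundary case is resolved conservatively to the strict side, so a
best score of exactly 0.8 is excluded. The mean-targets-per-compound
statistic divides distinct (compound, target) pairs by the number of kept
compounds, so annotation-free compounds dilute the mean rather than
disappearing.

## Network topology and hub screening

Interaction edges carry combined confidence scores in [0, 1]; the edge
filter keeps scores strictly above the median of all scores (retained
fraction is therefore ≤ 1/2, and an all-equal score set retains nothing —
warned, not fatal). Shortest paths are unweighted: the score expresses
confidence, not distance.

Betweenness uses the unnormalized unordered pair-fraction convention
(Σ σ_st(v)/σ_st over pairs s < t, s ≠ v ≠ t), the convention of standard
network-analysis software, implemented via networkx's Brandes algorithm and
cross-checked in the test suite against exhaustive simple-path enumeration
on every connected graph with ≤ 6 nodes plus 100 random ≤ 8-node graphs.
Closeness is the Wasserman–Faust per-component form
(n_comp − 1)/Σ d(v, u), with isolated nodes scored 0, because integrated
herb–compound–target–disease networks are frequently disconnected.

The hub screen computes the median of each centrality over all nodes and
keeps nodes strictly exceeding all three. The cut statistic is configurable
(`median` default, `mean` available): the median is the defining choice for
the screen, robust to the heavy degree tail of scale-free-like networks,
while the mean option accommodates the looser "above average" reading of
the same rule.

## Overrepresentation

The p-value is the exact hypergeometric upper tail P[X ≥ k] (scipy),
verified in tests against explicit combinatorial sums for all N ≤ 12; fold
enrichment is (k/n)/(K/N). Raw p-values are reported by default because
single-digit candidate sets rarely warrant correction and the reference
analyses report unadjusted values; Benjamini–Hochberg q-values are
available behind `adjust=True`. The universe defaults to the union of all
pathway genes in the GMT — the only background recoverable offline — and
can be overridden by file. Pathways with zero overlap are omitted; ties in
p are broken lexicographically by pathway id for determinism.

## Integration

Predicted hubs and experimental DEPs are merged as a deduplicated union
with dual provenance; accessions may be translated to gene symbols by a
user-supplied two-column mapping, unmapped ids surviving under their own
name (warned). The PPI subgraph induced on the merged set is median-
filtered and the same triple-median screen is re-applied — "strong
interaction in the network" is deliberately operationalized as the one
screening rule defined upstream rather than a new ad-hoc criterion.
Nominees are ranked by degree, then betweenness, closeness and node id,
making reports byte-stable for a fixed config and seed. Fewer than three
nodes is an error; a topologically uniform network (e.g. a cycle) yields an
empty nomination with an explanatory note, since no node can strictly
exceed the medians.

## Synthetic data: what it emulates, and what it does not

`synthetic.gen_itraq_dataset` plants `round(frac_up·n)` up- and
`round(frac_down·n)` down-regulated proteins (up planted first if rounding
collides, so counts are exact), each with a single true fold applied to all
case channels, and draws areas as per-protein lognormal baselines times
unit-mean lognormal noise with configurable CV — multiplicative noise
because reporter ratios are strictly positive and observed fold changes
span roughly 0.5–3.3. Defaults mirror the study design: 10 batches × 3
patients, noise CV 0.2, folds 2.0/0.5, 500 proteins, 2–6 peptides per
protein. An optional per-batch scalar on all channels (off by default)
exercises normalization. Simulated identification scores are generated
above the score filter (2 + 1.5 × peptide count): score assignment belongs
to the upstream spectral search, which is out of scope, so the simulator
does not model score-based losses.

`gen_compound_library` plants similar compounds by copying a reference
fingerprint and swapping at most as many bits as keeps Tanimoto strictly
above 0.8, and rejection-samples the rest below 0.8, so truth labels are
verifiable by set arithmetic. `gen_ppi_and_pathways` uses preferential
attachment (or a configuration model) for heavy-tailed degrees,
i.i.d. Beta-distributed combined scores (default Beta(4, 2), centred near
typical curated-interaction confidences), and plants one clique-like
pathway over the highest-degree nodes so that hub queries are genuinely
enriched for it. `gen_key_target_scenario` wires the planted key targets to
every merged candidate with high-confidence edges and gives all background
edges one identical low score, with background edges outnumbering
high-confidence ones — the strict median filter then removes exactly the
background band.

What passing on these generators does **not** show: real spectra have
correlated peptide noise, missing channels, shared peptides between
proteins and batch-specific biases; real PPI scores are not i.i.d.; real
pathway sets overlap heavily. The generators validate the *screening
logic*, not instrument- or database-specific behaviour, and
database-derived quantities (specific network sizes, specific enrichment
scores) are snapshot-dependent and not reproduction targets.

## Numerical choices and problem sizes

All thresholds compare strictly except the peptide-count minimum. Medians
are numpy medians (midpoint of the two central values for even counts).
The t-test and hypergeometric tail come from scipy; centralities from
networkx; both are cross-checked against hand-written brute-force oracles
in the test suite. Test and acceptance runs use deliberately small problem
sizes — hundreds of proteins, ≤ ~350-node networks, 50-replicate oracle
sweeps — chosen so the full suite completes in seconds while every planted
effect is still recovered with margin.

## Known limitations

- Protein inference is out of scope: each spectrum row arrives with its
  accession; shared-peptide ambiguity must be resolved upstream.
- The isotope purity matrix defaults to identity; results with real data
  depend on supplying the vendor's lot-specific factors.
- The consensus rule assumes the mean ratio's side of 1.0 is the protein's
  "profile"; bimodal patient populations would be summarized poorly.
- Offline pathway backgrounds differ from web-service backgrounds, so
  absolute enrichment p-values are comparable only within one GMT.
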