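# Methods

## Inputs and identifier handling

Three delimited-text inputs drive the analysis: a differential-expression
(DE) miRNA table, two miRNA→gene predictor exports, and a regulator
catalog. Live querying of predictor web services or genome databases is
deliberately out of scope — the pipeline consumes exported tables, which
keeps every run offline and reproducible.

miRNA names are normalized to lowercase with any species prefix
(`rno-`, `hsa-`, …) stripped when it precedes a `mir-`/`let-` stem;
normalization is idempotent and case-insensitive. Gene symbols are folded
to the rodent Title-case convention and resolved through catalog aliases
(e.g. `Kat13d` → `Clock`) *before* the predictor intersection, so exports
using synonyms still match. Direction is stored separately from
fold-change magnitude because the source data publishes them separately;
readers also accept a signed fold-change column. Duplicate
(miRNA, gene) rows in a predictor export — predictor B reports one row per
binding site — collapse to the maximum score by default ("best evidence");
an `error` policy is available. The DE filter keeps fold change ≥ 2
(inclusive) and p < 0.05 (strict), matching the source dataset's stated
criteria.

## Regulator catalog

Sixteen GO molecular-function/process labels define the regulator
universe (writers and erasers of DNA methylation; histone acetylation,
methylation, ubiquitination, phosphorylation; the succinyl-, lactyl-,
glutaryl- and butyryl-transferase activities; two chromatin-programming
process terms). The catalog is flat — no GO graph traversal — and each
entry carries categories, aliases, a heart expression level and free-text
disease labels. Expression is binned on the published anchors (low
0.5–10 TPM, medium 11–1000 TPM); the printed bins leave (10, 11)
unassigned, resolved here as gap-free intervals low = [0.5, 10],
medium = (10, 1000], high > 1000, which keeps binning monotone. The
expression filter's floor is a parameter (`min_bin`, default `low`)
because the original description ("detectable expression") does not pin
down the exact cut.

## Consensus and scoring

Thresholds (60 / 0.8, strict tier 80 / 0.92) are all inclusive, matching
their published statement. The cumulative score `s_A/100 + s_B` is
computed exactly; rounding (half-up, two decimals for scores, one decimal
for percentages) happens only at report time, because the published
tables print half-up values. Consequences worth knowing: the minimum
cumulative score under thresholds is 1.40, the minimum for the strict
tier is 1.72, and lowering a threshold can only grow the consensus set
(monotonicity, property-tested). The consensus is verified against a
brute-force double loop over all (miRNA, gene) pairs on random small
inputs.

Prior-literature annotations (`previously_reported` flags, confirmed
pairs) are *inputs*, not computation: a literature search is not
reproducible code. Novel-interaction counts subtract the supplied
confirmed pairs from the consensus set.

## Network and Markov clustering

The network is bipartite and undirected: typed nodes (miRNA with
direction, gene), one edge per accepted interaction, weight = cumulative
score. Hubs use the degree ≥ 5 figure convention.

MCL is implemented from scratch on the weighted adjacency. Choices:

* **Self-loops** at each node's maximum incident weight (1.0 for isolated
  nodes) — common MCL practice; the upstream tooling the analysis
  emulates does not document its own transform.
* **Edge weights as raw similarities**, no rescaling: the original
  clustering's node-similarity transform is undocumented, so cluster
  *membership* from the published figure is not reproducible and is not a
  verification target; the implementation is instead held to algorithmic
  properties (partition validity, component separation, column
  stochasticity at every iteration, agreement with an independent dense
  reference run on a barbell graph).
* Iteration: expansion (matrix power 2), inflation (elementwise power,
  default 3, then column renormalization), pruning below 1e-6 with a
  stay-put fallback for starved columns; convergence when the max-norm
  change ≤ 1e-8, cap 200 iterations.
* Cluster read-out: attractors are nodes retaining flow on themselves;
  attractors attracting each other merge into one system; a non-attractor
  joins the system holding most of its column mass, ties broken by node
  name, so the result is always a partition.

Exports are SIF (`mirna targets gene`) and GraphML with node-type,
direction and edge-weight attributes; both round-trip node and edge sets.

## Tallies

Per-target summaries split counts by miRNA direction; the Venn partition
(up-only / down-only / both) always sums to the distinct-target count. A
target with several categories counts once per category, while shares use
the distinct-target denominator (the packaged catalog assigns exactly one
category per gene, so its shares sum to 100%). Disease tallies count
distinct targets per label plus an `any` bucket; unknown labels count
zero and are logged rather than raised. Percentages are half-up at one
decimal — note that 8 of 81 prints as 9.9%. The over-representation
helper is a one-sided hypergeometric tail with Benjamini–Hochberg
adjustment across sets (scipy/statsmodels underneath), validated against
exhaustive enumeration of draws on universes ≤ 12.

## Mark-direction inference

The published inference is prose; it is formalized here as a signed
interaction-count model using exactly the four quantities it names
(number of epi-miRNAs, their directions, number of targets per function,
predicted target change): target change = −(miRNA direction), a writer
contributes that change to its mark, an eraser the negation, each
interaction weighing 1. Interactions on genes outside the mark's
writer/eraser categories are ignored (logged). The model satisfies, and
is tested for, antisymmetry (flipping all miRNA directions negates the
net) and writer/eraser exchange symmetry.

Default mark specifications: DNA methylation (methyltransferase vs
demethylase), histone acetylation (acetyltransferase vs deacetylase),
histone methylation (methyltransferase vs demethylase). The qualitative
call adds "slightly" when |net| ≤ 20% of contributing interactions — the
figure style the analysis emulates distinguishes slight shifts without
stating a rule, so the band is explicit and configurable
(`slight_fraction`). An optional weighting by cumulative score is
available behind a flag, default off, since the described procedure
counts interactions. The output is predicted bookkeeping, not validated
biology, and carries no residue-level resolution.

## Synthetic data and the packaged fixture

The generator emulates input *structure*: configurable numbers of miRNAs
(default 94, directions Bernoulli(0.5), fold changes uniform on [2, 10],
p-values below 0.05), regulators (default 81, one uniform category each,
TPM uniform on [0.5, 1000]), planted pairs (default 202) whose scores are
uniform above both thresholds, and decoys that each fail exactly one way:
present in a single predictor, or sub-threshold in one score. It does not
emulate miRNA biology — no sequence, no seed-match structure, no
correlated scores, no expression noise — so passing recovery tests shows
the set logic is exact, not that real predictor errors are handled.
Everything is reproducible from the seed.

The packaged fixture transcribes the motivating study's two published
result tables: 202 interactions (miRNA, direction, gene, cumulative score
to two decimals, strict-tier flag, prior-literature flag) and 81
regulators (category, expression bin, disease labels, published per-gene
up/down counts kept for cross-validation). Files are checksummed at load.
Two components of the fixture are synthetic stand-ins, labelled as such:
the DE table's fold-change/p values (real per-miRNA statistics live in an
external supplement; names and directions are the published ones, padded
with filler miRNAs to 94 = 50 up + 44 down), and the per-predictor score
split — the published table prints only the cumulative score, so the
fixture sets the binding probability as high as the admissible target-
score range allows (b = min(1, c − 0.6); strict-tier rows use their own
floors; a non-strict row whose forced target score reaches 80 caps b at
0.91). Only the sum and the tier of each split are anchored in the
published table. The cardiomyopathy annotations follow the study's
narrative list of 11 genes where its table differs on two entries.

## Problem sizes and runtime

The full test suite runs the complete fixture analysis (202 interactions,
152-node network) plus 20-seed recovery at 15 miRNAs × 10 regulators with
25 planted / 30 decoy pairs, and finishes in a few seconds on one CPU;
the acceptance script uses the same sizes. MCL on the fixture network
converges in 9 iterations.

## Known limitations

* Predictor scores are taken as given; no re-implementation of the
  underlying target-prediction models, and no modelling of their error
  structure.
* Cluster membership of the published network figure is not reproducible
  (undocumented similarity transform upstream); MCL here is verified by
  algorithmic properties instead.
* The mark-direction model weighs every interaction equally and ignores
  enzyme abundance, kinetics and mark-site specificity.
* Disease annotation is flat free-text; no ontology reasoning.
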