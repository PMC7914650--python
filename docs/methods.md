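# Methods

`butyrnet` implements the integrative analysis used to dissect the
transcriptomic response of colorectal cancer (CRC) cells to butyrate, a
diet-derived histone deacetylase inhibitor. The pipeline consumes summary
tables (differential-expression results, per-source miRNA-target
predictions, interactome edge lists, gene sets, splicing-event counts,
combination-assay readouts) rather than raw reads; upstream read
processing and DE testing are out of scope by design.

## Differential-expression candidate selection

A record is classified `up`/`down`/`not_significant` from its log2 fold
change and BH-adjusted p-value, then filtered by an abundance floor in
reads per million (RPM). Two presets encode the selection criteria:

| preset | |log2FC| cut | adj. p cut | RPM floor |
|--------|-------------|-----------|-----------|
| miRNA  | > 1         | < 0.05    | > 4       |
| mRNA   | > 1.5       | < 0.01    | > 0.7     |

Design choices where the operational definition was genuinely open:

* **Boundary mode.** The fold-change cut is strict (`>`) by default;
  an inclusive mode (`>=`) is selectable because both conventions are
  common in practice and differ only on exact-boundary values.
* **Floor semantics.** A gene is removed only when its mean RPM is at or
  below the floor in *both* conditions (`either` mode): strong regulation
  legitimately produces near-zero abundance in one condition. A
  `mean`-across-conditions mode is available.
* **Missing p-values** never yield a significant call (fail-safe), with a
  logged warning.

The tunable unit is RPM throughout; if a caller's tables carry raw counts
they must be normalized first — the package does not guess.

## Consensus miRNA-target aggregation

Per-source predictions are admitted under each source's native score
convention: TargetScan total context++ score <= -0.3, miRDB prediction
score >= 85, DIANA microT-CDS miTG score >= 0.95, and miRTarBase /
miRecords entries at the strong-evidence tier (no numeric score). All
score boundaries are inclusive. A pair becomes a consensus interaction
when at least two *distinct* sources support it; duplicates within one
source count once. By default any two sources qualify, including two
validation databases (a `prediction_sources_only` switch restricts the
count to prediction programs). An interaction is `validated` iff a
validation database is among its supporters; free-text literature
annotations are carried as provenance without affecting logic.

Mature miRNA arms (`-5p`/`-3p`) are distinct identifiers and are never
collapsed to precursor names.

The anti-correlation filter retains pairs whose miRNA and target DE
directions are opposite — the expression pattern expected if the miRNA
degrades the target. It is idempotent and order-preserving. Gene-set
refinement (e.g. restriction to a cell-cycle set) rejects an empty gene
set so "no annotation" cannot masquerade as "nothing passed".

## Zero-order network construction and hub ranking

The zero-order protein-protein interaction (PPI) subnetwork of a seed set
keeps exactly the interactome edges with both endpoints among the seeds;
no neighbour expansion is performed, and nodes left below `min_degree`
(default 1) are removed in a single pass. Consensus interactions are then
integrated as miRNA -> target edges.

Degree counts all incident edges of both kinds, matching the
"number of connections" reading of hub centrality; a PPI-only degree is
also written to the node-attribute sidecar because the two can differ for
miRNA-targeted genes. Hub ranking sorts by degree descending with ties
broken by identifier ascending — the tie rule is arbitrary but required
for determinism. Exports: SIF (relations `pp` and `mt`, sorted emission
so identical networks serialize byte-identically, with a node-attribute
TSV), GraphML (round-trips the network exactly), and plain TSV.

## Enrichment and regulator concordance

Over-representation analysis is the upper-tail hypergeometric probability
of at least the observed overlap between query and set, both intersected
with an explicit universe, with Benjamini-Hochberg correction across sets
(`scipy.stats.hypergeom` / `statsmodels.multipletests` underneath). This
is a deliberate simplification of term-graph tools: no GO topology, no
kappa-score term clustering, upper tail only. The default universe is the
full DE table; an all-annotated-genes mode is available via the CLI.

Regulator concordance reports the fraction of a regulator's targets whose
DE direction matches expectation — sharing the regulator's direction for
an activator (default), opposing it for a repressor.

## Differential splicing (simplified)

Percent spliced-in is PSI = inclusion / (inclusion + skipping) per
replicate; delta-PSI is the treated-minus-untreated difference of
mean PSI (replicates with zero coverage are excluded from means and
counted in a log summary). Significance uses a two-proportion chi-square
test with Yates continuity correction on replicate-pooled counts, with
Fisher's exact test when any expected cell is below 5, followed by BH
across events. An event is flagged iff FDR < 0.05 AND |delta-PSI| >= 0.1;
an OR mode is provided because both combination rules appear in the
field. This is an explicit stand-in for replicate-aware likelihood models
(e.g. rMATS): it ignores replicate overdispersion and effective junction
lengths, and counts are assumed pre-normalized. The delta-PSI floor is
interpreted on the *difference* scale — a PSI-level floor would not
define a differential call.

## Combination synergy (CDI)

Replicate readouts for control, mono-treatments A and B and the
combination AB are reduced to control-normalized effect ratios
(arithmetic means by default; a geometric mode suits log-scale readouts),
and CDI = AB / (A x B). Classification: CDI < 0.7 significantly
synergistic, [0.7, 1) synergistic, = 1 additive (within a configurable
tolerance, default 1e-9, since float equality on measured ratios is
meaningless), > 1 antagonistic. CDI is scale-invariant in the readout
units, strictly increasing in AB and strictly decreasing in A and B. An
optional percentile bootstrap CI over replicates (2000 draws) is an
uncertainty extension beyond the point statistic.

## Synthetic data generator

The generator emulates every input with planted ground truth so the full
cascade is testable without external downloads. Default study conditions:
300 miRNAs and 2000 protein-coding genes with 10% regulated at
|log2FC| >= 2.5, 24 planted anti-correlated miRNA-target pairs (about a
third carrying a validation-database entry), 200 decoy predictions, a
500-node preferential-attachment interactome, a splicing-event mix of
60.3% skipped exons (SE) with retained introns, mutually exclusive exons
and alternative 5'/3' splice sites sharing the remainder, planted
delta-PSI 0.4 at ~100x coverage, and a significantly synergistic
combination (true CDI 0.63; mono-treatment effects 0.5 and 0.7) read out
in quadruplicate at 10% CV.

Generative choices, none of which real data pin down:

* **Null p-values** are uniform(0,1); a strict-null mode pins them to 1
  so zero-count expectations are exact rather than stochastic.
* **Source scores** are truncated normals on the requested side of each
  cut-off, so both passing and failing values occur near every boundary.
* **Decoys** cycle through three failure modes — failing scores,
  single-source support, and same-direction pairs that pass every filter
  until anti-correlation — so each rejection path is exercised.
* **Splicing counts** are binomial inclusion draws at Poisson coverage;
  true PSI values sit on a 1/100 grid, and the exact-counts mode (counts
  equal to expectation at coverage 100) realizes the noiseless limit in
  integers. Planted base PSI is drawn so the shifted PSI stays in [0,1]
  whenever the shift leaves room; otherwise it is clipped with a warning.
* **Readout noise** is mean-one lognormal at the configured CV, so the
  ratio estimator is unbiased to first order and exact at CV 0.
* **Randomness** flows through named substreams derived from the master
  seed, so identical configs are bit-identical and adding one generator
  call never perturbs another (stable fixtures).

What passing tests on this generator do *not* show: robustness to
count-level overdispersion, annotation bias, correlated replicates,
batch effects, or realistic score correlations between prediction
databases — the decoy structure is adversarial by construction, not
learned from real databases.

## Problem sizes used in the test and acceptance runs

Simulation studies run at the scales that make their Monte-Carlo error
small relative to the tested margins while keeping runs quick: splicing
null calibration at 50 seeds x 2000 events, splicing power at 50 seeds x
400 events (10% planted), enrichment calibration at 100 seeds x 10 sets,
CDI recovery at 200 simulated assays, noiseless pair recall over 10
replicate simulations, and oracle-equivalence checks on 100 random
instances per operation (universes <= 20 for exact enumeration, networks
<= 200 nodes).

## Known limitations

* The splicing test is a pooled two-proportion test, anticonservative
  under replicate overdispersion; it is a summarizer, not a replacement
  for likelihood-based splicing models.
* Enrichment ignores gene-set overlap structure and GO topology.
* The consensus stage trusts its input score conventions; it does not
  harmonize scores across database versions.
* CDI is a point statistic on means; with few replicates its sampling
  error is substantial (use the bootstrap CI).
* Degree-based hub ranking is sensitive to interactome ascertainment
  bias; well-studied proteins accumulate edges regardless of biology.
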