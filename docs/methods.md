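# Methods

This note documents the statistical models and procedures implemented in
`lik`, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical edge cases.

## Interactor calling

### Experiment design model

A pulldown experiment has three crosslinking arms. Each pulldown sample
records its probe combination and a paired control of the same arm:

- **native** (no crosslink): five single antisense probes, each run once
  against a non-homologous-probe control, plus a pooled-probe capture run
  in replicate (default 4×, each with a paired control). The single-probe
  captures drive the probe-combination vote and presence/absence counting;
  the replicated pooled captures define the native fold-change contrast
  and supply the replicates for its t-test. This split is a design choice
  of this package: the probe-voting rule needs per-probe captures while
  the t-test needs replication, and a single capture per combination
  cannot serve both.
- **uv** and **formaldehyde**: pooled-probe pulldowns (default one each)
  against no-probe and scrambled-probe controls respectively.

### QC

Contaminant-flagged rows, decoy (reversed-sequence) rows and protein
groups identified from fewer than 2 unique peptides are removed before any
calling. Row order is preserved.

### Presence/absence criterion

Detection is intensity strictly greater than 0 (the LFQ convention that a
missing value is stored as 0). A protein is called when detected in ≥ 2
native pulldowns, or ≥ 1 UV pulldown, or ≥ 1 formaldehyde pulldown.
Controls never contribute to detection counts. The thresholds are config
fields (`min_native_pulldowns`, `min_crosslinked_pulldowns`).

### Fold-change criterion

Per-protein, per-arm log₂ ratio = mean(log₂ pulldown intensities over
*detected* samples) − mean(log₂ control intensities), i.e. a ratio of
geometric means — the standard label-free aggregation when replicate
counts are small. Numerical policy for zeros:

- control intensity 0 → replaced by half the smallest positive intensity
  anywhere in the table (a global detection-limit pseudocount) before the
  log transform; configurable (`pseudocount_policy`);
- pulldown undetected in every contrast sample → no ratio (NaN), the
  protein is simply not tested in that arm.

UV and formaldehyde proteins are called on the ratio alone, strictly above
the threshold log₂ 3 = 1.584963 (a protein at exactly threefold is not
called). The default is threefold; twofold reporting conventions exist in
this assay family, so the threshold is a config field rather than a
constant.

Native proteins must additionally pass:

1. the probe vote — detected by more than 4 of the 6 probe combinations,
   where a combination detects a protein iff intensity > 0 in at least one
   of its pulldown samples;
2. a two-sided Welch t-test on log₂ intensities, pooled-capture pulldown
   replicates vs their controls, with Benjamini–Hochberg adjustment across
   all proteins that have a computable native ratio, adjusted p < 0.05.
   Welch rather than Student because variance equality between pulldown
   and control intensities is not a safe assumption. If fewer than 2
   pulldown or 2 control replicates exist the call raises an explicit
   insufficient-replication error rather than silently passing proteins.

Degenerate case: under zero noise a non-enriched protein has identical
values in both groups and the t statistic is 0/0; such NaN p-values are
set to 1 (no evidence) before BH adjustment.

BH is implemented directly (step-up with a reverse cumulative minimum) and
is cross-checked against `statsmodels` in the tests.

Candidates from any criterion are unioned; independently validated
proteins enter with evidence label `rip_validated`. Every candidate
carries at least one evidence record naming its criterion, supporting
modes, ratio and adjusted p where applicable.

Calls are invariant to row order and to rescaling all intensities by a
common positive constant (the pseudocount scales with the table, so ratios
are unchanged; the t-test sees a constant shift in log space).

## Orthologue mapping and interactome comparison

Curated one-to-one entries are applied first. Remaining sources map to
target T iff T is the source's best-scoring target **and** the source is
T's best-scoring source (reciprocal best hit). Determinism rules, chosen
because the underlying convention is usually unstated in publications:

- a tie for a best score disqualifies the pair (conservative: an ambiguous
  best hit is no hit);
- sources are processed in lexicographic order, and a source whose target
  is already taken (by the curated table, an earlier source, or the
  `already_represented` set) is excluded with reason
  `target_already_represented`; sources with no scored target are excluded
  with `no_orthologue`.

The mapping is therefore injective and order-independent. Comparison of
two mapped sets is exact set algebra and satisfies inclusion–exclusion by
construction; the enriched-term overlap fraction is |A∩B|/|A| and is an
error for empty A.

## Association network

Edges carry confidence in [0, 1]; STRING-style integer scores (0–1000) are
divided by 1000 at parse time. Self-loops and zero-confidence edges are
dropped by the parser; duplicate undirected edges keep the maximum score.
The network keeps edges with confidence **≥** 0.400 by default — a
"minimum confidence" is read as inclusive; an `inclusive=False` flag gives
the strict reading. Isolated universe proteins stay in the node set so
that edges-per-protein can be reported over the full universe
(`n_edges / total_proteins`, rounded to 1 decimal, the reporting
convention of the motivating study).

**Edge-count null.** The expected number of induced edges for a random
protein set is estimated by drawing `n_perm` uniform subsets of the
universe network without replacement and counting induced edges; the
p-value is the add-one estimator (1 + #{null ≥ observed}) / (n_perm + 1),
whose floor 1/(n_perm+1) is the smallest reportable value. An explicit
permutation null replaces database-internal analytic expectations because
it is verifiable: under the null the p-value is uniform, which the tests
check by KS test.

**Clustering.** Confidence-weighted greedy modularity maximisation (CNM,
as implemented in networkx) over the non-isolated subgraph stands in for
connectivity-based clustering plugins whose internals are external
software. The greedy merge order is deterministic, so results are
reproducible; clusters are renumbered 1..k by decreasing size. Planted
3×50-node partitions at p_in = 0.3, p_out = 0.01 are recovered with mean
adjusted Rand index > 0.99 in the acceptance suite. Mean intracluster node
degree is the average, over a cluster's members, of each member's
within-cluster edge count.

## Over-representation analysis

One-sided hypergeometric tail P[overlap ≥ k] per term
(`scipy.stats.hypergeom.sf`), with:

- term membership and size measured **after** intersection with the
  declared background (prevents inflation from unassayable genes);
- terms with restricted size ≥ 1600 excluded before testing (very broad
  ontology terms carry little information and dominate multiple-testing
  burden);
- BH FDR across the tested terms; the g:SCS-style corrections of web
  services are replaced by BH because BH is the standard FDR procedure and
  exactly testable.

The population size N is the declared background size as given, matching
the exact-enumeration identity p = 1/C(N, n) for a fully overlapping term
(e.g. 1/252 for a 5-member term fully covering a 5-gene query in a 10-gene
background). Significance uses a strict inequality (default p < 10⁻³),
with a switch between raw and adjusted p because published term counts
rarely state which was thresholded.

## IDR analysis

Disorder predictors are external; the package consumes per-residue score
tracks in [0, 1]. The per-protein score is the exact sample median (mean
of central order statistics for even length); the disordered fraction uses
the strict > 0.5 rule. The ontology-constrained background is the union of
the members of the enriched terms intersected with the proteome, sampled
as n_sets (default 20) independent draws of set_size (default 200)
proteins without replacement.

Group comparison: Kruskal–Wallis with tie correction (via
`scipy.stats.kruskal`) as the omnibus test, then Dunn's z for every
unordered pair using the *same* pooled mid-ranks and the tie-corrected
variance (N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ), two-sided normal p,
Holm step-down across the pairs. Dunn's test is implemented in the package
(no installed library provides it) and is oracle-tested against
hand-computed rank statistics; Holm is cross-checked against
`statsmodels`. Median scores tie frequently, hence the mid-rank/tie
convention throughout. Both comparison modes — the 20 background sets
pooled into one group, or kept as separate groups — are possible by how
the caller builds the groups mapping.

## Validation statistics

**ΔΔCt.** Technical replicates are averaged (arithmetic mean of Ct)
before ΔCt = mean target Ct − mean reference Ct per condition; ΔΔCt =
ΔCt(treatment) − ΔCt(control); relative expression 2^−ΔΔCt; knockdown % =
100(1 − 2^−ΔΔCt). Adding a constant to every Ct of a sample (a machine
offset) cancels. Amplification-efficiency correction (Pfaffl) is out of
scope.

**RIP enrichment.** fold = 2^(mean Ct_IgG − mean Ct_IP); the tenfold
enrichment flag uses a strict inequality. Input-fraction normalisation is
omitted (protocol-dependent); the Cts are assumed to come from the same
input material.

**FISH goodness of fit.** Binary scoring (biallelic vs not). Expected
treatment counts are control proportions × treatment total; Pearson χ²
with df = 1, upper-tail p, no continuity correction (a config-free choice:
on counts reconstructed from published percentages the uncorrected
statistic reproduces the published orders of magnitude). A zero expected
cell is an error. *Limitation:* the goodness-of-fit design treats the
control proportions as known. When the control arm is itself a small
sample, its sampling variance is ignored and the test is anti-conservative
(at a 286-vs-159 split the χ² statistic is over-dispersed by roughly
1 + n_t/n_c ≈ 1.6). The calibration test therefore verifies p-uniformity
in the test's own null regime (control ≫ treatment); conclusions drawn
from small control arms inherit this caveat.

## Synthetic-data generators

All generators fan a single integer seed out through
`numpy.random.SeedSequence` substreams; regeneration with the same seed is
byte-identical.

- **Pulldown tables**: per-protein baseline log₂ abundance ~ U(20, 30)
  (spanning the dynamic range typical of LFQ intensities), per-sample
  Gaussian noise on the log₂ scale, planted interactors shifted by
  `effect_log2fc` in every pulldown, values exponentiated, optional
  uniform dropout to exact 0. Default scenario: 500 proteins, 50 planted,
  effect log₂FC 3, noise sd 0.4, 4 native pooled replicates, dropout 0. A
  handful of contaminant-flagged and single-peptide rows exercise QC.
  Dropout defaults to 0 because, under the global-pseudocount policy, a
  random control dropout in a single-replicate crosslinked arm is
  indistinguishable from genuine strong enrichment — an artifact inherent
  to fold-change calling against one control, demonstrated in the tests by
  switching dropout on. What the generator does **not** emulate:
  peptide-level inference, intensity-dependent (left-censored) missingness,
  correlated noise between samples, or abundance-dependent variance; a
  pass on synthetic data therefore shows the calling rules and their
  statistics are implemented correctly, not that the thresholds are
  optimal for real LFQ data.
- **Networks**: planted-partition graphs (round-robin community
  assignment, Bernoulli edges at p_in/p_out, uniform confidences in
  [0.4, 1]).
- **Gene sets**: uniform random terms; planted terms oversample query
  genes by Gumbel-top-k weighted sampling at a configurable odds ratio
  (odds 1 reduces to uniform, which the calibration tests rely on).
- **Disorder tracks**: two-state — ordered baseline ≈ 0.2 with disordered
  blocks ≈ 0.85 of length ≥ 30 residues (the long-IDR design target of
  per-residue predictors), clipped to [0, 1]. A naive track generator, not
  a disorder predictor.
- **Validation fixtures**: triplicate Cts with a planted expression shift
  (−log₂ r cycles on the treatment target), FISH counts drawn binomially
  per arm at configurable proportions and the published arm sizes
  (286 / 159).

## Pipeline

`lik run` executes all seven stages on the synthetic scenario from one
YAML config, writing per-stage TSVs and a JSON manifest with the config,
per-stage summary quantities and SHA-256 hashes of every output; rerunning
an identical config reproduces identical hashes. Thresholds are monotone
by construction: raising the log₂FC threshold never enlarges the called
set (asserted in the tests).

## Problem sizes in the test and acceptance suites

The suites run at deliberately compact sizes chosen to keep the
Monte-Carlo error bars meaningful: 500-protein pulldowns, 150–300-node
networks with 100–2000 permutations, 100-replicate ORA calibration,
200-replicate permutation-null calibration, 1000-replicate FISH
calibration, 10-seed community recovery. All asserted tolerances are 3–4.5
standard errors of the corresponding estimator, or exact where the
quantity is deterministic.
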