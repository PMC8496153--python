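# Methods

## Model and assumptions

The pipeline treats a cancer cohort as a gene × sample matrix of quantized
somatic-mutation scores diffused over an undirected, weighted PPI network
G = (V, E) with weight matrix W. Propagation is a random walk with restart:
with the column-normalized operator W′ = W·D⁻¹ (D = diag of column sums),

    S⁽ᵗ⁺¹⁾ = α W′ S⁽ᵗ⁾ + (1 − α) S⁽⁰⁾.

W′ is column-stochastic, so by Perron–Frobenius the spectral radius of αW′
is at most α; for α < 1 the map is a contraction and converges to the unique
fixed point S = (1 − α)(I − αW′)⁻¹S⁽⁰⁾. (I − αW′) is an M-matrix, hence
inverse-positive: non-negative seeds give non-negative scores. Two further
consequences are used as invariants in the test suite: the solution is
linear in the seed, and — because columns of W′ sum to one — the total score
of each sample is conserved exactly.

The method's core assumption is topological: genes that are rarely mutated
themselves but adjacent to recurrently mutated neighborhoods accumulate
score during diffusion and rise in cohort-level rank, while recurrently
mutated drivers start at the top and cannot rise. Rank mobility, not final
score, is therefore the selection signal.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| α | restart complement | 0.8 | results stable over [0.6, 0.8]; α < 1 enforced (convergence requires it, so the closed interval's right endpoint is excluded by design) |
| tolerance | max per-column L1 change | 1e-8 | far below rank resolution; the literature names only the iteration cap |
| max_iterations | iteration cap | 350 | geometric contraction at rate α means ≈ log(tol)/log(α) ≈ 83 iterations in practice |
| β | minimum rank jump as a fraction of \|G\| | cohort-specific | 0.25 (BRCA, COAD, HNSC, LUAD, LUSC, PRAD, STAD, UCEC), 0.20 (CESC, KIRC, KIRP, LIHC), 0.15 (ESCA, READ), 0.05 (CHOL, KICH, THCA); unknown cohorts must set β explicitly |
| T | post-propagation rank threshold | 1000 | "top of the ranking" cut-off; compared with ≥/≤ inclusively, and β·\|G\| is not rounded |
| p | dependency-support threshold | 0.5 | DM ≥ p, DM = max over assays of the fraction of cancer-type cell lines with strictly negative effect score |
| FPKM filter | expression rule | > 15 in > 20% of samples | strict inequalities on both sides |
| confidence / top-fraction | edge filters | 0.7 / 0.10 | 0.7 on the [0,1] scale; `scale_hint=1000` maps it to STRING's 0–1000 integer scores |
| positionality | driver stratification | score ≥ 0.075, degree ≥ 150, zero-floor 0.0015 | 150 is a degree (integer, hundreds), 0.075 a score (quantized means ≤ 4): the only unit-consistent assignment |

## Quantization

Counts are divided by gene length (counts per bp) and each non-zero entry
is mapped through the 50th/70th/90th percentiles of the pooled non-zero
entries: v ≤ p50 → 1, (p50, p70] → 2, (p70, p90] → 3, above → 4.
Percentiles use linear interpolation between order statistics (numpy
default). Pooling over entries (rather than per-gene means) is the default
because the conversion is defined per entry; a `per_gene` basis is available
behind a switch. The bin edges are left-open/right-closed, which makes the
map deterministic and monotone; on continuous data the levels occupy
≈ 50/20/20/10% of non-zero entries.

## Ranks, ties, and selection

IS/FS are arithmetic means across samples; RIS/RFS use tie-aware *average*
ranks. This matters: the zero-score long tail is a single huge tie block,
and average ranks make the result deterministic and independent of input
order (an ordinal "first-seen" mode exists behind a switch). MS = RIS − RFS.
Selection is MS ≥ β·|G| ∧ RFS ≤ T, evaluated in reals. Consequences worth
stating: the top-ranked initial gene can never be selected for β > 0, and
raising β or lowering T can only shrink the selected set (both are verified
exhaustively against a brute-force selector on small universes).

Per-network lists are intersected first; the dependency filter is applied
to the intersected list (matching the pipeline order in which dependency
evidence is the last, optional stage). Genes absent from every dependency
assay pass the filter flagged `no dependency data` — the filter is optional
evidence, not a hard requirement. "Negative" is strictly < 0: a score of
exactly 0 means no effect. When a cancer type has no annotated cell lines,
fractions are computed across all cell lines of the assay.

## Statistics

Ranking validation is a one-sided Mann–Whitney U test that reference genes
(e.g. a driver or census set) hold better final ranks. For combined group
sizes ≤ 12 the p-value is computed by exact enumeration over rank
assignments (which handles tie-averaged ranks natively); above that, the
tie-corrected normal approximation (scipy) is used. A normal approximation
at n ≤ 10 is *not* accurate to three decimals, so the exact branch is not an
optimization but the definition of the small-sample behavior.

The impact score of a gene over k cancer-type cell lines is
ψ = (Σbⱼ + b̄)/(k + 2) with bⱼ = 1[scoreⱼ < 0]: the k indicators plus their
mean, smoothed by an assumed extra line with a non-negative score, so
ψ < 1 strictly and small-k cohorts are not saturated. The prose this formula
condenses admits other readings; the plain fraction Σb/k is available via
`smoothed=False` (and is exactly the DM proportion used by the dependency
filter, which is defined separately). UMG-vs-background comparison is a
one-sided test that ψ(UMG) is right-shifted.

## Synthetic cohorts

`umg.synthdata` generates the study conditions the tests and the acceptance
script run under. Defaults: 2000 genes, 100 samples, two preferential-
attachment networks (m = 3, weights uniform on (0.5, 1]) sharing a planted
subgraph, 10 driver hubs (top combined degree; mutated in 50% of samples
with 1 + Poisson(0.8) hits), 15 planted UMGs and 5-gene neighborhoods per
UMG drawn from the low-degree pool. Background per-gene mutation
propensities follow a rank power law (0.25·rank⁻⁰·⁶, capped at 0.35)
assigned to a random gene permutation, giving the heavy-tailed marginal the
method assumes (the top 1% of genes carry ≥ 20% of mutations). Planted UMGs
are mutated in exactly one sample and receive above-median gene lengths so
their normalized frequency is genuinely low; their neighborhoods are mutated
in 25% of samples. Dependency matrices (CRISPR and RNAi, 25 cell lines) make
planted genes negative in 90% of lines, drivers 75%, background 25%.
Expression keeps all planted structure above the FPKM rule and drops 2% of
background genes. The synthetic cohort label `SYNTH` uses β = 0.2, between
the moderate- and high-variance cohort settings, with T = 1000 and p = 0.5
unchanged. All values were fixed when the generator was designed.

What the generator does *not* emulate: real mutational signatures,
hypermutators, copy-number events, STRING's multi-channel evidence
structure, correlated expression/mutation noise, or annotation errors.
Passing the recovery properties therefore shows the pipeline implements the
intended selection semantics on data with the assumed shape — not that the
thresholds are optimal on any real cohort.

## Numerical choices

- Node order is lexicographic everywhere, making runs bit-stable on one
  platform; rerunning any stage on identical inputs is bit-identical.
- The iterative solver is sparse; the dense closed-form solve is guarded to
  ≤ 5000 nodes and doubles as the verification oracle (agreement to 1e-8 is
  asserted on random graphs in the tests).
- Tiny negative round-off in the closed form (> −1e-9) is clipped to zero.
- Largest-component ties break toward the component containing the
  lexicographically smallest node.
- Top-fraction edge filtering keeps ceil(f·|E|) edges and includes all ties
  at the cutoff weight, so the kept set can exceed the nominal count.
- Expression filtering can disconnect a network; the pipeline re-takes the
  largest connected component afterwards (flagged in provenance) so the
  propagation operator stays irreducible. An expression filter that empties
  the network is an error surfaced to the caller.
- Duplicate edges collapse to the maximum weight; self-loops are dropped;
  the composite union rescales each source's weights to [0, 1] by min-max
  before taking the per-edge maximum (the composite is only used for
  adjacency and degree, where weights are immaterial).
- Genes with variants but no network node are excluded from propagation and
  reported in a sidecar count.

## Positionality

Only immediate (1-hop) driver adjacency is used to categorize UMGs; the
k-step intuition sometimes given for such analyses is not implemented.
Driver stratification zeroes initial scores below 0.0015 before comparing
against the 0.075 score threshold. The category for UMGs with essentially
no observed mutations is labeled `low_evidence` rather than "drug target or
false positive" to avoid over-claiming.

## Problem sizes

The test suite and the acceptance script run the default 2000-gene,
100-sample cohort (seconds per run), 60 random graphs up to 200 nodes for
the propagation oracle, 1000 null simulations for type-I control, and
exhaustive enumerations up to |G| = 12 for the selection and rank-test
oracles — sizes chosen so the full suite completes in about a minute while
still exercising every contract at meaningful scale.

## Known limitations

- No identifier harmonization: gene symbols are opaque case-sensitive
  strings and must be pre-harmonized across all inputs.
- α = 1 (pure diffusion, no restart) is rejected even though some
  formulations nominally allow it; convergence is not guaranteed there.
- No FDR machinery over UMG membership; the method is a ranked filter, not
  a calibrated test, and per-gene error rates are not defined.
- STRING multi-channel filtering ("each channel separately") is not
  implemented; filtering applies to the single provided score column.
- The composite-union weights are only meaningful up to each source's
  min-max rescaling; do not interpret them as confidences.
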