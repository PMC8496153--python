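# umg — upward-mobility-gene detection on PPI networks

Frequently mutated cancer driver genes are easy to find by counting; the
long tail of rarely mutated genes that still matter functionally is not.
`umg` implements a network-propagation strategy for prioritizing such
long-tail genes: somatic mutation scores are diffused over a protein–protein
interaction (PPI) network, and the genes of interest are the ones whose
cohort-level rank **rises sharply** during diffusion — *upward mobility
genes* (UMGs). These are genes that are themselves rarely mutated but sit in
densely mutated network neighborhoods, so the walk concentrates score on
them.

The package is aimed at computational cancer-genomics practitioners with a
cohort of somatic variant calls (MAF-like), one or more weighted PPI
networks (STRING- or HumanNet-style edge lists), tumor expression data, and
optionally DepMap-style gene-dependency screens.

## Method

1. **Mutation matrix.** Variants are restricted to splicing/coding-exonic
   classes, counted per gene × sample, normalized by gene length, and each
   non-zero frequency is quantized to {1,2,3,4} by its position against the
   50th/70th/90th percentiles of the cohort's non-zero frequency
   distribution, giving the seed matrix S⁽⁰⁾.
2. **Network preparation.** Each PPI network is edge-filtered (confidence
   ≥ 0.7 for STRING-style scores, top 10% for HumanNet-style scores),
   restricted to its largest connected component, stripped of genes not
   expressed in the cohort (FPKM > 15 in > 20% of samples), and restricted
   to the largest component again.
3. **Propagation (random walk with restart).** With W′ = W·D⁻¹ the
   column-normalized adjacency matrix,

       S⁽ᵗ⁺¹⁾ = α W′ S⁽ᵗ⁾ + (1 − α) S⁽⁰⁾,   α = 0.8

   iterated per sample to convergence (cap 350 iterations). Because W′ is
   column-stochastic and α < 1, the iteration contracts to the unique
   non-negative solution S = (1 − α)(I − αW′)⁻¹S⁽⁰⁾, which the package also
   computes in closed form as a verification oracle.
4. **Selection.** Per gene, IS/FS are the mean initial/final scores, RIS/RFS
   their tie-aware ranks (1 = best), and the mobility status is
   MS = RIS − RFS. A gene is a UMG when **MS ≥ β·|G| and RFS ≤ T**
   (T = 1000; β is cohort-specific, 0.05–0.25). Per-network lists are
   intersected across networks, and genes may additionally be required to
   show dependency evidence: DM ≥ p (p = 0.5), where DM is the maximum
   across CRISPR/RNAi assays of the fraction of cancer-type cell lines with
   a negative effect score.
5. **Validation & positionality.** One-sided Mann–Whitney U tests check
   (a) enrichment of reference genes (e.g. the COSMIC census) toward top
   final ranks and (b) a right-shift of the smoothed impact score
   ψ = (Σbⱼ + b̄)/(k+2) for UMGs versus background. Finally each UMG is
   categorized on the composite (union) network by its 1-hop adjacency to
   score/degree-stratified drivers: `drug_target`, `weak_driver`, `both`, or
   `low_evidence`.

## Worked example

The bundled generator builds a fully synthetic cohort — two scale-free
networks, a long-tail mutation table, expression, dependency screens — with
15 planted upward-mobility genes (rarely mutated, but wired to driver hubs
and to a recurrently mutated neighborhood):

```python
from umg import SyntheticCohortSpec, generate_cohort, run_cohort

cohort = generate_cohort(SyntheticCohortSpec(random_seed=1))
report = run_cohort(cohort)

print("per-network candidates:", {t: len(g) for t, g in report.per_network.items()})
print("final UMGs:", len(report.final_genes))
print(report.final.head(8).round(3).to_string())
```

prints

```
per-network candidates: {'netA': 494, 'netB': 472}
final UMGs: 15
       mean_RFS    DM flag     category                              neighbor_classes
gene
G1652      13.5  0.88       drug_target                         high_score_low_degree
G1739      14.5  0.96       drug_target                         high_score_low_degree
G0922      17.5  0.88       drug_target                         high_score_low_degree
G0966      18.0  0.92       drug_target  high_score_high_degree;high_score_low_degree
G0977      18.0  0.92       drug_target  high_score_high_degree;high_score_low_degree
G1985      18.0  0.92       drug_target                         high_score_low_degree
G1342      21.0  0.92       drug_target                         high_score_low_degree
G1065      22.0  0.88       drug_target                         high_score_low_degree
```

Each per-network candidate list (~480 genes) is an over-call dominated by
zero-mutation genes that gained rank from diffusion alone; the
cross-network intersection plus the dependency filter (DM ≥ 0.5) cut it to
exactly the 15 planted genes (15/15 recovered, no background gene
survives). `mean_RFS` is the mean post-propagation rank across the two
networks, `DM` the dependency support, and `category` the positionality
label. The accompanying validation block reports a driver enrichment
p = 2.4 × 10⁻⁸ (network A) and a UMG-vs-background impact-score shift
p = 8.0 × 10⁻¹² (CRISPR).

The same run is available from the shell:

```bash
umg simulate --seed 1 --out data/
umg run --config config.yaml
umg validate-ranking --ranking out/ranking_netA.tsv --reference data/drivers.txt
```

with a config like

```yaml
cohort: SYNTH
networks:
  - {path: data/network_a.tsv, tag: netA, confidence_threshold: 0.6}
  - {path: data/network_b.tsv, tag: netB, top_fraction: 0.7}
expression: {path: data/expression.tsv}
variants: {path: data/variants.tsv}
gene_lengths: data/gene_lengths.tsv
selection: {beta: 0.2}
depmap:
  assays: {CRISPR: data/depmap_crispr.csv, RNAi: data/depmap_rnai.csv}
  annotations: data/cell_line_annotations.tsv
  cancer_type: SYNTH
drivers: data/drivers.txt
output_dir: out
```

Unknown keys are rejected; for real cohorts (`cohort: BRCA`, …) β defaults
to the cohort-specific value and `selection.beta` may be omitted.
`--skip-depmap` disables the optional dependency filter.

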