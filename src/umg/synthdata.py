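"""Seeded synthetic cancer cohorts with planted structure.

The generator emulates the statistical shape the prioritization method
relies on, without imitating any particular real dataset:

* two overlapping scale-free PPI networks (preferential-attachment growth,
  edge weights uniform on (0.5, 1]) sharing a planted subgraph, so the
  cross-network intersection step is exercised;
* a sparse somatic mutation table whose per-gene marginal is heavy-tailed
  (rank-power-law propensities), with planted high-frequency driver hubs;
* planted upward-mobility genes carrying background-level mutation counts
  (a single mutated sample, above-median gene length) but wired by several
  edges to drivers and to a boosted, recurrently mutated neighborhood;
* an expression matrix that keeps all planted structure above the FPKM
  filter while dropping a small random slice of background genes;
* CRISPR and RNAi dependency matrices where planted genes score negative in
  most cell lines and background genes in a minority.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .netio import WeightedNetwork
from .selection import DependencyData

__all__ = ["SyntheticCohortSpec", "SyntheticCohort", "generate_cohort", "write_cohort"]

NOISE_CLASSES = ("intronic", "UTR3", "intergenic")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions for one synthetic cohort.

    Rates are fractions of samples (mutations) or of cell lines (dependency
    negativity). The background propensity profile is a rank power law
    ``scale * rank**-exponent`` assigned to a random gene permutation, which
    gives the long-tail mutation marginal the method assumes.
    """

    random_seed: int
    n_genes: int = 2000
    n_samples: int = 100
    attachment: int = 3
    n_planted_drivers: int = 10
    n_planted_umgs: int = 15
    background_scale: float = 0.25
    background_exponent: float = 0.6
    driver_mutation_rate: float = 0.5
    driver_extra_hits: float = 0.8  # Poisson mean of extra variants per mutated driver sample
    umg_neighborhood_boost: float = 0.25
    n_neighbors_per_umg: int = 5
    n_driver_links_per_umg: int = 4
    umg_mutated_samples: int = 1
    dependency_negative_rate_planted: float = 0.9
    dependency_negative_rate_driver: float = 0.75
    dependency_negative_rate_background: float = 0.25
    n_cell_lines: int = 25
    expression_dropout: float = 0.02
    cancer_type: str = "SYNTH"

    def __post_init__(self):
        needed = self.n_planted_drivers + self.n_planted_umgs * (1 + self.n_neighbors_per_umg)
        if needed > self.n_genes:
            raise ValueError(f"planted structure needs {needed} genes but n_genes={self.n_genes}")
        if self.n_driver_links_per_umg > self.n_planted_drivers:
            raise ValueError("cannot link a planted gene to more drivers than exist")
        for name in (
            "driver_mutation_rate", "umg_neighborhood_boost", "dependency_negative_rate_planted",
            "dependency_negative_rate_driver", "dependency_negative_rate_background",
            "expression_dropout",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")


@dataclass
class SyntheticCohort:
    """Generated bundle: inputs for every pipeline stage plus the planted truth."""

    spec: SyntheticCohortSpec
    network_a: WeightedNetwork
    network_b: WeightedNetwork
    variants: pd.DataFrame
    gene_lengths: pd.Series
    expression: pd.DataFrame
    dependency: DependencyData
    drivers: list[str]
    planted_umgs: list[str]
    neighborhoods: dict[str, list[str]] = field(default_factory=dict)


def _grown_graph(n: int, m: int, seed: int) -> nx.Graph:
    return nx.barabasi_albert_graph(n, m, seed=int(seed))


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    rng = np.random.default_rng(spec.random_seed)
    genes = np.array([f"G{i:04d}" for i in range(spec.n_genes)])
    samples = [f"S{j:03d}" for j in range(spec.n_samples)]

    # --- networks: two independent scale-free growths over the same gene set
    seed_a, seed_b = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    raw_a = _grown_graph(spec.n_genes, spec.attachment, seed_a)
    raw_b = _grown_graph(spec.n_genes, spec.attachment, seed_b)

    combined_degree = pd.Series(
        [raw_a.degree(i) + raw_b.degree(i) for i in range(spec.n_genes)], index=genes
    )
    drivers = combined_degree.sort_values(ascending=False, kind="stable").index[: spec.n_planted_drivers].tolist()

    low_pool = combined_degree.drop(drivers).sort_values(kind="stable")
    low_pool = low_pool[low_pool <= low_pool.quantile(0.4)].index.to_numpy()
    n_nb = spec.n_planted_umgs * spec.n_neighbors_per_umg
    picked = rng.choice(low_pool, size=spec.n_planted_umgs + n_nb, replace=False)
    planted = sorted(picked[: spec.n_planted_umgs])
    nb_flat = picked[spec.n_planted_umgs:]
    neighborhoods = {
        u: sorted(nb_flat[i * spec.n_neighbors_per_umg : (i + 1) * spec.n_neighbors_per_umg])
        for i, u in enumerate(planted)
    }

    gidx = {g: i for i, g in enumerate(genes)}
    nets = {}
    for tag, raw in (("netA", raw_a), ("netB", raw_b)):
        g = nx.Graph()
        for u, v in raw.edges():
            g.add_edge(genes[u], genes[v], weight=float(rng.uniform(0.5, 1.0)))
        nets[tag] = g
    # shared planted subgraph: identical edges (and weights) in both networks
    for u in planted:
        link_drivers = sorted(rng.choice(drivers, size=spec.n_driver_links_per_umg, replace=False))
        for target in list(link_drivers) + neighborhoods[u]:
            w = float(rng.uniform(0.85, 1.0))
            for g in nets.values():
                g.add_edge(u, target, weight=w)
    network_a = WeightedNetwork(graph=nets["netA"], source_tag="netA")
    network_b = WeightedNetwork(graph=nets["netB"], source_tag="netB")

    # --- gene lengths: lognormal around 2.5 kb; planted genes drawn from the
    # upper half so a single hit stays a genuinely low normalized frequency
    lengths = np.maximum(200, rng.lognormal(np.log(2500), 0.6, size=spec.n_genes)).astype(int)
    gene_lengths = pd.Series(lengths, index=genes, name="length")
    upper = np.exp(np.log(2500) + 0.6 * rng.uniform(0.6, 1.8, size=len(planted)))
    gene_lengths.loc[planted] = upper.astype(int)

    # --- mutation propensities (fraction of mutated samples per gene)
    lam = np.empty(spec.n_genes)
    order = rng.permutation(spec.n_genes)
    ranks = np.empty(spec.n_genes)
    ranks[order] = np.arange(1, spec.n_genes + 1)
    lam[:] = np.minimum(0.35, spec.background_scale * ranks ** -spec.background_exponent)
    special = set(drivers) | set(planted) | set(nb_flat)
    for d in drivers:
        lam[gidx[d]] = spec.driver_mutation_rate
    for nbs in neighborhoods.values():
        for nb in nbs:
            lam[gidx[nb]] = spec.umg_neighborhood_boost

    rows = []
    for i, g in enumerate(genes):
        if g in planted:
            hit = rng.choice(spec.n_samples, size=min(spec.umg_mutated_samples, spec.n_samples), replace=False)
            counts = np.ones(len(hit), dtype=int)
        else:
            k = rng.binomial(spec.n_samples, lam[i])
            if k == 0:
                continue
            hit = rng.choice(spec.n_samples, size=k, replace=False)
            if g in drivers:
                counts = 1 + rng.poisson(spec.driver_extra_hits, size=k)
            else:
                counts = np.ones(k, dtype=int)
        for j, c in zip(hit, counts):
            rows.extend([(samples[j], g, "exonic")] * int(c))
    # non-coding noise rows, excluded by the class filter downstream
    n_noise = max(50, spec.n_genes // 5)
    for _ in range(n_noise):
        rows.append(
            (
                samples[int(rng.integers(spec.n_samples))],
                str(rng.choice(genes)),
                str(rng.choice(NOISE_CLASSES)),
            )
        )
    variants = pd.DataFrame(rows, columns=["sample", "gene", "variant_class"])

    # --- expression: planted structure always passes the FPKM>15 in >20% rule
    droppable = np.array([g for g in genes if g not in special])
    n_drop = int(round(spec.expression_dropout * len(droppable)))
    dropped = set(rng.choice(droppable, size=n_drop, replace=False)) if n_drop else set()
    log_mu = np.where(np.isin(genes, sorted(dropped)), np.log(3.0), np.log(60.0))
    expr = np.exp(rng.normal(log_mu[:, None], 0.8, size=(spec.n_genes, spec.n_samples)))
    expression = pd.DataFrame(expr, index=genes, columns=samples)

    # --- dependency matrices (CRISPR + RNAi)
    lines = [f"CL{j:03d}" for j in range(spec.n_cell_lines)]
    neg_rate = np.full(spec.n_genes, spec.dependency_negative_rate_background)
    for d in drivers:
        neg_rate[gidx[d]] = spec.dependency_negative_rate_driver
    for u in planted:
        neg_rate[gidx[u]] = spec.dependency_negative_rate_planted
    assays = {}
    for assay, factor in (("CRISPR", 1.0), ("RNAi", 0.9)):
        is_neg = rng.random((spec.n_genes, spec.n_cell_lines)) < (neg_rate * factor)[:, None]
        mag_neg = np.abs(rng.normal(0.8, 0.4, size=is_neg.shape))
        mag_pos = np.abs(rng.normal(0.2, 0.15, size=is_neg.shape))
        assays[assay] = pd.DataFrame(np.where(is_neg, -mag_neg, mag_pos), index=genes, columns=lines)
    annotations = pd.Series(spec.cancer_type, index=pd.Index(lines, name="cell_line"), name="cancer_type")
    dependency = DependencyData(assays=assays, annotations=annotations)

    return SyntheticCohort(
        spec=spec,
        network_a=network_a,
        network_b=network_b,
        variants=variants,
        gene_lengths=gene_lengths,
        expression=expression,
        dependency=dependency,
        drivers=drivers,
        planted_umgs=list(planted),
        neighborhoods=neighborhoods,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write the bundle as the plain-text formats the pipeline consumes."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name):
        paths[name] = str(out / name)
        return out / name

    from .netio import write_edge_list

    write_edge_list(cohort.network_a, _p("network_a.tsv"))
    write_edge_list(cohort.network_b, _p("network_b.tsv"))
    cohort.variants.to_csv(_p("variants.tsv"), sep="\t", index=False)
    cohort.gene_lengths.rename_axis("gene").to_csv(_p("gene_lengths.tsv"), sep="\t")
    cohort.expression.rename_axis("gene").round(3).to_csv(_p("expression.tsv"), sep="\t")
    for i, (assay, mat) in enumerate(sorted(cohort.dependency.assays.items())):
        labeled = mat.copy()
        labeled.index = [f"{g} ({10000 + j})" for j, g in enumerate(mat.index)]
        labeled.round(4).rename_axis("gene").to_csv(_p(f"depmap_{assay.lower()}.csv"))
    ann = cohort.dependency.annotations
    ann.rename_axis("cell_line").to_csv(_p("cell_line_annotations.tsv"), sep="\t")
    for name, gene_list in (("drivers.txt", cohort.drivers), ("planted_umgs.txt", cohort.planted_umgs)):
        with open(_p(name), "w") as fh:
            fh.write("# synthetic truth set\n")
            fh.writelines(g + "\n" for g in gene_list)
    with open(_p("spec.json"), "w") as fh:
        json.dump(dataclasses.asdict(cohort.spec), fh, indent=2)
    return paths
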