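"""End-to-end orchestration: network prep -> mutation matrix -> propagation ->
selection -> validation -> positionality, with a YAML-config front end,
content-addressed stage caching and JSON provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import netio, mutmatrix, propagate, selection, stats, positionality
from .netio import WeightedNetwork
from .positionality import PositionalityConfig
from .propagate import PropagationConfig
from .selection import BETA_BY_COHORT, DependencyData, UMGCriteria, UMGReport

logger = logging.getLogger("umg")

__all__ = [
    "PipelineParams",
    "RunConfig",
    "run",
    "run_cohort",
    "run_from_config",
    "load_config",
    "stage_keys",
    "write_report",
]


# --------------------------------------------------------------------------
# configuration schema (strict: unknown keys rejected)
# --------------------------------------------------------------------------
class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NetworkEntry(_Strict):
    path: str
    tag: str
    dialect: str = "generic_tsv"
    confidence_threshold: float | None = None
    top_fraction: float | None = None
    scale_hint: float | None = None

    @model_validator(mode="after")
    def _one_filter(self):
        if (self.confidence_threshold is None) == (self.top_fraction is None):
            raise ValueError(f"network {self.tag!r}: set exactly one of confidence_threshold / top_fraction")
        return self


class ExpressionEntry(_Strict):
    path: str
    fpkm_threshold: float = 15.0
    sample_fraction: float = 0.2


class VariantsEntry(_Strict):
    path: str
    sample_col: str = "sample"
    gene_col: str = "gene"
    class_col: str = "variant_class"
    keep_classes: list[str] = Field(default_factory=lambda: sorted(mutmatrix.DEFAULT_KEEP_CLASSES))


class PropagationEntry(_Strict):
    alpha: float = 0.8
    tolerance: float = 1e-8
    max_iterations: int = 350


class SelectionEntry(_Strict):
    beta: float | None = None
    rank_threshold: int = 1000
    depmap_fraction: float = 0.5
    tie_method: str = "average"


class DepmapEntry(_Strict):
    assays: dict[str, str]
    annotations: str | None = None
    cancer_type: str | None = None


class PositionalityEntry(_Strict):
    score_threshold: float = 0.075
    degree_threshold: int = 150
    zero_floor: float = 0.0015


class RunConfig(_Strict):
    schema_version: int = 1
    cohort: str
    networks: list[NetworkEntry]
    expression: ExpressionEntry
    variants: VariantsEntry
    gene_lengths: str
    propagation: PropagationEntry = PropagationEntry()
    selection: SelectionEntry = SelectionEntry()
    depmap: DepmapEntry | None = None
    drivers: str | None = None
    positionality: PositionalityEntry = PositionalityEntry()
    quantization_basis: str = "pooled"
    output_dir: str = "umg_out"
    cache_dir: str | None = None
    seed: int = 0


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


# --------------------------------------------------------------------------
# in-memory pipeline
# --------------------------------------------------------------------------
@dataclass
class PipelineParams:
    """Everything the in-memory pipeline needs beyond the data objects."""

    cohort: str = "SYNTH"
    beta: float | None = None
    rank_threshold: int = 1000
    depmap_fraction: float = 0.5
    skip_depmap: bool = False
    propagation: PropagationConfig = field(default_factory=PropagationConfig)
    fpkm_threshold: float = 15.0
    sample_fraction: float = 0.2
    keep_classes: frozenset = mutmatrix.DEFAULT_KEEP_CLASSES
    quantization_basis: str = "pooled"
    tie_method: str = "average"
    positionality: PositionalityConfig = field(default_factory=PositionalityConfig)

    def criteria(self) -> UMGCriteria:
        beta = self.beta if self.beta is not None else BETA_BY_COHORT.get(self.cohort)
        if beta is None:
            raise ValueError(f"no default beta for cohort {self.cohort!r}; set one in the config")
        return UMGCriteria(beta=beta, rank_threshold=self.rank_threshold, depmap_fraction=self.depmap_fraction)


def prepare_network(
    net: WeightedNetwork,
    expression: pd.DataFrame,
    params: PipelineParams,
    confidence_threshold: float | None = None,
    top_fraction: float | None = None,
    scale_hint: float | None = None,
) -> tuple[WeightedNetwork, dict]:
    """Edge filter -> LCC -> expression filter -> LCC (the cohort network)."""
    prov = {"input": {"nodes": net.number_of_nodes(), "edges": net.number_of_edges()}}
    if confidence_threshold is not None:
        net = netio.filter_by_confidence(net, confidence_threshold, scale_hint=scale_hint)
    elif top_fraction is not None:
        net = netio.filter_top_fraction(net, top_fraction)
    prov["edge_filtered"] = {"nodes": net.number_of_nodes(), "edges": net.number_of_edges()}
    net = netio.largest_connected_component(net)
    prov["lcc"] = {"nodes": net.number_of_nodes(), "edges": net.number_of_edges()}
    net = netio.filter_by_expression(net, expression, params.fpkm_threshold, params.sample_fraction)
    prov["expression_filtered_lcc"] = {"nodes": net.number_of_nodes(), "edges": net.number_of_edges()}
    return net, prov


def build_mutation_matrix(
    variants: pd.DataFrame, gene_lengths: pd.Series, params: PipelineParams
) -> tuple[pd.DataFrame, mutmatrix.QuantizationThresholds, dict]:
    counts = mutmatrix.count_matrix(variants, params.keep_classes)
    norm = mutmatrix.length_normalize(counts, gene_lengths)
    quantized, thresholds = mutmatrix.quantize(norm, basis=params.quantization_basis)
    prov = {
        "variants_total": int(len(variants)),
        "variants_kept": int(counts.to_numpy().sum()),
        "genes": int(quantized.shape[0]),
        "samples": int(quantized.shape[1]),
        "thresholds": {"p50": thresholds.p50, "p70": thresholds.p70, "p90": thresholds.p90},
    }
    return quantized, thresholds, prov


def propagate_network(
    net: WeightedNetwork, quantized: pd.DataFrame, params: PipelineParams
) -> tuple[pd.DataFrame, dict]:
    """Propagate the cohort matrix over one network; returns the gene ranking table."""
    adj = propagate.column_normalize(net)
    seed, dropped = propagate.align_seed(quantized, adj)
    final, iters, converged = propagate.propagate_iterative(adj, seed, params.propagation)
    nodes = list(adj.nodes)
    S0 = pd.DataFrame(seed, index=nodes, columns=quantized.columns)
    Sf = pd.DataFrame(final, index=nodes, columns=quantized.columns)
    ranking = selection.build_ranking(S0, Sf, tie_method=params.tie_method)
    prov = {
        "nodes": len(nodes),
        "iterations": iters,
        "converged": bool(converged),
        "genes_without_network_node": len(dropped),
    }
    return ranking, prov


def run(
    networks: dict[str, WeightedNetwork],
    filters: dict[str, dict],
    expression: pd.DataFrame,
    variants: pd.DataFrame,
    gene_lengths: pd.Series,
    params: PipelineParams,
    dependency: DependencyData | None = None,
    drivers: set[str] | None = None,
) -> UMGReport:
    """Execute the full prioritization on in-memory inputs."""
    criteria = params.criteria()
    prov: dict = {"cohort": params.cohort, "criteria": vars(criteria).copy(), "networks": {}}

    quantized, thresholds, prov["mutation_matrix"] = build_mutation_matrix(variants, gene_lengths, params)

    cohort_nets, rankings, per_network = {}, {}, {}
    for tag, net in networks.items():
        cohort_net, net_prov = prepare_network(net, expression, params, **filters.get(tag, {}))
        ranking, prop_prov = propagate_network(cohort_net, quantized, params)
        umgs = selection.select_umgs(ranking, criteria)
        logger.info("%s: %d nodes, %d UMG candidates", tag, len(ranking), len(umgs))
        cohort_nets[tag] = cohort_net
        rankings[tag] = ranking
        per_network[tag] = umgs
        prov["networks"][tag] = {**net_prov, "propagation": prop_prov, "umg_candidates": len(umgs)}

    final_genes = selection.intersect_networks(per_network, rankings)
    prov["intersection"] = {"genes": len(final_genes)}

    flags: dict[str, str] = {}
    if dependency is not None and not params.skip_depmap:
        kept, dm, flags = selection.depmap_filter(
            final_genes, dependency, params.cohort, criteria.depmap_fraction
        )
        prov["depmap"] = {"before": len(final_genes), "after": len(kept)}
        final_genes = kept
    else:
        dm = pd.Series(dtype=float, name="DM")

    final = pd.DataFrame(index=pd.Index(final_genes, name="gene"))
    if final_genes:
        final["mean_RFS"] = [
            float(pd.Series([r.loc[g, "RFS"] for r in rankings.values() if g in r.index]).mean())
            for g in final_genes
        ]
        final["DM"] = dm.reindex(final_genes)
        final["flag"] = [flags.get(g, "") for g in final_genes]

    # --- statistical validation
    validation: dict = {}
    if drivers:
        for tag, ranking in rankings.items():
            ref = drivers & set(ranking.index)
            if ref and len(ref) < len(ranking):
                res = stats.rank_enrichment(ranking["RFS"], ref)
                validation[f"rank_enrichment_{tag}"] = vars(res).copy()
    if dependency is not None and final_genes:
        universe = sorted(set().union(*(set(r.index) for r in rankings.values())))
        background = [g for g in universe if g not in set(final_genes)]
        assay = sorted(dependency.assays)[0]
        try:
            res = stats.compare_groups(final_genes, background, dependency, params.cohort, assay)
            validation[f"impact_shift_{assay}"] = vars(res).copy()
        except ValueError as exc:
            validation["impact_shift_error"] = str(exc)
    prov["validation"] = validation

    # --- positionality on the composite network
    if drivers and len(cohort_nets) >= 2:
        composite = netio.composite_union(list(cohort_nets.values()))
        pooled_is = quantized.mean(axis=1)
        strat = positionality.stratify_drivers(drivers, pooled_is, composite, params.positionality)
        cats = positionality.categorize_umgs(final_genes, strat, pooled_is, composite, params.positionality)
        final = final.join(cats[["category", "neighbor_classes"]], how="left")
        prov["positionality"] = {
            "drivers_classified": int(len(strat)),
            "drivers_missing": strat.attrs.get("missing", []),
            "category_counts": cats["category"].value_counts().to_dict() if len(cats) else {},
        }

    return UMGReport(
        criteria=criteria, per_network=per_network, rankings=rankings, final=final, provenance=prov
    )


def run_cohort(cohort, params: PipelineParams | None = None, filters: dict | None = None) -> UMGReport:
    """Run the pipeline on a :class:`~umg.synthdata.SyntheticCohort` bundle."""
    if params is None:
        params = PipelineParams(cohort=cohort.spec.cancer_type, beta=0.2)
    if filters is None:
        filters = {
            "netA": {"confidence_threshold": 0.6},
            "netB": {"top_fraction": 0.7},
        }
    return run(
        networks={"netA": cohort.network_a, "netB": cohort.network_b},
        filters=filters,
        expression=cohort.expression,
        variants=cohort.variants,
        gene_lengths=cohort.gene_lengths,
        params=params,
        dependency=cohort.dependency,
        drivers=set(cohort.drivers),
    )


# --------------------------------------------------------------------------
# file-based front end with content-addressed stage caching
# --------------------------------------------------------------------------
def _hash_parts(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def stage_keys(config: RunConfig) -> dict[str, str]:
    """Content-addressed cache keys per stage; downstream keys chain upstream ones."""
    keys: dict[str, str] = {}
    expr_hash = _hash_file(config.expression.path)
    for net in config.networks:
        keys[f"netio_{net.tag}"] = _hash_parts(
            _hash_file(net.path), net.dialect, net.confidence_threshold, net.top_fraction,
            net.scale_hint, expr_hash, config.expression.fpkm_threshold,
            config.expression.sample_fraction,
        )
    keys["mutmatrix"] = _hash_parts(
        _hash_file(config.variants.path), _hash_file(config.gene_lengths),
        sorted(config.variants.keep_classes), config.quantization_basis,
    )
    for net in config.networks:
        keys[f"propagate_{net.tag}"] = _hash_parts(
            keys[f"netio_{net.tag}"], keys["mutmatrix"], config.propagation.alpha,
            config.propagation.tolerance, config.propagation.max_iterations,
            config.selection.tie_method,
        )
    return keys


class _StageCache:
    def __init__(self, cache_dir):
        self.dir = Path(cache_dir)
        self.dir.mkdir(parents=True, exist_ok=True)

    def path(self, stage: str, key: str) -> Path:
        return self.dir / f"{stage}-{key}.tsv"

    def load_frame(self, stage, key):
        p = self.path(stage, key)
        return pd.read_csv(p, sep="\t", index_col=0) if p.exists() else None

    def store_frame(self, stage, key, frame: pd.DataFrame):
        frame.to_csv(self.path(stage, key), sep="\t")


def _params_from_config(config: RunConfig, skip_depmap: bool = False) -> PipelineParams:
    return PipelineParams(
        cohort=config.cohort,
        beta=config.selection.beta,
        rank_threshold=config.selection.rank_threshold,
        depmap_fraction=config.selection.depmap_fraction,
        skip_depmap=skip_depmap or config.depmap is None,
        propagation=PropagationConfig(
            alpha=config.propagation.alpha,
            tolerance=config.propagation.tolerance,
            max_iterations=config.propagation.max_iterations,
        ),
        fpkm_threshold=config.expression.fpkm_threshold,
        sample_fraction=config.expression.sample_fraction,
        keep_classes=frozenset(config.variants.keep_classes),
        quantization_basis=config.quantization_basis,
        tie_method=config.selection.tie_method,
        positionality=PositionalityConfig(
            score_threshold=config.positionality.score_threshold,
            degree_threshold=config.positionality.degree_threshold,
            zero_floor=config.positionality.zero_floor,
        ),
    )


def read_gene_set(path) -> set[str]:
    """Plain-text gene set: one symbol per line, '#' comments."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.add(line)
    return out


def run_from_config(config: RunConfig, skip_depmap: bool = False) -> UMGReport:
    params = _params_from_config(config, skip_depmap=skip_depmap)
    networks, filters = {}, {}
    for entry in config.networks:
        networks[entry.tag] = netio.read_edge_list(entry.path, dialect=entry.dialect, source_tag=entry.tag)
        filters[entry.tag] = {
            "confidence_threshold": entry.confidence_threshold,
            "top_fraction": entry.top_fraction,
            "scale_hint": entry.scale_hint,
        }
    expression = netio.read_expression(config.expression.path)
    variants = mutmatrix.read_variants(
        config.variants.path, config.variants.sample_col, config.variants.gene_col, config.variants.class_col
    )
    gene_lengths = mutmatrix.read_gene_lengths(config.gene_lengths)
    dependency = None
    if config.depmap is not None:
        dependency = DependencyData.from_files(config.depmap.assays, config.depmap.annotations)
        if config.depmap.cancer_type:
            params.cohort = config.depmap.cancer_type
    drivers = read_gene_set(config.drivers) if config.drivers else None

    report = run(networks, filters, expression, variants, gene_lengths, params,
                 dependency=dependency, drivers=drivers)
    report.provenance["stage_keys"] = stage_keys(config)
    report.provenance["seed"] = config.seed
    write_report(report, config.output_dir)
    if config.cache_dir:
        cache = _StageCache(config.cache_dir)
        for tag, ranking in report.rankings.items():
            cache.store_frame("propagate", report.provenance["stage_keys"][f"propagate_{tag}"], ranking)
    return report


def write_report(report: UMGReport, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for tag, ranking in report.rankings.items():
        ranking.rename_axis("gene").to_csv(out / f"ranking_{tag}.tsv", sep="\t")
        report.network_table(tag).rename_axis("gene").to_csv(out / f"umg_{tag}.tsv", sep="\t")
    report.final.to_csv(out / "umg_final.tsv", sep="\t")
    with open(out / "provenance.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2, default=str)
    if report.final.empty:
        warnings.warn("final UMG list is empty", stacklevel=2)
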