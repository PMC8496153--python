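"""Upward-mobility-gene selection.

Per gene the pipeline records the mean initial score IS, the mean
post-propagation score FS, their tie-aware ranks RIS and RFS (rank 1 =
highest score), and the mobility status MS = RIS - RFS. A gene is an upward
mobility gene (UMG) when

    MS >= beta * |G|   and   RFS <= T,

with beta a cohort-specific jump-size fraction and T the post-propagation
rank threshold (default 1000). Optional evidence filters then intersect the
per-network lists and drop genes whose cell-line dependency support DM
(maximum across CRISPR and RNAi of the fraction of cancer-type cell lines
with a negative effect score) falls below p (default 0.5).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BETA_BY_COHORT",
    "UMGCriteria",
    "DependencyData",
    "UMGReport",
    "mean_scores",
    "rank_scores",
    "mobility",
    "build_ranking",
    "select_umgs",
    "depmap_filter",
    "intersect_networks",
]

#: Cohort-specific mobility fractions: high-sample/high-variance cohorts 0.25,
#: moderate 0.2 and 0.15, low-variance/small cohorts 0.05.
BETA_BY_COHORT: dict[str, float] = {
    **dict.fromkeys(["BRCA", "COAD", "HNSC", "LUAD", "LUSC", "PRAD", "STAD", "UCEC"], 0.25),
    **dict.fromkeys(["CESC", "KIRC", "KIRP", "LIHC"], 0.20),
    **dict.fromkeys(["ESCA", "READ"], 0.15),
    **dict.fromkeys(["CHOL", "KICH", "THCA"], 0.05),
}


@dataclass(frozen=True)
class UMGCriteria:
    """Selection parameters: mobility fraction beta, rank threshold T, dependency fraction p."""

    beta: float
    rank_threshold: int = 1000
    depmap_fraction: float = 0.5

    def __post_init__(self):
        if not 0 < self.beta < 1:
            raise ValueError(f"beta must be in (0, 1); got {self.beta}")
        if self.rank_threshold < 1:
            raise ValueError("rank_threshold must be positive")
        if not 0 <= self.depmap_fraction <= 1:
            raise ValueError("depmap_fraction must be in [0, 1]")

    @classmethod
    def for_cohort(cls, cohort: str, **overrides) -> "UMGCriteria":
        beta = overrides.pop("beta", BETA_BY_COHORT.get(cohort))
        if beta is None:
            raise ValueError(f"no default beta for cohort {cohort!r}; supply one explicitly")
        return cls(beta=beta, **overrides)


def mean_scores(S0: pd.DataFrame, Sfinal: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Arithmetic mean initial and final scores across samples (IS, FS)."""
    if S0.shape[1] == 0:
        raise ValueError("score matrices have zero samples")
    if not S0.index.equals(Sfinal.index) or S0.shape != Sfinal.shape:
        raise ValueError("initial and final score matrices are not aligned")
    return S0.mean(axis=1).rename("IS"), Sfinal.mean(axis=1).rename("FS")


def rank_scores(scores: pd.Series, method: str = "average") -> pd.Series:
    """Ranks with 1 = highest score; ties share the average rank by default.

    ``method="first"`` gives ordinal (first-seen) ranks instead.
    """
    if not np.isfinite(scores.to_numpy(dtype=float)).all():
        raise ValueError("scores must be finite")
    return scores.rank(ascending=False, method=method)


def mobility(ris: pd.Series, rfs: pd.Series) -> pd.Series:
    """MS = RIS - RFS; positive values mean the gene moved up during propagation."""
    if not ris.index.equals(rfs.index):
        raise ValueError("rank vectors cover different gene universes")
    return (ris - rfs).rename("MS")


def build_ranking(S0: pd.DataFrame, Sfinal: pd.DataFrame, tie_method: str = "average") -> pd.DataFrame:
    """Assemble the per-gene table of IS, FS, RIS, RFS and MS."""
    IS, FS = mean_scores(S0, Sfinal)
    ris = rank_scores(IS, method=tie_method).rename("RIS")
    rfs = rank_scores(FS, method=tie_method).rename("RFS")
    return pd.DataFrame({"IS": IS, "FS": FS, "RIS": ris, "RFS": rfs, "MS": mobility(ris, rfs)})


def select_umgs(ranking: pd.DataFrame, criteria: UMGCriteria, g_size: int | None = None) -> list[str]:
    """Genes with MS >= beta*|G| and RFS <= T, ordered by ascending final rank.

    ``g_size`` defaults to the number of ranked genes; the beta*|G| comparison
    is done in reals (no rounding).
    """
    n = len(ranking) if g_size is None else g_size
    mask = (ranking["MS"] >= criteria.beta * n) & (ranking["RFS"] <= criteria.rank_threshold)
    return ranking.loc[mask].sort_values("RFS").index.tolist()


_SYMBOL_RE = re.compile(r"[\s(]")


def _strip_symbol(name: str) -> str:
    """``"TP53 (7157)" -> "TP53"`` — DepMap gene fields carry the Entrez id."""
    return _SYMBOL_RE.split(str(name).strip(), maxsplit=1)[0]


@dataclass
class DependencyData:
    """Gene x cell-line effect-score matrices per assay, with cancer-type annotations.

    Negative scores mean the knockout/knockdown impaired viability. When a
    cancer type has no annotated cell lines, queries fall back to all lines
    of the assay.
    """

    assays: dict[str, pd.DataFrame]
    annotations: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self):
        for name, mat in self.assays.items():
            if mat.columns.duplicated().any():
                raise ValueError(f"duplicate cell lines in assay {name!r}")

    @classmethod
    def from_files(cls, assay_paths: dict[str, str], annotation_path: str | None = None) -> "DependencyData":
        assays = {}
        for name, path in assay_paths.items():
            mat = pd.read_csv(path, index_col=0)
            mat.index = [_strip_symbol(g) for g in mat.index]
            mat = mat[~pd.Index(mat.index).duplicated()]
            assays[name] = mat
        ann = pd.Series(dtype=object)
        if annotation_path is not None:
            df = pd.read_csv(annotation_path, sep="\t")
            ann = df.set_index(df.columns[0])[df.columns[1]]
        return cls(assays=assays, annotations=ann)

    def lines_for(self, assay: str, cancer_type: str | None) -> list[str]:
        mat = self.assays[assay]
        if cancer_type is not None and len(self.annotations):
            annotated = set(self.annotations.index[self.annotations == cancer_type])
            lines = [c for c in mat.columns if c in annotated]
            if lines:
                return lines
        return list(mat.columns)  # fallback: all cell lines of the assay

    def negative_fraction(self, gene: str, assay: str, cancer_type: str | None) -> float | None:
        """Fraction of the cancer type's cell lines with a strictly negative score."""
        mat = self.assays[assay]
        if gene not in mat.index:
            return None
        lines = self.lines_for(assay, cancer_type)
        vals = mat.loc[gene, lines].astype(float).dropna()
        if vals.empty:
            return None
        return float((vals < 0).mean())

    def dm(self, gene: str, cancer_type: str | None) -> float | None:
        """DM = max over assays of the negative fraction; None if the gene is in no assay."""
        fracs = [
            f
            for assay in self.assays
            if (f := self.negative_fraction(gene, assay, cancer_type)) is not None
        ]
        return max(fracs) if fracs else None


def depmap_filter(
    genes: list[str],
    dep: DependencyData,
    cancer_type: str | None,
    p: float = 0.5,
) -> tuple[list[str], pd.Series, dict[str, str]]:
    """Keep genes with DM >= p; genes absent from every assay pass with a flag.

    Returns ``(kept, DM per input gene, flags)``. The filter is optional
    evidence, so missing dependency data never removes a gene.
    """
    if not dep.assays:
        raise ValueError("no dependency assays available")
    dm, kept, flags = {}, [], {}
    for g in genes:
        d = dep.dm(g, cancer_type)
        dm[g] = np.nan if d is None else d
        if d is None:
            kept.append(g)
            flags[g] = "no dependency data"
        elif d >= p:
            kept.append(g)
    return kept, pd.Series(dm, name="DM"), flags


def intersect_networks(
    per_network: dict[str, list[str]],
    rankings: dict[str, pd.DataFrame] | None = None,
) -> list[str]:
    """Intersection of per-network UMG lists, ordered by mean final rank.

    With a single network this is the identity; an empty intersection emits
    a warning and returns an empty list.
    """
    if not per_network:
        raise ValueError("need at least one per-network gene list")
    lists = list(per_network.values())
    final = set(lists[0]).intersection(*map(set, lists[1:]))
    if not final:
        warnings.warn("UMG intersection across networks is empty", stacklevel=2)
        return []
    if rankings:
        key = {
            g: np.mean([r.loc[g, "RFS"] for r in rankings.values() if g in r.index])
            for g in final
        }
    else:
        key = {g: min(lst.index(g) for lst in lists if g in lst) for g in final}
    return sorted(final, key=lambda g: (key[g], g))


@dataclass
class UMGReport:
    """Per-network selections, the intersected final list, and run provenance."""

    criteria: UMGCriteria
    per_network: dict[str, list[str]]
    rankings: dict[str, pd.DataFrame]
    final: pd.DataFrame  # gene-indexed: mean_RFS, DM, flag, (category later)
    provenance: dict = field(default_factory=dict)

    @property
    def final_genes(self) -> list[str]:
        return self.final.index.tolist()

    def network_table(self, tag: str) -> pd.DataFrame:
        """Ranking rows of the selected genes for one network, ordered by RFS."""
        return self.rankings[tag].loc[self.per_network[tag]]
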