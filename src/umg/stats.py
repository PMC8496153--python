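"""Statistical validation of rankings and dependency-based group comparisons.

Two one-sided Mann-Whitney U tests back the pipeline: (1) enrichment of a
reference gene set (e.g. the COSMIC census) toward the top of a ranking, and
(2) a right-shift of the percentage-based cell-line impact score psi for
selected genes versus background. For a gene with k cancer-type cell lines,

    psi = (sum_j b_j + mean_j b_j) / (k + 2),    b_j = 1[score_j < 0],

i.e. the k negativity indicators plus their mean, smoothed by a pseudo
cell line with a non-negative score so psi < 1 strictly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .selection import DependencyData

__all__ = [
    "EnrichmentResult",
    "rank_enrichment",
    "impact_score",
    "impact_table",
    "compare_groups",
]

EXACT_LIMIT = 12  # total group size at or below which the exact permutation p is enumerated


@dataclass(frozen=True)
class EnrichmentResult:
    statistic: float  # Mann-Whitney U of the reference group (on "better-ness")
    p_value: float
    n_reference: int
    n_other: int
    method: str  # "exact" or "asymptotic"


def _exact_rank_p(ref: np.ndarray, other: np.ndarray) -> tuple[float, float]:
    """Exact one-sided p that the reference ranks are stochastically smaller.

    Enumerates every assignment of the combined rank multiset to the two
    groups; handles tie-averaged (non-integer) ranks natively.
    """
    combined = np.concatenate([ref, other])
    observed = ref.sum()
    n_ref = len(ref)
    total = math.comb(len(combined), n_ref)
    hits = sum(1 for c in itertools.combinations(combined, n_ref) if sum(c) <= observed + 1e-9)
    # U of the reference group counted on "better than" pairs (smaller rank wins)
    u = sum((r < o) + 0.5 * (r == o) for r in ref for o in other)
    return float(u), hits / total


def rank_enrichment(ranks: pd.Series, reference: set[str]) -> EnrichmentResult:
    """One-sided Mann-Whitney U test that reference genes hold better (smaller) ranks.

    Exact enumeration when the two groups together hold at most
    ``EXACT_LIMIT`` genes; otherwise the tie-corrected normal approximation.
    """
    ref_mask = ranks.index.isin(reference)
    ref = ranks[ref_mask].to_numpy(dtype=float)
    other = ranks[~ref_mask].to_numpy(dtype=float)
    if len(ref) == 0 or len(other) == 0:
        raise ValueError("both the reference and the background group must be non-empty")
    if len(ref) + len(other) <= EXACT_LIMIT:
        u, p = _exact_rank_p(ref, other)
        method = "exact"
    else:
        # smaller rank value = better; "less" tests the reference shifted toward small ranks
        res = sps.mannwhitneyu(ref, other, alternative="less", method="asymptotic")
        # report U on the "better-ness" scale for consistency with the exact branch
        u, p, method = len(ref) * len(other) - float(res.statistic), float(res.pvalue), "asymptotic"
    return EnrichmentResult(u, p, len(ref), len(other), method)


def impact_score(
    gene: str,
    dep: DependencyData,
    cancer_type: str | None,
    assay: str,
    smoothed: bool = True,
) -> float | None:
    """Percentage-based impact score psi for one gene in one assay.

    ``smoothed=False`` returns the plain negative fraction sum(b)/k instead
    (the DM-style proportion). Returns None when the gene is absent.
    """
    mat = dep.assays[assay]
    if gene not in mat.index:
        return None
    lines = dep.lines_for(assay, cancer_type)
    vals = mat.loc[gene, lines].astype(float).dropna()
    k = len(vals)
    if k == 0:
        return None
    b = (vals < 0).to_numpy()
    if not smoothed:
        return float(b.mean())
    return float((b.sum() + b.mean()) / (k + 2))


def impact_table(
    genes: list[str],
    dep: DependencyData,
    cancer_type: str | None,
    assay: str,
    smoothed: bool = True,
) -> pd.Series:
    """psi for each gene; genes absent from the assay come back as NaN."""
    return pd.Series(
        {g: (v if (v := impact_score(g, dep, cancer_type, assay, smoothed)) is not None else np.nan) for g in genes},
        name="psi",
    )


def compare_groups(
    umg: list[str],
    background: list[str],
    dep: DependencyData,
    cancer_type: str | None,
    assay: str,
) -> EnrichmentResult:
    """One-sided test that psi(UMG) is shifted right of psi(background)."""
    x = impact_table(umg, dep, cancer_type, assay).dropna().to_numpy()
    y = impact_table(background, dep, cancer_type, assay).dropna().to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one gene with dependency data")
    res = sps.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return EnrichmentResult(float(res.statistic), float(res.pvalue), len(x), len(y), "asymptotic")
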