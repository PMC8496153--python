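"""Positionality of selected genes relative to known drivers.

On the composite network (union of the filtered source networks) each known
driver is stratified by its cohort initial score and its unweighted degree
(defaults: score >= 0.075 is high-score, degree >= 150 is high-degree;
initial scores below 0.0015 are zeroed first to curb false positives). Each
UMG is then categorized from its 1-hop driver neighborhood:

    drug_target   — adjacent to high-score drivers only
    weak_driver   — adjacent to low-score drivers only, or to none while
                    carrying a real initial score of its own
    both          — adjacent to drivers of both kinds
    low_evidence  — own initial score below the zero floor (or absent from
                    the composite network)
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .netio import WeightedNetwork

__all__ = [
    "PositionalityConfig",
    "stratify_drivers",
    "categorize_umgs",
]

DRIVER_CLASSES = (
    "high_score_high_degree",
    "high_score_low_degree",
    "low_score_low_degree",
    "low_score_high_degree",
)
UMG_CATEGORIES = ("drug_target", "weak_driver", "both", "low_evidence")


@dataclass(frozen=True)
class PositionalityConfig:
    score_threshold: float = 0.075
    degree_threshold: int = 150
    zero_floor: float = 0.0015


def stratify_drivers(
    drivers: set[str],
    initial_scores: pd.Series,
    net: WeightedNetwork,
    cfg: PositionalityConfig = PositionalityConfig(),
) -> pd.DataFrame:
    """Classify drivers by (score, degree); drivers outside the network are excluded.

    Returns a frame indexed by driver with columns ``IS`` (floored), ``degree``
    and ``driver_class``; excluded drivers are listed in ``frame.attrs["missing"]``.
    """
    rows, missing = {}, []
    for d in sorted(drivers):
        if not net.has_node(d):
            missing.append(d)
            continue
        score = float(initial_scores.get(d, 0.0))
        if score < cfg.zero_floor:
            score = 0.0
        deg = net.degree(d)
        cls = ("high" if score >= cfg.score_threshold else "low") + "_score_" + (
            "high" if deg >= cfg.degree_threshold else "low"
        ) + "_degree"
        rows[d] = {"IS": score, "degree": deg, "driver_class": cls}
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["IS", "degree", "driver_class"])
    out.attrs["missing"] = missing
    return out


def categorize_umgs(
    umgs: list[str],
    strat: pd.DataFrame,
    initial_scores: pd.Series,
    net: WeightedNetwork,
    cfg: PositionalityConfig = PositionalityConfig(),
) -> pd.DataFrame:
    """Label each UMG from its own initial score and 1-hop driver adjacency.

    Labels are mutually exclusive and every UMG receives exactly one;
    rerunning on identical inputs is bit-identical.
    """
    high = set(strat.index[strat["driver_class"].str.startswith("high_score")])
    low = set(strat.index[strat["driver_class"].str.startswith("low_score")])
    rows = {}
    for g in umgs:
        score = float(initial_scores.get(g, 0.0))
        if not net.has_node(g):
            rows[g] = {"category": "low_evidence", "IS": score, "degree": 0,
                       "neighbor_classes": "", "flag": "absent from composite network"}
            continue
        nbrs = set(net.graph.neighbors(g))
        hi, lo = nbrs & high, nbrs & low
        if score < cfg.zero_floor:
            cat = "low_evidence"
        elif hi and lo:
            cat = "both"
        elif hi:
            cat = "drug_target"
        else:
            # low-score driver neighbors, or no driver neighbors at all, with a
            # real mutation signal of its own: behaves like a weak driver
            cat = "weak_driver"
        nbr_classes = sorted(strat.loc[sorted(hi | lo), "driver_class"].unique()) if (hi or lo) else []
        rows[g] = {"category": cat, "IS": score, "degree": net.degree(g),
                   "neighbor_classes": ";".join(nbr_classes), "flag": ""}
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["category", "IS", "degree", "neighbor_classes", "flag"]
    )
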