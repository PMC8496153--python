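"""Quantized gene x sample somatic mutation matrices.

Variant calls are restricted to splicing and coding exonic classes, counted
per gene and sample, normalized by gene length (counts per bp), and each
non-zero value is mapped to a discrete level in {1, 2, 3, 4} by its position
relative to the 50th/70th/90th percentiles of the cohort's non-zero
normalized frequency distribution. The quantized matrix seeds propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_KEEP_CLASSES",
    "QuantizationThresholds",
    "read_variants",
    "read_gene_lengths",
    "count_matrix",
    "length_normalize",
    "quantize",
]

#: Variant classes treated as splicing / coding exonic by default.
DEFAULT_KEEP_CLASSES = frozenset({"exonic", "splicing"})


@dataclass(frozen=True)
class QuantizationThresholds:
    """50th/70th/90th percentiles of the non-zero normalized frequencies (counts per bp)."""

    p50: float
    p70: float
    p90: float

    def __post_init__(self):
        if not (self.p50 <= self.p70 <= self.p90):
            raise ValueError("quantization thresholds must be non-decreasing")

    def level(self, value: float) -> int:
        """Discrete level of a single non-zero normalized frequency."""
        if value <= 0:
            return 0
        if value <= self.p50:
            return 1
        if value <= self.p70:
            return 2
        if value <= self.p90:
            return 3
        return 4


def read_variants(
    path,
    sample_col: str = "sample",
    gene_col: str = "gene",
    class_col: str = "variant_class",
) -> pd.DataFrame:
    """Read a MAF-like TSV into a (sample, gene, variant_class) frame."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in (sample_col, gene_col, class_col) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    out = df[[sample_col, gene_col, class_col]].copy()
    out.columns = ["sample", "gene", "variant_class"]
    if out[["sample", "gene"]].isna().any().any() or (out[["sample", "gene"]] == "").any().any():
        raise ValueError(f"{path}: empty sample or gene identifiers")
    return out


def read_gene_lengths(path) -> pd.Series:
    """Read a two-column (gene, length-in-bp) TSV."""
    df = pd.read_csv(path, sep="\t")
    df.columns = ["gene", "length"][: len(df.columns)]
    s = df.set_index("gene")["length"].astype(float)
    if s.index.duplicated().any():
        raise ValueError("duplicate genes in length table")
    if (s <= 0).any():
        bad = s.index[s <= 0].tolist()
        raise ValueError(f"non-positive gene lengths for {bad[:5]}")
    return s


def count_matrix(variants: pd.DataFrame, keep_classes=DEFAULT_KEEP_CLASSES) -> pd.DataFrame:
    """Per-gene, per-sample counts of retained variants.

    ``variants`` needs columns ``sample``, ``gene``, ``variant_class``. Rows
    whose class is not in ``keep_classes`` are excluded; unknown classes are
    not an error. Returns an all-zero frame over the observed samples when
    nothing is retained.
    """
    if not keep_classes:
        raise ValueError("keep_classes must be non-empty")
    kept = variants[variants["variant_class"].isin(keep_classes)]
    samples = sorted(variants["sample"].unique())
    if kept.empty:
        return pd.DataFrame(0, index=pd.Index([], name="gene"), columns=samples, dtype=int)
    counts = (
        kept.groupby(["gene", "sample"]).size().unstack(fill_value=0).reindex(columns=samples, fill_value=0)
    )
    counts.index.name = "gene"
    return counts.sort_index().astype(int)


def length_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Divide each gene's counts by its length in bp (counts per bp)."""
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"no length for {len(missing)} counted gene(s): {sorted(missing)[:10]}")
    return counts.div(lengths.reindex(counts.index), axis=0)


def quantize(norm: pd.DataFrame, basis: str = "pooled") -> tuple[pd.DataFrame, QuantizationThresholds]:
    """Map non-zero normalized frequencies to levels {1, 2, 3, 4}; zeros stay 0.

    Percentiles use linear interpolation between order statistics. With
    ``basis="pooled"`` (default) they are taken over all non-zero matrix
    entries and each entry is converted by its own value; with
    ``basis="per_gene"`` they are taken over the per-gene mean normalized
    frequencies and every non-zero entry of a gene receives that gene's level.
    """
    values = norm.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("normalized matrix contains NaN")
    if basis == "pooled":
        nz = values[values > 0]
        if nz.size == 0:
            raise ValueError("all-zero mutation matrix cannot be quantized")
        p50, p70, p90 = np.percentile(nz, [50, 70, 90])
        thr = QuantizationThresholds(float(p50), float(p70), float(p90))
        levels = np.zeros_like(values, dtype=int)
        levels[values > 0] = _levels_of(values[values > 0], thr)
    elif basis == "per_gene":
        gene_freq = values.mean(axis=1)
        nz = gene_freq[gene_freq > 0]
        if nz.size == 0:
            raise ValueError("all-zero mutation matrix cannot be quantized")
        p50, p70, p90 = np.percentile(nz, [50, 70, 90])
        thr = QuantizationThresholds(float(p50), float(p70), float(p90))
        gene_levels = np.zeros(values.shape[0], dtype=int)
        gene_levels[gene_freq > 0] = _levels_of(gene_freq[gene_freq > 0], thr)
        levels = np.where(values > 0, gene_levels[:, None], 0)
    else:
        raise ValueError(f"unknown basis {basis!r}; expected 'pooled' or 'per_gene'")
    return pd.DataFrame(levels, index=norm.index, columns=norm.columns), thr


def _levels_of(nonzero: np.ndarray, thr: QuantizationThresholds) -> np.ndarray:
    # left-open/right-closed bins: v <= p50 -> 1, (p50, p70] -> 2, (p70, p90] -> 3, else 4
    return 1 + (nonzero > thr.p50).astype(int) + (nonzero > thr.p70) + (nonzero > thr.p90)
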