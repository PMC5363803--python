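"""Transcriptome filtering and developmental-axis projection.

Bulk RNA-seq samples (gene x sample TPM) from cells grown in different
geometries are placed on a reference differentiation trajectory: an axis
in log2(TPM+1) gene-expression space is drawn from the centroid of a
progenitor reference group (position 0) to that of an adult reference
group (position 1), and every sample's scalar position along the axis is
the normalized projection ((x - origin) . d) / (d . d).  The separation
between two sample groups is then expressed as a percentage of the full
progenitor-to-adult distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

__all__ = [
    "AxisProjection",
    "log_transform",
    "filter_expressed",
    "genes_detected",
    "define_axis",
    "project",
    "percent_closer",
    "zscore",
]


@dataclass
class AxisProjection:
    """A developmental axis: per-gene origin (start centroid) and vector d."""

    gene_set: pd.Index
    origin: pd.Series          # start-group centroid, log2(TPM+1)
    d: pd.Series               # per-gene log2 fold change start -> end
    start_samples: list = field(default_factory=list)
    end_samples: list = field(default_factory=list)


def log_transform(tpm) -> pd.DataFrame:
    """Elementwise log2(TPM + 1); the +1 avoids zeros."""
    tpm = pd.DataFrame(tpm)
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    return np.log2(tpm + 1.0)


def filter_expressed(tpm: pd.DataFrame, group_labels: pd.Series,
                     groups: tuple[str, str] = ("small", "confluent"),
                     threshold: float = 10.0) -> pd.Index:
    """Genes appreciably expressed in at least one of two named groups.

    A gene is excluded only when its average TPM is below the threshold in
    both groups (computed separately); i.e. retained iff mean TPM >=
    threshold in either.
    """
    group_labels = pd.Series(group_labels)
    for g in groups:
        if g not in set(group_labels):
            raise ValueError(f"unknown group label {g!r}")
    keep = np.zeros(tpm.shape[0], dtype=bool)
    for g in groups:
        cols = group_labels.index[group_labels == g]
        keep |= (tpm[cols].mean(axis=1) >= threshold).to_numpy()
    return tpm.index[keep]


def genes_detected(sample_tpm: pd.Series, threshold: float = 10.0) -> int:
    """Number of genes detected in one sample at TPM strictly above threshold."""
    return int((np.asarray(sample_tpm, dtype=float) > threshold).sum())


def define_axis(log_matrix: pd.DataFrame, start_samples, end_samples,
                gene_set=None) -> AxisProjection:
    """Axis from the start-group centroid to the end-group centroid.

    ``d`` is the per-gene difference of group means in log2(TPM+1) (the
    log-scale fold change); genes with d = 0 are dropped with a warning.
    """
    start_samples = list(start_samples)
    end_samples = list(end_samples)
    if not start_samples or not end_samples:
        raise ValueError("both reference groups must be non-empty")
    sub = log_matrix.loc[gene_set] if gene_set is not None else log_matrix
    origin = sub[start_samples].mean(axis=1)
    d = sub[end_samples].mean(axis=1) - origin
    degenerate = d == 0
    if degenerate.any():
        warnings.warn(f"dropping {int(degenerate.sum())} genes with zero fold change")
        origin, d = origin[~degenerate], d[~degenerate]
    if float(d @ d) == 0.0:
        raise ValueError("axis vector has zero norm")
    return AxisProjection(gene_set=d.index, origin=origin, d=d,
                          start_samples=start_samples, end_samples=end_samples)


def project(log_matrix: pd.DataFrame, axis: AxisProjection) -> pd.Series:
    """Scalar position of each sample: ((x - origin) . d) / (d . d).

    The start centroid maps to exactly 0 and the end centroid to exactly 1.
    Missing axis genes raise with the offending genes listed.
    """
    missing = axis.gene_set.difference(log_matrix.index)
    if len(missing):
        raise KeyError(f"samples lack axis genes: {list(missing[:10])}"
                       + ("..." if len(missing) > 10 else ""))
    X = log_matrix.loc[axis.gene_set]
    d = axis.d.to_numpy()
    pos = (X.sub(axis.origin, axis=0).to_numpy().T @ d) / float(d @ d)
    return pd.Series(pos, index=log_matrix.columns, name="position")


def percent_closer(positions_a: pd.Series, positions_b: pd.Series):
    """How much closer (in % of the axis) group B is to the axis end.

    Returns (delta_percent, sem, p): 100 x (mean_B - mean_A), the s.e.m.
    of the difference by independent-group error propagation, and a
    two-sided Welch t-test p-value (omitted for singleton groups).
    """
    a = np.asarray(positions_a, dtype=float)
    b = np.asarray(positions_b, dtype=float)
    delta = 100.0 * (b.mean() - a.mean())
    if a.size < 2 or b.size < 2:
        return delta, float("nan"), float("nan")
    sem = 100.0 * np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    _, p = ttest_ind(b, a, equal_var=False)
    return float(delta), float(sem), float(p)


def zscore(log_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene standardization across samples (mean 0, sd 1 per row).

    Constant genes cannot be standardized and are dropped with a warning.
    """
    X = pd.DataFrame(log_matrix)
    sd = X.std(axis=1, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant genes")
        X, sd = X[~const], sd[~const]
    return X.sub(X.mean(axis=1), axis=0).div(sd, axis=0)
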