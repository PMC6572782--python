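"""Population statistics of single-cell transcript counts.

Given per-cell molecule counts, this module computes the summary statistics
used to characterise the osmotic-stress response: the population mean, the
fraction of ON-cells (cells whose count exceeds a basal threshold derived
from the 95% point of the cumulative pre-stress distribution), the Fano
factor (variance over mean; 1 for a Poisson process, above 1 for bursty
transcription), empirical marginal distributions, joint nuclear-cytoplasmic
distributions, across-replicate aggregation, and two-sample
Kolmogorov-Smirnov comparisons of marginal distributions.

Conventions: the Fano factor uses the population variance (divide by N);
replicate spread uses the sample standard deviation (divide by n-1). Both
are switchable via the ``ddof`` arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

__all__ = [
    "ExpressionSummary",
    "basal_on_threshold",
    "on_fraction",
    "fano",
    "marginal_distribution",
    "joint_distribution",
    "summarize",
    "aggregate_replicates",
    "ks_compare",
]

#: Published basal ON thresholds for the deposited data: a cell is ON with
#: more than 2 STL1 or more than 8 CTT1 molecules. Recompute with
#: :func:`basal_on_threshold` for any other data set.
PUBLISHED_ON_THRESHOLDS = {"STL1": 2, "CTT1": 8}


@dataclass
class ExpressionSummary:
    """Per-condition/gene/timepoint expression statistics."""

    condition: str
    gene: str
    timepoint: float
    n_cells: int
    mean: float
    fano: float
    on_fraction: float
    on_threshold: int
    marginal: np.ndarray | None = None
    joint: np.ndarray | None = None
    replicate_stats: dict[str, tuple[float, float]] = field(default_factory=dict)


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValueError("empty count list")
    if arr.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    return arr


def basal_on_threshold(basal_counts, coverage: float = 0.95) -> int:
    """Basal cutoff T: smallest integer covering >= ``coverage`` of basal cells.

    T is the smallest integer such that the fraction of pre-stress (t = 0)
    cells with count <= T is at least ``coverage``; cells with count > T are
    classified ON. With the deposited data this rule gives T = 2 for STL1
    and T = 8 for CTT1 (ON means more than two, resp. eight, molecules).
    """
    arr = _as_counts(basal_counts)
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    values, cnts = np.unique(arr.astype(np.int64), return_counts=True)
    cumulative = np.cumsum(cnts) / arr.size
    idx = int(np.searchsorted(cumulative, coverage - 1e-12))
    return int(values[min(idx, values.size - 1)])


def on_fraction(counts, threshold: int) -> float:
    """Fraction of cells with count strictly above the basal threshold."""
    arr = _as_counts(counts)
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return float(np.mean(arr > threshold))


def fano(counts, ddof: int = 0) -> float:
    """Fano factor: variance divided by mean; NaN when the mean is zero.

    The default ``ddof=0`` is the population-variance convention.
    """
    arr = _as_counts(counts)
    m = float(arr.mean())
    if m == 0:
        return math.nan
    return float(arr.var(ddof=ddof) / m)


def marginal_distribution(counts) -> np.ndarray:
    """Empirical probability mass of counts over 0..max(counts); sums to 1."""
    arr = _as_counts(counts).astype(np.int64)
    pmf = np.bincount(arr).astype(np.float64)
    return pmf / pmf.sum()


def joint_distribution(nuclear, cytoplasmic) -> np.ndarray:
    """Empirical joint mass of paired (nuclear, cytoplasmic) counts per cell.

    Entry ``[i, j]`` is the fraction of cells with i nuclear and j
    cytoplasmic molecules; row sums give the nuclear marginal and column
    sums the cytoplasmic marginal, exactly.
    """
    nuc = _as_counts(nuclear).astype(np.int64)
    cyt = _as_counts(cytoplasmic).astype(np.int64)
    if nuc.size != cyt.size:
        raise ValueError("nuclear and cytoplasmic lists must be paired per cell")
    joint = np.zeros((nuc.max() + 1, cyt.max() + 1), dtype=np.float64)
    np.add.at(joint, (nuc, cyt), 1.0)
    return joint / nuc.size


def summarize(
    totals,
    condition: str = "",
    gene: str = "",
    timepoint: float = 0.0,
    on_threshold: int | None = None,
    basal_counts=None,
    coverage: float = 0.95,
    nuclear=None,
    cytoplasmic=None,
    fano_ddof: int = 0,
) -> ExpressionSummary:
    """Build the full summary for one condition/gene/timepoint.

    ``on_threshold`` may be given explicitly (e.g. the published values) or
    derived from ``basal_counts`` via :func:`basal_on_threshold`.
    """
    arr = _as_counts(totals)
    if on_threshold is None:
        if basal_counts is None:
            raise ValueError("need either on_threshold or basal_counts")
        on_threshold = basal_on_threshold(basal_counts, coverage)
    joint = None
    if nuclear is not None and cytoplasmic is not None:
        joint = joint_distribution(nuclear, cytoplasmic)
    return ExpressionSummary(
        condition=condition,
        gene=gene,
        timepoint=float(timepoint),
        n_cells=int(arr.size),
        mean=float(arr.mean()),
        fano=fano(arr, ddof=fano_ddof),
        on_fraction=on_fraction(arr, on_threshold),
        on_threshold=int(on_threshold),
        marginal=marginal_distribution(arr),
        joint=joint,
    )


def aggregate_replicates(replicas: list[ExpressionSummary], ddof: int = 1) -> ExpressionSummary:
    """Across-replicate mean and standard deviation of each scalar statistic.

    All replicas must describe the same condition, gene and timepoint. With
    a single replica the standard deviations are NaN. The returned summary
    carries the across-replica means as its point statistics and a
    ``replicate_stats`` map statistic -> (mean, sd).
    """
    if not replicas:
        raise ValueError("need at least one replica")
    keys = {(r.condition, r.gene, r.timepoint) for r in replicas}
    if len(keys) > 1:
        raise ValueError(f"replicas are not aligned: {sorted(keys)}")
    stats = {}
    for name in ("mean", "fano", "on_fraction"):
        vals = np.array([getattr(r, name) for r in replicas], dtype=np.float64)
        sd = float(vals.std(ddof=ddof)) if vals.size > ddof else math.nan
        stats[name] = (float(vals.mean()), sd)
    ref = replicas[0]
    return ExpressionSummary(
        condition=ref.condition,
        gene=ref.gene,
        timepoint=ref.timepoint,
        n_cells=int(sum(r.n_cells for r in replicas)),
        mean=stats["mean"][0],
        fano=stats["fano"][0],
        on_fraction=stats["on_fraction"][0],
        on_threshold=ref.on_threshold,
        replicate_stats=stats,
    )


def ks_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test between count samples.

    Returns (D, p) with D = sup |ECDF_a - ECDF_b| and the asymptotic
    p-value. Count data are discrete, so the asymptotic p-value is
    conservative for heavily tied samples; the D statistic itself is exact.
    """
    a = _as_counts(sample_a)
    b = _as_counts(sample_b)
    res = sstats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
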