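"""Dual per-receptor normalization of the energy matrix and outlier selection.

Raw binding energies are not comparable across receptors: each receptor has
its own energy scale set by its surface and size.  Two complementary
per-row normalizations address this:

* Z-score: Z_ij = (m_ij - mu_i) / sigma_i with the receptor-row mean and
  population standard deviation; a pair is flagged when Z_ij <= -1.541,
  roughly the lowest ~5% of a standard normal.
* MinMax: (m_ij - min_i) / (max_i - min_i), rescaling each row into [0, 1];
  the bottom 5% of the pooled scaled values are flagged.

Z-score assumes roughly Gaussian rows; MinMax is distribution-free but
sensitive to row range.  Pairs flagged by either are candidate high-affinity
interactions.  Rows with zero variance (or zero range) cannot rank their
cells and are excluded from selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aggregation import EnergyMatrix
from .errors import VinascreenError

#: Z threshold used by the selection rule (inclusive).  The exact standard
#: normal 5th percentile is -1.645; -1.541 (~6.2% tail) is this pipeline's
#: operational default.  Configurable.
DEFAULT_Z_THRESHOLD = -1.541

#: Pooled fraction of MinMax values flagged.
DEFAULT_MINMAX_FRACTION = 0.05


@dataclass
class RowStats:
    receptor_ids: list[str]
    mean: np.ndarray      # mu_i, kcal/mol
    sd: np.ndarray        # sigma_i (population, divisor n)
    minimum: np.ndarray
    maximum: np.ndarray


@dataclass
class NormalizedScores:
    kind: str                       # "zscore" | "minmax"
    values: np.ndarray              # same shape as M; NaN where M missing
    row_stats: RowStats
    degenerate_rows: np.ndarray     # bool per receptor
    receptor_ids: list[str] = field(default_factory=list)
    ligand_ids: list[str] = field(default_factory=list)


@dataclass
class SelectionResult:
    method: str                     # "zscore" | "minmax"
    threshold: float                # z cutoff, or the realized mm quantile
    flagged: set[tuple[str, str]]


def _row_stats(matrix: EnergyMatrix, ddof: int = 0) -> RowStats:
    m = matrix.m
    for i, rid in enumerate(matrix.receptor_ids):
        if np.sum(~np.isnan(m[i])) < 2:
            raise VinascreenError(f"receptor row {rid!r} has fewer than 2 values")
    return RowStats(
        receptor_ids=list(matrix.receptor_ids),
        mean=np.nanmean(m, axis=1),
        sd=np.sqrt(np.nanvar(m, axis=1, ddof=ddof)),
        minimum=np.nanmin(m, axis=1),
        maximum=np.nanmax(m, axis=1),
    )


def zscore_normalize(matrix: EnergyMatrix, ddof: int = 0) -> NormalizedScores:
    """Per-receptor standardization Z_ij = (m_ij - mu_i) / sigma_i.

    ``ddof=0`` (population sd) by default.  Zero-variance rows are flagged
    degenerate with Z set to 0 and never contribute to selection.
    """
    stats = _row_stats(matrix, ddof=ddof)
    degenerate = stats.sd == 0
    sd_safe = np.where(degenerate, 1.0, stats.sd)
    z = (matrix.m - stats.mean[:, None]) / sd_safe[:, None]
    z[degenerate, :] = np.where(np.isnan(matrix.m[degenerate, :]), np.nan, 0.0)
    return NormalizedScores(kind="zscore", values=z, row_stats=stats,
                            degenerate_rows=degenerate,
                            receptor_ids=list(matrix.receptor_ids),
                            ligand_ids=list(matrix.ligand_ids))


def minmax_normalize(matrix: EnergyMatrix) -> NormalizedScores:
    """Per-receptor rescaling into [0, 1]; the row minimum maps to 0 (the
    most favorable energy) and the maximum to 1.  Zero-range rows are
    degenerate: values set to 0.5 and excluded from selection."""
    stats = _row_stats(matrix)
    rng = stats.maximum - stats.minimum
    degenerate = rng == 0
    rng_safe = np.where(degenerate, 1.0, rng)
    mm = (matrix.m - stats.minimum[:, None]) / rng_safe[:, None]
    mm[degenerate, :] = np.where(np.isnan(matrix.m[degenerate, :]), np.nan, 0.5)
    return NormalizedScores(kind="minmax", values=mm, row_stats=stats,
                            degenerate_rows=degenerate,
                            receptor_ids=list(matrix.receptor_ids),
                            ligand_ids=list(matrix.ligand_ids))


def _flag(scores: NormalizedScores, keep: np.ndarray) -> set[tuple[str, str]]:
    keep = keep & ~np.isnan(scores.values) & ~scores.degenerate_rows[:, None]
    out = set()
    for i, j in zip(*np.where(keep)):
        out.add((scores.receptor_ids[i], scores.ligand_ids[j]))
    return out


def select_outliers_z(
    scores: NormalizedScores, threshold: float = DEFAULT_Z_THRESHOLD
) -> SelectionResult:
    """Pairs with Z_ij <= threshold (inclusive), skipping degenerate rows."""
    if scores.kind != "zscore":
        raise VinascreenError("select_outliers_z requires z-score normalized input")
    with np.errstate(invalid="ignore"):
        flagged = _flag(scores, scores.values <= threshold)
    return SelectionResult(method="zscore", threshold=threshold, flagged=flagged)


def select_outliers_minmax(
    scores: NormalizedScores,
    fraction: float = DEFAULT_MINMAX_FRACTION,
    per_row: bool = False,
) -> SelectionResult:
    """Bottom ``fraction`` of MinMax values, pooled matrix-wide by default.

    The cutoff is the empirical ``fraction``-quantile of the pooled
    non-degenerate values; ties at the cutoff are included.  ``per_row``
    applies the quantile within each receptor row instead.
    """
    if scores.kind != "minmax":
        raise VinascreenError("select_outliers_minmax requires minmax normalized input")
    if not 0 < fraction < 1:
        raise VinascreenError(f"fraction must lie in (0, 1), got {fraction}")
    values = scores.values
    valid = ~np.isnan(values) & ~scores.degenerate_rows[:, None]
    if per_row:
        keep = np.zeros_like(valid)
        for i in range(values.shape[0]):
            if scores.degenerate_rows[i] or not valid[i].any():
                continue
            cutoff = np.quantile(values[i][valid[i]], fraction)
            keep[i] = valid[i] & (values[i] <= cutoff)
        threshold = float("nan")
        with np.errstate(invalid="ignore"):
            flagged = _flag(scores, keep)
    else:
        pooled = values[valid]
        if pooled.size == 0:
            raise VinascreenError("no non-degenerate values to select from")
        threshold = float(np.quantile(pooled, fraction))
        with np.errstate(invalid="ignore"):
            flagged = _flag(scores, values <= threshold)
    return SelectionResult(method="minmax", threshold=threshold, flagged=flagged)


@dataclass
class GaussianFit:
    mean: float
    sd: float
    bin_edges: np.ndarray
    counts: np.ndarray
    percentile_5: float


def fit_gaussian(values: np.ndarray, bins: int = 50) -> GaussianFit:
    """Maximum-likelihood normal fit (sample mean, population sd) plus a
    histogram and the empirical 5th-percentile marker — the summary behind
    the score-distribution plots."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise VinascreenError("need at least 2 values to fit")
    sd = float(np.sqrt(np.var(values)))
    if sd == 0:
        raise VinascreenError("degenerate sample: zero variance")
    counts, edges = np.histogram(values, bins=bins)
    return GaussianFit(
        mean=float(np.mean(values)), sd=sd,
        bin_edges=edges, counts=counts,
        percentile_5=float(np.quantile(values, 0.05)),
    )
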