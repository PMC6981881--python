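"""Expression statistics: correlation screens, 2^-ΔΔCt, circadian profiles, clustering.

An expression matrix is a pandas DataFrame of non-negative values with
feature ids as the index and condition ids (e.g. Dark/BL/WL or ZT2..ZT70) as
columns. The trans-acting screen retains lncRNA-gene pairs whose Pearson
correlation magnitude reaches a threshold (methods default 0.9; the stricter
0.99 used for the headline co-expression table is available as a preset).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .duplex import DuplexError

__all__ = [
    "ExpressionError",
    "validate_expression",
    "pearson_r",
    "trans_candidates",
    "TABLE1_R_MIN",
    "CtTable",
    "ddct_fold_change",
    "CircadianProfile",
    "relative_profile",
    "PeakSummary",
    "peak_summary",
    "cluster_profiles",
]

TABLE1_R_MIN = 0.99  # the stricter screen used for the headline lincRNA table


class ExpressionError(ValueError):
    """Malformed expression matrix, Ct table, or degenerate statistic."""


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Require a rectangular, fully observed, non-negative numeric matrix."""
    if expr.isna().any().any():
        bad = expr.index[expr.isna().any(axis=1)].tolist()
        raise ExpressionError(f"missing values in expression rows {bad} (imputation is off by default)")
    values = expr.to_numpy(dtype=float)
    if (values < 0).any():
        raise ExpressionError("expression values must be non-negative")
    return expr


def pearson_r(x, y) -> float:
    """Product-moment correlation; refuses vectors shorter than 3 or with zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ExpressionError(f"vectors must be 1-D of equal length, got {x.shape} and {y.shape}")
    if x.size < 3:
        raise ExpressionError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ExpressionError("undefined correlation: an input vector has zero variance")
    return float(stats.pearsonr(x, y).statistic)


def trans_candidates(
    lnc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    r_min: float = 0.9,
    strict: bool = False,
) -> list[tuple[str, str, float]]:
    """All (lncRNA, gene) pairs with |r| >= r_min over shared conditions.

    ``strict=True`` uses |r| > r_min instead ("over 0.9" read exclusively).
    Sorted by |r| descending, ties by (lncRNA, gene) id.
    """
    shared = [c for c in lnc_expr.columns if c in set(gene_expr.columns)]
    if len(shared) < 3:
        raise ExpressionError(f"only {len(shared)} shared conditions; need at least 3")
    out = []
    for lnc in lnc_expr.index:
        for gene in gene_expr.index:
            r = pearson_r(lnc_expr.loc[lnc, shared], gene_expr.loc[gene, shared])
            keep = abs(r) > r_min if strict else abs(r) >= r_min
            if keep:
                out.append((str(lnc), str(gene), r))
    out.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    return out


@dataclass(frozen=True)
class CtTable:
    """qPCR Ct values in long format with a reference gene and calibrator sample.

    ``data`` columns: sample, gene, ct, and optionally replicate. Fold changes
    are computed per replicate and averaged, matching the usual
    biological-replicate design (six replicates in the source experiments).
    """

    data: pd.DataFrame
    reference_gene: str
    calibrator_sample: str

    def __post_init__(self) -> None:
        required = {"sample", "gene", "ct"}
        if not required <= set(self.data.columns):
            raise ExpressionError(f"Ct table must have columns {sorted(required)}")

    def _ct(self, sample: str, gene: str) -> np.ndarray:
        """Ct per replicate (a 1-vector when there is no replicate column)."""
        df = self.data
        rows = df[(df["sample"] == sample) & (df["gene"] == gene)]
        if rows.empty:
            raise ExpressionError(f"missing Ct for (sample={sample!r}, gene={gene!r})")
        if "replicate" in df.columns:
            rows = rows.sort_values("replicate")
        return rows["ct"].to_numpy(dtype=float)


def ddct_fold_change(
    ct: CtTable, target_gene: str, sample: str, with_sd: bool = False
):
    """Relative abundance 2^-ΔΔCt of ``target_gene`` in ``sample``.

    ΔCt = Ct_target - Ct_reference within each sample; ΔΔCt subtracts the
    calibrator sample's ΔCt. With replicates the per-replicate fold changes
    are averaged (mean, and sd if requested).
    """
    d_sample = ct._ct(sample, target_gene) - ct._ct(sample, ct.reference_gene)
    d_cal = ct._ct(ct.calibrator_sample, target_gene) - ct._ct(
        ct.calibrator_sample, ct.reference_gene
    )
    if d_sample.shape != d_cal.shape:
        raise ExpressionError(
            f"replicate counts differ between sample {sample!r} and calibrator "
            f"{ct.calibrator_sample!r}"
        )
    fc = 2.0 ** -(d_sample - d_cal)
    if with_sd:
        return float(fc.mean()), float(fc.std(ddof=1)) if fc.size > 1 else 0.0
    return float(fc.mean())


_ZT = re.compile(r"^ZT(\d+(?:\.\d+)?)$")


def _parse_timepoint(label) -> float:
    if isinstance(label, (int, float)):
        return float(label)
    m = _ZT.match(str(label))
    if not m:
        raise ExpressionError(f"cannot parse timepoint label {label!r} (expected e.g. 'ZT6')")
    return float(m.group(1))


@dataclass(frozen=True)
class CircadianProfile:
    """Fold changes relative to a baseline timepoint on the Zeitgeber-hour scale."""

    timepoints: tuple[float, ...]
    fold_changes: tuple[float, ...]
    photoperiod: tuple[int, int] = (12, 12)

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.fold_changes):
            raise ExpressionError("timepoints and fold_changes differ in length")


def relative_profile(
    expr_row: pd.Series,
    baseline_condition: str = "ZT2",
    photoperiod: tuple[int, int] = (12, 12),
) -> CircadianProfile:
    """Divide a timecourse row by its value at the baseline condition (e.g. ZT2)."""
    if baseline_condition not in expr_row.index:
        raise ExpressionError(f"baseline condition {baseline_condition!r} absent from row")
    base = float(expr_row[baseline_condition])
    if base == 0:
        raise ExpressionError(f"baseline {baseline_condition!r} is zero; fold change undefined")
    times = tuple(_parse_timepoint(c) for c in expr_row.index)
    folds = tuple(float(v) / base for v in expr_row)
    order = np.argsort(times)
    return CircadianProfile(
        timepoints=tuple(times[i] for i in order),
        fold_changes=tuple(folds[i] for i in order),
        photoperiod=photoperiod,
    )


@dataclass(frozen=True)
class PeakSummary:
    peak_times: tuple[float, ...]
    intervals: tuple[float, ...]
    has_24h_periodicity: bool


def peak_summary(
    profile: CircadianProfile,
    prominence: float = 0.2,
    period: float = 24.0,
    tolerance: float = 4.0,
) -> PeakSummary:
    """Local maxima of a circadian profile and a 24-hour-periodicity check.

    Periodicity is accepted iff there are at least two peaks and every
    consecutive peak spacing lies within ``tolerance`` (default one 4-hour
    sampling interval) of ``period``.
    """
    if len(profile.timepoints) < 4:
        raise ExpressionError("need at least 4 timepoints for peak detection")
    y = np.asarray(profile.fold_changes, dtype=float)
    idx, _ = signal.find_peaks(y, prominence=prominence)
    peaks = tuple(profile.timepoints[i] for i in idx)
    intervals = tuple(np.diff(peaks)) if len(peaks) > 1 else ()
    periodic = len(peaks) >= 2 and all(abs(d - period) <= tolerance for d in intervals)
    return PeakSummary(peak_times=peaks, intervals=intervals, has_24h_periodicity=periodic)


def cluster_profiles(
    expr: pd.DataFrame,
    k: int | None = None,
    cut_height: float | None = None,
    method: str = "average",
) -> pd.Series:
    """Agglomerative clustering of feature rows with distance 1 - Pearson r.

    Exactly one of ``k`` (number of clusters) or ``cut_height`` (dendrogram
    cut on the 1 - r scale) must be given. Deterministic for a given row
    order; labels are arbitrary integers starting at 1.
    """
    if (k is None) == (cut_height is None):
        raise ExpressionError("specify exactly one of k or cut_height")
    if expr.shape[0] < 2:
        raise ExpressionError("need at least 2 features to cluster")
    values = expr.to_numpy(dtype=float)
    flat = values.std(axis=1) == 0
    if flat.any():
        bad = expr.index[flat].tolist()
        raise ExpressionError(
            f"constant feature rows {bad}: correlation distance undefined"
        )
    corr = np.corrcoef(values)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    # enforce exact symmetry against float noise before condensing
    dist = (dist + dist.T) / 2.0
    link = hierarchy.linkage(squareform(dist, checks=False), method=method)
    if k is not None:
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    else:
        labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    return pd.Series(labels, index=expr.index, name="cluster")
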