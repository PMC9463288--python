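"""Median distance maps between 2D-group and 3D-group metric vectors.

For each exercise, every metric's values over all attempts of one endoscope
group form a metric-specific vector. Every ordered pair (2D metric i,
3D metric j) is compared element-wise: all |v2d| x |v3d| scalar distances are
computed, sorted ascending, and the median is stored as the representative
value of cell (i, j) — a 160 x 160 map (25,600 cells) per exercise and
algorithm.

Two scalar distances are supported: Euclidean, |a - b|, and a Mahalanobis
variant, |a - b| / sqrt(pooled variance of the two vectors involved) — the
scalar covariance "between the two vectors" degenerates to the pooled
two-sample variance of the cell's row and column vector, which is symmetric
in the two groups and reduces to the textbook scalar Mahalanobis distance.

For visualisation the full map is reduced by affiliation: sEMG metrics are
averaged over the 8 channels of their feature, motion metrics over the 7
MAPs of their body part (plus the 4 orientation singletons when those extra
columns are included). Rows and columns of both maps are ordered by
descending mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emg_features import EMG_FEATURE_NAMES, IMU_FEATURE_NAMES
from .synth import BODY_PARTS
from .table import ANNOTATION_COLS, canonical_columns, imu_columns

__all__ = [
    "MetricVector",
    "DistanceMap",
    "pair_distance_euclidean",
    "pair_distance_mahalanobis",
    "median_representative",
    "build_maps",
    "affiliation_of",
]


@dataclass(frozen=True)
class MetricVector:
    """All attempts' values of one metric for one endoscope group."""

    metric: str
    endoscope: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ValueError(f"{self.metric}/{self.endoscope}: empty metric vector")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.metric}/{self.endoscope}: non-finite values")
        object.__setattr__(self, "values", v)


@dataclass
class DistanceMap:
    """Full (metric x metric) and affiliation-reduced median distance maps.

    ``full``: rows are 2D metrics, columns 3D metrics, both ordered by
    descending mean. ``reduced``: affiliation-averaged version. ``algorithm``
    is ``"euclidean"`` or ``"mahalanobis"``.
    """

    full: pd.DataFrame
    reduced: pd.DataFrame
    algorithm: str
    exercise: int


def pair_distance_euclidean(a: float, b: float) -> float:
    """Scalar Euclidean distance |a - b|."""
    return abs(a - b)


def pair_distance_mahalanobis(a: float, b: float, pooled_var: float) -> float:
    """Scalar Mahalanobis distance |a - b| / sqrt(pooled_var)."""
    if pooled_var <= 0:
        raise ValueError("pooled variance must be positive")
    return abs(a - b) / np.sqrt(pooled_var)


def median_representative(
    v2d: MetricVector | np.ndarray,
    v3d: MetricVector | np.ndarray,
    algorithm: str = "euclidean",
) -> float:
    """Median of all element-pair distances between two metric vectors.

    All |v2d| x |v3d| pairwise distances are ranked ascending and the median
    (midpoint of the central pair for even counts) is returned. For the
    Mahalanobis variant the pooled variance of the two vectors' concatenated
    values scales the distances; a zero pooled variance (two constant,
    identical-spread vectors) yields NaN — the cell is flagged missing.
    """
    a = v2d.values if isinstance(v2d, MetricVector) else np.asarray(v2d, dtype=float)
    b = v3d.values if isinstance(v3d, MetricVector) else np.asarray(v3d, dtype=float)
    d = np.abs(a[:, None] - b[None, :])
    if algorithm == "mahalanobis":
        pooled = float(np.var(np.concatenate([a, b])))
        if pooled <= 0:
            return float("nan")
        d = d / np.sqrt(pooled)
    elif algorithm != "euclidean":
        raise ValueError(f"unknown distance algorithm {algorithm!r}")
    return float(np.median(d))


def affiliation_of(metric: str) -> str:
    """Affiliation group of a metric column.

    sEMG metrics (``feature@chN``) belong to their feature, motion metrics
    (``feature@Part``) to their body part, orientation metrics to themselves.
    """
    if "@" not in metric:
        if metric in IMU_FEATURE_NAMES:
            return metric
        raise KeyError(f"unknown metric {metric!r}")
    feat, where = metric.split("@", 1)
    if where.startswith("ch") and feat in EMG_FEATURE_NAMES:
        return feat
    if where in BODY_PARTS:
        return where
    raise KeyError(f"unknown metric {metric!r}")


def _order_desc(df: pd.DataFrame) -> pd.DataFrame:
    rows = df.mean(axis=1).sort_values(ascending=False).index
    cols = df.mean(axis=0).sort_values(ascending=False).index
    return df.loc[rows, cols]


def build_maps(
    tbl: pd.DataFrame,
    algorithm: str = "euclidean",
    include_imu: bool = False,
    normalized: bool = False,
) -> DistanceMap:
    """Median distance maps of one exercise table.

    ``tbl`` must contain both endoscope groups. Distances are computed on
    raw feature values by default; ``normalized=True`` min-max normalises
    the table first. ``include_imu`` extends the canonical 160 metrics with
    the 4 orientation metrics (164 x 164 cells).
    """
    groups = set(tbl["endoscope"].unique())
    if not {"2D", "3D"} <= groups:
        raise ValueError(f"both endoscope groups required, found {sorted(groups)}")
    if normalized:
        from .table import normalize_minmax

        tbl = normalize_minmax(tbl)
    metrics = [c for c in canonical_columns() if c in tbl.columns]
    if include_imu:
        metrics += [c for c in imu_columns() if c in tbl.columns]
    v2 = {m: tbl.loc[tbl.endoscope == "2D", m].dropna().to_numpy() for m in metrics}
    v3 = {m: tbl.loc[tbl.endoscope == "3D", m].dropna().to_numpy() for m in metrics}

    n = len(metrics)
    cells = np.empty((n, n))
    for i, mi in enumerate(metrics):
        a = v2[mi]
        for j, mj in enumerate(metrics):
            cells[i, j] = median_representative(a, v3[mj], algorithm)
    full = pd.DataFrame(cells, index=metrics, columns=metrics)

    aff_row = pd.Series({m: affiliation_of(m) for m in metrics})
    reduced = full.groupby(aff_row).mean().T.groupby(aff_row).mean().T
    exercise = int(tbl["exercise"].iloc[0]) if "exercise" in tbl else 0
    return DistanceMap(
        full=_order_desc(full),
        reduced=_order_desc(reduced),
        algorithm=algorithm,
        exercise=exercise,
    )
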