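"""Per-network scalar features and subnetwork machinery.

Amplitude is the sample standard deviation of a network's stage-1 subject
time-series; shape is the mean of the z-values above the z > 2.3 cut of the
subject's stage-2 spatial map (missing when no voxel survives).  Between-
network connectivity is the Pearson correlation of stage-1 time-series.
High-order components are assigned to a parent network when their
concatenated time-course correlates with the parent's (r > 0.4) AND their
thresholded maps share more than 250 voxels — both criteria jointly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dualreg import SubjectNetworkSet
from .groupica import ComponentLabel, ComponentSet

__all__ = [
    "amplitude",
    "shape",
    "between_network_corr",
    "SubnetworkAssignment",
    "match_subnetworks",
    "mean_within_connectivity",
    "metric_rows",
    "connectivity_rows",
]

Z_THRESH_DEFAULT = 2.3
R_THRESH_DEFAULT = 0.4
OVERLAP_THRESH_DEFAULT = 250


def amplitude(ts: np.ndarray) -> float:
    """Sample SD (denominator T-1) of a stage-1 network time-series."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 1 or ts.size < 2:
        raise ValueError("amplitude needs a 1-D series with T >= 2")
    return float(ts.std(ddof=1))


def shape(z_map: np.ndarray, z_thresh: float = Z_THRESH_DEFAULT,
          within: np.ndarray | None = None) -> float:
    """Mean of the z-values strictly above ``z_thresh``; NaN (missing) when
    no voxel qualifies.

    By default the subject map is thresholded on its own values; ``within``
    optionally restricts the average to a group-map mask (the alternative
    reading of where the suprathreshold set comes from).
    """
    z = np.asarray(z_map, dtype=float)
    if within is not None:
        z = z[np.asarray(within, dtype=bool)]
    supra = z[z > z_thresh]
    if supra.size == 0:
        return math.nan
    return float(supra.mean())


def between_network_corr(ts_a: np.ndarray, ts_b: np.ndarray) -> float:
    """Pearson correlation of two network time-series; NaN when either has
    zero variance."""
    a = np.asarray(ts_a, dtype=float)
    b = np.asarray(ts_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("series must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero-variance series; correlation undefined")
        return math.nan
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class SubnetworkAssignment:
    """High-order components assigned to a parent network."""

    parent: str
    entries: list[dict] = field(default_factory=list)

    @property
    def component_ids(self) -> list[int]:
        return [e["component"] for e in self.entries]


def match_subnetworks(
    parent_label: str,
    cs_low: ComponentSet,
    labels_low: ComponentLabel,
    cs_high: ComponentSet,
    r_thresh: float = R_THRESH_DEFAULT,
    overlap_thresh: int = OVERLAP_THRESH_DEFAULT,
    z_thresh: float = Z_THRESH_DEFAULT,
    use_abs_r: bool = False,
) -> SubnetworkAssignment:
    """Spatio-temporal assignment of high-order components to a parent.

    A high-order component belongs to the parent iff the temporal correlation
    between its concatenated group time-course and the parent's exceeds
    ``r_thresh`` (signed by default) AND the number of voxels suprathreshold
    (z > ``z_thresh``) in both spatial maps exceeds ``overlap_thresh``.
    """
    parent_idx = labels_low.component_of(parent_label)  # KeyError if absent
    parent_course = cs_low.mixing[:, parent_idx]
    parent_supra = cs_low.maps_z[parent_idx] > z_thresh
    out = SubnetworkAssignment(parent=parent_label)
    for j in range(cs_high.order):
        r = float(np.corrcoef(parent_course, cs_high.mixing[:, j])[0, 1])
        r_eff = abs(r) if use_abs_r else r
        overlap = int((parent_supra & (cs_high.maps_z[j] > z_thresh)).sum())
        if r_eff > r_thresh and overlap > overlap_thresh:
            out.entries.append({"component": int(j), "temporal_r": r,
                                "overlap_voxels": overlap})
    return out


def mean_within_connectivity(timeseries: np.ndarray) -> float:
    """Average pairwise Pearson correlation of the subnetwork time-series of
    one acquisition; ``timeseries`` is ``(T, n)``; NaN when n < 2."""
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("expected a (T, n) matrix")
    n = ts.shape[1]
    if n < 2:
        return math.nan
    r = np.corrcoef(ts.T)
    iu = np.triu_indices(n, k=1)
    return float(r[iu].mean())


def metric_rows(
    sns: SubjectNetworkSet,
    labels: dict[int, str],
    group: int,
    age_months: float,
    z_thresh: float = Z_THRESH_DEFAULT,
) -> list[dict]:
    """Long-format (subject, network) metric records for one acquisition."""
    rows = []
    for idx, name in labels.items():
        rows.append({
            "subject_id": sns.subject_id,
            "group": group,
            "age_months": age_months,
            "timepoint": sns.timepoint,
            "network": name,
            "amplitude": amplitude(sns.timeseries[:, idx]),
            "shape": shape(sns.z_maps[idx], z_thresh),
        })
    return rows


def connectivity_rows(
    sns: SubjectNetworkSet, labels: dict[int, str]
) -> list[dict]:
    """Pearson correlations between all labeled network pairs of one
    acquisition."""
    items = sorted(labels.items(), key=lambda kv: kv[1])
    rows = []
    for i, (ki, ni) in enumerate(items):
        for kj, nj in items[i + 1:]:
            rows.append({
                "subject_id": sns.subject_id,
                "timepoint": sns.timepoint,
                "network_a": ni,
                "network_b": nj,
                "pearson_r": between_network_corr(
                    sns.timeseries[:, ki], sns.timeseries[:, kj]),
            })
    return rows


def metric_table(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    if (df["amplitude"] < 0).any():  # pragma: no cover - SD is nonnegative
        raise ValueError("negative amplitude")
    return df
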