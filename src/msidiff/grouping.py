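"""Peak grouping across pixels and median-log-intensity ranking.

Peak lists from every pixel and region are pooled and clustered on the 1-D
m/z coordinate with DBSCAN: a peak is a core point when at least
``min_density`` peaks (itself included) lie within ±eps of it; clusters are
the maximal density-connected sets of cores plus their border points, the
rest is noise. Groups below a minimum peak count are discarded, a
group-by-pixel intensity matrix is built (summed member-peak intensity per
pixel), and groups are ranked by the between-region difference in median
log intensity.

The DBSCAN is implemented directly on the sorted axis (neighborhood queries
by binary search) so that the partition is exactly the density-reachability
definition and invariant to input order: core components are maximal runs of
cores with consecutive gaps <= eps, and each border point joins the cluster
of its nearest core (ties to the lower-m/z core).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("msidiff")

__all__ = [
    "PeakGroup",
    "GroupIntensityMatrix",
    "dbscan_mz",
    "filter_groups",
    "build_matrix",
    "rank_groups",
]


@dataclass
class PeakGroup:
    """A DBSCAN cluster of pooled peaks treated as one molecular feature."""

    group_id: str
    member_idx: np.ndarray  # positional indices into the pooled peak table
    centroid_mz: float
    n_peaks: int
    mz_min: float
    mz_max: float


@dataclass
class GroupIntensityMatrix:
    """Per-pixel intensity of every retained peak group.

    ``values``: DataFrame, rows indexed by group_id, columns by pixel id
    (the spectrum_id); entries are summed member-peak intensities, 0 where
    the group has no peak in a pixel. ``pixels``: per-pixel metadata
    (patient_id, region, x, y) indexed by the same pixel ids. ``groups``:
    per-group metadata (centroid_mz, n_peaks).
    """

    values: pd.DataFrame
    pixels: pd.DataFrame
    groups: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        long = (
            self.values.rename_axis("group_id")
            .reset_index()
            .melt(id_vars="group_id", var_name="spectrum_id", value_name="intensity")
        )
        return long.merge(
            self.pixels.rename_axis("spectrum_id").reset_index(), on="spectrum_id"
        )

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "GroupIntensityMatrix":
        values = long.pivot_table(
            index="group_id", columns="spectrum_id", values="intensity", fill_value=0.0
        )
        pixels = (
            long[["spectrum_id", "patient_id", "region", "x", "y"]]
            .drop_duplicates("spectrum_id")
            .set_index("spectrum_id")
            .loc[values.columns]
        )
        groups = pd.DataFrame(index=values.index)
        if "centroid_mz" in long.columns:
            groups["centroid_mz"] = (
                long.drop_duplicates("group_id").set_index("group_id")["centroid_mz"]
            )
        else:
            groups["centroid_mz"] = np.nan
        return cls(values=values, pixels=pixels, groups=groups)


def dbscan_mz(peaks, eps: float, min_density: int) -> list[PeakGroup]:
    """Cluster pooled peaks into m/z peak groups with 1-D DBSCAN.

    Parameters
    ----------
    peaks : DataFrame with an ``mz`` column (and optionally ``intensity``
        for intensity-weighted centroids), or a 1-D array of m/z values.
    eps : float
        Neighborhood radius in Da (absolute, not ppm).
    min_density : int
        Minimum peaks within ±eps (the point itself included) for a core.

    Returns
    -------
    list of PeakGroup in ascending centroid order; non-core peaks not
    density-reachable from any core are noise and appear in no group.
    """
    if eps <= 0:
        raise ValueError(f"eps must be > 0, got {eps}")
    if min_density < 1:
        raise ValueError(f"min_density must be >= 1, got {min_density}")
    if isinstance(peaks, pd.DataFrame):
        mz = peaks["mz"].to_numpy(float)
        weight = (
            peaks["intensity"].to_numpy(float)
            if "intensity" in peaks.columns
            else np.ones(len(mz))
        )
    else:
        mz = np.asarray(peaks, float)
        weight = np.ones(len(mz))
    n = len(mz)
    if n == 0:
        return []
    order = np.argsort(mz, kind="stable")
    s = mz[order]
    left = np.searchsorted(s, s - eps, "left")
    right = np.searchsorted(s, s + eps, "right")
    core = (right - left) >= min_density
    if not core.any():
        return []

    core_pos = np.flatnonzero(core)
    core_mz = s[core_pos]
    # density-connected core components: consecutive core gaps <= eps
    breaks = np.flatnonzero(np.diff(core_mz) > eps)
    comp_of_core = np.zeros(len(core_pos), dtype=int)
    comp_of_core[breaks + 1] = 1
    comp_of_core = np.cumsum(comp_of_core)
    n_comp = comp_of_core[-1] + 1

    labels = np.full(n, -1, dtype=int)  # over sorted positions
    labels[core_pos] = comp_of_core
    # border points: non-core within eps of some core -> nearest core
    noncore_pos = np.flatnonzero(~core)
    if len(noncore_pos):
        ins = np.searchsorted(core_mz, s[noncore_pos])
        left_i = np.clip(ins - 1, 0, len(core_mz) - 1)
        right_i = np.clip(ins, 0, len(core_mz) - 1)
        dl = np.abs(s[noncore_pos] - core_mz[left_i])
        dr = np.abs(core_mz[right_i] - s[noncore_pos])
        nearest = np.where(dl <= dr, left_i, right_i)  # tie -> lower m/z core
        dist = np.minimum(dl, dr)
        reach = dist <= eps
        labels[noncore_pos[reach]] = comp_of_core[nearest[reach]]

    groups: list[PeakGroup] = []
    sorted_w = weight[order]
    for comp in range(n_comp):
        pos = np.flatnonzero(labels == comp)
        members = order[pos]
        w = sorted_w[pos]
        wsum = float(w.sum())
        centroid = float(np.sum(s[pos] * w) / wsum) if wsum > 0 else float(np.mean(s[pos]))
        groups.append(
            PeakGroup(
                group_id="",
                member_idx=np.sort(members),
                centroid_mz=centroid,
                n_peaks=len(members),
                mz_min=float(s[pos[0]]),
                mz_max=float(s[pos[-1]]),
            )
        )
    groups.sort(key=lambda g: g.centroid_mz)
    for k, g in enumerate(groups):
        g.group_id = f"G{k + 1:04d}"
    return groups


def filter_groups(groups: Sequence[PeakGroup], min_group_size: int) -> list[PeakGroup]:
    """Keep groups with at least ``min_group_size`` member peaks (inclusive)."""
    if min_group_size < 1:
        raise ValueError(f"min_group_size must be >= 1, got {min_group_size}")
    kept = [g for g in groups if g.n_peaks >= min_group_size]
    logger.info(
        "filter_groups: retained %d of %d groups (min size %d)",
        len(kept), len(groups), min_group_size,
    )
    return kept


def build_matrix(groups: Sequence[PeakGroup], peaks: pd.DataFrame) -> GroupIntensityMatrix:
    """Group-by-pixel intensity matrix: summed member-peak intensity per pixel."""
    pixels = (
        peaks[["spectrum_id", "patient_id", "region", "x", "y"]]
        .drop_duplicates("spectrum_id")
        .set_index("spectrum_id")
    )
    n = len(peaks)
    gid = np.full(n, "", dtype=object)
    for g in groups:
        if len(g.member_idx) and (g.member_idx.min() < 0 or g.member_idx.max() >= n):
            raise ValueError(f"group {g.group_id}: member index out of range")
        gid[g.member_idx] = g.group_id
    sub = peaks[["spectrum_id", "intensity"]].copy()
    sub["group_id"] = gid
    sub = sub[sub["group_id"] != ""]
    values = sub.pivot_table(
        index="group_id", columns="spectrum_id", values="intensity",
        aggfunc="sum", fill_value=0.0,
    )
    values = values.reindex(columns=pixels.index, fill_value=0.0)
    values = values.reindex(index=[g.group_id for g in groups], fill_value=0.0)
    meta = pd.DataFrame(
        {
            "centroid_mz": [g.centroid_mz for g in groups],
            "n_peaks": [g.n_peaks for g in groups],
        },
        index=pd.Index([g.group_id for g in groups], name="group_id"),
    )
    return GroupIntensityMatrix(values=values, pixels=pixels, groups=meta)


def rank_groups(
    matrix: GroupIntensityMatrix, log_offset: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank peak groups by between-region difference in median log intensity.

    Per group, patient and region, the median over pixels of
    ln(intensity + log_offset) is taken; the per-patient delta is
    relapse minus diagnosis; the cross-patient summary is the median of the
    per-patient deltas. Groups are ranked by |summary| descending, ties
    broken by centroid m/z ascending. The log base only rescales deltas and
    can never reorder ranks.

    Returns
    -------
    (ranked, detail) : group-level table with summary_delta and rank, and
    the per-(group, patient) medians/deltas behind it.
    """
    counts = matrix.pixels.groupby(["patient_id", "region"]).size()
    patients = matrix.pixels["patient_id"].unique()
    for p in patients:
        for r in ("diagnosis", "relapse"):
            if (p, r) not in counts.index:
                raise ValueError(f"no pixels for patient {p!r} region {r!r}")

    logged = np.log(matrix.values.to_numpy(float) + log_offset)
    key = pd.MultiIndex.from_frame(matrix.pixels[["patient_id", "region"]])
    med = (
        pd.DataFrame(logged, index=matrix.values.index, columns=key)
        .T.groupby(level=[0, 1])
        .median()
        .T
    )
    detail_rows = []
    for p in patients:
        d = med[(p, "diagnosis")]
        r = med[(p, "relapse")]
        detail_rows.append(
            pd.DataFrame(
                {
                    "group_id": med.index,
                    "patient_id": p,
                    "median_log_diagnosis": d.to_numpy(),
                    "median_log_relapse": r.to_numpy(),
                    "delta": (r - d).to_numpy(),
                }
            )
        )
    detail = pd.concat(detail_rows, ignore_index=True)
    summary = (
        detail.groupby("group_id")["delta"].median().rename("summary_delta").reset_index()
    )
    summary = summary.merge(
        matrix.groups["centroid_mz"].rename_axis("group_id").reset_index(),
        on="group_id", how="left",
    )
    summary["abs_summary"] = summary["summary_delta"].abs()
    summary = summary.sort_values(
        ["abs_summary", "centroid_mz"], ascending=[False, True], kind="stable"
    ).drop(columns="abs_summary")
    summary["rank"] = np.arange(1, len(summary) + 1)
    return summary.reset_index(drop=True), detail
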