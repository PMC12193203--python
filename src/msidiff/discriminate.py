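"""Diagnosis-vs-relapse discrimination per peak group.

The analysis unit is the pixel within one patient's matched tissue pair:
for every peak group and patient, the relapse-region pixel intensities are
scored against the diagnosis-region ones with a ROC curve. The AUC is
computed by the midrank (Mann-Whitney) formula — tied pairs contribute one
half — so auc = U / (n_pos * n_neg) holds exactly and the AUC equals the
probability that a random relapse pixel outranks a random diagnosis pixel.
Two-sided Mann-Whitney p-values are Benjamini-Hochberg adjusted across
groups within each patient, and a group is called differential for a
patient when its q-value and oriented AUC clear the configured thresholds.
Zero-intensity pixels are kept as scores: absence of a peak is informative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

__all__ = ["ROCResult", "roc_auc", "mwu_test", "benjamini_hochberg", "call_differentials"]


@dataclass
class ROCResult:
    """ROC summary for one score comparison (positives vs negatives)."""

    auc: float
    u_statistic: float
    fpr: np.ndarray = field(default_factory=lambda: np.array([]))
    tpr: np.ndarray = field(default_factory=lambda: np.array([]))
    direction: str = "none"
    p_value: float | None = None
    q_value: float | None = None
    group_id: str | None = None
    patient_id: str | None = None


def _auc_u(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """Midrank AUC and U statistic; ties contribute one half."""
    n1, n2 = len(pos), len(neg)
    ranks = rankdata(np.concatenate([pos, neg]))
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    return u / (n1 * n2), u


def roc_auc(scores_pos, scores_neg) -> ROCResult:
    """ROC curve and midrank AUC of positives vs negatives.

    The curve starts at (0,0), ends at (1,1) and is non-decreasing in both
    coordinates; the AUC equals the fraction of (pos, neg) pairs with
    pos > neg plus half the tied pairs, i.e. U / (n1*n2) exactly.
    """
    pos = np.asarray(scores_pos, float)
    neg = np.asarray(scores_neg, float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score groups must be non-empty")
    auc, u = _auc_u(pos, neg)
    from sklearn.metrics import roc_curve

    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    fpr, tpr, _ = roc_curve(labels, np.concatenate([pos, neg]))
    direction = "up_in_relapse" if auc > 0.5 else ("up_in_diagnosis" if auc < 0.5 else "none")
    return ROCResult(auc=auc, u_statistic=u, fpr=fpr, tpr=tpr, direction=direction)


def mwu_test(scores_pos, scores_neg, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test of the two score groups.

    Exact-enumeration p for pooled n <= 12 without ties, otherwise the
    normal approximation with tie and continuity corrections. The U
    statistic is the same count (with half-ties) that the ROC AUC is built
    from. When every value in both groups is identical the test is
    degenerate: U = n1*n2/2 and p = 1 are returned with a warning.
    """
    pos = np.asarray(scores_pos, float)
    neg = np.asarray(scores_neg, float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score groups must be non-empty")
    pooled = np.concatenate([pos, neg])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical in both groups; p = 1", stacklevel=2)
        return len(pos) * len(neg) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = mannwhitneyu(pos, neg, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values (monotone, q >= p)."""
    p = np.asarray(p_values, float)
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_differentials(
    matrix,
    auc_min: float = 0.6,
    q_max: float = 0.05,
    hotspot_quantile: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-(group, patient) ROC/AUC discrimination and differential calls.

    For every patient with both regions present, each group's relapse-pixel
    intensities are compared to its diagnosis-pixel intensities (AUC, U,
    two-sided MWU p); BH adjustment runs across groups within the patient.
    A call passes when q <= q_max and the AUC, oriented along its
    direction, is >= auc_min. Patients missing a region are skipped with a
    warning. Optionally intensities are capped at a per-group quantile
    first (hotspot removal).

    Returns
    -------
    (roc, calls, summary) : per-(group, patient) statistics, boolean calls,
    and per-patient counts of up/down calls.
    """
    values = matrix.values
    if hotspot_quantile is not None:
        cap = values.quantile(hotspot_quantile, axis=1)
        values = values.clip(upper=cap, axis=0)
    pixels = matrix.pixels
    rows = []
    for patient in pd.unique(pixels["patient_id"]):
        mask_r = (pixels["patient_id"] == patient) & (pixels["region"] == "relapse")
        mask_d = (pixels["patient_id"] == patient) & (pixels["region"] == "diagnosis")
        if not mask_r.any() or not mask_d.any():
            warnings.warn(f"patient {patient!r} missing a region; skipped", stacklevel=2)
            continue
        rel = values.loc[:, mask_r.to_numpy()].to_numpy(float)
        dia = values.loc[:, mask_d.to_numpy()].to_numpy(float)
        for gi, gid in enumerate(values.index):
            auc, u = _auc_u(rel[gi], dia[gi])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, p = mwu_test(rel[gi], dia[gi])
            rows.append((gid, patient, auc, u, p))
    roc = pd.DataFrame(rows, columns=["group_id", "patient_id", "auc", "u_statistic", "p_value"])
    if roc.empty:
        empty = roc.assign(q_value=[], direction=[], passes=[])
        return empty, empty, pd.DataFrame(columns=["patient_id", "up_in_relapse", "up_in_diagnosis"])
    roc["q_value"] = np.nan
    for patient, idx in roc.groupby("patient_id").groups.items():
        roc.loc[idx, "q_value"] = benjamini_hochberg(roc.loc[idx, "p_value"])
    roc["direction"] = np.select(
        [roc["auc"] > 0.5, roc["auc"] < 0.5], ["up_in_relapse", "up_in_diagnosis"], "none"
    )
    oriented = np.maximum(roc["auc"], 1.0 - roc["auc"])
    roc["passes"] = (roc["q_value"] <= q_max) & (oriented >= auc_min) & (roc["direction"] != "none")
    calls = roc[["group_id", "patient_id", "direction", "passes", "auc", "q_value"]].copy()
    passing = calls[calls["passes"]]
    summary = (
        passing.pivot_table(
            index="patient_id", columns="direction", values="group_id",
            aggfunc="count", fill_value=0,
        )
        .reindex(columns=["up_in_relapse", "up_in_diagnosis"], fill_value=0)
        .rename_axis(None, axis=1)
        .reset_index()
    )
    return roc, calls, summary
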