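"""Downstream validation statistics on tabular cohort data.

Covers the wet-lab and database follow-up of an imaging discovery run,
operating purely on measurement tables:

* IHC quantitation — H-score (0-300) from intensity-bin cell fractions,
  percent positive pixels for stromal markers, and the paired t test over
  matched diagnosis/relapse areas.
* Survival — Kaplan-Meier estimation, the log-rank test with an O/E hazard
  ratio (the observed/expected form, reported as a dependency-free
  approximation to a Cox HR), and marker dichotomization at the best
  cut-off: every admissible marker value is scanned, the cut-off minimizing
  the log-rank p is selected, and — because that scan is an optimization —
  a permutation-adjusted p is reported alongside the naive one to expose
  the selection optimism.
* Responder analysis — ROC/AUC of a marker against responder labels, and
  marker-vs-drug-response correlation (Pearson or Spearman, exact
  small-sample Spearman p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
from scipy import stats

from .discriminate import ROCResult, mwu_test, roc_auc

__all__ = [
    "LogrankResult",
    "SurvivalResult",
    "h_score",
    "percent_positive_pixels",
    "paired_t",
    "compare_ihc",
    "km_estimate",
    "logrank",
    "best_cutoff",
    "responder_roc",
    "drug_response_correlation",
]

_BIN_COLS = ["bin0", "bin1", "bin2", "bin3"]


# ---------------------------------------------------------------------------
# IHC
# ---------------------------------------------------------------------------


def h_score(areas: pd.DataFrame, per_area: bool = False):
    """H-score (0-300) from intensity-bin cell fractions.

    Per area, H = 100 * (1*f1 + 2*f2 + 3*f3); the tissue-level value is the
    mean over areas. Fractions must sum to 1 per area (tolerance 1e-6).
    """
    missing = [c for c in _BIN_COLS if c not in areas.columns]
    if missing:
        raise ValueError(f"missing bin fraction columns: {missing}")
    frac = areas[_BIN_COLS].to_numpy(float)
    sums = frac.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0) > 1e-6))
        raise ValueError(f"bin fractions sum to {sums[bad]:.6f} (not 1) at row {bad}")
    scores = 100.0 * (frac[:, 1] + 2 * frac[:, 2] + 3 * frac[:, 3])
    if per_area:
        return pd.Series(scores, index=areas.index, name="h_score")
    return float(scores.mean())


def percent_positive_pixels(pixels: pd.DataFrame, compartment: str | None = None) -> float:
    """Percentage of positive pixels, optionally within one compartment."""
    sub = pixels
    if compartment is not None:
        sub = sub[sub["compartment"] == compartment]
    if len(sub) == 0 or sub["total"].sum() == 0:
        raise ValueError(f"no pixels after compartment filter {compartment!r}")
    return 100.0 * float(sub["positive"].sum()) / float(sub["total"].sum())


def paired_t(diagnosis, relapse) -> tuple[float, int, float]:
    """Two-sided paired t test on relapse minus diagnosis differences.

    Returns (t, df, p) with t = mean(d) / (sd(d)/sqrt(n)) and df = n - 1.
    Zero-variance differences are an error (the statistic is undefined).
    """
    d = np.asarray(relapse, float) - np.asarray(diagnosis, float)
    if len(d) < 2:
        raise ValueError("need at least 2 pairs")
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero variance of paired differences; t undefined")
    res = stats.ttest_rel(np.asarray(relapse, float), np.asarray(diagnosis, float))
    return float(res.statistic), len(d) - 1, float(res.pvalue)


def compare_ihc(
    measurements: pd.DataFrame,
    value: str = "h_score",
    compartment: str = "epithelial",
    mode: str = "per_area",
) -> dict:
    """Paired diagnosis-vs-relapse comparison of IHC quantitation.

    ``value`` is "h_score" (intensity-bin rows) or "percent_positive"
    (positive/total rows); ``mode`` pairs individual areas within each
    patient ("per_area", areas beyond the common count are dropped) or
    averages areas per tissue first ("per_tissue").
    """
    if mode not in {"per_area", "per_tissue"}:
        raise ValueError(f"unknown mode {mode!r}")
    sub = measurements[measurements["compartment"] == compartment].copy()
    if sub.empty:
        raise ValueError(f"no rows for compartment {compartment!r}")
    if value == "h_score":
        sub["value"] = h_score(sub, per_area=True)
    elif value == "percent_positive":
        sub["value"] = 100.0 * sub["positive"] / sub["total"]
    else:
        raise ValueError(f"unknown value {value!r}")
    diag, rel = [], []
    for patient, grp in sub.groupby("patient_id"):
        d = grp[grp["timepoint"] == "diagnosis"].sort_values("area_id")["value"].to_numpy()
        r = grp[grp["timepoint"] == "relapse"].sort_values("area_id")["value"].to_numpy()
        if len(d) == 0 or len(r) == 0:
            raise ValueError(f"patient {patient!r} missing a timepoint")
        if mode == "per_tissue":
            diag.append(d.mean())
            rel.append(r.mean())
        else:
            k = min(len(d), len(r))
            diag.extend(d[:k])
            rel.extend(r[:k])
    t, df, p = paired_t(diag, rel)
    return {
        "t": t, "df": df, "p_value": p,
        "mean_diagnosis": float(np.mean(diag)), "mean_relapse": float(np.mean(rel)),
        "mean_difference": float(np.mean(np.asarray(rel) - np.asarray(diag))),
        "n_pairs": len(diag), "mode": mode, "value": value,
    }


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass
class LogrankResult:
    chi_square: float
    p_value: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    observed_a: float
    expected_a: float
    observed_b: float
    expected_b: float


@dataclass
class SurvivalResult:
    """Best-cutoff dichotomized survival comparison."""

    cutoff: float
    n_high: int
    n_low: int
    chi_square: float
    p_value: float            # naive log-rank p at the selected cutoff
    p_adjusted: float | None  # permutation-adjusted for the cutoff scan
    hazard_ratio: float       # O/E form, high vs low
    ci_low: float
    ci_high: float
    km_high: pd.DataFrame = field(default_factory=pd.DataFrame)
    km_low: pd.DataFrame = field(default_factory=pd.DataFrame)


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve with at-risk counts.

    ``records`` needs ``time`` (> 0) and ``event`` (1/0) columns. Without
    censoring the curve equals the empirical survivor function.
    """
    if len(records) == 0:
        raise ValueError("no survival records")
    t = records["time"].to_numpy(float)
    if np.any(t <= 0):
        raise ValueError("non-positive survival time")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(t, records["event"].to_numpy(int))
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(float),
            "at_risk": table["at_risk"].to_numpy(int),
            "events": table["observed"].to_numpy(int),
            "censored": table["censored"].to_numpy(int),
            "survival": surv.reindex(table.index).to_numpy(float),
        }
    )
    # lifelines inserts a baseline row at t=0; drop it (input times are > 0)
    empty_origin = (out["time"] == 0) & (out["events"] + out["censored"] == 0)
    return out[~empty_origin].reset_index(drop=True)


def _logrank_grid(
    time: np.ndarray, event: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Log-rank O-E statistics for many group assignments at once.

    ``groups`` is a boolean (n, k) matrix; column j defines membership of
    scenario j's "A" arm. Returns (chi2[k], O_A[k], E_A[k], total events).
    Hypergeometric variance with tie correction throughout.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    G = np.asarray(groups, bool)
    if G.ndim == 1:
        G = G[:, None]
    order = np.argsort(time, kind="stable")
    t, e, Gs = time[order], event[order], G[order]
    n = len(t)
    ut, first = np.unique(t, return_index=True)
    # at-risk counts at each distinct time
    n_at = n - first
    suffix = np.vstack([np.cumsum(Gs[::-1], axis=0)[::-1], np.zeros((1, G.shape[1]))])
    n1_at = suffix[first]
    # events per distinct time (total and in each scenario's A arm)
    d = np.add.reduceat(e.astype(float), first)
    d1 = np.add.reduceat((e[:, None] & Gs).astype(float), first, axis=0)
    keep = d > 0
    d, d1, n_at, n1_at = d[keep], d1[keep], n_at[keep], n1_at[keep]
    frac = n1_at / n_at[:, None]
    O = d1.sum(axis=0)
    E = (d[:, None] * frac).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_terms = d[:, None] * frac * (1 - frac) * (
            (n_at[:, None] - d[:, None]) / np.maximum(n_at[:, None] - 1, 1)
        )
    V = v_terms.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V > 0, (O - E) ** 2 / V, 0.0)
    return chi2, O, E, float(d.sum())


def logrank(group_a: pd.DataFrame, group_b: pd.DataFrame) -> LogrankResult:
    """Log-rank test with O/E hazard ratio between two survival groups.

    HR = (O_A/E_A) / (O_B/E_B); its 95% CI is
    exp(log HR ± 1.96 * sqrt(1/E_A + 1/E_B)). Errors when no events exist
    at all.
    """
    na, nb = len(group_a), len(group_b)
    if na == 0 or nb == 0:
        raise ValueError("both groups must be non-empty")
    time = np.concatenate([group_a["time"].to_numpy(float), group_b["time"].to_numpy(float)])
    event = np.concatenate(
        [group_a["event"].to_numpy(int), group_b["event"].to_numpy(int)]
    ).astype(bool)
    if not event.any():
        raise ValueError("no events in either group")
    member = np.concatenate([np.ones(na, bool), np.zeros(nb, bool)])
    chi2, O_a, E_a, total = _logrank_grid(time, event, member[:, None])
    chi_square = float(chi2[0])
    o_a, e_a = float(O_a[0]), float(E_a[0])
    o_b, e_b = total - o_a, total - e_a
    p = float(stats.chi2.sf(chi_square, df=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        hr = (o_a / e_a) / (o_b / e_b) if (e_a > 0 and e_b > 0 and o_b > 0) else math.inf
        if o_a == 0:
            hr = 0.0
    if e_a > 0 and e_b > 0 and 0 < hr < math.inf:
        half = 1.96 * math.sqrt(1 / e_a + 1 / e_b)
        ci = (hr * math.exp(-half), hr * math.exp(half))
    else:
        ci = (0.0, math.inf)
    return LogrankResult(chi_square, p, float(hr), ci[0], ci[1], o_a, e_a, o_b, e_b)


def _candidate_cutoffs(
    marker: np.ndarray, quantile_bounds: tuple[float, float], min_group_size: int
) -> np.ndarray:
    lo, hi = np.quantile(marker, quantile_bounds)
    values = np.unique(marker)
    values = values[(values >= lo) & (values <= hi)]
    n = len(marker)
    keep = []
    for v in values:
        n_high = int((marker >= v).sum())
        if min(n_high, n - n_high) >= min_group_size:
            keep.append(v)
    return np.asarray(keep)


def best_cutoff(
    records: pd.DataFrame,
    quantile_bounds: tuple[float, float] = (0.1, 0.9),
    min_group_frac: float = 0.1,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> SurvivalResult:
    """Dichotomize a continuous marker at the log-rank-optimal cut-off.

    Subjects with marker >= cutoff form the "high" arm. All distinct marker
    values inside the quantile bounds with both arms of at least
    ``min_group_frac`` of n are scanned; the cut-off minimizing the
    log-rank p is selected (ties to the smallest value). For markers with
    multiple probes (a ``probe_id`` column), the per-subject mean across
    probes is the marker. Because minimizing p over a scan is an
    optimization, a permutation-adjusted p (marker labels permuted,
    re-scanned) is reported next to the naive one.
    """
    df = records
    if "probe_id" in df.columns and df["probe_id"].notna().any():
        df = (
            df.groupby("subject_id")
            .agg(time=("time", "first"), event=("event", "first"), marker=("marker", "mean"))
            .reset_index()
        )
    time = df["time"].to_numpy(float)
    event = df["event"].to_numpy(int).astype(bool)
    marker = df["marker"].to_numpy(float)
    n = len(df)
    mgs = max(1, math.ceil(min_group_frac * n))
    if n < 2 * mgs:
        raise ValueError(f"too few subjects ({n}) for two arms of >= {mgs}")
    candidates = _candidate_cutoffs(marker, quantile_bounds, mgs)
    if len(candidates) == 0:
        raise ValueError("no admissible cut-off between the quantile bounds")
    G = marker[:, None] >= candidates[None, :]
    chi2, _, _, _ = _logrank_grid(time, event, G)
    p_grid = stats.chi2.sf(chi2, df=1)
    best = int(np.argmin(p_grid))  # argmin takes the first (smallest cutoff) on ties
    cutoff = float(candidates[best])
    naive_p = float(p_grid[best])

    p_adj = None
    if n_permutations and n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            chi2_p, _, _, _ = _logrank_grid(time, event, G[perm])
            if stats.chi2.sf(chi2_p, df=1).min() <= naive_p:
                count += 1
        p_adj = (1 + count) / (1 + n_permutations)

    high = df[marker >= cutoff]
    low = df[marker < cutoff]
    lr = logrank(high, low)
    return SurvivalResult(
        cutoff=cutoff,
        n_high=len(high),
        n_low=len(low),
        chi_square=lr.chi_square,
        p_value=naive_p,
        p_adjusted=p_adj,
        hazard_ratio=lr.hazard_ratio,
        ci_low=lr.ci_low,
        ci_high=lr.ci_high,
        km_high=km_estimate(high),
        km_low=km_estimate(low),
    )


# ---------------------------------------------------------------------------
# responder / drug-response analyses
# ---------------------------------------------------------------------------


def responder_roc(marker_values, responder_labels) -> tuple[ROCResult, float]:
    """ROC of a marker against responder status, plus the MWU p-value.

    Non-responders are the positive class: AUC > 0.5 means the marker is
    higher in non-responders. Errors when only one class is present.
    """
    marker = np.asarray(marker_values, float)
    resp = np.asarray(responder_labels, bool)
    if resp.all() or (~resp).all():
        raise ValueError("need both responders and non-responders")
    pos, neg = marker[~resp], marker[resp]
    result = roc_auc(pos, neg)
    result.direction = (
        "higher_in_non_responders" if result.auc > 0.5
        else ("higher_in_responders" if result.auc < 0.5 else "none")
    )
    _, p = mwu_test(pos, neg)
    result.p_value = p
    return result, p


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Two-sided exact Spearman p by full enumeration (no ties, small n)."""
    n = len(rx)
    denom = n * (n * n - 1)
    count = total = 0
    for perm in _iter_permutations(range(n)):
        d = rx - ry[list(perm)]
        r = 1 - 6 * float(np.sum(d * d)) / denom
        total += 1
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return count / total


def drug_response_correlation(
    marker_values, drug_auc_values, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation between marker level and drug-sensitivity AUC.

    Pearson p uses the exact t reference distribution; Spearman p is exact
    (full enumeration) for n <= 9 without ties, otherwise the large-sample
    approximation. Errors on zero variance or fewer than 3 pairs.
    """
    x = np.asarray(marker_values, float)
    y = np.asarray(drug_auc_values, float)
    if len(x) != len(y):
        raise ValueError("marker and drug AUC vectors differ in length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    if method != "spearman":
        raise ValueError(f"unknown method {method!r}")
    rho = float(stats.spearmanr(x, y).statistic)
    no_ties = len(np.unique(x)) == len(x) and len(np.unique(y)) == len(y)
    if len(x) <= 9 and no_ties:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        return rho, _exact_spearman_p(rx, ry, rho)
    return rho, float(stats.spearmanr(x, y).pvalue)
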