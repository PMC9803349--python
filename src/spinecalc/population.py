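"""Longitudinal and group-level analyses.

Baseline-normalised percent changes, inactive/persistent tracking, dendritic
clustering with a position-shuffle null, frequency-amplitude coupling across
spines, orientation selectivity, and global dendritic response analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "align_longitudinal",
    "normalized_pct_change",
    "add_normalized_changes",
    "inactive_fraction",
    "clustering_curve",
    "freq_amp_coupling",
    "osi",
    "global_dendrite_analysis",
    "ClusterCurve",
]


# ---------------------------------------------------------------------------
# longitudinal table
# ---------------------------------------------------------------------------


def align_longitudinal(metrics: pd.DataFrame,
                       baseline_labels: pd.Series | None = None
                       ) -> pd.DataFrame:
    """Build the longitudinal table from per-session metrics.

    ``metrics`` has one row per (spine_id, timepoint_hr) with columns
    mean_amplitude / frequency / integral / active.  Labels are assigned from
    baseline sessions only and held fixed.  Spines active at no timepoint are
    dropped ("included" spines were active at >= 1 timepoint); ``persistent``
    flags spines active at every timepoint.
    """
    df = metrics.copy()
    required = {"spine_id", "timepoint_hr", "active"}
    if not required <= set(df.columns):
        raise ValueError(f"metrics table must contain columns {sorted(required)}")
    tps = sorted(df.timepoint_hr.unique())
    counts = df.groupby("spine_id").timepoint_hr.nunique()
    if (counts != len(tps)).any():
        raise ValueError("every spine needs a row at every timepoint")
    act = df.groupby("spine_id").active.agg("sum")
    included = act[act >= 1].index
    persistent = df.groupby("spine_id").active.all()
    df = df[df.spine_id.isin(included)].copy()
    df["persistent"] = df.spine_id.map(persistent)
    if baseline_labels is not None:
        df["label"] = df.spine_id.map(baseline_labels)
    return df.sort_values(["spine_id", "timepoint_hr"]).reset_index(drop=True)


def normalized_pct_change(values: pd.Series | np.ndarray,
                          timepoints: np.ndarray,
                          baseline_timepoints: tuple | list) -> pd.Series:
    """Percent change of a metric series relative to its baseline mean.

    100 * (value_t - mean(baseline)) / mean(baseline); the baseline mean maps
    to 0% by construction.  Returns NaN for every timepoint when the baseline
    mean is missing or non-positive (flagged spine, omitted from group means).
    """
    values = pd.Series(np.asarray(values, dtype=float),
                       index=np.asarray(timepoints, dtype=float))
    base = values.loc[values.index.isin(baseline_timepoints)]
    b = base.mean()
    if not np.isfinite(b) or b <= 0 or base.isna().any():
        return pd.Series(np.nan, index=values.index)
    return 100.0 * (values - b) / b


def add_normalized_changes(table: pd.DataFrame, metric: str,
                           baseline_timepoints: tuple | list) -> pd.DataFrame:
    """Per-spine :func:`normalized_pct_change` of ``metric``, added as a column."""
    out = table.copy()
    col = f"{metric}_pct_change"

    def f(g):
        return normalized_pct_change(g[metric].to_numpy(),
                                     g.timepoint_hr.to_numpy(),
                                     baseline_timepoints).to_numpy()

    out[col] = np.concatenate([f(g) for _, g in out.groupby("spine_id", sort=False)])
    return out


def inactive_fraction(table: pd.DataFrame, timepoint_hr: float,
                      label: str | None = None) -> float:
    """Percentage of included spines that are inactive at ``timepoint_hr``,
    optionally restricted to a baseline class label."""
    sub = table[table.timepoint_hr == timepoint_hr]
    if label is not None:
        sub = sub[sub.label == label]
    if len(sub) == 0:
        return np.nan
    return 100.0 * float((~sub.active.astype(bool)).sum()) / len(sub)


# ---------------------------------------------------------------------------
# dendritic clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterCurve:
    distances: np.ndarray
    observed: np.ndarray
    shuffle_mean: np.ndarray
    shuffle_lo: np.ndarray  # 2.5th percentile
    shuffle_hi: np.ndarray  # 97.5th percentile

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "distance": self.distances,
            "observed": self.observed,
            "shuffle_mean": self.shuffle_mean,
            "shuffle_lo": self.shuffle_lo,
            "shuffle_hi": self.shuffle_hi,
        })


def _match_curve(branches: list[np.ndarray], max_n: int) -> np.ndarray:
    """Mean functional-match indicator over ordered within-branch pairs at
    each positional distance 1..max_n (NaN where no branch is long enough)."""
    out = np.full(max_n, np.nan)
    for n in range(1, max_n + 1):
        num = 0
        den = 0
        for lab in branches:
            if lab.size > n:
                eq = lab[:-n] == lab[n:]
                num += 2 * int(eq.sum())  # ordered pairs: both directions
                den += 2 * eq.size
        if den:
            out[n - 1] = num / den
    return out


def clustering_curve(branch_ids: np.ndarray, labels: np.ndarray,
                     positions: np.ndarray, n_shuffles: int = 1000,
                     seed: int = 0, max_distance: int | None = None
                     ) -> ClusterCurve:
    """Probability that spines n positions apart on a branch share a label,
    with a within-branch position-shuffle null.

    Distances are reported up to the 90th percentile of branch lengths
    (longer distances are supported by too few branches to be stable) unless
    ``max_distance`` overrides.  The shuffle permutes positions within each
    branch independently per replicate, preserving each branch's label
    multiset.
    """
    df = pd.DataFrame({"b": branch_ids, "l": labels, "p": positions})
    branches = [g.sort_values("p").l.to_numpy()
                for _, g in df.groupby("b") if len(g) >= 2]
    if not branches:
        raise ValueError("no branch with >= 2 spines")
    sizes = np.array([b.size for b in branches])
    if max_distance is None:
        max_distance = int(np.percentile(sizes, 90)) - 1
    max_distance = max(1, max_distance)
    observed = _match_curve(branches, max_distance)
    rng = np.random.default_rng(seed)
    sh = np.empty((n_shuffles, max_distance))
    for s in range(n_shuffles):
        shuffled = [b[rng.permutation(b.size)] for b in branches]
        sh[s] = _match_curve(shuffled, max_distance)
    return ClusterCurve(
        distances=np.arange(1, max_distance + 1),
        observed=observed,
        shuffle_mean=np.nanmean(sh, axis=0),
        shuffle_lo=np.nanpercentile(sh, 2.5, axis=0),
        shuffle_hi=np.nanpercentile(sh, 97.5, axis=0),
    )


# ---------------------------------------------------------------------------
# frequency-amplitude coupling, OSI, global dendritic responses
# ---------------------------------------------------------------------------


def freq_amp_coupling(table: pd.DataFrame, freq_timepoint: float,
                      amp_timepoint: float,
                      baseline_timepoints: tuple | list) -> dict:
    """Across persistent spines, correlation of the normalised frequency
    change at ``freq_timepoint`` with the normalised amplitude change at
    ``amp_timepoint`` (Pearson when both pass normality, else Spearman)."""
    t = table[table.persistent]
    t = add_normalized_changes(t, "frequency", baseline_timepoints)
    t = add_normalized_changes(t, "mean_amplitude", baseline_timepoints)
    f = t[t.timepoint_hr == freq_timepoint].set_index("spine_id")[
        "frequency_pct_change"]
    a = t[t.timepoint_hr == amp_timepoint].set_index("spine_id")[
        "mean_amplitude_pct_change"]
    j = pd.concat([f, a], axis=1).dropna()
    if len(j) < 3:
        raise ValueError("need >= 3 persistent spines with both changes")
    x, y = j.iloc[:, 0].to_numpy(), j.iloc[:, 1].to_numpy()
    normal = (len(j) >= 8
              and stats.shapiro(x).pvalue > 0.05
              and stats.shapiro(y).pvalue > 0.05)
    if normal:
        r, p = stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = stats.spearmanr(x, y)
        method = "spearman"
    return {"r": float(r), "p": float(p), "method": method, "n": len(j)}


def osi(direction_responses: np.ndarray,
        directions_deg: np.ndarray | None = None) -> float:
    """Orientation selectivity index from eight direction-wise mean evoked
    amplitudes.

    Opposite directions are averaged into four orientation responses;
    OSI = (R_pref - R_orth) / (R_pref + R_orth) with R_pref the maximal
    orientation response and R_orth the response 90° away.  Invariant to
    uniform scaling; NaN (flagged undefined) when all responses are zero.
    """
    r = np.asarray(direction_responses, dtype=float)
    if r.size != 8:
        raise ValueError("expect eight direction responses (45° steps)")
    if np.any(r < 0):
        raise ValueError("direction responses must be nonnegative")
    if directions_deg is not None:
        order = np.argsort(np.mod(directions_deg, 360))
        r = r[order]
    if np.all(r == 0):
        return np.nan
    orient = (r[:4] + r[4:]) / 2.0
    i_pref = int(np.argmax(orient))
    r_pref = orient[i_pref]
    r_orth = orient[(i_pref + 2) % 4]
    return float((r_pref - r_orth) / (r_pref + r_orth))


def global_dendrite_analysis(branch_changes: pd.Series,
                             spine_table: pd.DataFrame,
                             metric_col: str = "mean_amplitude_pct_change",
                             label_col: str = "label") -> pd.DataFrame:
    """Correlate per-branch global dendritic response changes with the mean
    spine change on the same branch, separately per functional class.

    ``branch_changes`` is indexed by branch_id; ``spine_table`` has one row
    per spine with branch_id, a class label and a normalised change column.
    Returns one row per class with (r, p, n_branches).
    """
    rows = []
    for label, g in spine_table.groupby(label_col):
        per_branch = g.groupby("branch_id")[metric_col].mean().dropna()
        j = pd.concat([branch_changes.rename("dend"), per_branch.rename("sp")],
                      axis=1).dropna()
        if len(j) >= 3:
            r, p = stats.pearsonr(j.dend, j.sp)
        else:
            r, p = np.nan, np.nan
        rows.append({"label": label,
                     "r": float(r) if np.isfinite(r) else np.nan,
                     "p": float(p) if np.isfinite(p) else np.nan,
                     "n_branches": len(j)})
    return pd.DataFrame(rows)
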