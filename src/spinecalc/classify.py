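"""Functional classification of spines from baseline sessions.

A spine is

* **sensory responsive** (visually / auditory responsive) when its trace has
  a significant positive correlation with the binarised stimulation track
  AND its fraction of stimulus presentations with a time-locked event onset
  (within 500 ms of stimulus onset) exceeds its chance level — or when it is
  sparse-noise responsive;
* **network-correlated** when its trace correlates positively and
  significantly with the leave-one-out network signal but it has no sensory
  responses;
* **unclassified** when neither holds;
* **excluded** when it would be non-sensory yet its time-locked percentage
  exceeds the chance threshold without a significant stimulus correlation.

Chance levels are estimated per spine with a dummy stimulation track laid
over the dark epochs; "above chance" is a one-sided binomial exceedance test
(alpha = 0.05) of the real time-locked count against the dummy rate, so the
stored ``fp_threshold_pct`` is the critical percentage the real time-locked
percentage must exceed.

Significance of Pearson correlations defaults to a circular-shift
permutation null (every circular lag of the trace, computed in one FFT
pass), which is calibrated for autocorrelated calcium traces; the parametric
t-distribution p-value is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "stim_correlation",
    "correlate_batch",
    "network_signal",
    "network_correlation",
    "network_correlation_batch",
    "timelocked_pct",
    "false_positive_threshold",
    "above_chance_threshold_pct",
    "sparse_noise_responsive",
    "classify_spine",
    "behavioral_regressor_correlation",
    "SpineClass",
]

ALPHA = 0.05
TIMELOCK_WINDOW_S = 0.5
MAHALANOBIS_CUT = 4.0
MIN_SPARSE_TRIALS = 50

LABELS = ("visually_responsive", "auditory_responsive", "network_correlated",
          "unclassified", "excluded")


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if np.std(y) == 0:
        raise ValueError("no stimulus in epoch: track is constant")
    if np.std(x) == 0:
        raise ValueError("degenerate trace: zero variance")
    return x, y


def _circular_r(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of x against y at every circular shift of x (FFT pass)."""
    n = x.size
    fx = np.fft.rfft(x - x.mean())
    fy = np.fft.rfft(y - y.mean())
    cov = np.fft.irfft(fx * np.conj(fy), n) / n
    return cov / (x.std() * y.std())


def stim_correlation(trace: np.ndarray, track: np.ndarray,
                     method: str = "circular") -> tuple[float, float]:
    """Pearson r of trace vs binary stimulation track, with p-value.

    ``method='circular'``: empirical two-sided p from the circular-shift null;
    ``method='parametric'``: conventional t-distribution p.
    """
    trace, track = _check_pair(trace, track)
    if method == "parametric":
        r, p = stats.pearsonr(trace, track)
        return float(r), float(p)
    if method != "circular":
        raise ValueError(f"unknown correlation method {method!r}")
    r_all = _circular_r(trace, track)
    r0 = r_all[0]
    p = (1.0 + np.count_nonzero(np.abs(r_all[1:]) >= abs(r0))) / r_all.size
    return float(r0), float(p)


def correlate_batch(traces: np.ndarray, track: np.ndarray,
                    method: str = "circular",
                    chunk: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise r and p of (m, n) traces against one track."""
    traces = np.asarray(traces, dtype=np.float64)
    track = np.asarray(track, dtype=np.float64)
    m, n = traces.shape
    if np.std(track) == 0:
        raise ValueError("no stimulus in epoch: track is constant")
    if method == "parametric":
        out = [stats.pearsonr(traces[i], track) for i in range(m)]
        return (np.array([o[0] for o in out]), np.array([o[1] for o in out]))
    fy = np.conj(np.fft.rfft(track - track.mean()))
    sy = track.std()
    r = np.empty(m)
    p = np.empty(m)
    for a in range(0, m, chunk):
        b = min(a + chunk, m)
        x = traces[a:b]
        xc = x - x.mean(axis=1, keepdims=True)
        cov = np.fft.irfft(np.fft.rfft(xc, axis=1) * fy[None, :], n, axis=1) / n
        r_all = cov / (x.std(axis=1)[:, None] * sy)
        r[a:b] = r_all[:, 0]
        p[a:b] = (1.0 + (np.abs(r_all[:, 1:])
                         >= np.abs(r_all[:, :1])).sum(axis=1)) / n
    return r, p


def network_signal(traces: np.ndarray, index: int) -> np.ndarray:
    """Leave-one-out network average: mean of all other spines' traces."""
    traces = np.asarray(traces, dtype=np.float64)
    m = traces.shape[0]
    if m < 3:
        raise ValueError("need at least 3 spines to form a network reference")
    return (traces.sum(axis=0) - traces[index]) / (m - 1)


def network_correlation(trace: np.ndarray, reference: np.ndarray,
                        method: str = "circular") -> tuple[float, float]:
    """Correlation of a spine trace with the network reference (as stim_correlation)."""
    return stim_correlation(trace, reference, method=method)


def network_correlation_batch(traces: np.ndarray, method: str = "circular",
                              chunk: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """r and p of every spine against its own leave-one-out network signal.

    Uses linearity of the FFT: the spectrum of spine i's reference is
    (F_sum - F_i) / (m - 1), so one FFT of each trace plus the population sum
    yields every leave-one-out correlation at every circular lag.
    """
    traces = np.asarray(traces, dtype=np.float64)
    m, n = traces.shape
    if m < 3:
        raise ValueError("need at least 3 spines to form a network reference")
    if method == "parametric":
        out = []
        for i in range(m):
            out.append(stats.pearsonr(traces[i], network_signal(traces, i)))
        return (np.array([o[0] for o in out]), np.array([o[1] for o in out]))
    xc = traces - traces.mean(axis=1, keepdims=True)
    sx = traces.std(axis=1)
    total = xc.sum(axis=0)
    f_total = np.fft.rfft(total)
    r = np.empty(m)
    p = np.empty(m)
    for a in range(0, m, chunk):
        b = min(a + chunk, m)
        fx = np.fft.rfft(xc[a:b], axis=1)
        f_ref = (f_total[None, :] - fx) / (m - 1)
        ref = (total[None, :] - xc[a:b]) / (m - 1)
        s_ref = ref.std(axis=1)
        cov = np.fft.irfft(fx * np.conj(f_ref), n, axis=1) / n
        r_all = cov / (sx[a:b, None] * s_ref[:, None])
        r[a:b] = r_all[:, 0]
        p[a:b] = (1.0 + (np.abs(r_all[:, 1:])
                         >= np.abs(r_all[:, :1])).sum(axis=1)) / n
    return r, p


def significant_positive(r: float, p: float, alpha: float = ALPHA) -> bool:
    return (r > 0) and (p < alpha)


# ---------------------------------------------------------------------------
# time-locking and the dummy-stimulus false-positive threshold
# ---------------------------------------------------------------------------


def timelocked_pct(event_onsets_s: np.ndarray, presentation_onsets_s: np.ndarray,
                   window_s: float = TIMELOCK_WINDOW_S) -> float:
    """Percentage of presentations with >= 1 event onset within ``window_s``
    of the presentation onset."""
    pres = np.asarray(presentation_onsets_s, dtype=float)
    if pres.size == 0:
        raise ValueError("need at least one presentation")
    ev = np.sort(np.asarray(event_onsets_s, dtype=float))
    lo = np.searchsorted(ev, pres, side="left")
    hi = np.searchsorted(ev, pres + window_s, side="right")
    return 100.0 * float(np.count_nonzero(hi > lo)) / pres.size


def false_positive_threshold(dark_event_onsets_s: np.ndarray,
                             dummy_onsets_s: np.ndarray,
                             window_s: float = TIMELOCK_WINDOW_S) -> float:
    """Per-spine chance level: time-locked % of dark-epoch events against a
    dummy stimulation track with the real track's presentation statistics."""
    if np.asarray(dummy_onsets_s).size == 0:
        raise ValueError("dummy track is empty; dark epoch missing?")
    return timelocked_pct(dark_event_onsets_s, dummy_onsets_s, window_s)


def above_chance_threshold_pct(fp_pct: float, n_presentations: int,
                               population_fp_pct: float | None = None,
                               alpha: float = ALPHA) -> float:
    """Critical time-locked percentage a spine must exceed to be above chance.

    One-sided binomial exceedance test of the real time-locked count against
    the spine's dummy false-positive rate (floored at the population mean so
    a lucky all-quiet dummy epoch cannot make a spine trivially 'responsive').
    Returns 100*(c-1)/n for the smallest count c with
    P(Bin(n, p_null) >= c) <= alpha, so that
    ``timelocked_pct > threshold  <=>  count >= c``.
    """
    p_null = fp_pct / 100.0
    if population_fp_pct is not None:
        p_null = max(p_null, population_fp_pct / 100.0)
    p_null = min(max(p_null, 1e-12), 1.0 - 1e-12)
    c = int(stats.binom.isf(alpha, n_presentations, p_null)) + 1
    return 100.0 * (c - 1) / n_presentations


# ---------------------------------------------------------------------------
# sparse-noise responsiveness
# ---------------------------------------------------------------------------


def sparse_noise_responsive(
    trace: np.ndarray,
    sparse_onsets_s: np.ndarray,
    sampling_rate: float,
    mahal_cut: float = MAHALANOBIS_CUT,
    alpha: float = ALPHA,
    max_iter: int = 20,
    null_onsets_s: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Per-trial responsiveness to the sparse-noise stimulus, and the decision.

    For each stimulus frame a local ΔF/F is formed against the mean of the
    preceding 1.0 s (15 samples at 15 Hz); the feature vector is the
    one-frame forward difference of that signal at the frame onset and again
    ~100 ms later (nearest frame: +2 samples = 133 ms at 15 Hz).  A
    bivariate Gaussian is fitted to the trial features by sample moments with
    iterative re-exclusion of >4 SD outliers (a one-pass moment fit would be
    masked by the responsive trials themselves); trials beyond 4 SD
    (Mahalanobis) of the final fit are responsive.  The spine is
    sparse-noise responsive when its responsive-trial count exceeds the
    one-sided binomial bound (at ``alpha``) for the false-positive rate
    implied by the 4-SD cut.

    ``null_onsets_s``, when given, are dummy trial onsets placed over
    stimulus-free (dark) recording; the same features and the same fitted
    Gaussian are evaluated there and the observed outlier rate replaces the
    chi-squared null rate when larger.  Spontaneous transient rises make the
    empirical trial-outlier rate exceed the Gaussian-implied one, so a purely
    parametric bound over-calls responders.
    """
    trace = np.asarray(trace, dtype=np.float64)
    onsets = np.asarray(sparse_onsets_s, dtype=float)
    if onsets.size < MIN_SPARSE_TRIALS:
        raise ValueError(
            f"insufficient trials: {onsets.size} < {MIN_SPARSE_TRIALS}")
    feats = _sparse_trial_features(trace, onsets, sampling_rate)

    mu, ic = _robust_gaussian_fit(feats, mahal_cut, max_iter)

    # a calcium response rises: require a positive onset derivative as well
    def flags(f: np.ndarray) -> np.ndarray:
        diff = f - mu
        d2 = np.einsum("ij,jk,ik->i", diff, ic, diff)
        return (d2 > mahal_cut ** 2) & (f[:, 0] > 0)

    responsive_trials = flags(feats)
    p_null = float(stats.chi2.sf(mahal_cut ** 2, df=2))  # exp(-8) for 4 SD
    if null_onsets_s is not None:
        nf = _sparse_trial_features(trace, np.asarray(null_onsets_s, float),
                                    sampling_rate)
        p_null = max(p_null, float(flags(nf).mean()))
    responsive = sparse_responder_decision(
        int(responsive_trials.sum()), responsive_trials.size, p_null, alpha)
    return responsive_trials, responsive


def sparse_responder_decision(count: int, n_trials: int, p_null: float,
                              alpha: float = ALPHA) -> bool:
    """One-sided binomial exceedance decision for sparse responsiveness."""
    p_null = min(max(p_null, 1e-12), 1 - 1e-12)
    crit = int(stats.binom.isf(alpha, n_trials, p_null)) + 1
    return count >= crit


def sparse_trial_outliers(trace: np.ndarray, sparse_onsets_s: np.ndarray,
                          sampling_rate: float,
                          null_onsets_s: np.ndarray,
                          mahal_cut: float = MAHALANOBIS_CUT,
                          max_iter: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Outlier flags for real sparse trials and for dummy (dark) trials.

    Shares the fitting procedure of :func:`sparse_noise_responsive`; the
    caller can pool the dummy-trial outlier rate across a spine population
    to obtain a stable empirical null for the responder decision.
    """
    feats = _sparse_trial_features(np.asarray(trace, np.float64),
                                   np.asarray(sparse_onsets_s, float),
                                   sampling_rate)
    mu, ic = _robust_gaussian_fit(feats, mahal_cut, max_iter)

    def flags(f: np.ndarray) -> np.ndarray:
        diff = f - mu
        d2 = np.einsum("ij,jk,ik->i", diff, ic, diff)
        return (d2 > mahal_cut ** 2) & (f[:, 0] > 0)

    nf = _sparse_trial_features(np.asarray(trace, np.float64),
                                np.asarray(null_onsets_s, float),
                                sampling_rate)
    return flags(feats), flags(nf)


def _robust_gaussian_fit(feats: np.ndarray, mahal_cut: float, max_iter: int):
    """Bivariate Gaussian by sample moments with iterative re-exclusion of
    outliers, started from a median/MAD fit so responses cannot mask
    themselves.  Returns (mean, inverse covariance)."""
    mu = np.median(feats, axis=0)
    mad = np.maximum(np.median(np.abs(feats - mu), axis=0) * 1.4826, 1e-12)
    ic = np.diag(1.0 / mad ** 2)
    d2 = (((feats - mu) / mad) ** 2).sum(axis=1)
    inlier = d2 <= mahal_cut ** 2
    for _ in range(max_iter):
        if inlier.sum() < 10:
            break
        mu = feats[inlier].mean(axis=0)
        cov = np.atleast_2d(np.cov(feats[inlier].T)) + 1e-18 * np.eye(2)
        ic = np.linalg.inv(cov)
        diff = feats - mu
        d2 = np.einsum("ij,jk,ik->i", diff, ic, diff)
        new_inlier = d2 <= mahal_cut ** 2
        if np.array_equal(new_inlier, inlier):
            break
        inlier = new_inlier
    return mu, ic


def _sparse_trial_features(trace: np.ndarray, onsets_s: np.ndarray,
                           sampling_rate: float) -> np.ndarray:
    """Per-trial (onset derivative, +100 ms derivative) features.

    Local ΔF/F re-references each trial to the mean of the preceding 1.0 s
    (15 frames at 15 Hz); derivatives are one-frame forward differences at
    the frame after onset and at +2 frames (133 ms, the nearest frame to
    +100 ms at 15 Hz).
    """
    fs = sampling_rate
    base_n = int(round(1.0 * fs))
    idx = np.round(onsets_s * fs).astype(int)
    idx = idx[(idx >= base_n) & (idx + 3 < trace.size)]
    csum = np.concatenate([[0.0], np.cumsum(trace)])
    f0 = (csum[idx] - csum[idx - base_n]) / base_n
    v = trace[idx[:, None] + np.arange(4)[None, :]] - f0[:, None]
    return np.stack([v[:, 1] - v[:, 0], v[:, 3] - v[:, 2]], axis=1)


# ---------------------------------------------------------------------------
# the decision rule
# ---------------------------------------------------------------------------


@dataclass
class SpineClass:
    label: str
    diagnostics: dict


def classify_spine(diag: dict, region: str = "V1") -> SpineClass:
    """Assign the functional label from a spine's diagnostics.

    ``diag`` carries, per available modality m in {vis, aud}:
    ``r_stim_<m>``, ``p_stim_<m>``, ``timelocked_<m>_pct``,
    ``fp_threshold_<m>_pct``; plus ``r_net``, ``p_net`` and optionally
    ``sparse_noise_responsive``.
    """
    def sensory(mod: str) -> bool:
        r, p = diag.get(f"r_stim_{mod}"), diag.get(f"p_stim_{mod}")
        if r is None:
            return False
        thr = diag.get(f"fp_threshold_{mod}_pct")
        if thr is None:
            raise ValueError(f"missing false-positive threshold for {mod!r}")
        locked = diag.get(f"timelocked_{mod}_pct", 0.0)
        return significant_positive(r, p) and locked > thr

    def chance_exceeded_without_corr(mod: str) -> bool:
        r, p = diag.get(f"r_stim_{mod}"), diag.get(f"p_stim_{mod}")
        if r is None:
            return False
        thr = diag.get(f"fp_threshold_{mod}_pct")
        locked = diag.get(f"timelocked_{mod}_pct", 0.0)
        return (locked > thr) and not significant_positive(r, p)

    visual = sensory("vis") or bool(diag.get("sparse_noise_responsive", False))
    if visual:
        return SpineClass("visually_responsive", diag)
    if region == "RSC" and sensory("aud"):
        return SpineClass("auditory_responsive", diag)

    mods = ("vis", "aud") if region == "RSC" else ("vis",)
    excluded = any(chance_exceeded_without_corr(m) for m in mods)
    net = significant_positive(diag.get("r_net", 0.0), diag.get("p_net", 1.0))
    if excluded:
        return SpineClass("excluded", diag)
    if net:
        return SpineClass("network_correlated", diag)
    return SpineClass("unclassified", diag)


def behavioral_regressor_correlation(trace: np.ndarray, regressor: np.ndarray,
                                     method: str = "circular"
                                     ) -> tuple[float, float]:
    """Correlation of a spine trace with an arbitrary behavioural regressor
    (pupil position/diameter, whisker motion, ...), aligned to the trace."""
    return stim_correlation(trace, regressor, method=method)
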