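"""Raw fluorescence -> drift-corrected ΔF/F -> spine-specific signal.

The three stages mirror the standard spine-imaging workflow:

1. :func:`remove_slow_drift` subtracts a rolling 8th-percentile baseline
   (±15 s window) from the raw fluorescence, removing slow drift while
   leaving calcium transients intact.
2. :func:`compute_dff` converts to ΔF/F using the rolling percentile as F0.
3. :func:`robust_slope` / :func:`subtract_dendrite` remove the
   back-propagating-action-potential component that bleeds from the parent
   dendrite into the spine ROI, by robust (IRLS / Tukey bisquare) regression
   of the spine ΔF/F on the paired dendrite ΔF/F and subtraction of the
   scaled dendrite signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "rolling_percentile",
    "remove_slow_drift",
    "compute_dff",
    "robust_slope",
    "subtract_dendrite",
    "DffTrace",
    "SubtractionResult",
]

BISQUARE_C = 4.685  # conventional 95%-efficiency tuning constant
MAD_TO_SIGMA = 1.4826


# ---------------------------------------------------------------------------
# rolling percentile baseline
# ---------------------------------------------------------------------------

if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _rolling_percentile_sorted(x, half, q):  # pragma: no cover - jit
        """Rolling percentile via an incrementally maintained sorted window.

        Windows shrink at the edges (no padding).  Percentile uses the
        linear-interpolation convention of ``np.percentile``.
        """
        n = x.shape[0]
        out = np.empty(n, dtype=x.dtype)
        buf = np.empty(min(n, 2 * half + 1), dtype=x.dtype)
        # initial window [0, half]
        m = min(half + 1, n)
        buf[:m] = np.sort(x[:m])
        lo = 0
        hi = m - 1  # inclusive indices of current window in x
        for t in range(n):
            new_lo = t - half if t - half > 0 else 0
            new_hi = t + half if t + half < n - 1 else n - 1
            while hi < new_hi:
                hi += 1
                v = x[hi]
                # insert v into buf[:m]
                j = np.searchsorted(buf[:m], v)
                for k in range(m, j, -1):
                    buf[k] = buf[k - 1]
                buf[j] = v
                m += 1
            while lo < new_lo:
                v = x[lo]
                lo += 1
                j = np.searchsorted(buf[:m], v)
                for k in range(j, m - 1):
                    buf[k] = buf[k + 1]
                m -= 1
            pos = q / 100.0 * (m - 1)
            i0 = int(pos)
            frac = pos - i0
            if i0 + 1 < m:
                out[t] = buf[i0] + frac * (buf[i0 + 1] - buf[i0])
            else:
                out[t] = buf[i0]
        return out


def _rolling_percentile_numpy(x: np.ndarray, half: int, q: float) -> np.ndarray:
    """Vectorised fallback: full windows via sliding_window_view, loop at edges."""
    n = x.shape[0]
    out = np.empty(n, dtype=x.dtype)
    w = 2 * half + 1
    if n >= w:
        from numpy.lib.stride_tricks import sliding_window_view

        wins = sliding_window_view(x, w)
        out[half : n - half] = np.percentile(wins, q, axis=-1)
    for t in range(min(half, n)):
        out[t] = np.percentile(x[: min(t + half + 1, n)], q)
    for t in range(max(n - half, 0), n):
        out[t] = np.percentile(x[t - half :], q)
    return out


def rolling_percentile(x: np.ndarray, half_window: int, q: float = 8.0) -> np.ndarray:
    """Exact rolling percentile of ``x`` over a ±``half_window``-sample window.

    Windows are truncated (shrink) at the trace edges rather than padded.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("rolling_percentile expects a 1-D trace")
    if _HAVE_NUMBA:
        return _rolling_percentile_sorted(x, half_window, q)
    return _rolling_percentile_numpy(x, half_window, q)


def remove_slow_drift(
    raw: np.ndarray,
    sampling_rate: float,
    half_window_s: float = 15.0,
    q: float = 8.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the rolling 8th-percentile baseline from a raw fluorescence trace.

    Returns ``(corrected, baseline)`` where ``baseline`` is the rolling
    percentile series (the F0 estimate used downstream).

    Raises ``ValueError`` when the trace is shorter than twice the window,
    where a rolling baseline is not meaningful.
    """
    raw = np.asarray(raw, dtype=np.float64)
    half = int(round(half_window_s * sampling_rate))
    min_len = 2 * half
    if raw.shape[0] < min_len:
        raise ValueError(
            f"trace has {raw.shape[0]} samples; need at least {min_len} "
            f"(2 x {half_window_s} s window at {sampling_rate} Hz)"
        )
    baseline = rolling_percentile(raw, half, q)
    return raw - baseline, baseline


# ---------------------------------------------------------------------------
# ΔF/F
# ---------------------------------------------------------------------------


@dataclass
class DffTrace:
    """ΔF/F series together with the per-sample baseline it was computed from."""

    samples: np.ndarray
    baseline: np.ndarray
    source_roi: str = ""

    def __post_init__(self) -> None:
        if self.samples.shape != self.baseline.shape:
            raise ValueError("samples and baseline must have equal length")
        if np.any(self.baseline <= 0):
            raise ValueError("baseline must be strictly positive")


def compute_dff(
    raw: np.ndarray,
    sampling_rate: float,
    half_window_s: float = 15.0,
    source_roi: str = "",
) -> DffTrace:
    """ΔF/F with F0 = rolling 8th percentile, floored at 1% of the median F.

    The epsilon floor guards against near-zero baselines; for any plausible
    fluorescence trace (positive median) the result is scale-invariant:
    ``compute_dff(k * raw) == compute_dff(raw)`` for k > 0.
    """
    raw = np.asarray(raw, dtype=np.float64)
    med = float(np.median(raw))
    if med <= 0:
        raise ValueError("non-positive median fluorescence: not a plausible signal")
    corrected, f0 = remove_slow_drift(raw, sampling_rate, half_window_s)
    eps = 0.01 * med
    denom = np.maximum(f0, eps)
    return DffTrace(samples=corrected / denom, baseline=denom, source_roi=source_roi)


# ---------------------------------------------------------------------------
# robust dendrite subtraction
# ---------------------------------------------------------------------------


@dataclass
class SubtractionResult:
    alpha: float
    spine_specific: np.ndarray
    fit_weights: np.ndarray
    n_iter: int = 0
    converged: bool = True


def _bisquare_weights(resid: np.ndarray, scale: np.ndarray | float) -> np.ndarray:
    u = resid / (BISQUARE_C * scale)
    w = (1.0 - u * u) ** 2
    w[np.abs(u) >= 1.0] = 0.0
    return w


def robust_slope(
    spine_dff: np.ndarray,
    dendrite_dff: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> SubtractionResult:
    """IRLS/bisquare slope of spine ΔF/F on dendrite ΔF/F (intercept included).

    Matches the behaviour of conventional robust-regression routines:
    Tukey bisquare weights with tuning constant 4.685 on an MAD-based residual
    scale, iterated to slope convergence (< ``tol``) or ``max_iter`` passes.
    Vectorised batch version: see :func:`robust_slope_batch`.
    """
    a, b, w, n_it, conv = _irls_batch(
        np.asarray(spine_dff, dtype=np.float64)[None, :],
        np.asarray(dendrite_dff, dtype=np.float64)[None, :],
        max_iter=max_iter,
        tol=tol,
    )
    sspec = np.asarray(spine_dff, dtype=np.float64) - a[0] * np.asarray(
        dendrite_dff, dtype=np.float64
    )
    return SubtractionResult(
        alpha=float(a[0]),
        spine_specific=sspec,
        fit_weights=w[0],
        n_iter=int(n_it[0]),
        converged=bool(conv[0]),
    )


def robust_slope_batch(
    spine_dff: np.ndarray,
    dendrite_dff: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise robust slopes for (n_spines, T) arrays.

    Returns ``(alpha, n_iter, converged)``.
    """
    a, _b, _w, n_it, conv = _irls_batch(
        np.asarray(spine_dff, dtype=np.float64),
        np.asarray(dendrite_dff, dtype=np.float64),
        max_iter=max_iter,
        tol=tol,
    )
    return a, n_it, conv


def _irls_batch(y: np.ndarray, x: np.ndarray, max_iter: int, tol: float):
    """Vectorised IRLS bisquare regression of each row of y on each row of x."""
    if y.shape != x.shape:
        raise ValueError("spine and dendrite traces must have equal shape")
    n_rows, n = y.shape
    if n < 300:
        raise ValueError(f"robust regression requires >= 300 samples, got {n}")
    xvar = x.var(axis=1)
    if np.any(xvar <= 0):
        raise ValueError("degenerate regressor: dendrite trace has zero variance")

    # OLS start
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    xc = x - xm
    yc = y - ym
    slope = (xc * yc).sum(axis=1) / (xc * xc).sum(axis=1)
    intercept = (ym - slope[:, None] * xm)[:, 0]

    n_iter = np.zeros(n_rows, dtype=np.int64)
    converged = np.zeros(n_rows, dtype=bool)
    active = np.ones(n_rows, dtype=bool)
    w = np.ones_like(y)

    for it in range(max_iter):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        xa, ya = x[idx], y[idx]
        resid = ya - slope[idx, None] * xa - intercept[idx, None]
        med = np.median(resid, axis=1, keepdims=True)
        mad = np.median(np.abs(resid - med), axis=1, keepdims=True)
        scale = np.maximum(mad * MAD_TO_SIGMA, 1e-12)
        wa = _bisquare_weights(resid, scale)
        # guard: if everything got zero weight, fall back to unit weights
        dead = wa.sum(axis=1) <= 0
        if np.any(dead):
            wa[dead] = 1.0
        sw = wa.sum(axis=1)
        xw = (wa * xa).sum(axis=1) / sw
        yw = (wa * ya).sum(axis=1) / sw
        dx = xa - xw[:, None]
        denom = (wa * dx * dx).sum(axis=1)
        new_slope = (wa * dx * (ya - yw[:, None])).sum(axis=1) / np.maximum(
            denom, 1e-300
        )
        new_intercept = yw - new_slope * xw
        delta = np.abs(new_slope - slope[idx])
        slope[idx] = new_slope
        intercept[idx] = new_intercept
        w[idx] = wa
        n_iter[idx] = it + 1
        done = delta < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    return slope, intercept, w, n_iter, converged


def subtract_dendrite(
    spine_dff: np.ndarray, dendrite_dff: np.ndarray, alpha: float
) -> np.ndarray:
    """Spine-specific ΔF/F: exact sample-wise ``spine - alpha * dendrite``."""
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    spine_dff = np.asarray(spine_dff, dtype=np.float64)
    dendrite_dff = np.asarray(dendrite_dff, dtype=np.float64)
    if spine_dff.shape != dendrite_dff.shape:
        raise ValueError("length mismatch between spine and dendrite traces")
    return spine_dff - alpha * dendrite_dff
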