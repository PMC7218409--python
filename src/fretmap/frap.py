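"""FRAP recovery analysis: trace extraction, double normalization, fitting.

A single endocytic spot is bleached by a brief laser pulse and its
fluorescence followed (default every 0.5 s). The normalized trace is fitted
with a single-exponential recovery

    F(t) = F0 + M * (1 - F0) * (1 - exp(-(t - t0)/tau)),   t >= t0,

whose mobile fraction M measures the exchanging pool and tau the effective
exchange time (half-time tau*ln 2). Double normalization against an
unbleached reference region removes acquisition photobleaching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .io import ImageSeries, Roi
from .stats import mean_ci


@dataclass
class FrapTrace:
    times_s: np.ndarray
    spot: np.ndarray                      # background-subtracted spot means
    reference: np.ndarray                 # background-subtracted reference means
    bleach_index: int                     # first post-bleach frame
    normalized: np.ndarray | None = None
    F_pre: float | None = None
    F_post0: float | None = None


@dataclass
class RecoveryFit:
    mobile_fraction: float
    tau_s: float
    half_time_s: float
    F0: float
    residual_rms: float
    success: bool


def _roi_mean(frames: np.ndarray, roi, shape) -> np.ndarray:
    mask = roi.rasterize(shape) if isinstance(roi, Roi) else roi
    return frames[:, mask].mean(axis=1)


def detect_bleach_frame(spot: np.ndarray) -> int:
    """Index of the first post-bleach frame: the largest single-frame
    fractional drop in the spot trace."""
    s = np.asarray(spot, dtype=float)
    prev = np.maximum(s[:-1], 1e-12)
    drops = (s[:-1] - s[1:]) / prev
    return int(np.argmax(drops)) + 1


def extract_trace(series: ImageSeries, spot_roi, reference_roi,
                  background_roi) -> FrapTrace:
    """Background-subtracted per-frame means of the bleached spot and an
    unbleached reference region; ROIs must be pairwise disjoint."""
    shape = series.shape
    masks = [r.rasterize(shape) if isinstance(r, Roi) else r
             for r in (spot_roi, reference_roi, background_roi)]
    for i in range(3):
        for j in range(i + 1, 3):
            if (masks[i] & masks[j]).any():
                raise ValueError("spot/reference/background ROIs must be disjoint")
    frames = series.frames.astype(float)
    bg = np.array([np.median(f[masks[2]]) for f in frames])
    spot = _roi_mean(frames, masks[0], shape) - bg
    ref = _roi_mean(frames, masks[1], shape) - bg
    return FrapTrace(times_s=series.times_s.copy(), spot=spot, reference=ref,
                     bleach_index=detect_bleach_frame(spot))


def normalize_trace(trace: FrapTrace) -> FrapTrace:
    """Double normalization: ``F~(t) = [spot/ref] / mean_pre[spot/ref]``.

    The pre-bleach mean of the normalized trace is exactly 1; dividing by
    the reference removes acquisition photobleaching shared by the whole
    cell.
    """
    nb = trace.bleach_index
    if nb < 3:
        raise ValueError("need >= 3 pre-bleach frames")
    if np.any(trace.reference <= 0):
        raise ValueError("non-positive reference intensity")
    ratio = trace.spot / trace.reference
    norm = ratio / ratio[:nb].mean()
    trace.normalized = norm
    trace.F_pre = 1.0
    trace.F_post0 = float(norm[nb])
    return trace


def fit_recovery(trace: FrapTrace, max_mobile: float = 1.2) -> RecoveryFit:
    """Bounded least-squares fit of the single-exponential recovery model
    to the normalized post-bleach trace."""
    if trace.normalized is None:
        normalize_trace(trace)
    nb = trace.bleach_index
    t = trace.times_s[nb:] - trace.times_s[nb]
    y = trace.normalized[nb:]
    if t.size < 10:
        raise ValueError("need >= 10 post-bleach points")

    def resid(p):
        f0, m, tau = p
        return f0 + m * (1.0 - f0) * (1.0 - np.exp(-t / tau)) - y

    f0_init = float(np.clip(y[0], 0.0, 0.99))
    span = max(y[-5:].mean() - f0_init, 0.0)
    m_init = float(np.clip(span / max(1.0 - f0_init, 1e-6), 0.05, 1.0))
    # tau init: time to half of the observed span
    target = f0_init + 0.5 * span
    above = np.nonzero(y >= target)[0]
    tau_init = float(max(t[above[0]] / np.log(2), 0.5)) if above.size else \
        float(max(t[-1] / 3, 0.5))
    best = None
    for tau0 in {tau_init, 2.0, 10.0}:
        try:
            res = least_squares(resid, x0=[f0_init, m_init, tau0],
                                bounds=([0.0, 0.0, 1e-3],
                                        [0.999, max_mobile, 10 * t[-1]]))
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        return RecoveryFit(np.nan, np.nan, np.nan, np.nan, np.nan, False)
    f0, m, tau = best.x
    rms = float(np.sqrt(2 * best.cost / t.size))
    return RecoveryFit(mobile_fraction=float(np.clip(m, 0.0, max_mobile)),
                       tau_s=float(tau), half_time_s=float(tau * np.log(2)),
                       F0=float(f0), residual_rms=rms, success=True)


def mean_recovery_curve(traces: list[FrapTrace], level: float = 0.95
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-timepoint mean and t-based CI halfwidth across cells.

    Traces are aligned on their bleach frame and truncated to the shortest
    common length (a shared time base).
    """
    if len(traces) < 2:
        raise ValueError("need >= 2 traces")
    for tr in traces:
        if tr.normalized is None:
            normalize_trace(tr)
    pre = min(tr.bleach_index for tr in traces)
    post = min(len(tr.normalized) - tr.bleach_index for tr in traces)
    dt = float(np.median(np.diff(traces[0].times_s)))
    aligned = np.stack([tr.normalized[tr.bleach_index - pre:tr.bleach_index + post]
                        for tr in traces])
    times = (np.arange(pre + post) - pre) * dt
    mean = aligned.mean(axis=0)
    hw = np.array([mean_ci(aligned[:, j], level)[1] for j in range(aligned.shape[1])])
    return times, mean, hw
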