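"""Unsupervised detection of discontinuous oscillatory events.

Neonatal cortical activity is discontinuous: spindle-shaped oscillations
alternate with long stretches of network silence. Events are detected as
deflections of the sliding RMS of the 1-100 Hz band-passed signal above a
variance-dependent threshold. The threshold comes from a Gaussian fit to
the low side of the RMS amplitude histogram (values from 0 up to the
histogram's global maximum), which captures the silent-background mode
while excluding the right-tail event mass. Detections closer than 200 ms
are merged, and only events lasting more than 1 s are kept.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import curve_fit

from .core import OscillationEvent

MERGE_GAP_S = 0.2  # oscillations within 200 ms are considered one
MIN_DURATION_S = 1.0  # only oscillations lasting > 1 s are included
DEFAULT_RMS_WINDOW_MS = 200.0
DEFAULT_K = 2.0
DEFAULT_N_BINS = 100


def rms_envelope(
    x: np.ndarray, fs: float, window_ms: float = DEFAULT_RMS_WINDOW_MS
) -> np.ndarray:
    """Centered sliding root-mean-square of a band-passed signal.

    Same length as the input; edges use a shrinking (reflected) window via
    uniform filtering of the squared signal.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    n = int(round(window_ms / 1000.0 * fs))
    if n < 1 or n > x.size:
        raise ValueError(
            f"RMS window of {n} samples invalid for signal of {x.size}"
        )
    sq = ndi.uniform_filter1d(
        np.asarray(x, dtype=float) ** 2, size=n, mode="reflect"
    )
    return np.sqrt(np.maximum(sq, 0.0))


def _gaussian(x: np.ndarray, amp: float, mu: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_rms_threshold(
    envelope: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    k: float = DEFAULT_K,
    upper: str = "max",
) -> float:
    """Variance-dependent threshold from the RMS amplitude histogram.

    A Gaussian is least-squares fitted to the histogram restricted to the
    range from 0 to its global maximum, and the threshold is mu + k*sigma.

    Parameters
    ----------
    envelope : array
        Non-negative RMS envelope values.
    n_bins : int
        Histogram bins over [0, max(envelope)].
    k : float
        SD multiplier; the single most result-sensitive free parameter.
    upper : {"max", "mode"}
        Reading of "global maximum of the RMS histogram": ``max`` (default)
        fits the full range up to the largest RMS value, which recovers the
        noise width reliably; ``mode`` fits only up to the peak (tallest)
        bin and systematically underestimates the spread of skewed
        envelope histograms.
    """
    env = np.asarray(envelope, dtype=float)
    if env.size == 0:
        raise ValueError("empty envelope")
    if np.any(env < 0):
        raise ValueError("RMS envelope must be non-negative")
    counts, edges = np.histogram(env, bins=n_bins, range=(0.0, env.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    if np.count_nonzero(counts) < 2:
        raise ValueError("degenerate RMS histogram (single occupied bin)")
    if upper == "mode":
        hi = int(np.argmax(counts))
    elif upper == "max":
        hi = len(counts) - 1
    else:
        raise ValueError("upper must be 'mode' or 'max'")
    xs, ys = centers[: hi + 1], counts[: hi + 1].astype(float)
    if xs.size < 3:
        raise ValueError("too few bins below the histogram mode to fit")
    # initialize at the histogram peak with sigma from its half-width and
    # bound the fit so it cannot diverge on sparse or skewed histograms
    mode_i = int(np.argmax(ys))
    half_region = np.flatnonzero(ys >= ys.max() / 2)
    bin_w = float(xs[1] - xs[0])
    sigma0 = max((xs[half_region[-1]] - xs[half_region[0]]) / 2.355, bin_w)
    p0 = (float(ys.max()), float(xs[mode_i]), sigma0)
    bounds = ([0.0, 0.0, bin_w / 10], [10.0 * ys.max(), xs[-1], xs[-1]])
    popt, _ = curve_fit(_gaussian, xs, ys, p0=p0, bounds=bounds, maxfev=20000)
    _, mu, sigma = popt
    return float(mu + k * abs(sigma))


def _intervals_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts.tolist(), stops.tolist()))


def detect_oscillations(
    x: np.ndarray,
    fs: float,
    window_ms: float = DEFAULT_RMS_WINDOW_MS,
    k: float = DEFAULT_K,
    threshold: float | None = None,
    channel: str = "ch0",
    upper: str = "max",
) -> list[OscillationEvent]:
    """Detect network oscillations in a 1-100 Hz band-passed trace.

    Supra-threshold RMS intervals are merged when separated by less than
    200 ms (merge first, then the > 1 s duration gate, matching the order
    of the detection rules), and summarized per event.
    """
    env = rms_envelope(x, fs, window_ms)
    if threshold is None:
        threshold = fit_rms_threshold(env, k=k, upper=upper)
    mask = env > threshold
    if not mask.any():
        return []
    raw = _intervals_above(mask)
    gap = int(round(MERGE_GAP_S * fs))
    # merged intervals carry their total supra-threshold time: bridged
    # sub-200-ms gaps join oscillations into one but contribute no
    # oscillating time themselves
    merged: list[list[int]] = [[raw[0][0], raw[0][1], raw[0][1] - raw[0][0]]]
    for s, e in raw[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
            merged[-1][2] += e - s
        else:
            merged.append([s, e, e - s])
    out: list[OscillationEvent] = []
    # the > 1 s inclusion rule is applied to the supra-threshold time,
    # corrected by one RMS window: the centered window smears each edge
    # outward by up to half a window, so the measured crossing
    # overestimates the true oscillation duration by about one window.
    # Reported boundaries stay at the measured crossings.
    min_len = (MIN_DURATION_S + window_ms / 1000.0) * fs
    for s, e, supra in merged:
        if supra <= min_len:
            continue
        seg = np.asarray(x[s:e], dtype=float)
        out.append(
            OscillationEvent(
                channel=channel,
                start_s=s / fs,
                stop_s=e / fs,
                peak_amplitude=float(np.abs(seg).max()),
                mean_rms=float(env[s:e].mean()),
            )
        )
    return out


def summarize_events(
    events: list[OscillationEvent], total_duration_s: float
) -> dict:
    """Occurrence (events/min), mean duration/amplitude, active fraction.

    With no events the occurrence is 0 and the per-event means are reported
    as ``None`` (absent, not zero).
    """
    if total_duration_s <= 0:
        raise ValueError("total_duration_s must be positive")
    n = len(events)
    occurrence = n / (total_duration_s / 60.0)
    if n == 0:
        return {
            "occurrence_per_min": 0.0,
            "mean_duration_s": None,
            "mean_amplitude_uv": None,
            "active_fraction": 0.0,
        }
    durations = np.array([e.duration_s for e in events])
    amplitudes = np.array([e.peak_amplitude for e in events])
    return {
        "occurrence_per_min": occurrence,
        "mean_duration_s": float(durations.mean()),
        "mean_amplitude_uv": float(amplitudes.mean()),
        "active_fraction": float(durations.sum() / total_duration_s),
    }


def match_events(
    detected: list[OscillationEvent],
    truth_intervals: list[tuple[float, float]],
) -> dict:
    """Score detections against planted ground truth.

    A truth event is recovered if some detection overlaps it; a detection is
    a true positive if it overlaps some truth event. Boundary error is the
    mean absolute onset/offset offset over matched (detection, truth) pairs.
    """
    matched_truth = set()
    tp = 0
    boundary_errors: list[float] = []
    for d in detected:
        hit = None
        for i, (t0, t1) in enumerate(truth_intervals):
            if d.start_s < t1 and d.stop_s > t0:
                hit = i
                break
        if hit is not None:
            tp += 1
            matched_truth.add(hit)
            t0, t1 = truth_intervals[hit]
            boundary_errors.append(0.5 * (abs(d.start_s - t0) + abs(d.stop_s - t1)))
    sensitivity = len(matched_truth) / len(truth_intervals) if truth_intervals else float("nan")
    precision = tp / len(detected) if detected else float("nan")
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "mean_boundary_error_s": float(np.mean(boundary_errors)) if boundary_errors else float("nan"),
    }
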