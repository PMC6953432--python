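"""Multi-unit spike detection and firing statistics.

MUA spikes are detected in the 500-5,000 Hz band as negative deflections
whose trough exceeds five standard deviations of the filtered trace and
whose prominence is larger than half the trough depth itself — the
prominence gate rejects slow baseline excursions that cross the amplitude
threshold without a spike-like shape.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import SpikeSeries

THRESHOLD_SD = 5.0
DEAD_TIME_S = 0.001  # refractory gap between accepted troughs

ISI_BIN_MS = 2.0
ISI_RANGE_MS = (10.0, 500.0)


def detect_mua(
    x: np.ndarray,
    fs: float,
    threshold_sd: float = THRESHOLD_SD,
    robust_sd: bool = False,
    unit_id: str = "site0",
) -> SpikeSeries:
    """Detect multi-unit spikes in a 500-5,000 Hz filtered trace.

    Candidate troughs are minima below ``-threshold_sd * SD``; a trough is
    kept only if its prominence (on the inverted trace) exceeds half its own
    depth. ``robust_sd`` switches the scale estimate from the plain standard
    deviation to the median-absolute-deviation estimate, which is less
    inflated by heavy spiking.
    """
    x = np.asarray(x, dtype=float)
    if robust_sd:
        sd = float(np.median(np.abs(x)) / 0.6745)
    else:
        sd = float(x.std())
    if sd == 0:
        raise ValueError("flat signal: spike threshold undefined")
    height = threshold_sd * sd
    distance = max(1, int(round(DEAD_TIME_S * fs)))
    peaks, props = sps.find_peaks(-x, height=height, distance=distance)
    depth = props["peak_heights"]  # |x| at the trough
    prominences = sps.peak_prominences(-x, peaks)[0]
    keep = prominences > depth / 2.0
    return SpikeSeries(
        times_s=peaks[keep] / fs, duration_s=x.size / fs, unit_id=unit_id
    )


def firing_rate(
    spikes: SpikeSeries, window: tuple[float, float] | None = None
) -> float:
    """Spikes per second: count in the window over the window length."""
    if window is None:
        window = (0.0, spikes.duration_s)
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window end must exceed start")
    n = int(np.searchsorted(spikes.times_s, t1) - np.searchsorted(spikes.times_s, t0))
    return n / (t1 - t0)


def log_firing_rate(
    spikes: SpikeSeries, window: tuple[float, float] | None = None
) -> float:
    """log10 firing rate, the scale used for cohort features."""
    r = firing_rate(spikes, window)
    if r <= 0:
        raise ValueError("log firing rate undefined for a silent window")
    return float(np.log10(r))


def isi_histogram(spikes: SpikeSeries) -> dict[str, np.ndarray]:
    """Inter-spike-interval distribution at 2 ms resolution.

    The mass is normalized by the TOTAL number of intervals, but only the
    10-500 ms range is returned (so the returned mass can sum to < 1 when
    intervals fall outside that range).
    """
    if spikes.n_spikes < 2:
        raise ValueError("ISI histogram needs >= 2 spikes")
    isi_ms = np.diff(spikes.times_s) * 1000.0
    lo, hi = ISI_RANGE_MS
    # bin centers on the 2-ms grid (10, 12, ..., 500 ms): edges offset by
    # half a bin so a preferred interval on the grid falls mid-bin
    edges = np.arange(lo - ISI_BIN_MS / 2, hi + ISI_BIN_MS, ISI_BIN_MS)
    counts, _ = np.histogram(isi_ms, bins=edges)
    return {
        "bin_centers_ms": 0.5 * (edges[:-1] + edges[1:]),
        "mass": counts / isi_ms.size,
    }


def preferred_isi_ms(spikes: SpikeSeries) -> float:
    """Center of the modal 2-ms ISI bin within 10-500 ms."""
    h = isi_histogram(spikes)
    return float(h["bin_centers_ms"][int(np.argmax(h["mass"]))])
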