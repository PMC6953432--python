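"""Filtering, resampling and rereferencing of extracellular recordings.

All filters are zero-phase (forward-backward Butterworth), so oscillation
timing and spike-field phase relations are preserved. The LFP analysis band
is 4-100 Hz (order-3 Butterworth, decimated to 3.2 kHz from a 32 kHz
acquisition); the multi-unit band is 500-5,000 Hz. Recordings from
non-anesthetized animals are common-average rereferenced to suppress
movement artifacts shared across channels.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import Recording

LFP_BAND = (4.0, 100.0)
MUA_BAND = (500.0, 5000.0)
LFP_TARGET_FS = 3200.0
DEFAULT_ORDER = 3


def bandpass(
    x: np.ndarray,
    fs: float,
    low: float,
    high: float,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass filter.

    Parameters
    ----------
    x : array
        Signal (last axis is time), microvolts.
    fs : float
        Sampling rate in Hz.
    low, high : float
        Band edges in Hz; must satisfy 0 < low < high < fs/2.
    order : int
        Butterworth order of the one-way design (applied twice).

    Returns
    -------
    Filtered signal of the same shape, zero lag in the passband.
    """
    if not (0 < low < high):
        raise ValueError(f"need 0 < low < high, got [{low}, {high}]")
    if high >= fs / 2:
        raise ValueError(f"high edge {high} Hz violates Nyquist for fs={fs}")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    # reflect-pad 3 impulse-response lengths to suppress edge transients on
    # short segments
    padlen = min(x.shape[-1] - 1, 3 * 2 * (2 * order + 1))
    return sps.sosfiltfilt(sos, x, padtype="even", padlen=padlen)


def downsample(
    x: np.ndarray, fs: float, target_fs: float = LFP_TARGET_FS
) -> tuple[np.ndarray, float]:
    """Decimate an already low-passed signal by an integer factor.

    The caller is responsible for having band-limited the signal below
    ``target_fs / 2`` (the 4-100 Hz LFP band-pass provides a wide Nyquist
    margin for the default 3.2 kHz target).
    """
    ratio = fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"fs={fs} is not an integer multiple of target_fs={target_fs}"
        )
    step = int(round(ratio))
    return np.asarray(x)[..., ::step], target_fs


def common_average_rereference(rec: Recording) -> Recording:
    """Subtract the across-channel mean from every channel at every sample.

    Removes signal components shared by all sites (movement artifacts,
    volume-conducted far fields). Requires at least two channels.
    """
    if rec.n_channels < 2:
        raise ValueError("common-average rereferencing needs >= 2 channels")
    ref = rec.samples.mean(axis=0, keepdims=True)
    return Recording(
        samples=rec.samples - ref,
        fs=rec.fs,
        channels=list(rec.channels),
        animal_id=rec.animal_id,
        condition=rec.condition,
    )


def preprocess_lfp(
    x: np.ndarray, fs: float, target_fs: float = LFP_TARGET_FS
) -> tuple[np.ndarray, float]:
    """4-100 Hz band-pass then decimation: the standard LFP chain."""
    y = bandpass(x, fs, *LFP_BAND)
    return downsample(y, fs, target_fs)


def preprocess_mua(x: np.ndarray, fs: float) -> np.ndarray:
    """500-5,000 Hz band-pass: the multi-unit activity chain."""
    return bandpass(x, fs, *MUA_BAND)
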