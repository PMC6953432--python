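"""Welch power spectra of oscillatory activity and stimulation modulation.

Because neonatal activity is discontinuous, power is estimated only over
detected oscillations: 1-s windows of network oscillations are concatenated
and averaged with Welch's method (non-overlapping 1-s Hann segments, 1 Hz
resolution). Band powers integrate the PSD over theta (4-12 Hz), beta
(12-30 Hz) and gamma (30-100 Hz); band edges are half-open [lo, hi) so
adjacent bands never double count. Optogenetic ramp trials are summarized
by a bounded modulation index contrasting band power in the last 1.5 s of
the ramp against the 1.5 s preceding it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import BANDS, OscillationEvent, StimEpoch


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray  # Hz, strictly increasing
    psd: np.ndarray  # uV^2/Hz, >= 0

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def band_powers(self) -> dict[str, float]:
        return {name: band_power(self, name) for name in BANDS}


def concatenated_welch(
    x: np.ndarray, fs: float, events: list[OscillationEvent]
) -> PowerSpectrum:
    """Welch PSD over concatenated 1-s windows of detected oscillations.

    Each event contributes ``floor(duration)`` whole non-overlapping 1-s
    windows taken from its onset; Welch averages over all windows with 1-s
    Hann segments, giving 1 Hz frequency resolution.
    """
    if not events:
        raise ValueError("no oscillatory events: spectrum undefined")
    nper = int(round(fs))
    chunks = []
    for ev in events:
        s = int(round(ev.start_s * fs))
        n_win = int(ev.stop_s - ev.start_s)  # floor of the duration
        for w in range(n_win):
            seg = x[s + w * nper : s + (w + 1) * nper]
            if seg.size == nper:
                chunks.append(seg)
    if not chunks:
        raise ValueError("no complete 1-s windows inside the given events")
    concat = np.concatenate(chunks)
    f, p = sps.welch(
        concat, fs=fs, window="hann", nperseg=nper, noverlap=0, detrend="constant"
    )
    return PowerSpectrum(frequencies=f, psd=p)


def band_power(
    spectrum: PowerSpectrum, band: str | tuple[float, float]
) -> float:
    """Integrated PSD over a band, uV^2.

    Bins with lo <= f < hi each contribute psd * df, so disjoint bands are
    additive and a tone sitting exactly on a shared edge (e.g. 30 Hz) is
    counted once, in the upper band.
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    if hi <= lo:
        raise ValueError(f"empty band [{lo}, {hi})")
    f = spectrum.frequencies
    if lo < f[0] - spectrum.df / 2 or hi > f[-1] + spectrum.df:
        raise ValueError(f"band [{lo}, {hi}) outside spectrum range")
    sel = (f >= lo) & (f < hi)
    if not sel.any():
        raise ValueError(f"no frequency bins in band [{lo}, {hi})")
    return float(np.sum(spectrum.psd[sel]) * spectrum.df)


def modulation_index(pre_power: float, stim_power: float) -> float:
    """(stim - pre) / (stim + pre): bounded contrast in [-1, 1]."""
    if pre_power < 0 or stim_power < 0:
        raise ValueError("powers must be non-negative")
    total = pre_power + stim_power
    if total == 0:
        raise ValueError("modulation index undefined: both powers are zero")
    return (stim_power - pre_power) / total


def _window_band_power(
    x: np.ndarray, fs: float, t0: float, t1: float, band
) -> float:
    i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
    if i0 < 0 or i1 > x.size:
        raise ValueError("window outside the recording")
    seg = x[i0:i1]
    nper = int(round(0.75 * fs))  # two non-overlapping segments per 1.5 s
    f, p = sps.welch(
        seg, fs=fs, window="hann", nperseg=nper, noverlap=0, detrend="constant"
    )
    return band_power(PowerSpectrum(f, p), band)


def stim_power_pair(
    x: np.ndarray, fs: float, epoch: StimEpoch, band: str | tuple[float, float]
) -> dict[str, float]:
    """Band power in the pre-stimulation vs late-stimulation 1.5-s windows.

    Welch with 0.75-s non-overlapping Hann segments in each window.
    """
    pre = _window_band_power(x, fs, *epoch.pre_window, band)
    stim = _window_band_power(x, fs, *epoch.stim_window, band)
    return {"pre": pre, "stim": stim}


def stim_modulation(
    x: np.ndarray, fs: float, epochs: list[StimEpoch], band
) -> float:
    """Modulation index of trial-averaged band power across ramp epochs."""
    pairs = [stim_power_pair(x, fs, ep, band) for ep in epochs]
    pre = float(np.mean([p["pre"] for p in pairs]))
    stim = float(np.mean([p["stim"] for p in pairs]))
    return modulation_index(pre, stim)
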