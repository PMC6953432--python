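"""Shared containers for the neonatal prefrontal quantification pipeline.

The pipeline operates on three kinds of objects: multichannel extracellular
recordings (LFP + wide-band), spike-time series tied to a recording, and
per-animal feature tables used for group statistics and classification.
Ground-truth containers (:class:`EventTruth`, :class:`ImageTruth`) carry the
planted structure of synthetic inputs so detectors can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Canonical frequency bands (Hz, half-open [lo, hi)).
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 100.0),
}

# Carrier bands used by the synthetic generator: band-limited sinusoid
# mixtures stay analytically checkable while matching the theta and
# beta-gamma components of neonatal spindle bursts.
CARRIER_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 12.0),
    "beta": (15.0, 40.0),
    "gamma": (40.0, 90.0),
}


@dataclass
class Channel:
    """One recording site with its laminar assignment."""

    id: str
    layer: str  # "superficial" | "deep"
    depth_um: float = 0.0


@dataclass
class Recording:
    """Multichannel continuous signal in microvolts.

    ``samples`` is channels x time. ``fs`` is the sampling rate in Hz.
    """

    samples: np.ndarray
    fs: float
    channels: list[Channel]
    animal_id: str = "animal0"
    condition: str = "control"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel entries for "
                f"{self.samples.shape[0]} signal rows"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class TruthEvent:
    """One planted oscillatory event."""

    start_s: float
    stop_s: float
    carrier_bands: tuple[str, ...]
    peak_amplitude: float  # uV


@dataclass
class EventTruth:
    """Planted event times and background shape of a synthetic recording."""

    events: list[TruthEvent] = field(default_factory=list)
    background_exponent: float = 1.0

    def __post_init__(self) -> None:
        ev = sorted(self.events, key=lambda e: e.start_s)
        for e in ev:
            if e.stop_s <= e.start_s:
                raise ValueError("event stop must exceed start")
        for a, b in zip(ev, ev[1:]):
            if b.start_s < a.stop_s:
                raise ValueError("truth events overlap")
        self.events = ev

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class OscillationEvent:
    """A detected network oscillation on one channel."""

    channel: str
    start_s: float
    stop_s: float
    peak_amplitude: float  # max |filtered signal| within the event, uV
    mean_rms: float  # mean RMS envelope within the event, uV

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s


@dataclass
class SpikeSeries:
    """Sorted spike times (s) for one unit or recording site."""

    times_s: np.ndarray
    duration_s: float
    unit_id: str = "site0"

    def __post_init__(self) -> None:
        t = np.sort(np.asarray(self.times_s, dtype=float))
        if t.size and (t[0] < 0 or t[-1] > self.duration_s):
            raise ValueError("spike times outside [0, duration]")
        self.times_s = t

    @property
    def n_spikes(self) -> int:
        return self.times_s.size

    @property
    def rate(self) -> float:
        return self.n_spikes / self.duration_s


@dataclass
class StimEpoch:
    """One optogenetic ramp trial: a 3-s linearly increasing light power.

    The pre window is the 1.5 s preceding ramp onset; the stim window is the
    last 1.5 s of the ramp, where evoked activity is strongest.
    """

    ramp_onset_s: float
    ramp_offset_s: float

    def __post_init__(self) -> None:
        if not np.isclose(self.ramp_offset_s - self.ramp_onset_s, 3.0):
            raise ValueError("ramp duration must be 3 s")

    @property
    def pre_window(self) -> tuple[float, float]:
        return (self.ramp_onset_s - 1.5, self.ramp_onset_s)

    @property
    def stim_window(self) -> tuple[float, float]:
        return (self.ramp_offset_s - 1.5, self.ramp_offset_s)


@dataclass
class FeatureTable:
    """Per-animal feature vectors with optional two-class labels."""

    data: pd.DataFrame  # index: animal ids; columns: feature names
    labels: pd.Series | None = None  # aligned with data.index, or None

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")
        if self.data.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if self.labels is not None:
            self.labels = pd.Series(self.labels, index=self.data.index)
            counts = self.labels.value_counts()
            if (counts < 2).any():
                raise ValueError("each labeled class needs >= 2 animals")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray | None:
        return None if self.labels is None else self.labels.to_numpy()


@dataclass
class TruthCell:
    centroid_px: tuple[float, ...]
    semi_axes_px: tuple[float, ...]
    orientation_rad: float = 0.0
    branch_count: int = 0


@dataclass
class TruthPunctum:
    centroid_px: tuple[float, ...]
    volume_px: int
    inside_cell: int | None = None  # index into ImageTruth.cells


@dataclass
class ImageTruth:
    """Planted geometry of a synthetic microglia / VGLUT1 stack."""

    cells: list[TruthCell] = field(default_factory=list)
    puncta: list[TruthPunctum] = field(default_factory=list)
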