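"""Synthetic inputs with stored ground truth for every pipeline stage.

The generator emulates the statistical structure the quantification
pipeline assumes, with known truth so detectors and estimators can be
scored exactly:

* discontinuous LFP: 1/f background noise with silence-interleaved,
  Hann-edge-tapered band-limited oscillatory bursts (theta and beta
  carriers) at stored times and amplitudes;
* spike trains: inhomogeneous Poisson, rate elevated during oscillations,
  with von Mises phase locking to a carrier band implemented by thinning
  (so the marginal rate stays exactly controlled);
* optogenetic ramp sessions: 3-s ramps with evoked beta-band LFP power
  and either frequency-tuned (~60 ms preferred inter-spike interval) or
  untuned during-ramp firing;
* two-class feature cohorts with a scalable between-group effect;
* microglia / VGLUT1 image stacks with planted ellipsoidal cells and
  puncta of known containment;
* behavior tables whose expected discrimination ratio is exact.

Group-level defaults (log10 firing rates of superficial and deep-layer
units per condition) follow the reported cohort values; everything else is
invented fixture plumbing with realistic magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import i0

from .core import (
    CARRIER_BANDS,
    Channel,
    EventTruth,
    FeatureTable,
    ImageTruth,
    Recording,
    SpikeSeries,
    StimEpoch,
    TruthCell,
    TruthEvent,
    TruthPunctum,
)

EDGE_RAMP_S = 0.2  # Hann-taper length at each burst edge
MIN_EVENT_GAP_S = 1.0  # placement gap: well above the 200 ms merge rule


@dataclass
class GroupParams:
    """Condition-specific generative parameters.

    ``log10_rate_sup`` / ``log10_rate_deep`` are (mean, SD) of log10 firing
    rates in spikes/s for superficial and deep-layer units. The reported
    cohort means are log10(-0.61) +/- 0.04 for control superficial units
    vs -2.1 +/- 0.1 in the GE condition (and -0.95 / -1.3 in deep layers).
    ``band_power_scale`` multiplies oscillatory band amplitudes;
    ``kappa`` sets von Mises spike-phase concentration per band.
    """

    log10_rate_sup: tuple[float, float] = (-0.61, 0.04)
    log10_rate_deep: tuple[float, float] = (-0.95, 0.05)
    band_power_scale: dict = field(
        default_factory=lambda: {"theta": 1.0, "beta": 1.0, "gamma": 1.0}
    )
    kappa: dict = field(
        default_factory=lambda: {"theta": 0.5, "beta": 2.0, "gamma": 1.5}
    )

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.band_power_scale.values()):
            raise ValueError("band_power_scale entries must be positive")
        if any(v < 0 for v in self.kappa.values()):
            raise ValueError("kappa must be non-negative")


def default_groups() -> dict[str, GroupParams]:
    """Control vs GE defaults: reduced superficial firing, beta-gamma power
    and locking precision in the dual-hit condition."""
    return {
        "control": GroupParams(),
        "GE": GroupParams(
            log10_rate_sup=(-2.1, 0.1),
            log10_rate_deep=(-1.3, 0.2),
            band_power_scale={"theta": 0.8, "beta": 0.4, "gamma": 0.5},
            kappa={"theta": 0.4, "beta": 0.5, "gamma": 0.4},
        ),
    }


@dataclass
class CohortSpec:
    """Sizes, rates and condition parameters of a synthetic cohort."""

    n_per_group: int = 30
    group_params: dict = field(default_factory=default_groups)
    duration_s: float = 1200.0
    fs: float = 1000.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        highest = max(hi for _, hi in CARRIER_BANDS.values())
        if self.fs <= 2 * highest:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest carrier "
                f"frequency ({highest} Hz)"
            )


# ---------------------------------------------------------------------------
# continuous signals


def one_over_f_noise(
    n: int, fs: float, exponent: float = 1.0, rms: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, scaled to ``rms``."""
    rng = rng or np.random.default_rng()
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n)
    return x * (rms / x.std())


def _burst_waveform(
    n: int, fs: float, bands: tuple[str, ...], band_scale: dict,
    rng: np.random.Generator, n_components: int = 3,
) -> np.ndarray:
    """Band-limited sinusoid mixture, unit peak amplitude, Hann-tapered edges."""
    t = np.arange(n) / fs
    w = np.zeros(n)
    for band in bands:
        lo, hi = CARRIER_BANDS[band]
        freqs = rng.uniform(lo, hi, size=n_components)
        phases = rng.uniform(0, 2 * np.pi, size=n_components)
        comp = np.sum(
            [np.sin(2 * np.pi * f0 * t + p0) for f0, p0 in zip(freqs, phases)],
            axis=0,
        )
        w += band_scale.get(band, 1.0) * comp
    w /= np.abs(w).max()
    # flat-top envelope with Hann-shaped ramps: burst edges stay sharp enough
    # for boundary scoring while onset/offset remain click-free
    ramp_n = min(int(EDGE_RAMP_S * fs), n // 2)
    env = np.ones(n)
    if ramp_n > 0:
        hann = np.sin(0.5 * np.pi * np.arange(ramp_n) / ramp_n) ** 2
        env[:ramp_n] = hann
        env[-ramp_n:] = hann[::-1]
    return w * env


def _place_events(
    rng: np.random.Generator,
    duration_s: float,
    n_events: int,
    duration_range: tuple[float, float],
    min_gap_s: float = MIN_EVENT_GAP_S,
) -> list[tuple[float, float]]:
    """Non-overlapping event intervals via random gap allocation."""
    durations = rng.uniform(*duration_range, size=n_events)
    occupied = durations.sum() + min_gap_s * (n_events + 1)
    free = duration_s - occupied
    if free < 0:
        raise ValueError(
            f"cannot place {n_events} events of {duration_range} s with "
            f"{min_gap_s} s gaps in {duration_s} s"
        )
    extra = rng.dirichlet(np.ones(n_events + 1)) * free
    starts = []
    t = 0.0
    for i, d in enumerate(durations):
        t += min_gap_s + extra[i]
        starts.append(t)
        t += d
    return [(s, s + d) for s, d in zip(starts, durations)]


def gen_recording(
    spec: CohortSpec,
    event_rate_per_min: float = 4.0,
    duration_range: tuple[float, float] = (1.5, 4.0),
    n_channels: int = 4,
    group: str = "control",
    noise_rms_uv: float = 12.0,
    peak_amplitude_range_uv: tuple[float, float] = (60.0, 120.0),
    carrier_bands: tuple[str, ...] = ("theta", "beta"),
    background_exponent: float = 1.0,
    seed: int | None = None,
    animal_id: str = "animal0",
) -> tuple[Recording, EventTruth]:
    """Discontinuous LFP recording with stored event truth.

    Every channel shares the event times (volume conduction within the
    small neonatal tissue volume) with independent 1/f background noise.
    ``event_rate_per_min = 0`` yields stationary noise and an empty truth.
    """
    if duration_range[0] <= 1.0:
        raise ValueError(
            "event durations must exceed 1 s to be detectable under the "
            ">1 s inclusion rule"
        )
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    n_events = int(round(event_rate_per_min * spec.duration_s / 60.0))
    intervals = (
        _place_events(rng, spec.duration_s, n_events, duration_range)
        if n_events
        else []
    )
    params = spec.group_params[group]
    events = []
    samples = np.stack(
        [
            one_over_f_noise(n, spec.fs, background_exponent, noise_rms_uv, rng)
            for _ in range(n_channels)
        ]
    )
    for t0, t1 in intervals:
        i0, i1 = int(round(t0 * spec.fs)), int(round(t1 * spec.fs))
        amp = rng.uniform(*peak_amplitude_range_uv)
        burst = amp * _burst_waveform(
            i1 - i0, spec.fs, carrier_bands, params.band_power_scale, rng
        )
        samples[:, i0:i1] += burst[None, :]
        events.append(
            TruthEvent(
                start_s=t0, stop_s=t1, carrier_bands=carrier_bands,
                peak_amplitude=amp,
            )
        )
    channels = [
        Channel(
            id=f"ch{i}",
            layer="superficial" if i < n_channels / 2 else "deep",
            depth_um=100.0 * (i + 1),
        )
        for i in range(n_channels)
    ]
    rec = Recording(
        samples=samples, fs=spec.fs, channels=channels,
        animal_id=animal_id, condition=group,
    )
    return rec, EventTruth(events=events, background_exponent=background_exponent)


# ---------------------------------------------------------------------------
# spike trains


def gen_spiketrain(
    truth: EventTruth,
    log10_rate: float,
    kappa: float | dict,
    duration_s: float,
    fs: float = 1000.0,
    lfp: np.ndarray | None = None,
    band: str = "beta",
    event_rate_factor: float = 5.0,
    seed: int | None = None,
    unit_id: str = "site0",
) -> SpikeSeries:
    """Inhomogeneous Poisson spike train, optionally phase-locked.

    The rate is elevated ``event_rate_factor``-fold during truth events
    while the overall mean rate stays at ``10**log10_rate``. With
    ``kappa > 0`` and an LFP trace given, spikes inside events are thinned
    against the instantaneous carrier-band phase with acceptance
    proportional to the von Mises density, so spike phases follow a von
    Mises law with concentration kappa and the marginal rate is unchanged.
    """
    if isinstance(kappa, dict):
        kappa = float(kappa.get(band, 0.0))
    if kappa < 0 or not np.isfinite(kappa):
        raise ValueError("kappa must be finite and non-negative")
    target_rate = 10.0**log10_rate
    if target_rate <= 0:
        raise ValueError("rate must be positive")
    locked = kappa > 0 and lfp is not None
    if locked and not truth.events:
        raise ValueError("event-locked spiking requested but truth is empty")
    rng = np.random.default_rng(seed)
    intervals = [(e.start_s, e.stop_s) for e in truth.events]
    active = sum(t1 - t0 for t0, t1 in intervals) / duration_s
    # solve base rate so the overall mean equals the target
    base = target_rate / (1.0 - active + event_rate_factor * active)
    r_in = event_rate_factor * base

    phase = None
    if locked:
        from .coupling import band_phase

        phase = band_phase(np.asarray(lfp, dtype=float), fs, CARRIER_BANDS[band])

    def _homogeneous(t0: float, t1: float, rate: float) -> np.ndarray:
        n_exp = rng.poisson(rate * (t1 - t0))
        return np.sort(rng.uniform(t0, t1, size=n_exp))

    spikes: list[np.ndarray] = []
    cursor = 0.0
    for t0, t1 in intervals + [(duration_s, duration_s)]:
        if t0 > cursor:
            spikes.append(_homogeneous(cursor, t0, base))
        if t1 > t0:
            if locked:
                # candidates at r_in * max(2*pi*f_vM); accept with
                # exp(kappa*(cos(phi) - 1)) -> marginal rate is exactly r_in
                boost = float(np.exp(kappa) / i0(kappa))
                cand = _homogeneous(t0, t1, r_in * boost)
                idx = np.clip((cand * fs).round().astype(int), 0, len(phase) - 1)
                accept = rng.uniform(size=cand.size) < np.exp(
                    kappa * (np.cos(phase[idx]) - 1.0)
                )
                spikes.append(cand[accept])
            else:
                spikes.append(_homogeneous(t0, t1, r_in))
        cursor = max(cursor, t1)
    times = np.sort(np.concatenate(spikes)) if spikes else np.array([])
    return SpikeSeries(times_s=times, duration_s=duration_s, unit_id=unit_id)


def vonmises_phases(
    kappa: float, n: int, mu: float = 0.0, seed: int | None = None
) -> np.ndarray:
    """Direct von Mises phase sample (for estimator checks)."""
    rng = np.random.default_rng(seed)
    if kappa == 0:
        return rng.uniform(-np.pi, np.pi, size=n)
    return rng.vonmises(mu, kappa, size=n)


# ---------------------------------------------------------------------------
# optogenetic ramp sessions


def gen_ramp_session(
    spec: CohortSpec,
    mode: str = "tuned",
    n_trials: int = 30,
    preferred_isi_ms: float = 60.0,
    isi_jitter_ms: float = 4.0,
    untuned_rate: float = 2.0,
    baseline_rate: float = 0.5,
    evoked_band_hz: float = 25.0,
    evoked_amplitude_uv: float = 40.0,
    noise_rms_uv: float = 12.0,
    seed: int | None = None,
) -> tuple[Recording, SpikeSeries, list[StimEpoch]]:
    """Ramp light-stimulation session: 3-s ramps with evoked activity.

    During each ramp the LFP gains a beta-band oscillation whose amplitude
    grows linearly with the light power, and the firing rate rises above
    the pre-ramp baseline. In ``tuned`` mode during-ramp inter-spike
    intervals concentrate near the preferred ~60 ms interval (a ~16.7 Hz
    population rhythm); in ``untuned`` mode during-ramp firing is Poisson
    with no imposed ISI mode.
    """
    if mode not in ("tuned", "untuned"):
        raise ValueError("mode must be 'tuned' or 'untuned'")
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    fs = spec.fs
    pre_s, ramp_s, post_s = 2.0, 3.0, 2.0  # windows >= 1.5 s around the ramp
    trial_s = pre_s + ramp_s + post_s
    duration_s = n_trials * trial_s
    n = int(round(duration_s * fs))
    x = one_over_f_noise(n, fs, 1.0, noise_rms_uv, rng)
    epochs: list[StimEpoch] = []
    spike_times: list[float] = []
    for k in range(n_trials):
        onset = k * trial_s + pre_s
        offset = onset + ramp_s
        epochs.append(StimEpoch(ramp_onset_s=onset, ramp_offset_s=offset))
        i0, i1 = int(round(onset * fs)), int(round(offset * fs))
        t = np.arange(i1 - i0) / fs
        ramp_gain = t / ramp_s  # linearly increasing light power
        x[i0:i1] += (
            evoked_amplitude_uv
            * ramp_gain
            * np.sin(2 * np.pi * evoked_band_hz * t + rng.uniform(0, 2 * np.pi))
        )
        # baseline firing outside the ramp
        for a, b in ((onset - pre_s, onset), (offset, offset + post_s)):
            m = rng.poisson(baseline_rate * (b - a))
            spike_times.extend(rng.uniform(a, b, size=m))
        # during-ramp firing
        if mode == "tuned":
            t_sp = onset + rng.exponential(0.1)
            while t_sp < offset:
                spike_times.append(t_sp)
                t_sp += max(
                    rng.normal(preferred_isi_ms, isi_jitter_ms) / 1000.0, 0.002
                )
        else:
            m = rng.poisson(untuned_rate * ramp_s)
            spike_times.extend(rng.uniform(onset, offset, size=m))
    channels = [Channel(id="ch0", layer="superficial")]
    rec = Recording(samples=x[None, :], fs=fs, channels=channels)
    spikes = SpikeSeries(
        times_s=np.array(sorted(spike_times)), duration_s=duration_s
    )
    return rec, spikes, epochs


# ---------------------------------------------------------------------------
# feature cohorts

FEATURE_BASE = {
    "beta_power": 20.0,  # uV^2, superficial-layer oscillation beta power
    "gamma_power": 8.0,
    "log_firing_rate_sup": None,  # from group log10_rate_sup
    "st_beta": 0.3,  # spike-triggered relative power summaries
    "st_gamma": 0.2,
}


def _group_feature_means(params: GroupParams) -> np.ndarray:
    return np.array(
        [
            FEATURE_BASE["beta_power"] * params.band_power_scale["beta"],
            FEATURE_BASE["gamma_power"] * params.band_power_scale["gamma"],
            params.log10_rate_sup[0],
            FEATURE_BASE["st_beta"] * params.kappa["beta"] / 2.0,
            FEATURE_BASE["st_gamma"] * params.kappa["gamma"] / 1.5,
        ]
    )


def gen_feature_cohort(
    spec: CohortSpec,
    effect_scale: float = 1.0,
    groups: tuple[str, str] = ("control", "GE"),
    seed: int | None = None,
) -> FeatureTable:
    """Two-class per-animal feature cohort with scalable group separation.

    Features mirror the classifier inputs: beta/gamma oscillation power,
    superficial log10 firing rate, and spike-triggered relative power in
    beta and gamma. ``effect_scale`` multiplies each group mean's deviation
    from the grand mean; 0 gives identical group distributions.
    """
    if effect_scale < 0:
        raise ValueError("effect_scale must be >= 0")
    if spec.n_per_group < 2:
        raise ValueError("need n_per_group >= 2 for cross-validation")
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    means = {g: _group_feature_means(spec.group_params[g]) for g in groups}
    grand = np.mean([means[g] for g in groups], axis=0)
    names = list(FEATURE_BASE)
    rows, labels, ids = [], [], []
    sds = {
        g: np.r_[
            np.abs(grand[:2]) * 0.2,
            spec.group_params[g].log10_rate_sup[1] * 5,
            np.abs(grand[3:]) * 0.2,
        ]
        for g in groups
    }
    grand_sd = np.mean([sds[g] for g in groups], axis=0)
    for g in groups:
        mu = grand + effect_scale * (means[g] - grand)
        # heteroscedasticity is part of the effect: at effect_scale = 0 the
        # group distributions are identical, SDs included
        sd = grand_sd + effect_scale * (sds[g] - grand_sd)
        sd = np.abs(sd)
        for a in range(spec.n_per_group):
            rows.append(rng.normal(mu, np.maximum(sd, 1e-6)))
            labels.append(g)
            ids.append(f"{g}_{a}")
    data = pd.DataFrame(rows, index=ids, columns=names)
    return FeatureTable(data=data, labels=pd.Series(labels, index=ids))


# ---------------------------------------------------------------------------
# image stacks


def _rasterize_ellipsoid(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    semi_axes: tuple[float, float, float],
) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    az, ay, ax = semi_axes
    return (
        ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    ) <= 1.0


def gen_microglia_stack(
    n_cells: int = 5,
    n_puncta_inside: int = 8,
    n_puncta_outside: int = 5,
    shape: tuple[int, int, int] = (12, 400, 400),
    pixel_size_um: float = 0.103,
    z_step_um: float = 0.75,
    cell_semi_axes_px: tuple[float, float, float] = (3.5, 18.0, 14.0),
    punctum_semi_axes_px: tuple[float, float, float] = (2.2, 4.0, 4.0),
    min_cell_separation_px: float = 130.0,
    noise_sd: float = 0.02,
    seed: int | None = None,
    max_tries: int = 2000,
) -> tuple[np.ndarray, np.ndarray, ImageTruth]:
    """Two-channel synthetic stack: Iba-1-like cells and VGLUT1-like puncta.

    Cells are bright ellipsoids placed without touching each other or the
    borders; inside-puncta are rasterized fully within a host cell,
    outside-puncta away from every cell. Returns (iba_stack, vglut_stack,
    truth); both stacks are float in [0, ~1.1].
    """
    rng = np.random.default_rng(seed)
    iba = np.zeros(shape)
    vglut = np.zeros(shape)
    # xy margin of 60 px keeps every cell's 110x110 analysis ROI inside
    # the image; z margin just clears the stack faces
    margin = np.maximum(
        np.array(cell_semi_axes_px) + np.array([1.0, 4.0, 4.0]),
        np.array([0.0, 60.0, 60.0]),
    )
    if np.any(2 * margin >= np.array(shape)):
        raise ValueError("stack shape too small for the requested cell size")
    cell_centers: list[np.ndarray] = []
    cells: list[TruthCell] = []
    cell_masks: list[np.ndarray] = []
    # default separation keeps each cell alone in its 110x110 ROI
    min_sep = min_cell_separation_px
    # greedy random placement with full-layout restarts: a dead-end layout
    # (early cells blocking the rest) is simply redrawn
    for _restart in range(50):
        cell_centers, cells = [], []
        tries = 0
        while len(cells) < n_cells and tries <= max_tries:
            tries += 1
            c = np.array(
                [
                    rng.uniform(margin[0], shape[0] - margin[0]),
                    rng.uniform(margin[1], shape[1] - margin[1]),
                    rng.uniform(margin[2], shape[2] - margin[2]),
                ]
            )
            if any(
                np.linalg.norm((c - o)[1:]) < min_sep for o in cell_centers
            ):
                continue
            cell_centers.append(c)
            cells.append(
                TruthCell(
                    centroid_px=tuple(c),
                    semi_axes_px=cell_semi_axes_px,
                    branch_count=0,
                )
            )
        if len(cells) == n_cells:
            break
    else:
        raise ValueError("could not place cells without touching")
    cell_masks = []
    for c in cell_centers:
        mask = _rasterize_ellipsoid(shape, tuple(c), cell_semi_axes_px)
        iba[mask] = 1.0
        cell_masks.append(mask)
    puncta: list[TruthPunctum] = []

    def _add_punctum(inside_of: int | None) -> None:
        nonlocal vglut
        for _ in range(max_tries):
            if inside_of is not None:
                host = cell_centers[inside_of]
                # offset bounded by the per-axis slack between host and
                # punctum semi-axes; containment is re-checked on the raster
                slack = np.array(cell_semi_axes_px) - np.array(
                    punctum_semi_axes_px
                )
                off = rng.uniform(-0.6, 0.6, size=3) * slack
                c = host + off
            else:
                c = np.array(
                    [
                        rng.uniform(margin[0], shape[0] - margin[0]),
                        rng.uniform(margin[1], shape[1] - margin[1]),
                        rng.uniform(margin[2], shape[2] - margin[2]),
                    ]
                )
                if any(
                    np.linalg.norm((c - o)[1:]) < 1.5 * max(cell_semi_axes_px[1:])
                    for o in cell_centers
                ):
                    continue
            pmask = _rasterize_ellipsoid(shape, tuple(c), punctum_semi_axes_px)
            if inside_of is not None and not (
                pmask <= cell_masks[inside_of]
            ).all():
                continue
            min_p_sep = 2 * max(punctum_semi_axes_px[1:]) + 1
            if any(
                np.linalg.norm(np.array(p.centroid_px)[1:] - c[1:]) < min_p_sep
                for p in puncta
            ):
                continue
            # sharply peaked intensity profile (like a diffraction-limited
            # synaptic punctum): steep enough that small-radius rolling-ball
            # background subtraction preserves the core rather than
            # levelling the whole blob
            zz, yy, xx = np.nonzero(pmask)
            d = np.sqrt(
                ((zz - c[0]) / punctum_semi_axes_px[0]) ** 2
                + ((yy - c[1]) / punctum_semi_axes_px[1]) ** 2
                + ((xx - c[2]) / punctum_semi_axes_px[2]) ** 2
            )
            vglut[zz, yy, xx] = np.maximum(
                vglut[zz, yy, xx], np.exp(-3.0 * d**2)
            )
            puncta.append(
                TruthPunctum(
                    centroid_px=tuple(c),
                    volume_px=int(pmask.sum()),
                    inside_cell=inside_of,
                )
            )
            return
        raise ValueError("could not place a punctum with the requested layout")

    for i in range(n_puncta_inside):
        if not cells:
            raise ValueError("inside-puncta requested but no cells")
        _add_punctum(int(i % len(cells)))
    for _ in range(n_puncta_outside):
        _add_punctum(None)
    iba += rng.normal(0, noise_sd, size=shape)
    vglut += rng.normal(0, noise_sd, size=shape)
    return (
        np.clip(iba, 0, None),
        np.clip(vglut, 0, None),
        ImageTruth(cells=cells, puncta=puncta),
    )


# ---------------------------------------------------------------------------
# behavior


def gen_behavior(
    n_per_group: int,
    mean_dr: dict,
    noise_sd: float = 0.1,
    total_time_range_s: tuple[float, float] = (40.0, 80.0),
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-animal novel/familiar interaction times with known ratios.

    Each animal's discrimination ratio is drawn around its group mean and
    inverted exactly into interaction times: novel = T(1+dr)/2 and
    familiar = T(1-dr)/2, so the realized ratio equals the drawn dr.
    """
    for g, m in mean_dr.items():
        if not (-1.0 < m < 1.0):
            raise ValueError(f"mean_dr for {g} must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for g, m in mean_dr.items():
        dr = np.clip(
            rng.normal(m, noise_sd, size=n_per_group), -0.999, 0.999
        )
        total = rng.uniform(*total_time_range_s, size=n_per_group)
        for a in range(n_per_group):
            rows.append(
                {
                    "animal": f"{g}_{a}",
                    "group": g,
                    "t_novel_s": total[a] * (1 + dr[a]) / 2,
                    "t_familiar_s": total[a] * (1 - dr[a]) / 2,
                }
            )
    return pd.DataFrame(rows)
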