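"""File interfaces: HDF5 recordings, CSV tables, TIFF stacks.

Recording layout: ``/lfp`` (channels x samples, float32 uV), ``/fs``
(scalar Hz), ``/channels`` (table with id/layer/depth), ``/truth``
(JSON-encoded planted event times, present for synthetic recordings).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    Channel,
    EventTruth,
    OscillationEvent,
    Recording,
    SpikeSeries,
    TruthEvent,
)


def save_recording(
    path: str | Path, rec: Recording, truth: EventTruth | None = None
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=rec.samples.astype(np.float32))
        f.create_dataset("fs", data=float(rec.fs))
        ch = f.create_group("channels")
        ch.create_dataset(
            "id", data=np.array([c.id for c in rec.channels], dtype="S")
        )
        ch.create_dataset(
            "layer", data=np.array([c.layer for c in rec.channels], dtype="S")
        )
        ch.create_dataset(
            "depth_um", data=np.array([c.depth_um for c in rec.channels])
        )
        f.attrs["animal_id"] = rec.animal_id
        f.attrs["condition"] = rec.condition
        if truth is not None:
            payload = {
                "background_exponent": truth.background_exponent,
                "events": [
                    {
                        "start_s": e.start_s,
                        "stop_s": e.stop_s,
                        "carrier_bands": list(e.carrier_bands),
                        "peak_amplitude": e.peak_amplitude,
                    }
                    for e in truth.events
                ],
            }
            f.create_dataset("truth", data=json.dumps(payload))


def load_recording(path: str | Path) -> tuple[Recording, EventTruth | None]:
    with h5py.File(path, "r") as f:
        samples = f["lfp"][...]
        fs = float(f["fs"][()])
        channels = [
            Channel(id=i.decode(), layer=l.decode(), depth_um=float(d))
            for i, l, d in zip(
                f["channels/id"][...],
                f["channels/layer"][...],
                f["channels/depth_um"][...],
            )
        ]
        rec = Recording(
            samples=samples,
            fs=fs,
            channels=channels,
            animal_id=f.attrs.get("animal_id", "animal0"),
            condition=f.attrs.get("condition", "control"),
        )
        truth = None
        if "truth" in f:
            payload = json.loads(f["truth"][()])
            truth = EventTruth(
                events=[
                    TruthEvent(
                        start_s=e["start_s"],
                        stop_s=e["stop_s"],
                        carrier_bands=tuple(e["carrier_bands"]),
                        peak_amplitude=e["peak_amplitude"],
                    )
                    for e in payload["events"]
                ],
                background_exponent=payload["background_exponent"],
            )
    return rec, truth


def save_spikes(path: str | Path, spikes: SpikeSeries) -> None:
    pd.DataFrame(
        {"unit_id": spikes.unit_id, "time_s": spikes.times_s}
    ).to_csv(path, index=False)


def load_spikes(path: str | Path, duration_s: float) -> SpikeSeries:
    df = pd.read_csv(path)
    unit = str(df["unit_id"].iloc[0]) if len(df) else "site0"
    return SpikeSeries(
        times_s=df["time_s"].to_numpy(), duration_s=duration_s, unit_id=unit
    )


def events_to_frame(events: list[OscillationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "channel": e.channel,
                "start_s": e.start_s,
                "stop_s": e.stop_s,
                "duration_s": e.duration_s,
                "peak_amplitude_uv": e.peak_amplitude,
                "mean_rms_uv": e.mean_rms,
            }
            for e in events
        ]
    )
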