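"""HDF5 serialization for the shared pipeline containers.

Every time series is stored as a dataset with a ``rate`` attribute; a
synthetic session is a group tree holding its envelope streams, recording,
ground-truth kernels and configuration, sufficient to reload the session
and re-score any analysis stage from file alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np

from .containers import (
    AuditorySpectrogram,
    EchoSpec,
    EnvelopeTrack,
    Recording,
)
from .synth import SynthConfig, SynthSession

__all__ = [
    "save_envelope",
    "load_envelope",
    "save_recording",
    "load_recording",
    "save_spectrogram",
    "load_spectrogram",
    "save_session",
    "load_session",
]


def save_envelope(group: h5py.Group, name: str, env: EnvelopeTrack) -> None:
    ds = group.create_dataset(name, data=env.values)
    ds.attrs["rate"] = env.rate


def load_envelope(group: h5py.Group, name: str) -> EnvelopeTrack:
    ds = group[name]
    return EnvelopeTrack(ds[()], float(ds.attrs["rate"]))


def save_recording(group: h5py.Group, name: str, rec: Recording) -> None:
    g = group.create_group(name)
    g.create_dataset("data", data=rec.data)
    g.attrs["rate"] = rec.rate
    g.attrs["provenance"] = rec.provenance
    if rec.labels:
        g.create_dataset("labels", data=np.array(rec.labels, dtype="S"))


def load_recording(group: h5py.Group, name: str) -> Recording:
    g = group[name]
    labels = tuple(x.decode() for x in g["labels"][()]) if "labels" in g else ()
    return Recording(
        g["data"][()], float(g.attrs["rate"]), labels=labels,
        provenance=str(g.attrs.get("provenance", "unknown")),
    )


def save_spectrogram(group: h5py.Group, name: str, spec: AuditorySpectrogram) -> None:
    g = group.create_group(name)
    g.create_dataset("values", data=spec.values)
    g.create_dataset("center_frequencies", data=spec.center_frequencies)
    g.attrs["frame_rate"] = spec.frame_rate


def load_spectrogram(group: h5py.Group, name: str) -> AuditorySpectrogram:
    g = group[name]
    return AuditorySpectrogram(
        g["values"][()], g["center_frequencies"][()], float(g.attrs["frame_rate"])
    )


def save_session(path, session: SynthSession) -> None:
    with h5py.File(path, "w") as fh:
        for name in ("direct", "echo", "mixture"):
            save_envelope(fh, name, getattr(session, name))
        save_recording(fh, "recording", session.recording)
        kg = fh.create_group("kernels")
        for stream, kern in session.kernels.items():
            kg.create_dataset(stream, data=kern)
        fh.create_dataset("gains", data=session.gains)
        fh.attrs["regime"] = session.regime
        fh.attrs["echo_amplitude"] = session.echo_spec.amplitude
        fh.create_dataset("echo_schedule", data=np.array(session.echo_spec.schedule))
        fh.attrs["config"] = json.dumps(asdict(session.config))


def load_session(path) -> SynthSession:
    with h5py.File(path, "r") as fh:
        cfg_dict = json.loads(fh.attrs["config"])
        for key in ("voiced_range_s", "pause_range_s"):
            cfg_dict[key] = tuple(cfg_dict[key])
        schedule = tuple((float(a), float(b)) for a, b in fh["echo_schedule"][()])
        return SynthSession(
            direct=load_envelope(fh, "direct"),
            echo=load_envelope(fh, "echo"),
            mixture=load_envelope(fh, "mixture"),
            recording=load_recording(fh, "recording"),
            regime=str(fh.attrs["regime"]),
            kernels={k: fh["kernels"][k][()] for k in fh["kernels"]},
            gains=fh["gains"][()],
            echo_spec=EchoSpec(float(fh.attrs["echo_amplitude"]), schedule),
            config=SynthConfig(**cfg_dict),
        )
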