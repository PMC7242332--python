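"""Four-channel EOG recordings with trial/phase markers.

The recording montage mirrors a standard periorbital EOG setup: SO1 and
IO1 (superior/inferior orbital) capture vertical eye movement, LO1 and
LO2 (lateral orbital, left/right) capture horizontal eye movement.  All
series are in microvolts at a fixed sampling rate (500 Hz by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical channel order.
CHANNELS = ("SO1", "IO1", "LO1", "LO2")

#: Valid trial phase tags, in temporal order within a trial.
PHASES = ("baseline", "stimulus", "response", "feedback")


@dataclass(frozen=True)
class Marker:
    """A phase-onset marker: sample index, owning trial, phase tag."""

    sample: int
    trial_id: int
    phase: str

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase tag {self.phase!r}")
        if self.sample < 0:
            raise ValueError("marker sample index must be >= 0")


@dataclass
class EOGRecording:
    """Multichannel EOG time series (µV) with phase markers.

    Parameters
    ----------
    sample_rate : float
        Sampling frequency in Hz, > 0.
    data : dict[str, np.ndarray]
        One 1-D float array per channel in :data:`CHANNELS`; all equal
        length, amplitudes in microvolts.
    markers : list[Marker]
        Phase-onset markers; within each trial the sample indices must be
        strictly increasing.
    """

    sample_rate: float
    data: dict[str, np.ndarray]
    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        missing = [c for c in CHANNELS if c not in self.data]
        if missing:
            raise ValueError(f"missing channels: {missing}")
        lengths = {len(np.asarray(v)) for v in self.data.values()}
        if len(lengths) != 1:
            raise ValueError("all channel series must have equal length")
        self.data = {c: np.asarray(self.data[c], dtype=float) for c in CHANNELS}
        by_trial: dict[int, int] = {}
        for m in self.markers:
            prev = by_trial.get(m.trial_id)
            if prev is not None and m.sample <= prev:
                raise ValueError(
                    f"marker indices not strictly increasing in trial {m.trial_id}"
                )
            by_trial[m.trial_id] = m.sample

    @property
    def n_samples(self) -> int:
        return len(self.data["LO1"])

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def trial_ids(self) -> list[int]:
        seen: dict[int, None] = {}
        for m in self.markers:
            seen.setdefault(m.trial_id)
        return list(seen)

    def channel(self, name: str) -> np.ndarray:
        return self.data[name]

    def phase_bounds(self, trial_id: int, phase: str) -> tuple[int, int]:
        """Return [start, stop) sample bounds of ``phase`` in ``trial_id``.

        The phase extends from its marker to the next marker of any trial,
        or to the end of the recording.
        """
        if phase not in PHASES:
            raise ValueError(f"unknown phase tag {phase!r}")
        ordered = sorted(self.markers, key=lambda m: m.sample)
        for i, m in enumerate(ordered):
            if m.trial_id == trial_id and m.phase == phase:
                stop = ordered[i + 1].sample if i + 1 < len(ordered) else self.n_samples
                return m.sample, stop
        raise KeyError(f"no {phase!r} marker for trial {trial_id}")

    def response_window(self, trial_id: int) -> dict[str, np.ndarray]:
        """Slice all channels to the response phase of one trial."""
        start, stop = self.phase_bounds(trial_id, "response")
        return {c: self.data[c][start:stop] for c in CHANNELS}

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the recording as CSV (time_s, SO1, IO1, LO1, LO2) plus a
        ``<path>.markers.json`` sidecar with sample-indexed markers."""
        path = Path(path)
        t = np.arange(self.n_samples) / self.sample_rate
        df = pd.DataFrame({"time_s": t, **{c: self.data[c] for c in CHANNELS}})
        df.to_csv(path, index=False)
        sidecar = {
            "sample_rate": self.sample_rate,
            "markers": [
                {"sample": m.sample, "trial_id": m.trial_id, "phase": m.phase}
                for m in self.markers
            ],
        }
        Path(str(path) + ".markers.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "EOGRecording":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar_path = Path(str(path) + ".markers.json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            rate = float(sidecar["sample_rate"])
            markers = [
                Marker(int(m["sample"]), int(m["trial_id"]), m["phase"])
                for m in sidecar["markers"]
            ]
        else:
            dt = np.diff(df["time_s"].to_numpy())
            rate = 1.0 / float(np.median(dt))
            markers = []
        data = {c: df[c].to_numpy(dtype=float) for c in CHANNELS}
        return cls(sample_rate=rate, data=data, markers=markers)


def read_brainvision(vhdr_path: str | Path,
                     channel_map: dict[str, str] | None = None) -> EOGRecording:
    """Load a BrainVision (.vhdr/.eeg/.vmrk) recording as an EOGRecording.

    Intended for the publicly deposited clinical recordings; requires
    ``mne`` (optional extra).  ``channel_map`` maps recorded channel names
    to the canonical SO1/IO1/LO1/LO2 if they differ.  Amplitudes are
    converted from volts (mne convention) to microvolts.  No markers are
    attached; trial structure in such files lives in annotations, which
    are session-specific.
    """
    import mne  # deferred: optional dependency

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    channel_map = channel_map or {c: c for c in CHANNELS}
    data = {}
    for target, source in channel_map.items():
        if source not in raw.ch_names:
            raise KeyError(f"channel {source!r} not in recording")
        data[target] = raw.get_data(picks=[source])[0] * 1e6
    return EOGRecording(sample_rate=float(raw.info["sfreq"]), data=data)


def concatenate(recordings: Sequence[EOGRecording]) -> EOGRecording:
    """Concatenate recordings in time, shifting marker sample indices."""
    if not recordings:
        raise ValueError("nothing to concatenate")
    rate = recordings[0].sample_rate
    if any(r.sample_rate != rate for r in recordings):
        raise ValueError("sample rates differ")
    data = {c: np.concatenate([r.data[c] for r in recordings]) for c in CHANNELS}
    markers: list[Marker] = []
    offset = 0
    for r in recordings:
        markers.extend(Marker(m.sample + offset, m.trial_id, m.phase) for m in r.markers)
        offset += r.n_samples
    return EOGRecording(sample_rate=rate, data=data, markers=markers)
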