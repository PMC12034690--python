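"""Shared data containers for LDS-test recordings.

Times are stored in seconds for spike data and milliseconds for ABR data.
Stimulus onset defines t = 0 of each ABR sweep; sample indexing is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EpochSchedule:
    """Epoch layout of one LDS-test run.

    ``epochs`` maps epoch name -> (start_s, end_s). The canonical epochs are
    ``PRE_silence``, ``LDS`` and ``POST_silence``; POST_silence starts at LDS
    offset so afterdischarge onsets are referenced to it directly.
    ``pre_train_onsets`` / ``post_train_onsets`` hold pip-onset times grouped
    by train (6 trains on each side of the LDS).
    """

    epochs: dict[str, tuple[float, float]]
    pre_train_onsets: list[np.ndarray]
    post_train_onsets: list[np.ndarray]
    pip_rate_hz: float

    @property
    def lds_offset_s(self) -> float:
        return self.epochs["LDS"][1]

    @property
    def pip_cycle_s(self) -> float:
        return 1.0 / self.pip_rate_hz

    def n_pips(self, side: str) -> int:
        trains = self.pre_train_onsets if side == "pre" else self.post_train_onsets
        return int(sum(len(t) for t in trains))

    def to_dict(self) -> dict:
        return {
            "epochs": {k: [float(a), float(b)] for k, (a, b) in self.epochs.items()},
            "pre_train_onsets": [list(map(float, t)) for t in self.pre_train_onsets],
            "post_train_onsets": [list(map(float, t)) for t in self.post_train_onsets],
            "pip_rate_hz": float(self.pip_rate_hz),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EpochSchedule":
        return cls(
            epochs={k: (float(a), float(b)) for k, (a, b) in d["epochs"].items()},
            pre_train_onsets=[np.asarray(t, float) for t in d["pre_train_onsets"]],
            post_train_onsets=[np.asarray(t, float) for t in d["post_train_onsets"]],
            pip_rate_hz=float(d["pip_rate_hz"]),
        )


@dataclass
class SpikeChannelRecording:
    """Spike times of one electrode channel plus the run's epoch schedule."""

    channel_id: int
    spike_times_s: np.ndarray
    schedule: EpochSchedule

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.spike_times_s.size and np.any(np.diff(self.spike_times_s) < 0):
            raise ValueError(
                f"channel {self.channel_id}: spike_times_s must be sorted ascending"
            )
        if self.spike_times_s.size and self.spike_times_s[0] < 0:
            raise ValueError(f"channel {self.channel_id}: spike times must be >= 0")


@dataclass
class ABRSweepSet:
    """Stimulus-aligned single-sweep voltages for one ear/frequency/condition.

    ``sweeps`` is (n_sweeps, n_samples) in µV; sample 0 is stimulus onset.
    """

    sweeps: np.ndarray
    sample_rate: float
    condition: str  # "PRE" or "POST"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        if self.sweeps.ndim != 2:
            raise ValueError("sweeps must be a 2-D (n_sweeps x n_samples) matrix")
        if self.sweeps.shape[0] < 2:
            raise ValueError("need at least 2 sweeps")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.sweeps.shape[1]) / self.sample_rate * 1000.0


@dataclass
class ABRWaveform:
    """One averaged ABR waveform (time in ms, voltage in µV)."""

    time_ms: np.ndarray
    voltage_uv: np.ndarray
    sample_rate: float
    filter_band_hz: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage_uv = np.asarray(self.voltage_uv, dtype=float)
        if self.time_ms.shape != self.voltage_uv.shape:
            raise ValueError("time and voltage must have equal length")
        if self.time_ms.size > 1 and np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class AASessionSet:
    """Active-avoidance trial outcomes for one animal.

    ``trials`` has columns ``session``, ``frequency_khz``, ``avoided`` (0/1).
    """

    trials: pd.DataFrame
    animal_id: str = ""

    def __post_init__(self) -> None:
        required = {"session", "frequency_khz", "avoided"}
        missing = required - set(self.trials.columns)
        if missing:
            raise ValueError(f"trials missing columns: {sorted(missing)}")

    @property
    def sessions(self) -> np.ndarray:
        return np.sort(self.trials["session"].unique())

    @property
    def frequencies(self) -> np.ndarray:
        return np.sort(self.trials["frequency_khz"].unique())
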