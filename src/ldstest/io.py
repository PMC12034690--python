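"""Text file formats and run configuration.

All formats are plain text: CSV with a mandatory header (comma, UTF-8) plus
JSON sidecars for metadata. Floats are written with full decimal precision so
a write→read round trip reproduces values exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ldstest.core import AASessionSet, ABRSweepSet, EpochSchedule, SpikeChannelRecording

__all__ = [
    "RunConfig",
    "write_spike_csv", "read_spike_csv",
    "write_sweeps", "read_sweeps",
    "write_aa_csv", "read_aa_csv",
]

FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Every analysis switch with its documented default.

    The defaults implement the readings documented in each module; the hash
    of the full configuration is recorded in outputs so any switch change is
    visible downstream.
    """

    seed: int = 0
    ci_mode: str = "prediction_band"       # afterdischarge band reading
    psth_bin_width_ms: float = 0.5
    rate_bin_width_s: float = 2.5
    onset_window_s: float = 30.0
    min_valid_latency_ms: float = 3.4
    grand_mean_excludes_dip: bool = False  # AA grand-mean reading
    bootstrap_cross_mode: str = "half"     # PRE:POST split reading
    bootstrap_n_iter: int = 100
    window_ms: tuple[float, float] = (2.0, 14.0)
    filter_band_hz: tuple[float, float] = (500.0, 3000.0)
    ss_type: int = 2                       # two-way ANOVA sums of squares
    peak_prominence_frac: float = 0.05
    alpha: float = 0.05

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["config_hash"] = self.config_hash()
        return json.dumps(d, indent=2, default=str)


# ---------------------------------------------------------------------------
# spike events: CSV (channel_id, spike_time_s) + JSON epoch schedule sidecar
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_spike_csv(recordings: list[SpikeChannelRecording], path) -> None:
    path = Path(path)
    rows = [(rec.channel_id, t) for rec in recordings for t in rec.spike_times_s]
    df = pd.DataFrame(rows, columns=["channel_id", "spike_time_s"])
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    sched = recordings[0].schedule
    _sidecar(path).write_text(json.dumps(sched.to_dict()))


def read_spike_csv(path) -> list[SpikeChannelRecording]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"channel_id", "spike_time_s"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    sched = EpochSchedule.from_dict(json.loads(_sidecar(path).read_text()))
    recs = []
    for ch, sub in df.groupby("channel_id", sort=True):
        times = sub["spike_time_s"].to_numpy()
        bad = np.nonzero(np.diff(times) < 0)[0]
        if bad.size:
            row = sub.index[bad[0] + 1] + 2  # 1-based, after header
            raise ValueError(
                f"{path}: spike times not sorted for channel {ch} at row {row}")
        recs.append(SpikeChannelRecording(int(ch), times, sched))
    return recs


# ---------------------------------------------------------------------------
# ABR sweeps: CSV matrix (rows = sweeps) + JSON metadata sidecar
# ---------------------------------------------------------------------------

def write_sweeps(sweeps: ABRSweepSet, path) -> None:
    path = Path(path)
    np.savetxt(path, sweeps.sweeps, delimiter=",", fmt=FLOAT_FMT)
    meta = {
        "sample_rate": sweeps.sample_rate,
        "condition": sweeps.condition,
        "n_sweeps": sweeps.n_sweeps,
        "n_samples": sweeps.sweeps.shape[1],
        **sweeps.metadata,
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_sweeps(path) -> ABRSweepSet:
    path = Path(path)
    mat = np.loadtxt(path, delimiter=",", ndmin=2)
    meta = json.loads(_sidecar(path).read_text())
    return ABRSweepSet(
        sweeps=mat,
        sample_rate=float(meta.pop("sample_rate")),
        condition=str(meta.pop("condition")),
        metadata={k: v for k, v in meta.items() if k not in ("n_sweeps", "n_samples")},
    )


# ---------------------------------------------------------------------------
# active-avoidance trials: CSV (session, frequency_khz, avoided)
# ---------------------------------------------------------------------------

def write_aa_csv(sessions: AASessionSet, path) -> None:
    sessions.trials.to_csv(Path(path), index=False, float_format=FLOAT_FMT)


def read_aa_csv(path, animal_id: str = "") -> AASessionSet:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    missing = {"session", "frequency_khz", "avoided"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if not df["avoided"].isin((0, 1)).all():
        row = df.index[~df["avoided"].isin((0, 1))][0] + 2
        raise ValueError(f"{path}: avoided must be 0/1 (row {row})")
    return AASessionSet(trials=df, animal_id=animal_id)
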