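#!/usr/bin/env python
"""Generate one example synthetic dataset of each kind and exercise the file
formats end to end.

Writes a small multi-channel ICC spike recording, an ABR PRE/POST sweep pair
and an active-avoidance trial table under scratch/example_data/, reads each
back, and reports what was produced. Raw data live under scratch/ (they are
regenerable from the seed); only summaries belong in results/.
"""

import argparse
import json
from pathlib import Path

from ldstest import io, synth

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    out = ROOT / "scratch" / "example_data"
    out.mkdir(parents=True, exist_ok=True)

    spikes = synth.gen_spike_dataset(synth.SpikeSimConfig(
        n_channels=8, seed=seed,
        afterdischarge=tuple(synth.AfterdischargeSpec(i < 2) for i in range(8))))
    io.write_spike_csv(spikes, out / "icc_spikes.csv")

    pre, post = synth.gen_abr_dataset(synth.ABRSimConfig(
        n_sweeps=64, noise_sd_uv=1.0, seed=seed,
        metadata={"ear": "left", "frequency_khz": 16.0}))
    io.write_sweeps(pre, out / "abr_pre.csv")
    io.write_sweeps(post, out / "abr_post.csv")

    aa = synth.gen_aa_sessions(synth.AASimConfig(seed=seed), animal_id="example")
    io.write_aa_csv(aa, out / "aa_trials.csv")

    # round-trip sanity: everything read back intact
    back = io.read_spike_csv(out / "icc_spikes.csv")
    assert len(back) == 8
    assert io.read_sweeps(out / "abr_pre.csv").n_sweeps == 64
    assert len(io.read_aa_csv(out / "aa_trials.csv").trials) == len(aa.trials)

    inventory = {p.name: p.stat().st_size for p in sorted(out.iterdir())}
    print(json.dumps(inventory, indent=2))
    n_spikes = sum(len(r.spike_times_s) for r in spikes)
    print(f"ICC recording: 8 channels, {n_spikes} spikes, "
          f"2 channels with a planted afterdischarge")
    print(f"ABR pair: {pre.n_sweeps} sweeps x {pre.sweeps.shape[1]} samples per condition")
    print(f"AA table: {len(aa.trials)} trials over "
          f"{aa.trials['frequency_khz'].nunique()} frequencies x 5 sessions")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
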