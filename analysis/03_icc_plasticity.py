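#!/usr/bin/env python
"""Tone-evoked plasticity (delta spike rate, PRE vs. T1) across cohorts.

Simulates responsive ICC channels for tinnitus, non-tinnitus and control
cohorts with planted post-LDS suppression of the tone response: stronger in
the non-tinnitus cohort (the study's central plasticity finding is that
sound-driven activity in non-tinnitus animals is suppressed after the LDS
while tinnitus animals look like controls). Runs the full per-channel
pipeline (PSTH, rates, onset/duration, validity, delta), then a one-way
ANOVA over cohort deltas with Scheffé post-hoc contrasts.
"""

import argparse
from pathlib import Path

import pandas as pd

from ldstest.pipeline import analyze_spike_dataset
from ldstest.stats import one_way_anova, scheffe_posthoc
from ldstest.synth import SpikeSimConfig, ToneResponseSpec, gen_spike_dataset

ROOT = Path(__file__).resolve().parents[1]

# cohort -> (n_mice, planted T1 scale): delta approx (s-1)/(s+1) per channel
DESIGN = {
    "tinnitus": (14, 0.95),
    "non_tinnitus": (8, 0.55),
    "control": (6, 0.95),
}
CHANNELS_PER_MOUSE = 32


def main(seed: int = 1) -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    tables = {}
    for gi, (cohort, (n_mice, scale)) in enumerate(DESIGN.items()):
        cfg = SpikeSimConfig(
            n_channels=n_mice * CHANNELS_PER_MOUSE, spontaneous_rate=3.0,
            tone_response=ToneResponseSpec(0.008, 0.012, 150.0, post_scale=scale),
            seed=seed + 10 * gi)
        table = analyze_spike_dataset(gen_spike_dataset(cfg))
        table.insert(0, "cohort", cohort)
        tables[cohort] = table

    full = pd.concat(tables.values(), ignore_index=True)
    usable = full[full["responsive"] & full["valid"]]
    summary = (usable.groupby("cohort")["delta"]
               .agg(["count", "mean", "std"]).round(4).reset_index())
    summary.to_csv(results / "icc_plasticity_summary.csv", index=False)

    groups = [usable.loc[usable["cohort"] == c, "delta"].to_numpy()
              for c in DESIGN]
    anova = one_way_anova(*groups)
    posthoc = scheffe_posthoc(groups, anova, labels=list(DESIGN))
    posthoc.to_csv(results / "icc_plasticity_scheffe.csv", index=False)

    print(summary.to_string(index=False))
    print(f"\nOne-way ANOVA over cohort deltas: F = {anova.statistic:.2f}, "
          f"df = {anova.df}, p = {anova.p_value:.3g}")
    print(posthoc.round(4).to_string(index=False))
    print("\nExpected pattern: non-tinnitus delta well below zero (suppressed), "
          "tinnitus ~ control near the planted -0.026; Scheffé separates "
          "non-tinnitus from both.")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
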