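#!/usr/bin/env python
"""ABR waveform metrics per cohort ear: wave picking, amplitudes, latencies,
central-gain ratios and per-wave delta after the LDS.

Simulates one tone-evoked ABR recording (PRE/POST sweep pair) for each cohort
ear: tinnitus exposed/unexposed (TE, TU), non-tinnitus exposed/unexposed
(NTE, NTU) and control (C). Sound exposure is planted as a reduced wave-I
amplitude (peripheral damage) with wave V intact (central compensation), and
the LDS effect as post-LDS suppression of the late waves, strongest in the
non-tinnitus exposed ear. Averages and filters sweeps, picks waves I-VI,
tabulates metrics, and demonstrates the threshold midpoint rule.
"""

import argparse
from pathlib import Path

import pandas as pd

from ldstest.abr import threshold_midpoint
from ldstest.io import RunConfig
from ldstest.pipeline import analyze_abr_pair, wave_metrics_frame
from ldstest.synth import (
    ABRSimConfig,
    DEFAULT_WAVE_TEMPLATE,
    PostModifier,
    WaveComponent,
    gen_abr_dataset,
)

ROOT = Path(__file__).resolve().parents[1]

# cohort ear -> (wave-I amplitude scale PRE, post-LDS late-wave scale)
DESIGN = {
    "TE": (0.55, 0.80),
    "TU": (0.70, 0.85),
    "NTE": (0.55, 0.60),
    "NTU": (0.75, 0.85),
    "C": (1.00, 0.85),
}


def cohort_config(ear: str, seed: int) -> ABRSimConfig:
    wave1_scale, late_scale = DESIGN[ear]
    template = list(DEFAULT_WAVE_TEMPLATE)
    template[0] = WaveComponent(template[0].latency_ms,
                                template[0].amplitude_uv * wave1_scale,
                                template[0].width_ms)
    mods = tuple(PostModifier(late_scale if i >= 3 else 1.0) for i in range(6))
    return ABRSimConfig(n_sweeps=1266, noise_sd_uv=1.0,
                        wave_template=tuple(template), post_modifiers=mods,
                        seed=seed, metadata={"ear": ear, "frequency_khz": 16.0})


def main(seed: int = 1) -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    config = RunConfig(seed=seed, bootstrap_n_iter=50)

    frames = []
    ratio_rows = []
    for ei, ear in enumerate(DESIGN):
        pre, post = gen_abr_dataset(cohort_config(ear, seed + ei))
        res = analyze_abr_pair(pre, post, config)
        frames.append(wave_metrics_frame(res, ear=ear))
        m = res["metrics"]
        ratio_rows.append({
            "ear": ear,
            "v_over_i_pre": m.ratios_pre["V/I"],
            "v_over_i_post": m.ratios_post["V/I"],
            "i_v_latency_pre_ms": m.interwave_pre_ms["I-V"],
            "i_vi_latency_pre_ms": m.interwave_pre_ms["I-VI"],
        })

    waves = pd.concat(frames, ignore_index=True)
    waves.to_csv(results / "abr_wave_metrics.csv", index=False)
    ratios = pd.DataFrame(ratio_rows).round(3)
    ratios.to_csv(results / "abr_ratios.csv", index=False)

    print(waves.round(3).to_string(index=False))
    print()
    print(ratios.to_string(index=False))

    # threshold midpoint rule on an ascending 5 dB series
    thr = threshold_midpoint([20, 25, 30, 35, 40, 45],
                             [False, False, False, True, True, True])
    print(f"\nThreshold midpoint example (first detected 35 dB): "
          f"{thr.threshold_db} dB SPL (censored: {thr.censored})")
    print("Expected pattern: exposed ears show reduced wave-I amplitude with "
          "preserved wave V (raised V/I ratio = central gain); NTE shows the "
          "most negative late-wave deltas.")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
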