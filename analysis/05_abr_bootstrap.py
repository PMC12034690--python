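#!/usr/bin/env python
"""Split-half bootstrap correlation of PRE/POST ABR waveforms per cohort ear.

Simulates an ABR_LDS recording per cohort ear with a planted post-LDS
wave-V suppression that is strongest in the non-tinnitus exposed ear,
intermediate in the tinnitus exposed ear and absent in unexposed ears and
controls. Runs the three bootstrap distributions (PRE:PRE, POST:POST,
PRE:POST; 100 iterations each) and tabulates their means and SDs: the
PRE:POST mean drops below the within-condition means where the LDS changed
the waveform.
"""

import argparse
from pathlib import Path

import pandas as pd

from ldstest.pipeline import analyze_abr_pair
from ldstest.io import RunConfig
from ldstest.synth import ABRSimConfig, PostModifier, gen_abr_dataset

ROOT = Path(__file__).resolve().parents[1]

# cohort ear -> planted post-LDS wave-V amplitude scale
DESIGN = {"TE": 0.60, "TU": 0.95, "NTE": 0.25, "NTU": 0.95, "C": 0.90}


def main(seed: int = 1) -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    rows = []
    for ei, (ear, scale) in enumerate(DESIGN.items()):
        mods = tuple(PostModifier(scale if i == 4 else 1.0) for i in range(6))
        cfg = ABRSimConfig(n_sweeps=1266, noise_sd_uv=1.0, post_modifiers=mods,
                           seed=seed + ei, metadata={"ear": ear})
        pre, post = gen_abr_dataset(cfg)
        res = analyze_abr_pair(pre, post, RunConfig(seed=seed + ei))
        boot = res["bootstrap"]
        rows.append({
            "ear": ear, "planted_wave_v_scale": scale,
            "mean_r_pre_pre": boot.means["PRE:PRE"],
            "mean_r_post_post": boot.means["POST:POST"],
            "mean_r_pre_post": boot.means["PRE:POST"],
            "sd_r_pre_post": boot.sds["PRE:POST"],
        })

    table = pd.DataFrame(rows).round(4)
    table.to_csv(results / "abr_bootstrap_summary.csv", index=False)
    print(table.to_string(index=False))
    print("\nExpected pattern: mean PRE:POST R tracks the planted suppression "
          "(lowest for NTE, then TE), while PRE:PRE and POST:POST stay near 1; "
          "unexposed ears and control remain close to their within-condition "
          "reliability.")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
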