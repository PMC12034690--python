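"""Split-half bootstrap correlation of ABR waveforms.

Per iteration, random halves of the single sweeps are averaged and the two
averaged waveforms are Pearson-correlated over a response window (default
2–14 ms after stimulus onset). Repeating 100 times within PRE (PRE:PRE),
within POST (POST:POST) and across conditions (PRE:POST) yields three R-value
distributions whose means summarize waveform reliability and PRE/POST
similarity for each recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ldstest.abr import DEFAULT_BAND_HZ, DEFAULT_WINDOW_MS, bandpass
from ldstest.core import ABRSweepSet, ABRWaveform

__all__ = ["BootstrapResult", "split_half_r", "lds_correlation_suite"]


@dataclass
class BootstrapResult:
    r_pre_pre: np.ndarray
    r_post_post: np.ndarray
    r_pre_post: np.ndarray
    n_iter: int
    window_ms: tuple[float, float]
    seed: int | None = None

    @property
    def means(self) -> dict[str, float]:
        return {
            "PRE:PRE": float(np.mean(self.r_pre_pre)),
            "POST:POST": float(np.mean(self.r_post_post)),
            "PRE:POST": float(np.mean(self.r_pre_post)),
        }

    @property
    def sds(self) -> dict[str, float]:
        # SD of a single R-value is reported as 0 by convention
        def sd(x):
            return float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        return {
            "PRE:PRE": sd(self.r_pre_pre),
            "POST:POST": sd(self.r_post_post),
            "PRE:POST": sd(self.r_pre_post),
        }

    def to_dict(self) -> dict:
        return {
            "means": self.means,
            "sds": self.sds,
            "n_iter": self.n_iter,
            "window_ms": list(self.window_ms),
            "seed": self.seed,
        }


def _window_slice(sweeps: ABRSweepSet, window_ms) -> np.ndarray:
    t = sweeps.time_ms
    lo, hi = window_ms
    if lo < t[0] or hi > t[-1]:
        raise ValueError(f"window {window_ms} outside sweep extent "
                         f"({t[0]:.2f}-{t[-1]:.2f} ms)")
    return np.nonzero((t >= lo) & (t <= hi))[0]


def _filtered_average(sweeps: ABRSweepSet, idx: np.ndarray,
                      filter_band, window_idx: np.ndarray) -> np.ndarray:
    avg = sweeps.sweeps[idx].mean(axis=0)
    if filter_band is not None:
        wf = ABRWaveform(sweeps.time_ms, avg, sweeps.sample_rate)
        avg = bandpass(wf, *filter_band).voltage_uv
    return avg[window_idx]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return float("nan")
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def split_half_r(set_a: ABRSweepSet, set_b: ABRSweepSet,
                 window_ms=DEFAULT_WINDOW_MS, n_iter: int = 100,
                 seed=None, rng: np.random.Generator | None = None,
                 filter_band=DEFAULT_BAND_HZ,
                 cross_mode: str = "half") -> np.ndarray:
    """One bootstrap R-value distribution.

    Within a condition (``set_a is set_b``), each iteration splits the sweeps
    into complementary random halves (floor(n/2) vs. the rest), averages each
    half and correlates the two averages over ``window_ms``. Across conditions,
    an independent random half of each set is averaged and correlated
    (``cross_mode="full"`` instead correlates the full averages, which makes
    every iteration identical). Averages are band-pass filtered before
    windowing; correlation is computed at native sampling.
    """
    if set_a.n_sweeps < 4 or set_b.n_sweeps < 4:
        raise ValueError("need >= 4 sweeps per set")
    if set_a.sweeps.shape[1] != set_b.sweeps.shape[1]:
        raise ValueError("sweep sets must share sample count")
    if rng is None:
        rng = np.random.default_rng(seed)
    win = _window_slice(set_a, window_ms)
    within = set_a is set_b
    rs = np.empty(n_iter)
    for i in range(n_iter):
        if within:
            perm = rng.permutation(set_a.n_sweeps)
            h = set_a.n_sweeps // 2
            w1 = _filtered_average(set_a, perm[:h], filter_band, win)
            w2 = _filtered_average(set_a, perm[h:], filter_band, win)
        elif cross_mode == "half":
            if set_a.n_sweeps == set_b.n_sweeps:
                # complementary index halves: statistically equivalent for
                # independent sets, and avoids sharing sweeps when PRE and
                # POST have common provenance (e.g. a copied set)
                perm = rng.permutation(set_a.n_sweeps)
                h = set_a.n_sweeps // 2
                ia, ib = perm[:h], perm[h:]
            else:
                ia = rng.choice(set_a.n_sweeps, set_a.n_sweeps // 2, replace=False)
                ib = rng.choice(set_b.n_sweeps, set_b.n_sweeps // 2, replace=False)
            w1 = _filtered_average(set_a, ia, filter_band, win)
            w2 = _filtered_average(set_b, ib, filter_band, win)
        elif cross_mode == "full":
            w1 = _filtered_average(set_a, np.arange(set_a.n_sweeps), filter_band, win)
            w2 = _filtered_average(set_b, np.arange(set_b.n_sweeps), filter_band, win)
        else:
            raise ValueError(f"unknown cross_mode {cross_mode!r}")
        rs[i] = _pearson(w1, w2)
    return rs


def lds_correlation_suite(pre: ABRSweepSet, post: ABRSweepSet,
                          window_ms=DEFAULT_WINDOW_MS, n_iter: int = 100,
                          seed: int = 0, filter_band=DEFAULT_BAND_HZ,
                          cross_mode: str = "half") -> BootstrapResult:
    """The three R-value distributions (PRE:PRE, POST:POST, PRE:POST) for one
    ABR_LDS recording, drawn from one shared seed stream."""
    rng = np.random.default_rng(seed)
    r_pp = split_half_r(pre, pre, window_ms, n_iter, rng=rng, filter_band=filter_band)
    r_qq = split_half_r(post, post, window_ms, n_iter, rng=rng, filter_band=filter_band)
    r_pq = split_half_r(pre, post, window_ms, n_iter, rng=rng,
                        filter_band=filter_band, cross_mode=cross_mode)
    return BootstrapResult(r_pp, r_qq, r_pq, n_iter, tuple(window_ms), seed)
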