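"""Active-avoidance tinnitus classification.

Avoidance performance is summarized per frequency and session as percent
correct; the tinnitus decision compares the worst frequency's per-session
percentages against the grand mean with a one-sample, one-tailed (lower)
t-test at alpha = 0.05. Tinnitus is expected to depress avoidance at
frequencies overlapping the percept, producing a frequency-specific dip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ldstest.core import AASessionSet
from ldstest.stats import one_sample_t

__all__ = ["FrequencyAvoidanceProfile", "TinnitusCall", "percent_correct",
           "classify_tinnitus"]


@dataclass
class FrequencyAvoidanceProfile:
    """Percent-correct table: rows = sessions, columns = frequencies (kHz)."""

    per_session: pd.DataFrame
    animal_id: str = ""

    @property
    def frequency_means(self) -> pd.Series:
        return self.per_session.mean(axis=0)

    def grand_mean(self, exclude: float | None = None) -> float:
        """Unweighted mean of per-frequency means (robust to unequal trial
        counts); optionally excluding one frequency."""
        means = self.frequency_means
        if exclude is not None:
            means = means.drop(exclude)
        return float(means.mean())


@dataclass
class TinnitusCall:
    tinnitus: bool
    dip_frequency_khz: float
    t_statistic: float
    p_value: float
    alpha: float = 0.05
    degenerate: bool = False
    animal_id: str = ""

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "tinnitus": bool(self.tinnitus),
            "dip_frequency_khz": float(self.dip_frequency_khz),
            "t": float(self.t_statistic),
            "p": float(self.p_value),
            "alpha": self.alpha,
            "degenerate": self.degenerate,
        }


def percent_correct(sessions: AASessionSet) -> FrequencyAvoidanceProfile:
    """Per-(session, frequency) percent correct avoidance.

    Every (session, frequency) cell must contain at least one trial; an empty
    cell is an error naming the cell, since the classifier would otherwise
    silently average over missing data.
    """
    df = sessions.trials
    table = (df.groupby(["session", "frequency_khz"])["avoided"]
               .mean().mul(100.0).unstack("frequency_khz"))
    if table.isna().any().any():
        sess, freq = next(
            (s, f) for s in table.index for f in table.columns
            if pd.isna(table.loc[s, f]))
        raise ValueError(f"no trials for session {sess}, frequency {freq} kHz")
    return FrequencyAvoidanceProfile(per_session=table.sort_index(),
                                     animal_id=sessions.animal_id)


def classify_tinnitus(profile: FrequencyAvoidanceProfile, alpha: float = 0.05,
                      exclude_dip_from_grand_mean: bool = False,
                      sample: str = "sessions") -> TinnitusCall:
    """Worst-frequency tinnitus decision rule.

    The dip frequency is the one with the lowest mean percent correct (ties
    break to the lowest frequency, seed-independently). Its per-session
    percentages are tested against the grand mean — treated as a fixed
    constant — with a one-sample lower-tailed t-test (df = n_sessions - 1);
    tinnitus iff p < alpha. ``sample="frequencies"`` instead uses the
    per-frequency means as the sample (an alternative reading of the rule).

    Zero variance at the dip is degenerate: equal to the grand mean means no
    evidence (not tinnitus); strictly below it is treated as tinnitus with p
    reported as 0.
    """
    means = profile.frequency_means
    dip_freq = float(means.index[np.argmin(means.values)])  # ties: lowest frequency
    grand = profile.grand_mean(exclude=dip_freq if exclude_dip_from_grand_mean else None)
    if sample == "sessions":
        values = profile.per_session[dip_freq].to_numpy()
    elif sample == "frequencies":
        values = means.to_numpy()
    else:
        raise ValueError(f"unknown sample mode {sample!r}")
    if values.size < 2:
        raise ValueError("need >= 2 sessions at the dip frequency")
    res = one_sample_t(values, mu=grand, tail="lower")
    return TinnitusCall(
        tinnitus=bool(res.p_value < alpha),
        dip_frequency_khz=dip_freq,
        t_statistic=res.statistic,
        p_value=res.p_value,
        alpha=alpha,
        degenerate=res.degenerate,
        animal_id=profile.animal_id,
    )
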