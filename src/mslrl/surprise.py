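"""Trial-wise combination probabilities and Shannon surprise.

The probability of the stimulus combination ``x`` observed on trial ``t``
(0-based) is its Laplace-smoothed relative frequency over the run so far,

    p(x_t) = (1 + count of x in trials 0..t-1) / (n + t),

where ``n`` is the number of possible combinations, so the first trial of
every combination has p = 1/n.  Surprise is the negative natural
logarithm, I_t = -ln p(x_t) (nats).

Tracked events per task variant:

* match recognition — the (sound, visual) pair, n = 9;
* discriminative choice — the triplet of sound plus both shown visuals,
  n = 16 by convention (the count of sound x visual combinations, although
  only 12 distinct triplets can occur; ``n_override`` allows 12 for
  sensitivity analyses);
* discriminative-choice non-matching variant — only the (sound,
  non-matching visual) pair, n = 4, because the matching symbol is always
  shown and carries no surprise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mslrl.task_design import TrialSequence

DC_N_COMBINATIONS = 16
MR_N_COMBINATIONS = 9
DC_NONMATCH_N_COMBINATIONS = 4


@dataclass
class SurpriseTrace:
    """Per-trial combination keys, probabilities and surprise for one run."""

    keys: list[str]
    p: np.ndarray
    surprise: np.ndarray
    n: int

    def __len__(self) -> int:
        return len(self.keys)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(len(self.keys)),
                "key": self.keys,
                "p": self.p,
                "surprise": self.surprise,
            }
        )


def combination_probability(history: list, current, n: int) -> float:
    """Laplace-smoothed probability of ``current`` given the ``history`` seen.

    ``n`` is the number of possible combinations; with ``t = len(history)``
    the estimate is ``(1 + occurrences of current) / (n + t)``.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    t = len(history)
    return (1 + sum(1 for h in history if h == current)) / (n + t)


def _trace_from_keys(keys: list[str], n: int) -> SurpriseTrace:
    counts: dict[str, int] = {}
    p = np.empty(len(keys))
    for t, k in enumerate(keys):
        p[t] = (1 + counts.get(k, 0)) / (n + t)
        counts[k] = counts.get(k, 0) + 1
    return SurpriseTrace(keys=keys, p=p, surprise=-np.log(p), n=n)


def triplet_key(sound: str, v1: int, v2: int) -> str:
    """Unordered triplet key for discriminative-choice trials."""
    lo, hi = sorted((v1, v2))
    return f"{sound}|{lo}{hi}"


def pair_key(sound: str, visual: int) -> str:
    return f"{sound}|{visual}"


def shannon_surprise_trace(
    seq: TrialSequence, n_override: int | None = None
) -> SurpriseTrace:
    """Shannon surprise of the full stimulus combination on every trial.

    Discriminative choice tracks the unordered triplet (sound plus the two
    shown visuals) with n = 16; match recognition tracks the (sound,
    visual) pair with n = 9.
    """
    if seq.config.variant == "discriminative_choice":
        keys = [
            triplet_key(tr.audio_tactile, tr.visual_left, tr.visual_right)
            for tr in seq
        ]
        n = DC_N_COMBINATIONS
    else:
        keys = [pair_key(tr.audio_tactile, tr.visual) for tr in seq]
        n = MR_N_COMBINATIONS
    return _trace_from_keys(keys, n_override or n)


def nonmatching_surprise_trace(seq: TrialSequence) -> SurpriseTrace:
    """Surprise of the non-matching (sound, visual) pair only; n = 4.

    Only defined for the discriminative choice task, where the matching
    symbol is always shown and the non-matching partner carries all the
    statistical structure.
    """
    if seq.config.variant != "discriminative_choice":
        raise ValueError(
            "non-matching surprise is defined only for the discriminative "
            "choice task"
        )
    keys = []
    for tr in seq:
        match = tr.sound_index  # visual i matches sound i
        nonmatch = tr.visual_left if tr.visual_right == match else tr.visual_right
        keys.append(pair_key(tr.audio_tactile, nonmatch))
    return _trace_from_keys(keys, DC_NONMATCH_N_COMBINATIONS)


def write_trace(trace: SurpriseTrace, path) -> None:
    trace.to_frame().to_csv(path, sep="\t", index=False)
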