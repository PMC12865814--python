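"""Trial-sequence construction for the two multisensory learning tasks.

Two task variants are supported:

* ``discriminative_choice`` — 4 auditory/tactile x 4 visual stimuli, 44
  trials per run.  Two visual symbols are shown on each trial together with
  one sound/vibration; the participant picks the side whose symbol matches.
  The matching symbol is always one of the two, so the statistical structure
  lives in which *non-matching* symbol accompanies it: per sound the three
  non-matching partners appear on 7, 3 and 1 of its 11 trials.

* ``match_recognition`` — 3 x 3 stimuli, 42 trials per run.  A single
  visual symbol is shown with a sound/vibration and the participant judges
  match vs. non-match.  Per sound: 7 matching trials, 5 with the frequent
  non-matching partner, 2 with the rare one.

Feedback validity can be reversed on a scheduled fraction of trials
(difficulty calibration), allocated as evenly as possible across the
auditory/tactile stimuli.  Inter-trial and inter-stimulus intervals are
drawn from range-truncated gamma distributions.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import stats
from scipy.optimize import brentq

Variant = Literal["discriminative_choice", "match_recognition"]
Modality = Literal["audio_visual", "tactile_visual"]

VARIANTS = ("discriminative_choice", "match_recognition")
MODALITIES = ("audio_visual", "tactile_visual")
REVERSAL_RATES = (0.0, 0.05, 0.10, 0.20)

SOUND_LABELS = "ABCD"

#: Non-matching visual partner counts per sound for the discriminative
#: choice task (sound index -> {visual index: trials}).  Sound i always
#: appears with its matching visual i plus one of these partners.
_DC_NONMATCH_COUNTS = {
    0: {1: 7, 2: 3, 3: 1},
    1: {0: 7, 3: 3, 2: 1},
    2: {3: 7, 0: 3, 1: 1},
    3: {2: 7, 1: 3, 0: 1},
}

#: Pair presentation counts per sound for the match recognition task
#: (sound index -> {visual index: trials}); visual i matches sound i.
_MR_PAIR_COUNTS = {
    0: {0: 7, 2: 5, 1: 2},
    1: {1: 7, 0: 5, 2: 2},
    2: {2: 7, 1: 5, 0: 2},
}


@dataclass(frozen=True)
class TaskConfig:
    """Static description of one run's task structure and timing.

    Timing defaults follow the child versions of the tasks: 2 s stimuli,
    1.8 s feedback, gamma-distributed ITI/ISI with the printed means and
    ranges (seconds).
    """

    variant: Variant
    modality: Modality = "audio_visual"
    reversal_rate: float = 0.10
    n_audio_tactile: int = 4
    n_visual: int = 4
    n_trials: int = 44
    iti_mean: float = 1.87
    iti_range: tuple[float, float] = (0.76, 3.45)
    isi_mean: float = 3.45
    isi_range: tuple[float, float] = (2.28, 4.83)
    stimulus_duration: float = 2.0
    feedback_duration: float = 1.8

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not any(np.isclose(self.reversal_rate, r) for r in REVERSAL_RATES):
            raise ValueError(
                f"reversal_rate must be one of {REVERSAL_RATES}, "
                f"got {self.reversal_rate}"
            )
        if self.variant == "discriminative_choice":
            if (self.n_audio_tactile, self.n_visual, self.n_trials) != (4, 4, 44):
                raise ValueError(
                    "discriminative choice requires 4 x 4 stimuli and 44 trials"
                )
        else:
            if (self.n_audio_tactile, self.n_visual, self.n_trials) != (3, 3, 42):
                raise ValueError(
                    "match recognition requires 3 x 3 stimuli and 42 trials"
                )
        for mean, (lo, hi), name in (
            (self.iti_mean, self.iti_range, "iti"),
            (self.isi_mean, self.isi_range, "isi"),
        ):
            if not lo < mean < hi:
                raise ValueError(f"{name}_mean {mean} outside range [{lo}, {hi}]")

    @property
    def sounds(self) -> tuple[str, ...]:
        return tuple(SOUND_LABELS[: self.n_audio_tactile])


def default_config(
    variant: Variant,
    modality: Modality = "audio_visual",
    reversal_rate: float = 0.10,
    age_group: str = "child",
) -> TaskConfig:
    """Task configuration with the timing printed for each task version."""
    if variant == "discriminative_choice":
        return TaskConfig(
            variant=variant, modality=modality, reversal_rate=reversal_rate
        )
    if age_group == "adult":
        return TaskConfig(
            variant="match_recognition",
            modality=modality,
            reversal_rate=reversal_rate,
            n_audio_tactile=3,
            n_visual=3,
            n_trials=42,
            iti_mean=2.06,
            iti_range=(0.79, 3.39),
            isi_mean=2.67,
            isi_range=(1.11, 4.34),
            feedback_duration=2.0,
        )
    return TaskConfig(
        variant="match_recognition",
        modality=modality,
        reversal_rate=reversal_rate,
        n_audio_tactile=3,
        n_visual=3,
        n_trials=42,
        iti_mean=2.05,
        iti_range=(0.76, 3.45),
        isi_mean=3.28,
        isi_range=(2.04, 4.90),
    )


@dataclass(frozen=True)
class PairingFrequencyTable:
    """Scheduled per-run trial counts for each stimulus combination.

    ``counts`` maps (sound_index, visual_index) to a number of trials.  In
    the discriminative choice task the visual index is the *non-matching*
    partner (the matching symbol is additionally shown on every trial of
    its sound); in the match recognition task it is the single presented
    symbol.  ``matching`` maps each sound to its matching visual.
    """

    variant: Variant
    counts: dict[tuple[int, int], int]
    matching: dict[int, int]

    @property
    def n_trials(self) -> int:
        return sum(self.counts.values())

    def presentation_counts(self) -> dict[tuple[int, int], int]:
        """Times each (sound, visual) combination appears on screen.

        For the discriminative choice task this adds the matching symbol's
        presence on every trial of its sound (row marginals 22 per visual,
        11 per sound); for match recognition it equals ``counts``.
        """
        pres = dict(self.counts)
        if self.variant == "discriminative_choice":
            per_sound: dict[int, int] = {}
            for (s, _v), c in self.counts.items():
                per_sound[s] = per_sound.get(s, 0) + c
            for s, m in self.matching.items():
                pres[(s, m)] = pres.get((s, m), 0) + per_sound[s]
        return pres


@dataclass
class Trial:
    """One trial of either task variant.

    ``visual_left``/``visual_right``/``correct_side`` are used by the
    discriminative choice task; ``visual``/``is_match`` by match
    recognition.  Onsets are filled in by :func:`sample_timing`.
    """

    index: int
    audio_tactile: str
    visual_left: int | None = None
    visual_right: int | None = None
    correct_side: Literal["left", "right"] | None = None
    visual: int | None = None
    is_match: bool | None = None
    feedback_valid: bool = True
    iti: float | None = None
    isi: float | None = None
    onset_stimulus: float | None = None
    onset_feedback: float | None = None

    @property
    def sound_index(self) -> int:
        return SOUND_LABELS.index(self.audio_tactile)


@dataclass
class TrialSequence:
    """An ordered run of trials plus the configuration and seed that made it."""

    config: TaskConfig
    trials: list[Trial]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def realized_counts(self) -> dict[tuple[int, int], int]:
        """Realized (sound, visual) trial counts, keyed like the frequency table."""
        out: dict[tuple[int, int], int] = {}
        for tr in self.trials:
            s = tr.sound_index
            if self.config.variant == "discriminative_choice":
                match = _matching_map(self.config)[s]
                v = tr.visual_left if tr.visual_right == match else tr.visual_right
            else:
                v = tr.visual
            out[(s, v)] = out.get((s, v), 0) + 1
        return out


def _matching_map(config: TaskConfig) -> dict[int, int]:
    return {i: i for i in range(config.n_audio_tactile)}


def build_frequency_table(config: TaskConfig) -> PairingFrequencyTable:
    """Scheduled pairing counts for one run of either task variant."""
    if config.variant == "discriminative_choice":
        if config.n_audio_tactile != 4 or config.n_visual != 4:
            raise ValueError("discriminative choice supports only 4 x 4 stimuli")
        counts = {
            (s, v): c
            for s, row in _DC_NONMATCH_COUNTS.items()
            for v, c in row.items()
        }
    else:
        if config.n_audio_tactile != 3 or config.n_visual != 3:
            raise ValueError("match recognition supports only 3 x 3 stimuli")
        counts = {
            (s, v): c
            for s, row in _MR_PAIR_COUNTS.items()
            for v, c in row.items()
        }
    return PairingFrequencyTable(
        variant=config.variant, counts=counts, matching=_matching_map(config)
    )


def make_trial_sequence(config: TaskConfig, seed: int) -> TrialSequence:
    """Pseudorandomly ordered trials realizing the pairing frequency table.

    In the discriminative choice task the correct (matching) symbol's side
    is counterbalanced as evenly as the cell counts allow: each
    (sound, non-matching partner) cell splits its trials half left / half
    right, and the odd remainders are balanced globally.  Feedback is all
    valid and onsets unset; see :func:`schedule_feedback_reversal` and
    :func:`sample_timing`, or use :func:`generate_run`.
    """
    rng = np.random.default_rng(seed)
    table = build_frequency_table(config)
    trials: list[Trial] = []
    if config.variant == "discriminative_choice":
        leftovers: list[tuple[int, int]] = []
        for (s, v), c in sorted(table.counts.items()):
            n_left = c // 2
            n_right = c // 2
            sides = ["left"] * n_left + ["right"] * n_right
            for side in sides:
                trials.append(_dc_trial(s, v, side, table))
            if c % 2:
                leftovers.append((s, v))
        # balance odd remainders: half left, half right, in random order
        rng.shuffle(leftovers)
        for i, (s, v) in enumerate(leftovers):
            side = "left" if i % 2 == 0 else "right"
            trials.append(_dc_trial(s, v, side, table))
    else:
        for (s, v), c in sorted(table.counts.items()):
            for _ in range(c):
                trials.append(
                    Trial(
                        index=-1,
                        audio_tactile=SOUND_LABELS[s],
                        visual=v,
                        is_match=(table.matching[s] == v),
                    )
                )
    rng.shuffle(trials)
    for i, tr in enumerate(trials):
        tr.index = i
    return TrialSequence(config=config, trials=trials, seed=seed)


def _dc_trial(s: int, v: int, side: str, table: PairingFrequencyTable) -> Trial:
    match = table.matching[s]
    if side == "left":
        vl, vr = match, v
    else:
        vl, vr = v, match
    return Trial(
        index=-1,
        audio_tactile=SOUND_LABELS[s],
        visual_left=vl,
        visual_right=vr,
        correct_side=side,
    )


def schedule_feedback_reversal(
    seq: TrialSequence, rate: float, seed: int
) -> TrialSequence:
    """Mark ``round(rate * n_trials)`` trials as feedback-reversed.

    Reversed trials are allocated round-robin over the auditory/tactile
    stimuli in a random order (per-stimulus counts differ by at most one)
    and then drawn uniformly within each stimulus's trials.  Rounding is
    half-up.  Returns a new sequence; the input is not mutated.
    """
    if not any(np.isclose(rate, r) for r in REVERSAL_RATES):
        raise ValueError(f"reversal rate must be one of {REVERSAL_RATES}, got {rate}")
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(seq)
    for tr in out.trials:
        tr.feedback_valid = True
    n_rev = int(np.floor(rate * len(out) + 0.5))
    if n_rev == 0:
        return out
    sounds = list(range(out.config.n_audio_tactile))
    rng.shuffle(sounds)
    base, extra = divmod(n_rev, len(sounds))
    per_sound = {s: base + (1 if i < extra else 0) for i, s in enumerate(sounds)}
    by_sound: dict[int, list[Trial]] = {s: [] for s in sounds}
    for tr in out.trials:
        by_sound[tr.sound_index].append(tr)
    for s, k in per_sound.items():
        chosen = rng.choice(len(by_sound[s]), size=k, replace=False)
        for i in chosen:
            by_sound[s][i].feedback_valid = False
    return out


def _truncated_gamma_scale(
    mean: float, lo: float, hi: float, shape: float = 4.0
) -> float:
    """Gamma scale such that the [lo, hi]-truncated mean equals ``mean``.

    E[X | lo < X < hi] for X ~ Gamma(k, theta) is
    k*theta * (F_{k+1}(hi) - F_{k+1}(lo)) / (F_k(hi) - F_k(lo)).
    """

    def trunc_mean(scale: float) -> float:
        fk = stats.gamma.cdf([lo, hi], shape, scale=scale)
        fk1 = stats.gamma.cdf([lo, hi], shape + 1, scale=scale)
        mass = fk[1] - fk[0]
        if mass <= 0:
            # vanishing scale piles all truncated mass at the lower bound
            return lo
        return shape * scale * (fk1[1] - fk1[0]) / mass

    return brentq(lambda s: trunc_mean(s) - mean, mean / shape / 50, hi * 10)


def _sample_truncated_gamma(
    rng: np.random.Generator,
    n: int,
    mean: float,
    lo: float,
    hi: float,
    shape: float = 4.0,
) -> np.ndarray:
    """Range-truncated gamma draws whose truncated mean equals ``mean``.

    Sampling is by inverse-CDF on a uniform restricted to [F(lo), F(hi)]
    (exact truncation, fixed draw count).
    """
    scale = _truncated_gamma_scale(mean, lo, hi, shape)
    u_lo, u_hi = stats.gamma.cdf([lo, hi], shape, scale=scale)
    u = rng.uniform(u_lo, u_hi, size=n)
    return stats.gamma.ppf(u, shape, scale=scale)


def sample_timing(seq: TrialSequence, config: TaskConfig, seed: int) -> TrialSequence:
    """Draw per-trial ITI/ISI and cumulate stimulus/feedback onsets.

    Each trial is ITI -> stimulus (2 s) -> ISI -> feedback.  ITI and ISI
    follow gamma distributions (shape 4) truncated to the configured
    ranges, with scale solved so that the truncated mean equals the
    configured mean.  Returns a new sequence with onsets filled.
    """
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(seq)
    n = len(out)
    itis = _sample_truncated_gamma(rng, n, config.iti_mean, *config.iti_range)
    isis = _sample_truncated_gamma(rng, n, config.isi_mean, *config.isi_range)
    t = 0.0
    for tr, iti, isi in zip(out.trials, itis, isis):
        tr.iti = float(iti)
        tr.isi = float(isi)
        t += iti
        tr.onset_stimulus = t
        t += config.stimulus_duration + isi
        tr.onset_feedback = t
        t += config.feedback_duration
    return out


def generate_run(config: TaskConfig, seed: int) -> TrialSequence:
    """Full run generation: ordering, feedback-reversal schedule, timing.

    A single seed deterministically drives all three stages via spawned
    child seeds.
    """
    ss = np.random.SeedSequence(seed)
    s_order, s_rev, s_time = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    seq = make_trial_sequence(config, s_order)
    seq = schedule_feedback_reversal(seq, config.reversal_rate, s_rev)
    seq = sample_timing(seq, config, s_time)
    seq.seed = seed
    return seq
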