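"""Rescorla-Wagner learning variants and the value-to-drift mapping.

Association values V, one per (sound, visual) pair, start at 0.5
(uninformed, unbiased) and are updated trial by trial with the delta rule

    V <- V + eta * (target - V),

where the target is the binary learning signal derived from the delivered
feedback.  Four variants are implemented:

* ``simple`` — only the chosen (discriminative choice) or presented
  (match recognition) pair is updated, one learning rate.
* ``simple_asym`` — separate learning rates after positive and negative
  feedback.
* ``transfer`` — additionally, the non-chosen pair (discriminative
  choice) or every pair sharing a unisensory stimulus with the presented
  pair (match recognition, positive feedback only) is updated toward the
  complement of the learning signal.
* ``transfer_asym`` — transfer with feedback-sign-specific rates; in the
  match recognition task the transfer update keeps a single rate because
  it only fires after positive feedback (3 rates total; 4 in the
  discriminative choice task).

In the match recognition task the presented pair's learning signal is
recoded to match evidence: R' = 1 when the feedback confirms the pair is
a match (responded "match" and feedback positive, or responded
"non-match" and feedback negative), else 0.  The asymmetric rate is
selected by the delivered feedback's valence.

For the discriminative choice task the two competing pair values are
normalized with an odds-ratio rule before entering the drift rate,

    nc = Vc(1-Vo) / [Vc(1-Vo) + Vo(1-Vc)],   no = 1 - nc,

and the drift is v = (nc - no) * vmod.  Match recognition uses the raw
presented-pair value: v = (2 Vc - 1) * vmod.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mslrl.task_design import TrialSequence, Trial

MODELS = ("simple", "simple_asym", "transfer", "transfer_asym")

INITIAL_VALUE = 0.5
VALUE_CLAMP = 1e-6


@dataclass(frozen=True)
class RLParams:
    """Learning rates for one Rescorla-Wagner variant.

    Only the rates the variant uses are read: ``eta_c`` by the symmetric
    models, ``eta_c_pos``/``eta_c_neg`` by the asymmetric ones, ``eta_o``
    by the transfer models (``eta_o_pos``/``eta_o_neg`` by the asymmetric
    transfer model in the discriminative choice task).
    """

    model: str
    eta_c: float = 0.0
    eta_c_pos: float = 0.0
    eta_c_neg: float = 0.0
    eta_o: float = 0.0
    eta_o_pos: float = 0.0
    eta_o_neg: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        for name in ("eta_c", "eta_c_pos", "eta_c_neg", "eta_o", "eta_o_pos", "eta_o_neg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def effective_rates(self) -> tuple[float, float, float, float]:
        """(chosen+, chosen-, other+, other-) rates the forward pass uses."""
        if self.model in ("simple", "transfer"):
            cp = cn = self.eta_c
        else:
            cp, cn = self.eta_c_pos, self.eta_c_neg
        if self.model == "transfer":
            op = on = self.eta_o
        elif self.model == "transfer_asym":
            op, on = self.eta_o_pos, self.eta_o_neg
        else:
            op = on = 0.0
        return cp, cn, op, on

    def n_learning_rates(self, variant: str) -> int:
        if self.model == "simple":
            return 1
        if self.model in ("simple_asym", "transfer"):
            return 2
        # transfer_asym: the match-recognition transfer update fires only
        # after positive feedback, so it keeps a single rate
        return 4 if variant == "discriminative_choice" else 3


class ValueState:
    """Table of association values V, one per (sound, visual) pair."""

    def __init__(self, n_sounds: int, n_visuals: int, initial: float = INITIAL_VALUE):
        self.n_sounds = n_sounds
        self.n_visuals = n_visuals
        self.values = np.full(n_sounds * n_visuals, initial, dtype=float)

    def index(self, sound_index: int, visual: int) -> int:
        return sound_index * self.n_visuals + visual

    def get(self, sound_index: int, visual: int) -> float:
        return float(self.values[self.index(sound_index, visual)])

    def set(self, sound_index: int, visual: int, value: float) -> None:
        self.values[self.index(sound_index, visual)] = value

    def overlapping(self, sound_index: int, visual: int) -> list[int]:
        """Indices of all other pairs sharing the sound or the visual."""
        out = []
        me = self.index(sound_index, visual)
        for s in range(self.n_sounds):
            for v in range(self.n_visuals):
                i = self.index(s, v)
                if i != me and (s == sound_index or v == visual):
                    out.append(i)
        return out

    def copy(self) -> "ValueState":
        new = ValueState(self.n_sounds, self.n_visuals)
        new.values = self.values.copy()
        return new


def reward_prediction_error(R: float, V: float) -> float:
    """RPE = R - V, the delivered binary feedback minus the expectation."""
    return R - V


def normalize_values(
    V_c: float, V_o: float, eps: float = VALUE_CLAMP
) -> tuple[float, float]:
    """Odds-ratio normalization of two competing pair values.

    Both values are clamped to [eps, 1-eps] first so the ratio is always
    well defined; the outputs sum to one.
    """
    vc = min(max(V_c, eps), 1.0 - eps)
    vo = min(max(V_o, eps), 1.0 - eps)
    num = vc * (1.0 - vo)
    den = num + vo * (1.0 - vc)
    nc = num / den
    return nc, 1.0 - nc


def drift_rate(values, vmod: float, variant: str) -> float:
    """Map values to the trial's drift rate.

    ``values`` is (V_chosen-frame, V_other-frame) for the discriminative
    choice task (normalized internally) or a single presented-pair value
    for match recognition.
    """
    if variant == "discriminative_choice":
        nc, no = normalize_values(*values)
        return (nc - no) * vmod
    V = values[0] if isinstance(values, (tuple, list, np.ndarray)) else values
    return (2.0 * V - 1.0) * vmod


def update_values(
    state: ValueState,
    trial: Trial,
    response: str | None,
    outcome: int | None,
    params: RLParams,
    variant: str,
) -> ValueState:
    """Apply one trial's learning update; returns a new state.

    ``outcome`` is the delivered feedback (1 positive, 0 negative, None
    neutral).  Omissions (no response) leave the state unchanged.
    """
    new = state.copy()
    if response is None or outcome is None:
        return new
    R = int(outcome)
    cp, cn, op, on = params.effective_rates()
    transfer = params.model in ("transfer", "transfer_asym")
    s = trial.sound_index
    if variant == "discriminative_choice":
        chosen_v = trial.visual_left if response == "left" else trial.visual_right
        other_v = trial.visual_right if response == "left" else trial.visual_left
        eta_c = cp if R == 1 else cn
        vc = new.get(s, chosen_v)
        new.set(s, chosen_v, vc + eta_c * (R - vc))
        if transfer:
            eta_o = op if R == 1 else on
            vo = new.get(s, other_v)
            new.set(s, other_v, vo + eta_o * ((1 - R) - vo))
    elif variant == "match_recognition":
        # recode the feedback into match evidence for the presented pair
        r_prime = 1 if (response == "match") == (R == 1) else 0
        eta_c = cp if R == 1 else cn
        vp = new.get(s, trial.visual)
        new.set(s, trial.visual, vp + eta_c * (r_prime - vp))
        if transfer and R == 1:
            for i in new.overlapping(s, trial.visual):
                new.values[i] += op * ((1 - r_prime) - new.values[i])
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return new


def run_model(
    seq: TrialSequence,
    behaviour,
    params: RLParams,
    vmod: float,
    variant: str | None = None,
) -> pd.DataFrame:
    """Deterministic forward pass producing trial-wise latent traces.

    For each trial the recorded values are those holding *before* the
    trial's feedback (these drive the drift rate), the drift rate itself,
    and the RPE of the delivered feedback against the pre-update value.
    Omitted trials carry NaN drift/RPE and do not update values.

    ``behaviour`` provides per-trial ``responses`` (side/judgement or
    None) and ``outcomes`` (1/0/None); see
    :class:`mslrl.simulate.BehaviouralRecord`.
    """
    variant = variant or seq.config.variant
    if len(behaviour.responses) != len(seq):
        raise ValueError(
            f"behaviour length {len(behaviour.responses)} does not match "
            f"sequence length {len(seq)}"
        )
    state = ValueState(seq.config.n_audio_tactile, seq.config.n_visual)
    rows = []
    for tr, response, outcome in zip(seq, behaviour.responses, behaviour.outcomes):
        s = tr.sound_index
        if variant == "discriminative_choice":
            v_left = state.get(s, tr.visual_left)
            v_right = state.get(s, tr.visual_right)
            # fixed decision frame: upper boundary = left response
            drift = drift_rate((v_left, v_right), vmod, variant)
            if response is not None:
                v_chosen = v_left if response == "left" else v_right
                v_other = v_right if response == "left" else v_left
            else:
                v_chosen = v_other = np.nan
        else:
            v_pres = state.get(s, tr.visual)
            drift = drift_rate(v_pres, vmod, variant)
            v_chosen, v_other = v_pres, 1.0 - v_pres
        rpe = (
            reward_prediction_error(outcome, v_chosen)
            if outcome is not None and response is not None
            else np.nan
        )
        rows.append(
            {
                "trial": tr.index,
                "V_chosen": v_chosen,
                "V_other": v_other,
                "RPE": rpe,
                "drift": drift,
            }
        )
        state = update_values(state, tr, response, outcome, params, variant)
    return pd.DataFrame(rows)


def write_traces(traces: pd.DataFrame, path) -> None:
    traces.to_csv(path, sep="\t", index=False)
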