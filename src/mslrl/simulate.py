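"""Forward simulation of behaviour from the generative RLDDM.

One simulated trial: the current association values set the drift rate,
an Euler-Maruyama first passage of the diffusion yields (rt, boundary),
the boundary maps to a response in the task's fixed frame (upper = left
response in the discriminative choice task, upper = "match" in match
recognition), feedback is delivered according to correctness and the
trial's scheduled feedback validity, and the values are updated by the
active Rescorla-Wagner variant before the next trial.  Responses slower
than the response window are recorded as omissions with neutral feedback
and no learning.

Cohort simulation draws per-run parameters from truncated normal
population distributions whose default means/SDs are anchored on the
fitted group statistics of the original study (children, match
recognition, audio-visual: learning rate 0.38 (0.33), non-decision time
0.89 (0.44) s, drift weight 1.96 (2.26), boundary 2.48 (0.42), and the
corresponding entries for the other groups/modalities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mslrl.ddm import DDMParams, _em_batch
from mslrl.rl_models import RLParams, ValueState, drift_rate, update_values
from mslrl.task_design import TaskConfig, TrialSequence, default_config, generate_run


@dataclass
class BehaviouralRecord:
    """Per-trial responses, reaction times and delivered feedback.

    ``responses`` holds "left"/"right" (discriminative choice) or
    "match"/"nonmatch" (match recognition), or None for an omission;
    ``rts`` seconds (NaN on omission); ``feedback`` is
    "positive"/"negative"/"neutral" (neutral iff omission).
    """

    responses: list[str | None]
    rts: np.ndarray
    feedback: list[str]

    def __post_init__(self) -> None:
        self.rts = np.asarray(self.rts, dtype=float)
        for i, (resp, fb) in enumerate(zip(self.responses, self.feedback)):
            if (resp is None) != (fb == "neutral"):
                raise ValueError(
                    f"trial {i}: neutral feedback must coincide with omission"
                )

    @property
    def outcomes(self) -> list[int | None]:
        """Delivered feedback as a learning signal: 1 positive, 0 negative, None neutral."""
        return [
            None if fb == "neutral" else (1 if fb == "positive" else 0)
            for fb in self.feedback
        ]

    def __len__(self) -> int:
        return len(self.responses)

    @property
    def n_omissions(self) -> int:
        return sum(r is None for r in self.responses)


def _deliver_feedback(correct: bool, feedback_valid: bool) -> str:
    """Positive after correct, negative after incorrect - unless reversed."""
    if feedback_valid:
        return "positive" if correct else "negative"
    return "negative" if correct else "positive"


def simulate_run(
    seq: TrialSequence,
    rl: RLParams,
    ddm: DDMParams,
    vmod: float,
    response_window: float | None = None,
    seed: int = 0,
    dt: float = 1e-3,
) -> BehaviouralRecord:
    """Simulate one run's choices and RTs from the RLDDM.

    The response window defaults to the stimulus duration plus the
    trial's ISI (feedback follows the ISI, so slower responses cannot be
    registered); trials whose rt exceeds it become omissions with
    neutral feedback.
    """
    variant = seq.config.variant
    state = ValueState(seq.config.n_audio_tactile, seq.config.n_visual)
    responses: list[str | None] = []
    rts = np.full(len(seq), np.nan)
    feedback: list[str] = []
    rng = np.random.default_rng(seed)
    for i, tr in enumerate(seq):
        s = tr.sound_index
        if variant == "discriminative_choice":
            v_left = state.get(s, tr.visual_left)
            v_right = state.get(s, tr.visual_right)
            v = drift_rate((v_left, v_right), vmod, variant)
        else:
            v = drift_rate(state.get(s, tr.visual), vmod, variant)
        window = (
            response_window
            if response_window is not None
            else seq.config.stimulus_duration + (tr.isi if tr.isi is not None else 3.0)
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        t_max = max(window - ddm.tau, dt)
        times, bounds = _em_batch(
            np.array([v]), ddm.a, ddm.z, dt, t_max, sub_seed
        )
        rt = times[0] + ddm.tau
        if bounds[0] == -1 or rt > window:
            responses.append(None)
            feedback.append("neutral")
            continue
        if variant == "discriminative_choice":
            resp = "left" if bounds[0] == 1 else "right"
            correct = resp == tr.correct_side
        else:
            resp = "match" if bounds[0] == 1 else "nonmatch"
            correct = (resp == "match") == tr.is_match
        responses.append(resp)
        rts[i] = rt
        fb = _deliver_feedback(correct, tr.feedback_valid)
        feedback.append(fb)
        outcome = 1 if fb == "positive" else 0
        state = update_values(state, tr, resp, outcome, rl, variant)
    return BehaviouralRecord(responses=responses, rts=rts, feedback=feedback)


#: Population parameter (mean, sd) per group, keyed
#: (variant, age_group, modality) -> {eta, tau, vmod, a}.
DEFAULT_POPULATIONS: dict[tuple[str, str, str], dict[str, tuple[float, float]]] = {
    ("match_recognition", "adult", "audio_visual"): {
        "eta": (0.35, 0.28), "tau": (0.69, 0.20), "vmod": (3.60, 3.30), "a": (2.32, 0.41),
    },
    ("match_recognition", "adult", "tactile_visual"): {
        "eta": (0.23, 0.25), "tau": (0.92, 0.45), "vmod": (4.21, 3.50), "a": (2.28, 0.42),
    },
    ("match_recognition", "child", "audio_visual"): {
        "eta": (0.38, 0.33), "tau": (0.89, 0.44), "vmod": (1.96, 2.26), "a": (2.48, 0.42),
    },
    ("match_recognition", "child", "tactile_visual"): {
        "eta": (0.38, 0.36), "tau": (1.12, 0.45), "vmod": (1.10, 0.93), "a": (2.46, 0.38),
    },
    ("discriminative_choice", "child", "audio_visual"): {
        "eta": (0.33, 0.34), "tau": (0.90, 0.30), "vmod": (2.42, 3.27), "a": (2.48, 0.26),
    },
    ("discriminative_choice", "child", "tactile_visual"): {
        "eta": (0.36, 0.40), "tau": (1.14, 0.37), "vmod": (2.29, 3.47), "a": (2.59, 0.58),
    },
}

#: Admissible ranges the population draws are truncated to.
PARAM_RANGES = {
    "eta": (0.01, 1.0),
    "tau": (0.1, 1.5),
    "vmod": (0.1, 20.0),
    "a": (0.3, 5.0),
}


@dataclass
class CohortSpec:
    """Specification of a simulated cohort.

    Each subject completes one audio-visual and one tactile-visual run of
    ``variant``.  Per-run parameters are drawn from truncated normal
    distributions with the given (mean, sd) per parameter and modality.
    """

    n_subjects: int
    variant: str = "match_recognition"
    age_group: str = "child"
    reversal_rate: float = 0.10
    model: str = "simple"
    populations: dict[str, dict[str, tuple[float, float]]] | None = None
    seed: int = 0

    def population_for(self, modality: str) -> dict[str, tuple[float, float]]:
        if self.populations is not None:
            return self.populations[modality]
        return DEFAULT_POPULATIONS[(self.variant, self.age_group, modality)]


def draw_parameters(
    population: dict[str, tuple[float, float]],
    rng: np.random.Generator,
) -> dict[str, float]:
    """One draw of {eta, tau, vmod, a} from range-truncated normals."""
    out = {}
    for name, (mu, sd) in population.items():
        lo, hi = PARAM_RANGES[name]
        a_, b_ = (lo - mu) / sd, (hi - mu) / sd
        out[name] = float(
            stats.truncnorm.ppf(rng.uniform(), a_, b_, loc=mu, scale=sd)
        )
    return out


def simulate_cohort(spec: CohortSpec):
    """Simulate a cohort: per-trial behaviour table plus ground-truth parameters.

    Returns ``(trials, truth)`` where ``trials`` is a tidy per-trial
    DataFrame (subject, modality, trial, stimuli, response, rt, feedback)
    and ``truth`` one row per run with the generating parameters, and the
    generated sequences/records keyed (subject, modality).
    """
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    trial_rows = []
    truth_rows = []
    runs: dict[tuple[int, str], tuple[TrialSequence, BehaviouralRecord]] = {}
    for subject in range(spec.n_subjects):
        for modality in ("audio_visual", "tactile_visual"):
            pop = spec.population_for(modality)
            params = draw_parameters(pop, rng)
            cfg = default_config(
                spec.variant,
                modality=modality,
                reversal_rate=spec.reversal_rate,
                age_group=spec.age_group,
            )
            run_seed = int(rng.integers(0, 2**31 - 1))
            seq = generate_run(cfg, run_seed)
            rl = RLParams(model=spec.model, eta_c=params["eta"],
                          eta_c_pos=params["eta"], eta_c_neg=params["eta"],
                          eta_o=params["eta"], eta_o_pos=params["eta"],
                          eta_o_neg=params["eta"])
            ddm = DDMParams(a=params["a"], tau=params["tau"])
            beh_seed = int(rng.integers(0, 2**31 - 1))
            rec = simulate_run(seq, rl, ddm, params["vmod"], seed=beh_seed)
            runs[(subject, modality)] = (seq, rec)
            truth_rows.append(
                {"subject": subject, "modality": modality, "model": spec.model,
                 "seed": run_seed, **params}
            )
            for tr, resp, rt, fb in zip(seq, rec.responses, rec.rts, rec.feedback):
                trial_rows.append(
                    {
                        "subject": subject,
                        "modality": modality,
                        "trial": tr.index,
                        "audio_tactile": tr.audio_tactile,
                        "visual_left": tr.visual_left,
                        "visual_right": tr.visual_right,
                        "visual": tr.visual,
                        "is_match": tr.is_match,
                        "correct_side": tr.correct_side,
                        "feedback_valid": tr.feedback_valid,
                        "response": resp if resp is not None else "NA",
                        "rt": rt,
                        "feedback": fb,
                        "onset_stimulus": tr.onset_stimulus,
                        "onset_feedback": tr.onset_feedback,
                    }
                )
    return pd.DataFrame(trial_rows), pd.DataFrame(truth_rows), runs
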