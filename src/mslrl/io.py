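"""TSV readers/writers for trial sequences and behavioural records.

A single tidy per-trial table is the interchange format between stages:
the sequence columns (trial, audio_tactile, visual/visual_left/
visual_right, is_match, correct_side, feedback_valid, onsets) optionally
joined with behaviour columns (response, rt, feedback).  Omissions carry
``response = NA`` and an empty rt.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from mslrl.simulate import BehaviouralRecord
from mslrl.task_design import (
    SOUND_LABELS,
    TaskConfig,
    Trial,
    TrialSequence,
    default_config,
)

_SEQ_COLUMNS_DC = ["trial", "audio_tactile", "visual_left", "visual_right",
                   "correct_side", "feedback_valid", "onset_stimulus",
                   "onset_feedback"]
_SEQ_COLUMNS_MR = ["trial", "audio_tactile", "visual", "is_match",
                   "feedback_valid", "onset_stimulus", "onset_feedback"]


def sequence_frame(seq: TrialSequence) -> pd.DataFrame:
    rows = []
    for tr in seq:
        rows.append(
            {
                "trial": tr.index,
                "audio_tactile": tr.audio_tactile,
                "visual_left": tr.visual_left,
                "visual_right": tr.visual_right,
                "visual": tr.visual,
                "is_match": tr.is_match,
                "correct_side": tr.correct_side,
                "feedback_valid": tr.feedback_valid,
                "iti": tr.iti,
                "isi": tr.isi,
                "onset_stimulus": tr.onset_stimulus,
                "onset_feedback": tr.onset_feedback,
            }
        )
    df = pd.DataFrame(rows)
    if seq.config.variant == "discriminative_choice":
        df = df.drop(columns=["visual", "is_match"])
    else:
        df = df.drop(columns=["visual_left", "visual_right", "correct_side"])
    return df


def write_sequence(seq: TrialSequence, path) -> None:
    sequence_frame(seq).to_csv(path, sep="\t", index=False, na_rep="NA")


def _fail(path, row: int, message: str):
    raise ValueError(f"{path}, row {row}: {message}")


def _sequence_from_frame(df: pd.DataFrame, path="<frame>",
                         config: TaskConfig | None = None) -> TrialSequence:
    cols = set(df.columns)
    if {"visual_left", "visual_right"} <= cols:
        variant = "discriminative_choice"
        required = {"trial", "audio_tactile", "visual_left", "visual_right",
                    "correct_side"}
    elif "visual" in cols:
        variant = "match_recognition"
        required = {"trial", "audio_tactile", "visual", "is_match"}
    else:
        raise ValueError(
            f"{path}: cannot infer variant (need visual or visual_left/right)"
        )
    missing = required - cols
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    config = config or default_config(variant)
    trials = []
    prev_onset = -np.inf
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        sound = str(row.audio_tactile)
        if sound not in config.sounds:
            _fail(path, row_no, f"unknown audio/tactile stimulus {sound!r}")
        tr = Trial(index=int(row.trial), audio_tactile=sound)
        if variant == "discriminative_choice":
            tr.visual_left = int(row.visual_left)
            tr.visual_right = int(row.visual_right)
            tr.correct_side = str(row.correct_side)
            if tr.visual_left >= config.n_visual or tr.visual_right >= config.n_visual:
                _fail(path, row_no, "unknown visual stimulus id")
            if tr.correct_side not in ("left", "right"):
                _fail(path, row_no, f"bad correct_side {tr.correct_side!r}")
        else:
            tr.visual = int(row.visual)
            if tr.visual >= config.n_visual:
                _fail(path, row_no, "unknown visual stimulus id")
            tr.is_match = str(row.is_match) in ("True", "true", "1")
        if "feedback_valid" in cols:
            tr.feedback_valid = str(row.feedback_valid) in ("True", "true", "1")
        for attr in ("iti", "isi", "onset_stimulus", "onset_feedback"):
            if attr in cols:
                val = getattr(row, attr)
                setattr(tr, attr, None if pd.isna(val) else float(val))
        if tr.onset_stimulus is not None:
            if tr.onset_stimulus <= prev_onset:
                _fail(path, row_no, "onsets not strictly increasing")
            prev_onset = tr.onset_stimulus
        trials.append(tr)
    return TrialSequence(config=config, trials=trials)


def read_sequence(path, config: TaskConfig | None = None) -> TrialSequence:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return _sequence_from_frame(df, path=path, config=config)


def behaviour_frame(seq: TrialSequence, behaviour: BehaviouralRecord) -> pd.DataFrame:
    df = sequence_frame(seq)
    df["response"] = [r if r is not None else "NA" for r in behaviour.responses]
    df["rt"] = behaviour.rts
    df["feedback"] = behaviour.feedback
    return df


def write_behaviour(seq: TrialSequence, behaviour: BehaviouralRecord, path) -> None:
    behaviour_frame(seq, behaviour).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_behaviour(path, config: TaskConfig | None = None):
    """Read a joined per-trial TSV back into (TrialSequence, BehaviouralRecord).

    Column order is irrelevant (header-driven).  ``response`` is NA on
    omissions, in which case rt must be empty/NA and feedback neutral.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
    for col in ("response", "rt", "feedback"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing behaviour column {col!r}")
    seq = _sequence_from_frame(df, path=path, config=config)
    responses: list[str | None] = []
    rts = np.full(len(df), np.nan)
    feedback = []
    valid = ({"left", "right"} if seq.config.variant == "discriminative_choice"
             else {"match", "nonmatch"})
    for row_no, (i, row) in enumerate(df.iterrows(), start=2):
        resp = row["response"]
        if pd.isna(resp):
            responses.append(None)
            if not pd.isna(row["rt"]):
                _fail(path, row_no, "omission row carries an rt")
            if row["feedback"] != "neutral":
                _fail(path, row_no, "omission row must have neutral feedback")
        else:
            if resp not in valid:
                _fail(path, row_no, f"bad response {resp!r}")
            responses.append(str(resp))
            rts[i] = float(row["rt"])
        feedback.append(str(row["feedback"]))
    return seq, BehaviouralRecord(responses=responses, rts=rts, feedback=feedback)
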