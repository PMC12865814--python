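"""Behavioural post-processing and fMRI regressor export.

Trial exclusion follows the standard RT-cleaning recipe: omissions,
reaction times under 200 ms, and reaction times beyond 3 within-run
standard deviations of the within-run mean (computed once, on the trials
surviving the first two rules) are removed; whole runs with more than
20% omissions are dropped.  Runs are split into three bins by original
trial index (14/14/14 trials for match recognition, 15/15/14 for
discriminative choice) and summarized by mean correct-trial RT, accuracy
(correct / non-omitted) and mean absolute drift rate.

The trial-wise association between RT and Shannon surprise is estimated
by ordinary least squares per run, with a one-sample t-test on the
per-run slopes across runs as the group summary (a deliberately simple
stand-in for a mixed model, which belongs to downstream statistics
packages).

Regressor export writes BIDS-style ``events.tsv`` plus three-column
(onset, duration, weight) timing files: the surprise modulator rides on
the stimulus regressor and keeps *all* trials (statistical learning is
implicit, so no behavioural exclusion applies); the prediction-error
modulator rides on the feedback regressor and excludes the filtered
trials, which instead populate the neutral-feedback and RT-outlier
nuisance regressors.  Modulators are mean-centred per run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

RT_FLOOR = 0.2          # seconds
SD_CRITERION = 3.0
MAX_OMISSION_FRACTION = 0.2


def rt_inclusion_mask(rts: np.ndarray) -> np.ndarray:
    """Boolean mask of trials usable for RT analyses and the likelihood.

    A trial survives when a response was given (finite rt), rt >= 200 ms,
    and rt lies within mean +/- 3 SD, where mean and (sample) SD are
    computed once over the trials passing the first two rules.
    """
    rts = np.asarray(rts, dtype=float)
    base = np.isfinite(rts) & (rts >= RT_FLOOR)
    if base.sum() >= 2:
        m = rts[base].mean()
        s = rts[base].std(ddof=1)
        return base & (np.abs(rts - m) <= SD_CRITERION * s)
    return base


def filter_trials(run: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the trial- and run-level exclusion rules to one run.

    ``run`` needs columns ``trial``, ``response`` (``"NA"`` or None for
    omissions) and ``rt``.  Returns the surviving trials and an exclusion
    log with one row per removed trial (``rule`` one of ``omission``,
    ``rt_floor``, ``rt_sd`` or ``run_omission_rate``).
    """
    run = run.reset_index(drop=True)
    omitted = run["response"].isna() | (run["response"].astype(str) == "NA")
    log_rows = []
    if omitted.sum() > MAX_OMISSION_FRACTION * len(run):
        for _, row in run.iterrows():
            log_rows.append({"trial": row["trial"], "rule": "run_omission_rate"})
        return run.iloc[0:0], pd.DataFrame(log_rows)
    rts = np.where(omitted, np.nan, run["rt"].to_numpy(dtype=float))
    keep = rt_inclusion_mask(rts)
    for i in range(len(run)):
        if keep[i]:
            continue
        if omitted.iloc[i]:
            rule = "omission"
        elif rts[i] < RT_FLOOR:
            rule = "rt_floor"
        else:
            rule = "rt_sd"
        log_rows.append({"trial": run["trial"].iloc[i], "rule": rule})
    return run[keep], pd.DataFrame(log_rows, columns=["trial", "rule"])


def bin_edges(n_trials: int, n_bins: int = 3) -> list[tuple[int, int]]:
    """Original-trial-index bin boundaries; earlier bins take the remainder.

    44 trials -> 15/15/14, 42 -> 14/14/14.
    """
    sizes = [len(chunk) for chunk in np.array_split(np.arange(n_trials), n_bins)]
    edges = []
    start = 0
    for size in sizes:
        edges.append((start, start + size))
        start += size
    return edges


def bin_summaries(
    filtered: pd.DataFrame,
    traces: pd.DataFrame,
    n_trials: int,
    n_bins: int = 3,
) -> pd.DataFrame:
    """Per-bin mean correct-trial RT, accuracy and mean absolute drift.

    Binning is by original trial index, so exclusions shrink a bin's
    denominator rather than shifting its boundaries.  ``filtered`` needs
    columns ``trial``, ``rt`` and ``correct``; ``traces`` (from
    :func:`mslrl.rl_models.run_model`) supplies the drift rates and is
    indexed by the same original trial numbers.  Empty bins yield NaN.
    """
    rows = []
    for b, (lo, hi) in enumerate(bin_edges(n_trials, n_bins)):
        sel = filtered[(filtered["trial"] >= lo) & (filtered["trial"] < hi)]
        tsel = traces[(traces["trial"] >= lo) & (traces["trial"] < hi)]
        correct = sel["correct"].astype(bool)
        rows.append(
            {
                "bin": b + 1,
                "n_trials": len(sel),
                "mean_rt_correct": sel.loc[correct, "rt"].mean() if correct.any() else np.nan,
                "accuracy": correct.mean() if len(sel) else np.nan,
                "mean_abs_drift": tsel["drift"].abs().mean() if len(tsel) else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SlopeSummary:
    """Across-run summary of per-run RT ~ surprise regression slopes."""

    slopes: pd.DataFrame      # run id, slope, intercept, n
    mean_slope: float
    t_statistic: float
    p_value: float
    n_runs: int


def rt_surprise_slope(
    filtered: pd.DataFrame, surprise: np.ndarray, min_trials: int = 5
) -> tuple[float, float] | None:
    """OLS slope and intercept of RT on surprise for one run's surviving trials.

    ``surprise`` is indexed by original trial number.  Runs with fewer
    than ``min_trials`` surviving trials or a constant predictor are
    skipped (returns None).
    """
    if len(filtered) < min_trials:
        return None
    x = np.asarray(surprise)[filtered["trial"].to_numpy(dtype=int)]
    y = filtered["rt"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        warnings.warn("constant surprise predictor; run skipped")
        return None
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.params[1]), float(res.params[0])


def rt_surprise_association(
    runs: list[tuple[str, pd.DataFrame, np.ndarray]],
    min_trials: int = 5,
) -> SlopeSummary:
    """Per-run RT ~ surprise slopes and a one-sample test of their mean.

    ``runs`` is a list of (run id, filtered trials, per-trial surprise).
    """
    rows = []
    for run_id, filtered, surprise in runs:
        fit = rt_surprise_slope(filtered, surprise, min_trials=min_trials)
        if fit is None:
            continue
        slope, intercept = fit
        rows.append(
            {"run": run_id, "slope": slope, "intercept": intercept,
             "n": len(filtered)}
        )
    slopes = pd.DataFrame(rows, columns=["run", "slope", "intercept", "n"])
    if len(slopes) >= 2:
        t, p = stats.ttest_1samp(slopes["slope"], 0.0)
    else:
        t, p = np.nan, np.nan
    return SlopeSummary(
        slopes=slopes,
        mean_slope=float(slopes["slope"].mean()) if len(slopes) else np.nan,
        t_statistic=float(t),
        p_value=float(p),
        n_runs=len(slopes),
    )


@dataclass
class RegressorSet:
    """Event tables for a first-level fMRI model of one run."""

    events: pd.DataFrame               # BIDS-style long table
    stimulus_surprise: pd.DataFrame    # onset, duration, weight (all trials)
    feedback_rpe: pd.DataFrame         # onset, duration, weight (clean trials)
    neutral_feedback: pd.DataFrame     # onset, duration (omissions)
    rt_outlier_feedback: pd.DataFrame  # onset, duration (filtered responses)

    def write(self, out_dir) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        p = out_dir / "events.tsv"
        self.events.to_csv(p, sep="\t", index=False, na_rep="n/a")
        paths["events"] = p
        for name in ("stimulus_surprise", "feedback_rpe",
                     "neutral_feedback", "rt_outlier_feedback"):
            p = out_dir / f"{name}.txt"
            getattr(self, name).to_csv(p, sep="\t", index=False, header=False)
            paths[name] = p
        return paths


def export_regressors(seq, behaviour, traces: pd.DataFrame,
                      surprise: np.ndarray) -> RegressorSet:
    """Build the parametric-modulator regressors for one run.

    Surprise modulates every stimulus onset (no behavioural exclusion);
    the prediction error modulates feedback onsets of clean response
    trials only.  Omission feedback onsets go to the neutral nuisance
    regressor and excluded response trials to the RT-outlier nuisance
    regressor.  Both modulators are mean-centred over the events they
    cover.
    """
    n = len(seq)
    onsets_stim = np.array([tr.onset_stimulus for tr in seq], dtype=float)
    onsets_fb = np.array([tr.onset_feedback for tr in seq], dtype=float)
    if np.any(~np.isfinite(onsets_stim)) or np.any(~np.isfinite(onsets_fb)):
        raise ValueError("sequence has missing onsets; run sample_timing first")
    stim_dur = seq.config.stimulus_duration
    fb_dur = seq.config.feedback_duration
    rts = np.asarray(behaviour.rts, dtype=float)
    include = rt_inclusion_mask(rts)
    omitted = np.array([r is None for r in behaviour.responses])
    outlier = ~include & ~omitted
    surprise = np.asarray(surprise, dtype=float)
    surprise_c = surprise - surprise.mean()
    rpe = traces["RPE"].to_numpy(dtype=float)
    rpe_c = np.where(include, rpe - (rpe[include].mean() if include.any() else 0.0), np.nan)

    events_rows = []
    for i, tr in enumerate(seq):
        events_rows.append(
            {"onset": onsets_stim[i], "duration": stim_dur,
             "trial_type": "stimulus", "trial": i,
             "response": behaviour.responses[i] or "n/a",
             "rt": rts[i], "modulator": surprise_c[i]}
        )
        if omitted[i]:
            ttype = "feedback_neutral"
        elif outlier[i]:
            ttype = "feedback_rt_outlier"
        else:
            ttype = "feedback"
        events_rows.append(
            {"onset": onsets_fb[i], "duration": fb_dur,
             "trial_type": ttype, "trial": i,
             "response": behaviour.responses[i] or "n/a",
             "rt": rts[i],
             "modulator": rpe_c[i] if ttype == "feedback" else np.nan}
        )
    events = pd.DataFrame(events_rows)

    def three_col(onsets, durations, weights=None):
        d = {"onset": onsets, "duration": durations}
        d["weight"] = weights if weights is not None else np.ones(len(onsets))
        return pd.DataFrame(d)

    return RegressorSet(
        events=events,
        stimulus_surprise=three_col(onsets_stim, np.full(n, stim_dur), surprise_c),
        feedback_rpe=three_col(
            onsets_fb[include], np.full(include.sum(), fb_dur), rpe_c[include]
        ),
        neutral_feedback=three_col(
            onsets_fb[omitted], np.full(omitted.sum(), fb_dur)
        ),
        rt_outlier_feedback=three_col(
            onsets_fb[outlier], np.full(outlier.sum(), fb_dur)
        ),
    )
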