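"""Trial filtering, binning, RT~surprise association, regressor export."""

import numpy as np
import pandas as pd
import pytest

from mslrl.analysis import (
    bin_edges,
    bin_summaries,
    export_regressors,
    filter_trials,
    rt_inclusion_mask,
    rt_surprise_association,
    rt_surprise_slope,
)
from mslrl.rl_models import RLParams, run_model
from mslrl.simulate import BehaviouralRecord, simulate_run
from mslrl.surprise import shannon_surprise_trace
from mslrl.task_design import default_config, generate_run


def run_frame(rts, responses=None):
    n = len(rts)
    responses = responses or ["match"] * n
    return pd.DataFrame({
        "trial": np.arange(n),
        "response": responses,
        "rt": rts,
    })


class TestFilterTrials:
    def test_hand_computed_toy_run(self):
        """Fifteen trials: one omission, one fast guess, one huge outlier.

        After removing the omission and the 0.15 s trial, the remaining 13
        RTs (twelve at 0.5 s, one at 8.0 s) have mean 1.0769 and sample SD
        2.0803; 8.0 deviates by 6.92 > 3 SD and is removed.  12 survive.
        """
        rts = [0.15] + [0.5] * 12 + [8.0] + [np.nan]
        responses = ["match"] * 14 + ["NA"]
        filtered, log = filter_trials(run_frame(rts, responses))
        assert len(filtered) == 12
        assert set(filtered["rt"]) == {0.5}
        rules = log.set_index("trial")["rule"].to_dict()
        assert rules == {0: "rt_floor", 13: "rt_sd", 14: "omission"}

    def test_run_excluded_above_20_percent_omissions(self):
        rts = [0.5] * 33 + [np.nan] * 9  # 9/42 = 21.4%
        responses = ["match"] * 33 + ["NA"] * 9
        filtered, log = filter_trials(run_frame(rts, responses))
        assert len(filtered) == 0
        assert (log["rule"] == "run_omission_rate").all() and len(log) == 42

    def test_run_kept_at_exactly_20_percent(self):
        rts = [0.5] * 34 + [np.nan] * 8  # 8/42 < 20% is fine; 8.4 is the cap
        responses = ["match"] * 34 + ["NA"] * 8
        filtered, log = filter_trials(run_frame(rts, responses))
        assert len(filtered) == 34

    def test_clean_run_passes_through(self):
        rts = list(np.linspace(0.4, 1.2, 20))
        filtered, log = filter_trials(run_frame(rts))
        assert len(filtered) == 20 and len(log) == 0

    def test_log_plus_survivors_partition_run(self):
        rts = [0.1, 0.5, 0.6, np.nan, 0.7]
        responses = ["match", "match", "nonmatch", "NA", "match"]
        filtered, log = filter_trials(run_frame(rts, responses))
        assert len(filtered) + len(log) == 5
        assert set(filtered["trial"]) | set(log["trial"]) == set(range(5))

    def test_mask_used_by_fitting_matches_filter(self):
        rts = np.array([0.15] + [0.5] * 12 + [8.0] + [np.nan])
        mask = rt_inclusion_mask(rts)
        assert mask.sum() == 12 and not mask[0] and not mask[13] and not mask[14]


class TestBinning:
    def test_bin_sizes(self):
        assert [hi - lo for lo, hi in bin_edges(42)] == [14, 14, 14]
        assert [hi - lo for lo, hi in bin_edges(44)] == [15, 15, 14]

    def test_all_correct_run_has_ceiling_accuracy(self):
        df = run_frame(list(np.full(42, 0.6)))
        df["correct"] = True
        traces = pd.DataFrame({"trial": np.arange(42), "drift": np.ones(42)})
        bins = bin_summaries(df, traces, 42)
        assert list(bins["accuracy"]) == [1.0, 1.0, 1.0]
        assert list(bins["n_trials"]) == [14, 14, 14]
        assert np.allclose(bins["mean_abs_drift"], 1.0)

    def test_empty_bin_marked_missing(self):
        df = run_frame([0.5] * 10)
        df["correct"] = True
        df["trial"] = np.arange(10)  # all in bin 1 of a 42-trial run
        traces = pd.DataFrame({"trial": np.arange(10), "drift": np.ones(10)})
        bins = bin_summaries(df, traces, 42)
        assert np.isnan(bins["accuracy"].iloc[2])

    def test_accuracy_excluding_omissions_never_below_including(self):
        correct = np.array([True] * 20 + [False] * 8)
        n_omit = 6
        acc_excl = correct.mean()
        acc_incl = correct.sum() / (len(correct) + n_omit)
        assert acc_excl >= acc_incl


class TestRTSurprise:
    def test_planted_slope_recovered(self):
        cfg = default_config("match_recognition")
        rng = np.random.default_rng(8)
        beta = 0.3
        runs = []
        for seed in range(20):
            seq = generate_run(cfg, seed)
            s = shannon_surprise_trace(seq).surprise
            rts = 0.5 + beta * s + rng.normal(0, 0.05, len(s))
            df = run_frame(list(rts))
            runs.append((f"run{seed}", df, s))
        summary = rt_surprise_association(runs)
        se = summary.slopes["slope"].std() / np.sqrt(summary.n_runs)
        assert abs(summary.mean_slope - beta) < 3 * se + 0.01
        assert summary.p_value < 0.001

    def test_constant_surprise_skipped_with_warning(self):
        df = run_frame([0.5] * 10)
        with pytest.warns(UserWarning):
            assert rt_surprise_slope(df, np.ones(10)) is None

    def test_slope_invariant_to_rt_shift(self):
        df = run_frame(list(np.linspace(0.4, 1.0, 12)))
        x = np.linspace(0, 2, 12)
        s1, _ = rt_surprise_slope(df, x)
        df2 = df.copy()
        df2["rt"] = df2["rt"] + 5.0
        s2, _ = rt_surprise_slope(df2, x)
        assert s1 == pytest.approx(s2)

    def test_short_run_skipped(self):
        df = run_frame([0.5, 0.6, 0.7])
        assert rt_surprise_slope(df, np.arange(3.0)) is None


@pytest.fixture(scope="module")
def exported(mr_run, typical_rl):
    from mslrl.ddm import DDMParams

    rec = simulate_run(mr_run, typical_rl, DDMParams(a=3.6, tau=1.2), 0.8,
                       seed=17)  # slow: yields omissions
    traces = run_model(mr_run, rec, typical_rl, vmod=0.8)
    surprise = shannon_surprise_trace(mr_run).surprise
    return mr_run, rec, export_regressors(mr_run, rec, traces, surprise)


class TestRegressors:
    def test_surprise_regressor_covers_all_trials(self, exported):
        seq, rec, regs = exported
        assert len(regs.stimulus_surprise) == len(seq)

    def test_rpe_and_nuisance_partition_trials(self, exported):
        seq, rec, regs = exported
        assert (
            len(regs.feedback_rpe)
            + len(regs.neutral_feedback)
            + len(regs.rt_outlier_feedback)
        ) == len(seq)
        assert rec.n_omissions == len(regs.neutral_feedback)

    def test_omission_in_neutral_not_rpe(self, exported):
        seq, rec, regs = exported
        onsets_fb = np.array([t.onset_feedback for t in seq])
        omitted_onsets = set(onsets_fb[[r is None for r in rec.responses]])
        assert omitted_onsets <= set(regs.neutral_feedback["onset"])
        assert not omitted_onsets & set(regs.feedback_rpe["onset"])

    def test_modulators_mean_centred(self, exported):
        _, _, regs = exported
        assert regs.stimulus_surprise["weight"].mean() == pytest.approx(0, abs=1e-12)
        assert regs.feedback_rpe["weight"].mean() == pytest.approx(0, abs=1e-12)

    def test_events_round_trip(self, exported, tmp_path):
        _, _, regs = exported
        paths = regs.write(tmp_path)
        back = pd.read_csv(paths["events"], sep="\t", float_precision="round_trip")
        np.testing.assert_array_equal(
            back["onset"].to_numpy(), regs.events["onset"].to_numpy()
        )
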