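"""Rescorla-Wagner variants: update algebra, normalization, drift mapping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mslrl.rl_models import (
    RLParams,
    ValueState,
    drift_rate,
    normalize_values,
    reward_prediction_error,
    run_model,
    update_values,
)
from mslrl.simulate import BehaviouralRecord
from mslrl.task_design import Trial, TrialSequence, default_config


def mr_toy_sequence(specs):
    """Tiny match-recognition run from (sound, visual, is_match) tuples."""
    cfg = default_config("match_recognition")
    trials = [
        Trial(index=i, audio_tactile=s, visual=v, is_match=m)
        for i, (s, v, m) in enumerate(specs)
    ]
    return TrialSequence(config=cfg, trials=trials)


def behaviour(responses, feedback, rts=None):
    n = len(responses)
    rts = rts if rts is not None else [0.8 if r else np.nan for r in responses]
    return BehaviouralRecord(responses=responses, rts=np.array(rts, float),
                             feedback=feedback)


class TestPrimitives:
    @pytest.mark.parametrize("R,V,expected", [(1, 0.5, 0.5), (0, 0.0, 0.0),
                                              (1, 0.675, 0.325)])
    def test_rpe(self, R, V, expected):
        assert reward_prediction_error(R, V) == pytest.approx(expected)

    def test_normalize_symmetry_and_hand_value(self):
        assert normalize_values(0.3, 0.3) == pytest.approx((0.5, 0.5))
        nc, no = normalize_values(0.8, 0.6)
        assert nc == pytest.approx(0.32 / 0.44)
        assert nc + no == pytest.approx(1.0)

    def test_normalize_extremes_no_division_error(self):
        nc, _ = normalize_values(1.0, 0.0)
        assert nc > 1 - 1e-5
        nc, _ = normalize_values(0.0, 0.0)  # both clamped, well defined
        assert nc == pytest.approx(0.5)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_normalize_sums_to_one_and_order_consistent(self, vc, vo):
        nc, no = normalize_values(vc, vo)
        assert nc + no == pytest.approx(1.0)
        assert (nc > 0.5) == (vc > vo) or vc == vo

    def test_drift_rate(self):
        assert drift_rate((0.5, 0.5), 3.0, "discriminative_choice") == 0.0
        assert drift_rate(0.75, 2.0, "match_recognition") == pytest.approx(1.0)
        v1 = drift_rate((0.8, 0.3), 2.0, "discriminative_choice")
        v2 = drift_rate((0.3, 0.8), 2.0, "discriminative_choice")
        assert v1 == pytest.approx(-v2)


class TestUpdates:
    def test_zero_learning_rate_identity(self, mr_run):
        state = ValueState(3, 3)
        params = RLParams(model="simple", eta_c=0.0)
        new = update_values(state, mr_run.trials[0], "match", 1, params,
                            "match_recognition")
        np.testing.assert_array_equal(new.values, state.values)

    def test_full_update_reaches_outcome(self):
        seq = mr_toy_sequence([("A", 0, True)])
        state = ValueState(3, 3)
        params = RLParams(model="simple", eta_c=1.0)
        new = update_values(state, seq.trials[0], "match", 1, params,
                            "match_recognition")
        assert new.get(0, 0) == pytest.approx(1.0)

    def test_dc_transfer_moves_pairs_in_opposite_directions(self, dc_config):
        tr = Trial(index=0, audio_tactile="A", visual_left=0, visual_right=2,
                   correct_side="left")
        state = ValueState(4, 4)
        params = RLParams(model="transfer", eta_c=0.5, eta_o=0.5)
        new = update_values(state, tr, "left", 1, params, "discriminative_choice")
        assert new.get(0, 0) > 0.5   # chosen pair value increased
        assert new.get(0, 2) < 0.5   # other pair value decreased

    def test_mr_transfer_updates_overlapping_pairs_after_positive_feedback(self):
        seq = mr_toy_sequence([("A", 0, True)])
        state = ValueState(3, 3)
        params = RLParams(model="transfer", eta_c=0.5, eta_o=0.25)
        new = update_values(state, seq.trials[0], "match", 1, params,
                            "match_recognition")
        # confirmed match: presented pair up, every overlapping pair down
        assert new.get(0, 0) > 0.5
        for s, v in [(0, 1), (0, 2), (1, 0), (2, 0)]:
            assert new.get(s, v) < 0.5
        assert new.get(1, 1) == 0.5  # non-overlapping untouched

    def test_mr_transfer_silent_after_negative_feedback(self):
        seq = mr_toy_sequence([("A", 0, True)])
        state = ValueState(3, 3)
        params = RLParams(model="transfer", eta_c=0.5, eta_o=0.25)
        new = update_values(state, seq.trials[0], "match", 0, params,
                            "match_recognition")
        assert new.get(0, 1) == 0.5

    def test_omission_leaves_state_unchanged(self, mr_run):
        state = ValueState(3, 3)
        params = RLParams(model="simple", eta_c=0.9)
        new = update_values(state, mr_run.trials[0], None, None, params,
                            "match_recognition")
        np.testing.assert_array_equal(new.values, state.values)

    @given(
        eta=st.floats(0.0, 1.0),
        outcomes=st.lists(st.integers(0, 1), min_size=1, max_size=30),
    )
    def test_values_stay_in_unit_interval(self, eta, outcomes):
        seq = mr_toy_sequence([("A", 0, True)] * len(outcomes))
        params = RLParams(model="transfer", eta_c=eta, eta_o=eta)
        state = ValueState(3, 3)
        for tr, R in zip(seq, outcomes):
            state = update_values(state, tr, "match", R, params,
                                  "match_recognition")
            assert np.all(state.values >= 0) and np.all(state.values <= 1)


class TestRunModel:
    def test_no_learning_baseline(self, mr_run, mr_behaviour):
        params = RLParams(model="simple", eta_c=0.0)
        traces = run_model(mr_run, mr_behaviour, params, vmod=2.0)
        responded = [r is not None for r in mr_behaviour.responses]
        assert np.allclose(traces.loc[responded, "V_chosen"], 0.5)
        expected_rpe = [
            o - 0.5 for o, r in zip(mr_behaviour.outcomes, responded) if r
        ]
        np.testing.assert_allclose(traces.loc[responded, "RPE"], expected_rpe)
        assert np.allclose(traces["drift"], 0.0)

    def test_five_trial_hand_simulation(self):
        """Forward pass equals an independent step-by-step recomputation."""
        specs = [("A", 0, True), ("A", 2, False), ("B", 1, True),
                 ("A", 0, True), ("C", 0, False)]
        responses = ["match", "match", "nonmatch", "match", "nonmatch"]
        feedback = ["positive", "negative", "negative", "positive", "positive"]
        seq = mr_toy_sequence(specs)
        beh = behaviour(responses, feedback)
        eta, vmod = 0.3, 2.0
        traces = run_model(seq, beh, RLParams(model="simple", eta_c=eta), vmod)
        # oracle: dict-based replay of the recoded delta rule
        V = {}
        for i, ((s, v, _m), resp, fb) in enumerate(zip(specs, responses, feedback)):
            key = (s, v)
            val = V.get(key, 0.5)
            assert traces["V_chosen"].iloc[i] == pytest.approx(val)
            assert traces["drift"].iloc[i] == pytest.approx((2 * val - 1) * vmod)
            R = 1 if fb == "positive" else 0
            assert traces["RPE"].iloc[i] == pytest.approx(R - val)
            r_prime = 1 if (resp == "match") == (R == 1) else 0
            V[key] = val + eta * (r_prime - val)

    def test_asymmetric_with_equal_rates_reproduces_symmetric(
        self, mr_run, mr_behaviour, dc_run, dc_behaviour
    ):
        for seq, beh in [(mr_run, mr_behaviour), (dc_run, dc_behaviour)]:
            sym = run_model(seq, beh, RLParams(model="simple", eta_c=0.37), 2.0)
            asym = run_model(
                seq, beh,
                RLParams(model="simple_asym", eta_c_pos=0.37, eta_c_neg=0.37), 2.0
            )
            np.testing.assert_array_equal(sym.to_numpy(), asym.to_numpy())
            symt = run_model(
                seq, beh, RLParams(model="transfer", eta_c=0.37, eta_o=0.21), 2.0
            )
            asymt = run_model(
                seq, beh,
                RLParams(model="transfer_asym", eta_c_pos=0.37, eta_c_neg=0.37,
                         eta_o=0.21, eta_o_pos=0.21, eta_o_neg=0.21), 2.0,
            )
            np.testing.assert_array_equal(symt.to_numpy(), asymt.to_numpy())

    def test_causality_prefix_invariance(self, mr_run, mr_behaviour):
        params = RLParams(model="simple", eta_c=0.4)
        full = run_model(mr_run, mr_behaviour, params, 2.0)
        half_seq = TrialSequence(config=mr_run.config, trials=mr_run.trials[:20])
        half_beh = BehaviouralRecord(
            responses=mr_behaviour.responses[:20],
            rts=mr_behaviour.rts[:20],
            feedback=mr_behaviour.feedback[:20],
        )
        half = run_model(half_seq, half_beh, params, 2.0)
        np.testing.assert_array_equal(full.iloc[:20].to_numpy(), half.to_numpy())

    def test_length_mismatch_rejected(self, mr_run):
        beh = behaviour(["match"], ["positive"])
        with pytest.raises(ValueError):
            run_model(mr_run, beh, RLParams(model="simple", eta_c=0.1), 1.0)
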