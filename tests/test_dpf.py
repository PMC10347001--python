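"""Engine mechanics: routing, debounce commits, latency, reductions."""

import numpy as np
import pytest

from gaitdpf import (
    DPFConfig,
    DPFState,
    Phase,
    label_windows,
    model_for_phase,
    next_phase,
    run_stream,
    step,
)
from gaitdpf.dpf import UNDETERMINED
from gaitdpf.labeling import ONE_HOT


class ScriptedModel:
    """Mock classifier that replays a fixed per-window phase sequence.

    Sharing one instance across all model ids makes the script independent
    of the engine's routing decisions.
    """

    def __init__(self, seq):
        self.seq = [int(p) for p in seq]
        self.i = 0

    def predict_on_raw(self, windows6):
        out = ONE_HOT[self.seq[self.i]][None]
        self.i += 1
        return out


def scripted_models(seq):
    m = ScriptedModel(seq)
    return {"LSTM-CNN-1": m, "LSTM-CNN-2": m, "LSTM-CNN-3": m}


def debounce_reference(seq, k):
    """Independent debounce: commit after k consecutive identical values."""
    out, committed, cand, count = [], UNDETERMINED, None, 0
    for p in seq:
        count = count + 1 if p == cand else 1
        cand = p
        if count >= k and p != committed:
            committed = p
        out.append(committed)
    return np.array(out, dtype=np.int8)


class TestNextPhase:
    @pytest.mark.parametrize(
        "a,b",
        [
            (Phase.SU_RHS, Phase.SW_L),
            (Phase.SW_L, Phase.SU_LHS),
            (Phase.SU_LHS, Phase.SW_R),
            (Phase.SW_R, Phase.SU_RHS),
        ],
    )
    def test_cyclic_order(self, a, b):
        assert next_phase(a) == b

    def test_fourth_power_is_identity(self):
        for p in Phase:
            q = p
            for _ in range(4):
                q = next_phase(q)
            assert q == p


class TestModelForPhase:
    def test_default_map(self):
        cfg = DPFConfig()
        assert model_for_phase(Phase.SU_RHS, cfg) == "LSTM-CNN-1"
        assert model_for_phase(Phase.SW_L, cfg) == "LSTM-CNN-2"
        assert model_for_phase(Phase.SU_LHS, cfg) == "LSTM-CNN-3"
        assert model_for_phase(Phase.SW_R, cfg) == "LSTM-CNN-1"

    def test_incomplete_map_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            DPFConfig(model_map={Phase.SU_RHS: "LSTM-CNN-1"})

    def test_debounce_must_be_positive(self):
        with pytest.raises(ValueError, match="debounce"):
            DPFConfig(debounce_k=0)


class TestStep:
    def _run(self, seq, k=5):
        cfg = DPFConfig(debounce_k=k)
        models = scripted_models(seq)
        state = DPFState.initial(cfg)
        commits = []
        window = np.zeros((20, 6))
        for _ in seq:
            state, committed_now, pred = step(state, window, models, cfg)
            commits.append(committed_now)
        return state, commits

    def test_five_consecutive_commit_on_fifth(self):
        seq = [Phase.SW_L] * 5
        state, commits = self._run(seq)
        assert commits == [None, None, None, None, Phase.SW_L]
        assert state.committed == Phase.SW_L
        assert state.expected_next == Phase.SU_LHS
        # the committed phase's own specialist takes over
        assert state.active_model == "LSTM-CNN-2"

    def test_interrupted_run_resets_candidate(self):
        seq = [Phase.SW_L] * 4 + [Phase.SW_R]
        state, commits = self._run(seq)
        assert commits == [None] * 5
        assert state.committed is None
        assert state.candidate == Phase.SW_R
        assert state.count == 1

    def test_active_model_before_first_commit_is_initial(self):
        cfg = DPFConfig()
        state = DPFState.initial(cfg)
        assert state.active_model == cfg.initial_model == "LSTM-CNN-1"

    def test_wrong_window_shape_rejected(self):
        cfg = DPFConfig()
        with pytest.raises(ValueError, match="full"):
            step(
                DPFState.initial(cfg),
                np.zeros((20, 4)),
                scripted_models([Phase.SU_RHS]),
                cfg,
            )

    def test_out_of_sequence_commit_reanchors_and_warns(self, caplog):
        seq = [Phase.SU_RHS] * 5 + [Phase.SW_R] * 5
        with caplog.at_level("WARNING", logger="gaitdpf.dpf"):
            state, commits = self._run(seq)
        assert "out-of-sequence" in caplog.text
        assert state.committed == Phase.SW_R
        assert state.expected_next == Phase.SU_RHS  # re-anchored

    def test_debounce_one_reduces_to_per_window_switching(self):
        seq = [Phase.SU_RHS, Phase.SW_L, Phase.SW_L, Phase.SU_LHS]
        state, commits = self._run(seq, k=1)
        assert commits == [Phase.SU_RHS, Phase.SW_L, None, Phase.SU_LHS]


class TestRunStream:
    def test_truth_oracle_committed_track_lags_by_k_minus_1(self, clean_recording):
        # with perfect classifiers the committed track is the true window
        # track delayed by exactly debounce_k - 1 = 4 windows
        truth = label_windows(
            np.arange(clean_recording.n_samples - 19), clean_recording.truth_phase
        )
        res = run_stream(clean_recording, scripted_models(truth), DPFConfig())
        k = 5
        n = len(truth)
        np.testing.assert_array_equal(res.committed_track[: k - 1], UNDETERMINED)
        np.testing.assert_array_equal(res.committed_track[k - 1 :], truth[: n - (k - 1)])
        # the prediction track is scored, and here it is perfect
        assert res.report is not None and res.report.accuracy == 1.0

    def test_isolated_flips_never_reach_committed_track(self, clean_recording):
        truth = label_windows(
            np.arange(clean_recording.n_samples - 19), clean_recording.truth_phase
        )
        corrupted = truth.copy()
        rng = np.random.default_rng(0)
        flip_at = rng.choice(np.arange(30, len(truth) - 30), size=40, replace=False)
        for i in flip_at:
            if np.ptp(truth[i - 5 : i + 6]) == 0:  # inside a stable segment
                corrupted[i] = (truth[i] + 2) % 4
        res = run_stream(clean_recording, scripted_models(corrupted), DPFConfig())
        for i in flip_at:
            if corrupted[i] != truth[i]:
                assert res.committed_track[i] != corrupted[i]

    def test_committed_track_transitions_follow_cycle(self, clean_recording):
        truth = label_windows(
            np.arange(clean_recording.n_samples - 19), clean_recording.truth_phase
        )
        res = run_stream(clean_recording, scripted_models(truth), DPFConfig())
        tr = res.committed_track[res.committed_track != UNDETERMINED]
        changes = np.nonzero(np.diff(tr) != 0)[0]
        for i in changes:
            assert Phase(int(tr[i + 1])) == Phase(int(tr[i])).successor()

    def test_all_to_one_map_equals_debounced_single_model(self, clean_recording):
        # route every phase to LSTM-CNN-1: the committed track must match an
        # independently computed debounce of that model's prediction stream
        truth = label_windows(
            np.arange(clean_recording.n_samples - 19), clean_recording.truth_phase
        )
        rng = np.random.default_rng(3)
        noisy = truth.copy()
        flips = rng.choice(len(truth), size=60, replace=False)
        noisy[flips] = rng.integers(0, 4, size=60)
        cfg = DPFConfig(model_map={p: "LSTM-CNN-1" for p in Phase})
        models = {"LSTM-CNN-1": ScriptedModel(noisy)}
        res = run_stream(clean_recording, models, cfg)
        np.testing.assert_array_equal(
            res.committed_track, debounce_reference(noisy, cfg.debounce_k)
        )

    def test_trace_records_cover_every_window(self, clean_recording):
        truth = label_windows(
            np.arange(clean_recording.n_samples - 19), clean_recording.truth_phase
        )
        res = run_stream(clean_recording, scripted_models(truth), DPFConfig())
        recs = res.trace_records()
        assert len(recs) == len(res.starts)
        assert recs[0]["committed"] is None
        assert recs[10]["active_model"] in {"LSTM-CNN-1", "LSTM-CNN-2", "LSTM-CNN-3"}
        assert recs[-1]["truth"] == Phase(int(truth[-1])).label
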