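"""Phase-sequence-driven model switching: the DPF inference engine.

Because the four gait phases always appear in the fixed cyclic order
SU-RHS → SW-L → SU-LHS → SW-R → …, the phase that will occur next is known
as soon as the current phase is recognized.  The engine exploits this: once
a phase is committed, its windows are classified by the specialist that
recognizes that phase best (the shanks+feet model for SW-L, the
thighs+shanks model for SU-LHS, the full six-site model otherwise), with
the successor phase — and hence the next specialist to load — known in
advance.  A phase change is only *committed* after ``debounce_k``
consecutive identical predictions (default 5), which suppresses isolated
mispredictions at the cost of a fixed commit latency of ``debounce_k - 1``
windows at each true transition.

Two per-window outputs are therefore distinguished:

* the **prediction track** — the active specialist's argmax at every
  window; this is what the evaluation report scores, so the comparison
  against a single always-on model is like-for-like;
* the **committed track** — the debounced phase, which lags transitions by
  exactly ``debounce_k - 1`` windows under error-free prediction and is
  the signal a downstream controller would consume.

Before the first commit the committed phase is "undetermined" (code -1)
and the initial model (the full six-site one) is active.  If a commit ever
disagrees with the expected next phase, the engine accepts it, re-anchors
the cycle state, and logs the sequence violation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Protocol

import numpy as np

from .labeling import decode, label_windows, phases_from_grf
from .metrics import MetricsReport, evaluate
from .phases import Phase
from .preprocess import WINDOW_LEN, interpolate_recording, window_stack
from .synthgait import GaitRecording

logger = logging.getLogger(__name__)

#: committed-track code for "no phase committed yet"
UNDETERMINED = -1


class PhasePredictor(Protocol):
    """Anything that maps raw six-channel windows to phase probabilities."""

    def predict_on_raw(self, windows6: np.ndarray) -> np.ndarray: ...


def next_phase(phase: Phase | int) -> Phase:
    """The successor in the cycle SU-RHS→SW-L→SU-LHS→SW-R→SU-RHS."""
    return Phase(phase).successor()


@dataclass(frozen=True)
class DPFConfig:
    """Phase→model routing and the consecutive-prediction commit rule."""

    model_map: Mapping[Phase, str] = field(
        default_factory=lambda: {
            Phase.SU_RHS: "LSTM-CNN-1",
            Phase.SW_L: "LSTM-CNN-2",
            Phase.SU_LHS: "LSTM-CNN-3",
            Phase.SW_R: "LSTM-CNN-1",
        }
    )
    debounce_k: int = 5
    initial_model: str = "LSTM-CNN-1"

    def __post_init__(self) -> None:
        missing = [p.label for p in Phase if p not in self.model_map]
        if missing:
            raise ValueError(f"model map does not cover phase(s): {missing}")
        if self.debounce_k < 1:
            raise ValueError("debounce_k must be >= 1")


def model_for_phase(phase: Phase | int, config: DPFConfig) -> str:
    """The id of the specialist model assigned to a phase."""
    phase = Phase(phase)
    try:
        return config.model_map[phase]
    except KeyError:
        raise ValueError(f"no model mapped for phase {phase.label}") from None


@dataclass(frozen=True)
class DPFState:
    """Engine state between windows."""

    active_model: str
    committed: Phase | None = None
    expected_next: Phase | None = None
    candidate: Phase | None = None
    count: int = 0

    @classmethod
    def initial(cls, config: DPFConfig) -> "DPFState":
        return cls(active_model=config.initial_model)


def step(
    state: DPFState,
    window6: np.ndarray,
    models: Mapping[str, PhasePredictor],
    config: DPFConfig,
) -> tuple[DPFState, Phase | None, Phase]:
    """Process one raw six-channel window.

    Returns ``(new_state, committed_now, prediction)`` where
    ``committed_now`` is the newly committed phase (None when no commit
    happened this window) and ``prediction`` is the active model's argmax.
    """
    window6 = np.asarray(window6)
    if window6.shape != (WINDOW_LEN, 6):
        raise ValueError(
            f"DPF step needs a full ({WINDOW_LEN}, 6) window, got {window6.shape}"
        )
    if state.active_model not in models:
        raise ValueError(f"model {state.active_model!r} not provided")
    probs = models[state.active_model].predict_on_raw(window6[None])[0]
    pred = decode(probs)

    if pred == state.candidate:
        count = min(state.count + 1, config.debounce_k)
    else:
        count = 1
    new = replace(state, candidate=pred, count=count)

    committed_now: Phase | None = None
    if count >= config.debounce_k and pred != state.committed:
        committed_now = pred
        if state.expected_next is not None and pred != state.expected_next:
            logger.warning(
                "out-of-sequence commit: expected %s but committed %s; re-anchoring",
                state.expected_next.label,
                pred.label,
            )
        # the committed phase is now current: hand its windows to its own
        # specialist; the successor is what the engine expects to see next
        new = replace(
            new,
            committed=pred,
            expected_next=next_phase(pred),
            active_model=model_for_phase(pred, config),
        )
    return new, committed_now, pred


@dataclass
class DPFResult:
    """Per-window traces and the evaluation of one streamed recording."""

    starts: np.ndarray
    prediction_track: np.ndarray  # active model's argmax per window
    committed_track: np.ndarray  # debounced phase per window, -1 pre-commit
    active_models: list[str]
    truth: np.ndarray | None = None  # truth window labels, if available
    report: MetricsReport | None = None  # scores prediction_track vs truth

    def trace_records(self) -> list[dict]:
        out = []
        for i in range(len(self.starts)):
            rec = {
                "window": int(i),
                "start": int(self.starts[i]),
                "active_model": self.active_models[i],
                "prediction": Phase(int(self.prediction_track[i])).label,
                "committed": (
                    None
                    if self.committed_track[i] == UNDETERMINED
                    else Phase(int(self.committed_track[i])).label
                ),
            }
            if self.truth is not None:
                rec["truth"] = Phase(int(self.truth[i])).label
            out.append(rec)
        return out


def run_stream(
    recording: GaitRecording,
    models: Mapping[str, PhasePredictor],
    config: DPFConfig | None = None,
    stride: int = 1,
    evaluate_truth: bool = True,
) -> DPFResult:
    """Stream a recording through the engine, window by window.

    Missing samples are interpolated first; windows advance by ``stride``
    samples (1 emulates real-time recognition).  When the recording carries
    ground truth (or GRF channels to derive it from), every window gets a
    truth label (the phase of its final sample) and the result includes a
    MetricsReport of the prediction track against those labels.
    """
    config = config or DPFConfig()
    rec = interpolate_recording(recording)
    stack, starts = window_stack(rec.angle_matrix(), WINDOW_LEN, stride)

    n = len(starts)
    state = DPFState.initial(config)
    pred_track = np.empty(n, dtype=np.int8)
    committed_track = np.full(n, UNDETERMINED, dtype=np.int8)
    active: list[str] = []
    for i in range(n):
        active.append(state.active_model)
        state, _, pred = step(state, stack[i], models, config)
        pred_track[i] = int(pred)
        if state.committed is not None:
            committed_track[i] = int(state.committed)

    truth_labels = None
    report = None
    if evaluate_truth:
        track = rec.truth_phase
        if track is None:
            track = phases_from_grf(rec.grf_left, rec.grf_right)
        truth_labels = label_windows(starts, track, WINDOW_LEN)
        report = evaluate(truth_labels, pred_track)
    return DPFResult(
        starts=starts,
        prediction_track=pred_track,
        committed_track=committed_track,
        active_models=active,
        truth=truth_labels,
        report=report,
    )
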