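"""Per-sample phase labels from bilateral plantar force.

Ground truth for training comes from the ground-reaction-force channels:
a foot is in contact with the ground when its measured force reaches the
20 N threshold (values exactly at the threshold count as contact, making
the condition closed and deterministic on boundary samples).  Heel-strike
and toe-off events are the rising and falling edges of the two contact
tracks, and each event opens one of the four phases:

    right heel strike  -> SU-RHS      left toe-off      -> SW-L
    left heel strike   -> SU-LHS      right toe-off     -> SW-R

Samples before the first recognizable event carry the label implied by
extending the first event backwards; samples where both feet are off the
ground (not expected during walking) hold the previous phase and raise a
logged warning.
"""

from __future__ import annotations

import logging

import numpy as np

from .phases import N_PHASES, Phase
from .synthgait import CONTACT_THRESHOLD_N

logger = logging.getLogger(__name__)

#: one-hot rows in phase order: SU-RHS, SW-L, SU-LHS, SW-R
ONE_HOT = np.eye(N_PHASES)


def detect_contact(
    grf: np.ndarray, threshold: float = CONTACT_THRESHOLD_N
) -> np.ndarray:
    """Boolean ground-contact track: contact iff grf >= threshold."""
    grf = np.asarray(grf, dtype=float)
    if np.any(grf < 0):
        raise ValueError("GRF contains negative force values")
    return grf >= threshold


def derive_phases(
    left_contact: np.ndarray, right_contact: np.ndarray
) -> np.ndarray:
    """Phase codes for every sample, from the two contact tracks.

    The state machine is anchored on contact edges; at least one edge must
    be present.  Returns an int8 array of :class:`~gaitdpf.phases.Phase`
    codes.
    """
    left = np.asarray(left_contact, dtype=bool)
    right = np.asarray(right_contact, dtype=bool)
    if left.shape != right.shape:
        raise ValueError("contact tracks must have equal length")
    n = len(left)
    if n == 0:
        raise ValueError("empty contact tracks")

    # edges at index i mean track[i-1] != track[i]
    events: list[tuple[int, Phase]] = []
    for track, rising_phase, falling_phase in (
        (right, Phase.SU_RHS, Phase.SW_R),
        (left, Phase.SU_LHS, Phase.SW_L),
    ):
        d = np.diff(track.astype(np.int8))
        for i in np.nonzero(d > 0)[0] + 1:
            events.append((int(i), rising_phase))
        for i in np.nonzero(d < 0)[0] + 1:
            events.append((int(i), falling_phase))
    if not events:
        raise ValueError("contact tracks contain no edges; cannot anchor phases")
    events.sort(key=lambda e: (e[0], int(e[1])))

    phases = np.empty(n, dtype=np.int8)
    first_idx, first_phase = events[0]
    phases[:first_idx] = int(first_phase.predecessor())
    for (i, ph), (j, _) in zip(events, events[1:] + [(n, events[-1][1])]):
        phases[i:j] = int(ph)

    flight = ~left & ~right
    if flight.any():
        logger.warning(
            "both feet off the ground at %d sample(s); holding previous phase",
            int(flight.sum()),
        )
    return phases


def phases_from_grf(
    grf_left: np.ndarray,
    grf_right: np.ndarray,
    threshold: float = CONTACT_THRESHOLD_N,
) -> np.ndarray:
    """Convenience: threshold both GRF channels and derive the phase track."""
    return derive_phases(
        detect_contact(grf_left, threshold), detect_contact(grf_right, threshold)
    )


def one_hot(phase: Phase | int) -> np.ndarray:
    """The 4-vector encoding of a phase: SU-RHS=[1,0,0,0] ... SW-R=[0,0,0,1]."""
    return ONE_HOT[int(Phase(phase))].copy()


def decode(probabilities: np.ndarray) -> Phase:
    """Inverse of :func:`one_hot` by argmax over a probability 4-vector.

    Ties resolve deterministically to the lowest cyclic index (and are
    logged); exact one-hot vectors round-trip.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.shape != (N_PHASES,):
        raise ValueError(f"expected a length-{N_PHASES} vector, got shape {p.shape}")
    winners = np.nonzero(p == p.max())[0]
    if len(winners) > 1:
        logger.warning("argmax tie between phases %s; choosing lowest index", winners)
    return Phase(int(winners[0]))


def label_window(
    start: int,
    phase_track: np.ndarray,
    window_len: int = 20,
    rule: str = "last",
) -> Phase:
    """Label of the window starting at ``start``: its final sample's phase.

    The causal "last sample" rule is the default (matches streaming use,
    where the label is the phase being entered); ``rule="majority"`` labels
    by the most frequent phase in the window, ties to the earliest phase in
    cyclic order.
    """
    end = start + window_len
    if start < 0 or end > len(phase_track):
        raise IndexError("window exceeds phase track bounds")
    if rule == "last":
        return Phase(int(phase_track[end - 1]))
    if rule == "majority":
        counts = np.bincount(phase_track[start:end], minlength=N_PHASES)
        return Phase(int(np.argmax(counts)))
    raise ValueError(f"unknown window labeling rule {rule!r}")


def label_windows(
    starts: np.ndarray,
    phase_track: np.ndarray,
    window_len: int = 20,
    rule: str = "last",
) -> np.ndarray:
    """Vectorized :func:`label_window` over many window start indices."""
    starts = np.asarray(starts, dtype=int)
    if rule == "last":
        return np.asarray(phase_track, dtype=np.int8)[starts + window_len - 1]
    return np.array(
        [int(label_window(int(s), phase_track, window_len, rule)) for s in starts],
        dtype=np.int8,
    )
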