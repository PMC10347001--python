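"""The four-phase gait alphabet and the fixed sensor-site ordering.

A level walking cycle is segmented into four phases that repeat in a fixed
cyclic order: the double-support phase that begins at right heel strike
(SU-RHS), the left swing phase (SW-L), the double-support phase that begins
at left heel strike (SU-LHS), and the right swing phase (SW-R).  Every module
in this package indexes phases by the integer codes defined here.
"""

from __future__ import annotations

import enum


class Phase(enum.IntEnum):
    """One gait phase, ordered by its position in the cycle."""

    SU_RHS = 0
    SW_L = 1
    SU_LHS = 2
    SW_R = 3

    @property
    def label(self) -> str:
        """The conventional hyphenated name, e.g. ``"SU-RHS"``."""
        return PHASE_NAMES[int(self)]

    @classmethod
    def from_label(cls, label: str) -> "Phase":
        try:
            return cls(PHASE_NAMES.index(label))
        except ValueError:
            raise ValueError(f"unknown phase label {label!r}") from None

    def successor(self) -> "Phase":
        """The next phase in the cyclic order SU-RHS→SW-L→SU-LHS→SW-R→…"""
        return Phase((int(self) + 1) % 4)

    def predecessor(self) -> "Phase":
        return Phase((int(self) - 1) % 4)


PHASE_NAMES: tuple[str, ...] = ("SU-RHS", "SW-L", "SU-LHS", "SW-R")
N_PHASES = 4

#: Canonical ordering of the six IMU sites on the lower limbs.  All
#: multi-channel arrays in this package use this column order (or an
#: order-preserving subset of it for smaller sensor groups).
SITES: tuple[str, ...] = (
    "L_thigh",
    "R_thigh",
    "L_shank",
    "R_shank",
    "L_foot",
    "R_foot",
)
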