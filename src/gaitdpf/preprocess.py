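"""Interpolation of dropped samples, [-1, 1] normalization, sliding windows,
and sensor-group channel selection.

The preprocessing contract is deliberately minimal: lost samples are filled
by linear interpolation between their nearest present neighbours, every
channel is mapped affinely so that the *training-set* minimum and maximum
land on -1 and +1 (test values may exceed that range; no clamping), and the
streams are cut into fixed-length 20-sample windows.  Seven sensor groups —
subsets of the six IMU sites — define which channels a classifier sees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .phases import Phase, SITES
from .synthgait import GaitRecording

WINDOW_LEN = 20

#: The seven sensor-site combinations, keyed by group id: three 2-IMU
#: groups (thighs / shanks / feet), three 4-IMU groups, and the full set.
SENSOR_GROUPS: dict[int, tuple[str, ...]] = {
    1: ("L_thigh", "R_thigh"),
    2: ("L_shank", "R_shank"),
    3: ("L_foot", "R_foot"),
    4: ("L_thigh", "R_thigh", "L_shank", "R_shank"),
    5: ("L_thigh", "R_thigh", "L_foot", "R_foot"),
    6: ("L_shank", "R_shank", "L_foot", "R_foot"),
    7: SITES,
}


@dataclass(frozen=True)
class SensorGroup:
    """One of the seven IMU placement combinations."""

    group_id: int
    sites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.group_id not in SENSOR_GROUPS:
            raise ValueError(f"sensor group id must be 1..7, got {self.group_id}")
        expected = SENSOR_GROUPS[self.group_id]
        if not self.sites:
            object.__setattr__(self, "sites", expected)
        elif tuple(self.sites) != expected:
            raise ValueError(
                f"group {self.group_id} sites must be {expected}, got {self.sites}"
            )

    @property
    def n_channels(self) -> int:
        return len(self.sites)


@dataclass
class Window:
    """A fixed-length segment of selected channels with an optional label."""

    samples: np.ndarray  # (WINDOW_LEN, C)
    label: Phase | None = None
    origin: tuple[str, int] | None = None  # (recording id, start index)

    def __post_init__(self) -> None:
        if self.samples.ndim != 2 or self.samples.shape[0] != WINDOW_LEN:
            raise ValueError(
                f"window must have exactly {WINDOW_LEN} rows, got {self.samples.shape}"
            )


# ---------------------------------------------------------------------------
# linear interpolation of lost samples

def interpolate_missing(series: np.ndarray) -> np.ndarray:
    """Fill NaN entries by linear interpolation between present neighbours.

    For a missing sample at index x with nearest present neighbours
    (x0, y0) and (x1, y1), the filled value is
    y = (x - x0) / (x1 - x0) * (y1 - y0) + y0.  Present samples are
    returned unchanged; a complete series round-trips exactly.
    """
    series = np.asarray(series, dtype=float)
    missing = np.isnan(series)
    if not missing.any():
        return series.copy()
    if missing[0] or missing[-1]:
        raise ValueError("cannot interpolate: first or last sample is missing")
    idx = np.arange(len(series))
    out = series.copy()
    out[missing] = np.interp(idx[missing], idx[~missing], series[~missing])
    return out


def interpolate_recording(recording: GaitRecording) -> GaitRecording:
    """Apply :func:`interpolate_missing` to every angle channel."""
    import dataclasses

    return dataclasses.replace(
        recording,
        angles={s: interpolate_missing(recording.angles[s]) for s in SITES},
    )


# ---------------------------------------------------------------------------
# normalization

@dataclass
class NormalizerParams:
    """Per-channel affine map onto [y_min, y_max] fitted on training data."""

    channels: tuple[str, ...]
    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float = -1.0
    y_max: float = 1.0

    def __post_init__(self) -> None:
        self.x_min = np.asarray(self.x_min, dtype=float)
        self.x_max = np.asarray(self.x_max, dtype=float)
        bad = np.nonzero(~(self.x_max > self.x_min))[0]
        if bad.size:
            names = ", ".join(self.channels[i] for i in bad)
            raise ValueError(f"constant channel(s) cannot be normalized: {names}")

    def subset(self, sites: Sequence[str]) -> "NormalizerParams":
        """Parameters restricted to a channel subset, in the given order."""
        pos = [self.channels.index(s) for s in sites]
        return NormalizerParams(
            channels=tuple(sites),
            x_min=self.x_min[pos],
            x_max=self.x_max[pos],
            y_min=self.y_min,
            y_max=self.y_max,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "channels": list(self.channels),
                    "x_min": self.x_min.tolist(),
                    "x_max": self.x_max.tolist(),
                    "y_min": self.y_min,
                    "y_max": self.y_max,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "NormalizerParams":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            channels=tuple(d["channels"]),
            x_min=np.array(d["x_min"]),
            x_max=np.array(d["x_max"]),
            y_min=d["y_min"],
            y_max=d["y_max"],
        )


def fit_normalizer(
    recordings: Iterable[GaitRecording], channels: Sequence[str] = SITES
) -> NormalizerParams:
    """Per-channel min/max over the given (training) recordings.

    Fit on training data only and reuse the frozen parameters on test data,
    so no test information leaks into the scaling.
    """
    channels = tuple(channels)
    mins = np.full(len(channels), np.inf)
    maxs = np.full(len(channels), -np.inf)
    seen = False
    for rec in recordings:
        seen = True
        for j, ch in enumerate(channels):
            v = rec.angles[ch]
            if np.isnan(v).any():
                raise ValueError(
                    f"channel {ch!r} contains missing samples; interpolate first"
                )
            mins[j] = min(mins[j], float(np.min(v)))
            maxs[j] = max(maxs[j], float(np.max(v)))
    if not seen:
        raise ValueError("no recordings to fit on")
    return NormalizerParams(channels=channels, x_min=mins, x_max=maxs)


def apply_normalizer(params: NormalizerParams, data: np.ndarray) -> np.ndarray:
    """Affine map x -> (x - x_min)/(x_max - x_min)*(y_max - y_min) + y_min.

    ``data`` has channels on its last axis, in ``params.channels`` order.
    Values outside the fitted range map outside [y_min, y_max]; the map is
    affine, not saturating.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[-1] != len(params.channels):
        raise ValueError(
            f"expected {len(params.channels)} channels on the last axis, "
            f"got shape {data.shape}"
        )
    span = params.x_max - params.x_min
    scale = (params.y_max - params.y_min) / span
    return (data - params.x_min) * scale + params.y_min


# ---------------------------------------------------------------------------
# sliding windows and channel selection

def window_starts(n_samples: int, window_len: int = WINDOW_LEN, stride: int = 1) -> np.ndarray:
    if window_len < 1 or stride < 1:
        raise ValueError("window_len and stride must be positive")
    if n_samples < window_len:
        raise ValueError(
            f"recording of {n_samples} samples is shorter than window_len={window_len}"
        )
    return np.arange(0, n_samples - window_len + 1, stride)


def window_stack(
    matrix: np.ndarray, window_len: int = WINDOW_LEN, stride: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """All sliding windows of a (n, C) matrix as a (N, window_len, C) stack.

    Returns (stack, starts); starts[i] is the sample index of row 0 of
    window i.  N = floor((n - window_len)/stride) + 1.
    """
    matrix = np.ascontiguousarray(matrix)
    starts = window_starts(matrix.shape[0], window_len, stride)
    view = np.lib.stride_tricks.sliding_window_view(matrix, window_len, axis=0)
    # view: (n - window_len + 1, C, window_len) -> select strides, reorder
    stack = np.transpose(view[starts], (0, 2, 1))
    return np.ascontiguousarray(stack), starts


def segment_windows(
    recording: GaitRecording,
    window_len: int = WINDOW_LEN,
    stride: int = 1,
) -> list[Window]:
    """Cut a recording's 6-channel angle matrix into unlabeled windows."""
    stack, starts = window_stack(recording.angle_matrix(), window_len, stride)
    rec_id = f"{recording.subject_id}@{recording.speed}"
    return [
        Window(samples=stack[i], origin=(rec_id, int(starts[i])))
        for i in range(len(starts))
    ]


def select_channels(
    windows: np.ndarray | Sequence[Window],
    group: SensorGroup | int,
    source_sites: Sequence[str] = SITES,
) -> np.ndarray | list[Window]:
    """Restrict windows to a sensor group's sites, in canonical site order.

    Accepts either a (N, T, C) stack or a list of :class:`Window`; returns
    the same kind.  Group 7 over the full site list is the identity
    selection.
    """
    if isinstance(group, int):
        group = SensorGroup(group)
    source_sites = list(source_sites)
    missing = [s for s in group.sites if s not in source_sites]
    if missing:
        raise ValueError(f"source windows lack required site(s): {missing}")
    cols = [source_sites.index(s) for s in group.sites]
    if isinstance(windows, np.ndarray):
        return windows[..., cols]
    return [
        Window(samples=w.samples[:, cols], label=w.label, origin=w.origin)
        for w in windows
    ]
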