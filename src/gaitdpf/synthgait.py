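"""Seeded synthetic multi-IMU walking data with exact ground-truth phases.

Real lower-limb recordings of this kind (six joint-angle channels from IMUs
on the thighs, shanks and feet, plus bilateral plantar ground-reaction force,
all sampled at 100 Hz) are rarely shareable, so this module emulates the
collection protocol instead: a cohort of subjects walking at slow / medium /
fast speeds (≈1.2, 1.5, 1.8 m/s), ten gait cycles per speed, with stance
occupying ≈60% of the cycle and each double-support phase ≈10%.

The generator is built so that the 20 N ground-contact threshold used for
labeling is *exact* on its output: each GRF channel equals the threshold
precisely at the intended heel-strike instant, strictly exceeds it inside
stance, and is zero throughout swing.  Joint angles are smooth truncated
Fourier series of the cycle phase (order 3, site-specific coefficients,
left/right half-cycle offset), perturbed ±10% per subject, plus additive
Gaussian sensor noise.

Two phase-targeted disturbances make sensor sites differentially
informative — the condition under which per-phase specialist models pay
off.  They emulate strap slack that accumulates over a recording session:
the thigh channels around the SW-L onset, and the foot channels around the
SU-LHS onset, are smoothly warped in time by an offset that grows cycle by
cycle (plus small jitter), delaying the transition those channels appear
to show.  Early (training) cycles carry little slip, later (held-out)
cycles carry more, so a classifier that reads the affected channels
systematically mislocates exactly that transition on held-out cycles,
while models without those channels are untouched.  Shank+foot sites are
consequently the reliable witnesses of the SW-L onset, and thigh+shank
sites of the SU-LHS onset, by construction.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .phases import PHASE_NAMES, Phase, SITES

#: Ground-contact force threshold (newtons) used throughout the pipeline.
CONTACT_THRESHOLD_N = 20.0

# Truncated Fourier coefficients per site type for the *right* leg:
# angle(phi) = mean + sum_k amp_k * cos(2*pi*k*phi + phase_k), degrees.
# Left-leg sites evaluate the same series at phi + 0.5 (half-cycle offset).
# Values are loosely shaped on sagittal-plane hip/knee/ankle excursions
# during level walking; only smoothness, periodicity and per-phase
# distinctness matter to the method.
_SITE_WAVEFORMS: dict[str, tuple[float, tuple[float, ...], tuple[float, ...]]] = {
    "thigh": (12.0, (18.0, 4.0, 1.5), (0.3, 1.0, 2.0)),
    "shank": (-20.0, (25.0, 8.0, 3.0), (1.8, 0.4, 2.6)),
    "foot": (2.0, (10.0, 6.0, 2.5), (2.4, 1.2, 0.3)),
}


class ConfigError(ValueError):
    """Raised when a :class:`SynthConfig` violates its invariants."""


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-level parameters of the synthetic walking protocol.

    Defaults reproduce the emulated study conditions: 20 subjects, three
    speeds, ten cycles per speed, 60/40 stance/swing with symmetric 10%
    double supports, 100 Hz sampling, 0.5° sensor noise, 1% packet loss.
    """

    n_subjects: int = 20
    speeds: tuple[float, ...] = (1.2, 1.5, 1.8)
    cycles_per_speed: int = 10
    stance_fraction: float = 0.6
    double_support_fraction: float = 0.1
    sample_rate: float = 100.0
    noise_sd: float = 0.5
    packet_loss_rate: float = 0.01
    peak_grf: float = 700.0
    seed: int = 0
    #: stride length (m) used for cadence scaling: cycle_duration = stride/speed
    stride_length_m: float = 1.8
    #: ±fractional perturbation of waveform coefficients per subject
    subject_variability: float = 0.10
    #: thigh channels slip around the SW-L onset (session time-warp)
    swl_thigh_artifact: bool = True
    #: foot channels slip around the SU-LHS onset (session time-warp)
    sulhs_foot_artifact: bool = True
    #: timing slip (cycle fraction) reached by the session's final cycle
    session_slip: float = 0.12
    #: per-cycle random jitter (cycle fraction) added to the slip
    slip_jitter: float = 0.02
    #: width (cycle fraction) of the warped zone around the affected onset
    slip_zone_width: float = 0.08

    def __post_init__(self) -> None:
        sf, ds = self.stance_fraction, self.double_support_fraction
        if not (0.0 < sf < 1.0) or ds <= 0.0:
            raise ConfigError("stance and double-support fractions must be in (0,1)")
        if not 2.0 * ds < sf:
            raise ConfigError(
                f"need 2*double_support_fraction < stance_fraction < 1, got "
                f"ds={ds}, stance={sf}"
            )
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        if not 0.0 <= self.packet_loss_rate < 1.0:
            raise ConfigError("packet_loss_rate must be in [0, 1)")
        if self.n_subjects < 1 or self.cycles_per_speed < 1:
            raise ConfigError("need at least one subject and one cycle")
        if any(s <= 0 for s in self.speeds):
            raise ConfigError("walking speeds must be positive")
        if self.noise_sd < 0 or self.peak_grf <= CONTACT_THRESHOLD_N:
            raise ConfigError(
                f"noise_sd must be >= 0 and peak_grf > {CONTACT_THRESHOLD_N} N"
            )

    def cycle_duration(self, speed: float) -> float:
        """Cycle duration in seconds at a given speed (fixed stride length)."""
        if speed <= 0:
            raise ConfigError("speed must be positive")
        return self.stride_length_m / speed

    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]


@dataclass
class GaitRecording:
    """One walking trial: six angle channels, bilateral GRF, optional truth.

    Angle channels may contain NaN where a transmitted sample was lost;
    GRF channels are never masked.  ``truth_phase`` holds integer phase
    codes (:class:`~gaitdpf.phases.Phase`) when ground truth is known.
    """

    subject_id: str
    speed: float
    time: np.ndarray
    angles: dict[str, np.ndarray]
    grf_left: np.ndarray
    grf_right: np.ndarray
    truth_phase: np.ndarray | None = None
    sample_rate: float = 100.0
    #: samples per gait cycle, when the recording is cycle-aligned
    samples_per_cycle: int | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        for site in SITES:
            if site not in self.angles:
                raise ValueError(f"missing angle channel {site!r}")
            if len(self.angles[site]) != n:
                raise ValueError(f"channel {site!r} length != time length")
        for name, arr in (("grf_left", self.grf_left), ("grf_right", self.grf_right)):
            if len(arr) != n:
                raise ValueError(f"{name} length != time length")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative forces")
        if self.truth_phase is not None and len(self.truth_phase) != n:
            raise ValueError("truth_phase length != time length")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def angle_matrix(self) -> np.ndarray:
        """(n_samples, 6) array of angles in the canonical SITES order."""
        return np.column_stack([self.angles[s] for s in SITES])

    def slice(self, start: int, stop: int) -> "GaitRecording":
        """A view-like sub-recording over the sample range [start, stop)."""
        return GaitRecording(
            subject_id=self.subject_id,
            speed=self.speed,
            time=self.time[start:stop],
            angles={s: self.angles[s][start:stop] for s in SITES},
            grf_left=self.grf_left[start:stop],
            grf_right=self.grf_right[start:stop],
            truth_phase=None if self.truth_phase is None else self.truth_phase[start:stop],
            sample_rate=self.sample_rate,
            samples_per_cycle=self.samples_per_cycle,
        )

    # -- CSV round trip ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, object] = {"time": self.time}
        for s in SITES:
            cols[s] = self.angles[s]
        cols["grf_left"] = self.grf_left
        cols["grf_right"] = self.grf_right
        if self.truth_phase is not None:
            cols["phase"] = [PHASE_NAMES[p] for p in self.truth_phase]
        return pd.DataFrame(cols)

    def to_csv(self, path_or_buf) -> None:
        """Write the recording as CSV; masked samples become empty fields."""
        self.to_frame().to_csv(path_or_buf, index=False, na_rep="")

    @classmethod
    def from_csv(
        cls, path_or_buf, subject_id: str = "unknown", speed: float = float("nan"),
        sample_rate: float | None = None,
    ) -> "GaitRecording":
        df = pd.read_csv(path_or_buf)
        time = df["time"].to_numpy(float)
        rate = sample_rate
        if rate is None:
            rate = 1.0 / float(np.median(np.diff(time))) if len(time) > 1 else 100.0
        truth = None
        if "phase" in df.columns:
            truth = np.array(
                [Phase.from_label(str(v)) for v in df["phase"]], dtype=np.int8
            )
        return cls(
            subject_id=subject_id,
            speed=speed,
            time=time,
            angles={s: df[s].to_numpy(float) for s in SITES},
            grf_left=df["grf_left"].to_numpy(float),
            grf_right=df["grf_right"].to_numpy(float),
            truth_phase=truth,
            sample_rate=rate,
        )


# ---------------------------------------------------------------------------
# phase timing

def _phase_boundaries(config: SynthConfig) -> tuple[float, float, float]:
    """Cycle-fraction boundaries (SW-L start, SU-LHS start, SW-R start).

    Right heel strike anchors phi = 0.  Left toe-off ends SU-RHS at ds;
    left heel strike at stance - ds opens SU-LHS; right toe-off at the
    stance fraction opens SW-R.
    """
    sf, ds = config.stance_fraction, config.double_support_fraction
    return ds, sf - ds, sf


def _truth_from_phi(phi: np.ndarray, config: SynthConfig) -> np.ndarray:
    b1, b2, b3 = _phase_boundaries(config)
    codes = np.searchsorted([b1, b2, b3], phi, side="right")
    return codes.astype(np.int8)


def _grf_profile(s: np.ndarray) -> np.ndarray:
    """Double-bump stance loading profile on s in [0,1), normalized to max 1.

    Zero exactly at s=0 and s→1 so the force crosses the contact threshold
    precisely at heel strike and toe-off.
    """
    raw = np.sin(np.pi * s) * (1.0 + 0.4 * np.cos(2.0 * np.pi * s))
    grid = np.linspace(0.0, 1.0, 2001)
    peak = float(np.max(np.sin(np.pi * grid) * (1.0 + 0.4 * np.cos(2.0 * np.pi * grid))))
    return np.clip(raw, 0.0, None) / peak


def _grf_channel(
    phi: np.ndarray, onset: float, stance_len: float, peak: float
) -> np.ndarray:
    """GRF for one foot whose stance spans cycle fraction [onset, onset+len)."""
    s = np.mod(phi - onset, 1.0) / stance_len
    in_stance = s < 1.0
    grf = np.zeros_like(phi)
    thr = CONTACT_THRESHOLD_N
    grf[in_stance] = thr + (peak - thr) * _grf_profile(s[in_stance])
    return grf


def _subject_rng(config: SynthConfig, subject_id: str) -> np.random.Generator:
    tag = zlib.crc32(str(subject_id).encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def _subject_traits(config: SynthConfig, subject_id: str) -> dict:
    """Per-subject waveform perturbations and body-weight scaling.

    Derived only from (config.seed, subject_id) so the same subject keeps
    the same gait signature across speeds and trials.
    """
    rng = _subject_rng(config, subject_id)
    v = config.subject_variability
    traits: dict = {"weight_factor": 1.0 + rng.uniform(-v, v)}
    for stype, (mean, amps, phs) in _SITE_WAVEFORMS.items():
        traits[stype] = (
            mean * (1.0 + rng.uniform(-v, v)),
            tuple(a * (1.0 + rng.uniform(-v, v)) for a in amps),
            tuple(p + rng.uniform(-v, v) for p in phs),
        )
    return traits


def _angle_series(phi: np.ndarray, mean: float, amps, phs) -> np.ndarray:
    out = np.full_like(phi, mean)
    for k, (a, p) in enumerate(zip(amps, phs), start=1):
        out += a * np.cos(2.0 * np.pi * k * phi + p)
    return out


# ---------------------------------------------------------------------------
# public operations

def simulate_recording(
    config: SynthConfig,
    subject_id: str,
    speed: float,
    seed: int | None = None,
) -> GaitRecording:
    """Generate one trial of ``config.cycles_per_speed`` full gait cycles.

    The trial starts at a right heel strike.  ``seed`` controls the noise
    and packet-loss draws for this trial; when None it is derived from the
    cohort seed, the subject and the speed.  The subject's waveform
    signature depends only on (config.seed, subject_id).
    """
    if speed not in config.speeds:
        raise ConfigError(f"speed {speed} not in config.speeds {config.speeds}")
    if seed is None:
        tag = zlib.crc32(f"{subject_id}|{speed}".encode("utf8"))
        seed = int(np.random.SeedSequence([config.seed, tag]).generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(seed)

    duration = config.cycle_duration(speed)
    n_per_cycle = duration * config.sample_rate
    n = int(round(config.cycles_per_speed * n_per_cycle))
    idx = np.arange(n)
    time = idx / config.sample_rate
    phi = np.mod(idx / n_per_cycle, 1.0)

    truth = _truth_from_phi(phi, config)
    sf, ds = config.stance_fraction, config.double_support_fraction
    traits = _subject_traits(config, subject_id)
    peak = config.peak_grf * traits["weight_factor"]

    # right stance spans [0, sf); left stance starts at left heel strike
    # (sf - ds) and lasts until left toe-off at ds in the next cycle.
    grf_right = _grf_channel(phi, onset=0.0, stance_len=sf, peak=peak)
    grf_left = _grf_channel(phi, onset=sf - ds, stance_len=1.0 + 2.0 * ds - sf, peak=peak)

    angles: dict[str, np.ndarray] = {}
    for site in SITES:
        side, stype = site.split("_")
        mean, amps, phs = traits[stype]
        phi_site = np.mod(phi + 0.5, 1.0) if side == "L" else phi
        series = _angle_series(phi_site, mean, amps, phs)
        # session-slip artifact: a smooth local time-warp around one phase
        # onset whose magnitude ramps up over the session, delaying the
        # transition the channel appears to show; late cycles (held out by
        # the cycle-level split) slip the most
        warp_center = None
        if stype == "thigh" and config.swl_thigh_artifact:
            warp_center = ds  # SW-L onset (left toe-off)
        elif stype == "foot" and config.sulhs_foot_artifact:
            warp_center = sf - ds  # SU-LHS onset (left heel strike)
        if warp_center is not None and config.session_slip > 0:
            cycle_idx = (idx // int(round(n_per_cycle))).astype(int)
            n_cycles = cycle_idx.max() + 1
            ramp = config.session_slip * np.arange(n_cycles) / max(1, n_cycles - 1)
            offsets = ramp + rng.uniform(
                -config.slip_jitter, config.slip_jitter, size=n_cycles
            )
            d = np.mod(phi - warp_center + 0.5, 1.0) - 0.5
            bump = np.exp(-0.5 * (d / config.slip_zone_width) ** 2)
            # negative shift: the channel lags the true cycle position
            phi_warped = np.mod(phi_site - offsets[cycle_idx] * bump, 1.0)
            series = _angle_series(phi_warped, mean, amps, phs)
        if config.noise_sd > 0:
            series = series + rng.normal(0.0, config.noise_sd, size=n)
        angles[site] = series

    rec = GaitRecording(
        subject_id=subject_id,
        speed=speed,
        time=time,
        angles=angles,
        grf_left=grf_left,
        grf_right=grf_right,
        truth_phase=truth,
        sample_rate=config.sample_rate,
        samples_per_cycle=int(round(n_per_cycle)),
    )
    if config.packet_loss_rate > 0:
        rec = inject_packet_loss(
            rec, config.packet_loss_rate, seed=int(rng.integers(2**31))
        )
    return rec


def inject_packet_loss(
    recording: GaitRecording, rate: float, seed: int
) -> GaitRecording:
    """Mark angle samples as lost (NaN) with independent probability ``rate``.

    The first and last sample of every channel are never dropped, so linear
    interpolation is always bounded; GRF channels are never masked.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"packet loss rate must be in [0, 1), got {rate}")
    rng = np.random.default_rng(seed)
    n = recording.n_samples
    angles: dict[str, np.ndarray] = {}
    for site in SITES:
        ch = recording.angles[site].copy()
        if rate > 0 and n > 2:
            mask = rng.random(n) < rate
            mask[0] = mask[-1] = False
            ch[mask] = np.nan
        angles[site] = ch
    return dataclasses.replace(
        recording,
        time=recording.time.copy(),
        angles=angles,
        grf_left=recording.grf_left.copy(),
        grf_right=recording.grf_right.copy(),
        truth_phase=None if recording.truth_phase is None else recording.truth_phase.copy(),
    )


def simulate_cohort(
    config: SynthConfig, subjects: Sequence[str] | None = None
) -> list[GaitRecording]:
    """All trials for a cohort: one recording per subject per speed."""
    subjects = list(subjects) if subjects is not None else config.subject_ids()
    return [
        simulate_recording(config, sid, speed)
        for sid in subjects
        for speed in config.speeds
    ]
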