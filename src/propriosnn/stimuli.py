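"""Stimulus generation and joint-angle trace I/O.

Provides the ramp-and-hold hair-deflection protocols used to
characterise the afferent model, triangular constant-velocity joint
sweeps for velocity-tuning measurements, a seeded synthetic gait
generator that emulates 200 Hz motion-capture joint-angle traces from
walking stick insects, and CSV read/write plus resampling onto the
simulation grid.

Joint/leg labels use the closed vocabularies alpha/beta/gamma and
R1..R3, L1..L3.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "JointAngleTrace",
    "RampHoldProtocol",
    "SyntheticGaitParams",
    "ramp_and_hold",
    "constant_velocity_sweep",
    "synthetic_gait",
    "read_joint_csv",
    "write_joint_csv",
    "resample",
    "VELOCITY_BATTERY",
    "HOLD_ANGLE_BATTERY",
]

JOINTS = ("alpha", "beta", "gamma")
LEGS = ("R1", "R2", "R3", "L1", "L2", "L3")
SOURCES = ("experimental", "synthetic", "protocol")

#: Ramp velocities (deg/s) of the fixed-hold-angle battery: deflection
#: from 0 to 37 deg at each speed.
VELOCITY_BATTERY = (980.0, 604.0, 352.0, 188.0, 96.0)

#: Hold angles (deg) of the fixed-velocity battery, ramped at 240.4 deg/s.
HOLD_ANGLE_BATTERY = (60.0, 46.0, 34.0, 23.0, 15.0)
HOLD_BATTERY_VELOCITY = 240.4


@dataclass
class JointAngleTrace:
    """A uniformly sampled joint-angle time course theta(t)."""

    t: np.ndarray  # ms
    theta: np.ndarray  # deg
    joint_label: str = "alpha"
    leg_label: str = "R1"
    source: str = "protocol"
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.t.shape != self.theta.shape or self.t.ndim != 1:
            raise ValueError("t and theta must be 1-D arrays of equal length")
        if self.t.size >= 2:
            steps = np.diff(self.t)
            if steps.min() <= 0 or not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
                raise ValueError("time grid must be uniform and increasing")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("theta contains non-finite values")
        if self.joint_label not in JOINTS:
            raise ValueError(f"joint_label must be one of {JOINTS}")
        if self.leg_label not in LEGS:
            raise ValueError(f"leg_label must be one of {LEGS}")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0] + self.dt)


@dataclass(frozen=True)
class RampHoldProtocol:
    """Linear ramp from start to hold angle, hold, and return ramp.

    ``ramp_velocity`` is in deg/s; durations in ms.  The return ramp
    runs at the same speed as the up ramp.  Hair-deflection protocols
    must keep angles within [0, 90] deg.
    """

    start_angle: float = 0.0
    hold_angle: float = 37.0
    ramp_velocity: float = 980.0
    hold_duration: float = 500.0
    pre_duration: float = 100.0
    post_duration: float = 200.0

    def __post_init__(self) -> None:
        if self.ramp_velocity <= 0:
            raise ValueError("ramp_velocity must be positive")
        if min(self.hold_duration, self.pre_duration, self.post_duration) < 0:
            raise ValueError("durations must be non-negative")


def ramp_and_hold(p: RampHoldProtocol, dt: float = 0.25) -> JointAngleTrace:
    """Sample a ramp-and-hold protocol on a uniform grid of step ``dt`` ms.

    The ramp duration is |hold - start| / velocity exactly; an infinite-
    velocity limit can be approximated by a large ``ramp_velocity``,
    collapsing the ramp to a single step.
    """
    span = abs(p.hold_angle - p.start_angle)
    ramp_ms = span / p.ramp_velocity * 1000.0
    total = p.pre_duration + 2 * ramp_ms + p.hold_duration + p.post_duration
    n = max(int(round(total / dt)), 2)
    t = np.arange(n) * dt
    knots_t = np.cumsum(
        [0.0, p.pre_duration, ramp_ms, p.hold_duration, ramp_ms, p.post_duration]
    )
    knots_y = [
        p.start_angle,
        p.start_angle,
        p.hold_angle,
        p.hold_angle,
        p.start_angle,
        p.start_angle,
    ]
    theta = np.interp(t, knots_t, knots_y)
    return JointAngleTrace(t, theta, source="protocol")


def ramp_battery(dt: float = 0.25, hold_duration: float = 500.0) -> list[JointAngleTrace]:
    """The ten reference ramp-and-hold trials.

    Five trials ramp to 37 deg at 980, 604, 352, 188 and 96 deg/s; five
    ramp at 240.4 deg/s to hold angles 60, 46, 34, 23 and 15 deg.
    """
    trials = [
        ramp_and_hold(
            RampHoldProtocol(0.0, 37.0, v, hold_duration=hold_duration), dt
        )
        for v in VELOCITY_BATTERY
    ]
    trials += [
        ramp_and_hold(
            RampHoldProtocol(0.0, a, HOLD_BATTERY_VELOCITY, hold_duration=hold_duration),
            dt,
        )
        for a in HOLD_ANGLE_BATTERY
    ]
    return trials


def constant_velocity_sweep(
    speeds: Sequence[float],
    angle_range: tuple[float, float] = (0.0, 180.0),
    reps: int = 1,
    dt: float = 0.25,
    settle_ms: float = 500.0,
) -> list[JointAngleTrace]:
    """Triangular joint-angle waves traversing ``angle_range`` at each speed.

    Each trace holds the lower bound for ``settle_ms`` (letting afferent
    adaptation equilibrate), then runs ``reps`` full up-down cycles at
    constant |dtheta/dt| = speed.  One trace per speed.
    """
    lo, hi = float(angle_range[0]), float(angle_range[1])
    if not hi > lo:
        raise ValueError("angle_range must satisfy max > min")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    traces = []
    for v in speeds:
        if v <= 0:
            raise ValueError("sweep speeds must be positive")
        half_ms = (hi - lo) / v * 1000.0
        total = settle_ms + reps * 2 * half_ms
        n = int(round(total / dt))
        t = np.arange(n) * dt
        knots_t = [0.0, settle_ms]
        knots_y = [lo, lo]
        for _ in range(reps):
            knots_t += [knots_t[-1] + half_ms, knots_t[-1] + 2 * half_ms]
            knots_y += [hi, lo]
        theta = np.interp(t, knots_t, knots_y)
        traces.append(JointAngleTrace(t, theta, source="protocol"))
    return traces


@dataclass(frozen=True)
class SyntheticGaitParams:
    """Parameters of the synthetic stepping-like joint-angle generator.

    The generator emulates the statistical structure of 200 Hz
    motion-capture traces of flat walking: a quasi-periodic oscillation
    with a ~1 Hz stepping fundamental plus weaker harmonics, low-pass
    noise, and smooth saturation into a bounded working range.
    ``harmonic_amps`` are the relative amplitudes of the 1st..kth
    harmonics; the composite is rescaled so the deterministic part spans
    ``amplitude_frac`` of the working range.
    """

    fundamental_hz: float = 1.0
    harmonic_amps: tuple[float, ...] = (1.0, 0.3, 0.1)
    working_range: tuple[float, float] = (0.0, 180.0)
    amplitude_frac: float = 0.8
    noise_amp: float = 1.0  # deg, SD of the band-limited noise
    noise_corner_hz: float = 5.0
    duration: float = 5000.0  # ms
    dt: float = 0.25  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fundamental_hz <= 0 or self.duration <= 0 or self.dt <= 0:
            raise ValueError("fundamental_hz, duration and dt must be positive")
        if not self.working_range[1] > self.working_range[0]:
            raise ValueError("working_range must satisfy max > min")
        if not 0 < self.amplitude_frac <= 1:
            raise ValueError("amplitude_frac must lie in (0, 1]")


def synthetic_gait(
    p: SyntheticGaitParams, joint_label: str = "alpha", leg_label: str = "R1"
) -> JointAngleTrace:
    """Generate one synthetic stepping-like joint-angle trace.

    Pure function of (params, seed): identical parameters give a
    byte-identical trace.  The harmonic phases and the noise are drawn
    from a generator seeded with ``p.seed``; the result is soft-clipped
    (tanh) into the working range, producing smooth reversals and
    plateau/swing asymmetry without ever leaving the range.
    """
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration / p.dt))
    t = np.arange(n) * p.dt
    t_s = t / 1000.0
    lo, hi = p.working_range
    centre = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    base = np.zeros(n)
    for h, amp in enumerate(p.harmonic_amps, start=1):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        base += amp * np.cos(2.0 * np.pi * h * p.fundamental_hz * t_s + phase)
    peak = np.abs(base).max()
    if peak > 0:
        base *= p.amplitude_frac * half / peak
    if p.noise_amp > 0:
        white = rng.standard_normal(n)
        nyq = 1000.0 / p.dt / 2.0  # Hz
        sos = signal.butter(2, p.noise_corner_hz / nyq, output="sos")
        noise = signal.sosfiltfilt(sos, white)
        sd = noise.std()
        if sd > 0:
            noise *= p.noise_amp / sd
        base = base + noise
    theta = centre + half * np.tanh(base / half)
    return JointAngleTrace(
        t, theta, joint_label=joint_label, leg_label=leg_label, source="synthetic"
    )


def resample(trace: JointAngleTrace, dt_target: float) -> JointAngleTrace:
    """Linearly interpolate a trace onto a grid of step ``dt_target`` ms.

    Used to bring 5 ms motion-capture samples onto the 0.25 ms
    simulation grid.  Endpoints are preserved exactly and the operation
    is exact on piecewise-linear inputs whose knots lie on the source
    grid.
    """
    if dt_target <= 0:
        raise ValueError("dt_target must be positive")
    n = int(np.floor((trace.t[-1] - trace.t[0]) / dt_target)) + 1
    t_new = trace.t[0] + np.arange(n) * dt_target
    theta_new = np.interp(t_new, trace.t, trace.theta)
    return replace(trace, t=t_new, theta=theta_new)


# ---------------------------------------------------------------------------
# CSV dialect: long format with columns time_s, leg, joint, angle_deg, trial_id
# ---------------------------------------------------------------------------

def write_joint_csv(path: str | Path, traces: Iterable[JointAngleTrace]) -> None:
    """Write traces to the long-format CSV dialect."""
    frames = []
    for k, tr in enumerate(traces):
        frames.append(
            pd.DataFrame(
                {
                    "time_s": tr.t / 1000.0,
                    "leg": tr.leg_label,
                    "joint": tr.joint_label,
                    "angle_deg": tr.theta,
                    "trial_id": tr.trial_id or f"trial{k:03d}",
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_joint_csv(path: str | Path, source: str = "experimental") -> list[JointAngleTrace]:
    """Read traces from the long-format CSV dialect.

    Expects columns time_s, leg, joint, angle_deg and trial_id; returns
    one trace per (trial_id, leg, joint) group, in file order.
    """
    df = pd.read_csv(path)
    required = {"time_s", "leg", "joint", "angle_deg", "trial_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"joint CSV is missing columns: {sorted(missing)}")
    traces = []
    for (trial, leg, joint), grp in df.groupby(
        ["trial_id", "leg", "joint"], sort=False
    ):
        traces.append(
            JointAngleTrace(
                grp["time_s"].to_numpy() * 1000.0,
                grp["angle_deg"].to_numpy(),
                joint_label=str(joint),
                leg_label=str(leg),
                source=source,
                trial_id=str(trial),
            )
        )
    return traces


def load_sim_data(directory: str | Path, dt_target: float | None = 0.25) -> list[JointAngleTrace]:
    """Load a directory of deposited joint-angle CSV files.

    Shim for externally deposited motion-capture exports: every ``*.csv``
    file in ``directory`` is read with :func:`read_joint_csv` (long
    dialect) and, if ``dt_target`` is given, resampled onto that grid.
    The deposited layout is not formally documented, so this shim
    isolates the schema assumption in one place; files in other layouts
    should be converted to the long dialect first.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such data directory: {directory}")
    traces: list[JointAngleTrace] = []
    for path in sorted(directory.glob("*.csv")):
        for tr in read_joint_csv(path):
            traces.append(resample(tr, dt_target) if dt_target else tr)
    if not traces:
        raise FileNotFoundError(f"no CSV trace files found under {directory}")
    return traces
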