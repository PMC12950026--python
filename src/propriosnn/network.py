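"""Wiring and execution of the two-layer encoder network per joint.

Layer 1 is the sensory layer: one AdEx afferent per hair, driven by the
hair-deflection currents of the plate.  Layer 2 holds four interneurons
(INs) per joint:

* two position LIFs (tau = 120 ms, omega = 1 mV), each integrating every
  spike from the position-wired hairs of one field;
* two velocity chains, where each hair's afferent train passes through
  its own high-pass LIF (tau = 5 ms, omega = 10.8 mV) and the surviving
  spikes of a whole field converge on an integrator LIF whose weight
  (25 mV) exceeds the threshold gap, so it relays one spike per input
  spike.

The high-pass stage exploits the phasic-tonic afferent response: its
cutoff input rate f_c is tuned just above the tonic plateau rate f_ss of
a fully deflected hair, so only the phasic burst fired when the joint
crosses a hair's receptive field gets through.  The model is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .hair_field import HairPlateSpec, build_plate, plate_hair_angles
from .neurons import (
    AdExParams,
    CurrentTrace,
    LIFParams,
    SpikeTrain,
    adex_matrix,
    integrate_adex,
    lif_matrix,
)
from .stimuli import JointAngleTrace, ramp_and_hold, RampHoldProtocol

__all__ = [
    "JointEncoderConfig",
    "LayerOutputs",
    "CutoffCalibration",
    "default_config",
    "run_sensory_layer",
    "run_position_INs",
    "run_velocity_INs",
    "encode_joint",
    "calibrate_cutoff",
    "simulate_body",
]

DEFAULT_DT = 0.25  # ms

#: Optimized layer-2 parameter defaults.
POSITION_LIF = LIFParams(tau=120.0, omega=1.0)
#: High-pass weight from :func:`calibrate_cutoff` under this integrator:
#: the largest 0.2 mV grid value whose cutoff stays above the tonic
#: plateau of a fully deflected hair.  The endpoint is sensitive to the
#: afferent's discrete equilibrium ISI pattern: an afferent whose tonic
#: ISIs alternate between 16 and 17 steps tolerates 10.8 mV, whereas
#: this implementation's afferent equilibrates at 15/16 steps
#: (effective tonic rate ~258 Hz), which 10.8 mV lets ratchet through;
#: 10.4 mV blocks it while keeping the phasic burst of a 50 deg/s
#: receptive-field crossing above cutoff.
VELOCITY_HP_LIF = LIFParams(tau=5.0, omega=10.4)
#: The velocity integrator relays every input spike: omega > V_T - E_L.
VELOCITY_OUT_LIF = LIFParams(tau=5.0, omega=25.0)


@dataclass(frozen=True)
class JointEncoderConfig:
    """Everything needed to encode one joint's angle time course."""

    plate: HairPlateSpec
    adex: AdExParams = AdExParams()
    pos_lif: LIFParams = POSITION_LIF
    hp_lif: LIFParams = VELOCITY_HP_LIF
    vel_out_lif: LIFParams = VELOCITY_OUT_LIF
    dt: float = DEFAULT_DT
    joint_label: str = "alpha"
    leg_label: str = "R1"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        gap = self.vel_out_lif.V_T - self.vel_out_lif.E_L
        if not self.vel_out_lif.omega > gap:
            raise ValueError(
                "velocity integrator omega must exceed V_T - E_L so that "
                "every input spike is relayed"
            )


def default_config(
    working_range: tuple[float, float] = (0.0, 180.0),
    N_h: int = 50,
    theta_ol: float = 0.1,
    gain: float = 50.0,
    extended: bool = True,
    dt: float = DEFAULT_DT,
    joint_label: str = "alpha",
    leg_label: str = "R1",
) -> JointEncoderConfig:
    """Table-default encoder for one joint (extended plate, 50 hairs/field)."""
    plate = build_plate(working_range, N_h, theta_ol, gain, extended=extended)
    return JointEncoderConfig(
        plate=plate, dt=dt, joint_label=joint_label, leg_label=leg_label
    )


def config_for_trace(trace: JointAngleTrace, **kwargs) -> JointEncoderConfig:
    """Build a default config whose working range is the trace's min/max."""
    lo, hi = float(trace.theta.min()), float(trace.theta.max())
    if hi <= lo:
        hi = lo + 1.0  # degenerate constant trace: give the plate a range
    kwargs.setdefault("joint_label", trace.joint_label)
    kwargs.setdefault("leg_label", trace.leg_label)
    return default_config((lo, hi), **kwargs)


@dataclass
class LayerOutputs:
    """All spike trains produced for one joint."""

    sensory: list[SpikeTrain]
    pos_plus: SpikeTrain
    pos_minus: SpikeTrain
    vel_plus: SpikeTrain
    vel_minus: SpikeTrain
    t: np.ndarray = None  # type: ignore[assignment]  # simulation grid, ms

    @property
    def duration(self) -> float:
        return self.pos_plus.duration


@dataclass
class CutoffCalibration:
    """Outcome of tuning the high-pass synaptic weight.

    ``f_ss`` is the tonic rate of a fully deflected hair, ``f_c`` the
    minimum constant input rate that elicits any output from the
    high-pass LIF at the selected weight ``omega_hp``; calibration
    succeeds only with f_c > f_ss.
    """

    f_ss: float
    f_c: float
    omega_hp: float


# ---------------------------------------------------------------------------
# internal matrix pipeline
# ---------------------------------------------------------------------------

def _resolve_trace(trace: JointAngleTrace, cfg: JointEncoderConfig) -> JointAngleTrace:
    if not np.isclose(trace.dt, cfg.dt, rtol=1e-9, atol=1e-9):
        raise ValueError(
            f"trace dt {trace.dt} ms does not match simulation dt {cfg.dt} ms; "
            "resample the trace first"
        )
    return trace


def _sensory_matrix(trace: JointAngleTrace, cfg: JointEncoderConfig) -> np.ndarray:
    """Bool spike matrix (n_hairs, n_steps) of the afferent layer."""
    phi = plate_hair_angles(trace.theta, cfg.plate)
    return adex_matrix(cfg.plate.gain * phi, cfg.adex, cfg.dt)

def _matrix_to_trains(
    spikes: np.ndarray, dt: float, duration: float, prefix: str
) -> list[SpikeTrain]:
    return [
        SpikeTrain((np.flatnonzero(row) + 1) * dt, duration, f"{prefix}{i + 1}")
        for i, row in enumerate(spikes)
    ]


def _spike_counts(trains: Sequence[SpikeTrain], dt: float, n_steps: int) -> np.ndarray:
    """Per-step spike counts summed over a collection of trains."""
    counts = np.zeros(n_steps)
    for tr in trains:
        idx = np.clip(np.rint(tr.spike_times / dt).astype(int) - 1, 0, n_steps - 1)
        np.add.at(counts, idx, 1.0)
    return counts


def _single_lif(
    w_in: np.ndarray, params: LIFParams, dt: float, duration: float, neuron_id: str
) -> SpikeTrain:
    spikes = lif_matrix(w_in[None, :], params, dt)
    return SpikeTrain((np.flatnonzero(spikes[0]) + 1) * dt, duration, neuron_id)


# ---------------------------------------------------------------------------
# public runners
# ---------------------------------------------------------------------------

def run_sensory_layer(
    trace: JointAngleTrace, cfg: JointEncoderConfig
) -> list[SpikeTrain]:
    """Afferent spike trains for every hair of the plate.

    Raster order: negative-field hairs first (ascending receptive
    field), then positive-field hairs.
    """
    trace = _resolve_trace(trace, cfg)
    spikes = _sensory_matrix(trace, cfg)
    duration = trace.theta.size * cfg.dt
    return _matrix_to_trains(spikes, cfg.dt, duration, "hair")


def run_position_INs(
    sensory: Sequence[SpikeTrain], cfg: JointEncoderConfig
) -> tuple[SpikeTrain, SpikeTrain]:
    """(pos_plus, pos_minus) LIF spike trains.

    Each position IN integrates all spikes from the position-wired hairs
    of its field: pos_plus from the positively oriented field (joint
    above rest), pos_minus from the negatively oriented field.
    """
    n_neg = cfg.plate.field_neg.N_h
    duration = sensory[0].duration
    n_steps = int(round(duration / cfg.dt))
    neg_trains = [tr for tr, m in zip(sensory[:n_neg], cfg.plate.position_mask_neg) if m]
    pos_trains = [tr for tr, m in zip(sensory[n_neg:], cfg.plate.position_mask_pos) if m]
    out = []
    for trains, name in ((pos_trains, "pos_plus"), (neg_trains, "pos_minus")):
        w_in = cfg.pos_lif.omega * _spike_counts(trains, cfg.dt, n_steps)
        out.append(_single_lif(w_in, cfg.pos_lif, cfg.dt, duration, name))
    return out[0], out[1]


def run_velocity_INs(
    sensory: Sequence[SpikeTrain], cfg: JointEncoderConfig
) -> tuple[SpikeTrain, SpikeTrain]:
    """(vel_plus, vel_minus) spike trains from the high-pass chains.

    Every hair's afferent train drives its own high-pass LIF; surviving
    spikes from all hairs of the positively oriented field converge on
    the vel_plus integrator, and those of the negatively oriented field
    on vel_minus.  Requires an extended plate (full-range fields) for
    direction-selective coverage of the whole working range.
    """
    if not cfg.plate.extended:
        raise ValueError("velocity INs require an extended hair plate")
    n_neg = cfg.plate.field_neg.N_h
    duration = sensory[0].duration
    n_steps = int(round(duration / cfg.dt))
    w_hp = np.zeros((len(sensory), n_steps))
    for i, tr in enumerate(sensory):
        idx = np.clip(np.rint(tr.spike_times / cfg.dt).astype(int) - 1, 0, n_steps - 1)
        np.add.at(w_hp[i], idx, cfg.hp_lif.omega)
    hp_spikes = lif_matrix(w_hp, cfg.hp_lif, cfg.dt)
    out = []
    for rows, name in (
        (hp_spikes[n_neg:], "vel_plus"),
        (hp_spikes[:n_neg], "vel_minus"),
    ):
        w_in = cfg.vel_out_lif.omega * rows.sum(axis=0)
        out.append(_single_lif(w_in, cfg.vel_out_lif, cfg.dt, duration, name))
    return out[0], out[1]


def encode_joint(trace: JointAngleTrace, cfg: JointEncoderConfig) -> LayerOutputs:
    """Run the full two-layer network on one joint-angle trace."""
    trace = _resolve_trace(trace, cfg)
    sensory = run_sensory_layer(trace, cfg)
    pos_plus, pos_minus = run_position_INs(sensory, cfg)
    if cfg.plate.extended:
        vel_plus, vel_minus = run_velocity_INs(sensory, cfg)
    else:
        empty = lambda name: SpikeTrain(np.array([]), sensory[0].duration, name)
        vel_plus, vel_minus = empty("vel_plus"), empty("vel_minus")
    return LayerOutputs(sensory, pos_plus, pos_minus, vel_plus, vel_minus, t=trace.t)


def simulate_body(
    traces: Mapping[tuple[str, str], JointAngleTrace],
    cfgs: Mapping[tuple[str, str], JointEncoderConfig] | None = None,
) -> dict[tuple[str, str], LayerOutputs]:
    """Encode all supplied joints independently.

    ``traces`` maps (leg, joint) to a trace; ``cfgs`` optionally maps the
    same keys to encoder configs (defaults are derived per trace).  A
    full body comprises 18 joints (6 legs x alpha/beta/gamma); missing
    keys relative to that grid are rejected with the list of absentees.
    Per-joint runs are independent and deterministic, so results do not
    depend on iteration order.
    """
    from .stimuli import JOINTS, LEGS

    expected = {(leg, joint) for leg in LEGS for joint in JOINTS}
    missing = sorted(expected - set(traces))
    if missing:
        raise ValueError(f"missing joints: {missing}")
    dts = {round(tr.dt, 12) for tr in traces.values()}
    if len(dts) > 1:
        raise ValueError(f"inconsistent dt across traces: {sorted(dts)}")
    out = {}
    for key in sorted(traces):
        trace = traces[key]
        cfg = cfgs[key] if cfgs is not None else config_for_trace(trace)
        out[key] = encode_joint(trace, cfg)
    return out


# ---------------------------------------------------------------------------
# high-pass cutoff calibration
# ---------------------------------------------------------------------------

def lif_cutoff_rate(params: LIFParams, dt: float = DEFAULT_DT) -> float:
    """Minimum constant input rate (Hz) that makes the LIF fire.

    For a periodic input of inter-spike interval n steps, the voltage
    envelope converges to omega / (1 - rho^n) above rest, with rho the
    per-step decay 1/(1 + dt/tau); the neuron fires iff that envelope
    exceeds V_T - E_L.  Returns the rate of the largest passing interval
    (inf if even a single spike fires the neuron, 0 if nothing can).
    """
    gap = params.V_T - params.E_L
    if params.omega > gap:
        return 0.0
    rho = 1.0 / (1.0 + dt / params.tau)
    if params.omega <= gap * (1.0 - rho):
        return np.inf  # even back-to-back input cannot accumulate to threshold
    # largest n with omega / (1 - rho^n) > gap
    n_max = int(np.floor(np.log(1.0 - params.omega / gap) / np.log(rho)))
    while params.omega / (1.0 - rho ** n_max) <= gap:
        n_max -= 1
    while params.omega / (1.0 - rho ** (n_max + 1)) > gap:
        n_max += 1
    return 1000.0 / (n_max * dt)


def calibrate_cutoff(
    cfg: JointEncoderConfig,
    omega_grid: Sequence[float] | None = None,
    tonic_duration: float = 4000.0,
    reference_joint_velocity: float = 50.0,
) -> CutoffCalibration:
    """Tune the high-pass weight so f_c sits just above the tonic rate.

    The weight omega is raised along the grid — raising omega lowers the
    cutoff rate f_c toward the tonic plateau f_ss — and the calibration
    stops at the largest value satisfying both behavioural conditions,
    checked on actual afferent spike trains:

    1. the tonic condition — the equilibrium train of a fully deflected
       hair (constant current gain * 90 deg, after adaptation settles)
       must elicit *no* output from the high-pass LIF.  Using the real
       train matters: the discrete equilibrium alternates between two
       ISI values, which a weight tolerating the longer ISI alone would
       let ratchet through.
    2. the phasic condition — the burst fired while a hair's receptive
       field is crossed at a slow reference joint velocity (default
       50 deg/s, i.e. a 0-to-90 deg hair ramp at v * 90 / pitch) must
       elicit at least one output spike.

    Returns the selected weight with the measured tonic rate f_ss and
    the achieved cutoff f_c (minimum strictly periodic input rate that
    elicits output).  Raises RuntimeError when no grid value satisfies
    both conditions.
    """
    if omega_grid is None:
        omega_grid = np.round(np.arange(9.0, 12.01, 0.2), 10)
    dt = cfg.dt
    p = cfg.adex
    settle = max(10.0 * p.tau_w, 500.0)
    I_full = cfg.plate.gain * 90.0
    tonic_train = integrate_adex(
        CurrentTrace.constant(I_full, settle + tonic_duration, dt), p
    )
    tonic_tail = tonic_train.spike_times[tonic_train.spike_times >= settle] - settle
    f_ss = (
        1000.0 * (tonic_tail.size - 1) / float(tonic_tail[-1] - tonic_tail[0])
        if tonic_tail.size >= 2
        else 0.0
    )
    pitch = cfg.plate.field_pos.pitch
    hair_velocity = reference_joint_velocity * 90.0 / pitch
    ramp = ramp_and_hold(
        RampHoldProtocol(0.0, 90.0, hair_velocity, hold_duration=500.0), dt
    )
    ramp_train = integrate_adex(CurrentTrace(ramp.t, cfg.plate.gain * ramp.theta), p)
    n_tonic = int(round(tonic_duration / dt))
    n_ramp = ramp.theta.size
    best: CutoffCalibration | None = None
    for omega in sorted(omega_grid):
        hp = replace(cfg.hp_lif, omega=float(omega))
        w_tonic = np.zeros(n_tonic)
        idx = np.clip(np.rint(tonic_tail / dt).astype(int) - 1, 0, n_tonic - 1)
        np.add.at(w_tonic, idx, hp.omega)
        if lif_matrix(w_tonic[None, :], hp, dt).any():
            break  # tonic plateau leaks through; larger omega only worsens it
        w_ramp = np.zeros(n_ramp)
        idx = np.clip(
            np.rint(ramp_train.spike_times / dt).astype(int) - 1, 0, n_ramp - 1
        )
        np.add.at(w_ramp, idx, hp.omega)
        if not lif_matrix(w_ramp[None, :], hp, dt).any():
            continue  # phasic burst blocked: cutoff still too high
        best = CutoffCalibration(
            f_ss=f_ss, f_c=lif_cutoff_rate(hp, dt), omega_hp=float(omega)
        )
    if best is None:
        raise RuntimeError(
            "no omega in the grid blocks the tonic plateau while passing the "
            "phasic burst; widen the grid or adjust tau"
        )
    return best
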