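"""Receptive-field geometry of proprioceptive hair fields.

A hair field is a row of N_h cuticular hairs near a joint.  Each hair is
deflected only within its own receptive field, a sub-range of the joint
angle; together the receptive fields tile the field's working range
(range fractionation).  Hair deflection is linear in joint angle inside
the receptive field and saturates at 0 or 90 degrees outside it.  Two
opposing fields form a hair plate: one deflects as the joint angle rises
above the resting angle (positive orientation), the other as it falls
below (negative orientation).  A small overlap between the fields keeps
a low, non-zero drive at rest.

For velocity encoding the plate is "extended": both fields span the full
working range, so that transitions between adjacent receptive fields
occur in either movement direction anywhere in the range.  Only the
hairs lying in a field's original half-range are wired to the position
interneurons; the supplementary hairs serve the velocity pathway alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "HairFieldSpec",
    "HairPlateSpec",
    "HairDeflectionTrace",
    "receptive_field_edges",
    "hair_angles",
    "hair_currents",
    "overlap_at_rest",
    "build_plate",
]

#: Admissible range of the mechanotransduction gain I/phi, pA per degree.
GAIN_RANGE = (10.0, 150.0)


@dataclass(frozen=True)
class HairFieldSpec:
    """One row of hairs with uniformly spaced, overlapping receptive fields.

    ``orientation`` selects the deflection law: "positive" hairs deflect
    with increasing joint angle (0 deg below the receptive field, 90 deg
    above); "negative" hairs mirror this (fully deflected below, released
    above).
    """

    N_h: int
    theta_min: float
    theta_max: float
    theta_ol: float = 0.1
    orientation: Literal["positive", "negative"] = "positive"

    def __post_init__(self) -> None:
        if self.N_h < 1:
            raise ValueError("N_h must be >= 1")
        if not self.theta_max > self.theta_min:
            raise ValueError("theta_max must exceed theta_min")
        pitch = (self.theta_max - self.theta_min) / self.N_h
        if not (0.0 <= self.theta_ol < pitch):
            raise ValueError(
                f"theta_ol must lie in [0, {pitch}) for this field geometry"
            )
        if self.orientation not in ("positive", "negative"):
            raise ValueError("orientation must be 'positive' or 'negative'")

    @property
    def pitch(self) -> float:
        """Receptive-field spacing (theta_max - theta_min) / N_h, deg."""
        return (self.theta_max - self.theta_min) / self.N_h


def receptive_field_edges(spec: HairFieldSpec) -> tuple[np.ndarray, np.ndarray]:
    """Lower and upper receptive-field edges (rf0, rf90) per hair, deg.

    Interior edges: rf0_i = pitch*(i-1) + theta_min - theta_ol/2 and
    rf90_i = pitch*i + theta_min + theta_ol/2 for 1-based hair index i.
    The outer hairs are forced to the field bounds: rf0_1 = theta_min and
    rf90_N = theta_max, so coverage of [theta_min, theta_max] is exact.
    Edges are geometric and identical for both orientations; orientation
    enters only through the deflection law in :func:`hair_angles`.
    """
    i = np.arange(1, spec.N_h + 1, dtype=float)
    rf0 = spec.pitch * (i - 1) + spec.theta_min - spec.theta_ol / 2.0
    rf90 = spec.pitch * i + spec.theta_min + spec.theta_ol / 2.0
    rf0[0] = spec.theta_min
    rf90[-1] = spec.theta_max
    if np.any(rf90 - rf0 <= 0):
        raise ValueError("zero-width receptive field")
    return rf0, rf90


def hair_angles(theta: float | np.ndarray, spec: HairFieldSpec) -> np.ndarray:
    """Per-hair deflection angles phi in [0, 90] deg for joint angle theta.

    ``theta`` may be a scalar or a 1-D time series; the result has shape
    (N_h,) or (N_h, n_steps).  Joint angles outside the field's range are
    legal: hairs simply saturate at 0 or 90 deg.
    """
    rf0, rf90 = receptive_field_edges(spec)
    theta = np.asarray(theta, dtype=float)
    scalar = theta.ndim == 0
    th = theta[None] if scalar else theta
    frac = (th[None, :] - rf0[:, None]) / (rf90 - rf0)[:, None]
    frac = np.clip(frac, 0.0, 1.0)
    phi = 90.0 * frac if spec.orientation == "positive" else 90.0 * (1.0 - frac)
    return phi[:, 0] if scalar else phi


def hair_currents(phi: np.ndarray, gain: float) -> np.ndarray:
    """Convert hair deflection angles (deg) to afferent currents (pA)."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    return gain * np.asarray(phi, dtype=float)


@dataclass
class HairDeflectionTrace:
    """Per-hair deflection time courses phi_ij(t) on a uniform grid."""

    t: np.ndarray
    phi: np.ndarray  # shape (n_hairs, n_steps)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape[-1] != self.t.size:
            raise ValueError("phi and t lengths disagree")
        if self.phi.min() < 0.0 or self.phi.max() > 90.0:
            raise ValueError("hair deflections must lie in [0, 90] deg")


@dataclass(frozen=True)
class HairPlateSpec:
    """An opposing pair of hair fields covering one joint.

    ``field_neg`` covers the half-range below the resting angle (negative
    orientation), ``field_pos`` the half above.  In the extended variant
    both fields span the full working range and ``position_mask_*`` marks
    the hairs (per field, ascending receptive-field order) that remain
    wired to the position interneurons.
    """

    field_neg: HairFieldSpec
    field_pos: HairFieldSpec
    resting_angle: float
    gain: float = 50.0
    extended: bool = False
    position_mask_neg: np.ndarray = field(default=None)  # type: ignore[assignment]
    position_mask_pos: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (GAIN_RANGE[0] <= self.gain <= GAIN_RANGE[1]):
            raise ValueError(f"gain must lie within {GAIN_RANGE} pA/deg")
        for name in ("position_mask_neg", "position_mask_pos"):
            mask = getattr(self, name)
            fld = self.field_neg if name.endswith("neg") else self.field_pos
            if mask is None:
                mask = np.ones(fld.N_h, dtype=bool)
            mask = np.asarray(mask, dtype=bool)
            if mask.size != fld.N_h:
                raise ValueError(f"{name} length must equal the field's N_h")
            object.__setattr__(self, name, mask)

    @property
    def theta_olhf(self) -> float:
        return overlap_at_rest(self)

    @property
    def n_hairs(self) -> int:
        return self.field_neg.N_h + self.field_pos.N_h

    @property
    def working_range(self) -> tuple[float, float]:
        return (
            min(self.field_neg.theta_min, self.field_pos.theta_min),
            max(self.field_neg.theta_max, self.field_pos.theta_max),
        )


def overlap_at_rest(plate: HairPlateSpec) -> float:
    """Inter-field overlap at the resting angle (deg).

    Defined as theta_1^(max) - theta_2^(min), where field 1 is the
    negatively oriented (lower) field and field 2 the positively oriented
    (upper) field.  For extended plates the overlap of the *original*
    half-range fields is recovered from the position-masked hairs.
    """
    if not plate.extended:
        return plate.field_neg.theta_max - plate.field_pos.theta_min
    rf90_neg = receptive_field_edges(plate.field_neg)[1]
    rf0_pos = receptive_field_edges(plate.field_pos)[0]
    neg_top = rf90_neg[plate.position_mask_neg].max()
    pos_bottom = rf0_pos[plate.position_mask_pos].min()
    return float(neg_top - pos_bottom)


def build_plate(
    working_range: tuple[float, float],
    N_h: int = 50,
    theta_ol: float = 0.1,
    gain: float = 50.0,
    extended: bool = False,
) -> HairPlateSpec:
    """Construct a bi-directional hair plate for one joint.

    ``working_range`` is the joint's observed (min, max); the resting
    angle is its midpoint.  Non-extended: the two fields meet at the
    resting angle with inter-field overlap equal to ``theta_ol``
    (field_neg spans [min, rest + ol/2], field_pos [rest - ol/2, max]).
    Extended: both fields span the full working range with ``N_h`` hairs
    each, and the position mask marks, per field, only the hairs whose
    receptive field lies within that field's original half-range.
    """
    lo, hi = float(working_range[0]), float(working_range[1])
    if not hi > lo:
        raise ValueError("working_range must satisfy max > min")
    rest = 0.5 * (lo + hi)
    half_ol = theta_ol / 2.0
    if not extended:
        field_neg = HairFieldSpec(N_h, lo, rest + half_ol, theta_ol, "negative")
        field_pos = HairFieldSpec(N_h, rest - half_ol, hi, theta_ol, "positive")
        return HairPlateSpec(field_neg, field_pos, rest, gain, extended=False)
    field_neg = HairFieldSpec(N_h, lo, hi, theta_ol, "negative")
    field_pos = HairFieldSpec(N_h, lo, hi, theta_ol, "positive")
    tol = 1e-9 * (hi - lo)
    rf0_n, rf90_n = receptive_field_edges(field_neg)
    rf0_p, rf90_p = receptive_field_edges(field_pos)
    mask_neg = rf90_n <= rest + half_ol + tol
    mask_pos = rf0_p >= rest - half_ol - tol
    return HairPlateSpec(
        field_neg,
        field_pos,
        rest,
        gain,
        extended=True,
        position_mask_neg=mask_neg,
        position_mask_pos=mask_pos,
    )


def plate_hair_angles(theta: float | np.ndarray, plate: HairPlateSpec) -> np.ndarray:
    """Deflections of every hair on the plate, negative field first.

    Raster order: negative-field hairs 1..N (ascending receptive field),
    then positive-field hairs N+1..2N (ascending receptive field).
    """
    return np.concatenate(
        [hair_angles(theta, plate.field_neg), hair_angles(theta, plate.field_pos)],
        axis=0,
    )


def position_hair_order(plate: HairPlateSpec) -> np.ndarray:
    """Plate-raster indices of the position-wired hairs, innermost-centred.

    Returns the raster indices (0-based, negative field first) of all
    position-masked hairs, ordered so that the sequence runs from the far
    end of the negative field toward the resting angle and onward up the
    positive field — the numbering used for hair-field raster plots, in
    which the two innermost position hairs sit at positions N and N+1.
    """
    neg_idx = np.flatnonzero(plate.position_mask_neg)
    pos_idx = np.flatnonzero(plate.position_mask_pos) + plate.field_neg.N_h
    return np.concatenate([neg_idx, pos_idx])
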