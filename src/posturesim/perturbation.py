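"""Horizontal support-surface translation perturbations.

The platform is translated along a quintic smoothstep

    y(t) = d * (10 s^3 - 15 s^4 + 6 s^5),   s = (t - onset)/duration,

so displacement, velocity and acceleration are all continuous and the first
and second derivatives vanish at both ends of the translation.  With the
default 3 cm over 200 ms this is the classic s-shaped platform step.  The
standard protocol uses 12 directions separated by 30 deg, with 0 deg a
rightward translation and 90 deg a forward translation; the direction's
cosine drives the frontal plane and its sine the sagittal plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PerturbationSpec",
    "STANDARD_DIRECTIONS",
    "translation_profile",
    "translation_velocity_acceleration",
    "direction_components",
]

#: the 12 standard platform directions, degrees (0 = rightward, CCW)
STANDARD_DIRECTIONS = tuple(range(0, 360, 30))


@dataclass(frozen=True)
class PerturbationSpec:
    direction_deg: float = 270.0  # 0 = rightward, 90 = forward
    distance: float = 3.0  # cm
    duration: float = 200.0  # ms
    onset: float = 500.0  # ms

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (0 <= self.direction_deg < 360):
            raise ValueError("direction must lie in [0, 360)")


def _smoothstep(s):
    return 10.0 * s**3 - 15.0 * s**4 + 6.0 * s**5


def translation_profile(t, spec: PerturbationSpec):
    """Platform displacement in cm at time t (ms)."""
    t = np.asarray(t, dtype=float)
    s = np.clip((t - spec.onset) / spec.duration, 0.0, 1.0)
    out = spec.distance * _smoothstep(s)
    return out if out.ndim else float(out)


def translation_velocity_acceleration(t, spec: PerturbationSpec):
    """Analytic (velocity, acceleration) of the profile, cm/ms and cm/ms^2."""
    t = np.asarray(t, dtype=float)
    s = (t - spec.onset) / spec.duration
    inside = (s > 0.0) & (s < 1.0)
    s = np.clip(s, 0.0, 1.0)
    dsdt = 1.0 / spec.duration
    vel = spec.distance * (30.0 * s**2 - 60.0 * s**3 + 30.0 * s**4) * dsdt
    acc = spec.distance * (60.0 * s - 180.0 * s**2 + 120.0 * s**3) * dsdt**2
    vel = np.where(inside, vel, 0.0)
    acc = np.where(inside, acc, 0.0)
    if vel.ndim:
        return vel, acc
    return float(vel), float(acc)


def direction_components(direction_deg: float) -> tuple[float, float]:
    """(lateral, anterior) unit components of a platform direction.

    0 deg -> (1, 0) rightward; 90 deg -> (0, 1) forward.  The lateral
    component drives the frontal-plane plant, the anterior component the
    sagittal-plane plant.
    """
    rad = np.deg2rad(direction_deg)
    lat, ant = float(np.cos(rad)), float(np.sin(rad))
    # snap exact multiples of 90 deg to clean unit components
    if abs(lat) < 1e-15:
        lat = 0.0
    if abs(ant) < 1e-15:
        ant = 0.0
    return lat, ant
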