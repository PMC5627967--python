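"""Domain types describing the pendulum–fabric data-acquisition apparatus.

The simulated rig mirrors a bench-top device used to study loose-clothing
sensing: a weighted compound pendulum (57 cm) swinging in a vertical plane,
a strip of fabric (18 cm when taut) hanging from its tip, and single-axis
accelerometers at 57 cm (rigid tip, ``R1``), 66 cm (fabric middle, ``F2``)
and 75 cm (fabric tip, ``F3``) of arc length from the pivot.  A rigid
control replaces the fabric with a stiff extension carrying sensors ``R2``
and ``R3`` at the same distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GRAVITY",
    "PendulumSpec",
    "FabricSpec",
    "SensorSpec",
    "ApparatusConfig",
    "MotionSignal",
    "Trial",
    "FABRIC_PRESETS",
    "default_sensors",
]

#: Standard gravity used for newton→kilogram conversion and g-unit scaling.
GRAVITY = 9.81


@dataclass(frozen=True)
class PendulumSpec:
    """Rigid compound pendulum: uniform rod + permanent tip bob + test load.

    The pendulum is deliberately *weighted* (``bob_mass`` at the tip): this
    puts the tip sensor close to the centre of percussion, where tangential
    specific force nearly cancels, and makes the removable ``tip_load`` a
    small perturbation of the dynamics — the regime in which two motions are
    genuinely hard to tell apart from a rigidly mounted sensor.

    Parameters are SI: metres, kilograms, newtons, radians.  ``tip_load`` is
    given as a weight in newtons (converted internally to mass through
    ``gravity``).  ``release_angle`` is measured from the hanging-down
    vertical; ``pi/2`` is the horizontal release used in every experiment.
    """

    length: float = 0.57
    rod_mass: float = 0.1
    bob_mass: float = 2.5
    tip_load: float = 0.0
    pivot_damping: float = 0.04
    gravity: float = GRAVITY
    release_angle: float = math.pi / 2
    release_jitter_sd: float = math.radians(0.3)

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError(f"pendulum length must be positive, got {self.length}")
        if self.rod_mass < 0 or self.bob_mass < 0:
            raise ValueError("pendulum masses must be nonnegative")
        if self.rod_mass + self.bob_mass <= 0:
            raise ValueError("pendulum needs nonzero mass")
        if self.tip_load < 0:
            raise ValueError(f"tip_load must be >= 0 N, got {self.tip_load}")
        if not 0 < self.release_angle <= math.pi:
            raise ValueError("release_angle must lie in (0, pi]")
        if self.pivot_damping < 0 or self.release_jitter_sd < 0:
            raise ValueError("damping and jitter must be nonnegative")

    # -- derived rigid-body quantities -------------------------------------
    @property
    def tip_mass(self) -> float:
        """Mass equivalent of the removable tip weight (kg).

        The load is specified as a weight in newtons as measured on the
        bench, so the conversion always uses standard gravity even when the
        dynamical ``gravity`` is altered for thought experiments.
        """
        return self.tip_load / GRAVITY

    @property
    def inertia(self) -> float:
        """Moment of inertia about the pivot (kg·m²)."""
        L = self.length
        return (self.rod_mass / 3.0 + self.bob_mass + self.tip_mass) * L * L

    @property
    def mass_moment(self) -> float:
        """First mass moment M·d_com about the pivot (kg·m)."""
        L = self.length
        return (self.rod_mass / 2.0 + self.bob_mass + self.tip_mass) * L

    @property
    def equivalent_length(self) -> float:
        """Length of the simple pendulum with the same small-angle period."""
        return self.inertia / self.mass_moment

    @property
    def small_angle_frequency(self) -> float:
        """Small-angle natural frequency in Hz."""
        return math.sqrt(self.gravity / self.equivalent_length) / (2.0 * math.pi)


# Fabric surrogate presets.  The real garments were never characterised
# mechanically; these triples (bending stiffness per joint, linear density,
# quadratic translational drag) are chosen so that bending stiffness orders
# denim > jersey > roma, with denim the heaviest and roma the lightest —
# consistent with a stiff cotton denim, a heavy-weight jersey knit and a
# light four-way-stretch roma.  Overridable via FabricSpec(custom, ...).
FABRIC_PRESETS: dict[str, dict[str, float]] = {
    "denim": {"bending_stiffness": 2.0e-3, "linear_density": 0.12,
              "joint_damping": 1.0e-4, "drag_coefficient": 0.005},
    "jersey": {"bending_stiffness": 1.2e-4, "linear_density": 0.06,
               "joint_damping": 8.0e-6, "drag_coefficient": 0.005},
    "roma": {"bending_stiffness": 3.0e-5, "linear_density": 0.04,
             "joint_damping": 3.0e-6, "drag_coefficient": 0.005},
}


@dataclass(frozen=True)
class FabricSpec:
    """Fabric strip hanging from the pendulum tip, as a serial link chain.

    The strip is discretised into ``segment_count`` rigid links joined by
    torsional springs (stiffness ``bending_stiffness`` per joint, N·m/rad)
    and dampers, with quadratic aerodynamic drag on each link.  ``material``
    selects a documented preset; ``"rigid"`` replaces the strip by a rigid
    extension of the pendulum and ``"custom"`` uses the fields verbatim.
    """

    material: str = "jersey"
    taut_length: float = 0.18
    segment_count: int = 6
    bending_stiffness: float = float("nan")
    joint_damping: float = float("nan")
    linear_density: float = float("nan")
    drag_coefficient: float = float("nan")

    def __post_init__(self) -> None:
        known = set(FABRIC_PRESETS) | {"rigid", "custom"}
        if self.material not in known:
            raise ValueError(f"unknown material {self.material!r}; pick from {sorted(known)}")
        if not self.taut_length > 0:
            raise ValueError("taut_length must be positive")
        if self.segment_count < 1:
            raise ValueError("segment_count must be >= 1")
        if self.material in FABRIC_PRESETS:
            preset = FABRIC_PRESETS[self.material]
            for name, value in preset.items():
                if math.isnan(getattr(self, name)):
                    object.__setattr__(self, name, value)
        if self.material != "rigid":
            for name in ("bending_stiffness", "joint_damping",
                         "linear_density", "drag_coefficient"):
                v = getattr(self, name)
                if math.isnan(v) or v < 0:
                    raise ValueError(f"{name} must be a nonnegative number, got {v}")

    @property
    def is_rigid(self) -> bool:
        return self.material == "rigid"

    @property
    def segment_length(self) -> float:
        return self.taut_length / self.segment_count


@dataclass(frozen=True)
class SensorSpec:
    """One single-axis accelerometer at a given arc distance from the pivot.

    The sensing axis is the tangential axis of the carrying element (rigid
    pendulum or fabric link) — horizontal when the apparatus hangs at rest.
    Output is quantized to ``adc_bits`` over ``±full_scale`` standard
    gravities with additive Gaussian noise of ``noise_sd`` g.  ``mass`` is
    the weight of the sensor board itself (kg): sensors riding the fabric
    load their attachment node with it.
    """

    id: str
    arc_position: float
    noise_sd: float = 0.015
    full_scale: float = 3.0
    adc_bits: int = 16
    mass: float = 0.002

    def __post_init__(self) -> None:
        if self.arc_position < 0:
            raise ValueError("arc_position must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.full_scale <= 0 or self.adc_bits < 2:
            raise ValueError("full_scale must be positive and adc_bits >= 2")


def default_sensors(fabric: FabricSpec, pendulum: PendulumSpec | None = None,
                    noise_sd: float = 0.015) -> tuple[SensorSpec, ...]:
    """Standard three-sensor layout: tip of the rigid pendulum plus middle
    and end of the appendage (fabric → F2/F3, rigid extension → R2/R3)."""
    L = (pendulum or PendulumSpec()).length
    half = fabric.taut_length / 2.0
    mid, end = ("R2", "R3") if fabric.is_rigid else ("F2", "F3")
    return (
        SensorSpec("R1", L, noise_sd=noise_sd),
        SensorSpec(mid, L + half, noise_sd=noise_sd),
        SensorSpec(end, L + fabric.taut_length, noise_sd=noise_sd),
    )


@dataclass(frozen=True)
class ApparatusConfig:
    """Full description of one simulated condition."""

    pendulum: PendulumSpec = field(default_factory=PendulumSpec)
    fabric: FabricSpec = field(default_factory=FabricSpec)
    sensors: tuple[SensorSpec, ...] = ()
    sample_rate: float = 600.0
    duration: float = 10.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ValueError("sample_rate and duration must be positive")
        if not self.sensors:
            object.__setattr__(
                self, "sensors", default_sensors(self.fabric, self.pendulum))
        reach = self.pendulum.length + self.fabric.taut_length
        for s in self.sensors:
            if s.arc_position > reach + 1e-9:
                raise ValueError(
                    f"sensor {s.id} at {s.arc_position} m lies beyond the "
                    f"apparatus reach of {reach} m")

    @property
    def n_samples(self) -> int:
        return round(self.sample_rate * self.duration)

    def with_tip_load(self, newtons: float) -> "ApparatusConfig":
        return replace(self, pendulum=replace(self.pendulum, tip_load=newtons))

    def with_material(self, material: str) -> "ApparatusConfig":
        fabric = FabricSpec(material=material, taut_length=self.fabric.taut_length,
                            segment_count=self.fabric.segment_count)
        return replace(self, fabric=fabric, sensors=())


@dataclass
class MotionSignal:
    """One sensor's single-axis acceleration trace in standard gravities."""

    sensor_id: str
    sample_rate: float
    samples: np.ndarray
    trial_seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class Trial:
    """One recorded motion: all sensor channels of a single pendulum release."""

    label: str
    signals: dict[str, MotionSignal]
    config: ApparatusConfig
    seed: int

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.signals.values()}
        rates = {s.sample_rate for s in self.signals.values()}
        if len(lengths) > 1 or len(rates) > 1:
            raise ValueError("all channels of a trial must share rate and length")

    def __getitem__(self, sensor_id: str) -> MotionSignal:
        return self.signals[sensor_id]

    @property
    def sensor_ids(self) -> Sequence[str]:
        return list(self.signals)
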