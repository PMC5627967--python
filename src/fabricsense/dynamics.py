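"""Physics simulation of the pendulum–fabric rig and its virtual sensors.

A trial emulates one bench recording: the pendulum is held at the release
angle (nominally horizontal), the fabric hangs at rest, then the pendulum is
released and every sensor is sampled at the configured rate for the
configured duration.  Trial-to-trial variability comes from per-trial
release-angle jitter and per-sample Gaussian sensor noise; readings are
quantized to the ADC grid and clipped at full scale.

The pendulum is integrated with an adaptive high-order Runge–Kutta method
(DOP853, rtol 1e-8) with dense output; the driven chain with a fixed-step
classical RK4 whose step resolves the fastest joint mode (see `_chain`).
Quasi-rigid chains — all elastic modes above the sensor Nyquist rate — are
solved per sample as their instantaneous static equilibrium instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import _chain
from .apparatus import (GRAVITY, ApparatusConfig, FabricSpec, MotionSignal,
                        PendulumSpec, SensorSpec, Trial)

__all__ = [
    "rigid_pendulum_rhs",
    "pendulum_energy",
    "chain_rhs",
    "BaseKinematics",
    "virtual_accelerometer",
    "quantize",
    "simulate_pendulum",
    "simulate_trial",
    "generate_dataset",
    "Dataset",
    "condition_label",
]


class SimulationError(RuntimeError):
    """Raised when the integrator fails to produce a valid trajectory."""


# --------------------------------------------------------------------------
# rigid pendulum
# --------------------------------------------------------------------------

def rigid_pendulum_rhs(spec: PendulumSpec, state) -> float | np.ndarray:
    """Angular acceleration of the compound pendulum.

    ``state`` is ``(theta, theta_dot)`` (scalars or arrays).  The equation of
    motion about the pivot is

        I theta'' = -M_tot g d_com sin(theta) - c theta'

    with I and M_tot·d_com those of uniform rod + tip bob + tip load.
    """
    theta, dtheta = np.asarray(state[0]), np.asarray(state[1])
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(dtheta))):
        raise ValueError("pendulum state must be finite")
    acc = -(spec.mass_moment * spec.gravity * np.sin(theta)
            + spec.pivot_damping * dtheta) / spec.inertia
    return acc if acc.ndim else float(acc)


def pendulum_energy(spec: PendulumSpec, theta, dtheta) -> np.ndarray:
    """Total mechanical energy, zero at rest hanging down (J)."""
    theta = np.asarray(theta)
    dtheta = np.asarray(dtheta)
    return (0.5 * spec.inertia * dtheta**2
            + spec.mass_moment * spec.gravity * (1.0 - np.cos(theta)))


def simulate_pendulum(spec: PendulumSpec, release_angle: float | None = None,
                      duration: float = 10.0, rtol: float = 1e-8):
    """Integrate the free swing; returns the `solve_ivp` solution with dense
    output.  ``release_angle`` overrides the spec value (used for jitter)."""
    theta0 = spec.release_angle if release_angle is None else release_angle

    def rhs(t, y):
        return (y[1], rigid_pendulum_rhs(spec, y))

    sol = solve_ivp(rhs, (0.0, duration), (theta0, 0.0), method="DOP853",
                    rtol=rtol, atol=1e-11, dense_output=True)
    if not sol.success:
        raise SimulationError(
            f"pendulum integration failed ({sol.message}); spec={spec}")
    return sol


# --------------------------------------------------------------------------
# fabric chain
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BaseKinematics:
    """State of the chain root (the pendulum tip) driving the fabric."""

    angle: float = 0.0
    angular_rate: float = 0.0
    velocity: tuple[float, float] = (0.0, 0.0)
    acceleration: tuple[float, float] = (0.0, 0.0)


def _chain_params(fabric: FabricSpec):
    if fabric.is_rigid:
        raise ValueError("rigid extension has no chain dynamics")
    if fabric.linear_density <= 0:
        raise ValueError("chain dynamics require linear_density > 0")
    seg_len = fabric.segment_length
    seg_mass = fabric.linear_density * seg_len
    return (fabric.bending_stiffness, fabric.joint_damping, seg_mass, seg_len,
            fabric.drag_coefficient)


def chain_rhs(fabric: FabricSpec, base: BaseKinematics, state,
              node_masses=None, gravity: float = GRAVITY) -> np.ndarray:
    """Angular accelerations of the K fabric links for one instant.

    ``state`` is ``(phi, phi_dot)`` with K absolute link angles and rates.
    The root joint spring/damper references the pendulum angle in ``base``.
    ``node_masses`` optionally gives a point mass (sensor board) carried at
    the end node of each link.
    """
    phi = np.ascontiguousarray(state[0], dtype=float)
    dphi = np.ascontiguousarray(state[1], dtype=float)
    if phi.shape != (fabric.segment_count,) or dphi.shape != phi.shape:
        raise ValueError(
            f"state must hold {fabric.segment_count} angles and rates")
    if not (np.all(np.isfinite(phi)) and np.all(np.isfinite(dphi))):
        raise ValueError("chain state must be finite")
    kappa, cj, seg_mass, seg_len, drag = _chain_params(fabric)
    K = fabric.segment_count
    if node_masses is None:
        node_masses = np.zeros(K)
    node_masses = np.ascontiguousarray(node_masses, dtype=float)
    out = np.empty(K)
    nax = np.empty(K)
    nay = np.empty(K)
    _chain.chain_accelerations(
        phi, dphi, base.angle, base.angular_rate,
        base.velocity[0], base.velocity[1],
        base.acceleration[0], base.acceleration[1],
        kappa, cj, seg_mass, seg_len, drag, node_masses, gravity,
        out, nax, nay)
    return out


def _chain_fast_frequency(fabric: FabricSpec, gravity: float) -> float:
    """Upper bound on the fastest rate of the chain dynamics (rad/s).

    Governs the explicit integrator step: the stiffest joint mode, the
    gravity pendulum mode of one link, and the joint-damping decay rate all
    must be resolved.
    """
    kappa, cj, seg_mass, seg_len, _ = _chain_params(fabric)
    inertia = seg_mass * seg_len**2 / 3.0
    w_spring = math.sqrt(2.0 * kappa / inertia) if kappa > 0 else 0.0
    w_grav = math.sqrt(1.5 * gravity / seg_len) if gravity > 0 else 0.0
    w_damp = 4.0 * cj / inertia
    return max(w_spring, w_grav, w_damp, 1.0)


# --------------------------------------------------------------------------
# virtual accelerometer
# --------------------------------------------------------------------------

def quantize(samples, sensor: SensorSpec) -> np.ndarray:
    """Clip to ±full_scale and snap onto the ADC grid (g units).

    The grid is symmetric and includes ±full_scale exactly (2**bits - 1
    usable codes), so clipped samples stay on-grid.
    """
    fs = sensor.full_scale
    lsb = 2.0 * fs / (2**sensor.adc_bits - 2)
    x = np.asarray(samples, dtype=float)
    return np.clip(np.round(x / lsb) * lsb, -fs, fs)


def virtual_accelerometer(point_acceleration, segment_angle: float,
                          sensor: SensorSpec, rng: np.random.Generator | None = None,
                          gravity: float = GRAVITY) -> float:
    """One sample from a single-axis sensor riding a link at ``segment_angle``.

    The sensing axis is the link-tangential direction (horizontal when the
    apparatus hangs at rest).  The reading is the specific force — point
    acceleration minus the gravity vector — projected on that axis, in
    standard gravities, plus Gaussian noise, quantized and clipped.
    """
    ax, ay = float(point_acceleration[0]), float(point_acceleration[1])
    if not (math.isfinite(ax) and math.isfinite(ay) and math.isfinite(segment_angle)):
        raise ValueError("accelerometer inputs must be finite")
    reading = (ax * math.cos(segment_angle)
               + (ay + gravity) * math.sin(segment_angle)) / GRAVITY
    if rng is not None and sensor.noise_sd > 0:
        reading += rng.normal(0.0, sensor.noise_sd)
    return float(quantize(reading, sensor))


# --------------------------------------------------------------------------
# trials and datasets
# --------------------------------------------------------------------------

def _rigid_point_readings(spec: PendulumSpec, radius: float, theta, dtheta,
                          ddtheta) -> np.ndarray:
    """Tangential specific force at a point rigidly rotating with the
    pendulum, in standard gravities:  (d·theta'' + g·sin theta) / g0."""
    return (radius * ddtheta + spec.gravity * np.sin(theta)) / GRAVITY


def simulate_trial(config: ApparatusConfig, seed: int, label: str | None = None,
                   noise: bool = True) -> Trial:
    """Simulate one release of the apparatus and sample all sensors.

    Deterministic for a fixed ``seed``; ``noise=False`` disables both sensor
    noise and release jitter (quantization always applies).
    """
    rng = np.random.default_rng(seed)
    pend = config.pendulum
    theta0 = pend.release_angle
    if noise and pend.release_jitter_sd > 0:
        theta0 += rng.normal(0.0, pend.release_jitter_sd)
    theta0 = float(np.clip(theta0, 1e-6, math.pi))

    sol = simulate_pendulum(pend, release_angle=theta0, duration=config.duration)
    n = config.n_samples
    ts = np.arange(n) / config.sample_rate
    theta_s, dtheta_s = sol.sol(ts)
    ddtheta_s = rigid_pendulum_rhs(pend, (theta_s, dtheta_s))

    fabric = config.fabric
    L = pend.length
    node_readings = None
    if not fabric.is_rigid and any(s.arc_position > L + 1e-9 for s in config.sensors):
        node_readings = _simulate_chain_channel(config, sol, theta_s, dtheta_s,
                                                ddtheta_s)

    signals: dict[str, MotionSignal] = {}
    for sensor in config.sensors:
        if fabric.is_rigid or sensor.arc_position <= L + 1e-9:
            clean = _rigid_point_readings(pend, sensor.arc_position,
                                          theta_s, dtheta_s, ddtheta_s)
        else:
            node = int(round((sensor.arc_position - L) / fabric.segment_length))
            node = min(max(node, 1), fabric.segment_count)
            clean = node_readings[:, node - 1]
        samples = clean.copy()
        if noise and sensor.noise_sd > 0:
            samples += rng.normal(0.0, sensor.noise_sd, size=n)
        samples = quantize(samples, sensor)
        if not np.all(np.isfinite(samples)):
            raise SimulationError(
                f"non-finite samples from sensor {sensor.id}; config={config}")
        signals[sensor.id] = MotionSignal(sensor.id, config.sample_rate,
                                          samples, trial_seed=seed)
    if label is None:
        label = condition_label(pend.tip_load)
    return Trial(label=label, signals=signals, config=config, seed=seed)


def _sensor_node_masses(config) -> np.ndarray:
    """Point masses loading each chain node: the boards of fabric sensors."""
    fabric = config.fabric
    L = config.pendulum.length
    node_mass = np.zeros(fabric.segment_count)
    for s in config.sensors:
        if s.arc_position > L + 1e-9 and s.mass > 0:
            node = int(round((s.arc_position - L) / fabric.segment_length))
            node = min(max(node, 1), fabric.segment_count)
            node_mass[node - 1] += s.mass
    return node_mass


def _chain_equilibrium(fabric: FabricSpec, theta0: float, node_mass,
                       gravity: float) -> np.ndarray:
    """Static rest shape of the chain with the pendulum held at ``theta0``.

    A floppy strip dangles near the vertical; a stiff one sticks out along
    the pendulum.  Solved as the torque-balance root with the lowest total
    potential energy among converged candidates.
    """
    from scipy.optimize import root

    kappa, cj, seg_mass, seg_len, drag = _chain_params(fabric)
    K = fabric.segment_count
    zeros = np.zeros(K)
    out = np.empty(K)
    nax = np.empty(K)
    nay = np.empty(K)

    def acc(phi):
        _chain.chain_accelerations(
            np.ascontiguousarray(phi), zeros, theta0, 0.0,
            0.0, 0.0, 0.0, 0.0, kappa, cj, seg_mass, seg_len, drag,
            node_mass, gravity, out, nax, nay)
        return out.copy()

    def potential(phi):
        pe = 0.5 * kappa * (phi[0] - theta0) ** 2
        pe += 0.5 * kappa * np.sum(np.diff(phi) ** 2)
        y = 0.0
        for i in range(K):
            y_com = y - 0.5 * seg_len * math.cos(phi[i])
            y_node = y - seg_len * math.cos(phi[i])
            pe += gravity * (seg_mass * y_com + node_mass[i] * y_node)
            y = y_node
        return pe

    best = None
    for guess in (zeros, np.full(K, theta0)):
        res = root(acc, guess, method="hybr", tol=1e-12)
        if res.success and np.max(np.abs(acc(res.x))) < 1e-6:
            cand = (potential(res.x), res.x)
            if best is None or cand[0] < best[0]:
                best = cand
    return best[1] if best is not None else zeros


def _simulate_chain_channel(config, sol, theta_s, dtheta_s, ddtheta_s):
    fabric = config.fabric
    pend = config.pendulum
    kappa, cj, seg_mass, seg_len, drag = _chain_params(fabric)
    node_mass = _sensor_node_masses(config)
    rate = config.sample_rate
    w_max = _chain_fast_frequency(fabric, pend.gravity)
    dt_target = min(1.0 / (8.0 * rate), 0.2 / w_max)
    m = max(1, math.ceil((1.0 / rate) / dt_target))
    dt = 1.0 / (rate * m)
    n = config.n_samples
    n_steps = (n - 1) * m

    tg = np.arange(2 * n_steps + 1) * (dt / 2.0)
    theta_g, dtheta_g = sol.sol(tg)
    ddtheta_g = rigid_pendulum_rhs(pend, (theta_g, dtheta_g))

    K = fabric.segment_count
    phi0 = _chain_equilibrium(fabric, float(theta_g[0]), node_mass,
                              pend.gravity)
    w_spring = (math.sqrt(2.0 * kappa / (seg_mass * seg_len**2 / 3.0))
                if kappa > 0 else 0.0)
    ts = np.arange(n) / rate
    if w_spring > math.pi * rate:
        # quasi-rigid chain: every elastic mode lies above the Nyquist rate
        # of the sensors, so transients are unresolvable and the chain
        # follows its instantaneous equilibrium (zeroth-order slow
        # manifold).  Solve the statics per sample and recover the
        # band-limited specific force from the node velocities (direct
        # torque evaluation would amplify state noise by kappa/I).
        phi_rec, _ = _quasi_static_chain(
            fabric, pend, sol, node_mass, phi0, ts)
        # the chain co-rotates with the pendulum: node accelerations follow
        # from rigid-body kinematics on the instantaneous deflected shape
        cos_p = np.cos(phi_rec)
        sin_p = np.sin(phi_rec)
        L = pend.length
        tip_ax = L * (ddtheta_s * np.cos(theta_s)
                      - dtheta_s**2 * np.sin(theta_s))
        tip_ay = L * (ddtheta_s * np.sin(theta_s)
                      + dtheta_s**2 * np.cos(theta_s))
        seg_ax = seg_len * (ddtheta_s[:, None] * cos_p
                            - dtheta_s[:, None]**2 * sin_p)
        seg_ay = seg_len * (ddtheta_s[:, None] * sin_p
                            + dtheta_s[:, None]**2 * cos_p)
        nax = tip_ax[:, None] + np.cumsum(seg_ax, axis=1)
        nay = tip_ay[:, None] + np.cumsum(seg_ay, axis=1)
        return (nax * cos_p + (nay + pend.gravity) * sin_p) / GRAVITY
    phi_rec = np.empty((n, K))
    dphi_rec = np.empty((n, K))
    _chain.integrate_chain(phi0, np.ascontiguousarray(theta_g),
                           np.ascontiguousarray(dtheta_g),
                           np.ascontiguousarray(ddtheta_g),
                           pend.length, kappa, cj, seg_mass, seg_len, drag,
                           node_mass, pend.gravity, K, dt, n_steps, m,
                           phi_rec, dphi_rec)
    if not np.all(np.isfinite(phi_rec)):
        raise SimulationError(
            f"chain integration diverged; fabric={fabric}")
    out = np.empty((n, K))
    _chain.chain_node_readings(phi_rec, dphi_rec,
                               np.ascontiguousarray(theta_s),
                               np.ascontiguousarray(dtheta_s),
                               np.ascontiguousarray(ddtheta_s),
                               pend.length, kappa, cj, seg_mass, seg_len,
                               drag, node_mass, pend.gravity, GRAVITY, out)
    return out


def _quasi_static_chain(fabric, pend, sol, node_mass, phi0, ts):
    """Slow-manifold solution of a quasi-rigid chain.

    At each sample time the chain shape solves the torque balance under the
    instantaneous base kinematics (velocity-dependent torques are smaller
    than the elastic ones by the stiffness ratio and are neglected).  Link
    rates follow by differentiating the shape.
    """
    from scipy.optimize import root

    kappa, cj, seg_mass, seg_len, drag = _chain_params(fabric)
    K = fabric.segment_count
    L = pend.length
    out = np.empty(K)
    nax = np.empty(K)
    nay = np.empty(K)
    zeros = np.zeros(K)

    theta_s, dtheta_s = sol.sol(ts)
    ddtheta_s = rigid_pendulum_rhs(pend, (theta_s, dtheta_s))

    # rescale the residual to O(1): raw angular accelerations carry the
    # enormous kappa/I factor, which breaks the root-finder's step control
    scale = (seg_mass * seg_len**2 / 3.0) / max(kappa, 1e-12)

    def residual(phi, th, dth, ddth):
        c, s = math.cos(th), math.sin(th)
        ax = L * (ddth * c - dth * dth * s)
        ay = L * (ddth * s + dth * dth * c)
        _chain.chain_accelerations(
            np.ascontiguousarray(phi), zeros, th, dth, 0.0, 0.0, ax, ay,
            kappa, cj, seg_mass, seg_len, drag, node_mass, pend.gravity,
            out, nax, nay)
        return out * scale

    phi_rec = np.empty((len(ts), K))
    guess = phi0
    for i in range(len(ts)):
        res = root(residual, guess,
                   args=(float(theta_s[i]), float(dtheta_s[i]),
                         float(ddtheta_s[i])), method="hybr", tol=1e-12)
        # judge by the residual itself: hybr can report "no progress" after
        # converging below its own precision floor
        ok = np.max(np.abs(residual(res.x, float(theta_s[i]),
                                    float(dtheta_s[i]),
                                    float(ddtheta_s[i])))) < 1e-9
        if not ok:
            raise SimulationError(
                f"quasi-static chain solve failed at t={ts[i]:.4f}s; "
                f"fabric={fabric}")
        phi_rec[i] = res.x
        guess = res.x
    dphi_rec = np.gradient(phi_rec, ts[1] - ts[0], axis=0)
    return phi_rec, dphi_rec


def condition_label(tip_load: float) -> str:
    return f"{tip_load:g}N"


@dataclass
class Dataset:
    """Labelled collection of trials generated from one master seed."""

    trials: list[Trial] = field(default_factory=list)
    master_seed: int | None = None

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for t in self.trials:
            if t.label not in seen:
                seen.append(t.label)
        return seen

    def select(self, label: str) -> list[Trial]:
        return [t for t in self.trials if t.label == label]

    def signals(self, sensor_id: str, label: str) -> list[MotionSignal]:
        sigs = [t[sensor_id] for t in self.select(label)]
        if not sigs:
            raise KeyError(f"no trials with label {label!r} carrying sensor "
                           f"{sensor_id!r}")
        return sigs

    @property
    def sensor_ids(self) -> list[str]:
        return list(self.trials[0].signals) if self.trials else []


def generate_dataset(config: ApparatusConfig, trials_per_condition: int = 10,
                     conditions: tuple[float, ...] = (0.0, 3.0),
                     master_seed: int = 0, noise: bool = True,
                     labels: Sequence[str] | None = None) -> Dataset:
    """Simulate ``trials_per_condition`` independent releases per tip load.

    Each trial gets its own child seed from ``master_seed``; all trials share
    the release instant t=0, so channels are time-synchronised by
    construction.  Reproducible end-to-end from ``master_seed``.
    """
    if trials_per_condition < 2:
        raise ValueError("need at least 2 trials per condition for cluster "
                         "statistics")
    if labels is None:
        labels = [condition_label(c) for c in conditions]
    elif len(labels) != len(conditions):
        raise ValueError("labels must match conditions one-to-one")
    root = np.random.SeedSequence(master_seed)
    dataset = Dataset(master_seed=master_seed)
    for load, lab, cond_ss in zip(conditions, labels,
                                  root.spawn(len(conditions))):
        cond_config = config.with_tip_load(load)
        for trial_ss in cond_ss.spawn(trials_per_condition):
            seed = int(trial_ss.generate_state(1)[0]) & 0x7FFFFFFF
            dataset.trials.append(
                simulate_trial(cond_config, seed, label=lab, noise=noise))
    return dataset
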