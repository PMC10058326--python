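"""Adaptive-acceleration steered pulling on toy ligand-receptor systems.

The pulling protocol ramps a constant external acceleration applied to the
ligand: starting from a floor value, the controller boosts the acceleration
whenever the maximum ligand-receptor separation has stagnated for a full
window of steps, and damps it (never below the floor) once the separation
grows faster than a speed cap, i.e. after barrier crossing.  The tensile
force in pN is ``acceleration * mass * force_conversion``.  Dynamics are
Langevin (BAOAB splitting) at a single timestep; the run stops once the
ligand has traveled a set distance from its post-equilibration position.

The peak recorded pulling force (Fmax) and the accumulated pulling work are
the affinity scores consumed by the downstream calibration.  A
constant-velocity (stiff-spring) pull is also provided so that replicate
work values can feed the Jarzynski free-energy estimator in the
quasi-static limit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from ._units import (
    A_PS_TO_M_S,
    DEFAULT_FORCE_CONVERSION,
    INT_TO_KCALMOL,
    KB_KCALMOL,
    KCALMOL_TO_INT,
    PN_A_TO_KCALMOL,
    PN_TO_INT,
    kT_internal,
)
from .toy_complex import PullSystem

__all__ = [
    "SteeringConfig",
    "SteeringState",
    "PullTrajectory",
    "PullTimeoutError",
    "accel_to_force",
    "update_acceleration",
    "run_steered_pull",
    "total_work",
    "jarzynski_estimate",
    "run_constant_velocity_pull",
]


class PullTimeoutError(RuntimeError):
    """The ligand failed to reach the stop distance within the step budget."""

    def __init__(self, budget: int):
        self.budget = budget
        super().__init__(
            f"pull did not reach the stop distance within the step budget of {budget} steps"
        )


@dataclass(frozen=True)
class SteeringConfig:
    """Controller and integrator settings for an adaptive pull.

    ``temperature=None`` means "use the system's own temperature".
    ``pull_direction_mode`` is 'fixed' (egress direction of the system) or
    'com' (re-derived from the center-of-mass separation at every check).
    """

    a_min: float = 2000.0  # pm/ps^2
    a_boost: float = 500.0  # pm/ps^2
    stagnation_window: int = 400  # steps
    check_interval: int = 20  # steps
    speed_cap: float = 4000.0  # m/s
    stop_distance: float = 20.0  # A
    equilibration_time: float = 3.0  # ps
    timestep: float = 2.0  # fs
    temperature: Optional[float] = None  # K; None -> system temperature
    force_conversion: float = DEFAULT_FORCE_CONVERSION  # pN per Da*pm/ps^2
    seed: int = 0
    step_budget: int = 10_000_000
    pull_direction_mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.a_min <= 0:
            raise ValueError("a_min must be > 0")
        if self.a_boost < 0:
            raise ValueError("a_boost must be >= 0")
        if self.stop_distance <= 0:
            raise ValueError("stop_distance must be > 0")
        if not (0.0 < self.timestep <= 5.0):
            raise ValueError("timestep must be in (0, 5] fs")
        if self.check_interval < 1:
            raise ValueError("check_interval must be >= 1")
        if self.pull_direction_mode not in ("fixed", "com"):
            raise ValueError("pull_direction_mode must be 'fixed' or 'com'")


@dataclass
class SteeringState:
    """Live controller state during a pull."""

    acceleration: float  # pm/ps^2
    lam: float  # reaction coordinate, A
    max_com_distance: float  # A
    steps_since_improvement: int
    max_dis_speed: float  # m/s
    pull_direction: Tuple[float, float, float]


@dataclass
class PullTrajectory:
    """Per-step force/distance record of one pull."""

    times: np.ndarray  # ps
    forces: np.ndarray  # pN (applied pulling force)
    distances: np.ndarray  # A (traveled along the pulling coordinate)
    accelerations: np.ndarray  # pm/ps^2
    fmax: float  # pN
    total_work: float  # kcal/mol
    seed: int
    final_position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    final_velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))  # A/ps

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "time_ps": self.times,
                "distance_A": self.distances,
                "force_pN": self.forces,
                "acceleration": self.accelerations,
            }
        ).to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "fmax_pN": self.fmax,
            "total_work_kcalmol": self.total_work,
            "n_steps": int(len(self.times) - 1),
            "seed": self.seed,
        }


def accel_to_force(
    acceleration: float, mass: float, conversion: float = DEFAULT_FORCE_CONVERSION
) -> float:
    """Tensile force in pN from an acceleration (pm/ps^2) and mass (Da)."""
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    return acceleration * mass * conversion


def update_acceleration(state: SteeringState, config: SteeringConfig) -> SteeringState:
    """One controller decision: stagnation boost, then over-speed damping.

    Pure state transition.  If the separation has stagnated for a full
    window the acceleration is boosted and the counter resets; if the
    separation is growing faster than the speed cap the acceleration is
    scaled by ``1 - (1 - cap/speed)^2``, floored at the minimum.
    """
    a = state.acceleration
    ssi = state.steps_since_improvement
    if ssi >= config.stagnation_window:
        a += config.a_boost
        ssi = 0
    if state.max_dis_speed > config.speed_cap:
        a *= 1.0 - (1.0 - config.speed_cap / state.max_dis_speed) ** 2
        if a < config.a_min:
            a = config.a_min
    return replace(state, acceleration=a, steps_since_improvement=ssi)


def run_steered_pull(system: PullSystem, config: SteeringConfig) -> PullTrajectory:
    """Equilibrate, then pull the ligand out of its well adaptively.

    Langevin (BAOAB) dynamics with the external force applied along the
    pulling direction; the controller is consulted every
    ``config.check_interval`` steps.  Deterministic for a fixed
    (system.seed, config.seed) pair.
    """
    rng = np.random.default_rng((int(system.seed), int(config.seed)))
    dt = config.timestep * 1e-3  # ps
    mass = system.ligand_mass
    temp = system.temperature if config.temperature is None else config.temperature
    gamma = system.friction

    c1 = math.exp(-gamma * dt) if gamma > 0 else 1.0
    c2 = math.sqrt(max(0.0, (1.0 - c1 * c1)) * kT_internal(temp) / mass) if temp > 0 else 0.0

    eps_int = system.well_depth * KCALMOL_TO_INT
    inv_w = 1.0 / system.well_width
    cx, cy, cz = system.receptor_center
    px, py, pz = system.ligand_position
    vx = vy = vz = 0.0
    ex, ey, ez = system.egress_direction

    # noise buffer: one triple per step, drawn lazily in blocks
    _noise: List[np.ndarray] = []
    _noise_i = [0]

    def gauss3():
        i = _noise_i[0]
        if not _noise or i >= len(_noise[0]):
            _noise[:] = [rng.standard_normal((8192, 3))]
            i = 0
        _noise_i[0] = i + 1
        return _noise[0][i]

    def well_f(x, y, z):
        dx, dy, dz = x - cx, y - cy, z - cz
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r == 0.0:
            return 0.0, 0.0, 0.0
        e = math.exp(-r * inv_w)
        coef = -2.0 * eps_int * inv_w * (1.0 - e) * e / r
        return coef * dx, coef * dy, coef * dz

    half = 0.5 * dt

    def baoab(fx, fy, fz, fpx, fpy, fpz):
        """One BAOAB step; returns the force at the new position."""
        nonlocal px, py, pz, vx, vy, vz
        inv_m = 1.0 / mass
        vx += half * (fx + fpx) * inv_m
        vy += half * (fy + fpy) * inv_m
        vz += half * (fz + fpz) * inv_m
        px += half * vx
        py += half * vy
        pz += half * vz
        if c2 > 0.0:
            gx, gy, gz = gauss3()
            vx = c1 * vx + c2 * gx
            vy = c1 * vy + c2 * gy
            vz = c1 * vz + c2 * gz
        elif c1 != 1.0:
            vx *= c1
            vy *= c1
            vz *= c1
        px += half * vx
        py += half * vy
        pz += half * vz
        nfx, nfy, nfz = well_f(px, py, pz)
        vx += half * (nfx + fpx) * inv_m
        vy += half * (nfy + fpy) * inv_m
        vz += half * (nfz + fpz) * inv_m
        return nfx, nfy, nfz

    # --- equilibration: no external force ---------------------------------
    n_eq = int(round(config.equilibration_time / dt))
    fx, fy, fz = well_f(px, py, pz)
    for _ in range(n_eq):
        fx, fy, fz = baoab(fx, fy, fz, 0.0, 0.0, 0.0)

    # --- pulling phase -----------------------------------------------------
    sx, sy, sz = px, py, pz  # starting position after equilibration
    dx0, dy0, dz0 = px - cx, py - cy, pz - cz
    com_dist = math.sqrt(dx0 * dx0 + dy0 * dy0 + dz0 * dz0)
    state = SteeringState(
        acceleration=config.a_min,
        lam=dx0 * ex + dy0 * ey + dz0 * ez,
        max_com_distance=com_dist,
        steps_since_improvement=0,
        max_dis_speed=0.0,
        pull_direction=(ex, ey, ez),
    )
    fixed_dir = config.pull_direction_mode == "fixed"

    times = [0.0]
    forces = [accel_to_force(state.acceleration, mass, config.force_conversion)]
    distances = [0.0]
    accels = [state.acceleration]

    max_cd = com_dist
    max_cd_last_check = com_dist
    check_dt_ps = config.check_interval * dt
    step = 0
    traveled = 0.0
    while traveled < config.stop_distance:
        if step >= config.step_budget:
            raise PullTimeoutError(config.step_budget)
        step += 1
        f_pn = accel_to_force(state.acceleration, mass, config.force_conversion)
        f_int = f_pn * PN_TO_INT
        ex, ey, ez = state.pull_direction
        fx, fy, fz = baoab(fx, fy, fz, f_int * ex, f_int * ey, f_int * ez)

        dx, dy, dz = px - cx, py - cy, pz - cz
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r > max_cd:
            max_cd = r
        if fixed_dir:
            traveled = (px - sx) * ex + (py - sy) * ey + (pz - sz) * ez
        else:
            ddx, ddy, ddz = px - sx, py - sy, pz - sz
            traveled = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)

        times.append(step * dt)
        forces.append(f_pn)
        distances.append(traveled)
        accels.append(state.acceleration)

        if step % config.check_interval == 0:
            gained = max_cd - max_cd_last_check
            if gained > 0.0:
                ssi = 0
            else:
                ssi = state.steps_since_improvement + config.check_interval
            speed = gained / check_dt_ps * A_PS_TO_M_S
            direction = state.pull_direction
            if not fixed_dir and r > 0.0:
                direction = (dx / r, dy / r, dz / r)
            state = replace(
                state,
                lam=dx * ex + dy * ey + dz * ez,
                max_com_distance=max_cd,
                steps_since_improvement=ssi,
                max_dis_speed=speed,
                pull_direction=direction,
            )
            state = update_acceleration(state, config)
            max_cd_last_check = max_cd

    traj = PullTrajectory(
        times=np.asarray(times),
        forces=np.asarray(forces),
        distances=np.asarray(distances),
        accelerations=np.asarray(accels),
        fmax=float(max(forces)),
        total_work=0.0,
        seed=config.seed,
        final_position=np.array([px, py, pz]),
        final_velocity=np.array([vx, vy, vz]),
    )
    traj.total_work = total_work(traj)
    return traj


def total_work(trajectory: PullTrajectory) -> float:
    """Pulling work in kcal/mol by trapezoidal integration of F over distance."""
    if len(trajectory.forces) == 0:
        raise ValueError("empty trajectory")
    w_pn_a = float(np.trapezoid(trajectory.forces, trajectory.distances))
    return w_pn_a * PN_A_TO_KCALMOL


def jarzynski_estimate(works: Sequence[float], temperature: float) -> float:
    """Free-energy estimate -kT ln<exp(-W/kT)> over replicate work values.

    Computed with a log-sum-exp stable scheme; kT in kcal/mol.
    """
    works = np.asarray(works, dtype=float)
    if works.size == 0:
        raise ValueError("need at least one work value")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    kt = KB_KCALMOL * temperature
    return float(-kt * (logsumexp(-works / kt) - math.log(works.size)))


def run_constant_velocity_pull(
    system: PullSystem,
    *,
    speed: float,
    spring_k: float = 50.0,
    timestep_fs: float = 2.0,
    distance: float = 20.0,
    temperature: Optional[float] = None,
    friction: Optional[float] = None,
    seed: int = 0,
) -> float:
    """Stiff-spring constant-velocity pull; returns the external work (kcal/mol).

    The spring couples the projection of the ligand-receptor separation onto
    the egress direction to an anchor moving at ``speed`` (A/ps); the work is
    accumulated as the spring force times the anchor displacement.  In the
    quasi-static (slow-speed) limit the work converges to the free-energy
    difference across the well.
    """
    rng = np.random.default_rng((int(system.seed), int(seed)))
    dt = timestep_fs * 1e-3
    mass = system.ligand_mass
    temp = system.temperature if temperature is None else temperature
    gamma = system.friction if friction is None else friction
    c1 = math.exp(-gamma * dt) if gamma > 0 else 1.0
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1) * kT_internal(temp) / mass) if temp > 0 else 0.0

    k_int = spring_k * KCALMOL_TO_INT
    eps_int = system.well_depth * KCALMOL_TO_INT
    inv_w = 1.0 / system.well_width
    cx, cy, cz = system.receptor_center
    px, py, pz = system.ligand_position
    ex, ey, ez = system.egress_direction
    vx = vy = vz = 0.0
    half = 0.5 * dt
    inv_m = 1.0 / mass

    def forces(x, y, z, anchor):
        dx, dy, dz = x - cx, y - cy, z - cz
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r > 0:
            e = math.exp(-r * inv_w)
            coef = -2.0 * eps_int * inv_w * (1.0 - e) * e / r
            fx, fy, fz = coef * dx, coef * dy, coef * dz
        else:
            fx = fy = fz = 0.0
        lam = dx * ex + dy * ey + dz * ez
        fs = k_int * (anchor - lam)
        return fx + fs * ex, fy + fs * ey, fz + fs * ez, fs

    n_steps = int(math.ceil(distance / (speed * dt)))
    noise = rng.standard_normal((n_steps, 3)) if c2 > 0 else None
    anchor = 0.0
    work_int = 0.0
    fx, fy, fz, fs = forces(px, py, pz, anchor)
    for i in range(n_steps):
        vx += half * fx * inv_m
        vy += half * fy * inv_m
        vz += half * fz * inv_m
        px += half * vx
        py += half * vy
        pz += half * vz
        if c2 > 0:
            gx, gy, gz = noise[i]
            vx = c1 * vx + c2 * gx
            vy = c1 * vy + c2 * gy
            vz = c1 * vz + c2 * gz
        elif c1 != 1.0:
            vx *= c1
            vy *= c1
            vz *= c1
        px += half * vx
        py += half * vy
        pz += half * vz
        new_anchor = anchor + speed * dt
        nfx, nfy, nfz, nfs = forces(px, py, pz, new_anchor)
        # external work: spring force times anchor displacement (midpoint)
        work_int += 0.5 * (fs + nfs) * speed * dt
        anchor = new_anchor
        fx, fy, fz, fs = nfx, nfy, nfz, nfs
        vx += half * fx * inv_m
        vy += half * fy * inv_m
        vz += half * fz * inv_m
    return work_int * INT_TO_KCALMOL
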