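"""Forces, terminal velocity, hindered motion, and trajectory integration.

In the creeping-flow regime the magnetic body force on a capsule,

    F_m(x) = V_p · chi_eff / (mu0 · (1 + chi_eff)^2) · B_a(x)·dB_a/dx,

balances Stokes drag 3π·eta·d_p·v, giving the closed-form terminal velocity

    v_t(x) = V_p · chi_eff / (3π·eta·d_p·mu0·(1 + chi_eff)^2) · B_a·dB_a/dx.

Sign convention: x is distance from the magnet face, so B_a·dB_a/dx < 0 and
the signed velocity is negative (motion toward the magnet). User-facing
reports convert to a positive "approach speed".

Two integrators are provided: an overdamped mode (dx/dt = v_t(x), fixed-step
RK4) that treats velocity as always terminal, and an inertial mode that
integrates m·dv/dt = F_m - 3π·eta·d_p·v so the relaxation to terminal
velocity over the Stokes time tau = rho_p·d_p²/(18·eta) is resolved; the two
must agree once t >> tau, which is the main internal consistency check on
the closed form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .capsule import CapsuleSpec, FluidMedium
from .constants import MU_0
from .errors import DomainError, StepSizeError
from .field import MagnetFieldModel, field_gradient_term

__all__ = [
    "TrajectoryState",
    "SimulatedTrajectory",
    "terminal_velocity",
    "magnetic_force",
    "hindered_velocity",
    "stokes_relaxation_time",
    "simulate_trajectory",
]


@dataclass(frozen=True)
class TrajectoryState:
    """State of a simulated capsule: time (s), position (m, distance from
    magnet face), signed velocity (m/s; negative = toward the magnet)."""

    time: float
    position: float
    velocity: float


@dataclass(frozen=True)
class SimulatedTrajectory:
    """Integrator output: states in time order plus an arrival flag (capsule
    reached the stop distance, by default its own radius, and the physical
    trajectory ended at the magnet-side wall)."""

    states: list[TrajectoryState]
    arrived: bool

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.states])

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.states])

    @property
    def velocities(self) -> np.ndarray:
        return np.array([s.velocity for s in self.states])


def _chi_eff(capsule: CapsuleSpec, fluid: FluidMedium, chi_eff: Optional[float]) -> float:
    return capsule.effective_susceptibility(fluid) if chi_eff is None else chi_eff


def _mobility(capsule: CapsuleSpec, fluid: FluidMedium, chi: float) -> float:
    # V_p / (3*pi*eta*d_p) = d_p^2 / (18*eta); mobility multiplies Ba*dBa/dx
    return capsule.diameter**2 * chi / (18.0 * fluid.viscosity * MU_0 * (1.0 + chi) ** 2)


def magnetic_force(
    capsule: CapsuleSpec,
    fluid: FluidMedium,
    field: MagnetFieldModel,
    x,
    chi_eff: Optional[float] = None,
):
    """Magnetic body force F_m(x) in newtons (signed; negative = toward magnet)."""
    chi = _chi_eff(capsule, fluid, chi_eff)
    grad = field_gradient_term(field, x)
    return capsule.volume * chi / (MU_0 * (1.0 + chi) ** 2) * grad


def terminal_velocity(
    capsule: CapsuleSpec,
    fluid: FluidMedium,
    field: MagnetFieldModel,
    x,
    chi_eff: Optional[float] = None,
    check_reynolds: bool = True,
):
    """Closed-form terminal velocity v_t(x), m/s, signed (negative = approach).

    Equal to ``magnetic_force / (3*pi*eta*d_p)`` exactly. Warns if the local
    particle Reynolds number rho_f·|v|·d_p/eta exceeds 1, where the
    creeping-flow drag law underpinning the balance stops being valid.
    """
    chi = _chi_eff(capsule, fluid, chi_eff)
    v = _mobility(capsule, fluid, chi) * field_gradient_term(field, x)
    if check_reynolds:
        vmax = np.max(np.abs(v))
        reynolds = fluid.density * vmax * capsule.diameter / fluid.viscosity
        if reynolds > 1.0:
            warnings.warn(
                f"particle Reynolds number {reynolds:.3g} > 1: creeping-flow "
                "assumption violated; terminal velocity is unreliable",
                stacklevel=2,
            )
    return v


def hindered_velocity(v_unhindered, local_volume_fraction: float, exponent: float = 4.65):
    """Richardson–Zaki hindered-motion correction v·(1 - phi_local)^n.

    Reduces the speed at elevated local capsule volume fraction; the default
    exponent 4.65 is the low-Reynolds-number value. ``exponent = 0`` disables
    the correction.
    """
    if not (0 <= local_volume_fraction < 1):
        raise DomainError(
            f"local volume fraction must be in [0, 1), got {local_volume_fraction}"
        )
    if exponent < 0:
        raise DomainError(f"hindrance exponent must be >= 0, got {exponent}")
    return v_unhindered * (1.0 - local_volume_fraction) ** exponent


def stokes_relaxation_time(capsule: CapsuleSpec, fluid: FluidMedium) -> float:
    """Velocity relaxation time tau = rho_p·d_p² / (18·eta), seconds."""
    return capsule.density * capsule.diameter**2 / (18.0 * fluid.viscosity)


def _hindrance_fn(hindrance: Optional[tuple]) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    if hindrance is None:
        return lambda x, v: v
    phi_field, exponent = hindrance
    if exponent < 0:
        raise DomainError(f"hindrance exponent must be >= 0, got {exponent}")
    if callable(phi_field):
        def hind(x, v):
            phi = np.asarray(phi_field(x), dtype=float)
            if np.any(phi < 0) or np.any(phi >= 1):
                raise DomainError("local volume fraction must be in [0, 1)")
            return v * (1.0 - phi) ** exponent

        return hind
    return lambda x, v: hindered_velocity(v, float(phi_field), exponent)


def integrate_positions(
    capsule: CapsuleSpec,
    fluid: FluidMedium,
    field: MagnetFieldModel,
    x_start,
    times: Sequence[float],
    chi_eff: Optional[float] = None,
    stop_distance: Optional[float] = None,
    hindrance: Optional[tuple] = None,
    max_step_displacement: Optional[float] = None,
    max_substeps: int = 200,
) -> np.ndarray:
    """Overdamped positions at the requested ``times`` for one or many starts.

    Vectorized RK4 on dx/dt = v_t(x); sample intervals are internally
    subdivided so no sub-step moves a capsule more than
    ``max_step_displacement`` (default decay_length/20), up to
    ``max_substeps`` per interval — beyond that cap the capsule crosses the
    whole field within one sample interval anyway and lands clamped on the
    stop. Positions are
    clamped at ``stop_distance`` (default capsule radius); a clamped capsule
    stays there (arrived at the magnet-side wall).

    Returns an array of shape ``(len(times),) + shape(x_start)``.
    """
    x0 = np.atleast_1d(np.asarray(x_start, dtype=float))
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise DomainError("times must be strictly increasing")
    stop = capsule.radius if stop_distance is None else stop_distance
    if np.any(x0 <= stop):
        raise DomainError("start positions must exceed the stop distance")
    chi = _chi_eff(capsule, fluid, chi_eff)
    hind = _hindrance_fn(hindrance)
    mob = _mobility(capsule, fluid, chi)

    def rhs(x):
        xc = np.maximum(x, stop)
        return hind(xc, mob * field_gradient_term(field, xc))

    if max_step_displacement is None:
        max_step_displacement = field.decay_length / 20.0
    v_max = abs(float(np.max(np.abs(rhs(np.full(1, stop))))))
    out = np.empty((times.size,) + x0.shape, dtype=float)
    x = x0.copy()
    t_prev = 0.0
    for i, t in enumerate(times):
        dt_total = t - t_prev
        if dt_total > 0:
            n_sub = 1 if v_max == 0 else min(
                max_substeps, max(1, int(math.ceil(dt_total * v_max / max_step_displacement)))
            )
            h = dt_total / n_sub
            for _ in range(n_sub):
                k1 = rhs(x)
                k2 = rhs(np.maximum(x + 0.5 * h * k1, stop))
                k3 = rhs(np.maximum(x + 0.5 * h * k2, stop))
                k4 = rhs(np.maximum(x + h * k3, stop))
                x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                np.maximum(x, stop, out=x)
        out[i] = x
        t_prev = t
        if np.all(x <= stop):
            out[i + 1 :] = stop
            break
    return out[:, 0] if np.ndim(x_start) == 0 else out


def simulate_trajectory(
    capsule: CapsuleSpec,
    fluid: FluidMedium,
    field: MagnetFieldModel,
    x_start: float,
    duration: float,
    dt: Optional[float] = None,
    mode: str = "overdamped",
    hindrance: Optional[tuple] = None,
    stop_distance: Optional[float] = None,
    chi_eff: Optional[float] = None,
) -> SimulatedTrajectory:
    """Integrate one capsule trajectory toward the magnet.

    Parameters
    ----------
    x_start, duration, dt
        Initial distance from the magnet face (m), total simulated time (s),
        and time step (s). If ``dt`` is omitted it defaults to tau/5 in
        inertial mode and decay_length/(100·|v_max|) (capped at duration/100)
        in overdamped mode, where |v_max| is the terminal speed at the stop
        distance.
    mode
        ``"overdamped"``: dx/dt = v_t(x), RK4. ``"inertial"``: integrates
        m·dv/dt = F_m(x) - 3π·eta·d_p·v with the capsule mass from geometry
        and densities, using an integrating-factor (exponential) update that
        treats the stiff linear drag exactly within each step and freezes the
        slowly varying magnetic forcing — near-exact here because a step
        moves the capsule a tiny fraction of the field's decay length.
    hindrance
        Optional ``(phi_local, exponent)`` — a constant local volume fraction
        or a callable phi(x) — applying the Richardson–Zaki correction.
    stop_distance
        Position at which the trajectory physically ends (default: capsule
        radius, i.e. contact with the magnet-side wall).

    Raises
    ------
    StepSizeError
        If ``dt`` would move the capsule more than decay_length/10 per step.
    """
    if x_start <= 0 or duration <= 0:
        raise DomainError("x_start and duration must be positive")
    if mode not in ("overdamped", "inertial"):
        raise DomainError(f"unknown mode {mode!r}")
    stop = capsule.radius if stop_distance is None else stop_distance
    if x_start <= stop:
        raise DomainError(f"x_start must exceed the stop distance {stop}")
    chi = _chi_eff(capsule, fluid, chi_eff)
    hind = _hindrance_fn(hindrance)
    mob = _mobility(capsule, fluid, chi)

    def v_term(x):
        return float(hind(x, mob * field_gradient_term(field, x)))

    v_max = abs(v_term(stop))
    tau = stokes_relaxation_time(capsule, fluid)
    if dt is None:
        if mode == "inertial":
            dt = tau / 5.0
        else:
            dt = duration / 100.0 if v_max == 0 else min(
                field.decay_length / (100.0 * v_max), duration / 100.0
            )
    if dt <= 0:
        raise DomainError("dt must be positive")
    if v_max * dt > field.decay_length / 10.0:
        raise StepSizeError(
            f"dt = {dt:.3g} s moves the capsule up to {v_max * dt:.3g} m per step, "
            f"more than decay_length/10 = {field.decay_length / 10:.3g} m; use "
            f"dt <= {field.decay_length / (10 * v_max):.3g} s"
        )

    n_steps = int(math.ceil(duration / dt))
    states = [TrajectoryState(0.0, x_start, v_term(x_start) if mode == "overdamped" else 0.0)]
    arrived = False
    x = x_start
    t = 0.0

    if mode == "overdamped":
        def rhs(xx):
            return v_term(max(xx, stop))

        for _ in range(n_steps):
            k1 = rhs(x)
            k2 = rhs(x + 0.5 * dt * k1)
            k3 = rhs(x + 0.5 * dt * k2)
            k4 = rhs(x + dt * k3)
            x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
            if x <= stop:
                states.append(TrajectoryState(t, stop, v_term(stop)))
                arrived = True
                break
            states.append(TrajectoryState(t, x, v_term(x)))
    else:
        v = 0.0
        decay = math.exp(-dt / tau)
        for _ in range(n_steps):
            # v' = (v_t(x) - v)/tau with v_t frozen over the step: exact update
            vt_mid = v_term(max(x + 0.5 * v * dt, stop))  # midpoint forcing
            x = x + vt_mid * dt + (v - vt_mid) * tau * (1.0 - decay)
            v = vt_mid + (v - vt_mid) * decay
            t += dt
            if x <= stop:
                states.append(TrajectoryState(t, stop, v))
                arrived = True
                break
            states.append(TrajectoryState(t, x, v))

    return SimulatedTrajectory(states=states, arrived=arrived)
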