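"""Inverting the transport model against velocity–distance data.

Two inversions are provided:

* :func:`calibrate_susceptibility` — weighted least squares of the
  closed-form terminal speed over a measured (or synthetic) velocity profile,
  estimating the capsule's effective susceptibility. For chi_eff << 1 the
  model is nearly linear in chi_eff, so the linearized closed-form estimate
  (dropping the (1 + chi)^-2 factor) seeds the nonlinear solver.

* :func:`invert_for_target_mean_speed` — a monotone scalar root find for the
  chi_eff at which the window-averaged model speed equals a target mean
  speed. This anchors replication configurations to reported mean transport
  speeds. Two averaging conventions are supported: ``"spatial"``, the
  arithmetic mean of |v_t(x)| over the window, and ``"observed"``, the
  expected pooled frame-sampled mean of a tracked experiment (capsules
  sampled at the frame rate spend time ∝ 1/|v| at each position, so the
  observed pooled mean down-weights the fast region near the magnet; it is
  computed by noiselessly simulating a dense grid of start positions and
  pooling finite-difference speeds exactly as the tracking pipeline does).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, least_squares

from .capsule import CapsuleSpec, FluidMedium
from .dynamics import integrate_positions, terminal_velocity
from .errors import CalibrationError, DomainError, InfeasibleTargetError, InsufficientDataError
from .field import MagnetFieldModel
from .tracking import VelocityProfile, approach_speeds

__all__ = [
    "CalibrationResult",
    "calibrate_susceptibility",
    "window_average_speed",
    "invert_for_target_mean_speed",
]


@dataclass(frozen=True)
class CalibrationResult:
    """Susceptibility calibration output.

    ``chi_eff_hat`` is the effective-susceptibility estimate;
    ``se_chi_eff`` its standard error from the weighted-least-squares
    Jacobian; ``residual_norm`` the weighted residual norm at the optimum.
    ``decay_length_hat`` is populated only when the field decay length was
    co-estimated.
    """

    chi_eff_hat: float
    se_chi_eff: float
    residual_norm: float
    n_points: int
    decay_length_hat: Optional[float] = None
    se_decay_length: Optional[float] = None


def _profile_arrays(profile: VelocityProfile, weighting: str):
    x = np.asarray(profile.bin_centers, dtype=float)
    v = np.asarray(profile.mean_speed, dtype=float)
    if weighting == "counts":
        w = np.asarray(profile.n_obs, dtype=float)
    elif weighting == "inverse_variance":
        sd = np.asarray(profile.speed_sd, dtype=float)
        n = np.asarray(profile.n_obs, dtype=float)
        var = np.where(sd > 0, sd**2 / n, np.nan)
        fill = np.nanmedian(var) if np.any(np.isfinite(var)) else 1.0
        w = 1.0 / np.where(np.isfinite(var), var, fill)
    else:
        raise DomainError(f"unknown weighting {weighting!r}")
    return x, v, w


def calibrate_susceptibility(
    profile: VelocityProfile,
    capsule: CapsuleSpec,
    fluid: FluidMedium,
    field: MagnetFieldModel,
    weighting: str = "counts",
    fit_decay_length: bool = False,
) -> CalibrationResult:
    """Estimate chi_eff from a velocity profile by weighted least squares.

    Minimizes sum_i w_i (|v_t(x_i; chi)| - v_i)^2 over chi (and optionally
    the field decay length). Weights are the per-bin counts by default, or
    inverse variances with ``weighting="inverse_variance"``.

    Raises :class:`CalibrationError` on non-convergence or a non-positive
    estimate, :class:`InsufficientDataError` below 3 profile points.
    """
    x, v, w = _profile_arrays(profile, weighting)
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 profile points, got {x.size}")
    sw = np.sqrt(w)

    def speed(xx, chi, decay=None):
        fld = field if decay is None else MagnetFieldModel(field.surface_field, decay, field.origin)
        return np.abs(
            terminal_velocity(capsule, fluid, fld, xx, chi_eff=chi, check_reynolds=False)
        )

    # linearized initial guess: speed ~ K(x) * chi for chi << 1
    k = speed(x, 1.0) * 4.0  # K(x) = speed(chi=1)*(1+1)^2
    chi0 = float(np.sum(w * v * k) / np.sum(w * k * k))
    chi0 = max(chi0, 1e-12)

    if fit_decay_length:
        def resid(p):
            return sw * (speed(x, p[0], p[1]) - v)

        p0 = [chi0, field.decay_length]
        res = least_squares(resid, p0, bounds=([1e-15, 1e-9], [np.inf, np.inf]))
    else:
        def resid(p):
            return sw * (speed(x, p[0]) - v)

        res = least_squares(resid, [chi0], bounds=([1e-15], [np.inf]))

    if not res.success or not np.all(np.isfinite(res.x)):
        raise CalibrationError(
            "susceptibility calibration did not converge",
            diagnostics={"status": res.status, "message": res.message},
        )
    dof = max(x.size - res.x.size, 1)
    s2 = float(res.cost * 2.0 / dof)
    jtj = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(res.x.size, np.nan)
    chi_hat = float(res.x[0])
    if chi_hat <= 0:
        raise CalibrationError(
            f"calibrated chi_eff = {chi_hat} is non-positive",
            diagnostics={"residual_norm": float(np.linalg.norm(res.fun))},
        )
    return CalibrationResult(
        chi_eff_hat=chi_hat,
        se_chi_eff=float(se[0]),
        residual_norm=float(np.linalg.norm(res.fun)),
        n_points=int(x.size),
        decay_length_hat=float(res.x[1]) if fit_decay_length else None,
        se_decay_length=float(se[1]) if fit_decay_length else None,
    )


def window_average_speed(
    capsule: CapsuleSpec,
    fluid: FluidMedium,
    field: MagnetFieldModel,
    window: tuple[float, float],
    chi_eff: float,
    average: str = "spatial",
    frame_rate: float = 24.0,
    duration: float = 60.0,
    n_starts: int = 192,
) -> float:
    """Window-averaged model approach speed at a given chi_eff, m/s.

    ``average="spatial"``: arithmetic mean of |v_t(x)| over the window
    (adaptive quadrature). ``average="observed"``: expected
    pooled frame-sampled mean of an experiment — ``n_starts`` capsules on an
    evenly spaced start grid over the window are integrated noiselessly,
    sampled at ``frame_rate`` for ``duration``, differentiated by the same
    central differences the tracking pipeline uses, and all speed samples
    with window distances are pooled.
    """
    lo, hi = window
    if not (0 <= lo < hi):
        raise DomainError("window must satisfy 0 <= x_min < x_max")
    if average == "spatial":
        integral, _ = quad(
            lambda xx: abs(
                terminal_velocity(capsule, fluid, field, xx, chi_eff=chi_eff, check_reynolds=False)
            ),
            lo,
            hi,
            epsabs=0.0,
            epsrel=1e-12,
        )
        return float(integral / (hi - lo))
    if average != "observed":
        raise DomainError(f"unknown average {average!r}")
    times = np.arange(int(math.floor(duration * frame_rate)) + 1) / frame_rate
    starts = lo + (hi - lo) * (np.arange(n_starts) + 0.5) / n_starts
    stop = capsule.radius
    starts = starts[starts > stop]
    pos = integrate_positions(capsule, fluid, field, starts, times, chi_eff=chi_eff)
    total, count = 0.0, 0
    for i in range(pos.shape[1]):
        xi = pos[:, i]
        arrived = xi <= stop * (1 + 1e-12)
        last = int(np.argmax(arrived)) if arrived.any() else xi.size - 1
        if last < 1:
            continue
        speeds = approach_speeds(times[: last + 1], xi[: last + 1])
        sel = (xi[: last + 1] >= lo) & (xi[: last + 1] <= hi)
        total += float(np.sum(speeds[sel]))
        count += int(np.sum(sel))
    if count == 0:
        raise DomainError("no frame samples fell inside the window")
    return total / count


def invert_for_target_mean_speed(
    target_mean_speed: float,
    capsule: CapsuleSpec,
    fluid: FluidMedium,
    field: MagnetFieldModel,
    observation_window: tuple[float, float],
    average: str = "spatial",
    chi_max: float = 1.0,
    rtol: float = 1e-9,
    **avg_kwargs,
) -> float:
    """The chi_eff whose window-averaged model speed equals the target.

    The window-averaged speed is strictly increasing in chi_eff on
    (0, chi_max], so the root is unique; it is found by bracketed Brent
    iteration to ``rtol`` relative tolerance. ``average`` and ``avg_kwargs``
    are forwarded to :func:`window_average_speed`.

    Raises
    ------
    DomainError
        Non-positive target.
    InfeasibleTargetError
        The target exceeds the window-averaged speed at ``chi_max``.
    """
    if target_mean_speed <= 0:
        raise DomainError("target mean speed must be positive")

    def avg(chi):
        return window_average_speed(
            capsule, fluid, field, observation_window, chi, average=average, **avg_kwargs
        )

    v_upper = avg(chi_max)
    if v_upper < target_mean_speed:
        raise InfeasibleTargetError(
            f"target {target_mean_speed} m/s unreachable: window-averaged speed at the "
            f"chi_eff bound {chi_max} is only {v_upper:.6g} m/s"
        )
    # near-linear problem: seed a tight bracket from the small-chi slope
    chi_lin = 1e-6 * target_mean_speed / avg(1e-6)
    lo_b, hi_b = chi_lin / 4.0, min(chi_lin * 4.0, chi_max)

    def f(chi):
        return avg(chi) - target_mean_speed

    if not (f(lo_b) < 0 < f(hi_b)):
        lo_b, hi_b = 1e-15, chi_max
    chi_hat = brentq(f, lo_b, hi_b, rtol=min(rtol, 1e-12), xtol=1e-30, maxiter=200)
    return float(chi_hat)
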