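"""Capsule detection, trajectory linking, velocity profiles, and curve fits.

This mirrors the measurement side of a magnetophoresis experiment: bright
capsules are detected per frame with sub-pixel centroids, detections are
linked frame-to-frame into trajectories by globally optimal (minimum total
squared displacement) assignment with a hard displacement gate, per-point
approach speeds are computed by central finite differences, binned by
distance from the magnet into a velocity profile, and the profile is fitted
with the model-shaped curve v(x) = A·exp(-2x/x0) that an exponentially
decaying field imposes on the terminal velocity.

Speeds are reported as positive approach speed — the x-component of motion
toward the magnet; the y-component is excluded (the physics is 1-D).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, linear_sum_assignment
from skimage.measure import label as sk_label, regionprops

from .errors import DomainError, FitFailureError, InsufficientDataError

__all__ = [
    "Trajectory",
    "VelocityProfile",
    "VelocityCurveFit",
    "detect_capsules",
    "detect_stack",
    "link_trajectories",
    "approach_speeds",
    "velocity_profile",
    "pooled_mean_speed",
    "fit_velocity_curve",
]


@dataclass
class Trajectory:
    """One tracked capsule.

    ``positions`` is an (n, 2) array of (x, y) in meters; ``frames`` are the
    acquisition frame numbers (strictly increasing); ``times`` are
    frames/frame_rate; ``interpolated`` flags points bridged across detection
    gaps rather than observed.
    """

    track_id: int
    frames: np.ndarray
    times: np.ndarray
    positions: np.ndarray
    interpolated: np.ndarray = dc_field(default=None)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if self.interpolated is None:
            self.interpolated = np.zeros(self.frames.size, dtype=bool)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if self.frames.size < 2:
            raise DomainError("a trajectory needs at least 2 detections")
        if np.any(np.diff(self.frames) <= 0):
            raise DomainError("frames must be strictly increasing")
        if not (self.frames.size == self.times.size == self.positions.shape[0]):
            raise DomainError("frames, times and positions must have equal length")

    def __len__(self) -> int:
        return self.frames.size


@dataclass(frozen=True)
class VelocityProfile:
    """Binned mean approach speed vs distance from the magnet face.

    Only non-empty bins are reported; bins are ordered by distance and
    non-overlapping (fixed width). ``pooling`` records whether the means are
    pooled per-point means (default) or means of per-track means.
    """

    bin_centers: np.ndarray
    mean_speed: np.ndarray
    speed_sd: np.ndarray
    n_obs: np.ndarray
    bin_width: float
    pooling: str = "pooled"

    def __post_init__(self):
        for name in ("bin_centers", "mean_speed", "speed_sd", "n_obs"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if np.any(np.diff(self.bin_centers) <= 0):
            raise DomainError("bins must be ordered and non-overlapping")
        if np.any(self.n_obs < 1):
            raise DomainError("reported bins must have n_obs >= 1")

    @property
    def n_points(self) -> int:
        return int(self.bin_centers.size)


# --------------------------------------------------------------------------
# detection


def detect_capsules(image: np.ndarray, min_area: int = 3) -> np.ndarray:
    """Sub-pixel centroids of bright spots in a single 2-D frame.

    Background is the image median; a spot mask is everything above
    5 robust noise SDs (1.4826·MAD) or, on noise-free images, above 5% of
    the peak excess (where a Gaussian spot's footprint is compact enough
    that neighbors ~6 sigma apart stay disconnected, and still symmetric so
    the weighted centroid is unbiased). Centroids are intensity-weighted
    over each connected
    component in pixel-center coordinates: a spot centered at pixel index
    (r, c) returns (x, y) = (c, r).

    Returns an (n, 2) array of (x, y) pixel coordinates (may be empty). An
    empty, uniform or saturated frame yields an empty array with a warning.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise DomainError("detect_capsules expects a single 2-D frame")
    bg = np.median(img)
    resid = img - bg
    peak = resid.max()
    if peak <= 0:
        warnings.warn("empty or uniform frame: no detections", stacklevel=2)
        return np.empty((0, 2))
    noise = 1.4826 * np.median(np.abs(resid))
    thr = max(5.0 * noise, 0.05 * peak)
    mask = resid > thr
    if not mask.any():
        warnings.warn("no pixels above detection threshold", stacklevel=2)
        return np.empty((0, 2))
    labels = sk_label(mask)
    weights = np.clip(resid, 0, None)
    out = []
    for region in regionprops(labels, intensity_image=weights):
        if region.area < min_area:
            continue
        r, c = region.centroid_weighted
        out.append((c, r))
    return np.array(sorted(out)) if out else np.empty((0, 2))


def detect_stack(
    stack: np.ndarray, pixel_size: float = 1e-6, min_area: int = 3
) -> pd.DataFrame:
    """Run :func:`detect_capsules` over a stack; return ``frame, x_m, y_m``.

    Pixel-center coordinates are converted to physical ones with
    x_m = (x_px + 0.5)·pixel_size (matching the renderer's convention).
    """
    rows = []
    for f, frame in enumerate(stack):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            det = detect_capsules(frame, min_area=min_area)
        for x_px, y_px in det:
            rows.append((f, (x_px + 0.5) * pixel_size, (y_px + 0.5) * pixel_size))
    return pd.DataFrame(rows, columns=["frame", "x_m", "y_m"])


# --------------------------------------------------------------------------
# linking


def _group_by_frame(detections: pd.DataFrame) -> dict[int, np.ndarray]:
    grouped = {}
    for frame, g in detections.groupby("frame"):
        grouped[int(frame)] = g[["x_m", "y_m"]].to_numpy(dtype=float)
    return grouped


class _OpenTrack:
    __slots__ = ("frames", "points", "last_frame")

    def __init__(self, frame: int, point: np.ndarray):
        self.frames = [frame]
        self.points = [point]
        self.last_frame = frame

    def extend(self, frame: int, point: np.ndarray):
        self.frames.append(frame)
        self.points.append(point)
        self.last_frame = frame


def solve_frame_assignment(
    prev_points: np.ndarray, new_points: np.ndarray, gate: float
) -> list[tuple[int, int]]:
    """Minimum-total-squared-displacement assignment between two point sets.

    Classic linear assignment with birth/death: the (T+D)x(D+T) padded cost
    matrix carries squared displacements (infeasible beyond ``gate``) and a
    skip cost of gate² per unmatched point, so a link is made exactly when it
    is cheaper than abandoning the track and starting a new one. Returns the
    accepted (prev_index, new_index) pairs.
    """
    t, d = len(prev_points), len(new_points)
    if t == 0 or d == 0:
        return []
    big = 1e30
    gate2 = gate * gate
    dist2 = np.sum((prev_points[:, None, :] - new_points[None, :, :]) ** 2, axis=2)
    cost = np.full((t + d, d + t), 0.0)
    cost[:t, :d] = np.where(dist2 <= gate2, dist2, big)
    cost[:t, d:] = big
    cost[np.arange(t), d + np.arange(t)] = gate2
    cost[t:, :d] = big
    cost[t + np.arange(d), np.arange(d)] = gate2
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if r < t and c < d and cost[r, c] < big]


def link_trajectories(
    detections: pd.DataFrame,
    max_displacement: float,
    max_gap: int = 2,
    frame_rate: float = 1.0,
    min_length: int = 2,
) -> list[Trajectory]:
    """Link per-frame detections into trajectories.

    Frame pairs are resolved by minimum total squared displacement
    (:func:`solve_frame_assignment`); links longer than
    ``max_displacement × (frame gap)`` are forbidden; tracks unseen for more
    than ``max_gap`` frames are closed; detections left unassigned start new
    tracks. Gaps of 1..max_gap frames are bridged by linear interpolation and
    the inserted points flagged ``interpolated``. Tracks shorter than
    ``min_length`` detections are dropped (a trajectory needs >= 2 points).
    """
    if max_displacement <= 0:
        raise DomainError("max_displacement must be > 0")
    if max_gap < 0:
        raise DomainError("max_gap must be >= 0")
    by_frame = _group_by_frame(detections)
    if not by_frame:
        return []
    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    for frame in sorted(by_frame):
        pts = by_frame[frame]
        still_open = []
        for tr in open_tracks:
            (still_open if frame - tr.last_frame <= max_gap + 1 else closed).append(tr)
        open_tracks = still_open
        if open_tracks and len(pts):
            prev = np.array([tr.points[-1] for tr in open_tracks])
            gaps = np.array([frame - tr.last_frame for tr in open_tracks])
            # gate grows with the bridged gap length
            big_gate = max_displacement * gaps.max()
            pairs = solve_frame_assignment(prev, pts, big_gate)
            # re-check the per-track gate (gap-dependent)
            pairs = [
                (i, j)
                for i, j in pairs
                if np.linalg.norm(prev[i] - pts[j]) <= max_displacement * gaps[i]
            ]
        else:
            pairs = []
        used = set()
        for i, j in pairs:
            open_tracks[i].extend(frame, pts[j])
            used.add(j)
        for j in range(len(pts)):
            if j not in used:
                open_tracks.append(_OpenTrack(frame, pts[j]))
    closed.extend(open_tracks)

    trajectories = []
    tid = 0
    for tr in closed:
        if len(tr.frames) < max(min_length, 2):
            continue
        frames = np.array(tr.frames)
        points = np.array(tr.points)
        # bridge gaps by linear interpolation, flagged as inferred
        full_frames = np.arange(frames[0], frames[-1] + 1)
        interp = ~np.isin(full_frames, frames)
        xs = np.interp(full_frames, frames, points[:, 0])
        ys = np.interp(full_frames, frames, points[:, 1])
        trajectories.append(
            Trajectory(
                track_id=tid,
                frames=full_frames,
                times=full_frames / frame_rate,
                positions=np.column_stack([xs, ys]),
                interpolated=interp,
            )
        )
        tid += 1
    return trajectories


# --------------------------------------------------------------------------
# velocities


def approach_speeds(times: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Per-point approach speed -dx/dt by central differences.

    Central differences at interior points, one-sided at the ends; positive
    values mean motion toward the magnet (decreasing x). Inputs must have at
    least 2 samples.
    """
    times = np.asarray(times, dtype=float)
    x = np.asarray(x, dtype=float)
    if times.size < 2:
        raise DomainError("need at least 2 samples to differentiate")
    return -np.gradient(x, times)


def _track_speed_table(tracks: Sequence[Trajectory], magnet_position: float) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        if len(tr) < 2:
            warnings.warn(f"track {tr.track_id} shorter than 2 points excluded", stacklevel=3)
            continue
        speeds = approach_speeds(tr.times, tr.positions[:, 0])
        dist = tr.positions[:, 0] - magnet_position
        rows.append(
            pd.DataFrame({"track_id": tr.track_id, "distance_m": dist, "speed_m_s": speeds})
        )
    if not rows:
        raise InsufficientDataError("no usable tracks (all shorter than 2 points)")
    return pd.concat(rows, ignore_index=True)


def velocity_profile(
    tracks: Sequence[Trajectory],
    magnet_position: float = 0.0,
    bin_width: float = 1e-4,
    pooling: str = "pooled",
) -> VelocityProfile:
    """Bin per-point approach speeds by distance from the magnet face.

    ``pooling="pooled"`` (default) averages all speed samples falling in a
    bin; ``pooling="per_track"`` first averages within each track, then
    across tracks (n_obs then counts tracks). Empty bins are omitted. The
    total pooled n_obs equals the number of speed samples.
    """
    if bin_width <= 0:
        raise DomainError("bin_width must be > 0")
    if pooling not in ("pooled", "per_track"):
        raise DomainError(f"unknown pooling {pooling!r}")
    table = _track_speed_table(tracks, magnet_position)
    table = table[table["distance_m"] >= 0].copy()
    if not len(table):
        raise InsufficientDataError("no speed samples at non-negative distance")
    table["bin"] = np.floor(table["distance_m"] / bin_width).astype(int)
    if pooling == "per_track":
        table = (
            table.groupby(["bin", "track_id"], as_index=False)["speed_m_s"].mean()
        )
    g = table.groupby("bin")["speed_m_s"]
    agg = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1).fillna(0.0), "n": g.size()})
    agg = agg.sort_index()
    return VelocityProfile(
        bin_centers=(agg.index.to_numpy() + 0.5) * bin_width,
        mean_speed=agg["mean"].to_numpy(),
        speed_sd=agg["sd"].to_numpy(),
        n_obs=agg["n"].to_numpy(),
        bin_width=bin_width,
        pooling=pooling,
    )


def pooled_mean_speed(
    tracks: Sequence[Trajectory],
    window: tuple[float, float],
    magnet_position: float = 0.0,
    method: str = "pooled",
) -> float:
    """Mean approach speed over a distance window, m/s.

    ``method="pooled"`` pools every speed sample whose distance from the
    magnet lies in ``window``; ``method="per_track"`` averages per-track
    means. Pooled is the default reported statistic.
    """
    lo, hi = window
    table = _track_speed_table(tracks, magnet_position)
    sel = table[(table["distance_m"] >= lo) & (table["distance_m"] <= hi)]
    if not len(sel):
        raise InsufficientDataError("no speed samples inside the window")
    if method == "pooled":
        return float(sel["speed_m_s"].mean())
    if method == "per_track":
        return float(sel.groupby("track_id")["speed_m_s"].mean().mean())
    raise DomainError(f"unknown method {method!r}")


# --------------------------------------------------------------------------
# curve fitting


@dataclass(frozen=True)
class VelocityCurveFit:
    """Fit of v(x) = A·exp(-2x/x0) to a velocity profile (A in m/s, x0 in m).

    ``se_decay_length`` is NaN when the decay length was held fixed.
    """

    amplitude: float
    decay_length: float
    se_amplitude: float
    se_decay_length: float
    rss: float
    n_bins: int
    fixed_decay_length: bool


def fit_velocity_curve(
    profile: VelocityProfile, field_decay_length: Optional[float] = None
) -> VelocityCurveFit:
    """Weighted least-squares fit of the model-shaped speed curve.

    Weights are the per-bin counts n_obs. With ``field_decay_length`` given,
    x0 is fixed (the amplitude has the closed-form weighted solution);
    otherwise both A and x0 are fitted. The amplitude maps onto the terminal
    velocity prefactor V_p·chi_eff·B0² / (3π·eta·d_p·mu0·(1+chi_eff)²·x0).
    """
    x = np.asarray(profile.bin_centers, dtype=float)
    v = np.asarray(profile.mean_speed, dtype=float)
    w = np.asarray(profile.n_obs, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 profile bins, got {x.size}")
    if np.any(v <= 0):
        raise DomainError("profile speeds must be positive for the curve fit")
    if field_decay_length is not None:
        if field_decay_length <= 0:
            raise DomainError("field_decay_length must be > 0")
        f = np.exp(-2.0 * x / field_decay_length)
        amp = float(np.sum(w * f * v) / np.sum(w * f * f))
        resid = v - amp * f
        rss = float(np.sum(w * resid**2))
        dof = max(x.size - 1, 1)
        se_amp = math.sqrt(rss / dof / np.sum(w * f * f)) if x.size > 1 else float("nan")
        return VelocityCurveFit(amp, field_decay_length, se_amp, float("nan"), rss, x.size, True)

    slope, intercept = np.polyfit(x, np.log(v), 1, w=np.sqrt(w))
    if slope >= 0:
        raise FitFailureError("profile speeds do not decay with distance", {"log_slope": slope})
    p0 = [float(np.exp(intercept)), float(-2.0 / slope)]

    def model(xx, a, x0):
        return a * np.exp(-2.0 * xx / x0)

    try:
        popt, pcov = curve_fit(model, x, v, p0=p0, sigma=1.0 / np.sqrt(w), absolute_sigma=False, maxfev=10000)
    except RuntimeError as exc:
        raise FitFailureError(f"velocity curve fit did not converge: {exc}", {"p0": p0}) from exc
    resid = v - model(x, *popt)
    se = np.sqrt(np.diag(pcov))
    return VelocityCurveFit(
        amplitude=float(popt[0]),
        decay_length=float(popt[1]),
        se_amplitude=float(se[0]),
        se_decay_length=float(se[1]),
        rss=float(np.sum(w * resid**2)),
        n_bins=int(x.size),
        fixed_decay_length=False,
    )
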