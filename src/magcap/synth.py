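"""Synthetic magnetophoresis experiments.

Emulates the imaging experiment used to measure capsule transport: a dozen or
so 180–200 μm capsules suspended in a chamber next to a permanent magnet,
recorded at 24 fps, each capsule migrating toward the magnet along x. The
generator samples the physics model's trajectories at the frame rate and
perturbs them with Gaussian localization noise (centroid-tracking error) and
optional detection dropout, returning both the unlabeled detection table a
tracking algorithm would see and the labelled ground truth for recovery
testing.

Randomness uses one master seed with per-track child streams
(``numpy.random.SeedSequence(seed).spawn``): track ``i`` always consumes
stream ``i``, so with the plain ``uniform`` start sampler, adding tracks
never perturbs existing ones. The default ``stratified`` sampler places one
capsule per equal-width stratum of the start window (capsules dispersed
through the chamber); its strata depend on ``n_tracks``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .capsule import CapsuleSpec, FluidMedium
from .dynamics import integrate_positions
from .errors import DomainError
from .field import MagnetFieldModel

__all__ = ["ExperimentDesign", "generate_observations", "render_frames"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentDesign:
    """Acquisition design of one synthetic experiment.

    Parameters
    ----------
    n_tracks
        Number of capsules in the field of view.
    frame_rate
        Acquisition rate, frames/s (24 fps in the reference experiment).
    duration
        Recording length, seconds.
    field_of_view
        (width, height) of the imaged region, meters; x spans
        [0, width] from the magnet face, y spans [0, height].
    start_x_min, start_x_max
        Window over which initial capsule positions are drawn, meters from
        the magnet face.
    start_sampler
        ``"stratified"`` (default; one capsule per equal-width stratum,
        uniform within it) or ``"uniform"``.
    localization_noise_sd
        Isotropic Gaussian localization error of the detections, meters.
    detection_dropout_prob
        Probability that any individual detection is missed.
    seed
        Master seed for all randomness.
    """

    n_tracks: int
    frame_rate: float = 24.0
    duration: float = 60.0
    field_of_view: tuple[float, float] = (6e-3, 2e-3)
    start_x_min: float = 5e-4
    start_x_max: float = 5e-3
    start_sampler: str = "stratified"
    localization_noise_sd: float = 5e-7
    detection_dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_tracks < 1:
            raise DomainError("n_tracks must be >= 1")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise DomainError("frame_rate and duration must be positive")
        if self.localization_noise_sd < 0:
            raise DomainError("localization_noise_sd must be >= 0")
        if not (0 <= self.detection_dropout_prob < 1):
            raise DomainError("detection_dropout_prob must be in [0, 1)")
        if not (0 <= self.start_x_min < self.start_x_max):
            raise DomainError("need 0 <= start_x_min < start_x_max")
        if self.start_sampler not in ("stratified", "uniform"):
            raise DomainError(f"unknown start_sampler {self.start_sampler!r}")

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration * self.frame_rate)) + 1

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


def _start_positions(design: ExperimentDesign, rngs: list[np.random.Generator]) -> np.ndarray:
    lo, hi = design.start_x_min, design.start_x_max
    n = design.n_tracks
    starts = np.empty(n)
    for i, rng in enumerate(rngs):
        u = rng.uniform()
        if design.start_sampler == "stratified":
            starts[i] = lo + (hi - lo) * (i + u) / n
        else:
            starts[i] = lo + (hi - lo) * u
    return starts


def generate_observations(
    design: ExperimentDesign,
    capsule: CapsuleSpec,
    fluid: FluidMedium,
    field: MagnetFieldModel,
    chi_eff: Optional[float] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one imaging experiment.

    Returns ``(detections, truth)``: ``detections`` has columns
    ``frame, x_m, y_m`` (no track labels, localization noise applied,
    dropout removed, sorted by frame then x); ``truth`` has
    ``track_id, frame, time_s, x_m, y_m`` with exact model positions. A
    track's rows end when the capsule arrives at the stop distance (capsule
    radius). y positions are constant per track in truth (the physics is
    1-D); detections scatter about them isotropically.
    """
    ss = np.random.SeedSequence(design.seed)
    rngs = [np.random.default_rng(c) for c in ss.spawn(design.n_tracks)]
    starts = _start_positions(design, rngs)
    ys = np.array(
        [rng.uniform(0.1, 0.9) * design.field_of_view[1] for rng in rngs]
    )
    times = design.frame_times
    # positions: (n_frames, n_tracks), clamped at the stop distance
    pos = integrate_positions(
        capsule, fluid, field, starts, times, chi_eff=chi_eff
    )
    stop = capsule.radius

    truth_rows = []
    det_rows = []
    for i in range(design.n_tracks):
        xi = pos[:, i]
        arrived = xi <= stop * (1 + 1e-12)
        if arrived.any():
            last = int(np.argmax(arrived))  # include the arrival frame
        else:
            last = xi.size - 1
        frames = np.arange(last + 1)
        truth_rows.append(
            pd.DataFrame(
                {
                    "track_id": i,
                    "frame": frames,
                    "time_s": times[: last + 1],
                    "x_m": xi[: last + 1],
                    "y_m": ys[i],
                }
            )
        )
        rng = rngs[i]
        noise = rng.normal(0.0, design.localization_noise_sd, size=(last + 1, 2))
        keep = rng.uniform(size=last + 1) >= design.detection_dropout_prob
        det_rows.append(
            pd.DataFrame(
                {
                    "frame": frames[keep],
                    "x_m": xi[: last + 1][keep] + noise[keep, 0],
                    "y_m": ys[i] + noise[keep, 1],
                }
            )
        )
    truth = pd.concat(truth_rows, ignore_index=True)
    detections = (
        pd.concat(det_rows, ignore_index=True)
        .sort_values(["frame", "x_m"], kind="mergesort")
        .reset_index(drop=True)
    )
    return detections, truth


def render_frames(
    detections: pd.DataFrame,
    design: ExperimentDesign,
    psf_sigma: float = 2e-6,
    background_level: float = 100.0,
    photon_noise: bool = False,
    pixel_size: float = 1e-6,
    spot_amplitude: float = 2000.0,
    seed: int = 0,
) -> np.ndarray:
    """Render detections as a 16-bit grayscale image stack.

    Each capsule becomes an isotropic 2-D Gaussian spot of width
    ``psf_sigma`` on a uniform background; with ``photon_noise`` the pixel
    values are Poisson-sampled. Pixel (row r, col c) covers
    x in [c, c+1)·pixel_size, y in [r, r+1)·pixel_size; intensities are
    evaluated at pixel centers. Detections outside the field of view are
    clipped (logged), not raised.

    Returns an array of shape ``(n_frames, height_px, width_px)``, dtype
    uint16, frame index = acquisition frame number.
    """
    if psf_sigma <= 0 or pixel_size <= 0:
        raise DomainError("psf_sigma and pixel_size must be positive")
    width_px = int(round(design.field_of_view[0] / pixel_size))
    height_px = int(round(design.field_of_view[1] / pixel_size))
    stack = np.full((design.n_frames, height_px, width_px), background_level, dtype=float)
    sig_px = psf_sigma / pixel_size
    half = max(3, int(math.ceil(4 * sig_px)))
    n_clipped = 0
    for frame, x_m, y_m in detections[["frame", "x_m", "y_m"]].itertuples(index=False):
        f = int(frame)
        if not (0 <= f < design.n_frames):
            n_clipped += 1
            continue
        cx = x_m / pixel_size - 0.5  # pixel-center coordinates
        cy = y_m / pixel_size - 0.5
        if not (-half < cx < width_px + half and -half < cy < height_px + half):
            n_clipped += 1
            continue
        c0, c1 = max(0, int(cx) - half), min(width_px, int(cx) + half + 1)
        r0, r1 = max(0, int(cy) - half), min(height_px, int(cy) + half + 1)
        if c0 >= c1 or r0 >= r1:
            n_clipped += 1
            continue
        cols = np.arange(c0, c1)
        rows = np.arange(r0, r1)
        gx = np.exp(-0.5 * ((cols - cx) / sig_px) ** 2)
        gy = np.exp(-0.5 * ((rows - cy) / sig_px) ** 2)
        stack[f, r0:r1, c0:c1] += spot_amplitude * gy[:, None] * gx[None, :]
    if n_clipped:
        logger.info("render_frames: %d detections outside the field of view were clipped", n_clipped)
    if photon_noise:
        rng = np.random.default_rng(seed)
        stack = rng.poisson(np.clip(stack, 0, None)).astype(float)
    return np.clip(np.rint(stack), 0, 65535).astype(np.uint16)
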