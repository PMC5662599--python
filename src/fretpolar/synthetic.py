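"""Synthetic two-channel biosensor movies, star masks and trajectories.

Every downstream stage of the pipeline is testable against known ground
truth generated here: a migrating elliptical cell with a spatially
polarized activation field (high at the rear, fluctuating at the front),
multiplicative biosensor signal on a smooth donor intensity profile,
additive background, Poisson shot noise plus Gaussian read noise, optional
mid-movie repolarization, star-shaped masks with arms of known length and
angle, and persistent-random-walk trajectories.

The noise model is the standard fluorescence camera model: per-channel
Poisson statistics on the expected counts followed by additive zero-mean
Gaussian read noise.  The FRET channel is activation x (donor - background)
+ background — a single-chain sensor puts donor and acceptor in the same
molecule, so the two channels share one background and need no
bleed-through term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motility import Trajectory
from .polarity import LineScanProfile
from .ratio import TwoChannelMovie

__all__ = [
    "SyntheticCellParams",
    "GroundTruth",
    "StarMaskParams",
    "RandomWalkParams",
    "generate_polarized_cell_movie",
    "generate_star_mask",
    "generate_trajectory",
    "generate_intensity_profile_pair",
    "trajectory_from_ground_truth",
]


@dataclass
class SyntheticCellParams:
    """Conditions of a synthetic polarized-cell acquisition.

    Defaults emulate confocal ratio imaging of an emigrating neural crest
    cell: 0.16 µm pixels, 15-min frame interval, a rear activation of 2.0
    against a front of 1.0 with a sinusoidally fluctuating front level.
    """

    image_shape: tuple[int, int] = (256, 256)   # (H, W) pixels
    pixel_size: float = 0.16                    # µm / pixel
    n_frames: int = 16
    frame_interval: float = 15.0                # minutes
    cell_radius: float = 8.0                    # µm, semi-major axis
    cell_aspect: float = 0.8                    # semi-minor / semi-major
    activation_back: float = 2.0                # dimensionless true ratio
    activation_front_mean: float = 1.0
    activation_front_fluctuation_amplitude: float = 0.3
    fluctuation_period: float = 8.0             # frames
    donor_intensity: float = 1000.0             # counts above background
    background_level: float = 100.0             # counts
    read_noise_sd: float = 5.0                  # counts
    shot_noise: bool = True
    migration_speed: float = 0.1                # µm / min
    migration_direction: float = 0.0            # degrees, east=0, CCW
    repolarization_frame: int | None = None
    edge_softness: float = 0.05                 # ellipse edge width, fraction of radius
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.activation_back <= 0 or self.activation_front_mean <= 0:
            raise ValueError("activation values must be positive")
        amp = self.activation_front_fluctuation_amplitude
        if amp < 0 or self.activation_front_mean - amp <= 0:
            raise ValueError("front activation must stay positive over the "
                             "fluctuation cycle")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.cell_radius <= 0 or not (0 < self.cell_aspect <= 1):
            raise ValueError("invalid cell geometry")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.repolarization_frame is not None and not (
            0 < self.repolarization_frame < self.n_frames
        ):
            raise ValueError("repolarization_frame must fall inside the movie")


@dataclass
class GroundTruth:
    """Everything the generator knows, for use as an acceptance oracle."""

    true_masks: np.ndarray             # (F, H, W) bool
    true_activation_field: np.ndarray  # (F, H, W) dimensionless
    true_centroid_track: np.ndarray    # (F, 2) µm, (x, y) with y up
    true_front_axis: np.ndarray        # (F,) degrees
    true_back_front_ratio: np.ndarray  # (F,)
    true_protrusions: list = field(default_factory=list)
    params: dict = field(default_factory=dict)


@dataclass
class StarMaskParams:
    """A disc body with rectangular arms of known length and angle."""

    body_radius: float                  # µm
    arm_lengths: list[float] = field(default_factory=list)   # µm beyond body
    arm_angles: list[float] = field(default_factory=list)    # degrees
    arm_width: float = 1.6              # µm
    pixel_size: float = 0.16
    image_shape: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if len(self.arm_lengths) != len(self.arm_angles):
            raise ValueError("arm_lengths and arm_angles must match in length")
        if any(l < 0 for l in self.arm_lengths):
            raise ValueError("arm lengths must be >= 0")
        if self.body_radius <= 0 or self.arm_width <= 0:
            raise ValueError("body_radius and arm_width must be positive")
        # arms must not overlap: angular separation must exceed the angular
        # width an arm subtends at the body boundary
        if len(self.arm_angles) > 1:
            half = np.degrees(np.arcsin(
                min(1.0, (self.arm_width / 2) / self.body_radius)))
            angles = np.sort(np.asarray(self.arm_angles, dtype=float) % 360.0)
            gaps = np.diff(np.concatenate([angles, [angles[0] + 360.0]]))
            if np.any(gaps <= 2 * half):
                raise ValueError("arms overlap: angular separation too small")


@dataclass
class RandomWalkParams:
    """Persistent random walk: Gaussian turning angles and step lengths."""

    n_steps: int = 64
    step_length_mean: float = 1.5       # µm per step
    step_length_sd: float = 0.0
    turning_angle_sd: float = 20.0      # degrees; 0 => straight line
    frame_interval: float = 15.0        # minutes
    initial_direction: float = 0.0      # degrees
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.step_length_mean <= 0:
            raise ValueError("step_length_mean must be positive")
        if self.step_length_sd < 0 or self.turning_angle_sd < 0:
            raise ValueError("spreads must be >= 0")


def _pixel_grid_um(shape: tuple[int, int], pixel_size: float):
    """Physical (x, y) coordinates of pixel centers, y up."""
    H, W = shape
    x = np.arange(W, dtype=float) * pixel_size
    y = (H - 1 - np.arange(H, dtype=float)) * pixel_size
    return np.meshgrid(x, y)


def generate_polarized_cell_movie(
    params: SyntheticCellParams,
) -> tuple[TwoChannelMovie, GroundTruth]:
    """Render a migrating polarized cell into donor and FRET channels.

    The cell is an ellipse with a smooth edge profile oriented along the
    front axis.  Activation is ``activation_back`` in the rear half and a
    sinusoidally fluctuating level around ``activation_front_mean`` in the
    front half.  Donor is ``profile * donor_intensity + background``; the
    noise-free FRET channel is ``activation * (donor - background) +
    background``, so the background-corrected channel ratio restricted to
    the mask reproduces the activation field exactly.  When
    ``repolarization_frame`` is set, the back/front activation assignment
    flips there and the migration direction reverses.
    """
    p = params
    rng = np.random.default_rng(p.rng_seed)
    H, W = p.image_shape
    X, Y = _pixel_grid_um(p.image_shape, p.pixel_size)

    # front axis and displacement per frame (direction reverses after
    # repolarization)
    axes = np.full(p.n_frames, p.migration_direction, dtype=float)
    if p.repolarization_frame is not None:
        axes[p.repolarization_frame:] = (p.migration_direction + 180.0) % 360.0
    step = p.migration_speed * p.frame_interval
    centroids = np.zeros((p.n_frames, 2))
    for t in range(1, p.n_frames):
        theta = np.radians(axes[t - 1])
        centroids[t] = centroids[t - 1] + step * np.array(
            [np.cos(theta), np.sin(theta)])
    # centre the whole path in the field of view
    extent = np.array([(W - 1) * p.pixel_size, (H - 1) * p.pixel_size])
    bbox_center = (centroids.min(axis=0) + centroids.max(axis=0)) / 2
    centroids += extent / 2 - bbox_center

    a = p.cell_radius
    b = p.cell_radius * p.cell_aspect
    for t in range(p.n_frames):
        cx, cy = centroids[t]
        if cx - a < 0 or cx + a > extent[0] or cy - a < 0 or cy + a > extent[1]:
            raise ValueError(
                f"cell leaves the field of view at frame {t}: "
                f"centroid ({cx:.1f}, {cy:.1f}) µm, radius {a} µm, "
                f"field {extent[0]:.1f} x {extent[1]:.1f} µm")

    donor = np.empty((p.n_frames, H, W))
    fret = np.empty((p.n_frames, H, W))
    masks = np.empty((p.n_frames, H, W), dtype=bool)
    activation = np.empty((p.n_frames, H, W))
    bf_ratio = np.empty(p.n_frames)

    for t in range(p.n_frames):
        theta = np.radians(axes[t])
        u = np.array([np.cos(theta), np.sin(theta)])
        dx, dy = X - centroids[t, 0], Y - centroids[t, 1]
        along = dx * u[0] + dy * u[1]
        across = -dx * u[1] + dy * u[0]
        rho = np.sqrt((along / a) ** 2 + (across / b) ** 2)
        profile = 1.0 / (1.0 + np.exp((rho - 1.0) / p.edge_softness))
        mask = rho <= 1.0

        front_level = p.activation_front_mean + (
            p.activation_front_fluctuation_amplitude
            * np.sin(2 * np.pi * t / p.fluctuation_period))
        act = np.where(along >= 0, front_level, p.activation_back)

        d_clean = profile * p.donor_intensity + p.background_level
        f_clean = act * profile * p.donor_intensity + p.background_level

        if p.shot_noise:
            d_noisy = rng.poisson(d_clean).astype(float)
            f_noisy = rng.poisson(f_clean).astype(float)
        else:
            d_noisy, f_noisy = d_clean.copy(), f_clean.copy()
        if p.read_noise_sd > 0:
            d_noisy = d_noisy + rng.normal(0.0, p.read_noise_sd, d_noisy.shape)
            f_noisy = f_noisy + rng.normal(0.0, p.read_noise_sd, f_noisy.shape)

        donor[t], fret[t] = d_noisy, f_noisy
        masks[t], activation[t] = mask, act
        back = mask & (along < 0)
        front = mask & (along >= 0)
        bf_ratio[t] = act[back].mean() / act[front].mean()

    movie = TwoChannelMovie(
        donor_frames=donor, fret_frames=fret,
        pixel_size=p.pixel_size, frame_interval=p.frame_interval,
    )
    truth = GroundTruth(
        true_masks=masks,
        true_activation_field=activation,
        true_centroid_track=centroids,
        true_front_axis=axes,
        true_back_front_ratio=bf_ratio,
        params=vars(p).copy(),
    )
    return movie, truth


def generate_star_mask(params: StarMaskParams) -> tuple[np.ndarray, list[dict]]:
    """Rasterize a disc body with rectangular arms; return mask + truth.

    Each arm of positive length is recorded as a protrusion with its base
    on the body boundary, its tip, its length beyond the body boundary and
    its direction, all in physical µm / degrees.
    """
    p = params
    X, Y = _pixel_grid_um(p.image_shape, p.pixel_size)
    extent = np.array([(p.image_shape[1] - 1) * p.pixel_size,
                       (p.image_shape[0] - 1) * p.pixel_size])
    center = extent / 2
    dx, dy = X - center[0], Y - center[1]
    mask = dx ** 2 + dy ** 2 <= p.body_radius ** 2
    protrusions: list[dict] = []
    for length, angle in zip(p.arm_lengths, p.arm_angles):
        if length == 0:
            continue
        theta = np.radians(angle)
        u = np.array([np.cos(theta), np.sin(theta)])
        along = dx * u[0] + dy * u[1]
        across = -dx * u[1] + dy * u[0]
        arm = (along >= 0) & (along <= p.body_radius + length) \
            & (np.abs(across) <= p.arm_width / 2)
        base = center + u * p.body_radius
        tip = center + u * (p.body_radius + length)
        if np.any(tip < 0) or np.any(tip > extent):
            raise ValueError("arm extends beyond the field of view")
        mask |= arm
        protrusions.append({
            "base": base.tolist(), "tip": tip.tolist(),
            "length": float(length), "angle": float(angle % 360.0),
        })
    return mask, protrusions


def generate_trajectory(params: RandomWalkParams) -> Trajectory:
    """Persistent random walk with Gaussian turning angles.

    With ``turning_angle_sd = 0`` and ``step_length_sd = 0`` the path is a
    perfectly straight, equally spaced line.
    """
    p = params
    rng = np.random.default_rng(p.rng_seed)
    turns = rng.normal(0.0, p.turning_angle_sd, p.n_steps)
    turns[0] = 0.0
    headings = np.radians(p.initial_direction + np.cumsum(turns))
    lengths = np.clip(
        rng.normal(p.step_length_mean, p.step_length_sd, p.n_steps), 0.0, None
    ) if p.step_length_sd > 0 else np.full(p.n_steps, p.step_length_mean)
    steps = np.stack([lengths * np.cos(headings),
                      lengths * np.sin(headings)], axis=1)
    positions = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    times = np.arange(p.n_steps + 1) * p.frame_interval
    return Trajectory(cell_id=f"walk-{p.rng_seed}", times=times,
                      positions=positions)


def trajectory_from_ground_truth(truth: GroundTruth, cell_id: str = "cell0",
                                 frame_interval: float | None = None) -> Trajectory:
    """Build a trajectory from the true centroid track of a movie."""
    if frame_interval is None:
        frame_interval = float(truth.params.get("frame_interval", 15.0))
    n = truth.true_centroid_track.shape[0]
    return Trajectory(cell_id=cell_id,
                      times=np.arange(n) * frame_interval,
                      positions=truth.true_centroid_track.copy())


def generate_intensity_profile_pair(
    n_samples: int = 50,
    noise_fraction: float = 0.1,
    rng_seed: int = 0,
) -> tuple[LineScanProfile, LineScanProfile]:
    """Anti-correlated front-to-perinuclear intensity profiles.

    Emulates line scans of a RhoGAP (high at the leading front, decaying
    toward the perinuclear region) against RHOA activity (the mirror
    image): the first profile is a decreasing sigmoid, the second its
    complement, each with additive Gaussian noise of ``noise_fraction``
    times the profile range.
    """
    rng = np.random.default_rng(rng_seed)
    s = np.linspace(0.0, 1.0, n_samples)
    base = 1.0 / (1.0 + np.exp((s - 0.5) / 0.15))   # high at the front
    gap_like = base + rng.normal(0.0, noise_fraction, n_samples)
    rhoa_like = (1.0 - base) + rng.normal(0.0, noise_fraction, n_samples)
    arclength = s * 20.0  # a 20 µm scan
    kwargs = dict(normalized_position=s, averaging_width=3)
    return (LineScanProfile(arclength=arclength, intensity=gap_like, **kwargs),
            LineScanProfile(arclength=arclength, intensity=rhoa_like, **kwargs))
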