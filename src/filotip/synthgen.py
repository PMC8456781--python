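"""Synthetic ground-truth data for every pipeline stage.

No raw microscopy from the original experiments is redistributable, so each
quantification stage is exercised on synthetic data whose generating law is
known exactly:

* 16-bit fluorescence scenes with a central cell body and straight
  filopodia radiating from it, rendered per channel-specific intensity laws
  (tip-concentrated exponential decay for active integrin / MYO10 versus
  uniform occupancy for inactive integrin / F-actin), plus Poisson shot
  noise and Gaussian read noise;
* immunogold particle distances (truncated-exponential from the tip, or
  uniform along the filopodium);
* ligand-depletion titrations obeying the mass-action quadratic;
* log-normal flow-cytometry stain populations;
* time-lapse spot movies with exponential lifetimes and bounded per-frame
  motion.

Every generator is a pure function of its configuration and seed, and every
quantity a downstream module estimates is stored as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binding import Titration, make_titration_signal
from .distributions import GoldParticleSet
from .errors import ArgumentError, SceneSizeError
from .flow_stats import FlowSample

UINT16_MAX = 65535


@dataclass(frozen=True)
class ChannelLaw:
    """Spatial intensity law of one fluorescence channel.

    ``spatial_mode`` is one of:

    * ``"tip_exponential"`` — amplitude * exp(-d / decay_length) with d the
      arc distance from the filopodium tip (um); rendered only on filopodia
      drawn tip-positive with probability ``tip_positive_fraction``;
    * ``"uniform"`` — constant amplitude on the cell body and all filopodia;
    * ``"shaft_uniform"`` — constant amplitude on filopodia only;
    * ``"body_only"`` — constant amplitude on the cell body only.
    """

    name: str
    spatial_mode: str
    amplitude: float
    decay_length: float | None = None  # um, tip_exponential only
    tip_positive_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.spatial_mode not in {"tip_exponential", "uniform", "shaft_uniform", "body_only"}:
            raise ArgumentError(f"unknown spatial_mode {self.spatial_mode!r}")
        if self.spatial_mode == "tip_exponential":
            if self.decay_length is None or self.decay_length <= 0:
                raise ArgumentError("tip_exponential needs decay_length > 0")
        if self.amplitude < 0:
            raise ArgumentError("amplitude must be >= 0")
        if not 0.0 <= self.tip_positive_fraction <= 1.0:
            raise ArgumentError("tip_positive_fraction must be in [0, 1]")


def default_channel_models() -> list[ChannelLaw]:
    """The four-channel staining panel the fixtures emulate.

    MYO10 and active beta-1 integrin concentrate at tips (decaying over
    ~1 um); F-actin fills the cell and filopodia; inactive beta-1 integrin
    occupies filopodia uniformly.
    """
    return [
        ChannelLaw("MYO10", "tip_exponential", 30000.0, decay_length=0.8),
        ChannelLaw("F-actin", "uniform", 20000.0),
        ChannelLaw("active-integrin", "tip_exponential", 25000.0, decay_length=1.0,
                   tip_positive_fraction=0.75),
        ChannelLaw("inactive-integrin", "shaft_uniform", 12000.0),
    ]


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, optics and noise of a synthetic scene.

    Defaults resemble the structured-illumination scale of the imaged
    filopodia: 0.08 um pixels, an 8 um-radius cell body and 2-8 um
    filopodia, so absolute ADU thresholds keep their meaning.
    """

    image_size: tuple[int, int] = (512, 512)
    pixel_size: float = 0.08               # um / pixel
    n_filopodia: int = 30
    filopodium_length_range: tuple[float, float] = (2.0, 8.0)  # um
    cell_radius: float = 8.0               # um
    channel_models: tuple[ChannelLaw, ...] = field(
        default_factory=lambda: tuple(default_channel_models())
    )
    poisson_scale: float = 2.0             # ADU per photon; <= 0 disables shot noise
    read_sd: float = 100.0                 # ADU; <= 0 disables read noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ArgumentError("pixel_size must be > 0")
        lmin, lmax = self.filopodium_length_range
        if not (0 < lmin <= lmax):
            raise ArgumentError("filopodium lengths must be positive, min <= max")
        if self.n_filopodia < 0:
            raise ArgumentError("n_filopodia must be >= 0")
        if self.cell_radius <= 0:
            raise ArgumentError("cell_radius must be > 0")


@dataclass
class SyntheticScene:
    """A rendered scene plus its complete ground truth."""

    config: SceneConfig
    polylines: list[np.ndarray]            # per filopodium, (n, 2) x,y px, tip first
    lengths_um: np.ndarray
    ground_truth_positive: dict[str, np.ndarray]  # channel -> per-filopodium bool
    images: dict[str, np.ndarray]          # channel -> uint16 (h, w)

    @property
    def channel_names(self) -> list[str]:
        return [law.name for law in self.config.channel_models]


def _render_polyline(
    canvas: np.ndarray,
    polyline_xy: np.ndarray,
    law_of_arc,
    pixel_size: float,
    halfwidth: float = 1.0,
) -> None:
    """Render a 1-px-wide anti-aliased curve whose value follows law(arc_um).

    Each pixel within ``halfwidth`` of the line receives
    law(arc) * max(0, 1 - perpendicular distance); contributions combine by
    maximum so pixel centres that lie exactly on the line carry the law
    value unchanged.
    """
    verts = np.asarray(polyline_xy, dtype=float)
    seg = np.diff(verts, axis=0)
    seg_len_px = np.hypot(seg[:, 0], seg[:, 1])
    cum_px = np.concatenate([[0.0], np.cumsum(seg_len_px)])
    h, w = canvas.shape
    for i in range(len(seg)):
        p0, p1 = verts[i], verts[i + 1]
        x_lo = max(int(np.floor(min(p0[0], p1[0]) - halfwidth)), 0)
        x_hi = min(int(np.ceil(max(p0[0], p1[0]) + halfwidth)), w - 1)
        y_lo = max(int(np.floor(min(p0[1], p1[1]) - halfwidth)), 0)
        y_hi = min(int(np.ceil(max(p0[1], p1[1]) + halfwidth)), h - 1)
        if x_hi < x_lo or y_hi < y_lo:
            continue
        xs, ys = np.meshgrid(
            np.arange(x_lo, x_hi + 1), np.arange(y_lo, y_hi + 1)
        )
        d = p1 - p0
        len2 = float(d @ d)
        t = ((xs - p0[0]) * d[0] + (ys - p0[1]) * d[1]) / len2
        t = np.clip(t, 0.0, 1.0)
        px = p0[0] + t * d[0]
        py = p0[1] + t * d[1]
        dist = np.hypot(xs - px, ys - py)
        weight = np.clip(1.0 - dist, 0.0, 1.0)
        arc_um = (cum_px[i] + t * seg_len_px[i]) * pixel_size
        value = law_of_arc(arc_um) * weight
        region = canvas[y_lo : y_hi + 1, x_lo : x_hi + 1]
        np.maximum(region, value, out=region)


def _apply_noise(clean: np.ndarray, config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    noisy = clean.astype(float)
    if config.poisson_scale > 0:
        noisy = rng.poisson(noisy / config.poisson_scale) * config.poisson_scale
    if config.read_sd > 0:
        noisy = noisy + rng.normal(0.0, config.read_sd, size=noisy.shape)
    return np.clip(np.round(noisy), 0, UINT16_MAX).astype(np.uint16)


def make_scene(config: SceneConfig) -> SyntheticScene:
    """Render a synthetic multi-channel scene with full ground truth.

    Filopodia are straight 1-px-wide segments radiating from a central
    circular cell body; polylines are stored tip-first and end on the cell
    boundary (the base).  Deterministic given ``config.seed``.
    """
    h, w = config.image_size
    lmin, lmax = config.filopodium_length_range
    reach_px = (config.cell_radius + lmax) / config.pixel_size
    if 2 * (reach_px + 2) > min(h, w):
        raise SceneSizeError(
            f"image {config.image_size} cannot contain cell radius "
            f"{config.cell_radius} um plus filopodia up to {lmax} um at "
            f"{config.pixel_size} um/px (needs >= {int(2 * (reach_px + 2)) + 1} px)"
        )
    rng = np.random.default_rng(config.seed)
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    r_px = config.cell_radius / config.pixel_size

    angles = rng.uniform(0.0, 2.0 * np.pi, config.n_filopodia)
    lengths = rng.uniform(lmin, lmax, config.n_filopodia)
    polylines = []
    for ang, length in zip(angles, lengths):
        direction = np.array([np.cos(ang), np.sin(ang)])
        base = center + r_px * direction
        tip = center + (r_px + length / config.pixel_size) * direction
        polylines.append(np.stack([tip, base]))

    yy, xx = np.mgrid[0:h, 0:w]
    body = np.hypot(xx - center[0], yy - center[1]) <= r_px

    positives: dict[str, np.ndarray] = {}
    images: dict[str, np.ndarray] = {}
    for law in config.channel_models:
        if law.spatial_mode == "tip_exponential":
            pos = rng.random(config.n_filopodia) < law.tip_positive_fraction
        else:
            pos = np.ones(config.n_filopodia, dtype=bool)
        positives[law.name] = pos

        clean = np.zeros((h, w))
        if law.spatial_mode in {"uniform", "body_only"}:
            clean[body] = law.amplitude
        if law.spatial_mode != "body_only":
            for k, poly in enumerate(polylines):
                if law.spatial_mode == "tip_exponential":
                    if not pos[k]:
                        continue
                    decay = law.decay_length
                    amp = law.amplitude
                    fn = lambda arc, a=amp, d=decay: a * np.exp(-arc / d)
                else:
                    fn = lambda arc, a=law.amplitude: np.full_like(
                        np.asarray(arc, dtype=float), a
                    )
                _render_polyline(clean, poly, fn, config.pixel_size)
        images[law.name] = _apply_noise(clean, config, rng)

    return SyntheticScene(
        config=config,
        polylines=polylines,
        lengths_um=lengths,
        ground_truth_positive=positives,
        images=images,
    )


def make_gold_particles(
    n: int,
    mode: str,
    filo_length: float,
    seed: int | None = None,
    scale: float = 200.0,
    label: str = "synthetic",
) -> GoldParticleSet:
    """Sample gold-particle distances from a filopodium tip (nm).

    ``mode="tip_exponential"`` draws from an exponential of the given
    ``scale`` truncated to [0, filo_length]; ``mode="uniform"`` draws
    uniformly along the filopodium.
    """
    if n < 0:
        raise ArgumentError("n must be >= 0")
    if filo_length <= 0:
        raise ArgumentError("filo_length must be > 0")
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        d = rng.uniform(0.0, filo_length, n)
    elif mode == "tip_exponential":
        if scale <= 0:
            raise ArgumentError("scale must be > 0")
        u = rng.random(n)
        # inverse CDF of the exponential truncated to [0, L]
        d = -scale * np.log1p(-u * (1.0 - math.exp(-filo_length / scale)))
    else:
        raise ArgumentError(f"unknown mode {mode!r}")
    return GoldParticleSet(label=label, distances=d)


def make_titration(
    a0: float,
    top_l0: float,
    n_points: int,
    dilution_factor: float,
    kd: float,
    f_free: float,
    f_bound: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Titration:
    """Generate a serial-dilution titration obeying the depletion quadratic.

    ``l0`` is a geometric series of ``n_points`` concentrations descending
    from ``top_l0`` by ``dilution_factor``; the signal is the affine
    bound-fraction model plus Gaussian noise of sd ``noise_sd``.
    """
    if a0 <= 0 or top_l0 <= 0 or kd <= 0:
        raise ArgumentError("concentrations and kd must be > 0")
    if dilution_factor <= 1:
        raise ArgumentError("dilution_factor must be > 1")
    if n_points < 4:
        raise ArgumentError("n_points must be >= 4")
    l0 = top_l0 / dilution_factor ** np.arange(n_points)
    signal = make_titration_signal(l0, a0, kd, f_free, f_bound)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return Titration(a0=a0, l0=l0, signal=np.asarray(signal, dtype=float),
                     meta={"kd_true": kd, "f_free": f_free, "f_bound": f_bound})


def make_flow_population(
    n_cells: int,
    stain_params: dict[str, tuple[float, float]],
    seed: int | None = None,
    condition: str = "synthetic",
) -> FlowSample:
    """Log-normal per-cell stain intensities (mu, sigma on the log scale)."""
    if n_cells < 1:
        raise ArgumentError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    cols = {}
    for stain, (mu, sigma) in stain_params.items():
        if sigma < 0:
            raise ArgumentError(f"sigma for {stain!r} must be >= 0")
        cols[stain] = (
            np.full(n_cells, math.exp(mu)) if sigma == 0 else rng.lognormal(mu, sigma, n_cells)
        )
    return FlowSample(condition=condition, intensities=pd.DataFrame(cols))


@dataclass
class SpotFrames:
    """Ground-truth time-lapse spot coordinates.

    ``detections`` has columns (frame, x_um, y_um, spot_id); ``lifetimes``
    holds each spot's true span in frames (possibly extending beyond the
    movie).  Spots alive in frame 0 or the last frame are censored for
    lifetime statistics.
    """

    detections: pd.DataFrame
    lifetimes_frames: np.ndarray
    birth_frames: np.ndarray
    n_frames: int
    interval_s: float
    arena_um: tuple[float, float]

    def uncensored_lifetimes_s(self) -> np.ndarray:
        last = self.birth_frames + self.lifetimes_frames - 1
        keep = (self.birth_frames > 0) & (last < self.n_frames - 1)
        return (self.lifetimes_frames[keep] - 1) * self.interval_s


def make_timelapse(
    n_spots: int,
    mean_lifetime: float,
    interval: float,
    arena: tuple[float, float] = (60.0, 60.0),
    max_step: float = 0.4,
    seed: int | None = None,
    n_frames: int = 120,
) -> SpotFrames:
    """Simulate blinking spots with exponential lifetimes in a 2D arena.

    Lifetimes are Exp(mean_lifetime) in seconds, discretized by rounding up
    to at least one frame of ``interval`` seconds.  Spots appear at uniform
    random birth frames and positions and take uniformly-oriented steps of
    length <= ``max_step`` um per frame, reflected at the arena boundary.
    """
    if interval <= 0:
        raise ArgumentError("interval must be > 0")
    if n_spots < 0 or mean_lifetime <= 0 or n_frames < 2:
        raise ArgumentError("need n_spots >= 0, mean_lifetime > 0, n_frames >= 2")
    rng = np.random.default_rng(seed)
    w, h = arena
    life_s = rng.exponential(mean_lifetime, n_spots)
    life_frames = np.maximum(1, np.ceil(life_s / interval)).astype(int)
    births = rng.integers(0, n_frames, n_spots)
    rows = []
    for sid in range(n_spots):
        x, y = rng.uniform(0, w), rng.uniform(0, h)
        for k in range(life_frames[sid]):
            f = births[sid] + k
            if f >= n_frames:
                break
            rows.append({"frame": int(f), "x_um": x, "y_um": y, "spot_id": sid})
            ang = rng.uniform(0, 2 * np.pi)
            step = rng.uniform(0, max_step)
            x = min(max(x + step * np.cos(ang), 0.0), w)
            y = min(max(y + step * np.sin(ang), 0.0), h)
    det = pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "spot_id"])
    return SpotFrames(
        detections=det,
        lifetimes_frames=life_frames,
        birth_frames=births,
        n_frames=n_frames,
        interval_s=interval,
        arena_um=arena,
    )


def paper_like_config(seed: int = 0, **overrides) -> SceneConfig:
    """The default four-channel, 30-filopodium fixture configuration."""
    return replace(SceneConfig(seed=seed), **overrides)
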