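"""Synthetic microscopy generators with exact ground truth.

Three generators mirror the three imaging assays handled by the package:

* :func:`simulate_optic_nerve` — a 2D projection of a cleared nerve with
  curvilinear labelled fibers whose survival past a crush site is
  exponentially distributed;
* :func:`simulate_explant` — a saturated central tissue disk with neurites
  radiating outward, lengths drawn from a configurable distribution;
* :func:`simulate_organelle_movie` — a time-lapse of punctate organelles
  moving along a straight axon under a two-state (moving/paused) Markov
  chain with fixed per-organelle direction.

Every generator is deterministic given its config (which embeds the seed)
and returns a :class:`SyntheticGroundTruth` describing exactly what was
rendered, so downstream quantification can be validated without any
external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError

__all__ = [
    "NerveSimConfig",
    "ExplantSimConfig",
    "TrackSimConfig",
    "LengthDistribution",
    "SyntheticGroundTruth",
    "simulate_optic_nerve",
    "simulate_explant",
    "simulate_organelle_movie",
    "preset",
    "PRESET_NAMES",
]


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class NerveSimConfig:
    """Parameters for a synthetic cleared-nerve projection.

    The nerve runs along the image x axis, centred vertically. Fibers start
    at the left edge and each extends past ``injury_x_um`` by an
    exponentially distributed length with mean ``decay_length_um``.
    """

    image_height_px: int = 128
    image_width_px: int = 512
    pixel_size_um: float = 5.0
    injury_x_um: float = 400.0
    n_fibers: int = 50
    decay_length_um: float = 500.0
    fiber_intensity: float = 100.0
    fiber_sigma_um: float = 6.0
    nerve_width_profile: Sequence[float] = (120.0,)
    background_level: float = 5.0
    noise_sd: float = 1.0
    nerve_fill_intensity: float = 25.0
    tortuosity: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ConfigurationError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")
        if self.decay_length_um <= 0:
            raise ConfigurationError("decay_length_um must be positive")
        if self.n_fibers < 0:
            raise ConfigurationError("n_fibers must be >= 0")
        if len(self.nerve_width_profile) == 0 or any(
            w <= 0 for w in self.nerve_width_profile
        ):
            raise ConfigurationError("nerve_width_profile values must all be > 0")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ConfigurationError("background/noise must be nonnegative")
        if self.fiber_sigma_um <= 0 or self.fiber_intensity <= 0:
            raise ConfigurationError("fiber rendering parameters must be positive")


@dataclass(frozen=True)
class LengthDistribution:
    """Named length distribution with truncation.

    Supported names: ``constant`` (params: value), ``uniform`` (low, high),
    ``lognormal`` (mu, sigma — parameters of the underlying normal, μm).
    Samples above ``max_length_um`` are clipped to it.
    """

    name: str = "lognormal"
    params: dict = field(default_factory=lambda: {"mu": 5.5, "sigma": 0.7})
    max_length_um: float = 8000.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.name == "constant":
            lengths = np.full(n, float(self.params["value"]))
        elif self.name == "uniform":
            lengths = rng.uniform(self.params["low"], self.params["high"], n)
        elif self.name == "lognormal":
            lengths = rng.lognormal(self.params["mu"], self.params["sigma"], n)
        else:
            raise ConfigurationError(f"unknown length distribution {self.name!r}")
        return np.minimum(lengths, self.max_length_um)


@dataclass(frozen=True)
class ExplantSimConfig:
    """Parameters for a synthetic explant outgrowth image.

    The explant is a disk of radius ``explant_radius_um`` (default 250 μm,
    i.e. a ~500 μm piece of tissue) rendered at saturating intensity;
    ``n_axons`` neurites emanate radially from its border.
    """

    explant_radius_um: float = 250.0
    n_axons: int = 20
    axon_length_um_distribution: LengthDistribution = field(
        default_factory=LengthDistribution
    )
    tortuosity: float = 0.0
    pixel_size_um: float = 2.0
    noise_sd: float = 0.0
    margin_um: float = 50.0
    image_size_px: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.explant_radius_um <= 0:
            raise ConfigurationError("explant_radius_um must be positive")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")
        if self.n_axons < 0:
            raise ConfigurationError("n_axons must be >= 0")
        if self.tortuosity < 0 or self.noise_sd < 0:
            raise ConfigurationError("tortuosity/noise must be nonnegative")


@dataclass(frozen=True)
class TrackSimConfig:
    """Parameters for a synthetic organelle transport movie.

    The axon is a straight horizontal segment of length ``axon_length_um``;
    anterograde is the +x direction. Each organelle is either permanently
    stationary or a "mover" with a fixed direction; movers alternate
    between moving and paused states with per-frame transition
    probabilities. An organelle reaching either end of the field stops
    there for the remainder of the movie.
    """

    n_organelles: int = 15
    frac_moving: float = 0.9
    frac_anterograde_among_moving: float = 0.5
    speed_antero_um_s: float = 0.3
    speed_retro_um_s: float = 0.6
    pause_prob_per_frame: float = 0.1
    resume_prob_per_frame: float = 0.1
    frame_interval_s: float = 1.0
    n_frames: int = 300
    axon_length_um: float = 120.0
    punctum_sigma_um: float = 0.3
    pixel_size_um: float = 0.2
    image_height_px: int = 9
    punctum_intensity: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_moving",
            "frac_anterograde_among_moving",
            "pause_prob_per_frame",
            "resume_prob_per_frame",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.frame_interval_s <= 0:
            raise ConfigurationError("frame_interval_s must be positive")
        if self.n_frames < 1 or self.n_organelles < 0:
            raise ConfigurationError("n_frames >= 1 and n_organelles >= 0 required")
        if self.axon_length_um <= 0 or self.pixel_size_um <= 0:
            raise ConfigurationError("axon_length_um and pixel_size_um must be > 0")
        if self.speed_antero_um_s < 0 or self.speed_retro_um_s < 0:
            raise ConfigurationError("speeds must be nonnegative")
        if self.punctum_sigma_um <= 0:
            raise ConfigurationError("punctum_sigma_um must be positive")


@dataclass
class SyntheticGroundTruth:
    """Generator-side truth paired with a synthetic image or movie.

    ``kind`` is one of ``nerve`` / ``explant`` / ``movie``; ``data`` holds
    kind-specific arrays (documented per generator).
    """

    kind: str
    data: dict

    # -- nerve -------------------------------------------------------------
    def fiber_count_at(self, distance_um: float) -> int:
        """Number of fibers still present ``distance_um`` past the injury."""
        if self.kind != "nerve":
            raise ValueError("fiber_count_at is only defined for nerve truth")
        ends = self.data["fiber_end_x_um"]
        return int(np.sum(ends >= self.data["injury_x_um"] + distance_um))

    # -- explant -----------------------------------------------------------
    def band_crossings(self, step_um: float = 50.0, n_bands: int | None = None):
        """Per-band axon crossing counts at ``k*step_um`` from the border."""
        if self.kind != "explant":
            raise ValueError("band_crossings is only defined for explant truth")
        extents = self.data["axon_max_border_distance_um"]
        if n_bands is None:
            n_bands = int(math.floor(max(extents, default=0.0) / step_um))
        radii = step_um * np.arange(1, n_bands + 1)
        # epsilon guards float round-off when an axon tip lands exactly
        # on a band radius
        eps = 1e-9 * max(step_um, 1.0)
        return radii, np.array([int(np.sum(extents >= r - eps)) for r in radii])

    # -- movie -------------------------------------------------------------
    def moving_fraction(self, v_min_um_s: float = 0.02) -> float:
        """Fraction of organelles whose net speed is at least ``v_min_um_s``."""
        if self.kind != "movie":
            raise ValueError("moving_fraction is only defined for movie truth")
        pos = self.data["positions_um"]
        duration = (pos.shape[1] - 1) * self.data["frame_interval_s"]
        if duration <= 0:
            return 0.0
        net = np.abs(pos[:, -1] - pos[:, 0]) / duration
        return float(np.mean(net >= v_min_um_s))


# ---------------------------------------------------------------------------
# nerve


def _half_width_at(profile: np.ndarray, x_frac: float) -> float:
    """Linear interpolation of the half-width profile over [0, 1]."""
    if profile.size == 1:
        return float(profile[0])
    knots = np.linspace(0.0, 1.0, profile.size)
    return float(np.interp(x_frac, knots, profile))


def _splat_polyline(canvas: np.ndarray, xs: np.ndarray, ys: np.ndarray, w: float):
    """Accumulate weight ``w`` per vertex onto the canvas bilinearly."""
    h, wd = canvas.shape
    x0 = np.floor(xs).astype(int)
    y0 = np.floor(ys).astype(int)
    fx = xs - x0
    fy = ys - y0
    for dy in (0, 1):
        for dx in (0, 1):
            wx = fx if dx else 1.0 - fx
            wy = fy if dy else 1.0 - fy
            xi = x0 + dx
            yi = y0 + dy
            ok = (xi >= 0) & (xi < wd) & (yi >= 0) & (yi < h)
            np.add.at(canvas, (yi[ok], xi[ok]), w * (wx * wy)[ok])


def simulate_optic_nerve(config: NerveSimConfig):
    """Render a synthetic nerve projection and its ground truth.

    Returns ``(image, truth)`` where ``image`` is float64 of shape
    ``(image_height_px, image_width_px)`` and ``truth.data`` holds
    ``fiber_end_x_um``, ``fiber_paths_px`` (list of (y, x) arrays),
    ``injury_x_um`` and ``half_width_um(x)`` samples per column.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height_px, config.image_width_px
    px = config.pixel_size_um
    width_um = w * px
    profile = np.asarray(config.nerve_width_profile, dtype=float)

    cy = (h - 1) / 2.0  # nerve centreline row
    canvas = np.zeros((h, w), dtype=float)

    # exponential survival past the crush; drawn up-front so truth counts
    # are exact regardless of rendering clipping
    survival = rng.exponential(config.decay_length_um, size=config.n_fibers)
    end_x_um = config.injury_x_um + survival

    col_halfwidth_um = np.array(
        [_half_width_at(profile, c / max(w - 1, 1)) for c in range(w)]
    )

    paths = []
    step_um = px  # advance one pixel per step
    for i in range(config.n_fibers):
        n_steps = int(min(end_x_um[i], width_um - px) / step_um)
        xs_um = np.arange(max(n_steps, 1)) * step_um
        h0 = _half_width_at(profile, 0.0)
        y_um = rng.uniform(-0.9 * h0, 0.9 * h0)
        heading = 0.0
        ys_um = np.empty(xs_um.size)
        for k, xu in enumerate(xs_um):
            hw = _half_width_at(profile, xu / width_um)
            y_um = float(np.clip(y_um, -0.9 * hw, 0.9 * hw))
            ys_um[k] = y_um
            heading = 0.9 * heading + rng.normal(0.0, config.tortuosity)
            y_um += heading * step_um
        xs_px = xs_um / px
        ys_px = cy + ys_um / px
        paths.append(np.column_stack([ys_px, xs_px]))
        _splat_polyline(canvas, xs_px, ys_px, config.fiber_intensity)

    sigma_px = config.fiber_sigma_um / px
    image = gaussian_filter(canvas, sigma_px)

    # nerve "autofluorescence" fill makes the tissue segmentable, as in
    # real cleared-nerve acquisitions
    if config.nerve_fill_intensity > 0:
        rows = np.arange(h)[:, None]
        fill_mask = np.abs(rows - cy) * px <= col_halfwidth_um[None, :]
        image = image + config.nerve_fill_intensity * fill_mask

    image = image + config.background_level
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)
    np.clip(image, 0.0, None, out=image)

    truth = SyntheticGroundTruth(
        kind="nerve",
        data={
            "fiber_end_x_um": end_x_um,
            "fiber_paths_px": paths,
            "injury_x_um": config.injury_x_um,
            "half_width_um_per_col": col_halfwidth_um,
            "pixel_size_um": px,
        },
    )
    return image, truth


# ---------------------------------------------------------------------------
# explant


def simulate_explant(config: ExplantSimConfig):
    """Render a synthetic explant image and its ground truth.

    ``truth.data`` holds ``axon_length_um`` (arc lengths),
    ``axon_max_border_distance_um`` (radial extent from the disk border,
    which determines band crossings), ``axon_paths_px`` and the disk
    geometry (``center_px``, ``radius_px``).
    """
    rng = np.random.default_rng(config.seed)
    px = config.pixel_size_um
    dist = config.axon_length_um_distribution
    lengths = dist.sample(rng, config.n_axons)

    if config.image_size_px is not None:
        size = int(config.image_size_px)
    else:
        # size the canvas from the realized lengths, not the truncation
        # bound, so heavy-tailed length distributions stay affordable
        longest = float(lengths.max()) if lengths.size else 0.0
        extent_um = config.explant_radius_um + longest + config.margin_um
        size = int(math.ceil(2 * extent_um / px))
    c = (size - 1) / 2.0
    r_px = config.explant_radius_um / px

    canvas = np.zeros((size, size), dtype=float)
    paths = []
    max_border_dist = np.zeros(config.n_axons)
    step_um = px
    for i in range(config.n_axons):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        heading = theta
        x_um = config.explant_radius_um * math.cos(theta)
        y_um = config.explant_radius_um * math.sin(theta)
        # arc-length stations include the exact endpoint so the rendered and
        # recorded length equals the drawn length
        stations = np.append(np.arange(0.0, lengths[i], step_um), lengths[i])
        xs = np.empty(stations.size)
        ys = np.empty(stations.size)
        for k, s in enumerate(stations):
            xs[k] = x_um
            ys[k] = y_um
            if k == stations.size - 1:
                break
            ds = stations[k + 1] - s
            heading += rng.normal(0.0, config.tortuosity * ds)
            x_um += ds * math.cos(heading)
            y_um += ds * math.sin(heading)
        radial = np.hypot(xs, ys) - config.explant_radius_um
        max_border_dist[i] = max(float(radial.max()), 0.0)
        xs_px = c + xs / px
        ys_px = c + ys / px
        inb = (xs_px >= 0) & (xs_px < size) & (ys_px >= 0) & (ys_px < size)
        paths.append(np.column_stack([ys_px[inb], xs_px[inb]]))
        _splat_polyline(canvas, xs_px, ys_px, 1.0)

    image = gaussian_filter(canvas, 1.0)
    peak = image.max() if image.max() > 0 else 1.0
    image = image / peak  # axons ~1.0

    yy, xx = np.mgrid[0:size, 0:size]
    disk = (xx - c) ** 2 + (yy - c) ** 2 <= r_px**2
    image[disk] = 4.0  # saturating tissue disk

    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)
        np.clip(image, 0.0, None, out=image)

    truth = SyntheticGroundTruth(
        kind="explant",
        data={
            "axon_length_um": lengths,
            "axon_max_border_distance_um": max_border_dist,
            "axon_paths_px": paths,
            "center_px": (c, c),
            "radius_px": r_px,
            "pixel_size_um": px,
        },
    )
    return image, truth


# ---------------------------------------------------------------------------
# organelle movie


def simulate_organelle_movie(config: TrackSimConfig):
    """Render a transport movie and its frame-by-frame ground truth.

    ``truth.data`` holds ``positions_um`` (n_organelles × n_frames),
    ``interval_moving`` (boolean, n_organelles × n_frames-1: chain state
    during each inter-frame interval), ``direction`` (+1 anterograde /
    −1 retrograde / 0 stationary), ``speed_um_s`` and ``is_mover``.

    Mover/direction assignment uses exact rounded counts (not Bernoulli
    draws) so the realized composition matches the config fractions.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_organelles
    nf = config.n_frames
    dt = config.frame_interval_s
    L = config.axon_length_um

    n_moving = int(round(config.frac_moving * n))
    n_antero = int(round(config.frac_anterograde_among_moving * n_moving))
    order = rng.permutation(n)
    is_mover = np.zeros(n, dtype=bool)
    is_mover[order[:n_moving]] = True
    direction = np.zeros(n, dtype=int)
    mover_ids = order[:n_moving]
    direction[mover_ids[:n_antero]] = 1
    direction[mover_ids[n_antero:]] = -1
    speed = np.where(
        direction > 0,
        config.speed_antero_um_s,
        np.where(direction < 0, config.speed_retro_um_s, 0.0),
    )

    positions = np.empty((n, nf))
    positions[:, 0] = rng.uniform(0.0, L, size=n)
    interval_moving = np.zeros((n, max(nf - 1, 0)), dtype=bool)

    pp, pr = config.pause_prob_per_frame, config.resume_prob_per_frame
    # start movers in the chain's stationary distribution
    p_paused0 = pp / (pp + pr) if (pp + pr) > 0 else 0.0
    paused = rng.random(n) < p_paused0
    stuck = np.zeros(n, dtype=bool)  # absorbed at a field boundary

    for t in range(nf - 1):
        u = rng.random(n)
        # chain update per organelle (stationary organelles stay paused)
        newly_paused = np.where(paused, u >= pr, u < pp)
        paused = np.where(is_mover & ~stuck, newly_paused, True)
        moving_now = is_mover & ~paused & ~stuck
        interval_moving[:, t] = moving_now
        step = np.where(moving_now, direction * speed * dt, 0.0)
        nxt = positions[:, t] + step
        hit = (nxt <= 0.0) | (nxt >= L)
        nxt = np.clip(nxt, 0.0, L)
        stuck = stuck | (hit & moving_now)
        positions[:, t + 1] = nxt

    movie = _render_movie(config, positions)

    truth = SyntheticGroundTruth(
        kind="movie",
        data={
            "positions_um": positions,
            "interval_moving": interval_moving,
            "direction": direction,
            "speed_um_s": speed,
            "is_mover": is_mover,
            "frame_interval_s": dt,
            "pixel_size_um": config.pixel_size_um,
            "axon_length_um": L,
        },
    )
    return movie, truth


def _render_movie(config: TrackSimConfig, positions_um: np.ndarray) -> np.ndarray:
    px = config.pixel_size_um
    n, nf = positions_um.shape
    width_px = int(math.ceil(config.axon_length_um / px)) + 1
    h = config.image_height_px
    cy = (h - 1) / 2.0
    sig = config.punctum_sigma_um / px
    half = max(int(math.ceil(4 * sig)), 1)

    rng = np.random.default_rng(config.seed + 1)  # noise stream separate
    movie = np.zeros((nf, h, width_px), dtype=float)
    rows = np.arange(h)
    row_g = np.exp(-0.5 * ((rows - cy) / sig) ** 2)
    for t in range(nf):
        frame = movie[t]
        for i in range(n):
            xc = positions_um[i, t] / px
            x0 = max(int(math.floor(xc)) - half, 0)
            x1 = min(int(math.ceil(xc)) + half + 1, width_px)
            if x1 <= x0:
                continue
            cols = np.arange(x0, x1)
            col_g = np.exp(-0.5 * ((cols - xc) / sig) ** 2)
            frame[:, x0:x1] += config.punctum_intensity * row_g[:, None] * col_g[None, :]
        if config.noise_sd > 0:
            frame += rng.normal(0.0, config.noise_sd, size=frame.shape)
    np.clip(movie, 0.0, None, out=movie)
    return movie


# ---------------------------------------------------------------------------
# presets


def _make_presets() -> dict:
    return {
        # intact axons: most lysosomes motile, retrograde-dominated, ~50%
        # of time paused while motile
        "intact_lysosome": TrackSimConfig(
            frac_moving=0.90,
            frac_anterograde_among_moving=0.4,
            speed_antero_um_s=0.3,
            speed_retro_um_s=0.6,
            pause_prob_per_frame=0.1,
            resume_prob_per_frame=0.1,
        ),
        # after axotomy: most lysosomes arrest; residual movers crawl
        "postcut_lysosome": TrackSimConfig(
            frac_moving=0.30,
            frac_anterograde_among_moving=0.5,
            speed_antero_um_s=0.05,
            speed_retro_um_s=0.05,
            pause_prob_per_frame=0.05,
            resume_prob_per_frame=0.2,
        ),
        # mature intact axons: mitochondria overwhelmingly stationary
        "intact_mito": TrackSimConfig(
            frac_moving=0.10,
            frac_anterograde_among_moving=0.5,
            speed_antero_um_s=0.15,
            speed_retro_um_s=0.15,
            pause_prob_per_frame=0.1,
            resume_prob_per_frame=0.1,
        ),
    }


PRESET_NAMES = tuple(sorted(_make_presets()))


def preset(name: str, **overrides) -> TrackSimConfig:
    """Return a named transport regime config, optionally overridden.

    Known names: ``intact_lysosome``, ``postcut_lysosome``, ``intact_mito``.
    """
    presets = _make_presets()
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(presets)}"
        )
    base = presets[name]
    if overrides:
        from dataclasses import replace

        return replace(base, **overrides)
    return base
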