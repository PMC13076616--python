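"""Parametric visual stimuli rendered as space-time intensity fields.

All stimuli are sampled on a regular pixel grid covering a rectangular
arena.  Units follow the conventions used throughout the package:
lengths in micrometres (µm), times in milliseconds (ms) and speeds in
mm/s, which conveniently equals µm/ms so no conversion factors appear
in the kinematics.

Intensity is dimensionless in [0, 1]: the background is 0 (or 0.5 for
gratings, which ride on a gray background) and full contrast is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Arena",
    "Stimulus",
    "make_moving_bar",
    "make_drifting_grating",
    "make_1d_bar_noise",
    "make_variable_velocity_bar",
    "make_full_field_flash",
    "default_directions",
    "save_stimulus",
    "load_stimulus",
]

#: The five bar speeds (mm/s) used in the standard tuning protocol.
DEFAULT_SPEEDS = (0.25, 0.5, 1.0, 2.0, 4.0)

#: Spatial periods (µm/cycle) of the standard drifting-grating protocol.
DEFAULT_GRATING_PERIODS = (100.0, 200.0, 400.0, 800.0, 1600.0)


def default_directions(n: int = 12) -> np.ndarray:
    """Equally spaced motion directions ``k * 2*pi/n`` in radians."""
    return np.arange(n) * (2.0 * np.pi / n)


@dataclass(frozen=True)
class Arena:
    """Square (by default) stimulation arena and sampling parameters.

    Parameters
    ----------
    width, height:
        Arena extent in µm.  The default is an 800 µm-wide square.
    pixel_size:
        Grid spacing in µm.  5 µm keeps the narrowest admissible
        receptive-field component (10 µm half-width scale) sampled by
        several pixels, which the overlap-convergence tests rely on.
    dt:
        Stimulus sampling interval in ms.
    duration:
        Optional default presentation length in ms; stimulus builders
        that can derive a natural duration (e.g. a bar traversal) use
        it only as an override.
    """

    width: float = 800.0
    height: float = 800.0
    pixel_size: float = 5.0
    dt: float = 5.0
    duration: Optional[float] = None

    def __post_init__(self):
        for name in ("width", "height", "pixel_size", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Arena.{name} must be strictly positive")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("Arena.duration must be strictly positive")

    @property
    def nx(self) -> int:
        return int(round(self.width / self.pixel_size))

    @property
    def ny(self) -> int:
        return int(round(self.height / self.pixel_size))

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates ``(x, y)``, origin at the arena centre."""
        return _cached_grid(self.width, self.height, self.pixel_size)


from functools import lru_cache


@lru_cache(maxsize=16)
def _cached_grid(width: float, height: float, pixel_size: float):
    nx = int(round(width / pixel_size))
    ny = int(round(height / pixel_size))
    x = (np.arange(nx) + 0.5) * pixel_size - width / 2.0
    y = (np.arange(ny) + 0.5) * pixel_size - height / 2.0
    return np.meshgrid(x, y)


@dataclass
class Stimulus:
    """A space-time intensity field with kinematic metadata.

    ``frames`` has shape ``(n_frames, ny, nx)`` with every value in
    [0, 1].  ``direction`` is the motion direction in radians and
    ``speed`` the nominal speed in mm/s (µm/ms); both are NaN-free only
    where meaningful for the stimulus kind.
    """

    frames: np.ndarray
    kind: str
    arena: Arena
    direction: float = 0.0
    speed: float = 0.0
    seed: Optional[int] = None
    background: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (t, y, x) array")
        if self.frames.shape[1:] != (self.arena.ny, self.arena.nx):
            raise ValueError("frames do not match the arena grid")
        lo, hi = float(self.frames.min(initial=0.0)), float(self.frames.max(initial=0.0))
        if lo < -1e-6 or hi > 1.0 + 1e-6:
            raise ValueError(f"intensity out of [0, 1]: [{lo}, {hi}]")

    @property
    def dt(self) -> float:
        return self.arena.dt

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


def _motion_axis(arena: Arena, direction: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Coordinates along/perpendicular to motion and the projected half-extent."""
    x, y = arena.grid()
    c, s = np.cos(direction), np.sin(direction)
    # snap near-cardinal directions so boundary pixels don't flip on
    # floating-point residue (cos(pi) = -1 but sin(pi) = 1.2e-16)
    c = 0.0 if abs(c) < 1e-9 else (np.sign(c) if abs(abs(c) - 1) < 1e-9 else c)
    s = 0.0 if abs(s) < 1e-9 else (np.sign(s) if abs(abs(s) - 1) < 1e-9 else s)
    along = x * c + y * s
    perp = -x * s + y * c
    extent = (abs(c) * arena.width + abs(s) * arena.height) / 2.0
    return along, perp, extent


def make_moving_bar(
    arena: Arena,
    speed: float,
    direction: float,
    bar_height: float = 1000.0,
    bar_time_width: float = 200.0,
    bar_width: Optional[float] = None,
    duration: Optional[float] = None,
) -> Stimulus:
    """A bright bar translating across the full arena at constant speed.

    The bar is perpendicular to the motion direction, ``bar_height`` µm
    tall (1 mm by default, clipped to the arena) and, by default,
    ``speed * bar_time_width`` wide along the motion axis so that any
    fixed point stays covered for exactly ``bar_time_width`` (0.2 s)
    regardless of speed.  ``bar_width`` (µm) overrides the
    speed-invariant-dwell construction with a fixed spatial width.
    """
    if speed <= 0:
        raise ValueError("speed must be strictly positive")
    if bar_height <= 0 or bar_time_width <= 0:
        raise ValueError("bar dimensions must be strictly positive")
    width_along = speed * bar_time_width if bar_width is None else float(bar_width)
    if width_along <= 0:
        raise ValueError("bar width must be strictly positive")

    along, perp, extent = _motion_axis(arena, direction)
    pad = 2.0 * arena.pixel_size
    start = -extent - pad  # leading-edge position at t = 0
    natural = (2.0 * extent + width_along + 2.0 * pad) / speed
    total = duration if duration is not None else (arena.duration or natural)
    n_frames = int(np.ceil(total / arena.dt))

    in_height = np.abs(perp) <= bar_height / 2.0
    t = np.arange(n_frames) * arena.dt
    edges = start + speed * t
    e3 = edges[:, None, None]
    frames = ((along[None] > e3 - width_along) & (along[None] <= e3)
              & in_height[None]).astype(np.float32)
    return Stimulus(
        frames,
        "bar",
        arena,
        direction=direction,
        speed=speed,
        meta={
            "bar_height": bar_height,
            "bar_time_width": bar_time_width,
            "bar_width": width_along,
            "leading_edge_start": start,
        },
    )


def make_drifting_grating(
    arena: Arena,
    spatial_period: float,
    speed: float = 1.0,
    direction: float = 0.0,
    duration: Optional[float] = None,
) -> Stimulus:
    """Full-contrast sinusoidal grating on a gray (0.5) background.

    Drifts along ``direction`` with temporal frequency
    ``speed / spatial_period`` (cycles/ms with speed in µm/ms).
    """
    if spatial_period <= 0:
        raise ValueError("spatial_period must be strictly positive")
    if speed <= 0:
        raise ValueError("speed must be strictly positive")
    along, _, _ = _motion_axis(arena, direction)
    total = duration if duration is not None else (arena.duration or 3000.0)
    n_frames = int(np.ceil(total / arena.dt))
    t = np.arange(n_frames) * arena.dt
    phase = 2.0 * np.pi * (along[None, :, :] - speed * t[:, None, None]) / spatial_period
    frames = 0.5 * (1.0 + np.cos(phase))
    return Stimulus(
        frames,
        "grating",
        arena,
        direction=direction,
        speed=speed,
        background=0.5,
        meta={"spatial_period": spatial_period},
    )


def make_1d_bar_noise(
    arena: Arena,
    bar_width: float = 20.0,
    update_interval: float = 50.0,
    seed: int = 0,
    duration: Optional[float] = None,
    direction: float = 0.0,
) -> Stimulus:
    """Binary 1-D contrast noise: full-height bars flickering 0/1.

    The arena is tiled with ``bar_width``-µm bars perpendicular to
    ``direction`` (vertical for the default direction 0).  Each bar
    independently takes contrast 0 or 1 with probability 1/2, redrawn
    every ``update_interval`` ms (valid range 20–200 ms).
    """
    if not (20.0 <= update_interval <= 200.0):
        raise ValueError("update_interval must lie in [20, 200] ms")
    n_bars = int(round(arena.width / bar_width))
    if abs(n_bars * bar_width - arena.width) > arena.pixel_size:
        raise ValueError("bar_width must divide the arena width within one pixel")
    along, _, _ = _motion_axis(arena, direction)
    total = duration if duration is not None else (arena.duration or 3000.0)
    n_frames = int(np.ceil(total / arena.dt))
    n_epochs = int(np.ceil(n_frames * arena.dt / update_interval))

    rng = np.random.default_rng(seed)
    values = rng.integers(0, 2, size=(n_epochs, n_bars)).astype(np.float32)
    # map each pixel to its bar index along the motion axis
    bar_idx = np.clip(((along + arena.width / 2.0) // bar_width).astype(int), 0, n_bars - 1)
    epoch_of_frame = (np.arange(n_frames) * arena.dt / update_interval).astype(int)
    frames = values[epoch_of_frame][:, bar_idx.ravel()].reshape(n_frames, arena.ny, arena.nx)
    return Stimulus(
        frames,
        "bar_noise",
        arena,
        direction=direction,
        seed=seed,
        meta={
            "bar_width": bar_width,
            "update_interval": update_interval,
            "n_bars": n_bars,
            "bar_index": bar_idx[0].copy() if direction == 0.0 else bar_idx,
            "epoch_values": values,
            "epoch_of_frame": epoch_of_frame,
        },
    )


def make_variable_velocity_bar(
    arena: Arena,
    direction: float,
    noise_sd: float,
    seed: int = 0,
    base_speed: float = 1.0,
    update_interval: float = 50.0,
    bar_height: float = 1000.0,
    bar_time_width: float = 200.0,
    max_duration: Optional[float] = None,
) -> Stimulus:
    """A moving bar whose speed is resampled every ``update_interval`` ms.

    Each new speed is drawn from the positive half of a normal
    distribution ``|N(base_speed, noise_sd)|`` (noise_sd up to 5 mm/s),
    so the bar always advances and never reverses.  ``noise_sd = 0``
    degenerates to :func:`make_moving_bar` at ``base_speed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 5.0:
        raise ValueError("noise_sd above 5 mm/s is outside the protocol range")
    if base_speed <= 0:
        raise ValueError("base_speed must be strictly positive")

    along, perp, extent = _motion_axis(arena, direction)
    width_along = base_speed * bar_time_width
    pad = 2.0 * arena.pixel_size
    start = -extent - pad
    end = extent + width_along + pad
    cap = max_duration if max_duration is not None else 8.0 * (end - start) / base_speed

    rng = np.random.default_rng(seed)
    # piecewise-constant speed, integrated to a position per frame
    positions = [start]
    speeds = []
    pos, t = start, 0.0
    speed_now = abs(rng.normal(base_speed, noise_sd)) if noise_sd > 0 else base_speed
    speeds.append(speed_now)
    next_update = update_interval
    while pos < end and t < cap:
        t += arena.dt
        if t >= next_update - 1e-9:
            speed_now = abs(rng.normal(base_speed, noise_sd)) if noise_sd > 0 else base_speed
            speeds.append(speed_now)
            next_update += update_interval
        pos += speed_now * arena.dt
        positions.append(pos)
    edges = np.asarray(positions)

    in_height = np.abs(perp) <= bar_height / 2.0
    e3 = edges[:, None, None]
    frames = ((along[None] > e3 - width_along) & (along[None] <= e3)
              & in_height[None]).astype(np.float32)
    return Stimulus(
        frames,
        "variable_velocity_bar",
        arena,
        direction=direction,
        speed=base_speed,
        seed=seed,
        meta={
            "noise_sd": noise_sd,
            "update_interval": update_interval,
            "bar_width": width_along,
            "speeds": np.asarray(speeds),
            "edges": edges,
            "traversal_time": len(edges) * arena.dt,
        },
    )


def make_full_field_flash(
    arena: Arena,
    onset: float,
    offset: float,
    duration: Optional[float] = None,
) -> Stimulus:
    """Uniform intensity 1 over the whole arena during [onset, offset)."""
    total = duration if duration is not None else (arena.duration or offset + 200.0)
    if not (0 <= onset < offset <= total):
        raise ValueError("require 0 <= onset < offset <= duration")
    n_frames = int(np.ceil(total / arena.dt))
    t = np.arange(n_frames) * arena.dt
    on = (t >= onset) & (t < offset)
    frames = np.zeros((n_frames, arena.ny, arena.nx), dtype=np.float32)
    frames[on] = 1.0
    return Stimulus(frames, "flash", arena, meta={"onset": onset, "offset": offset})


# ---------------------------------------------------------------------------
# HDF5 serialization


def save_stimulus(stimulus: Stimulus, path) -> None:
    """Write a stimulus to HDF5 (frames dataset plus metadata attributes)."""
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("frames", data=stimulus.frames, compression="gzip")
        d.attrs["kind"] = stimulus.kind
        d.attrs["direction"] = stimulus.direction
        d.attrs["speed"] = stimulus.speed
        d.attrs["background"] = stimulus.background
        d.attrs["seed"] = -1 if stimulus.seed is None else stimulus.seed
        for name in ("width", "height", "pixel_size", "dt"):
            d.attrs[name] = getattr(stimulus.arena, name)


def load_stimulus(path) -> Stimulus:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["frames"]
        arena = Arena(
            width=float(d.attrs["width"]),
            height=float(d.attrs["height"]),
            pixel_size=float(d.attrs["pixel_size"]),
            dt=float(d.attrs["dt"]),
        )
        seed = int(d.attrs["seed"])
        return Stimulus(
            d[...],
            str(d.attrs["kind"]),
            arena,
            direction=float(d.attrs["direction"]),
            speed=float(d.attrs["speed"]),
            seed=None if seed < 0 else seed,
            background=float(d.attrs["background"]),
        )
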