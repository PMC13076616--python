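"""Presynaptic receptive fields: from stimulus frames to synaptic release.

Each presynaptic cell filters the stimulus through one or two 2-D
Gaussian receptive-field components (a center and an optional,
spatially aligned, antagonistic surround).  The per-frame overlap of a
component with the stimulus,

    area_t = sum_xy stimulus_xyt * exp(-(x_th*sqrt(ln2)/size_x)^2
                                       -(y_th*sqrt(ln2)/size_y)^2),

normalized by the component's full Gaussian sum so that full-field
illumination gives area_t = 1, drives a first-order activation with a
depletable readily-releasable-pool (RRP) "adaptation" state:

    RF_t         = (area_t - RF_{t-1}) * dt/rise + RF_{t-1} * adapt_{t-1}
    adapt_t      = max(0, adapt_{t-1} - RF_t * dt/decay)

Center and surround activations are then combined, scaled and
rectified,

    RF_full,t = w_syn * max(0, RF_center,t - w_surround * RF_surround,t),

and finally passed through optional short-term depression (a
multiplicative release factor depleted by activity, recovering toward
1) and facilitation (an exponent in [0, 1] that multiplies release by
up to a factor of ten, 10**syn_fac).

Note on the size parameter: the Gaussian above falls to half its peak
at a distance of exactly ``size`` from the centre, i.e. ``size`` is a
half-width-at-half-maximum scale (full width 2*size).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lfilter

from .stimuli import Arena, Stimulus

__all__ = [
    "RFComponent",
    "PlasticityParams",
    "PresynapticCell",
    "ConductanceTrace",
    "gaussian_weights",
    "rf_overlap_area",
    "rf_temporal_response",
    "integrate_center_surround",
    "apply_depression",
    "apply_facilitation",
    "presynaptic_spike_train",
    "population_release",
    "random_population",
    "assign_groups",
]

_SQRT_LN2 = np.sqrt(np.log(2.0))


@dataclass
class RFComponent:
    """One Gaussian spatiotemporal receptive-field component.

    ``size_x``/``size_y`` are the half-width-at-half-maximum scales in
    µm (see module docstring); ``orientation`` rotates the ellipse.
    ``rise_time`` and ``decay_time`` (ms) set the activation kinetics:
    the rise time low-pass filters the overlap area, the decay time
    governs RRP depletion when ``adaptation_enabled``.
    ``response_delay`` (ms) shifts the response in time and is used
    only in models with kinetic asymmetries.
    """

    center_x: float = 0.0
    center_y: float = 0.0
    size_x: float = 50.0
    size_y: float = 50.0
    orientation: float = 0.0
    rise_time: float = 30.0
    decay_time: float = 200.0
    response_delay: float = 0.0
    adaptation_enabled: bool = True

    def __post_init__(self):
        if self.size_x <= 0 or self.size_y <= 0:
            raise ValueError("RF sizes must be strictly positive")
        if self.rise_time <= 0 or self.decay_time <= 0:
            raise ValueError("rise and decay times must be strictly positive")
        if self.response_delay < 0:
            raise ValueError("response_delay must be non-negative")


@dataclass
class PlasticityParams:
    """Short-term plasticity parameters (amplitudes in [0,1], taus in ms)."""

    dep_amp: float = 0.0
    dep_tau: float = 200.0
    fac_amp: float = 0.0
    fac_tau: float = 200.0
    dep_enabled: bool = False
    fac_enabled: bool = False

    def __post_init__(self):
        for name in ("dep_amp", "fac_amp"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dep_tau <= 0 or self.fac_tau <= 0:
            raise ValueError("plasticity time constants must be positive")


@dataclass
class PresynapticCell:
    """A presynaptic unit: center (+ optional surround) RF and synapse.

    The surround must be spatially aligned with the center; its
    contribution is scaled by ``surround_strength`` in [0, 1].
    ``polarity`` only determines the postsynaptic reversal potential.
    """

    center: RFComponent
    surround: Optional[RFComponent] = None
    syn_weight: float = 1.0
    surround_strength: float = 0.0
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    polarity: str = "excitatory"
    group_id: int = 0
    mode: str = "graded"
    cell_id: int = -1

    def __post_init__(self):
        if self.syn_weight < 0:
            raise ValueError("syn_weight must be non-negative")
        if not (0.0 <= self.surround_strength <= 1.0):
            raise ValueError("surround_strength must lie in [0, 1]")
        if self.polarity not in ("excitatory", "inhibitory"):
            raise ValueError("polarity must be excitatory or inhibitory")
        if self.mode not in ("graded", "spiking"):
            raise ValueError("mode must be graded or spiking")
        if self.surround is not None:
            if (self.surround.center_x != self.center.center_x
                    or self.surround.center_y != self.center.center_y):
                raise ValueError("surround must be spatially aligned with the center")

    @property
    def position(self) -> tuple[float, float]:
        return (self.center.center_x, self.center.center_y)


@dataclass
class ConductanceTrace:
    """Non-negative release/conductance series in normalized units."""

    values: np.ndarray
    dt: float
    cell_id: int = -1
    polarity: str = "excitatory"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


# ---------------------------------------------------------------------------
# Spatial overlap


def gaussian_weights(component: RFComponent, arena: Arena) -> tuple[np.ndarray, float]:
    """Gaussian pixel weights on the arena grid and their full sum.

    Returns the flattened (ny*nx,) weight map and its sum, the
    normalizer that makes a full-field stimulus give overlap area 1.
    """
    x, y = arena.grid()
    dx = x - component.center_x
    dy = y - component.center_y
    c, s = np.cos(component.orientation), np.sin(component.orientation)
    x_th = dx * c + dy * s
    y_th = -dx * s + dy * c
    w = np.exp(-((x_th * _SQRT_LN2 / component.size_x) ** 2)
               - ((y_th * _SQRT_LN2 / component.size_y) ** 2))
    w = w.ravel()
    norm = float(w.sum())
    if norm <= 0:
        raise ValueError("receptive field has no support on the arena grid")
    return w, norm


def rf_overlap_area(component: RFComponent, stimulus: Stimulus, t: Optional[float] = None):
    """Normalized stimulus/RF overlap, for one frame or the whole series.

    With ``t`` given (ms), returns the scalar area at the frame
    containing ``t``; otherwise the full (n_frames,) series.
    """
    w, norm = gaussian_weights(component, stimulus.arena)
    if t is None:
        flat = stimulus.frames.reshape(stimulus.n_frames, -1)
        return (flat @ w.astype(np.float32)).astype(float) / norm
    idx = int(t / stimulus.dt)
    if not (0 <= idx < stimulus.n_frames):
        raise ValueError("t outside the stimulus duration")
    return float(stimulus.frames[idx].ravel() @ w) / norm


# ---------------------------------------------------------------------------
# Temporal kinetics


def _shift(series: np.ndarray, n: int) -> np.ndarray:
    """Delay a series by n samples, zero-padding at the front."""
    if n <= 0:
        return series
    out = np.zeros_like(series)
    out[n:] = series[:-n]
    return out


def rf_temporal_response(
    area: np.ndarray,
    component: RFComponent,
    dt: float,
    return_adaptation: bool = False,
):
    """First-order activation with RRP adaptation (module docstring eqns).

    ``dt`` must be smaller than both kinetic time constants.  When
    ``component.adaptation_enabled`` is False the adaptation state is
    held at 1 and the recursion reduces to a linear low-pass filter.
    """
    if dt >= component.rise_time or dt >= component.decay_time:
        raise ValueError("dt must be smaller than rise_time and decay_time")
    area = np.asarray(area, dtype=float)
    if component.response_delay > 0:
        area = _shift(area, int(round(component.response_delay / dt)))
    k = dt / component.rise_time
    if not component.adaptation_enabled:
        # RF_t = k*area_t + (1-k)*RF_{t-1}
        rf = lfilter([k], [1.0, -(1.0 - k)], area)
        if return_adaptation:
            return rf, np.ones_like(rf)
        return rf
    rf = np.empty_like(area)
    adapt = np.empty_like(area)
    rf_prev, a_prev = 0.0, 1.0
    kd = dt / component.decay_time
    for i in range(area.size):
        rf_prev = (area[i] - rf_prev) * k + rf_prev * a_prev
        a_prev = max(0.0, a_prev - rf_prev * kd)
        rf[i] = rf_prev
        adapt[i] = a_prev
    if return_adaptation:
        return rf, adapt
    return rf


def _batch_temporal_response(
    areas: np.ndarray,
    rise: np.ndarray,
    decay: np.ndarray,
    delay_steps: np.ndarray,
    adaptation: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Vectorized recursion across components: areas (T, M) -> rf (T, M)."""
    T, M = areas.shape
    if np.any(delay_steps > 0):
        shifted = np.zeros_like(areas)
        for j in range(M):
            n = int(delay_steps[j])
            if n > 0:
                shifted[n:, j] = areas[:T - n, j]
            else:
                shifted[:, j] = areas[:, j]
        areas = shifted
    k = dt / rise
    kd = dt / decay
    rf = np.zeros(M)
    adapt = np.ones(M)
    out = np.empty((T, M))
    adapt_on = adaptation.astype(bool)
    for i in range(T):
        rf = (areas[i] - rf) * k + rf * adapt
        np.maximum(adapt - rf * kd, 0.0, out=adapt, where=adapt_on)
        out[i] = rf
    return out


def integrate_center_surround(
    center_trace: np.ndarray,
    surround_trace: Optional[np.ndarray],
    cell: PresynapticCell,
    dt: float = 1.0,
) -> ConductanceTrace:
    """Weighted, rectified center-minus-surround combination."""
    center_trace = np.asarray(center_trace, dtype=float)
    if surround_trace is None:
        full = cell.syn_weight * np.maximum(0.0, center_trace)
    else:
        surround_trace = np.asarray(surround_trace, dtype=float)
        if surround_trace.shape != center_trace.shape:
            raise ValueError("center and surround traces must share length")
        full = cell.syn_weight * np.maximum(
            0.0, center_trace - cell.surround_strength * surround_trace)
    return ConductanceTrace(full, dt, cell_id=cell.cell_id, polarity=cell.polarity)


# ---------------------------------------------------------------------------
# Short-term plasticity


def _depression_factor(drive: np.ndarray, p: PlasticityParams, dt: float,
                       as_printed: bool = False) -> np.ndarray:
    """Per-step depression factor series, state starting at 1 (full RRP)."""
    out = np.empty_like(drive)
    d = 1.0
    if as_printed:
        # literal equations: the depletion step is scaled by fac_amp and
        # the recovery denominator uses fac_tau
        for i in range(drive.size):
            d_prev = d
            d = d_prev * p.fac_amp * (1.0 - p.dep_amp * drive[i])
            d = d * (1.0 - d_prev / (p.fac_tau / dt))
            out[i] = d
        return out
    k = dt / p.dep_tau
    for i in range(drive.size):
        d = d * (1.0 - p.dep_amp * drive[i])
        d = d + (1.0 - d) * k
        out[i] = d
    return out


def _facilitation_exponent(drive: np.ndarray, p: PlasticityParams, dt: float) -> np.ndarray:
    """Facilitation state series, accumulated from drive, clipped to [0, 1]."""
    out = np.empty_like(drive)
    f = 0.0
    k = dt / p.fac_tau
    for i in range(drive.size):
        f = p.fac_amp * drive[i] + f
        f = f - f * k
        f = min(max(f, 0.0), 1.0)
        out[i] = f
    return out


def apply_depression(trace: ConductanceTrace, p: PlasticityParams, dt: Optional[float] = None,
                     as_printed: bool = False) -> ConductanceTrace:
    """Multiply release by a depletable RRP factor (starts at 1).

    The factor is reduced in proportion to instantaneous release
    (``dep_amp``) and recovers toward 1 with time constant ``dep_tau``.
    """
    dt = trace.dt if dt is None else dt
    factor = _depression_factor(trace.values, p, dt, as_printed=as_printed)
    return ConductanceTrace(trace.values * factor, dt, trace.cell_id, trace.polarity)


def apply_facilitation(trace: ConductanceTrace, p: PlasticityParams,
                       dt: Optional[float] = None) -> ConductanceTrace:
    """Scale release by 10**syn_fac with syn_fac in [0, 1] (up to 10x)."""
    dt = trace.dt if dt is None else dt
    expo = _facilitation_exponent(trace.values, p, dt)
    return ConductanceTrace(trace.values * 10.0 ** expo, dt, trace.cell_id, trace.polarity)


# ---------------------------------------------------------------------------
# Spiking read-out


def presynaptic_spike_train(
    trace: ConductanceTrace,
    seed: int = 0,
    as_printed: bool = False,
    ceiling: float = 0.3,
):
    """Stochastic spikes from a release trace.

    At every step a uniform value u ~ U[0, ceiling] is drawn; in the
    default mode a spike is emitted when u < RF_full (rate grows with
    drive, saturating at one spike per step for drive >= ceiling).
    ``as_printed=True`` uses the literal comparator (spike when
    u > RF_full).
    """
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, ceiling, size=trace.values.size)
    spikes = (u > trace.values) if as_printed else (u < trace.values)
    return np.nonzero(spikes)[0] * trace.dt, spikes


# ---------------------------------------------------------------------------
# Population pipeline


def population_release(
    cells: Sequence[PresynapticCell],
    stimulus: Stimulus,
    areas: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Release traces for a whole population, shape (n_frames, n_cells).

    Runs the full presynaptic cascade (overlap -> kinetics ->
    center-surround -> rectification -> plasticity) with the spatial
    overlap computed as one matrix product over all components.
    ``areas`` can supply precomputed per-component overlap series (as
    returned by :func:`population_areas`) to skip the spatial step.
    """
    if areas is None:
        areas = population_areas(cells, stimulus)
    dt = stimulus.dt
    comps: list[RFComponent] = []
    for cell in cells:
        comps.append(cell.center)
        if cell.surround is not None:
            comps.append(cell.surround)
    rise = np.array([c.rise_time for c in comps])
    decay = np.array([c.decay_time for c in comps])
    delay = np.array([int(round(c.response_delay / dt)) for c in comps])
    adapt = np.array([c.adaptation_enabled for c in comps])
    if np.any(dt >= rise) or np.any(dt >= decay):
        raise ValueError("stimulus dt must be smaller than all kinetic time constants")
    rf = _batch_temporal_response(areas, rise, decay, delay, adapt, dt)

    T = areas.shape[0]
    out = np.empty((T, len(cells)))
    j = 0
    for i, cell in enumerate(cells):
        if cell.surround is not None:
            full = np.maximum(0.0, rf[:, j] - cell.surround_strength * rf[:, j + 1])
            j += 2
        else:
            full = np.maximum(0.0, rf[:, j])
            j += 1
        full = cell.syn_weight * full
        p = cell.plasticity
        if p.dep_enabled and p.dep_amp > 0:
            full = full * _depression_factor(full, p, dt)
        if p.fac_enabled and p.fac_amp > 0:
            full = full * 10.0 ** _facilitation_exponent(full, p, dt)
        out[:, i] = full
    return out


def population_weights(cells: Sequence[PresynapticCell], arena: Arena) -> np.ndarray:
    """Stacked normalized Gaussian maps, shape (n_pixels, n_components).

    Components are ordered cell by cell, center first then surround
    (when present) — the layout :func:`population_release` expects.
    Computing this once and reusing it across stimuli on the same
    arena skips the dominant cost of repeated overlap evaluation.
    """
    weights = []
    for cell in cells:
        for comp in ([cell.center] if cell.surround is None else [cell.center, cell.surround]):
            w, norm = gaussian_weights(comp, arena)
            weights.append(w / norm)
    return np.stack(weights, axis=1).astype(np.float32)


def population_areas(cells: Sequence[PresynapticCell], stimulus: Stimulus,
                     weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Normalized overlap series for every RF component, shape (T, M)."""
    if weights is None:
        weights = population_weights(cells, stimulus.arena)
    flat = stimulus.frames.reshape(stimulus.n_frames, -1)
    return (flat @ weights).astype(float)


def random_population(
    n: int,
    rng: np.random.Generator,
    radius: float = 150.0,
    center: tuple[float, float] = (0.0, 0.0),
    template: Optional[PresynapticCell] = None,
    polarity: str = "excitatory",
) -> list[PresynapticCell]:
    """Cells with RF centres uniform in a circle of the given radius.

    Every cell is a copy of ``template`` (default: a plain 50 µm
    center-only cell) moved to its sampled position.
    """
    if template is None:
        template = PresynapticCell(center=RFComponent(), polarity=polarity)
    cells = []
    for i in range(n):
        r = radius * np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * np.pi)
        cx, cy = center[0] + r * np.cos(phi), center[1] + r * np.sin(phi)
        c = replace(template.center, center_x=cx, center_y=cy)
        s = None
        if template.surround is not None:
            s = replace(template.surround, center_x=cx, center_y=cy)
        cells.append(replace(template, center=c, surround=s, cell_id=i))
    return cells


def assign_groups(cells: Sequence[PresynapticCell], axis_direction: float = 0.0,
                  n_groups: int = 4) -> None:
    """Partition cells into groups by position quantiles along an axis.

    Groups are numbered along the preferred motion axis: group 0 is the
    side a preferred-direction stimulus enters first.
    """
    proj = np.array([c.center.center_x * np.cos(axis_direction)
                     + c.center.center_y * np.sin(axis_direction) for c in cells])
    order = np.argsort(proj, kind="stable")
    for rank, idx in enumerate(order):
        cells[idx].group_id = min(rank * n_groups // len(cells), n_groups - 1)
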