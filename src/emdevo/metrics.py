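"""Direction selectivity and computational-primitive metrics.

Direction selectivity is quantified as the vector-sum index

    DSI = sum_th R_th cos(th) / sum_th R_th,

with th = 0 aligned to the designated preferred direction and R_th the
peak somatic depolarization (floored at zero).  Evolved circuits are
placed in a two-dimensional "primitive space": the horizontal axis
separates delay-and-compare arrangements (H&R, responses narrowing
along the preferred motion axis) from their mirror (anti-H&R), the
vertical axis separates temporal-alignment from amplitude-based
strategies.  Circuits with inhibitory inputs get an analogous pair of
axes (B&L vs anti-B&L; pause-in-inhibition vs tuned inhibition).
A primitive counts as present when the circuit sits more than 0.20
from the origin along its axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .stimuli import Arena, make_variable_velocity_bar

__all__ = [
    "DirectionalTuning",
    "PrimitiveCoordinates",
    "SpaceTimeMap",
    "dsi",
    "grating_dsi",
    "response_duration_fwhm",
    "amplitude_metric",
    "alignment_metric",
    "hr_metric",
    "bl_metrics",
    "classify_primitives",
    "noise_robustness_curve",
    "spacetime_map",
    "compare_slopes",
]

PRESENCE_THRESHOLD = 0.20


def dsi(responses: Sequence[float], directions: Sequence[float]) -> float:
    """Vector-sum direction selectivity index.

    ``responses`` are non-negative response magnitudes (peak
    depolarization relative to rest; negative values are floored at 0),
    ``directions`` the matching angles in radians with 0 = preferred.
    Returns 0 when all responses vanish.
    """
    r = np.maximum(np.asarray(responses, dtype=float), 0.0)
    th = np.asarray(directions, dtype=float)
    if r.shape != th.shape:
        raise ValueError("responses and directions must have equal length")
    total = r.sum()
    if total == 0:
        return 0.0
    return float(np.sum(r * np.cos(th)) / total)


def grating_dsi(traces: Sequence[np.ndarray], directions: Sequence[float],
                steady_fraction: float = 0.3) -> float:
    """DSI from drifting-grating responses.

    The response magnitude per direction is the steady-state
    peak-to-peak voltage over the final ``steady_fraction`` of each
    trial rather than the peak amplitude.
    """
    amps = []
    for v in traces:
        v = np.asarray(v, dtype=float)
        tail = v[int(np.floor(v.size * (1.0 - steady_fraction))):]
        amps.append(float(tail.max() - tail.min()))
    return dsi(amps, directions)


@dataclass
class DirectionalTuning:
    """Per-direction responses and DSI, optionally per speed."""

    directions: np.ndarray
    responses: dict  # speed (mm/s) -> array of R_th
    preferred_axis: float = 0.0

    @property
    def dsi_per_speed(self) -> dict:
        return {s: dsi(r, self.directions) for s, r in self.responses.items()}

    @property
    def mean_dsi(self) -> float:
        vals = list(self.dsi_per_speed.values())
        return float(np.mean(vals)) if vals else 0.0


# ---------------------------------------------------------------------------
# Excitatory primitive metrics


def response_duration_fwhm(trace: np.ndarray, dt: float) -> float:
    """Duration (ms) of the largest contiguous run at or above half max."""
    trace = np.asarray(trace, dtype=float)
    peak = trace.max()
    if peak <= 0:
        return 0.0
    above = trace >= 0.5 * peak
    best = run = 0
    for a in above:
        run = run + 1 if a else 0
        best = max(best, run)
    return best * dt


def _align_by_peak(traces: np.ndarray) -> np.ndarray:
    """Shift each row so all peaks coincide (removes position lag)."""
    peaks = traces.argmax(axis=1)
    ref = int(peaks.max())
    out = np.zeros_like(traces)
    for i, p in enumerate(peaks):
        shift = ref - int(p)
        if shift > 0:
            out[i, shift:] = traces[i, :traces.shape[1] - shift]
        else:
            out[i] = traces[i]
    return out


def _overlap_metric(traces: np.ndarray, quorum: float, align: bool) -> float:
    """Shared machinery of the amplitude and alignment metrics.

    At each time where any waveform is active, overlap is present when
    at least ``quorum`` of the waveforms reach 20% of their own peak;
    the overlap value there is the population mean of the peak-
    normalized waveforms, and the metric is the mean of that overlap
    waveform over the active window.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    peaks = traces.max(axis=1)
    if np.all(peaks <= 0):
        warnings.warn("all-zero traces: overlap metric set to 0")
        return 0.0
    traces = traces[peaks > 0]
    peaks = peaks[peaks > 0]
    if align:
        traces = _align_by_peak(traces)
    normed = traces / peaks[:, None] if not align else traces / traces.max(axis=1)[:, None]
    active = np.any(normed > 0, axis=0)
    if not active.any():
        return 0.0
    above = normed >= 0.2
    quorum_met = above.mean(axis=0) >= quorum
    overlap = np.where(active & quorum_met, normed.mean(axis=0), 0.0)
    return float(overlap[active].mean())


def amplitude_metric(traces: np.ndarray) -> float:
    """Waveform-similarity metric after removing position-dependent lag.

    Computed on per-synapse responses to a preferred-direction bar at
    1 mm/s, temporally aligned by peak time; overlap requires at least
    75% of the waveforms at 20% of their peak.
    """
    return _overlap_metric(traces, quorum=0.75, align=True)


def alignment_metric(traces: np.ndarray) -> float:
    """As :func:`amplitude_metric` but on raw (unaligned) motion
    responses with a 25% quorum — high when the circuit itself
    synchronizes preferred-direction peaks."""
    return _overlap_metric(traces, quorum=0.25, align=False)


def hr_metric(traces: np.ndarray, positions: Sequence[float], dt: float) -> float:
    """Signed delay-and-compare coordinate in [-1, 1].

    Per-synapse response duration (FWHM) is regressed on position
    along the preferred axis; narrowing durations (H&R) give a
    positive sign, widening (anti-H&R) negative.  The magnitude is
    (1 - narrowest/widest)^2 over synapses with nonzero responses.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    positions = np.asarray(positions, dtype=float)
    durations = np.array([response_duration_fwhm(tr, dt) for tr in traces])
    ok = durations > 0
    if ok.sum() < 2:
        raise ValueError("need at least two synapses with nonzero responses")
    durations, positions = durations[ok], positions[ok]
    widest, narrowest = durations.max(), durations.min()
    if widest == narrowest:
        return 0.0
    slope = np.polyfit(positions, durations, 1)[0]
    magnitude = (1.0 - narrowest / widest) ** 2
    return float(-np.sign(slope) * magnitude)


# ---------------------------------------------------------------------------
# Inhibitory primitive metrics


def bl_metrics(exc_pref: np.ndarray, inh_pref: np.ndarray, inh_null: np.ndarray,
               dt: float = 1.0) -> dict:
    """Timing and amplitude metrics of the inhibitory drive.

    The preferred-direction excitatory response's area under the curve
    is split into equal thirds by two time points; B&L is the fraction
    of preferred-direction inhibition falling in the last third-window,
    anti-B&L in the first.  ``amp_inhib`` compares peak inhibition
    across directions; ``pause`` (reported only when both B&L scores
    are below 20%) compares null-direction peak inhibition with the
    preferred-direction peak inside the middle window.
    """
    exc_pref = np.asarray(exc_pref, dtype=float)
    inh_pref = np.asarray(inh_pref, dtype=float)
    inh_null = np.asarray(inh_null, dtype=float)
    auc = np.cumsum(exc_pref)
    if auc[-1] <= 0:
        raise ValueError("excitatory response has zero area: windows undefined")
    t1 = int(np.searchsorted(auc, auc[-1] / 3.0))
    t2 = int(np.searchsorted(auc, 2.0 * auc[-1] / 3.0))
    total_inh = inh_pref.sum()
    if total_inh > 0:
        anti_bl = float(inh_pref[:t1].sum() / total_inh)
        bl = float(inh_pref[t2:].sum() / total_inh)
    else:
        anti_bl = bl = 0.0
    amp_pref = float(inh_pref.max(initial=0.0))
    amp_null = float(inh_null.max(initial=0.0))
    denom = amp_null + amp_pref
    amp_inhib = max(0.0, (amp_null - amp_pref) / denom) if denom > 0 else 0.0
    pause = None
    if anti_bl < PRESENCE_THRESHOLD and bl < PRESENCE_THRESHOLD:
        amp_pref_mid = float(inh_pref[t1:t2].max(initial=0.0))
        d = amp_null + amp_pref_mid
        pause = (amp_null - amp_pref_mid) / d if d > 0 else 0.0
    return {"bl": bl, "anti_bl": anti_bl, "amp_inhib": amp_inhib, "pause": pause,
            "window_edges": (t1 * dt, t2 * dt)}


@dataclass
class PrimitiveCoordinates:
    """Position of a circuit in primitive space.

    ``x``: anti-H&R (-1) to H&R (+1); ``y``: amplitude (-1) to
    temporal alignment (+1).  ``x_inh``: anti-B&L to B&L; ``y_inh``:
    tuned inhibition (-1) to pause-in-inhibition (+1); both None for
    excitation-only circuits.
    """

    x: float
    y: float
    x_inh: Optional[float] = None
    y_inh: Optional[float] = None
    dsi: Optional[float] = None
    present: set = field(default_factory=set)

    def __post_init__(self):
        if not self.present:
            self.present = self._detect()

    def _detect(self) -> set:
        out = set()
        if self.x > PRESENCE_THRESHOLD:
            out.add("HR")
        elif self.x < -PRESENCE_THRESHOLD:
            out.add("anti-HR")
        if self.y > PRESENCE_THRESHOLD:
            out.add("alignment")
        elif self.y < -PRESENCE_THRESHOLD:
            out.add("amplitude")
        if self.x_inh is not None:
            if self.x_inh > PRESENCE_THRESHOLD:
                out.add("BL")
            elif self.x_inh < -PRESENCE_THRESHOLD:
                out.add("anti-BL")
        if self.y_inh is not None:
            if self.y_inh > PRESENCE_THRESHOLD:
                out.add("pause")
            elif self.y_inh < -PRESENCE_THRESHOLD:
                out.add("tuned-inhibition")
        return out

    @property
    def hybrid(self) -> bool:
        """True when two primitives on orthogonal axes are both present."""
        exc = {"HR", "anti-HR"} & self.present, {"alignment", "amplitude"} & self.present
        inh = {"BL", "anti-BL"} & self.present, {"pause", "tuned-inhibition"} & self.present
        return (bool(exc[0]) and bool(exc[1])) or (bool(inh[0]) and bool(inh[1]))


def classify_primitives(
    exc_traces: np.ndarray,
    positions: Sequence[float],
    dt: float,
    exc_drive_pref: Optional[np.ndarray] = None,
    inh_drive_pref: Optional[np.ndarray] = None,
    inh_drive_null: Optional[np.ndarray] = None,
    dsi_value: Optional[float] = None,
) -> PrimitiveCoordinates:
    """Place a circuit in primitive space from its motion responses.

    ``exc_traces`` are per-synapse preferred-direction release traces
    (rows) and ``positions`` their RF-centre coordinates along the
    preferred axis.  Summed excitatory/inhibitory drives (preferred and
    null direction) activate the inhibitory axes when provided.
    """
    x = hr_metric(exc_traces, positions, dt)
    y = alignment_metric(exc_traces) - amplitude_metric(exc_traces)
    x_inh = y_inh = None
    if inh_drive_pref is not None and inh_drive_null is not None:
        exc_sum = (exc_drive_pref if exc_drive_pref is not None
                   else np.asarray(exc_traces).sum(axis=0))
        m = bl_metrics(exc_sum, inh_drive_pref, inh_drive_null, dt)
        x_inh = m["bl"] - m["anti_bl"]
        y_inh = (m["pause"] if m["pause"] is not None else 0.0) - m["amp_inhib"]
    return PrimitiveCoordinates(x=x, y=y, x_inh=x_inh, y_inh=y_inh, dsi=dsi_value)


# ---------------------------------------------------------------------------
# Noise robustness


def noise_robustness_curve(
    response_fn: Callable[[float, float, int], float],
    noise_levels: Sequence[float] = (0.0, 1.0, 2.5, 5.0),
    n_trials: int = 50,
    seed: int = 0,
    preferred: float = 0.0,
) -> dict:
    """Two-direction DSI versus velocity-noise level.

    ``response_fn(noise_sd, direction, trial_seed)`` must return the
    (non-negative) response magnitude to one variable-velocity bar
    presentation; the same trial seed is used for the preferred and
    null direction so both see the same velocity trajectory.  Returns
    per-level mean and sd of the single-trial DSI, the mean normalized
    to the no-noise baseline, and the slope of normalized DSI vs noise
    from a linear regression.
    """
    null = preferred + np.pi
    rng = np.random.default_rng(seed)
    means, sds, per_level = [], [], []
    for level in noise_levels:
        trials = 1 if level == 0 else n_trials
        vals = np.empty(trials)
        for k in range(trials):
            trial_seed = int(rng.integers(2 ** 31 - 1))
            rp = max(0.0, response_fn(level, preferred, trial_seed))
            rn = max(0.0, response_fn(level, null, trial_seed))
            vals[k] = 0.0 if rp + rn == 0 else (rp - rn) / (rp + rn)
        per_level.append(vals)
        means.append(vals.mean())
        sds.append(vals.std(ddof=1) if trials > 1 else 0.0)
    means = np.asarray(means)
    baseline = means[np.asarray(noise_levels) == 0.0]
    baseline = baseline[0] if baseline.size else means[0]
    if baseline == 0:
        warnings.warn("zero baseline DSI: normalized values undefined")
        normalized = np.full_like(means, np.nan)
        slope = np.nan
    else:
        normalized = means / baseline
        slope = float(np.polyfit(noise_levels, normalized, 1)[0])
    return {
        "noise_levels": np.asarray(noise_levels, dtype=float),
        "mean_dsi": means,
        "sd_dsi": np.asarray(sds),
        "normalized_dsi": normalized,
        "slope": slope,
        "trials": per_level,
    }


def compare_slopes(slopes_a: Sequence[float], slopes_b: Sequence[float]):
    """One-way ANOVA on per-run noise-dependence slopes; returns (F, p)."""
    res = stats.f_oneway(np.asarray(slopes_a), np.asarray(slopes_b))
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# 1-D noise space-time mapping


@dataclass
class SpaceTimeMap:
    """Bar-onset-triggered response map (signed, e.g. mV).

    ``values[i, j]`` is the mean response at spatial bar ``i`` and time
    bin ``j`` (20 ms bins) after a white-bar onset at that position.
    """

    values: np.ndarray
    bar_positions: np.ndarray
    bin_times: np.ndarray
    event_counts: np.ndarray

    @property
    def temporal_rf(self) -> np.ndarray:
        """Response time course at the central spatial position."""
        return self.values[self.values.shape[0] // 2]

    @property
    def spatial_rf(self) -> np.ndarray:
        """Spatial profile at the time of the maximal absolute response."""
        j = int(np.unravel_index(np.abs(self.values).argmax(), self.values.shape)[1])
        return self.values[:, j]


def spacetime_map(
    response: np.ndarray,
    response_dt: float,
    stimulus,
    window: float = 400.0,
    bin_width: float = 20.0,
    min_events: int = 5,
) -> SpaceTimeMap:
    """Event-triggered space-time receptive-field map from 1-D bar noise.

    For every bar position, response fluctuations following white-bar
    (OFF -> ON) onsets are averaged in ``bin_width`` ms bins; only the
    rising (ON) phase triggers are used.  The response sample at onset
    is subtracted so the map shows the onset-driven deflection.
    """
    if stimulus.kind != "bar_noise":
        raise ValueError("spacetime_map requires a 1-D bar-noise stimulus")
    values = stimulus.meta["epoch_values"]  # (n_epochs, n_bars)
    interval = stimulus.meta["update_interval"]
    bar_width = stimulus.meta["bar_width"]
    n_bars = values.shape[1]
    response = np.asarray(response, dtype=float)
    n_bins = int(round(window / bin_width))
    samples_per_bin = max(1, int(round(bin_width / response_dt)))

    out = np.zeros((n_bars, n_bins))
    counts = np.zeros(n_bars, dtype=int)
    onsets = np.diff(values, axis=0, prepend=np.zeros((1, n_bars))) > 0
    for b in range(n_bars):
        for e in np.nonzero(onsets[:, b])[0]:
            t0 = int(round(e * interval / response_dt))
            t1 = t0 + n_bins * samples_per_bin
            if t1 > response.size:
                continue
            seg = response[t0:t1] - response[t0]
            out[b] += seg.reshape(n_bins, samples_per_bin).mean(axis=1)
            counts[b] += 1
    if np.any(counts < min_events):
        warnings.warn(f"under-sampled space-time map: min {counts.min()} events "
                      f"(counts per position: {counts.tolist()})")
    out[counts > 0] /= counts[counts > 0, None]
    positions = (np.arange(n_bars) + 0.5) * bar_width - stimulus.arena.width / 2.0
    bins = (np.arange(n_bins) + 0.5) * bin_width
    return SpaceTimeMap(out, positions, bins, counts)
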