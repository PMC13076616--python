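"""Passive branched-cable solver and optional spiking soma.

The membrane equation on the compartmental tree,

    C_i dV_i/dt = -g_pas,i (V_i - E_rest) + sum_j g_axial,ij (V_j - V_i)
                  + sum_s g_s(t) (E_s - V_i)  [+ HH currents at the soma],

is integrated with a fully implicit backward-Euler step solved exactly
per step by Hines-ordered Gaussian elimination on the tree (O(n) per
step, unconditionally stable).  Hodgkin-Huxley sodium/potassium
conductances can be added at the soma; their gating variables advance
explicitly between voltage steps.

Internal units: mV, ms, µS, nF (so currents are in nA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .morphology import Morphology

__all__ = [
    "PassiveProperties",
    "SynapseSite",
    "HHSoma",
    "VoltageTrace",
    "place_synapses",
    "simulate_compartmental",
    "simulate_minimal_detector",
    "add_spiking_soma",
    "count_spikes",
]


@dataclass
class PassiveProperties:
    """Global passive membrane parameters.

    g_pas in S/cm² (default 4e-4), c_m in µF/cm² (1), e_rest in mV
    (-60) and axial resistivity r_a in Ω·cm (150).  The evolvable
    ranges are g_pas in [1e-5, 1e-3] and r_a in [50, 200].
    """

    g_pas: float = 4e-4
    c_m: float = 1.0
    e_rest: float = -60.0
    r_a: float = 150.0

    def __post_init__(self):
        if min(self.g_pas, self.c_m, self.r_a) <= 0:
            raise ValueError("passive parameters must be positive")


@dataclass
class SynapseSite:
    """One synapse: presynaptic cell -> dendritic segment."""

    cell_id: int
    segment: int
    e_rev: float = 0.0
    g_scale: float = 1.0  # nS of conductance per unit of presynaptic release


@dataclass
class HHSoma:
    """Somatic Na/K spiking conductances (densities in S/cm²).

    Defaults correspond to 10,000 and 2000 pS/µm².
    """

    gbar_na: float = 1.0
    gbar_k: float = 0.2
    e_na: float = 50.0
    e_k: float = -77.0


@dataclass
class VoltageTrace:
    """Somatic membrane potential (mV) sampled at dt (ms)."""

    v: np.ndarray
    dt: float
    e_rest: float = -60.0
    spike_count: Optional[int] = None
    v_all: Optional[np.ndarray] = None

    @property
    def peak_depolarization(self) -> float:
        """Peak deviation above rest, floored at 0 (mV)."""
        return max(0.0, float(self.v.max() - self.e_rest))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.v.size) * self.dt


def place_synapses(
    cells: Sequence,
    morph: Morphology,
    mode: str = "retina",
    seed: int = 0,
    e_rev_exc: float = 0.0,
    e_rev_inh: float = -70.0,
    g_scale: float = 1.0,
    g_scale_inh: Optional[float] = None,
) -> list[SynapseSite]:
    """Map presynaptic cells onto dendritic segments, one synapse each.

    Retinal mode connects each cell's RF centre to the nearest
    dendritic segment (soma excluded); cortical mode assigns uniformly
    random branches, independent of RF position.  ``g_scale_inh``
    gives inhibitory synapses their own conductance scale (nS per unit
    release); it defaults to ``g_scale``.
    """
    if len(cells) == 0:
        raise ValueError("population must be non-empty")
    if morph.n_segments < 2:
        raise ValueError("morphology has no dendrites")
    if mode not in ("retina", "cortex"):
        raise ValueError("mode must be 'retina' or 'cortex'")
    rng = np.random.default_rng(seed)
    sites = []
    dend_xy = morph.xyz[1:, :2]
    for cell in cells:
        if mode == "retina":
            px, py = cell.position
            seg = 1 + int(np.argmin(np.sum((dend_xy - (px, py)) ** 2, axis=1)))
        else:
            seg = int(rng.integers(1, morph.n_segments))
        if cell.polarity == "excitatory":
            e_rev, g = e_rev_exc, g_scale
        else:
            e_rev = e_rev_inh
            g = g_scale if g_scale_inh is None else g_scale_inh
        sites.append(SynapseSite(cell.cell_id, seg, e_rev, g))
    return sites


def add_spiking_soma(passive: PassiveProperties, **kwargs) -> HHSoma:
    """Somatic spiking mechanism to pass to :func:`simulate_compartmental`."""
    return HHSoma(**kwargs)


def count_spikes(v: VoltageTrace | np.ndarray, threshold: float = 0.0) -> int:
    """Number of upward crossings of the threshold (0 mV)."""
    vals = v.v if isinstance(v, VoltageTrace) else np.asarray(v, dtype=float)
    above = vals >= threshold
    return int(np.count_nonzero(above[1:] & ~above[:-1]))


@njit(cache=True)
def _hines_backward_euler(parent, g_axial, cap, g_leak, e_rest, syn_seg, syn_erev,
                          g_syn, dt, v0, use_hh, gbar_na, gbar_k, e_na, e_k,
                          soma_area_factor):
    n = parent.shape[0]
    T = g_syn.shape[0]
    v = np.empty(n)
    for i in range(n):
        v[i] = v0
    d = np.empty(n)
    rhs = np.empty(n)
    out = np.empty(T)
    n_syn = syn_seg.shape[0]

    # HH gating state initialized at steady state for v0
    m = 0.0
    h = 1.0
    ngate = 0.0
    if use_hh:
        vv = v0
        am = 0.1 * (vv + 40.0) / (1.0 - np.exp(-(vv + 40.0) / 10.0))
        bm = 4.0 * np.exp(-(vv + 65.0) / 18.0)
        ah = 0.07 * np.exp(-(vv + 65.0) / 20.0)
        bh = 1.0 / (1.0 + np.exp(-(vv + 35.0) / 10.0))
        an = 0.01 * (vv + 55.0) / (1.0 - np.exp(-(vv + 55.0) / 10.0))
        bn = 0.125 * np.exp(-(vv + 65.0) / 80.0)
        m = am / (am + bm)
        h = ah / (ah + bh)
        ngate = an / (an + bn)

    for t in range(T):
        for i in range(n):
            ci = cap[i] / dt
            d[i] = ci + g_leak[i]
            rhs[i] = ci * v[i] + g_leak[i] * e_rest
        for s in range(n_syn):
            g = g_syn[t, s]
            i = syn_seg[s]
            d[i] += g
            rhs[i] += g * syn_erev[s]
        if use_hh:
            vv = v[0]
            am = 0.1 * (vv + 40.0) / (1.0 - np.exp(-(vv + 40.0) / 10.0)) \
                if abs(vv + 40.0) > 1e-6 else 1.0
            bm = 4.0 * np.exp(-(vv + 65.0) / 18.0)
            ah = 0.07 * np.exp(-(vv + 65.0) / 20.0)
            bh = 1.0 / (1.0 + np.exp(-(vv + 35.0) / 10.0))
            an = 0.01 * (vv + 55.0) / (1.0 - np.exp(-(vv + 55.0) / 10.0)) \
                if abs(vv + 55.0) > 1e-6 else 0.1
            bn = 0.125 * np.exp(-(vv + 65.0) / 80.0)
            m += dt * (am * (1.0 - m) - bm * m)
            h += dt * (ah * (1.0 - h) - bh * h)
            ngate += dt * (an * (1.0 - ngate) - bn * ngate)
            m = min(max(m, 0.0), 1.0)
            h = min(max(h, 0.0), 1.0)
            ngate = min(max(ngate, 0.0), 1.0)
            gna = gbar_na * m * m * m * h * soma_area_factor
            gk = gbar_k * ngate ** 4 * soma_area_factor
            d[0] += gna + gk
            rhs[0] += gna * e_na + gk * e_k
        # axial coupling
        for i in range(1, n):
            d[i] += g_axial[i]
            d[parent[i]] += g_axial[i]
        # eliminate leaves -> root (parents precede children in index order)
        for i in range(n - 1, 0, -1):
            f = g_axial[i] / d[i]
            p = parent[i]
            d[p] -= f * g_axial[i]
            rhs[p] += f * rhs[i]
        v[0] = rhs[0] / d[0]
        for i in range(1, n):
            v[i] = (rhs[i] + g_axial[i] * v[parent[i]]) / d[i]
        out[t] = v[0]
    return out


def _electrical_arrays(morph: Morphology, passive: PassiveProperties):
    """Per-segment capacitance (nF), leak (µS) and axial coupling (µS)."""
    area_cm2 = morph.areas() * 1e-8
    cap = passive.c_m * area_cm2 * 1e3          # µF/cm² * cm² -> µF -> nF is *1e3
    g_leak = passive.g_pas * area_cm2 * 1e6     # S -> µS
    L_cm = morph.lengths() * 1e-4
    r_cm = morph.diameter / 2.0 * 1e-4
    r_half = passive.r_a * (L_cm / 2.0) / (np.pi * r_cm ** 2)  # Ω, half-segment
    g_axial = np.zeros(morph.n_segments)
    for i in range(1, morph.n_segments):
        p = morph.parent[i]
        rp = r_half[p] if p != 0 else 0.0  # treat the soma as isopotential
        g_axial[i] = 1e6 / (r_half[i] + rp)
    return cap, g_leak, g_axial


def simulate_compartmental(
    morph: Morphology,
    passive: PassiveProperties,
    sites: Sequence[SynapseSite],
    traces: np.ndarray,
    trace_dt: float,
    dt: float = 0.1,
    duration: Optional[float] = None,
    hh: Optional[HHSoma] = None,
    record_all: bool = False,
) -> VoltageTrace:
    """Integrate the passive tree under synaptic conductance drive.

    ``traces`` is (n_t, n_sites) presynaptic release sampled at
    ``trace_dt`` (ms); each column is scaled by its site's ``g_scale``
    (nS per unit release) and linearly interpolated onto the solver
    step ``dt`` (0.1 ms by default).
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.ndim != 2 or traces.shape[1] != len(sites):
        raise ValueError("traces must be (n_t, n_sites)")
    if np.any(traces < 0):
        raise ValueError("synaptic conductances must be non-negative")
    total = duration if duration is not None else traces.shape[0] * trace_dt
    n_steps = int(round(total / dt))
    t_out = np.arange(n_steps) * dt
    t_in = np.arange(traces.shape[0]) * trace_dt
    g_syn = np.empty((n_steps, len(sites)))
    for s, site in enumerate(sites):
        g_syn[:, s] = np.interp(t_out, t_in, traces[:, s]) * site.g_scale * 1e-3  # nS->µS

    cap, g_leak, g_axial = _electrical_arrays(morph, passive)
    syn_seg = np.array([s.segment for s in sites], dtype=np.int64)
    if np.any(syn_seg < 0) or np.any(syn_seg >= morph.n_segments):
        raise ValueError("synapse segment index out of range")
    syn_erev = np.array([s.e_rev for s in sites], dtype=float)
    soma_area_factor = morph.areas()[0] * 1e-8 * 1e6  # cm² -> µS per (S/cm²)

    v = _hines_backward_euler(
        morph.parent.astype(np.int64), g_axial, cap, g_leak, passive.e_rest,
        syn_seg, syn_erev, g_syn, dt, passive.e_rest,
        hh is not None,
        hh.gbar_na if hh else 0.0, hh.gbar_k if hh else 0.0,
        hh.e_na if hh else 0.0, hh.e_k if hh else 0.0,
        soma_area_factor)
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("cable solver produced non-finite voltages")
    trace = VoltageTrace(v, dt, e_rest=passive.e_rest)
    if hh is not None:
        trace.spike_count = count_spikes(v)
    return trace


def simulate_minimal_detector(trace_a: np.ndarray, trace_b: np.ndarray,
                              w_a: float, w_b: float) -> np.ndarray:
    """Two-input linear detector: w_a*a(t) + w_b*b(t), no cable, no rectification."""
    trace_a = np.asarray(trace_a, dtype=float)
    trace_b = np.asarray(trace_b, dtype=float)
    if trace_a.shape != trace_b.shape:
        raise ValueError("detector inputs must share a time base")
    return w_a * trace_a + w_b * trace_b
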