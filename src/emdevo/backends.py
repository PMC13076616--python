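"""Circuit back-ends: genome -> stimuli -> release -> read-out -> fitness.

A backend owns a fixed population layout (presynaptic cell positions
and group structure), a stimulus protocol (bars at the configured
speeds and directions) and a postsynaptic read-out:

* ``linear`` — the minimal detector: a weighted sum of presynaptic
  waveforms (inhibitory cells enter with negative sign);
* ``compartmental`` — release traces drive conductance synapses on a
  multicompartment morphology; the response is the peak somatic
  depolarization in mV;
* a spiking soma can be attached to the compartmental read-out.

``evaluate`` applies a genome to the layout, simulates every stimulus
and returns the directional metric DSI * tanh(max R) averaged over
speeds.  Spatial overlap series are cached per stimulus whenever no
spatial receptive-field parameter is free to evolve.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .cable import (HHSoma, PassiveProperties, SynapseSite, place_synapses,
                    simulate_compartmental)
from .evolution import EvalResult, Genome, ParamSpec
from .metrics import dsi
from .morphology import Morphology
from .receptive_fields import (PresynapticCell, population_areas,
                               population_release, population_weights,
                               presynaptic_spike_train, ConductanceTrace)
from .stimuli import Arena, Stimulus, make_moving_bar

__all__ = ["CircuitBackend", "make_bar_protocol", "build_minimal_weight_backend",
           "build_point_backend"]

#: receptive-field parameters that change the spatial overlap
_SPATIAL_PARAMS = frozenset({
    "size", "size_x", "size_y", "orientation",
    "surround_size", "surround_size_x", "surround_size_y", "surround_orientation",
})

_CENTER_ATTRS = {
    "rise_time": "rise_time", "decay_time": "decay_time",
    "response_delay": "response_delay", "orientation": "orientation",
    "size_x": "size_x", "size_y": "size_y",
}
_SURROUND_ATTRS = {
    "surround_rise": "rise_time", "surround_decay": "decay_time",
    "surround_delay": "response_delay", "surround_orientation": "orientation",
    "surround_size_x": "size_x", "surround_size_y": "size_y",
}
_CELL_ATTRS = {"syn_weight", "surround_strength"}
_PLASTICITY_ATTRS = {"dep_amp", "dep_tau", "fac_amp", "fac_tau"}
_GLOBAL_PARAMS = {"g_pas", "r_a"}


def make_bar_protocol(
    arena: Arena,
    speeds: Sequence[float] = (1.0,),
    directions: Sequence[float] = (0.0, np.pi),
    bar_height: float = 1000.0,
    bar_time_width: float = 200.0,
) -> list[tuple[float, float, Stimulus]]:
    """Moving-bar stimuli for every (speed, direction) combination."""
    return [(s, d, make_moving_bar(arena, s, d, bar_height=bar_height,
                                   bar_time_width=bar_time_width))
            for s in speeds for d in directions]


def _strip_inh(name: str) -> tuple[str, bool]:
    if name.startswith("inh_"):
        return name[4:], True
    return name, False


def _apply_params(cells: list[PresynapticCell], genome: Genome,
                  inhibitory: bool) -> list[PresynapticCell]:
    """New cell list with the genome's values written into each cell."""
    out = []
    for cell in cells:
        center = cell.center
        surround = cell.surround
        cell_kw = {}
        plast_kw = {}
        for spec in genome.specs:
            base, is_inh = _strip_inh(spec.name)
            if is_inh != inhibitory or base in _GLOBAL_PARAMS:
                continue
            vals = genome[spec.name]
            v = float(vals[cell.group_id]) if spec.size > 1 else float(vals[0])
            if base == "size":
                center = replace(center, size_x=v, size_y=v)
            elif base == "surround_size":
                if surround is not None:
                    surround = replace(surround, size_x=v, size_y=v)
            elif base in _CENTER_ATTRS:
                center = replace(center, **{_CENTER_ATTRS[base]: v})
            elif base in _SURROUND_ATTRS:
                if surround is not None:
                    surround = replace(surround, **{_SURROUND_ATTRS[base]: v})
            elif base in _CELL_ATTRS:
                cell_kw[base] = v
            elif base in _PLASTICITY_ATTRS:
                plast_kw[base] = v
            else:
                raise KeyError(f"unknown circuit parameter {spec.name!r}")
        plast = replace(cell.plasticity, **plast_kw) if plast_kw else cell.plasticity
        out.append(replace(cell, center=center, surround=surround,
                           plasticity=plast, **cell_kw))
    return out


class CircuitBackend:
    """Evaluate genomes on a fixed circuit layout and stimulus protocol.

    Parameters
    ----------
    exc_cells, inh_cells:
        Base presynaptic populations (positions, groups and any fixed
        properties).  Genome values overwrite the evolvable attributes
        per input group at evaluation time.
    stimuli:
        ``(speed, direction, Stimulus)`` triples; directions must
        include the designated preferred direction 0.
    readout:
        "linear" or "compartmental".
    response_scale:
        Multiplies the response magnitude inside tanh; with the
        compartmental read-out responses are in mV and the default 1.0
        saturates the reward around a few mV of depolarization.
    """

    def __init__(
        self,
        exc_cells: Sequence[PresynapticCell],
        stimuli: Sequence[tuple[float, float, Stimulus]],
        template: Genome,
        inh_cells: Sequence[PresynapticCell] = (),
        readout: str = "linear",
        morph: Optional[Morphology] = None,
        passive: Optional[PassiveProperties] = None,
        dt_v: float = 0.5,
        g_scale: float = 1.0,
        g_scale_inh: Optional[float] = None,
        placement_mode: str = "retina",
        placement_seed: int = 0,
        hh: Optional[HHSoma] = None,
        response_scale: float = 1.0,
        presyn_spike_seed: Optional[int] = None,
        transform=None,
    ):
        if readout not in ("linear", "compartmental"):
            raise ValueError("readout must be 'linear' or 'compartmental'")
        self.exc_cells = list(exc_cells)
        self.inh_cells = list(inh_cells)
        self.stimuli = list(stimuli)
        self.template = template
        self.readout = readout
        self.morph = morph
        self.passive = passive or PassiveProperties()
        self.dt_v = dt_v
        self.hh = hh
        self.response_scale = response_scale
        self.presyn_spike_seed = presyn_spike_seed
        #: optional map from the search-space genome to the circuit genome,
        #: used e.g. to confine the search to one solution branch
        self.transform = transform
        self.n_evaluations = 0

        free = {s.name for s in template.free_specs}
        self._spatial_free = any(_strip_inh(n)[0] in _SPATIAL_PARAMS for n in free)
        self._area_cache: Optional[list[np.ndarray]] = None
        if not self._spatial_free:
            base = self._all_cells(template)
            self._area_cache = [population_areas(base, stim)
                                for _, _, stim in self.stimuli]
        if readout == "compartmental":
            if morph is None:
                raise ValueError("compartmental read-out requires a morphology")
            all_cells = self.exc_cells + self.inh_cells
            self.sites = place_synapses(all_cells, morph, mode=placement_mode,
                                        seed=placement_seed, g_scale=g_scale,
                                        g_scale_inh=g_scale_inh)
        else:
            self.sites = None

    # -- helpers ----------------------------------------------------------

    def _all_cells(self, genome: Genome) -> list[PresynapticCell]:
        if self.transform is not None:
            genome = self.transform(genome)
        cells = _apply_params(self.exc_cells, genome, inhibitory=False)
        if self.inh_cells:
            cells += _apply_params(self.inh_cells, genome, inhibitory=True)
        return cells

    def _passive_for(self, genome: Genome) -> PassiveProperties:
        kw = {}
        names = {s.name for s in genome.specs}
        if "g_pas" in names:
            kw["g_pas"] = float(genome["g_pas"][0])
        if "r_a" in names:
            kw["r_a"] = float(genome["r_a"][0])
        return replace(self.passive, **kw) if kw else self.passive

    def release_traces(self, genome: Genome, stim_index: int) -> np.ndarray:
        """(n_frames, n_cells) release for one stimulus of the protocol."""
        cells = self._all_cells(genome)
        areas = self._area_cache[stim_index] if self._area_cache is not None else None
        release = population_release(cells, self.stimuli[stim_index][2], areas=areas)
        if self.presyn_spike_seed is not None:
            release = self._spiking_release(release, self.stimuli[stim_index][2].dt,
                                            stim_index)
        return release

    def _spiking_release(self, release: np.ndarray, dt: float,
                         stim_index: int) -> np.ndarray:
        """Replace graded release by spike-driven conductance pulses.

        Spikes are drawn per cell from the release trace and convolved
        with a 2 ms exponential synaptic kernel.
        """
        tau_syn = 2.0
        T, C = release.shape
        out = np.zeros_like(release)
        kern_decay = np.exp(-dt / tau_syn)
        for c in range(C):
            tr = ConductanceTrace(release[:, c], dt)
            _, spikes = presynaptic_spike_train(
                tr, seed=self.presyn_spike_seed + 1000 * stim_index + c)
            g = 0.0
            for t in range(T):
                g = g * kern_decay + (1.0 if spikes[t] else 0.0)
                out[t, c] = g
        return out

    def response_to(self, genome: Genome, stimulus: Stimulus,
                    spike_seed_offset: int = 0) -> float:
        """Response magnitude to an arbitrary stimulus (no caching)."""
        cells = self._all_cells(genome)
        release = population_release(cells, stimulus)
        if self.presyn_spike_seed is not None:
            release = self._spiking_release(release, stimulus.dt,
                                            1000 + spike_seed_offset)
        return self._readout(genome, release, stimulus.dt)

    def _readout(self, genome: Genome, release: np.ndarray, trace_dt: float) -> float:
        if self.readout == "linear":
            n_exc = len(self.exc_cells)
            det = release[:, :n_exc].sum(axis=1)
            if self.inh_cells:
                det = det - release[:, n_exc:].sum(axis=1)
            return float(det.max(initial=0.0))
        passive = self._passive_for(genome)
        vt = simulate_compartmental(self.morph, passive, self.sites, release,
                                    trace_dt=trace_dt, dt=self.dt_v, hh=self.hh)
        return vt.peak_depolarization

    def response(self, genome: Genome, stim_index: int) -> float:
        """Scalar response magnitude (peak) for one stimulus."""
        release = self.release_traces(genome, stim_index)
        return self._readout(genome, release, self.stimuli[stim_index][2].dt)

    def positions_along_axis(self, axis_direction: float = 0.0) -> np.ndarray:
        """Excitatory RF-centre projections on the preferred axis (µm)."""
        c, s = np.cos(axis_direction), np.sin(axis_direction)
        return np.array([cell.center.center_x * c + cell.center.center_y * s
                         for cell in self.exc_cells])

    def find_stimulus(self, speed: float, direction: float) -> int:
        for i, (sp, d, _) in enumerate(self.stimuli):
            if np.isclose(sp, speed) and np.isclose(d % (2 * np.pi), direction % (2 * np.pi)):
                return i
        raise KeyError(f"no stimulus at speed={speed}, direction={direction}")

    # -- the fitness contract --------------------------------------------

    def evaluate(self, genome: Genome) -> EvalResult:
        """Directional metric DSI * tanh(max R), averaged over speeds."""
        self.n_evaluations += 1
        cells = self._all_cells(genome)
        weights = None
        if self._area_cache is None:
            arenas = {s.arena for _, _, s in self.stimuli}
            if len(arenas) == 1:  # one Gaussian-map build serves all stimuli
                weights = population_weights(cells, next(iter(arenas)))
        by_speed: dict[float, list[tuple[float, float]]] = {}
        for i, (speed, direction, stim) in enumerate(self.stimuli):
            if self._area_cache is not None:
                areas = self._area_cache[i]
            else:
                areas = population_areas(cells, stim, weights=weights)
            release = population_release(cells, stim, areas=areas)
            if self.presyn_spike_seed is not None:
                release = self._spiking_release(release, stim.dt, i)
            r = max(0.0, self._readout(genome, release, stim.dt))
            by_speed.setdefault(speed, []).append((direction, r))
        dsi_per_speed, responses, metrics = {}, {}, []
        max_r = 0.0
        for speed, pairs in by_speed.items():
            dirs = np.array([p[0] for p in pairs])
            rs = np.array([p[1] for p in pairs])
            d = dsi(rs, dirs)
            dsi_per_speed[speed] = d
            responses[speed] = rs
            mr = float(rs.max(initial=0.0))
            max_r = max(max_r, mr)
            metrics.append(d * np.tanh(self.response_scale * mr))
        return EvalResult(fitness=float(np.mean(metrics)),
                          dsi_per_speed=dsi_per_speed,
                          responses=responses, max_response=max_r)


# ---------------------------------------------------------------------------
# The minimal two-input weight-asymmetry model


def build_minimal_weight_backend(
    separation: float = 160.0,
    rf_size: float = 15.0,
    speed: float = 1.0,
    arena: Optional[Arena] = None,
    weight_bounds: tuple[float, float] = (0.0, 1.0),
    kinetic_init_high: float = 300.0,
    branch: str = "free",
) -> tuple[CircuitBackend, Genome]:
    """The two-cell linear-detector circuit with free synaptic weights.

    Two presynaptic cells with identical, jointly evolvable rise/decay
    kinetics sit ``separation`` µm apart along the preferred axis; a
    linear detector sums their waveforms.  DSI is computed from two
    opposite directions at a single velocity.

    ``branch="reversed"`` confines the search to the alternative
    solution branch in which the input recruited first in the
    preferred direction is the stronger one: the weights are
    reparametrized as (w_lead, w_lead * w_ratio) with w_ratio in
    [0, 1], so the weight ordering cannot flip during evolution.
    """
    arena = arena or Arena(width=800.0, height=800.0, pixel_size=10.0, dt=5.0)
    from .receptive_fields import RFComponent

    cells = [
        PresynapticCell(
            center=RFComponent(center_x=x, center_y=0.0, size_x=rf_size,
                               size_y=rf_size, adaptation_enabled=True),
            group_id=g, cell_id=g)
        for g, x in enumerate((-separation / 2.0, separation / 2.0))
    ]
    kinetics = (
        ParamSpec("rise_time", 10.0, 10000.0, size=2, shared=True,
                  init_high=kinetic_init_high),
        ParamSpec("decay_time", 10.0, 10000.0, size=2, shared=True,
                  init_high=kinetic_init_high),
    )
    stimuli = make_bar_protocol(arena, speeds=(speed,), directions=(0.0, np.pi))
    if branch == "free":
        template = Genome(specs=(
            ParamSpec("syn_weight", *weight_bounds, size=2, shared=False),
        ) + kinetics)
        backend = CircuitBackend(cells, stimuli, template, readout="linear")
        return backend, template
    if branch != "reversed":
        raise ValueError("branch must be 'free' or 'reversed'")
    circuit_specs = (ParamSpec("syn_weight", *weight_bounds, size=2),) + kinetics
    template = Genome(specs=(
        ParamSpec("w_lead", *weight_bounds, size=1),
        ParamSpec("w_ratio", 0.0, 1.0, size=1),
    ) + kinetics)

    def _to_circuit(genome: Genome) -> Genome:
        w = float(genome["w_lead"][0])
        return Genome(circuit_specs, {
            "syn_weight": np.array([w, w * float(genome["w_ratio"][0])]),
            "rise_time": genome["rise_time"].copy(),
            "decay_time": genome["decay_time"].copy(),
        })

    backend = CircuitBackend(cells, stimuli, template, readout="linear",
                             transform=_to_circuit)
    return backend, template


def build_point_backend(
    kind: str,
    n_cells: int = 4,
    spacing: float = 60.0,
    rf_size: float = 30.0,
    speed: float = 1.0,
    directions: Sequence[float] = (0.0, np.pi),
    arena: Optional[Arena] = None,
    kinetic_init_high: float = 300.0,
) -> tuple[CircuitBackend, Genome]:
    """Point-detector circuit: n cells along the preferred axis, linear sum.

    ``kind`` selects the evolvable template:

    * "kinetic" — per-group response delay, rise and decay times are
      free; spatial receptive fields are identical (delay-and-compare
      solutions of the H&R family);
    * "rfsize" — per-group RF size is free with shared fixed kinetics
      (spatial solutions of the anti-H&R family).

    Each cell forms its own input group, evenly spaced ``spacing`` µm
    apart and centred on the arena.  The default arena is short along
    y: for full-height bars the perpendicular extent cancels exactly in
    the normalized overlap, so a narrow strip gives identical responses
    at a fraction of the rendering cost.
    """
    arena = arena or Arena(width=800.0, height=200.0, pixel_size=10.0, dt=5.0)
    from .receptive_fields import RFComponent

    xs = (np.arange(n_cells) - (n_cells - 1) / 2.0) * spacing
    cells = [
        PresynapticCell(
            center=RFComponent(center_x=float(x), center_y=0.0, size_x=rf_size,
                               size_y=rf_size, rise_time=30.0, decay_time=150.0,
                               adaptation_enabled=True),
            group_id=g, cell_id=g)
        for g, x in enumerate(xs)
    ]
    if kind == "kinetic":
        template = Genome(specs=(
            ParamSpec("response_delay", 0.0, 50.0, size=n_cells),
            ParamSpec("rise_time", 10.0, 10000.0, size=n_cells,
                      init_high=kinetic_init_high),
            ParamSpec("decay_time", 10.0, 10000.0, size=n_cells,
                      init_high=kinetic_init_high),
        ))
    elif kind == "rfsize":
        # spatial template: per-group sizes plus jointly evolvable shared
        # kinetics, so the search can pick the kinetic regime in which
        # size differences translate into response timing
        template = Genome(specs=(
            ParamSpec("size", 10.0, 200.0, size=n_cells),
            ParamSpec("rise_time", 10.0, 10000.0, size=n_cells, shared=True,
                      init_high=kinetic_init_high),
            ParamSpec("decay_time", 10.0, 10000.0, size=n_cells, shared=True,
                      init_high=10.0 * kinetic_init_high),
        ))
    else:
        raise ValueError("kind must be 'kinetic' or 'rfsize'")
    stimuli = make_bar_protocol(arena, speeds=(speed,), directions=tuple(directions))
    backend = CircuitBackend(cells, stimuli, template, readout="linear")
    return backend, template
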