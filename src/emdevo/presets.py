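"""Experiment presets: packaged circuit-evolution scenarios.

Each preset captures one published experiment family — which
receptive-field parameters are free to evolve, which are shared across
input groups, the stimulus protocol and the postsynaptic back-end —
as a plain, YAML-serializable :class:`ExperimentConfig`.

Presets come in two scales.  ``"full"`` reproduces the stated
campaign conditions (800 µm arena, 100 presynaptic cells per
population, 12 directions x 5 speeds, 352-segment arbor, 0.1 ms
voltage step, 300 generations).  ``"desk"`` is the package's reduced
study condition for interactive use and testing: a 500 µm arena at
10 µm pixels, 32 cells in 4 groups, 4 directions at 1 mm/s, a
144-segment surrogate arbor, 1 ms voltage step and 100 generations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .backends import (CircuitBackend, build_minimal_weight_backend,
                       build_point_backend, make_bar_protocol)
from .cable import HHSoma, PassiveProperties
from .evolution import EvolutionConfig, Genome, ParamSpec, RunResult, evolve
from .metrics import classify_primitives, dsi
from .morphology import generate_dsgc_morphology, generate_pyramidal_morphology
from .receptive_fields import (PlasticityParams, PresynapticCell, RFComponent,
                               assign_groups, random_population)
from .stimuli import Arena, default_directions

__all__ = ["ExperimentConfig", "load_preset", "preset_names", "build_backend",
           "run_experiment", "report"]

_BACKENDS = ("minimal", "point", "compartmental", "cortical")

#: parameter clip bounds from the training recipe (initialization and
#: mutation share the same biologically motivated limits)
_BOUNDS = {
    "response_delay": (0.0, 50.0),
    "rise_time": (10.0, 10000.0),
    "decay_time": (10.0, 10000.0),
    "size": (10.0, 200.0),
    "size_x": (10.0, 200.0),
    "size_y": (10.0, 200.0),
    "orientation": (0.0, np.pi),
    "syn_weight": (0.0, 1.0),
    "surround_strength": (0.0, 1.0),
    "surround_size": (10.0, 400.0),
    "surround_rise": (10.0, 10000.0),
    "surround_decay": (10.0, 10000.0),
    "surround_delay": (0.0, 50.0),
    "dep_amp": (0.0, 1.0),
    "dep_tau": (10.0, 10000.0),
    "fac_amp": (0.0, 1.0),
    "fac_tau": (10.0, 10000.0),
    "g_pas": (1e-5, 1e-3),
    "r_a": (50.0, 200.0),
}
_KINETIC_INIT_HIGH = 300.0


@dataclass
class ExperimentConfig:
    """A fully specified, serializable circuit-evolution experiment."""

    name: str
    backend: str
    scale: str = "desk"
    seed: int = 0
    arena: dict = field(default_factory=dict)
    speeds: list = field(default_factory=lambda: [1.0])
    directions: list = field(default_factory=list)
    n_exc: int = 32
    n_inh: int = 0
    n_groups: int = 4
    rf_radius: float = 150.0
    base_exc: dict = field(default_factory=dict)
    base_inh: Optional[dict] = None
    free_params: list = field(default_factory=list)
    morphology: Optional[dict] = None
    placement: dict = field(default_factory=dict)
    dt_v: float = 1.0
    ga: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.backend not in _BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}; choose from {_BACKENDS}")
        if self.n_exc < 1:
            raise ValueError("n_exc must be positive")
        for p in self.free_params:
            if "name" not in p:
                raise ValueError("free parameter entries need a 'name'")
            if "low" not in p or "high" not in p:
                raise ValueError(f"free parameter {p['name']!r} needs bounds")
        per_kinds = {p.get("per", "group") for p in self.free_params}
        if "cell" in per_kinds and "group" in per_kinds:
            raise ValueError("per-cell and per-group free parameters cannot mix")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ExperimentConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Preset registry


def _scale_defaults(scale: str) -> dict:
    if scale == "full":
        return dict(
            arena={"width": 800.0, "height": 800.0, "pixel_size": 5.0, "dt": 5.0},
            speeds=[0.25, 0.5, 1.0, 2.0, 4.0],
            directions=default_directions(12).tolist(),
            n_exc=100, n_groups=4, rf_radius=150.0,
            morphology={"kind": "dsgc", "n_segments": 352, "radius": 150.0, "seed": 0},
            dt_v=0.1,
            ga={"population_size": 10, "generations": 300,
                "mutation_sd": 0.10, "additive_range": 0.015, "n_elite": 1},
        )
    if scale == "desk":
        return dict(
            arena={"width": 500.0, "height": 500.0, "pixel_size": 10.0, "dt": 5.0},
            speeds=[1.0],
            directions=default_directions(4).tolist(),
            n_exc=32, n_groups=4, rf_radius=150.0,
            morphology={"kind": "dsgc", "n_segments": 144, "radius": 150.0, "seed": 0},
            dt_v=1.0,
            ga={"population_size": 10, "generations": 100,
                "mutation_sd": 0.10, "additive_range": 0.015, "n_elite": 1},
        )
    raise ValueError("scale must be 'desk' or 'full'")


_BASE_EXC = {"size": 50.0, "rise_time": 30.0, "decay_time": 150.0,
             "adaptation": True, "syn_weight": 1.0}
_BASE_SURROUND = {"surround": True, "surround_size": 100.0, "surround_rise": 60.0,
                  "surround_decay": 300.0, "surround_strength": 0.6}


def _free(name, shared=False, per="group", **kw) -> dict:
    low, high = _BOUNDS[name.removeprefix("inh_")]
    entry = {"name": name, "low": low, "high": high, "shared": shared, "per": per}
    base = name.removeprefix("inh_")
    if base in ("rise_time", "decay_time", "surround_rise", "surround_decay",
                "dep_tau", "fac_tau"):
        entry["init_high"] = _KINETIC_INIT_HIGH
    entry.update(kw)
    return entry


def _compartmental(name, scale, free_params, base_exc=None, base_inh=None,
                   n_inh=0, protocol=None) -> ExperimentConfig:
    d = _scale_defaults(scale)
    return ExperimentConfig(
        name=name, backend="compartmental", scale=scale,
        base_exc={**_BASE_EXC, **(base_exc or {})},
        base_inh={**_BASE_EXC, **(base_inh or {})} if n_inh else None,
        n_inh=n_inh, free_params=free_params,
        placement={"mode": "retina", "g_scale": 1.0, "g_scale_inh": 4.0,
                   "e_rev_inh": -70.0},
        protocol=protocol or {}, **d)


def _shared_center_kinetics(prefix: str = "") -> list[dict]:
    """Jointly evolvable center kinetics (one value for all groups).

    The decay (RRP depletion) constant is initialized over a wide
    range because its relevant regimes extend to effectively
    non-depleting kinetics.
    """
    return [_free(prefix + "rise_time", shared=True, per="global"),
            _free(prefix + "decay_time", shared=True, per="global",
                  init_high=3000.0)]


def _preset_fig1b(scale):
    return _compartmental("fig1b_kinetic", scale, [
        _free("response_delay"), _free("rise_time"), _free("decay_time")])


def _preset_fig1c(scale):
    return _compartmental("fig1c_rfsize", scale,
                          [_free("size")] + _shared_center_kinetics())


def _preset_fig1d(scale):
    return _compartmental("fig1d_orientation", scale,
                          [_free("orientation")] + _shared_center_kinetics(),
                          base_exc={"size_x": 25.0, "size_y": 75.0})


def _preset_fig2_strength(scale):
    return _compartmental("fig2_surround_strength", scale,
                          [_free("surround_strength")] + _shared_center_kinetics(),
                          base_exc=_BASE_SURROUND)


def _preset_fig2_kinetics(scale):
    return _compartmental("fig2_surround_kinetics", scale,
                          [_free("surround_rise"),
                           _free("surround_decay", init_high=3000.0)]
                          + _shared_center_kinetics(),
                          base_exc=_BASE_SURROUND)


def _preset_fig2_extent(scale):
    return _compartmental("fig2_surround_extent", scale,
                          [_free("surround_size")] + _shared_center_kinetics(),
                          base_exc=_BASE_SURROUND)


def _preset_fig3_weights(scale):
    return _compartmental("fig3_weights", scale,
                          [_free("syn_weight", per="cell")]
                          + _shared_center_kinetics())


def _preset_fig3_minimal(scale):
    d = _scale_defaults(scale)
    return ExperimentConfig(
        name="fig3_minimal", backend="minimal", scale=scale,
        arena={"width": 800.0, "height": 800.0, "pixel_size": 10.0, "dt": 5.0},
        speeds=[1.0], directions=[0.0, float(np.pi)], n_exc=2, n_groups=2,
        ga=d["ga"], protocol={"separation": 160.0, "rf_size": 15.0, "branch": "free"})


def _inh_preset(name, scale, free_params, base_inh=None):
    n_inh = 32 if scale == "desk" else 100
    return _compartmental(name, scale, free_params, base_inh=base_inh, n_inh=n_inh)


def _shared_inh_kinetics() -> list[dict]:
    return _shared_center_kinetics("inh_") + [
        _free("inh_response_delay", shared=True, per="global")]


def _preset_fig5b(scale):
    return _inh_preset("fig5b_inh_kinetics", scale, [
        _free("inh_response_delay"), _free("inh_rise_time"),
        _free("inh_decay_time", init_high=3000.0)])


def _preset_fig5c(scale):
    return _inh_preset("fig5c_inh_rfsize", scale,
                       [_free("inh_size")] + _shared_inh_kinetics())


def _preset_fig5df(scale):
    return _inh_preset("fig5d-f_inh_surround", scale, [
        _free("inh_surround_strength"), _free("inh_surround_size"),
        _free("inh_surround_rise"),
        _free("inh_surround_decay", init_high=3000.0)]
        + _shared_inh_kinetics(),
        base_inh=_BASE_SURROUND)


def _preset_fig7(scale):
    cfg = _compartmental("fig7_cortical", scale, [
        _free("response_delay"), _free("rise_time"), _free("decay_time")])
    cfg.backend = "cortical"
    cfg.rf_radius = 200.0
    cfg.morphology = {"kind": "pyramidal", "n_segments": 69, "seed": 0}
    cfg.placement = {"mode": "cortex", "g_scale": 1.0, "e_rev_inh": -70.0}
    return cfg


def _preset_fig8(scale):
    d = _scale_defaults(scale)
    return ExperimentConfig(
        name="fig8_noise", backend="point", scale=scale,
        arena={"width": 800.0, "height": 200.0, "pixel_size": 10.0, "dt": 5.0},
        speeds=[1.0], directions=[0.0, float(np.pi)], n_exc=4, n_groups=4,
        ga=d["ga"],
        protocol={"kind": "kinetic",
                  "noise_levels": [0.0, 1.0, 2.5, 5.0],
                  "n_trials": 50 if scale == "full" else 20})


def _preset_fig9(scale):
    d = _scale_defaults(scale)
    return ExperimentConfig(
        name="fig9_mapping", backend="point", scale=scale,
        arena={"width": 800.0, "height": 200.0, "pixel_size": 10.0, "dt": 5.0},
        speeds=[1.0], directions=[0.0, float(np.pi)], n_exc=4, n_groups=4,
        ga=d["ga"],
        protocol={"kind": "kinetic", "mapping": True,
                  "mapping_duration": 60000.0 if scale == "full" else 20000.0,
                  "mapping_bar_width": 20.0, "mapping_update": 50.0})


def _preset_symmetric(scale):
    return _compartmental("symmetric_control", scale, [
        _free("rise_time", shared=True),
        _free("decay_time", shared=True, init_high=3000.0),
        _free("size", shared=True)])


_PRESETS = {
    "fig1b_kinetic": _preset_fig1b,
    "fig1c_rfsize": _preset_fig1c,
    "fig1d_orientation": _preset_fig1d,
    "fig2_surround_strength": _preset_fig2_strength,
    "fig2_surround_kinetics": _preset_fig2_kinetics,
    "fig2_surround_extent": _preset_fig2_extent,
    "fig3_weights": _preset_fig3_weights,
    "fig3_minimal": _preset_fig3_minimal,
    "fig5a_inh_weights": lambda s: _inh_preset(
        "fig5a_inh_weights", s,
        [_free("inh_syn_weight")] + _shared_inh_kinetics()),
    "fig5b_inh_kinetics": _preset_fig5b,
    "fig5c_inh_rfsize": _preset_fig5c,
    "fig5d-f_inh_surround": _preset_fig5df,
    "fig7_cortical": _preset_fig7,
    "fig8_noise": _preset_fig8,
    "fig9_mapping": _preset_fig9,
    "symmetric_control": _preset_symmetric,
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def load_preset(name: str, scale: str = "desk", **overrides) -> ExperimentConfig:
    """Fully populated, validated configuration for a named scenario."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}")
    cfg = _PRESETS[name](scale)
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise AttributeError(f"ExperimentConfig has no field {key!r}")
        setattr(cfg, key, val)
    return ExperimentConfig.from_dict(cfg.to_dict())  # re-validate


# ---------------------------------------------------------------------------
# Backend construction


def _cell_from_base(base: dict, polarity: str) -> PresynapticCell:
    center = RFComponent(
        size_x=base.get("size_x", base.get("size", 50.0)),
        size_y=base.get("size_y", base.get("size", 50.0)),
        orientation=base.get("orientation", 0.0),
        rise_time=base.get("rise_time", 30.0),
        decay_time=base.get("decay_time", 150.0),
        response_delay=base.get("response_delay", 0.0),
        adaptation_enabled=base.get("adaptation", True),
    )
    surround = None
    if base.get("surround"):
        surround = RFComponent(
            size_x=base.get("surround_size", 100.0),
            size_y=base.get("surround_size", 100.0),
            rise_time=base.get("surround_rise", 60.0),
            decay_time=base.get("surround_decay", 300.0),
            response_delay=base.get("surround_delay", 0.0),
            adaptation_enabled=base.get("adaptation", True),
        )
    plast = PlasticityParams(
        dep_amp=base.get("dep_amp", 0.0), dep_tau=base.get("dep_tau", 200.0),
        fac_amp=base.get("fac_amp", 0.0), fac_tau=base.get("fac_tau", 200.0),
        dep_enabled=base.get("dep_enabled", False),
        fac_enabled=base.get("fac_enabled", False),
    )
    return PresynapticCell(
        center=center, surround=surround,
        syn_weight=base.get("syn_weight", 1.0),
        surround_strength=base.get("surround_strength", 0.0),
        plasticity=plast, polarity=polarity,
        mode=base.get("mode", "graded"))


def _build_specs(config: ExperimentConfig) -> tuple[ParamSpec, ...]:
    specs = []
    for p in config.free_params:
        per = p.get("per", "group")
        if per == "global" or p["name"] in ("g_pas", "r_a"):
            size = 1
        elif per == "cell":
            size = config.n_inh if p["name"].startswith("inh_") else config.n_exc
        else:
            size = config.n_groups
        specs.append(ParamSpec(
            p["name"], p["low"], p["high"], size=size,
            shared=p.get("shared", False),
            init_low=p.get("init_low"), init_high=p.get("init_high")))
    return tuple(specs)


def build_backend(config: ExperimentConfig):
    """Instantiate the circuit backend and genome template for a config."""
    if config.backend == "minimal":
        proto = config.protocol
        arena = Arena(**config.arena) if config.arena else None
        return build_minimal_weight_backend(
            separation=proto.get("separation", 160.0),
            rf_size=proto.get("rf_size", 15.0),
            speed=config.speeds[0], arena=arena,
            branch=proto.get("branch", "free"),
            kinetic_init_high=proto.get("kinetic_init_high", _KINETIC_INIT_HIGH))
    if config.backend == "point":
        return build_point_backend(
            config.protocol.get("kind", "kinetic"), n_cells=config.n_exc,
            arena=Arena(**config.arena) if config.arena else None,
            speed=config.speeds[0], directions=tuple(config.directions))

    arena = Arena(**config.arena)
    ss = np.random.SeedSequence(config.seed)
    pos_seed, place_seed, spike_seed = [int(s.generate_state(1)[0] % (2**31))
                                        for s in ss.spawn(3)]
    per_cell = any(p.get("per") == "cell" for p in config.free_params)
    rng = np.random.default_rng(pos_seed)
    exc = random_population(config.n_exc, rng, radius=config.rf_radius,
                            template=_cell_from_base(config.base_exc, "excitatory"))
    if per_cell:
        for i, c in enumerate(exc):
            c.group_id = i
    else:
        assign_groups(exc, 0.0, config.n_groups)
    inh = []
    if config.n_inh:
        inh = random_population(config.n_inh, rng, radius=config.rf_radius,
                                template=_cell_from_base(config.base_inh or config.base_exc,
                                                         "inhibitory"))
        for i, c in enumerate(inh):
            c.cell_id = config.n_exc + i
        if per_cell:
            for i, c in enumerate(inh):
                c.group_id = i
        else:
            assign_groups(inh, 0.0, config.n_groups)

    m = config.morphology or {}
    if m.get("kind", "dsgc") == "dsgc":
        morph = generate_dsgc_morphology(m.get("n_segments", 144),
                                         m.get("radius", 150.0), m.get("seed", 0))
    else:
        morph = generate_pyramidal_morphology(m.get("n_segments", 69),
                                              m.get("seed", 0))
    template = Genome(specs=_build_specs(config))
    hh = None
    if config.protocol.get("spiking_soma"):
        hh = HHSoma()
    spiking = config.backend == "cortical"
    if spiking:
        for c in exc + inh:
            c.mode = "spiking"
    backend = CircuitBackend(
        exc, make_bar_protocol(arena, speeds=tuple(config.speeds),
                               directions=tuple(config.directions)),
        template, inh_cells=inh, readout="compartmental", morph=morph,
        dt_v=config.dt_v,
        g_scale=config.placement.get("g_scale", 1.0),
        g_scale_inh=config.placement.get("g_scale_inh"),
        placement_mode=config.placement.get("mode",
                                            "cortex" if spiking else "retina"),
        placement_seed=place_seed, hh=hh,
        presyn_spike_seed=spike_seed if spiking else None)
    return backend, template


# ---------------------------------------------------------------------------
# Orchestration


def run_experiment(config: ExperimentConfig, out: Optional[str] = None) -> dict:
    """Run one evolution campaign for a config and collect its metrics.

    Returns (and optionally writes, as HDF5) a self-contained archive:
    configuration snapshot, per-generation best fitness, the best
    genome, per-speed DSI, and — where the protocol asks for them —
    primitive-space coordinates, a noise-robustness curve or a
    space-time map.
    """
    backend, template = build_backend(config)
    ga_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31))
    ga = EvolutionConfig(seed=ga_seed, **config.ga) if config.ga else \
        EvolutionConfig(seed=ga_seed)
    result = evolve(ga, template, backend)
    best = result.best_genome
    archive: dict = {
        "config_yaml": config.to_yaml(),
        "name": config.name,
        "seed": config.seed,
        "ga_seed": ga_seed,
        "best_fitness": result.best_fitness,
        "n_evaluations": result.n_evaluations,
        "genome": {k: v for k, v in best.values.items()},
        "dsi_per_speed": {str(s): d for s, d in
                          result.best_eval.dsi_per_speed.items()},
        "mean_dsi": result.best_eval.mean_dsi,
        "max_response": result.best_eval.max_response,
        "bounds": {s.name: [s.low, s.high] for s in best.specs},
    }

    if config.backend in ("point", "compartmental") and len(backend.exc_cells) >= 2:
        try:
            idx = backend.find_stimulus(config.speeds[0], 0.0)
            release = backend.release_traces(best, idx)
            n_exc = len(backend.exc_cells)
            exc_traces = release[:, :n_exc].T
            kw = {}
            if backend.inh_cells:
                null_idx = backend.find_stimulus(config.speeds[0], np.pi)
                release_null = backend.release_traces(best, null_idx)
                kw = dict(exc_drive_pref=release[:, :n_exc].sum(axis=1),
                          inh_drive_pref=release[:, n_exc:].sum(axis=1),
                          inh_drive_null=release_null[:, n_exc:].sum(axis=1))
            coords = classify_primitives(
                exc_traces, backend.positions_along_axis(), config.arena.get("dt", 5.0)
                if config.arena else 5.0,
                dsi_value=result.best_eval.mean_dsi, **kw)
            archive["primitives"] = {
                "x": coords.x, "y": coords.y,
                "x_inh": coords.x_inh, "y_inh": coords.y_inh,
                "present": sorted(coords.present),
            }
        except (ValueError, KeyError):
            pass

    if config.protocol.get("noise_levels"):
        from .metrics import noise_robustness_curve
        from .stimuli import make_variable_velocity_bar
        arena = backend.stimuli[0][2].arena

        def respond(noise_sd, direction, trial_seed):
            stim = make_variable_velocity_bar(arena, direction, noise_sd,
                                              seed=trial_seed,
                                              base_speed=config.speeds[0])
            return backend.response_to(best, stim)

        curve = noise_robustness_curve(
            respond, noise_levels=config.protocol["noise_levels"],
            n_trials=config.protocol.get("n_trials", 20), seed=config.seed)
        archive["noise"] = {k: v for k, v in curve.items() if k != "trials"}

    if config.protocol.get("mapping"):
        from .metrics import spacetime_map
        from .receptive_fields import population_release
        from .stimuli import make_1d_bar_noise
        arena = backend.stimuli[0][2].arena
        stim = make_1d_bar_noise(
            arena, bar_width=config.protocol.get("mapping_bar_width", 20.0),
            update_interval=config.protocol.get("mapping_update", 50.0),
            seed=config.seed,
            duration=config.protocol.get("mapping_duration", 20000.0))
        release = population_release(backend._all_cells(best), stim)
        detector = release[:, :len(backend.exc_cells)].sum(axis=1)
        st = spacetime_map(detector, stim.dt, stim)
        archive["spacetime"] = {"values": st.values,
                                "bar_positions": st.bar_positions,
                                "bin_times": st.bin_times,
                                "event_counts": st.event_counts}

    if out is not None:
        from .io import save_archive
        save_archive(archive, out)
    return archive


def report(archive: dict) -> str:
    """Human-readable summary of a run archive."""
    lines = [f"experiment: {archive.get('name', '?')}",
             f"seed: {archive.get('seed')}  (GA seed {archive.get('ga_seed')})",
             f"evaluations: {archive.get('n_evaluations')}"]
    hist = np.asarray(archive.get("best_fitness", []))
    if hist.size:
        lines.append(f"best fitness: {hist[-1]:.4f} "
                     f"(generation 0: {hist[0]:.4f}, n={hist.size})")
    dps = archive.get("dsi_per_speed", {})
    if dps:
        lines.append("DSI per speed (mm/s):")
        for s in sorted(dps, key=float):
            lines.append(f"  {float(s):5.2f}: {100 * float(dps[s]):6.2f}%")
    lines.append(f"mean DSI: {100 * float(archive.get('mean_dsi', 0.0)):.2f}%")
    genome = archive.get("genome", {})
    bounds = archive.get("bounds", {})
    if genome:
        lines.append("best genome:")
        for k in sorted(genome):
            vals = np.atleast_1d(np.asarray(genome[k]))
            b = bounds.get(k)
            btxt = f"  bounds [{b[0]:g}, {b[1]:g}]" if b is not None else ""
            lines.append(f"  {k}: {np.array2string(vals, precision=3)}{btxt}")
    prim = archive.get("primitives")
    if prim:
        lines.append(f"primitive coordinates: x={prim['x']:+.3f} y={prim['y']:+.3f}"
                     + (f" x_inh={prim['x_inh']:+.3f} y_inh={prim['y_inh']:+.3f}"
                        if prim.get("x_inh") is not None else ""))
        lines.append(f"primitives present: {', '.join(prim['present']) or 'none'}")
    noise = archive.get("noise")
    if noise is not None:
        lvl = np.asarray(noise["noise_levels"])
        nd = np.asarray(noise["normalized_dsi"])
        lines.append("noise robustness (normalized DSI): "
                     + ", ".join(f"{l:g}->{v:.2f}" for l, v in zip(lvl, nd))
                     + f"  slope {float(noise['slope']):+.3f}")
    return "\n".join(lines)
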