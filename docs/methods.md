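# Methods

`emdevo` simulates and evolves elementary motion detectors: shallow
feedforward circuits in which directionally untuned presynaptic units
converge on a postsynaptic detector whose output is stronger for one
motion direction than the opposite one.

## Stimuli

All stimuli are space–time intensity fields in [0, 1] sampled on a
regular pixel grid over a square arena (default 800 µm wide, 5 µm
pixels, 5 ms frames). Conventions:

* **Moving bar** — a bright (intensity 1) bar on a dark background,
  perpendicular to the motion direction, 1 mm tall, translating at a
  constant speed from the standard set {0.25, 0.5, 1, 2, 4} mm/s
  across up to 12 equally spaced directions. The bar's *temporal*
  width is fixed at 0.2 s, so its spatial width is `speed × 0.2 s` and
  every point in the arena is covered for exactly 0.2 s regardless of
  speed. A fixed spatial width can be requested instead
  (`bar_width=`). Bars are rendered with hard binary edges; no
  anti-aliasing. Near-cardinal direction cosines are snapped to
  {0, ±1} so that mirror-symmetric protocols render mirror-identical
  frames.
* **Drifting grating** — 100% contrast sinusoid on a gray (0.5)
  background, default 1 mm/s, spatial periods
  {100, 200, 400, 800, 1600} µm/cycle.
* **1-D bar noise** — full-height bars (default 20 µm) independently
  set to 0 or 1 with probability ½, redrawn every 20–200 ms.
* **Variable-velocity bar** — a moving bar whose speed is resampled
  every 50 ms from the positive half of N(v₀, σ), σ ≤ 5 mm/s; the
  bar never reverses. The base speed v₀ defaults to 1 mm/s (the
  protocol's reference speed; the source protocol does not state it).

## Presynaptic receptive fields

Each presynaptic cell is a center (plus optional, spatially aligned,
antagonistic surround) 2-D Gaussian. The per-frame overlap

    area_t = Σ_xy stimulus · exp(−(x_θ √ln2 / size_x)² − (y_θ √ln2 / size_y)²)

is normalized by the component's full on-grid Gaussian sum so that
full-field illumination gives `area_t = 1` for every component; this
makes center and surround commensurate and gives the full-field
equivalence property (cells differing only spatially respond
identically to a flash). Note the `size` parameter in this functional
form is a half-width-at-half-maximum scale: the profile falls to half
its peak at a distance `size` from the center.

Activation follows a first-order rise with a depletable
readily-releasable-pool (RRP) state:

    RF_t    = (area_t − RF_{t−1})·Δt/rise + RF_{t−1}·adapt_{t−1}
    adapt_t = max(0, adapt_{t−1} − RF_t·Δt/decay)

As written, the RRP state never recovers within a trial; state is
reset per stimulus presentation. When RRP dynamics are disabled the
adaptation term is held at 1 and the recursion is a linear low-pass
(implemented with `scipy.signal.lfilter`). The decay constant
therefore controls depletion, not the off-kinetics of the response —
with depletion disabled, on- and off-kinetics share the rise constant.
This interplay matters for the minimal weight model (below).

Center and surround are filtered independently, then combined,
scaled, and rectified:

    RF_full = ω_syn · max(0, RF_center − ω_surround · RF_surround).

Short-term depression multiplies release by a factor that starts at 1
(full RRP), is depleted in proportion to release (`dep_amp` ∈ [0,1])
and recovers toward 1 with time constant `dep_tau`; facilitation
accumulates an exponent in [0, 1] (`fac_amp`, decay `fac_tau`) that
multiplies release by `10^syn_fac`, i.e. by at most a factor of ten.
The printed update equations cross-reference facilitation symbols
inside the depression rule; the default implementation reads these as
depression quantities (depression should not depend on facilitation
parameters), and an `as_printed=True` mode preserves the literal
equations for comparison.

Spiking (cortical) presynaptic mode draws, at each step, u ~ U[0, 0.3]
and emits a spike when `u < RF_full`, so that stronger drive produces
more spikes, saturating at one spike per step at drive ≥ 0.3. The
literal comparator (spike when `u > RF_full`, which yields fewer
spikes for stronger drive) is available behind `as_printed=True`.
Spikes are converted to postsynaptic conductance by a 2 ms exponential
kernel of unit amplitude — a minimal synaptic event model chosen
because the event shape is not otherwise specified.

## Postsynaptic models

* **Minimal detector** — a pure weighted sum of two (or more)
  presynaptic waveforms; no cable, no rectification.
* **Passive multicompartment model** — surrogate morphologies stand
  in for published reconstructions: a planar radially branching
  DSGC-like arbor (352 segments, ~150 µm reach; desk scale uses 144
  segments) and an apical/basal pyramidal-like arbor (69 segments).
  Both are grown by seeded stochastic outward branching, round-trip
  through SWC, and have a single root (the soma). Passive defaults:
  g_pas = 4·10⁻⁴ S/cm², C_m = 1 µF/cm², E_rest = −60 mV,
  R_a = 150 Ω·cm; the evolvable ranges are g_pas ∈ [10⁻⁵, 10⁻³] and
  R_a ∈ [50, 200]. The cable equation is integrated by backward Euler
  with a Hines-ordered direct solve on the tree (O(n) per step,
  unconditionally stable; all conductances implicit, so with only
  excitatory input the voltage stays within [E_rest, E_syn]). The
  default voltage step is 0.1 ms (1 ms at desk scale); analytic
  oracle tests (RC charging, two-compartment matrix exponential) are
  run at 5–10 µs steps where first-order accuracy must reach 0.1%.
* **Synapses** — one synapse per presynaptic cell. Retinal placement
  puts RF centers uniformly in a 300 µm circle centered on the soma
  and connects each to the nearest dendritic segment; cortical
  placement covers 400 µm and picks uniformly random branches.
  Conductance scale: 1 nS per unit of release, calibrated so one
  maximal synapse depolarizes the surrogate DSGC soma by ~1 mV.
  Inhibitory synapses reverse at −70 mV (shunting-hyperpolarizing;
  not stated in the source, configurable) and default to 4 nS per
  unit release: because the inhibitory driving force near rest
  (~10 mV) is an order of magnitude below the excitatory one
  (~60 mV), a larger unitary conductance is required for inhibition
  to be able to veto excitation at all — the premise of the
  Barlow–Levick-style mechanisms.
* **Spiking soma (optional)** — classic squid-axon Na/K kinetics at
  the soma only, densities 1.0 and 0.2 S/cm² (10,000 and
  2000 pS/µm²), E_Na = +50 mV, E_K = −77 mV; spikes are counted as
  upward 0 mV crossings.

## Fitness and the genetic algorithm

Per speed, the direction selectivity index is the vector sum
DSI = Σ R_θ cosθ / Σ R_θ with θ = 0 the designated preferred
direction and R_θ the peak somatic depolarization above rest, floored
at 0 (for gratings, the peak-to-peak voltage over the final 30% of
the trial). The fitness of a genome is the mean over speeds of
DSI · tanh(max R_θ); responses enter tanh in mV, so the reward for
response amplitude saturates around a few millivolts of somatic
depolarization (the scale is configurable; the source states no
units).

The GA holds 10 models per generation; the best model seeds the next
generation, one copy kept intact (elitism) and nine mutated. Each
free parameter is multiplied by N(1, 0.1) and shifted by
U(−0.015, 0.015) (the additive term is applied literally in each
parameter's native unit), then clipped to its bounds. Shared
parameters mutate once and are copied to all input groups;
independent parameters mutate per group. Initial values are uniform
within the stated ranges: response delay 0–50 ms, center size
10–200 µm, surround size > 10 µm, kinetic and plasticity time
constants > 10 ms (initialization caps these at 300 ms — 3000 ms for
decay constants, whose relevant regimes extend to effectively
non-depleting kinetics), strengths and plasticity factors 0–1. The
elite's fitness is carried over rather than re-evaluated, so best
fitness is exactly non-decreasing with deterministic back-ends.
A brute-force grid search over ≤ 6 free parameters provides an
independent optimization oracle for the minimal models.

The four input groups of the full model are position quantiles along
the designated preferred axis (group 0 = the side a
preferred-direction stimulus enters first); the exact partition rule
is not stated in the source.

## The minimal two-input weight model

Two cells with identical, jointly evolvable rise/decay kinetics and
independent weights w ∈ [0, 1] feed a linear detector; DSI uses two
opposite directions at 1 mm/s. Geometry (not stated in the source):
RF half-width scale 15 µm, separation 160 µm. The mechanism requires
compact, well-separated receptive fields — when the RF scale is
comparable to the separation or the 200 µm bar, spatial smearing
washes out the waveform asymmetry the weight difference exploits.
With waveforms idealized as boxcars of height 1 and a relative tail
φ at the inter-cell lag, the two peak responses are
max(w + φ·1, 1 + ...) — working through the candidates gives
P(weak first) = 1 + wφ and P(strong first) = max(1, w + φ), so the
weak-input-first ordering always wins, with the optimum at
w = φ = ½: DSI = 0.25/2.25 ≈ 11%. The alternative branch (slower
kinetics, reversed weights) is a genuine local optimum separated by
the w₁ = w₂ fitness valley; in this geometry it converges to ~6%
DSI. Because the free campaign almost always finds the global branch,
the alternative branch is characterized by evolution constrained to
it: weights are reparametrized as (w_lead, w_lead·ratio), ratio ∈
[0, 1], so the leading input remains the stronger one, and the search
is initialized in the slow-kinetics regime that defines the branch.

## Primitive-space analysis

For the excitatory axes, per-synapse preferred-direction responses to
a 1 mm/s bar are used. Response duration is the FWHM of the largest
contiguous super-half-maximum interval. The H&R coordinate is signed
by a linear fit of duration against position along the preferred
axis (narrowing → +H&R, widening → −anti-H&R) with magnitude
(1 − narrowest/widest)². The amplitude metric peak-aligns the
normalized waveforms (the alignment anchor is each trace's peak time
— the least parametric reading of "temporally aligned"), requires at
least 75% of waveforms at ≥ 20% of their peaks for overlap, and
averages the population-mean waveform over the active window; the
alignment metric is identical but unaligned with a 25% quorum. The
vertical coordinate is alignment − amplitude.

For the inhibitory axes, the preferred-direction excitatory drive's
area under the curve is split into equal thirds; B&L (anti-B&L) is
the fraction of preferred-direction inhibition in the last (first)
window. amp_inhib = max(0, (ampN − ampP)/(ampN + ampP)) on peak
inhibitory drives per direction; the pause metric, computed only when
both B&L scores are below 20%, replaces ampP by the preferred-
direction peak within the middle window. The B&L axis coordinate is
B&L − anti-B&L; the second inhibitory axis is pause − amp_inhib
(pause-in-inhibition positive, tuned/amplitude inhibition negative) —
the source describes four cardinal segments without giving the
combination rule, so a single signed axis mirrors the excitatory
construction. A primitive is "present" beyond 0.20 from the origin
on its axis; two orthogonal presences make a hybrid.

Noise robustness presents the same variable-velocity trajectory in
the preferred and null directions (shared trial seed), computes
single-trial two-direction DSI, and normalizes per-level means to
the no-noise baseline; noise-dependence slopes come from linear
regression and are compared across model families by one-way ANOVA.
Space-time maps average response fluctuations (onset sample
subtracted) in 20 ms bins after white-bar onsets of a 1-D noise
stimulus, ON phase only; the temporal RF is the central position's
row and the spatial RF the profile at the time of maximal absolute
response.

## Study conditions and desk scale

Paper-scale campaign conditions (800 µm arena at 5 µm pixels, 100
cells per population, 12 directions × 5 speeds, 352-segment arbor,
0.1 ms voltage step, 300 generations, ≥ 50 runs) are preserved in
the `scale="full"` presets. The package's reduced study conditions
(`scale="desk"`), used by the test suite, are: 500 µm arena at 10 µm
pixels for the compartmental scenarios (minimal and point-detector
protocols keep the 800 µm arena width; for full-height bars the
arena height cancels exactly in the normalized overlap, so point
protocols use a 200 µm strip), 32 cells per population in 4 groups,
4–8 directions at 1 mm/s, a 144-segment surrogate arbor, 1 ms
voltage step, and 100–150 generations with ~10–20 runs per campaign.
Under these conditions the evolved kinetic model reaches ~20–23%
DSI, the symmetric control stays near 1% (full-scale control:
2.4%), and the minimal weight model reproduces its two solution
branches at ~10.7% and ~6%. Quantities that depend on the published
morphologies and 100-run campaigns are treated as scaled-down,
ordinal comparisons.

What the synthetic conditions do not emulate: real bipolar/SAC
synaptic noise, light-adaptation and contrast gain control, natural
scene statistics, dendritic active conductances, and the exact
published arbor geometries — so passing tests demonstrate the
computational mechanisms and their ordering, not quantitative
agreement with biological recordings.

## Known limitations

* The RRP "adaptation" state never recovers within a trial (as
  specified); long protocols (noise mapping) therefore run with
  depletion disabled or rely on per-trial state reset.
* Backward Euler is first-order; oracle-grade accuracy needs small
  steps (the dt-halving invariant is satisfied at the default steps
  because synaptic drive is slow relative to the membrane time
  constant).
* Paper-scale presets hold all stimulus frames in memory
  (~1 GB for the full 12-direction × 5-speed protocol at 5 µm
  pixels); campaigns at that scale should stream protocols
  speed-by-speed.
* With only 32 cells and few directions, finite-size placement
  asymmetry contributes ~1–2% DSI to any model, which sets the floor
  visible in the symmetric control.
* In this implementation the RF-size mechanism evolves the expected
  phenotype (receptive fields growing along the preferred axis) but
  its selectivity saturates near 8% DSI across every regime probed
  (kinetic co-tuning, multi-speed protocols, larger arenas, longer
  evolution): with the filtering equations as written, RF size acts
  primarily on response amplitude and only weakly on response
  timing, so size-based circuits behave closer to amplitude-based
  than to delay-and-compare solutions. A downstream consequence is
  that these size-based circuits are *less* tolerant of velocity
  noise than kinetic circuits here (amplitude mechanisms are
  noise-fragile), not more.
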