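# Methods

## The circuit

The model is a four-cell firing-rate circuit representing shape-selective
processing at one spatial location. Two excitatory cells prefer shapes *a*
and *b*; each drives a dedicated inhibitory interneuron that suppresses the
other shape cell (mutual inhibition through disinhibition). A two-location
variant consists of two disjoint copies of this module — the locations
share no connections, so all cross-location effects in cueing experiments
are zero by construction.

Each cell's membrane activity V follows shunting (Grossberg-form) dynamics:

    dV/dt = -decay * V + (B - V) * E(t) - (V + D) * I(t)

with B = `upper_bound`, D = `lower_bound`. Excitatory drive E is gated by
the remaining headroom to the ceiling and inhibitory drive I by the distance
to the floor, so V is confined to [-D, B] regardless of input. Firing rates
are threshold-linear, `rate = max(0, V - gamma)`: zero below the firing
threshold, slope one above. All activities and drives are in arbitrary
simulation units (SU); time is in seconds.

Drives:

* every cell receives the tonic input R through its excitatory input
  synapse — this sets the spontaneous baseline firing;
* stimuli are rectangular pulses (default 200 ms, amplitude `I_exc_on`)
  added to the target cell's input-synapse signal;
* shape cell → interneuron couplings carry weight `W_exc`; interneuron →
  shape cell couplings carry weight `W_inh`;
* global inhibition (GI) pulses enter every cell's inhibitory term with
  unit weight — a minimal stand-in for a voluntary reset signal.

## Habituative synaptic gains (repetition suppression)

Synapses carry a habituative gain g in [0, 1] (a transmitter gate):

    dg/dt = (1 - g)/tau_gain - eta * S(t) * g

where S is the presynaptic signal. The gate recovers toward 1 with time
constant `tau_gain` and is depleted in proportion to the signal it
transmits; at steady signal S it settles at `1/(1 + eta*tau_gain*S)`, so
depletion depth is monotone in eta and eta = 0 pins the gate at 1.

Two synapse classes adapt; the external-input synapses do not.

* the **shape cell → interneuron excitatory coupling** (parameter
  `eta_exc`), whose presynaptic signal is the shape cell's firing rate.
  Because the depleting signal is the cell's own activity, the gain is
  lower whenever baseline or stimulus-evoked firing is higher — the
  circuit's repetition suppression. During a maintained-activity episode
  the elevated cell's output gain sags, which erodes the suppression of
  its competitor; this is why increasing `eta_exc` monotonically weakens
  maintained activity.
* the **interneuron → shape cell inhibitory coupling** (parameter
  `eta_inh`), whose presynaptic signal is the interneuron's firing rate.
  Adaptation here weakens sustained inhibition. Jointly the two adapting
  classes confine the network to the single-equilibrium regime at the
  reference point: with `eta_inh = eta_exc = 0` the disinhibition loop
  latches and the model operates in the dual regime.

## Operating regimes and memory

Briefly stimulating one shape cell triggers a disinhibition loop: the
stimulated cell silences its competitor via the interneuron, which in turn
silences the inhibition returning to the stimulated cell. Depending on
parameters the circuit operates in one of two regimes:

* **single-equilibrium regime** — the baseline (spontaneous) state is the
  unique stable fixed point. The loop slows the return to baseline without
  arresting it: the memory trace decays at a rate set by the distance to
  the regime boundary (critical slowing). This is the functionally useful
  regime: maintained activity is graded with stimulus strength.
* **dual-equilibrium regime** — past a critical mutual-inhibition strength
  (or below a critical baseline drive) a second stable fixed point with
  elevated activity exists and the baseline becomes unstable; any
  perturbation latches and maintained activity is input-independent.

The reference parameter set places the model in the single regime close to
the boundary, which is what makes multi-second memory possible with
sub-second membrane and gate time constants: the slow mode is a network
property, not a cellular one. Near the boundary the leading eigenvalue of
the baseline is real, so the memory decays monotonically rather than by
damped alternation between the two shape cells (the oscillatory decay that
mutual-inhibition-with-adaptation circuits produce when the boundary is
approached through a Hopf bifurcation; the reference set deliberately sits
in the real-eigenvalue corner).

## Analysis machinery

* **Fixed points** are found two ways: a constrained solve that assumes
  all cells are above threshold (removing the rectification leaves a
  smooth algebraic system; solutions violating the assumption are
  discarded) and a multistart rectified root search over a grid of initial
  states (5 levels per cell over [0, B], subsampled when the grid is
  combinatorially large), which catches fixed points with silent cells.
  Gain states are eliminated analytically (`g* = 1/(1+eta*tau*S*)`), so
  the search runs in membrane space. Duplicates merge within 1e-6 SU.
* **Stability** comes from the eigenvalues of the full-system Jacobian
  (membranes + gain states, central differences with step 1e-6); a point
  is unstable if any eigenvalue's real part exceeds 1e-8. For the baseline
  point the label is cross-checked by simulation: +1% of B on one shape
  cell, 60 s relaxation. Only a strong disagreement (settling on a
  different fixed point despite a stable label, or returning exactly to
  baseline despite an unstable label) raises an error — near-critical
  relaxations are slow and inconclusive, and are left to the eigenvalue
  verdict.
* **Regime classification**: dual if a stable fixed point with elevated
  shape-cell activity exists (the baseline is then typically unstable) or
  if the baseline is unstable; single if the baseline is stable and is the
  only stable point. A bistable configuration (stable baseline plus stable
  elevated point) counts as dual — it has two stable equilibria and
  latches under stimulation.
* **Critical parameters** are located by bisection on the classifier
  (default tolerance 1e-3 in parameter units, noise off). When both
  interval endpoints share a regime — as happens for the baseline drive R,
  where the regime is single at both R = 0 and large R with a dual window
  in between — a coarse scan locates the rightmost regime flip and that
  bracket is bisected.

## Measurement conventions

With the standard protocol (pulse onset 5 s, offset 5.2 s, 16 s simulated):
baseline window [2, 5) s, short-term window [5.5, 8.5] s, long-term window
[12, 15] s. Maintained activity is the window mean of the firing rate minus
the baseline-window mean. The transient peak is the maximum rate during the
pulse and the following 300 ms, minus the mean over the 500 ms preceding
the pulse. All windows are configurable.

## Integration

Explicit Euler (Euler–Maruyama with noise) at a fixed step, default
dt = 0.5 ms; the model's time scales (200 ms pulses, multi-second decay)
are orders of magnitude slower, and the step-halving check in the test
suite bounds the rate-trace difference between dt = 1 ms and dt = 0.5 ms.
The analysis and test suites use dt = 1 ms; long relaxations inside the
equilibrium solver use dt = 1 ms over 30–60 s. Membrane noise is additive,
zero-mean, uniform with half-width `noise_amp`, independent per cell and
step, scaled by sqrt(dt) so trajectory statistics are step-size stable;
it enters membrane equations only (gain states are deterministic), and all
analyses run noise-free except the noisy-trace demonstration.
Habituative gains are clamped to [0, 1] after every step (transmitter-gate
semantics).

## Cueing readout

The behavioral link (reaction time) is proxied by the target-evoked
transient of the target-shape cell at the target location: the peak rate
during the target response (pulse duration + 300 ms) minus the mean rate
over the 500 ms preceding target onset — the same convention as the
transient peak in `ActivitySummary`. A larger transient means a larger
phasic signal to the downstream localization decision. The cueing effect
at each cue–target onset asynchrony (CTOA) is that transient with a
same-location cue minus the transient with an other-location cue (the
latter is identical to a no-cue control because the location modules are
disjoint).

The measure produces the bimodal time course from two competing effects.
At short CTOAs (≲ 0.2 s) the 500 ms pre-target window lies mostly before
the cue, so the cue-evoked surge still inside the target window inflates
the transient: facilitation. At longer CTOAs the pre-target level is the
cue's maintained activity, and the shunting ceiling compresses the extra
peak the elevation buys (the closer V sits to B, the smaller the
increment a fixed input produces), so the cued transient falls below the
uncued one: inhibition of return. The crossover on the default CTOA grid
falls between 0.2 and 0.3 s.

## The reference parameter set

See `configs/reference.yaml` (all fields of `ModelParams`, with
`canoncircuit.reference_params()` as the in-code source of truth). The set
was chosen so that the circuit exhibits, at one operating point, the full
phenomenology described above: non-zero baseline firing (≈ 1.4 SU per
shape cell); graded, multi-second maintained activity in the single
regime (long-term maintained ≈ 0.2 SU for the standard pulse); a
single→dual transition in W_inh near 0.57 (inside the 0.55–0.7 band, with
the reference W_inh = 0.55 on the single side) and a loss of single-regime
operation when the tonic drive falls below R ≈ 0.98; a sharp rise of
long-term memory around W_inh ≈ 0.5; regime flip when all adaptation is
removed; and the facilitation→IOR cueing time course at the same
parameters.

Two deliberate features of this operating point deserve note. First, the
membrane and gate time constants are fast (≤ 5 s and 0.15 s); the
multi-second memory is critical slowing of a network mode, not a slow
cellular process — an isolated cell returns to baseline within ~1 s.
Second, near the regime boundary the slow mode is real (overdamped), so
the memory decays monotonically instead of by damped alternation between
the two shape cells; parameter sets that approach the boundary through an
oscillatory (Hopf-type) instability produce rivalry-like seesawing that
the reference set avoids.

## Global-inhibition strengths

The reset experiment uses GI strengths {0.3, 0.35, 0.45} (plus 0). In
this range a 200 ms GI pulse partially cancels the elevated trace, and
stronger GI lands the state closer to baseline, so the time to settle
back within 5% of baseline decreases with strength — the graded-reset
effect. Much stronger GI pulses drive every cell to the shunting floor;
the state then re-approaches baseline from below and the settling time
grows again with strength. The default strengths sit on the graded branch.

## What the simulations do and do not show

All inputs are synthetic rectangular pulses and the network is four cells
per location; passing tests demonstrate the internal consistency of the
dynamical mechanism (disinhibition memory, its modulators, and the cueing
time course), not a fit to recorded spike trains. Firing rates are in
arbitrary units, so only signs, orderings and ratios are meaningful.
Known limitations: a single shared recovery time constant for both
adaptive synapse classes; rate (not spiking) dynamics; no cross-location
coupling, so the model cannot express competition between locations; the
global-inhibition reset is a stylized external signal rather than a
modeled population; the dual-regime window along the tonic drive R is
narrow (roughly 0.92–0.98 at reference), so the baseline-drive boundary
is best read as the minimum drive for single-regime operation rather
than the edge of a wide runaway region; and removing the excitatory
adaptation alone (`eta_exc` ≲ 0.15 with `eta_inh` at reference) already
tips the network into the dual regime, i.e. single-regime operation at
the reference point relies on both adapting synapse classes.
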