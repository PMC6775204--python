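# Methods

This note records the model as implemented, the parameter conventions, the
numerical choices, and the limits of what the simulations demonstrate.

## Model components

**Intentional planning fields.** Each tract variable has a 1-D field
u(x, t) on a uniform grid over [0, 1] (101 points by default; enough to
resolve force distributions with σ ≥ 0.02).  The field obeys a linear
decay–plus–forcing law with non-negativity imposed after every step.
Distinct fields do not interact; there are no 2-D fields.  The dynamic
target is the activation centroid, which is always defined because the
neutral attractor keeps total activation positive — a zero-activation
field raises an error rather than silently defaulting.

**Gestures.** A phonological gesture is a pair of systems on one field: an
excitatory member with a Gaussian force distribution centered on the
target region, and an inhibitory member with a single-mode distribution
placed at the opposite end of the axis and conventionally about twice as
broad.  Gaussians are unit-peak (not unit-area), so a gesture's weight
reads directly as its maximal force amplitude.  The gating function is a
logistic sigmoid of excitation; "strong" gating (midpoint at the selection
threshold 0.9, slope 50) passes < 10⁻⁶ of the force at queue-level
excitation, while "leaky" gating (midpoint 0.6, slope 10) passes half of
it.  Antagonism is decided geometrically — an inhibitor antagonizes an
excitor on the same field when |μ⁻ − μ⁺| < σ⁻ + σ⁺ — and can be augmented
by explicit declarations in config.

**Neutral attractor.** One permanent, ungated excitatory Gaussian per
field (default strength 0.1, one tenth of a fully gated gesture), encoding
the rest posture.  Because it is constant, constriction releases are
driven either by field decay toward the neutral distribution or by
explicit opening gestures; no competitive gating of the attractor exists.
Off-center attractors show a small (≈ 4·10⁻⁴) centroid bias from grid
truncation at the axis boundary.

**Selection.** Competition is resolved deterministically: the excitation
race is abstracted to an event-driven reorganization whose outcome order
is the canonical rank order, since every phenomenon modeled here depends
only on that order.  The level ladder is ordinal; its numeric values
(selected 1.0, queue 0.6/0.45/0.3, suppressed 0.1, threshold 0.9) matter
only through the gating function.  The queue levels sit ≥ 0.3 below the
threshold so that a strongly gated queued gesture is silent while a
leaky-gated one is not, and the post-suppression level lies strictly below
every queue level, which is what makes agreement predominantly
anticipatory.  Within a selected set, gestures act from selection onset;
finer within-set phasing is out of scope.

**Dissociation and blocking.** Early promotion and late demotion are
directives naming a gesture and a span of epochs.  An excitatory gesture
is refused in any epoch whose selected members include an antagonist; its
paired inhibitory member inherits exactly the admitted epochs, so the pair
dissociates or is refused together.  A refusal in the middle of a
multi-epoch span truncates the span (promotion starts after the last
blocked epoch; demotion ends before the first), so each gesture's selected
time is one contiguous interval by construction — refused epochs are
logged as blocking or contiguity events.  Canonical co-selection of an
antagonistic pair is permitted; the blocking rule constrains dissociated
selection only.

**Feedback regimes.** A set's targets are achieved when every excitatory
canonical member's tract variable has stayed within ε = 0.05 field units
of its target for 10 ms.  External feedback places the reorganization
50 ms after achievement; internal feedback places it 60 ms *before*
detected achievement, realized by rewinding the stored trajectory to the
boundary (never earlier than 1 ms into the epoch); `fixed_epochs` uses
scripted durations.  Achievement never detected within 2000 ms raises an
error naming the set.  These timing constants are desk conventions,
exposed in config.

**Task dynamics.** Tract variables follow ẍ = k(T − x) − bẋ with
k = 0.0015 ms⁻² (≈ 100 ms to 90% of a step) and critical damping
b = 2√k by default.  The field model supplies T exclusively via the
centroid; the weighted-average blending rule is retained only as the
baseline it replaces and for worked examples.  One blending example in
the source material pairs a negative weight with printed result 1.25;
that value follows from the formula only when the negative weight
attaches to the gesture with target 0, which is the association this
package's examples use.

## Numerical choices

- Time base: explicit stepping at dt = 1 ms.  The field uses an
  exponential-Euler update (exact for force constant over a step,
  unconditionally stable); plain explicit Euler is available as an option
  but has O(dt) decay error (0.2% over two decay constants at the
  documented test resolution, outside the 0.1% oracle band).
- The tract variable uses the exact matrix-exponential propagator of the
  linear second-order system under piecewise-constant T, cached per
  (k, b, dt).  This makes constant-target trajectories match the
  closed-form damped response to machine precision and guarantees zero
  overshoot at critical damping; a semi-implicit Euler option exists for
  comparison (measured ≈ 1.2% peak error at dt = 1 ms on a critically
  damped step).
- Clamping u ≥ 0 is applied after each full step.
- Halving dt changes endpoint targets and tract values by < 10⁻³ field
  units (the axis has unit full scale) on every library scenario; the
  residual O(dt) coupling comes from sampling T per step.
- Classifier measurement windows are the final third of each epoch, so
  field transients from the previous epoch (time constant 1/α = 20 ms)
  decay below the 0.01 transparency tolerance; the tolerance itself sits
  between integration noise (≲ 10⁻³) and the smallest demonstrated
  leaky-gating shift (≈ 0.3).
- Ties in competition are broken by canonical rank; the engine is
  deterministic.  The only randomness is optional excitation noise
  (off by default), driven by a single integer seed.

## Scenario library conventions

Axes are oriented so larger values mean more constricted (oral fields,
rest 0.5) or more open (velum, rest 0.3).  Excitatory σ = 0.08; weights 1;
epochs in harmony fixtures are scripted at 150 ms so a run and its control
share boundaries exactly; the anticipatory-posturing fixture uses external
feedback with live achievement detection (ready phase 400 ms).  Control
runs delete the scenario's declared manipulated gestures (by default the
trigger pair) with everything else fixed; in the dissimilation fixture the
manipulated set also includes the broad inhibitory response the distractor
elicits, since that inhibition exists only on distractor trials.  In the
agreement fixture the trigger's inhibitory member is strongly gated while
the excitatory member leaks: a leaky inhibitory leak onto the antagonist's
own excitation would otherwise masquerade as an articulatory effect in the
transparent epoch.  The phonologized-agreement fixture adds an independent
copy of the trigger pair to the first set (set membership is unique per
gesture system); whether the original trigger remains leaky is
configurable, and it defaults to leaky.

## What the fixtures do and do not show

The scenarios are synthetic configurations authored to isolate each
mechanism; no articulometry, acoustics, or vocal-tract geometry is
simulated, and tract variables are the terminal observable.  Passing tests
show that the implemented mechanisms generate the intended qualitative
contrasts (sign of distractor shifts, partial vs. negligible anticipatory
assimilation, spreading/blocking/agreement/transparency, anticipatory
directionality bias) and that these contrasts are robust to ±25%
perturbation of force gains where asserted.  They do not show quantitative
fits to kinematic data: no published parameter values exist for the field
gains, gating shapes, or ladder levels, so all defaults are conventions.
Microscale neuron-population dynamics, within-set coupled-oscillator
phasing, stochastic competition races, and diachronic population dynamics
of phonologization are out of scope.

## Known limitations

- Achievement detection requires every excitatory canonical member to
  reach its band; strongly blended targets (e.g. the deliberate
  undershoot demo) would time out under feedback-driven modes and are run
  with scripted epochs instead.
- A dissociated gesture's span is a directive parameter, not an emergent
  quantity; persistence across more than two epochs must be requested.
- The contiguity-by-construction rule means a blocker inside a requested
  span silently shortens the dissociation (with a logged event) rather
  than producing a second selected interval.
- Internal-feedback rewinds assume boundaries on the step grid; the lead
  and delay constants should be multiples of dt.
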