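# scintax

A simulator of the **selection–coordination–intention** model of speech
articulatory control, for researchers in speech motor control,
Articulatory Phonology, and computational phonology who want to study how
non-local sound patterns (harmonies) can *originate* in the planning
dynamics of individual utterances.

## The model

Each vocal-tract parameter (tract variable: lip aperture LA, velum
aperture VEL, tongue-tip constriction degree TTCD, ...) has a 1-D
**intentional planning field** u(x, t) over its normalized parameter axis
x ∈ [0, 1]:

    du(x)/dt = −α u(x) + β⁺ Σᵢ Gᵢ⁺ 𝒩(x; μᵢ⁺, σᵢ⁺) + β⁻ Σᵢ Gᵢ⁻ 𝒩(x; μᵢ⁻, σᵢ⁻),   u ≥ 0

Gestures come in excitatory (+) and inhibitory (−) pairs; each exerts a
Gaussian force distribution on its field, scaled by a sigmoid **gating
function** G(e) of the gesture's excitation e.  The field's activation
centroid

    T(t) = Σₓ x·u(x) / Σₓ u(x)

is the **dynamic target** that drives the tract variable's damped
mass-spring dynamics, (1/k)ẍ + (b/k)ẋ + x = T(t).  A weak, constant
**neutral attractor** force keeps every field active and encodes the rest
posture.  Gestural excitations are organized by a **competitive-queuing**
engine: sets of gestures (≈ syllables) hold ranked sub-threshold levels in
a step potential and are selected, executed, and suppressed in sequence,
with reorganizations timed by external feedback, internal (predictive)
feedback, or scripted epochs.

Two mechanisms then generate non-local patterns:

- **spreading** — a gesture's *selection* is dissociated from its
  canonical epoch (early promotion / late demotion).  Selection of an
  antagonistic inhibitory gesture blocks the dissociation, so spreading
  is blockable and articulatorily continuous.
- **agreement** — a *leaky-gated* gesture forces its field while still
  below the selection threshold.  Epochs whose selected antagonist
  cancels that force are transparent, and agreement is never blocked.

The same sub-threshold leak produces anticipatory posturing before a
response, and planned-but-unexecuted "distractor" gestures produce
assimilatory or dissimilatory target shifts.

## Worked example

Run the agreement-harmony fixture — a three-set word form {A}{By⁺y⁻}{Cx⁺x⁻}
where the leaky-gated velum trigger x⁺ is canonically selected last and the
middle set contains its antagonist y⁻ — and classify it against the
auto-generated no-trigger control:

```python
import scintax as sx
from scintax.metrics import classify_harmony_outcome

sc = sx.make_scenario("agreement_fig12a")
result = sx.run_simulation(sc, seed=1)
control = sx.run_simulation(sc.control(), seed=1)
report = classify_harmony_outcome(result, control, "x+")
print("classification:", report.classification)
for k, s in report.per_epoch_shift.items():
    print(f"epoch {k}: shift vs control = {s:+.4f}"
          f"  (transparent: {k in report.transparent_epochs})")
```

prints

```
classification: agreement
epoch 1: shift vs control = +0.3327  (transparent: False)
epoch 2: shift vs control = +0.0000  (transparent: True)
epoch 3: shift vs control = +0.5561  (transparent: False)
```

Epoch 1 shows a 0.33-field-unit displacement of the velum target toward
the trigger's target even though x⁺ is never selected there — the
agreement precursor.  Epoch 2 is transparent: the selected antagonist y⁻
cancels the trigger's sub-threshold force exactly.  Epoch 3 is the
trigger's own canonical epoch.

The same scenarios are available from the shell:

```bash
scintax list
scintax scenario agreement_fig12a --out runs/agree --seed 1
scintax scenario agreement_fig12a --control --out runs/agree_ctl --seed 1
scintax classify --run runs/agree --control runs/agree_ctl
scintax simulate --config my_scenario.yaml --out runs/custom --seed 1
```

Runs are written as plain CSV trace tables (field activation, dynamic
targets, tract variables, excitations, score-style selection intervals)
plus a `meta.json` with the epoch schedule and event log.

## Layout

- `src/scintax/field_dynamics.py` — planning fields, neutral attractor, centroid readout
- `src/scintax/gestures.py` — gestures, gating functions, antagonism
- `src/scintax/selection.py` — competitive queuing, dissociation, blocking
- `src/scintax/task_dynamics.py` — tract-variable dynamics, target blending
- `src/scintax/scenarios.py` / `library.py` — coupled simulator and named fixtures
- `src/scintax/metrics.py` — assimilation indices, shifts, harmony classifier
- `src/scintax/config_io.py` / `cli.py` / `plotting.py` — configs, CLI, plots
- `docs/methods.md` — modeling assumptions, parameters, and numerical choices
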