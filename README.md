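# shcspeech

A hierarchical nonlinear-dynamical model of sound-sequence learning and
recognition, exercised end to end on synthetic speech-like stimuli.

The package is aimed at computational neuroscientists studying online
(predictive-coding) accounts of auditory recognition: it provides the full
loop from sound wave to word label — a cochlear front end, a two-level
dynamical generative model, its online Bayesian inversion, slow feedback-
weight learning, and a bank-of-modules classifier — together with a seeded
synthetic-stimulus generator so that every experiment runs with no external
corpora.

## The model

**Generative model.** A reduced cochleagram `z(t)` (6 channels × 100 model
time units) is generated by a two-level hierarchy:

* *Second level (sequencer).* `N = 8` neuronal ensembles compete in a
  Lotka–Volterra-type winnerless-competition network,

      x2' = ts · κ₂ (1 − λ x2 − ρ S(x2)),      S = logistic sigmoid,
      y2' = κ₁ (softmax(x2/τ) − y2),            v2 = y2,

  with decay rate `λ = 1/8` and rate constants `κ₁ = 2, κ₂ = 1`. The
  inhibition matrix ρ (weak current→next, strong otherwise) turns the
  saddles into a stable heteroclinic channel: each ensemble dominates for a
  contiguous window (~12.5 units) before handing over to its successor, so
  one cycle acts as the word's timing chain. The exponential normalization
  `y2` confines the causal output `v2` to [0, 1] and keeps it near one-hot.

* *First level (spectral).* A Hopfield network with self-decay `a = 0.2`
  and asymmetric coupling `W`,

      x1' = κ (−A x1 + W tanh(x1) + I v2),      v1 = x1,

  has a unique global attractor for any fixed drive (contraction condition
  on `W`). Column `j` of the feedback weights `I` is the drive that makes a
  desired 6-channel firing-rate pattern the attractor while ensemble `j` is
  active (`I_j = A x* − W tanh(x*)`), so the predicted cochleagram follows
  the second-level sequence.

**Inversion.** A *module* inverts this model against an incoming stimulus by
gradient flow on precision-weighted prediction errors (free-energy
minimization under the Laplace assumption, states in generalized
coordinates; the filter is causal). Fixed prior log-precisions per level
set the operating mode: a high first-level sensory/internal ratio forces
learning of the feedback weights `I` (one natural update per stimulus
presentation, typically converging within a handful of repetitions); a low
ratio makes deviations be explained as sensory noise (robust recognition).
An *agent* is a bank of learned word modules; classification is
winner-take-all on the time-summed precision-weighted prediction error.

**Cochlea.** A passive filter cascade in the style of Lyon's classical
model (86 channels at 16 kHz with default parameters, half-wave
rectification, AGC, decimation) produces cochleagrams in [0, 1]; 14-channel
block averaging and linear time rescaling give the 6 × 100 model input.

## Worked example

```python
import numpy as np
from shcspeech.synth import make_class_specs, make_word
from shcspeech.agent import Agent, train_module, classify
from shcspeech.inference import PrecisionConfig

specs = make_class_specs(3, seed=0)            # three synthetic word classes
mods = [train_module(s.label, [make_word(s, token_seed=1)]) for s in specs]
agent = Agent(modules=mods)

z = make_word(specs[1], token_seed=9)          # a fresh token of class "1"
res = classify(agent, z, pc=PrecisionConfig.clean_recognition())
print(res.predicted, {k: round(v, 2) for k, v in res.scores.items()})
```

Output:

```
1 {'0': 5.62, '1': 1.9, '2': 6.51}
```

The fresh token of class "1" is assigned to module "1", whose accumulated
precision-weighted sensory prediction error (1.90) is far below that of the
mismatched modules (5.62, 6.51) — the winner-take-all margin that drives
word recognition.

The same functionality is available from the shell:

```bash
shc-speech synth --classes 10 --speakers 5 --tokens 2 -o data/
shc-speech cochlea word.wav --reduce -o word.csv
shc-speech experiment recognition --seed 1 -o results/
```

## Layout

| module | contents |
| --- | --- |
| `shcspeech.cochlea` | filterbank design, cochleagram, reduction, rescaling, denoising, compression |
| `shcspeech.dynamics` | sequencer + Hopfield generative core, forward simulation |
| `shcspeech.inference` | precision configs, generalized-coordinate filter, feedback learning |
| `shcspeech.agent` | word modules, averaging, classification, cross-validation |
| `shcspeech.synth` | synthetic words, speakers, datasets, noise/mixture/accent manipulations |
| `shcspeech.experiments` | scripted desk-scale experiment runners |
| `shcspeech.cli` | `shc-speech` command-line interface |

See `docs/methods.md` for the modeling choices, parameter rationale and
known limitations.
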