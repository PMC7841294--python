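# astrosnn

Astrocyte-mediated self-repair for unsupervised STDP-trained spiking neural
networks.

Neuromorphic hardware is fault-prone: synapses die, and a trained spiking
classifier loses accuracy as its weight matrix is punctured. In the brain,
astrocytes at the *tripartite synapse* implement a repair loop through
retrograde endocannabinoid signalling: post-synaptic firing releases 2-AG,
which both depresses the neuron's own synapses directly (DSE) and — via
astrocytic IP3-gated Ca2+ dynamics and glutamate release — drives a slow,
astrocyte-wide potentiating signal (e-SP). Each synapse's probability of
release follows

    PR = PR0 + PR0 * (DSE + eSP) / 100,

so when faults silence part of a neuron's input, its |DSE| collapses while
the global e-SP persists, the surviving synapses' PR rises, and the firing
rate self-repairs.

`astrosnn` provides, for computational-neuroscience and neuromorphic
researchers:

* **`astrosnn.tripartite`** — a biophysical simulator of this loop
  (Li-Rinzel Ca2+/IP3 dynamics, gliotransmission, DSE/e-SP feedback) on a
  toy LIF network with scriptable synapse-fault schedules;
* **`astrosnn.snn`** — a single-layer unsupervised spiking classifier:
  LIF neurons with adaptive thresholds (homeostasis), trace-based STDP,
  soft winner-take-all lateral inhibition, Poisson rate coding, per-neuron
  weight normalization;
* **`astrosnn.repair`** — fault injection (i.i.d. synapse deletion with
  probability `p_del`) and the astrocyte-augmented STDP rule

      dw = eta_post * x_pre * (w / w_alpha)^sigma   (post-synaptic spike)
      dw = -eta_pre * x_post                        (pre-synaptic spike)

  where `w_alpha` is the 98th percentile of the network's weight
  distribution — a class-independent surrogate for repair progress that
  makes healthy synapses relearn aggressively and saturates as the network
  heals;
* **`astrosnn.harness`** — neuron labeling, prediction, accuracy, the full
  train → fault → normalize → re-train protocol with per-phase accuracies
  over independent runs, and the alpha/sigma ablation sweep;
* **`astrosnn.datasets`** — a synthetic 10-class grayscale pattern
  generator, IDX file I/O for the standard digit benchmarks, and Sobel
  pre-processing.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

Simulate the two-neuron self-repair scenario (400 s; at 200 s, 70% of
neuron N2's ten synapses fail; all PR0 = 0.5):

```python
import numpy as np
from astrosnn import AstroParams, simulate_toy
from astrosnn.config import fig2_toy_config

rec = simulate_toy(fig2_toy_config(seed=1), AstroParams())

def rate(neuron, lo, hi):
    sel = (rec.times > lo) & (rec.times <= hi)
    return rec.rate[neuron, sel].mean()

print(f"N2 pre-fault  {rate(1, 150, 200):5.2f} Hz")
print(f"N2 post-fault {rate(1, 205, 215):5.2f} Hz")
print(f"N2 recovered  {rate(1, 390, 400):5.2f} Hz")
print(f"surviving PR  {rec.pr[1, ~rec.faulty[1]][:, rec.times > 390].mean():.3f}")
```

prints

```
N2 pre-fault  14.05 Hz
N2 post-fault 10.43 Hz
N2 recovered  11.54 Hz
surviving PR  0.837
```

— the fault cuts N2's rate, the astrocyte raises the surviving synapses'
release probability from 0.5 to ~0.84, and the rate recovers to ~82% of its
pre-fault value while N1 is untouched.

The full desk-scale classifier experiment (10-class synthetic task,
50 neurons, 5 independent runs):

```python
from astrosnn import ExperimentConfig, run_experiment

record = run_experiment(ExperimentConfig(seed=1))
print(record.to_markdown())
```

| Fault probability | baseline | post_fault | post_norm | stdp_repair | astdp_repair | gain |
|---|---|---|---|---|---|---|
| 0% | 97.00 ± 1.26 | — | — | — | — | — |
| 50% | — | 23.32 ± 4.00 | 85.40 ± 5.60 | 92.40 ± 2.55 | 94.76 ± 2.06 | 2.36 |
| 80% | — | 0.00 ± 0.00 | 51.44 ± 9.17 | 62.56 ± 6.81 | 62.76 ± 5.73 | 0.20 |
| 90% | — | 0.00 ± 0.00 | — | — | — | — |

Each row is a fault level: accuracy after fault injection, after weight
normalization, after one epoch of sole-STDP re-training, and the best
A-STDP checkpoint; `gain` is the A-STDP minus sole-STDP column. At 90%
faults the network collapses to (below-)chance before repair — silent
responses abstain and count as errors.

## Command line

```
astrosnn toy-astro --scenario fig2 --seed 1 --out toy/ --plot
astrosnn make-synth --out data/
astrosnn train --data synthetic --epochs 2 --seed 0 --out run/
astrosnn inject --checkpoint run/checkpoint.h5 --p-del 0.8 --seed 1 --out faulty.h5
astrosnn repair --checkpoint faulty.h5 --rule astdp --alpha 98 --sigma 2 --epochs 2 --out repaired/
astrosnn evaluate --checkpoint repaired/repaired.h5
astrosnn experiment --seed 1 --out results/
astrosnn ablate --alphas 90,95,98,99 --sigmas 0,1,2,3 --out ablation.csv
```

`train`/`repair`/`evaluate` also accept a directory of IDX files
(`--data path/`) for full-scale runs on user-supplied digit benchmarks.

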