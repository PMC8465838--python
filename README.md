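# localte

**Inferring excitatory and inhibitory neuronal connections from
calcium-imaging-like activity with local transfer entropy — plus the full
in-silico benchmark to validate it.**

## The problem

Calcium imaging records the activity of hundreds of cultured neurons at
once, but at coarse temporal resolution (5–20 ms frames), and the standard
tools for reconstructing *which neuron drives which* — correlation, Granger
causality, transfer entropy — cannot tell an excitatory synapse from an
inhibitory one. `localte` implements an estimator that can, and the
synthetic ground-truth pipeline needed to measure how well.

For binary activity series (target X, source Y) the transfer entropy

    TE_{Y→X} = Σ P(x_n, x_n₋₁⁽ᵏˣ⁾, y_n₋d⁽ᵏʸ⁾) · log₂ [ P(x_n | x_n₋₁⁽ᵏˣ⁾, y_n₋d⁽ᵏʸ⁾) / P(x_n | x_n₋₁⁽ᵏˣ⁾) ]

is split *summand by summand* into a local excitatory part TE_E (source
activity matches the target's current state) and a local inhibitory part
TE_I (they oppose), with TE_E + TE_I = TE exactly. Scanning the source
delay d separates the two synapse classes: excitation is fastest (best at
d = 0, which includes same-bin interaction), while inhibition — carried by
slower GABA_A currents — surfaces as delayed anti-correlation, best at
d ≈ 10–20 ms. Estimation can be conditioned on non-synchronous network
states (ROI selection on the population-average fluorescence), which
matters in bursty cultures.

The benchmark half of the package generates everything the estimator is
tested on: spatial Gaussian-kernel networks (100 cells, 80/20 E/I, mean
in-degree 20), quadratic integrate-and-fire dynamics with adaptation,
depressing alpha synapses and Poisson drive (RK4, 0.1 ms steps),
a calcium kernel forward model (10 ms rise / 700 ms decay, 10% acquisition
noise, 5–20 ms frames), derivative-threshold spike re-extraction, and ROC
scoring of the TE matrices against the ground-truth signed adjacency.

## Worked example

Score a pair of cells with a known signature — a 1-bin-lagged copier
(pure excitatory coupling) and a lagged inverter (pure inhibitory):

```python
import localte as lt

cfg = lt.TEConfig(k_x=1, k_y=1, delay_bins=1)
cop, _ = lt.make_fixtures("copier", t_bins=3000, seed=1)
inv, _ = lt.make_fixtures("inverter", t_bins=3000, seed=2)
print("copier  :", lt.local_te_split(cop.states[1], cop.states[0], cfg))
print("inverter:", lt.local_te_split(inv.states[1], inv.states[0], cfg))
```

```
copier  : (0.9985772605604601, 0.0)
inverter: (0.0, 0.9987464006348818)
```

The copier's full transfer entropy (≈ 1 bit: the source determines the
target) lands entirely in the excitatory component; the inverter's lands
entirely in the inhibitory one. Mixed, noisy couplings distribute between
the two, and their d-profile identifies the synapse class.

Run a miniature end-to-end benchmark (10 cells are too few for stable
accuracy — this is the smoke-test scale):

```python
from localte.pipeline import run_benchmark
bench = run_benchmark(seed=0, n_realizations=2, duration=60_000.0,
                      grid=({"g_i": 400.0, "bin_size": 10.0,
                             "noisy": False, "delays": (0, 2)},))
print(bench.table()[["component", "delay", "auc", "j"]])
```

The same pipeline is exposed on the command line:

```bash
localte simulate --seed 1 --n-realizations 3 --out runs/sims
localte reproduce --table 1 --realizations 10 --seed 1 --out runs/table1.csv
localte fixtures --kind copier --out runs/fixtures
```

At benchmark scale (100 cells, 5-minute simulations, 10 ms frames,
gE:gI = 1:2), the excitatory component at d = 0 reaches a mean ROC AUC of
≈ 0.84 and the inhibitory component at d = 2 bins ≈ 0.88, with inhibitory
accuracy rising further (≈ 0.90) when inhibition is strengthened to 1:3 —
while at d = 0 the inhibitory component is near chance, which is exactly
the delay signature the decomposition predicts.

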