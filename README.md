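# curebag

Bagging survival trees for populations containing **nonsusceptible (cured)
individuals** — subjects who will never experience the event and contribute
only censored follow-up. `curebag` is aimed at clinical-genomics settings
(e.g. relapse after curative treatment) where the goals are (i) selecting
event-related covariates with possibly high-order interactions among the
*susceptible* subjects and (ii) predicting individual cumulative hazards,
while adjusting for known confounders tied to the cured fraction.

## The model and criterion

The survival function is improper, S(∞) > 0, with a bounded cumulative
hazard

&nbsp;&nbsp;&nbsp;&nbsp;Λ(t | Z₁, leaf) = θ e^{α′Z₁} (1 − e^{−H(t; leaf)}),

so exp(−θ e^{α′Z₁}) is the cured proportion given the confounders Z₁. The
explanatory covariates Z₂ act through a binary tree. Each candidate split
Z\* is scored by the pseudo-R²

&nbsp;&nbsp;&nbsp;&nbsp;S = (U²/V)/K, &nbsp; U = Σᵢ δᵢ ω(Xᵢ)(Z\*ᵢ − r̄(Xᵢ)), &nbsp; ω(t) = 1 + log(1 − Λ̂₀(t−)/θ̂),

the score of the improper-model partial likelihood at γ = 0 with robust
variance V and K the number of distinct event times: a unit-free [0, 1]
index of how well the split separates susceptible subjects by event time.
As θ̂ → ∞ it reduces to the adjusted log-rank criterion (also available as
`criterion="logrank"`). On top of that sit a B-tree bagging loop with
Breslow-type / Nelson–Aalen leaf cumulative hazards, out-of-bag IPCW
(integrated) Brier scores, three importance scores (IIS, DIIS, PPIS) and a
permutation test that selects a Bonferroni-controlled *basket* of
important variables. A simulation engine generating data from a five-leaf
improper survival tree is included and fully tested. See
[docs/methods.md](docs/methods.md) for the details and design choices.

## Worked example

Simulate one replicate of the baseline scenario (n = 250, 25% cured in the
reference group, 10% censoring among susceptibles, 10 noise covariates)
and fit the bagging procedure adjusted for the confounder G1:

```sh
$ curebag simulate --scenario 1 --noise 10 --seed 7 --out sim
wrote 250 rows to sim/data.csv (censoring rate 0.3792)

$ curebag fit sim/data.csv --time time --event event --conf G1 --B 100 --seed 1 --out fit
OOB-IBS = 0.14194 (pseudoR2, BRE, B=100)
```

The censoring rate 0.3792 is the exponential rate calibrated so that 10%
of susceptible subjects are censored; `OOB-IBS` is the out-of-bag
integrated Brier score of the ensemble (lower is better; 0.25 is the
score of a constant ½ prediction). `fit/importance.csv` ranks the
candidates by the index importance score, which sums Δ×S over every split
using the variable and normalizes to a total of 100:

```text
variable  iis    diis   ppis
G4        19.58  42.55  -0.0002
N1         9.17   7.35  -0.0014
G3         8.96   9.15   0.0011
N4         8.70   7.40   0.0006
...
```

On a single n = 250 replicate the explanatory variables (G2–G5) and the
strongest noise columns overlap; averaged over replicates the signal
variables separate cleanly (the test suite checks exactly this on ten
replicates). The same library calls are available in Python:

```python
from curebag import scenario_config, simulate_scenario, fit_bagging, oob_ibs

sim = simulate_scenario(scenario_config(1, n_noise=10, seed=7))
ens = fit_bagging(sim.dataset, B=100, criterion="pseudoR2", seed=1)
print(oob_ibs(ens))
```

Variable selection with the permutation test (Q permuted refits, Bonferroni
level α):

```sh
curebag select sim/data.csv --time time --event event --conf G1 \
    --B 100 --Q 100 --alpha 0.05 --seed 1 --out sel
```

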