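# lcnet

Latent-cause inference with context-vector networks: a computational
cognitive-neuroscience model family for studying how a learner can
simultaneously maintain *shared* structure across contexts and
*context-specific* structure, and how inferred latent causes segment
continuous experience into events.

## The model

Experience arrives as a stream of observations generated by hidden,
temporally persistent contexts ("latent causes", LCs). At each step the
model decides which LC explains the current observation — or whether to
open a new one — with a Bayesian nonparametric assignment:

- **Prior** — the sticky Chinese Restaurant Process (sCRP):

  ```
  P(z_t = k | z_{1:t-1}) ∝  count_k + λ·1[z_{t-1} = k]    for existing k
                            α                              for a new LC
  ```

  Frequently used LCs and the immediately preceding LC are favoured
  (α = concentration, λ = stickiness).

- **Likelihood** — every LC k is indexed by a fixed random Gaussian
  context vector c_k that modulates a single shared predictive network
  f. LC k's loss is `MSE(f(x_{t-1}, c_k), x_t)`; a preallocated random
  vector scores the not-yet-created LC; the likelihood is
  `softmax(−loss / τ)`.

- **Posterior** — prior × likelihood, with a local MAP commitment: the
  argmax LC is selected, its count incremented, and (if it is the new
  slot) the candidate vector adopted.

Because all LCs share one network, structure common across contexts
accumulates in the shared weights, while context-specific structure is
carried by the context-to-hidden pathway. Comparator models bracket the
design space: a context-blind network (fully shared representation) and
a one-network-per-LC ensemble (fully separated representations, the
Structured Event Memory scheme). Event boundaries are operationalized as
switch points of the inferred LC sequence.

Three simulation suites exercise the model:

1. **Continual function learning** — four polynomials sharing a common
   term, learned in a fully blocked curriculum with a noisy 128-bit
   context-indicative signal; measures catastrophic interference,
   shared-structure reuse, and a lesion probe of the shared pathway.
2. **Schema learning** — two context-dependent transition graphs over
   aliased states (the "cafe/bar" task), learned blocked vs interleaved;
   measures test-phase two-alternative forced choice and LC purity.
3. **Event segmentation** — a recurrent (GRU) variant predicts the next
   frame of a synthetic corpus of 30-dimensional event streams with
   ground-truth labels and simulated annotator boundary probabilities;
   measures adjusted mutual information and boundary/annotator
   point-biserial correlation against permutation nulls.

All data are generated by the package (`lcnet.taskgen`); no external
corpora are used or required.

## Worked example

```python
from lcnet import default_config, run_sim2, aggregate_runs

table = run_sim2(default_config(2, n_runs=5))
summary = aggregate_runs([table[table.phase == "summary"]])
print(summary[summary.measure.isin(["test_accuracy", "test_purity", "n_lcs"])])
```

prints

```
  condition       measure  mean    se  n
    blocked         n_lcs  2.00 0.316  5
    blocked test_accuracy  0.63 0.103  5
    blocked   test_purity  0.83 0.104  5
interleaved         n_lcs  1.20 0.200  5
interleaved test_accuracy  0.52 0.031  5
interleaved   test_purity  0.58 0.034  5
```

Read: with blocked training the model typically infers exactly two LCs
(`n_lcs` = one per context), its assignments during the random-context
test phase track the true context (`test_purity` 0.83), and its choice
accuracy is above the interleaved condition's, which lumps both contexts
into a single LC (`n_lcs` ≈ 1, purity near the 0.55 chance level) — the
curriculum effect on schema learning, where blocked exposure lets
temporal persistence and predictive evidence carve out context-specific
knowledge.

The same pattern is available from a shell:

```
lcnet run sim2 --seed 0 --n-runs 5 --out results/sim2
lcnet report results/sim2
lcnet sweep sim2 --stickiness 0,0.5,1,2 --out results/sweep
```

## Layout

```
src/lcnet/lci.py          sCRP prior, likelihood, local-MAP inference
src/lcnet/networks.py     feedforward & GRU networks, SEM-style ensemble
src/lcnet/taskgen.py      the three synthetic environments
src/lcnet/metrics.py      purity, AMI, point-biserial, permutation tests
src/lcnet/experiments.py  simulation runners, configs, aggregation
src/lcnet/cli.py          `lcnet run / sweep / report`
docs/methods.md           model account, parameter choices, limitations
```
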