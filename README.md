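# gmmkin

Generalized-method-of-moments (GMM) parameter estimation for discrete-state
stochastic reaction networks from population snapshot data (flow-cytometry
style: many independent cells, one or a few observation times).

Theoretical moments come from one of two engines derived symbolically from
the mass-action network:

* **standard** — raw-moment ODEs closed by setting central moments above the
  chosen order to zero;
* **hybrid** — conditional moments of high-copy species combined with a small
  master equation over the reachable configurations ("modes") of low-copy
  species (promoter/gene states), integrated as partial moments so the system
  stays an ODE system.

Sample moments come from snapshot datasets, generated here by a built-in
Gillespie SSA simulator (numba-accelerated, exactly reproducible from a
seed).  The GMM layer matches the two through a weighted quadratic objective
with the weight variants `identity`, `two_step`, `demean`, `demean_diagonal`,
`iterated` and `continuous_update`, minimized by bounded seeded-multistart
L-BFGS-B.

## Library quick start

```python
import gmmkin as gk

net = gk.builtin_model("gene_expression")          # or parse_network(text)
truth = gk.FIXTURE_TRUTH["gene_expression"]

data = gk.sample_snapshots(net, truth, times=[100.0],
                           observed_species=["mRNA"], n_samples=10_000, seed=1)

spec = gk.MomentConditionSpec(observed_species=("mRNA",), max_order=3,
                              times=(100.0,))
result = gk.estimate_parameters(data, net, spec, estimator="demean",
                                engine="standard", seed=1)
print(result.theta)
```

Two fixture models are bundled: `gene_expression` (two-state promoter
producing mRNA; 3 reactions, parameters a, b, c) and `exclusive_switch`
(two proteins competing for one promoter site; 10 reactions, parameters
p_i, d_i, b_i, u_i).  Requesting moments up to order `r` derives and closes
the engine at order `r+1` and exposes only orders ≤ r (the top closure order
is the least accurate).

## Model-definition format

```
[species]
DNA_ON 0 low        # name, initial count, copy class (default high)
mRNA 10

[reactions]
DNA_ON -> DNA_ON + mRNA @ c     # mass action only, at most bimolecular

[parameters]
c = 0.4 in [0.0, 0.5]           # value and/or bounding interval
```

Snapshot datasets are TSV with columns `time`, `sample_id`, then one column
per observed species; `#` lines carry seed and provenance.

## CLI

```sh
gmmkin simulate --model gene_expression --times 100 --species mRNA \
    --n-samples 10000 --seed 1 --out snap.tsv
gmmkin derive-moments --model exclusive_switch --engine hybrid --order 4
gmmkin estimate --model gene_expression --data snap.tsv --order 3 \
    --estimator demean --seed 1 --out report.txt
gmmkin recover --model gene_expression --order 3 --repetitions 10 \
    --seed 1 --out summary.tsv
gmmkin report --runs summary.runs.tsv
```

`recover` runs the scaled-down replication harness (fresh seeded dataset per
repetition, estimator grid, far-corner initial optimizer point) and writes a
per-parameter mean/SD/relative-error table plus per-run records.

## Layout

| module                | contents                                              |
|-----------------------|-------------------------------------------------------|
| `gmmkin.network`      | species/reactions/parameters, config parser, builtins |
| `gmmkin.ssa`          | Gillespie direct method, snapshot datasets, TSV I/O   |
| `gmmkin.moments`      | raw-moment ODE derivation, zero closure, integration  |
| `gmmkin.hybrid`       | mode enumeration, partial-moment ODEs, reconstruction |
| `gmmkin.gmm`          | sample/theoretical moments, F estimators, estimation  |
| `gmmkin.experiments`  | recovery-study harness                                |
| `gmmkin.cli`          | `gmmkin` command-line entry point                     |
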