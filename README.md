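# dentate

Connectivity inference and network simulation for adult neurogenesis in the
dentate gyrus (DG).

Immature granule cells (GCs) born by adult neurogenesis are intrinsically
hyperexcitable yet receive far fewer excitatory synapses from the entorhinal
cortex (EC) than mature GCs. This package implements the two computational
halves of that story:

1. **Shared-input inference from paired recordings.** When two GCs are
   recorded simultaneously and perforant-path fibres are stimulated at
   increasing intensity, the fraction of trials with an evoked EPSC in *both*
   cells ("% simultaneous success") reflects how many input fibres the pair
   shares. Under random sampling of a pool of N<sub>∞</sub> fibres, a pair
   with N<sub>total</sub> synapses each shares
   N<sub>shared</sub> = N<sub>total</sub>²/N<sub>∞</sub> fibres, and with
   per-fibre activation probability *p* the joint-success probability is

       P_overlap = 1 − (1 − P_both_ind) · (1 − p)^N_shared,
       P_both_ind = (1 − (1−p)^N_ind,A)(1 − (1−p)^N_ind,B).

   A Monte Carlo random search (`MonteCarloOverlapFitter`, 250,000 uniform
   candidates over *p*, N<sub>ind</sub>, N<sub>shared</sub>) minimizes the
   squared error against the measured overlap curves, constrained by the
   immature/mature synapse-count ratio (0.35, from constant EPSC amplitude
   ratios) and N<sub>ind</sub> ≤ 5·N<sub>shared</sub>.

2. **Feedforward threshold network.** 13,000 binary GC units are randomly
   wired to 1,300 EC units with age-specific connection probabilities
   (219/1296 mature, 77/1296 immature, from the fit). A GC fires when more
   than 20% of its synapses are co-active, so immature cells fire with fewer
   active inputs. Output similarity between random EC patterns is the
   normalized dot product (NDP); a network's *dynamic range* is the width of
   the EC-activity interval between mean NDP 0.005 and 0.05 — the range of
   cortical drive with near-orthogonal outputs. Sweeping the immature
   fraction (0–100%) shows that a small admixture of immature GCs more than
   doubles that range, with the optimum below 5%.

Because the original paired-recording data are not deposited, the package
includes a seeded generator of synthetic recordings with exactly the
statistical structure the model assumes (Bernoulli fibre activation, binomial
trial noise, EPSC-amplitude proxy), used for testing and parameter-recovery
experiments.

## Worked example

```python
from dentate import (
    MonteCarloOverlapFitter, NetworkConfig, SweepConfig,
    derive_quantities, neurogenesis_sweep,
)
from dentate.fit import candidate_to_pairs, ModelConstraints
from dentate.recordings import RecordingDesign, simulate_pair_trials, to_overlap_dataset

# synthetic paired recordings from the reference connectivity
pairs = candidate_to_pairs(0.0039, 182, 37, ModelConstraints())
design = RecordingDesign(multiples=tuple(range(1, 11)), p_min=0.0039,
                         n_trials_per_multiple=200)
datasets = [to_overlap_dataset(simulate_pair_trials(pair, design, seed=i), kind)
            for i, (kind, (pair, _)) in enumerate(pairs.items())]

est = MonteCarloOverlapFitter(n_samples=250_000, random_state=0).fit(datasets)
print(est.best_)
print(est.derived_)
```

prints:

```
FitResult(p_min=0.004855294752633176, n_ind_mature=100, n_shared_mature=69,
          error=0.01684131534942635, percentile=0.0)
DerivedConnectivity(n_total_mature=169, n_inf=414, n_total_young=59,
                    n_shared_young=8, n_ind_young=51)
```

Note what is and is not identified here: the single best candidate trades a
higher *p* (0.00486 vs the true 0.0039) for fewer synapses (169 vs 219),
because at these activation levels the overlap curve depends on *p* and the
counts almost solely through their product — the identifiable quantity
p·N<sub>total</sub> is recovered within ~4% (0.82 vs 0.85), while
N<sub>total</sub> itself wanders along that ridge from one noise realization
to the next and is only pinned down in aggregate over seeds (see
`docs/methods.md`). Derived counts for the reference fit itself are exact:

```python
>>> derive_quantities((182, 37))
DerivedConnectivity(n_total_mature=219, n_inf=1296, n_total_young=77,
                    n_shared_young=5, n_ind_young=72)
```

A reduced-resolution neurogenesis sweep (full-size networks, EC levels
0.10–0.22 in 0.005 steps, 100 input sets, 3 runs per level):

```python
sweep = SweepConfig(ec_levels=tuple(0.10 + 0.005 * k for k in range(25)),
                    ng_levels=(0.0, 0.01, 0.02, 0.05, 0.1, 0.5, 1.0),
                    n_input_sets=100, n_runs=3, seed=0)
print(neurogenesis_sweep(NetworkConfig(), sweep).summary())
```

```
{'argmax_ng_level': 0.02, 'max_mean_range': 0.0567, 'mean_range_at_ng0': 0.0200,
 'range_ratio_vs_ng0': 2.83}
```

— the tolerable EC input range peaks at 2% immature GCs and is ~2.8× wider
than in an all-mature network.

The same stages are available from the shell:

```bash
dentate run-all --config config.yaml --seed 1 --out results/
dentate fit --data overlap.csv --samples 250000 --seed 1 --out results/
dentate sweep --seed 1 --out results/     # full-resolution by default
```

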