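# Methods

## Shared-input overlap model

Two granule cells (GCs) are assumed to sample their perforant-path synapses
independently and uniformly from a common pool of `n_inf` potential fibres,
one fibre per synapse, with release probability 1. For cells carrying
`n_total_a` and `n_total_b` synapses the expected number of fibres innervating
both is the sampling-density product

    N_shared = n_total_a * n_total_b / n_inf,

with the per-cell remainders `N_ind = n_total − N_shared` unique to each cell.
Focal stimulation is modelled as activating each fibre independently with
probability `p_eff = min(1, m · p_min)`, where `p_min` is the activation
probability at the minimal stimulation intensity and `m` the experimental
stimulus multiple; proportionality is assumed to hold below saturation and the
cap at 1 merely keeps the function total for large multiples. A cell shows an
evoked EPSC ("success") when at least one of its fibres is active, so the
joint-success probability is

    P_overlap = 1 − (1 − P_both_ind) · (1 − p_eff)^N_shared
    P_both_ind = (1 − (1 − p_eff)^N_ind,A) · (1 − (1 − p_eff)^N_ind,B).

Expected counts are kept real-valued; integerization (round half up) happens
once, in `make_pair`, because the fit and the simulators need integer fibre
pools — consistent with the integer counts the analysis reports (37, 5).
Mixed-age pairs use the generalized asymmetric product form
`n_a · n_b / n_inf`; the symmetric formula is its special case.

## Monte Carlo fit

Free parameters: `p_min`, `n_ind_mature`, `n_shared_mature`. Candidates are
drawn independently and uniformly (p continuous; counts integer, endpoints
inclusive), default 250,000 draws over `p ∈ (0.001, 0.005)`,
`n_ind ∈ (100, 500)`, `n_shared ∈ (20, 100)`; ranges are config-overridable.
Two hard constraints are applied by rejection (not penalty):
`n_ind ≤ 5 · n_shared`, and the immature synapse count is tied to the mature
one by the measured EPSC-amplitude ratio,
`n_total_young = round(0.35 · n_total_mature)`. Each surviving candidate
implies a fibre pool `n_inf = round(n_total² / n_shared)` and hence all three
pair kinds (mature–mature, mature–immature, immature–immature); its score is
the squared error between predicted overlap probabilities and measured
simultaneous-success fractions, on the 0–1 scale, summed over points and over
datasets with equal weight. No gradient refinement is applied — the binomial
relation is poorly suited to analytic optimization and the point of retaining
the full ranked table (with a top-20% percentile summary) is to show how flat
the error landscape is.

**Identifiability.** At these activation levels
`(1 − p)^n ≈ exp(−p·n)` to second order, so the overlap curves constrain the
*products* `p·N` far more strongly than `p` and the counts separately. With
binomial trial noise the single best candidate therefore wanders along a
`p × N` ridge (tens of percent in `N_total`), while `p·N_total` is recovered
within a few percent per seed and `N_total` is unbiased in aggregate over
seeds at the reference truth. Tests assert exactly this: per-seed recovery of
the product, aggregate recovery of the count. Users interpreting a single fit
should read the absolute synapse counts with that ridge in mind — as the
flat top-20% table makes visible.

## Synthetic recordings

The generator is the exact generative twin of the closed-form model: per
trial, every shared and independent fibre is active independently with
probability `p_eff`; a cell's active-input count is the sum of its active
shared and own fibres; success is ≥ 1 active input, with no detection
threshold or recording noise. Defaults follow the experimental paradigm: 20
trials per intensity, stimulus multiples 1–10, `p_min = 0.0039`, and the
immature/mature synapse-count ratio 0.35 for mixed datasets. An
EPSC-amplitude proxy (active inputs × quantal size, fixed quantal size by
default since miniature-EPSC amplitudes do not differ by age) yields an
immature/mature amplitude ratio whose expectation equals the synapse-count
ratio at every multiple.

What the generator deliberately omits — and hence what passing tests do *not*
establish about real recordings: release-probability dynamics and
paired-pulse effects, quantal variance, detection thresholds and recording
noise, inhibition, and any mapping from μA stimulus steps to fibre counts
beyond linear proportionality. It validates the inference machinery, not the
biological assumptions.

## Threshold network

13,000 binary GC units receive input from 1,300 EC units. Each GC–EC edge is
an independent Bernoulli draw with probability `n_total_age / n_inf`
(219/1296 mature, 77/1296 immature), matching the binomial statistics of the
overlap model; a fixed in-degree variant is available as a config option. The
fitted pool (1,296 fibres) and the modelled EC population (1,300 cells) are
both kept as printed; both are config fields. The first
`round(frac_immature · n_gc)` cells are immature. All weights are 1; no
inhibition, no learning, no temporal dynamics.

Activation: an EC pattern activates exactly `round(f · n_ec)` cells chosen
uniformly (fixed activity mass per level, rather than per-neuron Bernoulli).
A GC fires iff its number of active inputs strictly exceeds
`threshold_frac · in_degree` (default 20%; "above threshold" read literally,
so with integer counts the required count is `floor(0.2k) + 1` when `0.2k` is
integral, and in-degree-0 cells never fire). Near-integer products are
snapped before flooring to keep the strict comparison exact under floating
point.

Output overlap is the normalized dot product (cosine) of GC activity vectors,
averaged over all unordered pairs of (default) 100 random input sets per EC
level. A pair involving an all-zero output contributes 0 and is *included* in
the mean (excluding such pairs would leave low-drive NDP undefined); the
fraction of silent outputs is reported alongside. Dynamic range scans the EC
grid in increasing order: (first level with mean NDP ≥ 0.05) − (first level
with mean NDP ≥ 0.005); 0 if the low bound is never reached; capped at the
last swept level if only the high bound is missing.

Each (neurogenesis level, run) cell rebuilds the network from a child seed
derived arithmetically from the master seed and the cell's indices (stage
name + indices via a SeedSequence), so sweeps are reproducible and invariant
to execution order or parallelism; rebuilding per run is the stricter
reproducibility test versus resampling inputs only.

## Problem sizes and numerical choices

- Full-resolution defaults: 101 neurogenesis levels (0–100% by 1%), 481 EC
  levels (0.10–0.22; the default step is 0.00025, which is what 481 levels
  over that span implies), 100 input sets, 5 runs per level.
- The packaged reduced-resolution sweep — used by the acceptance script and
  end-to-end tests — keeps networks full-size (13,000 × 1,300) and reduces
  only the grids: NG {0–10% by 1%, 20–100% by 10%}, EC step 0.005 (25
  levels), 3 runs (5 for the variability check). At the 0.005 step, dynamic
  ranges are quantized to grid multiples; run-to-run SDs are correspondingly
  either 0 or of order one step.
- Propagation is a single float32 matrix product per (network, level);
  counts are exact small integers in float32, and the threshold comparison
  adds 0.5 to the integer threshold to avoid equality ambiguity.
- Monte Carlo scoring is fully vectorized over candidates (arrays of
  250,000 × n_multiples), so a full search takes seconds.
- Rounding is round-half-up throughout the integerization of expected counts.

## Known limitations

- The overlap model ignores release-probability heterogeneity and quantal
  variance; it models the *event* "≥ 1 active input", not EPSC amplitudes.
- The network has no inhibition, which compresses the orthogonalizable input
  range; results quantify relative effects of connectivity/excitability
  mixtures, not absolute DG performance.
- Output overlap is measured against input *level*, not input correlation, so
  it is not a conventional pattern-separation index.
- Absolute synapse counts from a single fit are ridge-identified only (see
  Identifiability above).
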