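# Methods

## Scope and model

`ssanet` studies how the structure of a balanced excitatory-inhibitory
synaptic weight matrix determines slow-switching assembly (SSA)
dynamics: sustained epochs of elevated firing localized on a group of
neurons, transitioning slowly between groups. The package contains the
network constructors, a leaky integrate-and-fire (LIF) simulator,
stylized linear rate models with exact Schur analysis, and the spectral
and statistical diagnostics that connect the two levels.

## Network construction

All networks have a 4:1 excitatory:inhibitory split. At the N = 2000
reference: connection probabilities p^EE = 0.2,
p^EI = p^IE = p^II = 0.5 and weights w^EE = 0.0156, w^IE = 0.0074,
w^EI = w^II = −0.0297 (superscripts: destination then origin). Weights
scale as 1/N — at N = 1000 every weight is doubled. Edges are
independent Bernoulli draws per *ordered* pair (directed graph, no
self-connections); columns are single-signed per Dale's principle.

Structured variants redistribute probability (R ratios) or weight (W
ratios) between an in-group and an out-group value subject to exact
conservation of the average over potential partners:
`f_in·x_in + (1 − f_in)·x_out = x̄` with `x_in = ratio · x_out`, where
`f_in` counts in-group partners excluding self for same-population
blocks. Solving gives `x_out = x̄ / (1 + f_in(ratio − 1))`. The same
primitive serves:

- **clustered_prob / clustered_weight** — E-E in/out split over c
  equal groups (default 20 × 80 at reference; the assembly size of 80
  excitatory neurons is held fixed when N varies, so N = 1000 has
  c = 10);
- **ei_coclustered** — c pairs of (80 E + 20 I); E→I ratios R_IE/W_IE
  elevate the in-pair drive, I→E ratios R_EI/W_EI are applied as
  *inverse* ratios (in-pair inhibition is the weaker one), so each
  excitatory group excites its paired inhibitory group which feeds
  back more weakly onto it. Probability and weight averages are each
  conserved separately over potential pairs; when both are clustered
  simultaneously their product (expected summed input) shifts by
  second order, which is accepted;
- **small_world** — elevated probability on a ±40-neighbor ring
  (periodic) among excitatory neurons, ratio R_sw, average 0.2
  conserved;
- **hierarchical** — 16 top groups × 2 subgroups, three probability
  tiers p_sub = R_sub·p_group, p_group = R_top·p_out solved against
  the 0.2 average; within-subgroup weight w_sub = 0.0163, all other
  E-E weights 0.0156;
- **scale_free** — Barabási-Albert preferential attachment on the
  excitatory population (networkx implementation; d = 64 attachments
  per node), adjacency used in both directions at w^EE. No partition
  is meaningful; the hub rank order is recorded instead.

For unclustered, small-world and scale-free networks the SSA metrics
still need a partition; contiguous equal blocks of excitatory indices
serve as putative assemblies (their scores form the null reference).

## LIF simulation

Per neuron: dV_i/dt = (μ_i − V_i)/τ_m + Σ_j W_ij g_j, threshold 1,
reset 0, refractory 5 ms; τ_m = 15 ms (E) / 10 ms (I); μ_i drawn once
uniformly in [1.1, 1.2] (E) / [1, 1.05] (I); synaptic gates g_j jump
by 1 one time step after each presynaptic spike and decay with
τ_E = 3 ms / τ_I = 2 ms; dt = 0.1 ms. The supra-threshold constant
drive is offset by the inhibition-dominated recurrent input (expected
net input to an excitatory neuron at reference: 0.2·1600·0.0156 +
0.5·400·(−0.0297) = −0.948).

Numerics: since all gates of one type share a decay constant, the
summed drives h_E, h_I evolve in closed form (multiply by
exp(−dt/τ) per step, add column W[:, j] on presynaptic spikes); the
membrane is advanced by exponential-Euler treating the drive as
constant within a step. Spikes are detected at step boundaries, no
sub-step interpolation; refractoriness is enforced by an integer step
counter (a floating-point countdown accumulates rounding and
lengthens the period by one step). Initial V ~ U[0, 1) per seed; the
one-step synaptic delay avoids same-step causality ambiguity. With
W = 0 the simulated inter-spike interval matches the closed form
τ_m ln(μ/(μ−1)) + 5 ms within one dt; halving dt changes the
reference network's population rate by < 5%.

## Stylized rate models

Both models follow τ dr/dt = −(I − W) r + ξ with rates measured
relative to baseline. ξ is additive white Gaussian noise
(Euler-Maruyama, per-component sd `noise_sd·√dt`, default
noise_sd = 0.1; its law is a modeling choice).

**3-node** (two excitatory clusters + shared inhibition), with
s > ε > 0, k ≥ 1, w = s + ε:

```
W3 = [[ s,   ε,  −kw],
      [ ε,   s,  −kw],
      [w/2, w/2, −kw]]
```

Exact eigenvalues (−w(k−1), 0, s−ε); Schur basis u1 = (1,1,1)/√3,
u2 = (0.5,0.5,−1)/√1.5, u3 = (−1,1,0)/√2. The switching mode u3 is an
antagonistic pattern on the two clusters, zero on the inhibitory node,
and dynamically uncoupled; its drift eigenvalue is −1 + (s−ε), so
stability requires s − ε < 1 and the eigengap λ₃ − λ₂ = s − ε sets the
slow timescale 1/(1−(s−ε)). The feedforward entry coupling the global
modes is Q₁₂ = √2 (k + 1/2) w for the unit-norm basis (this resolved
form is verified against the reconstruction W = U Q Uᵀ, which holds to
machine precision and is the binding contract).

**4-node** (two E-I feedback pairs, order e1, e2, i1, i2), with
w = (s + ε)/2:

```
W4 = [[w, w, −kε, −ks],
      [w, w, −ks, −kε],
      [s, ε, −kw, −kw],
      [ε, s, −kw, −kw]]
```

Its exact eigenvalues are (−(k−1)(s+ε), 0, +√k(s−ε), −√k(s−ε)) with
localized Schur modes u3 = (√k, −√k, 1, −1)/√(2k+2) and
u4 = (1, −1, −√k, √k)/√(2k+2): u3 correlates each excitatory group
with its paired inhibitory group and anti-correlates the two pairs;
u4 is the fastest, anti-paired mode. Feedforward terms
w⁺ = (k−1)(s+ε), w_ff = (k+1)(s+ε) (balanced amplification between
the global modes) and w_ff,2 = −(k−1)(s−ε) (coupling the localized
pair). The frequently quoted eigenvalues ±k(s−ε) and mode entries k
are the k ≈ 1 simplification; they coincide with the exact forms at
k = 1 (where also the printed stability bound k(s−ε) < 1 is exact).
The implemented stability margin uses the exact η_max = −1 + √k(s−ε),
which is the form that cross-validates against the numerical drift
spectrum for all k.

## Spectral diagnostics

- `spectrum` sorts eigenvalues by descending real part (slow
  timescales are set by real parts; conjugate pairs stay adjacent).
- `detect_gap` with a known group count uses m = c − 1; auto-detection
  maximizes the consecutive real-part difference within the top
  K = min(max(N/10, 10), 50) eigenvalues — the cap keeps screening
  from locking onto spurious spacings deep in the bulk.
- `dominant_schur_basis` computes a real ordered Schur decomposition
  (eigenvalues above the mid-gap threshold sorted to the leading
  block). A conjugate pair straddling the cut extends the basis by one
  column. Sign convention: first non-negligible component positive.
- `block_localization_score` is the mean energy fraction
  ‖Π u‖²/‖u‖² of basis columns under the projector onto
  block-constant vectors (zero on unassigned neurons). Group
  indicators score 1; an isotropic random vector scores ≈ c/N. No
  standard numeric score exists for this visual diagnostic; this
  projection score is the package's choice and is labeled as such in
  reports.
- The balance pair (damped global activation mode of a balanced
  network) is reported when the most-negative eigenvalue is complex
  and separated from its neighbor by > 10x the local eigenvalue
  spacing at the bulk edge; informational only.
- Winner-takes-all flag: λ_max ≥ 1. The linear condition is
  indicative, not exact, for the nonlinear LIF dynamics.

## SSA metrics

Group rates are spike counts per group and 100 ms window divided by
group size and window (Hz). Ŝ = time-mean of the across-group
standard deviation minus the mean of 10 partition-shuffled surrogates
(shuffles permute group labels among exactly the partitioned neurons,
preserving sizes, with an RNG independent of the simulation).
Ŝ_T = group-mean of the across-time standard deviation, corrected the
same way; it distinguishes slow switching (high Ŝ_T) from one
permanently dominant assembly (high Ŝ, low Ŝ_T). Standard deviations
use the population convention (ddof = 0); the choice is fixed and
recorded here.

PCA patterns: per-neuron rates in 250 ms bins, row-centered (no
variance scaling), left singular vectors; the leading c − 1 patterns
span the observed subspace. Alignment is the first principal angle
between that span and the dominant Schur subspace,
cos θ = largest singular value of the orthonormalized cross-Gram.

## Sweeps and seeds

`run_point` composes generate → simulate → spectral → metrics; a
master seed expands into independent per-stage seeds (topology,
initial conditions, shuffles) via `SeedSequence` spawn keys, so
results are reproducible end-to-end and stages can be re-run in
isolation. Default sweep grids are scaled down (3 seeds, 10 s, N =
1000) relative to the reference 20 s runs to stay desk-scale; the
acceptance checks use these stated conditions.

## What the generators do and do not emulate

The synthetic networks reproduce the stated ensemble: Bernoulli
block-structured connectivity, exact average conservation,
inhibition-dominated balance, and the 1/N weight scaling. They do not
model lognormal weight/degree distributions, distance-dependent
connectivity, synaptic delays beyond one step, conductance synapses,
or plasticity. A green metric therefore establishes behavior of this
idealized ensemble, not of biological microcircuits.

## Known limitations and open choices

- The exact probability/weight split uses potential-partner fractions
  with self excluded; other conventions ("kept the same" on realized
  averages) differ at O(1/N).
- Whether clustered draws should be reciprocal-symmetric rather than
  directed is unresolved in the literature the construction follows;
  directed matches the general convention for W and is used
  throughout.
- The scale-free generator follows networkx's Barabási-Albert
  initialization (empty d-node seed set) rather than a d-clique
  nucleus; hub ordering and the single separated eigenvalue are
  insensitive to this choice. Its E-E edge count is ≈ 38% of the
  unclustered reference (the accounting convention for the quoted
  "35%" is ambiguous between directed/undirected readings).
- Auto gap detection reports the largest consecutive difference, which
  on a gapless spectrum still returns some m; screening decisions
  should weigh the gap magnitude and the localization score together.
- S_hat of an unstructured network is a near-zero stochastic score
  with realization-to-realization spread of a few hundredths of a Hz;
  single printed values are indicative only.
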