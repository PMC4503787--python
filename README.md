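# ssanet

Predicting and measuring **slow-switching assembly (SSA) dynamics** in
balanced spiking networks from the spectrum of their synaptic weight
matrix.

In balanced excitatory-inhibitory networks with structured connectivity
(clustered excitatory groups, excitatory-to-inhibitory feedback pairs,
small-world rings, connectivity hierarchies), groups of neurons can fire
at an elevated rate for sustained epochs, with activity switching slowly
between groups. `ssanet` implements the full chain that links this
behavior to connectivity:

1. **Network generators** for signed directed weight matrices `W`
   (`W[i, j]` = weight of the synapse j → i) that conserve average
   connectivity and weight exactly as clustering ratios are varied.
2. A fast **leaky integrate-and-fire (LIF) simulator**
   (exponential-Euler, numba-compiled) with exponential synapses.
3. **Analytic linear rate models** — tau dr/dt = −(I − W) r + xi — for a
   3-node clustered circuit and a 4-node E-I feedback circuit, with
   closed-form Schur decompositions W = U Q Uᵀ and stability analysis.
4. **Spectral diagnostics**: eigengap detection (Δλ), ordered dominant
   Schur bases, block-localization scores, winner-takes-all flag
   (λ_max ≥ 1).
5. **SSA metrics** from spike rasters: spike-rate variability across
   groups (Ŝ) and across time (Ŝ_T), both bootstrap-corrected against
   shuffled partitions; PCA firing patterns; and the first principal
   angle θ between observed patterns and the dominant Schur subspace.

The central result the package operationalizes: SSA emerges when the
leading eigenvalues of `W` separate from the bulk (gap Δλ) *and* the
associated Schur vectors are block-localized on groups of neurons; in
the stylized 3-node model the gap is exactly the clustering strength,
λ₃ − λ₂ = s − ε, and the slow mode decays with time constant
1/(1 − (s − ε)), diverging at the stability boundary s − ε = 1. Beyond
λ_max ≥ 1 one assembly dominates and switching collapses
(winner-takes-all), detected by the fall of Ŝ_T.

## Worked example

```python
import numpy as np
from ssanet import (NetworkSpec, make_network, simulate, LIFParams,
                    spectral_summary, spike_rate_variability,
                    pca_firing_patterns, principal_angle)

spec = NetworkSpec(kind="clustered_prob", N=2000, c=20, R_EE=3.4, seed=0)
W, part = make_network(spec)

summ = spectral_summary(W, partition=part)
print(f"m={summ.m} gap={summ.gap:.3f} lambda_max={summ.lambda_max:.3f}")
print(f"localization leading={summ.localization_leading:.3f} "
      f"bulk={summ.localization_bulk:.3f}")

raster = simulate(W, LIFParams(duration=20.0, seed=1))
sv = spike_rate_variability(raster, part)
P = pca_firing_patterns(raster, n_components=summ.dominant_basis.shape[1])
align = principal_angle(P, summ.dominant_basis)
print(f"S_hat={sv.S_hat:.2f} Hz  theta={align.theta_deg:.1f} deg")
```

Output:

```
m=19 gap=0.138 lambda_max=0.560
localization leading=0.738 bulk=0.014
S_hat=6.56 Hz  theta=19.9 deg
```

Reading: the 20-assembly clustered network has 19 eigenvalues isolated
above the bulk (one per independent assembly contrast), whose Schur
vectors are ~50x more block-localized than bulk vectors; the simulated
dynamics show strong assembly rate heterogeneity (Ŝ ≈ 6.6 Hz versus
~0 for an unclustered network) and the observed firing patterns align
with the dominant Schur subspace (θ ≈ 20°, cos θ ≈ 0.94). The same
spec with `kind="unclustered"` gives Ŝ ≈ 0 and θ near 60-90°.

## Command line

```
ssa generate --kind clustered_prob --N 2000 --c 20 --R-EE 3.4 --seed 7 -o net.mtx
ssa simulate net.mtx --duration 20 --seed 3 -o raster.csv
ssa analyze net.mtx --m 19 -o spectral.json
ssa metrics raster.csv --network net.mtx -o scores.json
ssa sweep config.json -o results/
```

Weight matrices are Matrix Market files with a JSON sidecar (neuron
types + partition); rasters are `neuron_id,time_ms` CSV.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the analytic eigenvalues of the 3-node rate
model and its drift matrix; the stability thresholds of both rate
models located by bisection on the numerically computed drift spectrum;
the number of eigenvalues above the auto-detected gap of the clustered
N=2000 reference network (3 realizations, modal count); and the
unclustered 20 s LIF baseline Ŝ (mean of 3 realizations). Runtime is a
few minutes on one CPU. See `docs/methods.md` for model details and
numerical conventions.
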