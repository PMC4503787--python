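"""Quantifying slow-switching assembly dynamics from spike rasters.

Two complementary spike-rate variability scores, both computed on the
c x T matrix of mean group firing rates in non-overlapping 100 ms
windows and referenced against a shuffled-partition bootstrap:

* ``S`` averages over time the standard deviation *across groups* of
  the instantaneous group rates; large values mean some assemblies
  fire above others.  ``S_hat = S - <S_shuff>`` subtracts the mean of
  10 random reshufflings of neurons into equally sized groups, so an
  unstructured raster scores ~0.
* ``S_T`` averages over groups the standard deviation *across time* of
  each group-rate trace; it distinguishes true switching from a single
  permanently dominant assembly (whose across-time variation is low).
  ``S_hat_T`` is bootstrap-corrected the same way.

Alignment of the observed dynamics with the connectivity is measured
by the first principal angle between the span of the leading c - 1
principal components of per-neuron binned rates (250 ms bins) and the
dominant Schur subspace of W: cos(theta) ~ 1 indicates the firing
patterns live in the slow subspace predicted from structure alone.

Standard deviations use the population convention (ddof = 0) and
rates are reported in Hz per neuron.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from ssanet.lif import SpikeRaster
from ssanet.topology import Partition

__all__ = [
    "GroupRateMatrix", "VariabilityScores", "AlignmentResult",
    "group_rate_matrix", "spike_rate_variability",
    "temporal_rate_variability", "pca_firing_patterns", "principal_angle",
]


@dataclass
class GroupRateMatrix:
    rates: np.ndarray        # c x T, Hz
    window_ms: float
    partition: Partition


@dataclass
class VariabilityScores:
    S: float = np.nan
    S_shuff_mean: float = np.nan
    S_hat: float = np.nan
    S_T: float = np.nan
    S_T_shuff_mean: float = np.nan
    S_hat_T: float = np.nan
    n_shuffles: int = 10
    shuffle_seed: int = 0


@dataclass
class AlignmentResult:
    theta_deg: float
    cos_theta: float
    pattern_basis: np.ndarray
    schur_basis: np.ndarray


def _binned_counts(raster: SpikeRaster, neuron_ids: np.ndarray,
                   window_ms: float) -> tuple[np.ndarray, int]:
    """Spike counts per (neuron, window); drops the trailing partial bin."""
    T = int(raster.duration_ms // window_ms)
    if T < 1:
        raise ValueError("window longer than the simulation")
    sel = np.isin(raster.neurons, neuron_ids)
    remap = np.full(raster.N, -1)
    remap[neuron_ids] = np.arange(neuron_ids.size)
    rows = remap[raster.neurons[sel]]
    # times lie in (0, duration]; clip the exact right edge into the last bin
    cols = np.minimum((raster.times[sel] / window_ms).astype(int), T - 1)
    keep = cols < T
    counts = np.zeros((neuron_ids.size, T))
    np.add.at(counts, (rows[keep], cols[keep]), 1.0)
    return counts, T


def group_rate_matrix(raster: SpikeRaster, partition: Partition,
                      window_ms: float = 100.0) -> GroupRateMatrix:
    """Mean firing rate (Hz) of each partition group per time window."""
    ids = partition.assigned
    if ids.size == 0:
        raise ValueError("partition covers no neurons")
    counts, T = _binned_counts(raster, ids, window_ms)
    g = partition.group_of[ids]
    c = partition.n_groups
    sizes = partition.group_sizes().astype(float)
    group_counts = np.zeros((c, T))
    np.add.at(group_counts, g, counts)
    rates = group_counts / sizes[:, None] / (window_ms / 1000.0)
    return GroupRateMatrix(rates=rates, window_ms=window_ms,
                           partition=partition)


def _S_from_rates(rates: np.ndarray) -> float:
    """Time-mean of the across-group standard deviation (population)."""
    return float(rates.std(axis=0, ddof=0).mean())


def _S_T_from_rates(rates: np.ndarray) -> float:
    """Group-mean of the across-time standard deviation (population)."""
    return float(rates.std(axis=1, ddof=0).mean())


def _shuffled_stats(counts: np.ndarray, g: np.ndarray, sizes: np.ndarray,
                    window_ms: float, stat, n_shuffles: int,
                    rng: np.random.Generator) -> float:
    c = sizes.size
    vals = np.empty(n_shuffles)
    for r in range(n_shuffles):
        perm = rng.permutation(g)
        gc = np.zeros((c, counts.shape[1]))
        np.add.at(gc, perm, counts)
        vals[r] = stat(gc / sizes[:, None] / (window_ms / 1000.0))
    return float(vals.mean())


def _variability(raster: SpikeRaster, partition: Partition,
                 window_ms: float, n_shuffles: int, seed: int,
                 stat) -> tuple[float, float]:
    if partition.n_groups < 2:
        raise ValueError("need at least two groups")
    ids = partition.assigned
    counts, _ = _binned_counts(raster, ids, window_ms)
    g = partition.group_of[ids]
    sizes = partition.group_sizes().astype(float)
    c = sizes.size
    gc = np.zeros((c, counts.shape[1]))
    np.add.at(gc, g, counts)
    S = stat(gc / sizes[:, None] / (window_ms / 1000.0))
    rng = np.random.default_rng(seed)
    S_shuff = _shuffled_stats(counts, g, sizes, window_ms, stat,
                              n_shuffles, rng)
    return S, S_shuff


def spike_rate_variability(raster: SpikeRaster, partition: Partition,
                           window_ms: float = 100.0, n_shuffles: int = 10,
                           seed: int = 0) -> VariabilityScores:
    """Across-group score S and its bootstrap-corrected S_hat (Hz).

    Shuffles permute the group assignment uniformly among exactly the
    partitioned neurons, preserving group sizes; the shuffle RNG is
    seeded independently of the simulation.
    """
    S, S_shuff = _variability(raster, partition, window_ms, n_shuffles,
                              seed, _S_from_rates)
    return VariabilityScores(S=S, S_shuff_mean=S_shuff, S_hat=S - S_shuff,
                             n_shuffles=n_shuffles, shuffle_seed=seed)


def temporal_rate_variability(raster: SpikeRaster, partition: Partition,
                              window_ms: float = 100.0, n_shuffles: int = 10,
                              seed: int = 0) -> VariabilityScores:
    """Across-time score S_T and its bootstrap-corrected S_hat_T (Hz)."""
    S_T, S_T_shuff = _variability(raster, partition, window_ms, n_shuffles,
                                  seed, _S_T_from_rates)
    return VariabilityScores(S_T=S_T, S_T_shuff_mean=S_T_shuff,
                             S_hat_T=S_T - S_T_shuff,
                             n_shuffles=n_shuffles, shuffle_seed=seed)


def pca_firing_patterns(raster: SpikeRaster, bin_ms: float = 250.0,
                        n_components: int = 19) -> np.ndarray:
    """Leading principal firing patterns of per-neuron binned rates.

    Builds the N x T matrix of per-neuron rates in ``bin_ms`` bins,
    subtracts each neuron's mean (no variance scaling), and returns
    the first ``n_components`` left singular vectors: N-dimensional
    activation patterns.  If the matrix has lower rank, the available
    components are returned.
    """
    all_ids = np.arange(raster.N)
    counts, T = _binned_counts(raster, all_ids, bin_ms)
    if T < n_components:
        raise ValueError(f"only {T} bins for {n_components} components")
    rates = counts / (bin_ms / 1000.0)
    centered = rates - rates.mean(axis=1, keepdims=True)
    U, sv, _ = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(sv > sv[0] * 1e-12)) if sv.size else 0
    return U[:, :min(n_components, rank)]


def principal_angle(P: np.ndarray, U: np.ndarray) -> AlignmentResult:
    """First principal angle between the subspaces spanned by P and U.

    Both bases are orthonormalized; cos(theta) is the largest singular
    value of the cross-Gram matrix, i.e. the maximum correlation
    achievable between unit vectors of the two subspaces.
    """
    P = np.atleast_2d(np.asarray(P, float))
    U = np.atleast_2d(np.asarray(U, float))
    if P.ndim != 2 or U.ndim != 2 or P.shape[0] != U.shape[0]:
        raise ValueError("bases must share the ambient dimension")
    Po = sla.orth(P)
    Uo = sla.orth(U)
    sv = np.linalg.svd(Uo.T @ Po, compute_uv=False)
    cos_t = float(np.clip(sv[0], 0.0, 1.0))
    theta = float(np.degrees(np.arccos(cos_t)))
    return AlignmentResult(theta_deg=theta, cos_theta=cos_t,
                           pattern_basis=P, schur_basis=U)
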