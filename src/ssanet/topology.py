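"""Generators for balanced excitatory-inhibitory weight matrices.

All generators produce a signed, directed synaptic weight matrix ``W``
with the convention that ``W[i, j]`` is the weight of the connection
from neuron ``j`` onto neuron ``i`` (columns are presynaptic).  Columns
obey Dale's principle: excitatory columns are non-negative, inhibitory
columns non-positive.  Self-connections are excluded.

The reference network has N = 2000 neurons (1600 excitatory, 400
inhibitory; the 4:1 ratio is fixed).  Baseline connection probabilities
are p^EE = 0.2 and p^EI = p^IE = p^II = 0.5, with synaptic weights
w^EE = 0.0156, w^IE = 0.0074, w^EI = w^II = -0.0297 (first superscript
is the destination type).  For other sizes every weight is scaled by
2000/N, the usual 1/N scaling of balanced networks.

Structured variants (clustered, co-clustered, small-world,
hierarchical) redistribute probability or weight between an in-group
and an out-group value while *exactly* conserving the block average,
via :func:`solve_in_out`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np

__all__ = [
    "BASE_PROBS", "BASE_WEIGHTS", "REFERENCE_N",
    "NetworkSpec", "WeightMatrix", "Partition",
    "solve_in_out", "scale_weights_for_size", "make_network",
    "make_unclustered", "make_clustered", "make_ei_coclustered",
    "make_small_world", "make_scale_free", "make_hierarchical",
]

REFERENCE_N = 2000

#: Connection probabilities, keyed (destination, origin).
BASE_PROBS = {"EE": 0.2, "EI": 0.5, "IE": 0.5, "II": 0.5}

#: Synaptic weights at the N = 2000 reference, keyed (destination, origin).
BASE_WEIGHTS = {"EE": 0.0156, "IE": 0.0074, "EI": -0.0297, "II": -0.0297}

Kind = Literal[
    "unclustered", "clustered_prob", "clustered_weight",
    "ei_coclustered", "small_world", "scale_free", "hierarchical",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Configuration for one network realization.

    Parameters not relevant to ``kind`` are ignored.  Ratios are
    dimensionless in-group / out-group quotients; ``R_EI`` / ``W_EI``
    are *inverse* ratios (in-pair inhibition weaker when > 1).
    """

    kind: Kind = "unclustered"
    N: int = REFERENCE_N
    c: int = 20
    R_EE: float = 1.0
    W_EE: float = 1.0
    R_EI: float = 1.0
    R_IE: float = 1.0
    W_EI: float = 1.0
    W_IE: float = 1.0
    R_sw: float = 1.0
    sw_radius: int = 40
    R_top: float = 1.0
    R_sub: float = 1.0
    w_sub: float = 0.0163
    n_top: int = 16
    n_sub: int = 2
    d: int = 64
    base_probs: dict = field(default_factory=lambda: dict(BASE_PROBS))
    base_weights: dict = field(default_factory=lambda: dict(BASE_WEIGHTS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N % 5:
            raise ValueError("N must be divisible by 5 for the 4:1 E:I ratio")
        for name in ("R_EE", "W_EE", "R_EI", "R_IE", "W_EI", "W_IE",
                     "R_sw", "R_top", "R_sub"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for key, p in self.base_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"base probability {key}={p} outside [0, 1]")
        if self.base_weights["EE"] <= 0 or self.base_weights["IE"] <= 0:
            raise ValueError("excitatory weights must be positive")
        if self.base_weights["EI"] >= 0 or self.base_weights["II"] >= 0:
            raise ValueError("inhibitory weights must be negative")

    @property
    def N_E(self) -> int:
        return 4 * self.N // 5

    @property
    def N_I(self) -> int:
        return self.N // 5

    def replace(self, **kw) -> "NetworkSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class WeightMatrix:
    """Signed directed weight matrix with neuron-type labels.

    ``values[i, j]`` is the synaptic weight j -> i; ``neuron_types`` is
    a length-N array of ``"E"`` / ``"I"``.
    """

    values: np.ndarray
    neuron_types: np.ndarray

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def excitatory(self) -> np.ndarray:
        return self.neuron_types == "E"

    def validate(self) -> None:
        W, types = self.values, self.neuron_types
        if W.shape[0] != W.shape[1] or W.shape[0] != types.shape[0]:
            raise ValueError("shape mismatch between values and neuron_types")
        if np.any(np.diag(W) != 0.0):
            raise ValueError("self-connections present on the diagonal")
        exc = self.excitatory
        if np.any(W[:, exc] < 0) or np.any(W[:, ~exc] > 0):
            raise ValueError("column sign violates neuron type (Dale)")


@dataclass
class Partition:
    """Assignment of neurons to groups.

    ``group_of`` maps neuron index -> group id, with -1 for neurons not
    covered (e.g. inhibitory neurons in E-only designs).  ``scope``
    records which types are partitioned.  ``levels`` optionally holds
    coarser-to-finer nested assignments (hierarchical designs); the
    finest level equals ``group_of``.
    """

    group_of: np.ndarray
    scope: Literal["E", "EI", "none"] = "E"
    levels: list[np.ndarray] | None = None

    @property
    def n_groups(self) -> int:
        assigned = self.group_of[self.group_of >= 0]
        return 0 if assigned.size == 0 else int(assigned.max()) + 1

    @property
    def assigned(self) -> np.ndarray:
        return np.flatnonzero(self.group_of >= 0)

    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.group_of[self.group_of >= 0],
                           minlength=self.n_groups)

    def members(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.group_of == g)


def solve_in_out(avg: float, ratio: float, f_in: float,
                 probability: bool = False) -> tuple[float, float]:
    """Split an average value into (in-group, out-group) at a given ratio.

    Solves ``in = ratio * out`` subject to exact conservation of the
    average over potential partners, ``f_in * in + (1 - f_in) * out =
    avg``, where ``f_in`` is the fraction of potential partners that
    are in-group.  Works for negative averages (inhibitory weights).

    With ``probability=True`` the in-group value is rejected if it
    exceeds 1 (the requested ratio is unreachable for this partition).
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if not 0.0 < f_in < 1.0:
        raise ValueError("f_in must lie strictly between 0 and 1")
    out = avg / (1.0 + f_in * (ratio - 1.0))
    inn = ratio * out
    if probability and inn > 1.0:
        raise ValueError(
            f"in-group probability {inn:.4f} > 1: ratio {ratio} is too large "
            f"for f_in={f_in:.4g} at average {avg}")
    return inn, out


def scale_weights_for_size(weights: dict, N: int) -> dict:
    """Scale reference (N=2000) weights by 2000/N.

    Balanced-network weights scale as 1/N: e.g. at N = 1000 every
    weight is doubled relative to the N = 2000 reference.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    factor = REFERENCE_N / N
    return {k: v * factor for k, v in weights.items()}


# ---------------------------------------------------------------------------
# internal helpers

def _type_labels(spec: NetworkSpec) -> np.ndarray:
    return np.array(["E"] * spec.N_E + ["I"] * spec.N_I)


def _block_slices(spec: NetworkSpec) -> dict:
    E = slice(0, spec.N_E)
    I = slice(spec.N_E, spec.N)
    # key (destination, origin)
    return {"EE": (E, E), "EI": (E, I), "IE": (I, E), "II": (I, I)}


def _base_matrices(spec: NetworkSpec) -> tuple[np.ndarray, np.ndarray]:
    """Dense per-pair probability and weight matrices for the baseline."""
    w = scale_weights_for_size(spec.base_weights, spec.N)
    P = np.empty((spec.N, spec.N))
    V = np.empty((spec.N, spec.N))
    for key, (dst, src) in _block_slices(spec).items():
        P[dst, src] = spec.base_probs[key]
        V[dst, src] = w[key]
    return P, V


def _realize(spec: NetworkSpec, P: np.ndarray, V: np.ndarray,
             rng: np.random.Generator) -> WeightMatrix:
    """Draw independent Bernoulli edges per ordered pair and weight them."""
    mask = rng.random((spec.N, spec.N)) < P
    W = np.where(mask, V, 0.0)
    np.fill_diagonal(W, 0.0)
    return WeightMatrix(values=W, neuron_types=_type_labels(spec))


def _contiguous_groups(n: int, c: int) -> np.ndarray:
    if n % c:
        raise ValueError(f"{n} neurons not divisible into {c} equal groups")
    return np.repeat(np.arange(c), n // c)


def _putative_partition(spec: NetworkSpec) -> Partition:
    """Contiguous equal E-groups used when no structure is embedded.

    The variability metrics require a partition even for unclustered or
    ring-like networks; contiguous blocks of excitatory indices serve
    as the putative assemblies.
    """
    group_of = np.full(spec.N, -1)
    group_of[: spec.N_E] = _contiguous_groups(spec.N_E, spec.c)
    return Partition(group_of=group_of, scope="E")


# ---------------------------------------------------------------------------
# generators

def make_unclustered(spec: NetworkSpec) -> tuple[WeightMatrix, Partition]:
    """Erdos-Renyi balanced network at the baseline probabilities."""
    rng = np.random.default_rng(spec.seed)
    P, V = _base_matrices(spec)
    return _realize(spec, P, V, rng), _putative_partition(spec)


def make_clustered(spec: NetworkSpec,
                   mode: Literal["prob", "weight"] | None = None,
                   ) -> tuple[WeightMatrix, Partition]:
    """E-E clustered network, by connection probability or by weight.

    ``prob`` mode raises the in-group connection probability by the
    factor ``R_EE`` (out-group lowered to conserve the 0.2 average);
    ``weight`` mode keeps p^EE uniform and redistributes the synaptic
    weight by ``W_EE`` instead, conserving the 0.0156 average.
    """
    if mode is None:
        mode = "weight" if spec.kind == "clustered_weight" else "prob"
    ratio = spec.R_EE if mode == "prob" else spec.W_EE
    if ratio < 1.0:
        raise ValueError("clustering ratio must be >= 1")
    rng = np.random.default_rng(spec.seed)
    P, V = _base_matrices(spec)
    part = _putative_partition(spec)

    g = part.group_of[: spec.N_E]
    same = g[:, None] == g[None, :]
    n_g = spec.N_E // spec.c
    f_in = (n_g - 1) / (spec.N_E - 1)  # self excluded
    EE = (slice(0, spec.N_E),) * 2
    if mode == "prob":
        p_in, p_out = solve_in_out(spec.base_probs["EE"], spec.R_EE, f_in,
                                   probability=True)
        P[EE] = np.where(same, p_in, p_out)
    else:
        w_ref = scale_weights_for_size(spec.base_weights, spec.N)["EE"]
        w_in, w_out = solve_in_out(w_ref, spec.W_EE, f_in)
        V[EE] = np.where(same, w_in, w_out)
    return _realize(spec, P, V, rng), part


def make_ei_coclustered(spec: NetworkSpec) -> tuple[WeightMatrix, Partition]:
    """Network with excitatory-to-inhibitory feedback-loop pairs.

    Each of ``c`` pairs couples a group of excitatory neurons with an
    associated group of inhibitory neurons: E -> I connections are
    preferentially strong within the pair (ratios ``R_IE`` / ``W_IE``),
    while the I -> E feedback is preferentially *weak* within the pair
    (``R_EI`` / ``W_EI`` are inverse in/out ratios, as befits an
    inhibitory effect).  E-E and I-I couplings stay uniform, and all
    block averages are conserved.
    """
    for name in ("R_EI", "R_IE", "W_EI", "W_IE"):
        if getattr(spec, name) < 1.0:
            raise ValueError(f"{name} must be >= 1")
    rng = np.random.default_rng(spec.seed)
    P, V = _base_matrices(spec)
    w = scale_weights_for_size(spec.base_weights, spec.N)

    gE = _contiguous_groups(spec.N_E, spec.c)
    gI = _contiguous_groups(spec.N_I, spec.c)
    pair_IE = gI[:, None] == gE[None, :]   # dest I, src E
    pair_EI = gE[:, None] == gI[None, :]   # dest E, src I
    f_in_IE = (spec.N_E // spec.c) / spec.N_E
    f_in_EI = (spec.N_I // spec.c) / spec.N_I

    IE = (slice(spec.N_E, spec.N), slice(0, spec.N_E))
    EI = (slice(0, spec.N_E), slice(spec.N_E, spec.N))
    p_in, p_out = solve_in_out(spec.base_probs["IE"], spec.R_IE, f_in_IE,
                               probability=True)
    P[IE] = np.where(pair_IE, p_in, p_out)
    # inverse ratio: in-pair inhibition is the *weaker* one
    p_in, p_out = solve_in_out(spec.base_probs["EI"], 1.0 / spec.R_EI,
                               f_in_EI, probability=True)
    P[EI] = np.where(pair_EI, p_in, p_out)
    w_in, w_out = solve_in_out(w["IE"], spec.W_IE, f_in_IE)
    V[IE] = np.where(pair_IE, w_in, w_out)
    w_in, w_out = solve_in_out(w["EI"], 1.0 / spec.W_EI, f_in_EI)
    V[EI] = np.where(pair_EI, w_in, w_out)

    group_of = np.concatenate([gE, gI])
    return (_realize(spec, P, V, rng),
            Partition(group_of=group_of, scope="EI"))


def make_small_world(spec: NetworkSpec) -> tuple[WeightMatrix, Partition]:
    """Watts-Strogatz-like ring backbone among excitatory neurons.

    Excitatory neuron i connects to j with elevated probability when
    ``|i - j| <= sw_radius`` on a periodic ring (ratio ``R_sw``), and
    with a correspondingly reduced probability elsewhere, keeping the
    average at p^EE = 0.2.  Other blocks are unclustered.
    """
    if spec.R_sw < 1.0:
        raise ValueError("R_sw must be >= 1")
    rng = np.random.default_rng(spec.seed)
    P, V = _base_matrices(spec)

    idx = np.arange(spec.N_E)
    dist = np.abs(idx[:, None] - idx[None, :])
    dist = np.minimum(dist, spec.N_E - dist)
    ring = (dist <= spec.sw_radius) & (dist > 0)
    f_in = (2 * spec.sw_radius) / (spec.N_E - 1)
    p_in, p_out = solve_in_out(spec.base_probs["EE"], spec.R_sw, f_in,
                               probability=True)
    EE = (slice(0, spec.N_E),) * 2
    P[EE] = np.where(ring, p_in, p_out)
    return _realize(spec, P, V, rng), _putative_partition(spec)


def make_scale_free(spec: NetworkSpec) -> tuple[WeightMatrix, Partition]:
    """Preferential-attachment (Barabasi-Albert) excitatory topology.

    The E-E graph is grown undirected, one node at a time, each new
    node attaching to ``d`` existing nodes with probability
    proportional to their current degree; the adjacency is then used
    in both directions with weight w^EE.  Earlier nodes become hubs.
    Other blocks are unclustered.  No partition is meaningful here;
    the hub rank order (descending degree) is recorded instead.
    """
    if not 1 <= spec.d < spec.N_E:
        raise ValueError("need 1 <= d < N_E")
    rng = np.random.default_rng(spec.seed)
    P, V = _base_matrices(spec)
    w = scale_weights_for_size(spec.base_weights, spec.N)

    G = nx.barabasi_albert_graph(spec.N_E, spec.d, seed=int(spec.seed))
    A = nx.to_numpy_array(G, nodelist=range(spec.N_E), dtype=float)
    mask = rng.random((spec.N, spec.N)) < P
    W = np.where(mask, V, 0.0)
    W[: spec.N_E, : spec.N_E] = A * w["EE"]
    np.fill_diagonal(W, 0.0)
    wm = WeightMatrix(values=W, neuron_types=_type_labels(spec))

    part = Partition(group_of=np.full(spec.N, -1), scope="none")
    degree = A.sum(axis=0)
    part.hub_order = np.argsort(-degree)  # informational attribute
    return wm, part


def make_hierarchical(spec: NetworkSpec) -> tuple[WeightMatrix, Partition]:
    """Two-level nested clustering of the excitatory neurons.

    E neurons are divided into ``n_top`` top-level groups, each split
    into ``n_sub`` subgroups (16 x 2 = 32 at the reference size).
    Connection probabilities form three tiers,
    ``p_sub = R_sub * p_group`` and ``p_group = R_top * p_out``, solved
    so the overall E-E average stays at 0.2.  Within-subgroup synapses
    carry the slightly elevated weight ``w_sub``; every other E-E
    synapse keeps w^EE.
    """
    rng = np.random.default_rng(spec.seed)
    P, V = _base_matrices(spec)
    w = scale_weights_for_size(spec.base_weights, spec.N)
    w_sub = spec.w_sub * REFERENCE_N / spec.N

    n_groups = spec.n_top * spec.n_sub
    top = _contiguous_groups(spec.N_E, spec.n_top)
    sub = _contiguous_groups(spec.N_E, n_groups)
    n_sub_sz = spec.N_E // n_groups
    n_top_sz = spec.N_E // spec.n_top

    # three-tier average over the N_E - 1 potential partners of a neuron
    f_sub = (n_sub_sz - 1) / (spec.N_E - 1)
    f_group = (n_top_sz - n_sub_sz) / (spec.N_E - 1)
    f_out = (spec.N_E - n_top_sz) / (spec.N_E - 1)
    denom = f_sub * spec.R_top * spec.R_sub + f_group * spec.R_top + f_out
    p_out = spec.base_probs["EE"] / denom
    p_group = spec.R_top * p_out
    p_sub = spec.R_sub * p_group
    if p_sub > 1.0:
        raise ValueError(f"within-subgroup probability {p_sub:.4f} > 1")

    same_top = top[:, None] == top[None, :]
    same_sub = sub[:, None] == sub[None, :]
    EE = (slice(0, spec.N_E),) * 2
    P[EE] = np.where(same_sub, p_sub, np.where(same_top, p_group, p_out))
    V[EE] = np.where(same_sub, w_sub, w["EE"])

    group_of = np.full(spec.N, -1)
    group_of[: spec.N_E] = sub
    top_of = np.full(spec.N, -1)
    top_of[: spec.N_E] = top
    part = Partition(group_of=group_of, scope="E",
                     levels=[top_of, group_of])
    return _realize(spec, P, V, rng), part


_GENERATORS = {
    "unclustered": make_unclustered,
    "clustered_prob": make_clustered,
    "clustered_weight": make_clustered,
    "ei_coclustered": make_ei_coclustered,
    "small_world": make_small_world,
    "scale_free": make_scale_free,
    "hierarchical": make_hierarchical,
}


def make_network(spec: NetworkSpec) -> tuple[WeightMatrix, Partition]:
    """Dispatch to the generator selected by ``spec.kind``."""
    try:
        gen = _GENERATORS[spec.kind]
    except KeyError:
        raise ValueError(f"unknown network kind {spec.kind!r}") from None
    return gen(spec)
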