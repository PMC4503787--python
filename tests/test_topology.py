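"""Generators: conservation laws, Dale signs, reproducibility."""

import numpy as np
import pytest

from ssanet.topology import (BASE_PROBS, BASE_WEIGHTS, NetworkSpec,
                             make_clustered, make_ei_coclustered,
                             make_hierarchical, make_network,
                             make_scale_free, make_small_world,
                             make_unclustered, scale_weights_for_size,
                             solve_in_out)


class TestSolveInOut:
    def test_ratio_one_is_identity(self):
        assert solve_in_out(0.2, 1.0, 0.3) == (0.2, 0.2)

    def test_clustered_reference_values(self):
        # f_in for 20 groups of 80 excitatory neurons, self excluded
        f_in = (80 - 1) / (1600 - 1)
        inn, out = solve_in_out(0.2, 3.4, f_in, probability=True)
        assert out == pytest.approx(0.2 / (1 + f_in * 2.4))
        assert inn == pytest.approx(3.4 * out)
        assert out == pytest.approx(0.1788, abs=5e-4)
        assert inn == pytest.approx(0.6079, abs=5e-4)

    @pytest.mark.parametrize("avg,ratio,f_in", [
        (0.2, 3.4, 0.0494), (0.5, 2.0, 0.05), (-0.0297, 0.25, 0.05),
        (0.0156, 10.0, 0.049),
    ])
    def test_conservation_identity(self, avg, ratio, f_in):
        inn, out = solve_in_out(avg, ratio, f_in)
        assert f_in * inn + (1 - f_in) * out == pytest.approx(avg, rel=1e-12)
        assert inn == pytest.approx(ratio * out, rel=1e-12)

    def test_probability_overflow_rejected(self):
        with pytest.raises(ValueError, match="> 1"):
            solve_in_out(0.2, 50.0, 0.05, probability=True)


class TestScaleWeights:
    def test_quoted_rule_n1000_doubles(self):
        assert scale_weights_for_size({"EE": 0.0156}, 1000)["EE"] == \
            pytest.approx(0.0312)

    def test_identity_at_reference(self):
        assert scale_weights_for_size(BASE_WEIGHTS, 2000) == BASE_WEIGHTS


def _block_density(W, dst, src):
    return (W.values[dst, src] != 0).mean()


class TestUnclustered:
    def test_block_densities_and_weights(self, small_unclustered):
        spec, W, part = small_unclustered
        NE = spec.N_E
        E, I = slice(0, NE), slice(NE, spec.N)
        for key, (dst, src) in {"EE": (E, E), "EI": (E, I),
                                "IE": (I, E), "II": (I, I)}.items():
            p = BASE_PROBS[key]
            n = W.values[dst, src].size
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(_block_density(W, dst, src) - p) < 3 * sigma + 2 / n
        # inhibitory columns carry only the inhibitory weights or zero
        vals = np.unique(W.values[:, I])
        w = scale_weights_for_size(BASE_WEIGHTS, spec.N)
        assert set(np.round(vals, 12)) <= {0.0, round(w["EI"], 12),
                                           round(w["II"], 12)}

    def test_balanced_expected_input_negative(self, small_unclustered):
        spec, W, _ = small_unclustered
        # 0.2*1600*0.0156 + 0.5*400*(-0.0297) = -0.948 at reference scale,
        # invariant under the 1/N weight scaling
        net_E = W.values[: spec.N_E].sum(axis=1).mean()
        assert net_E == pytest.approx(-0.948, abs=0.15)

    def test_dale_and_no_self(self, small_unclustered):
        _, W, _ = small_unclustered
        W.validate()


class TestClustered:
    def test_realized_density_ratio(self, small_clustered):
        spec, W, part = small_clustered
        g = part.group_of[: spec.N_E]
        EE = W.values[: spec.N_E, : spec.N_E] != 0
        same = g[:, None] == g[None, :]
        np.fill_diagonal(same, False)
        inn = EE[same].mean()
        out = EE[~same & ~np.eye(spec.N_E, dtype=bool)].mean()
        assert inn / out == pytest.approx(3.4, rel=0.1)

    def test_average_density_conserved(self, small_clustered):
        spec, W, _ = small_clustered
        EE = W.values[: spec.N_E, : spec.N_E] != 0
        off = ~np.eye(spec.N_E, dtype=bool)
        assert EE[off].mean() == pytest.approx(0.2, abs=0.01)

    def test_weight_mode_mean_weight_conserved(self):
        spec = NetworkSpec(kind="clustered_weight", N=500, c=10,
                           W_EE=4.0, seed=3)
        W, part = make_clustered(spec, mode="weight")
        g = part.group_of[: spec.N_E]
        EE = W.values[: spec.N_E, : spec.N_E]
        same = g[:, None] == g[None, :]
        np.fill_diagonal(same, False)
        w_ref = scale_weights_for_size(BASE_WEIGHTS, spec.N)["EE"]
        w_in, w_out = solve_in_out(w_ref, 4.0, (40 - 1) / (400 - 1))
        nz = EE != 0
        assert np.allclose(np.unique(EE[nz & same]), w_in)
        assert np.allclose(np.unique(EE[nz & ~same]), w_out)
        # potential-pair average conserved exactly by construction
        f_in = (40 - 1) / (400 - 1)
        assert f_in * w_in + (1 - f_in) * w_out == pytest.approx(w_ref)

    def test_ratio_one_matches_unclustered_law(self):
        a, _ = make_clustered(NetworkSpec(kind="clustered_prob", N=500,
                                          c=10, R_EE=1.0, seed=9))
        b, _ = make_unclustered(NetworkSpec(kind="unclustered", N=500,
                                            c=10, seed=9))
        assert np.array_equal(a.values, b.values)

    def test_infeasible_ratio_rejected(self):
        with pytest.raises(ValueError, match="> 1"):
            make_clustered(NetworkSpec(kind="clustered_prob", N=500, c=10,
                                       R_EE=40.0, seed=0))


class TestEICoclustered:
    def test_inverse_ratio_weakens_in_pair_inhibition(self):
        spec = NetworkSpec(kind="ei_coclustered", N=500, c=5,
                           R_EI=2, R_IE=2, W_EI=3, W_IE=3, seed=4)
        W, part = make_ei_coclustered(spec)
        W.validate()
        NE = spec.N_E
        gE = part.group_of[:NE]
        gI = part.group_of[NE:]
        EI = W.values[:NE, NE:]
        pair = gE[:, None] == gI[None, :]
        w_in = np.unique(EI[(EI != 0) & pair])
        w_out = np.unique(EI[(EI != 0) & ~pair])
        assert w_in.size == 1 and w_out.size == 1
        assert abs(w_in[0]) < abs(w_out[0])  # in-pair inhibition weaker

    def test_category_weight_average_conserved(self):
        spec = NetworkSpec(kind="ei_coclustered", N=500, c=5,
                           R_EI=2, R_IE=2, W_EI=5, W_IE=5, seed=4)
        W, part = make_ei_coclustered(spec)
        NE = spec.N_E
        f = (spec.N_I // spec.c) / spec.N_I
        EI = W.values[:NE, NE:]
        pair = part.group_of[:NE][:, None] == part.group_of[NE:][None, :]
        w_in = EI[(EI != 0) & pair].mean()
        w_out = EI[(EI != 0) & ~pair].mean()
        w_ref = scale_weights_for_size(BASE_WEIGHTS, spec.N)["EI"]
        assert f * w_in + (1 - f) * w_out == pytest.approx(w_ref, rel=1e-9)

    def test_all_ratios_one_matches_unclustered_law(self):
        a, _ = make_ei_coclustered(NetworkSpec(kind="ei_coclustered",
                                               N=500, c=5, seed=7))
        b, _ = make_unclustered(NetworkSpec(kind="unclustered", N=500,
                                            c=5, seed=7))
        assert np.array_equal(a.values, b.values)


class TestSmallWorld:
    def test_density_conserved_and_ring_elevated(self):
        spec = NetworkSpec(kind="small_world", N=500, c=10, R_sw=4, seed=2)
        W, _ = make_small_world(spec)
        NE = spec.N_E
        EE = W.values[:NE, :NE] != 0
        off = ~np.eye(NE, dtype=bool)
        assert EE[off].mean() == pytest.approx(0.2, abs=0.015)
        idx = np.arange(NE)
        dist = np.abs(idx[:, None] - idx[None, :])
        dist = np.minimum(dist, NE - dist)
        ring = (dist <= 40) & (dist > 0)
        assert EE[ring].mean() / EE[off & ~ring].mean() == \
            pytest.approx(4.0, rel=0.15)

    def test_excessive_ratio_rejected(self):
        # narrow ring (f_in small): large R_sw pushes p_in past 1
        with pytest.raises(ValueError, match="> 1"):
            make_small_world(NetworkSpec(kind="small_world", N=500,
                                         R_sw=50, sw_radius=5, seed=0))


class TestScaleFree:
    def test_tiny_tree(self):
        spec = NetworkSpec(kind="scale_free", N=5, c=1, d=1, seed=0)
        W, _ = make_scale_free(spec)
        A = W.values[: spec.N_E, : spec.N_E] != 0
        assert A.sum() == 2 * (spec.N_E - 1)  # tree, both directions

    def test_hub_is_early_node_and_symmetry(self):
        spec = NetworkSpec(kind="scale_free", N=500, c=1, d=16, seed=1)
        W, part = make_scale_free(spec)
        NE = spec.N_E
        A = W.values[:NE, :NE]
        assert np.array_equal(A, A.T)
        deg = (A != 0).sum(axis=0)
        assert part.hub_order[0] == np.argmax(deg)
        # earlier nodes dominate the degree ranking (in expectation)
        assert part.hub_order[0] < 4 * 16
        assert deg[:32].mean() > 1.5 * deg[32:].mean()


class TestHierarchical:
    def test_three_tier_average_exact(self):
        spec = NetworkSpec(kind="hierarchical", N=2000, R_top=1.45,
                           R_sub=3.7, seed=0)
        NE = spec.N_E
        f_sub, f_group, f_out = 49 / 1599, 50 / 1599, 1500 / 1599
        denom = f_sub * 1.45 * 3.7 + f_group * 1.45 + f_out
        p_out = 0.2 / denom
        assert f_sub * 3.7 * 1.45 * p_out + f_group * 1.45 * p_out + \
            f_out * p_out == pytest.approx(0.2, rel=1e-12)

    def test_nested_partition_and_weights(self):
        spec = NetworkSpec(kind="hierarchical", N=800, R_top=1.45,
                           R_sub=3.7, seed=6)
        W, part = make_hierarchical(spec)
        W.validate()
        top, sub = part.levels
        # each subgroup lies wholly inside one top group
        for s in range(int(sub.max()) + 1):
            assert np.unique(top[sub == s]).size == 1
        NE = spec.N_E
        EE = W.values[:NE, :NE]
        same_sub = sub[:NE][:, None] == sub[:NE][None, :]
        w_sub = 0.0163 * 2000 / spec.N
        nz = EE != 0
        assert np.allclose(EE[nz & same_sub], w_sub)

    def test_degenerate_ratios_match_unclustered_law(self):
        spec = NetworkSpec(kind="hierarchical", N=800, R_top=1, R_sub=1,
                           w_sub=0.0156, seed=9)
        a, _ = make_hierarchical(spec)
        b, _ = make_unclustered(NetworkSpec(kind="unclustered", N=800,
                                            c=16, seed=9))
        assert np.array_equal(a.values, b.values)


class TestReproducibility:
    @pytest.mark.parametrize("kind", ["unclustered", "clustered_prob",
                                      "ei_coclustered", "small_world",
                                      "scale_free", "hierarchical"])
    def test_same_seed_bitwise_identical(self, kind):
        spec = NetworkSpec(kind=kind, N=100, c=5, R_EE=2, R_sw=2,
                           sw_radius=5, R_top=1.2, R_sub=1.5, d=4,
                           n_top=4, n_sub=2, seed=13)
        a, _ = make_network(spec)
        b, _ = make_network(spec)
        assert np.array_equal(a.values, b.values)
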