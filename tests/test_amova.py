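"""AMOVA distance decomposition, variance components and permutation tests."""

import numpy as np
import pytest

from isopop import (
    AFLPMatrix,
    DistanceMatrix,
    amova_one_level,
    amova_two_level,
    binary_squared_distance,
    components_from_summary,
    pairwise_phi_pt,
)
from isopop.amova import NoMolecularVarianceError, ONE_LEVEL_STRATA, TWO_LEVEL_STRATA

from conftest import make_matrix


def anova_ss_oracle(X, pops):
    """Design-matrix ANOVA on the raw 0/1 data: per-locus sums of squares.

    For squared Euclidean distances the AMOVA sums of squares equal the
    per-locus ANOVA decomposition summed over loci.
    """
    X = np.asarray(X, dtype=float)
    sst = ((X - X.mean(axis=0)) ** 2).sum()
    ssw = 0.0
    for pop in dict.fromkeys(pops):
        idx = [i for i, p in enumerate(pops) if p == pop]
        block = X[idx]
        ssw += ((block - block.mean(axis=0)) ** 2).sum()
    return sst - ssw, ssw


class TestDistance:
    def test_identical_and_single_difference(self):
        X = np.array([[1, 0, 1], [1, 0, 1], [0, 0, 1], [0, 0, 1]])
        m = AFLPMatrix(
            X, ["a", "b", "c", "d"], ["P1", "P1", "P2", "P2"],
            {"P1": "R", "P2": "R"}, ["L1", "L2", "L3"],
        )
        d = binary_squared_distance(m)
        assert d.values[0, 1] == 0
        assert d.values[0, 2] == 1  # one differing locus

    def test_matches_pair_loop_oracle(self, rng):
        m = make_matrix(rng, n_pops=2, n_per_pop=5, n_loci=20, two_regions=False)
        d = binary_squared_distance(m)
        for i in range(m.n_samples):
            for j in range(m.n_samples):
                assert d.values[i, j] == np.sum(m.genotypes[i] != m.genotypes[j])

    def test_distance_matrix_contract(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 0.0]]))


class TestOneLevel:
    def test_all_variance_among(self):
        # two internally identical populations that differ from each other
        X = np.array([[1] * 6] * 4 + [[0] * 6] * 4)
        m = AFLPMatrix(
            X, [f"s{i}" for i in range(8)], ["P1"] * 4 + ["P2"] * 4,
            {"P1": "R", "P2": "R"}, [f"L{j}" for j in range(6)],
        )
        res = amova_one_level(binary_squared_distance(m), list(m.populations), n_perm=0)
        assert res.phi["Phi_PT"] == pytest.approx(1.0)
        assert res.percentages[ONE_LEVEL_STRATA[1]] == pytest.approx(0.0)

    def test_null_split_population(self, rng):
        # one homogeneous pool split arbitrarily into two labels
        X = rng.integers(0, 2, (40, 60)).astype(np.int8)
        pops = ["A"] * 20 + ["B"] * 20
        d = DistanceMatrix(
            [f"s{i}" for i in range(40)],
            binary_squared_distance(
                AFLPMatrix(X, [f"s{i}" for i in range(40)], pops,
                           {"A": "R", "B": "R"}, [f"L{j}" for j in range(60)])
            ).values,
        )
        res = amova_one_level(d, pops, n_perm=199, seed=7)
        assert abs(res.phi["Phi_PT"]) < 0.05
        assert res.perm_p["Phi_PT"] > 0.05

    def test_matches_design_matrix_oracle(self, rng):
        for _ in range(10):
            m = make_matrix(rng, n_pops=3, n_per_pop=4, n_loci=8, two_regions=False)
            ssa_o, ssw_o = anova_ss_oracle(m.genotypes, m.populations)
            res = amova_one_level(
                binary_squared_distance(m), list(m.populations), n_perm=0
            )
            assert res.strata[0].ss == pytest.approx(ssa_o, abs=1e-9)
            assert res.strata[1].ss == pytest.approx(ssw_o, abs=1e-9)
            # literal component formulas
            sizes = [4, 4, 4]
            N, k = 12, 3
            n0 = (N - sum(s**2 for s in sizes) / N) / (k - 1)
            ms_a, ms_w = ssa_o / (k - 1), ssw_o / (N - k)
            assert res.components[ONE_LEVEL_STRATA[0]] == pytest.approx(
                (ms_a - ms_w) / n0, abs=1e-9
            )

    def test_equal_sizes_n0_equals_n(self):
        from isopop.amova import _one_level_components

        _, _, n0 = _one_level_components(1.0, 1.0, [7, 7, 7, 7])
        assert n0 == pytest.approx(7.0)

    def test_invariance_to_locus_permutation_and_relabeling(self, rng):
        m = make_matrix(rng, n_pops=4, n_per_pop=5, n_loci=25)
        res = amova_one_level(binary_squared_distance(m), list(m.populations), n_perm=0)
        perm = rng.permutation(m.n_loci)
        m2 = AFLPMatrix(
            m.genotypes[:, perm], m.sample_ids, m.populations, m.region_of,
            [m.locus_ids[j] for j in perm],
        )
        res2 = amova_one_level(binary_squared_distance(m2), list(m2.populations), n_perm=0)
        assert res2.phi["Phi_PT"] == pytest.approx(res.phi["Phi_PT"], abs=1e-12)
        # shuffling individuals within their populations changes nothing
        order = np.arange(m.n_samples)
        for pop in m.population_labels:
            idx = m.rows_for(pop)
            order[idx] = rng.permutation(idx)
        m3 = AFLPMatrix(
            m.genotypes[order], [m.sample_ids[i] for i in order],
            [m.populations[i] for i in order], m.region_of, m.locus_ids,
        )
        res3 = amova_one_level(binary_squared_distance(m3), list(m3.populations), n_perm=0)
        assert res3.phi["Phi_PT"] == pytest.approx(res.phi["Phi_PT"], abs=1e-12)

    def test_no_variance_error(self):
        X = np.ones((4, 5), dtype=int)
        m = AFLPMatrix(
            X, list("abcd"), ["P1", "P1", "P2", "P2"],
            {"P1": "R", "P2": "R"}, [f"L{j}" for j in range(5)],
        )
        with pytest.raises(NoMolecularVarianceError):
            amova_one_level(binary_squared_distance(m), list(m.populations), n_perm=0)


class TestTwoLevel:
    def test_identical_regions_have_no_region_component(self, rng):
        # both regions assembled from the same homogeneous pool
        X = rng.integers(0, 2, (48, 40)).astype(np.int8)
        pops = [f"P{i}" for i in range(1, 5) for _ in range(12)]
        regions = ["R1"] * 24 + ["R2"] * 24
        m = AFLPMatrix(
            X, [f"s{i}" for i in range(48)], pops,
            {"P1": "R1", "P2": "R1", "P3": "R2", "P4": "R2"},
            [f"L{j}" for j in range(40)],
        )
        res = amova_two_level(
            binary_squared_distance(m), pops, regions, n_perm=99, seed=3
        )
        assert abs(res.phi["Phi_RT"]) < 0.05
        assert res.perm_p["Phi_RT"] > 0.05

    def test_literal_coefficient_oracle(self, rng):
        m = make_matrix(rng, n_pops=4, n_per_pop=5, n_loci=30)
        pops = list(m.populations)
        regions = list(m.regions_per_sample())
        d = binary_squared_distance(m)
        res = amova_two_level(d, pops, regions, n_perm=0)
        # literal formulas, spelled out independently
        sizes = {"R1": [5, 5], "R2": [5, 5]}
        N, P, G = 20, 4, 2
        s_g = sum(sum(s**2 for s in v) / sum(v) for v in sizes.values())
        n = (N - s_g) / (P - G)
        n_p = (s_g - sum(s**2 for v in sizes.values() for s in v) / N) / (G - 1)
        n_pp = (N - sum(sum(v) ** 2 for v in sizes.values()) / N) / (G - 1)
        ms = [s.ms for s in res.strata]
        sc = ms[2]
        sb = (ms[1] - sc) / n
        sa = (ms[0] - sc - n_p * sb) / n_pp
        assert res.components[TWO_LEVEL_STRATA[0]] == pytest.approx(sa, abs=1e-9)
        assert res.components[TWO_LEVEL_STRATA[1]] == pytest.approx(sb, abs=1e-9)
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-6)
        assert sum(s.df for s in res.strata) == m.n_samples - 1

    def test_strong_region_divergence_detected(self):
        from isopop import SimulationConfig, simulate_aflp

        # enough populations per region that the whole-population
        # permutation scheme can resolve p below 0.05
        cfg = SimulationConfig(
            n_regions=2, pops_per_region=6, inds_per_pop=8, n_loci=120,
            f_within=(0.05, 0.05), f_between=0.3, ibd_region=None, seed=9,
        )
        m, _ = simulate_aflp(cfg)
        res = amova_two_level(
            binary_squared_distance(m), list(m.populations),
            list(m.regions_per_sample()), n_perm=999, seed=10,
        )
        assert res.phi["Phi_RT"] > res.phi["Phi_PR"]
        assert res.perm_p["Phi_RT"] < 0.05


class TestFromSummary:
    def test_consistency_with_raw_run(self, rng):
        m = make_matrix(rng, n_pops=4, n_per_pop=6, n_loci=30)
        res = amova_one_level(binary_squared_distance(m), list(m.populations), n_perm=0)
        summ = components_from_summary(
            [(s.df, s.ss) for s in res.strata], [6, 6, 6, 6]
        )
        for name in ONE_LEVEL_STRATA:
            assert summ.components[name] == pytest.approx(res.components[name])
        assert summ.phi["Phi_PT"] == pytest.approx(res.phi["Phi_PT"])
        # and for the nested analysis
        res2 = amova_two_level(
            binary_squared_distance(m), list(m.populations),
            list(m.regions_per_sample()), n_perm=0,
        )
        summ2 = components_from_summary(
            [(s.df, s.ss) for s in res2.strata], {"R1": [6, 6], "R2": [6, 6]}
        )
        for name in TWO_LEVEL_STRATA:
            assert summ2.components[name] == pytest.approx(res2.components[name])

    def test_inconsistent_df_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            components_from_summary([(5, 100.0), (20, 50.0)], [5, 5, 5])


class TestPairwise:
    def test_identical_and_disjoint_pairs(self):
        X = np.vstack([
            np.tile([1, 0, 1, 0], (3, 1)),      # P1: all identical
            np.tile([1, 0, 1, 0], (3, 1)),      # P2: same as P1
            np.tile([0, 1, 0, 1], (3, 1)),      # P3: opposite pattern
        ]).astype(np.int8)
        m = AFLPMatrix(
            X, [f"s{i}" for i in range(9)],
            ["P1"] * 3 + ["P2"] * 3 + ["P3"] * 3,
            {"P1": "R", "P2": "R", "P3": "R"}, [f"L{j}" for j in range(4)],
        )
        res = pairwise_phi_pt(m)
        mat = res.matrix.to_dataframe()
        assert mat.loc["P1", "P2"] == pytest.approx(0.0)
        assert mat.loc["P1", "P3"] == pytest.approx(1.0)

    def test_matches_one_level_calls(self, rng):
        m = make_matrix(rng, n_pops=3, n_per_pop=5, n_loci=25, two_regions=False)
        res = pairwise_phi_pt(m)
        d = binary_squared_distance(m)
        for a, b in [("P1", "P2"), ("P1", "P3"), ("P2", "P3")]:
            idx = [i for i, p in enumerate(m.populations) if p in (a, b)]
            sub = DistanceMatrix(
                [m.sample_ids[i] for i in idx], d.values[np.ix_(idx, idx)]
            )
            single = amova_one_level(sub, [m.populations[i] for i in idx], n_perm=0)
            assert res.matrix.to_dataframe().loc[a, b] == pytest.approx(
                max(single.phi["Phi_PT"], 0.0)
            )
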