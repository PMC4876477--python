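"""The four stability algorithms: worked examples, oracles, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from refstab.ct_data import CtMatrix
from refstab.stability import (
    bestkeeper,
    delta_ct_stability,
    dense_ranks,
    genorm,
    normfinder,
    pairwise_delta_ct_sd,
)
from refstab.synthetic import (
    Effect,
    GeneSpec,
    SimulationDesign,
    default_design,
    simulate_ct,
)


def _random_ct(seed: int, n_samples: int = 12, n_genes: int = 5) -> CtMatrix:
    rng = np.random.default_rng(seed)
    return CtMatrix(
        rng.uniform(15, 35, size=(n_samples, n_genes)),
        [f"s{i}" for i in range(n_samples)],
        [f"g{j}" for j in range(n_genes)],
    )


def _shift_gene(ct: CtMatrix, gene: str, c: float) -> CtMatrix:
    vals = ct.values.copy()
    vals[:, ct.gene_ids.index(gene)] += c
    return CtMatrix(vals, ct.sample_ids, ct.gene_ids)


def _shift_sample(ct: CtMatrix, sample: str, c: float) -> CtMatrix:
    vals = ct.values.copy()
    vals[ct.sample_ids.index(sample), :] += c
    return CtMatrix(vals, ct.sample_ids, ct.gene_ids)


class TestPairwiseDeltaCt:
    def test_constant_offset_pair_has_zero_sd(self, toy_abc):
        sd = pairwise_delta_ct_sd(toy_abc)
        assert sd.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_pair(self, toy_abc):
        sd = pairwise_delta_ct_sd(toy_abc)
        assert sd.loc["A", "C"] == pytest.approx(1.2909944487358056, abs=1e-9)

    def test_symmetric_zero_diagonal(self, random_matrix):
        sd = pairwise_delta_ct_sd(random_matrix).to_numpy()
        assert np.allclose(sd, sd.T)
        assert np.all(np.diag(sd) == 0)

    def test_per_sample_shift_cancels(self, random_matrix):
        shifted = _shift_sample(random_matrix, "s3", 5.0)
        a = pairwise_delta_ct_sd(random_matrix).to_numpy()
        b = pairwise_delta_ct_sd(shifted).to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_missing_values_rejected(self):
        vals = np.full((4, 3), 25.0)
        vals[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            pairwise_delta_ct_sd(CtMatrix(vals, list("abcd"), list("xyz")))


class TestDeltaCtStability:
    def test_toy_statistics_and_tied_ranks(self, toy_abc):
        res = delta_ct_stability(toy_abc)
        assert res.per_gene["A"] == pytest.approx(0.6454972243679028, abs=1e-9)
        assert res.per_gene["B"] == pytest.approx(0.6454972243679028, abs=1e-9)
        assert res.per_gene["C"] == pytest.approx(1.2909944487358056, abs=1e-9)
        assert res.ranks == {"A": 1, "B": 1, "C": 2}

    def test_all_genes_offset_copies_all_rank_one(self):
        base = np.linspace(20, 24, 5)
        vals = np.column_stack([base, base + 1, base + 3])
        res = delta_ct_stability(CtMatrix(vals, [f"s{i}" for i in range(5)], list("abc")))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in res.per_gene.values())
        assert set(res.ranks.values()) == {1}

    def test_brute_force_oracle(self):
        # independent double loop over pairs and samples
        ct = _random_ct(3)
        res = delta_ct_stability(ct)
        for j, g in enumerate(ct.gene_ids):
            sds = []
            for k in range(ct.n_genes):
                if k == j:
                    continue
                diffs = [
                    ct.values[s, j] - ct.values[s, k] for s in range(ct.n_samples)
                ]
                mean = sum(diffs) / len(diffs)
                var = sum((d - mean) ** 2 for d in diffs) / (len(diffs) - 1)
                sds.append(var**0.5)
            assert res.per_gene[g] == pytest.approx(sum(sds) / len(sds), abs=1e-12)


class TestGeNorm:
    def test_first_round_m_equals_delta_ct_statistic(self):
        for seed in range(10):
            ct = _random_ct(seed)
            first_m = genorm(ct).aux["steps"][0]
            delta = delta_ct_stability(ct).per_gene
            for g in ct.gene_ids:
                assert first_m[g] == pytest.approx(delta[g], abs=1e-10)

    def test_toy_final_pair_and_ranks(self, toy_abc):
        res = genorm(toy_abc)
        assert res.aux["final_pair"] == ["A", "B"]
        assert res.per_gene["A"] == pytest.approx(0.0, abs=1e-12)
        assert res.per_gene["B"] == pytest.approx(0.0, abs=1e-12)
        assert res.ranks == {"A": 1, "B": 1, "C": 2}

    def test_final_pair_shares_identical_m(self, random_matrix):
        res = genorm(random_matrix)
        a, b = res.aux["final_pair"]
        assert res.per_gene[a] == res.per_gene[b]
        assert res.ranks[a] == res.ranks[b] == 1

    def test_per_sample_shift_invariant(self, random_matrix):
        res_a = genorm(random_matrix)
        res_b = genorm(_shift_sample(random_matrix, "s0", 5.0))
        for g in random_matrix.gene_ids:
            assert res_a.per_gene[g] == pytest.approx(res_b.per_gene[g], abs=1e-10)

    def test_two_genes_warns_and_ranks_both_first(self):
        ct = _random_ct(1, n_genes=2)
        with pytest.warns(UserWarning, match="≥ 3 genes"):
            res = genorm(ct)
        assert set(res.ranks.values()) == {1}

    def test_custom_efficiencies_change_scale_not_validity(self, random_matrix):
        res = genorm(random_matrix, efficiencies={"g0": 1.9, "g1": 2.1})
        assert all(v >= 0 for v in res.per_gene.values())


class TestNormFinder:
    def test_pure_loading_effect_gives_zero_stability(self):
        rng = np.random.default_rng(5)
        u = rng.normal(0, 1.0, size=10)
        baselines = np.array([20.0, 25.0, 30.0, 22.0])
        vals = baselines[None, :] + u[:, None]
        res = normfinder(CtMatrix(vals, [f"s{i}" for i in range(10)], list("abcd")))
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in res.per_gene.values())

    def test_estimating_equations_self_consistent(self):
        # plugging the variance estimates back into the decomposition
        # reproduces the observed centred variances
        ct = _random_ct(8, n_samples=12, n_genes=4)
        res = normfinder(ct)
        sigma2 = np.array([res.aux["sigma2"][g] for g in ct.gene_ids])
        d = ct.values - ct.values.mean(axis=1, keepdims=True)
        v = d.var(axis=0, ddof=1)
        n = ct.n_genes
        reconstructed = sigma2 * (n - 2) / n + sigma2.sum() / n**2
        np.testing.assert_allclose(reconstructed, v, atol=1e-9)

    def test_fewer_than_three_genes_rejected(self):
        with pytest.raises(ValueError, match="genes"):
            normfinder(_random_ct(0, n_genes=2))

    def test_grouped_requires_annotations_and_group_size(self, default_dataset):
        with pytest.raises(ValueError, match="requires annotations"):
            normfinder(default_dataset.ct, mode="grouped")

    def test_grouped_detects_group_shifted_gene(self):
        # a +3-cycle shift in half the groups on top of the study-default
        # design: the grouped statistic flags that gene worst
        base = default_design()
        design = SimulationDesign(
            genes=base.genes + [GeneSpec("SHIFTY", 25.0, 0.5)],
            groups=base.groups,
            locations=base.locations,
            sample_effect_sd=base.sample_effect_sd,
            effects=base.effects
            + [Effect("SHIFTY", g, "*", 3.0) for g in ("V3", "V4", "V5")],
            seed=0,
        )
        worst_count = 0
        n_rep = 50
        for seed in range(n_rep):
            ds = simulate_ct(design, seed=seed)
            res = normfinder(ds.ct, ds.annotations, mode="grouped")
            worst_count += max(res.per_gene, key=res.per_gene.get) == "SHIFTY"
        assert worst_count >= 0.95 * n_rep


class TestBestKeeper:
    def test_constant_gene_rank_one(self):
        rng = np.random.default_rng(2)
        vals = np.column_stack(
            [np.full(6, 20.0), rng.uniform(24, 26, 6), rng.uniform(29, 33, 6)]
        )
        res = bestkeeper(CtMatrix(vals, [f"s{i}" for i in range(6)], list("abc")))
        assert res.per_gene["a"] == 0.0
        assert res.ranks["a"] == 1
        desc = res.aux["descriptives"]
        assert desc.loc["a", "cv_pct"] == 0.0

    def test_index_is_geometric_mean(self):
        vals = np.array([[20.0, 30.0], [20.0, 20.0], [25.0, 16.0]])
        res = bestkeeper(CtMatrix(vals, ["s1", "s2", "s3"], ["a", "b"]))
        assert res.aux["index"]["s1"] == pytest.approx(np.sqrt(600.0), abs=1e-9)

    def test_gene_equal_to_index_has_unit_correlation(self):
        rng = np.random.default_rng(3)
        g = rng.uniform(20, 25, 8)
        vals = np.column_stack([g, g])  # index == gene exactly
        res = bestkeeper(CtMatrix(vals, [f"s{i}" for i in range(8)], ["a", "b"]))
        assert res.aux["descriptives"].loc["a", "r_vs_index"] == pytest.approx(1.0)

    def test_mean_abs_dev_variant(self, random_matrix):
        res = bestkeeper(random_matrix, sd_variant="mean_abs_dev")
        desc = res.aux["descriptives"]
        for g in random_matrix.gene_ids:
            assert res.per_gene[g] == pytest.approx(desc.loc[g, "mean_abs_dev"])
            assert res.per_gene[g] <= desc.loc[g, "sd"]  # MAD ≤ SD always

    def test_dispersion_flags(self, default_dataset):
        res = bestkeeper(default_dataset.ct)
        assert set(res.aux["unstable"]) == {
            g for g, s in res.per_gene.items() if s >= 1.0
        }


class TestCrossMethodInvariances:
    @pytest.mark.parametrize(
        "method",
        [
            delta_ct_stability,
            genorm,
            normfinder,
            bestkeeper,
        ],
        ids=["delta_ct", "genorm", "normfinder", "bestkeeper"],
    )
    def test_per_gene_constant_shift_leaves_statistics_unchanged(self, method, random_matrix):
        shifted = _shift_gene(random_matrix, "g2", 3.7)
        a, b = method(random_matrix), method(shifted)
        for g in random_matrix.gene_ids:
            assert a.per_gene[g] == pytest.approx(b.per_gene[g], abs=1e-10)

    @pytest.mark.parametrize(
        "method",
        [delta_ct_stability, genorm, normfinder],
        ids=["delta_ct", "genorm", "normfinder"],
    )
    def test_per_sample_shift_invariance_excludes_bestkeeper(self, method, random_matrix):
        shifted = _shift_sample(random_matrix, "s7", -2.3)
        a, b = method(random_matrix), method(shifted)
        for g in random_matrix.gene_ids:
            assert a.per_gene[g] == pytest.approx(b.per_gene[g], abs=1e-10)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_sample_permutation_invariance(self, seed):
        ct = _random_ct(seed, n_samples=8, n_genes=4)
        rng = np.random.default_rng(seed + 1)
        perm = rng.permutation(ct.n_samples)
        shuffled = ct.subset(samples=[ct.sample_ids[i] for i in perm])
        for method in (delta_ct_stability, genorm, normfinder, bestkeeper):
            a, b = method(ct), method(shuffled)
            for g in ct.gene_ids:
                assert a.per_gene[g] == pytest.approx(b.per_gene[g], abs=1e-10)
            assert a.ranks == b.ranks


def test_dense_ranks_share_on_ties():
    assert dense_ranks({"a": 1.0, "b": 1.0 + 1e-12, "c": 2.0}) == {"a": 1, "b": 1, "c": 2}
    assert dense_ranks({"a": 3.0, "b": 1.0, "c": 2.0}) == {"b": 1, "c": 2, "a": 3}
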