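"""Adjacency, topological overlap, module detection, eigengenes, traits."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from pepnet import coexpr, io_model, wgcna
from pepnet.errors import ValidationError

from conftest import make_ratio_matrix
from oracles import naive_tom, prim_mst_weight


def corr_from(values, proteins=None):
    peps = [f"pep{i}" for i in range(values.shape[0])]
    proteins = proteins or [f"prot{i}" for i in range(values.shape[0])]
    return coexpr.CorrelationMatrix(
        values=pd.DataFrame(values, index=peps, columns=peps),
        protein_of=pd.Series(proteins, index=peps))


def tom_from(adj_values, proteins=None):
    peps = [f"pep{i}" for i in range(adj_values.shape[0])]
    proteins = proteins or [f"prot{i}" for i in range(adj_values.shape[0])]
    adj = wgcna.AdjacencyMatrix(
        values=pd.DataFrame(adj_values, index=peps, columns=peps),
        protein_of=pd.Series(proteins, index=peps))
    return wgcna.topological_overlap(adj)


class TestSoftAdjacency:
    @pytest.mark.parametrize("r,power,expected", [(1.0, 6, 1.0), (-0.5, 2, 0.25),
                                                  (0.0, 6, 0.0)])
    def test_unsigned_power_values(self, r, power, expected):
        corr = corr_from(np.array([[1.0, r], [r, 1.0]]))
        adj = wgcna.soft_adjacency(corr, power=power)
        assert adj.values.iloc[0, 1] == pytest.approx(expected)
        assert adj.values.iloc[0, 0] == 0.0  # zero diagonal

    def test_missing_coefficients_become_zero_strength(self):
        corr = corr_from(np.array([[1.0, np.nan], [np.nan, 1.0]]))
        assert wgcna.soft_adjacency(corr, power=6).values.iloc[0, 1] == 0.0


class TestTopologicalOverlap:
    def test_isolated_dyad_saturates(self):
        tom = tom_from(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert tom.values.iloc[0, 1] == pytest.approx(1.0)

    def test_unit_triangle_saturates(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = tom_from(a)
        assert np.allclose(tom.values.to_numpy(), 1.0)

    def test_two_step_path_is_half(self):
        # i - u - j with unit weights and a_ij = 0
        a = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        tom = tom_from(a)
        assert tom.values.iloc[0, 2] == pytest.approx(0.5)

    def test_matches_naive_triple_loop_on_random_matrices(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            n = int(rng.integers(5, 41))
            a = rng.random((n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            tom = tom_from(a).values.to_numpy()
            assert np.allclose(tom, naive_tom(a), atol=1e-10)

    def test_numerator_monotone_under_edge_strengthening(self):
        rng = np.random.default_rng(4)
        a = rng.random((8, 8)) * 0.5
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        i, j, u, v = 0, 1, 4, 5
        l_before = float(a[i] @ a[:, j])
        a2 = a.copy()
        a2[u, v] = a2[v, u] = min(1.0, a2[u, v] + 0.4)
        l_after = float(a2[i] @ a2[:, j])
        assert l_after >= l_before - 1e-12


class TestPickPower:
    def test_single_candidate_returned(self, benchmark_ratios):
        corr = coexpr.pearson_matrix(benchmark_ratios)
        assert wgcna.pick_power(corr, candidates=(7,)) == 7

    def test_deterministic_on_rerun(self, benchmark_ratios):
        corr = coexpr.pearson_matrix(benchmark_ratios)
        p1 = wgcna.pick_power(corr)
        p2 = wgcna.pick_power(corr)
        assert p1 == p2

    def test_degenerate_connectivity_warns_and_returns_smallest(self):
        vals = np.full((6, 6), 0.8)
        np.fill_diagonal(vals, 1.0)
        corr = corr_from(vals)
        with pytest.warns(UserWarning):
            assert wgcna.pick_power(corr, candidates=(2, 4, 6)) == 2


class TestClusterModules:
    def test_perfect_blocks_recovered(self):
        a = np.zeros((10, 10))
        a[:5, :5] = 1.0
        a[5:, 5:] = 1.0
        np.fill_diagonal(a, 0.0)
        tom = tom_from(a)
        _, part = wgcna.cluster_modules(tom, min_size=3)
        assert len(part.modules()) == 2
        labels = part.labels
        assert labels.iloc[:5].nunique() == 1
        assert labels.iloc[5:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[9]

    def test_uniform_tom_is_deterministic_degenerate(self):
        a = np.full((8, 8), 0.5)
        np.fill_diagonal(a, 0.0)
        tom = tom_from(a)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, part1 = wgcna.cluster_modules(tom, min_size=3)
            _, part2 = wgcna.cluster_modules(tom, min_size=3)
        pd.testing.assert_series_equal(part1.labels, part2.labels)
        assert len(part1.modules()) <= 1  # one module or all background

    def test_min_size_above_n_gives_all_background(self, benchmark_tom):
        with pytest.warns(UserWarning):
            _, part = wgcna.cluster_modules(benchmark_tom, min_size=10_000)
        assert part.n_background == len(benchmark_tom.peptides)

    def test_planted_modules_recovered_with_high_ari(self, benchmark_tom,
                                                     benchmark_bundle,
                                                     benchmark_ratios):
        from sklearn.metrics import adjusted_rand_score
        _, part = wgcna.cluster_modules(benchmark_tom, min_size=10)
        truth = benchmark_bundle["truth"].module_of_peptide(
            benchmark_ratios.protein_of)
        ari = adjusted_rand_score(truth.loc[part.labels.index], part.labels)
        assert ari >= 0.8

    def test_labels_are_roman_in_decreasing_size(self, benchmark_tom):
        _, part = wgcna.cluster_modules(benchmark_tom, min_size=10)
        sizes = [len(part.members(m)) for m in part.modules()]
        assert sizes == sorted(sizes, reverse=True)
        assert part.modules()[0] == "I"


class TestEigengene:
    def test_rank_one_module_recovers_shared_profile(self):
        v = np.array([1.0, -1.0, 2.0, 0.0, -2.0])
        vals = np.vstack([3 * v + 1, 0.5 * v - 2, v])
        m = make_ratio_matrix(vals)
        part = wgcna.ModulePartition(
            labels=pd.Series(["I"] * 3, index=m.peptides), min_module_size=2)
        eig = wgcna.module_eigengene(m, part, "I")
        vz = (v - v.mean()) / v.std()
        vz = vz / np.linalg.norm(vz)
        assert np.allclose(np.abs(eig.to_numpy()), np.abs(vz), atol=1e-10)
        assert np.corrcoef(eig, v)[0, 1] > 0  # orientation positive

    def test_antiparallel_members_orientation_rule(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        vals = np.vstack([v, -v, v])  # majority positive
        m = make_ratio_matrix(vals)
        part = wgcna.ModulePartition(
            labels=pd.Series(["I"] * 3, index=m.peptides), min_module_size=2)
        eig = wgcna.module_eigengene(m, part, "I")
        corrs = [np.corrcoef(vals[i], eig)[0, 1] for i in range(3)]
        assert np.mean(corrs) >= 0

    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(9)
        vals = rng.standard_normal((10, 8))
        m = make_ratio_matrix(vals)
        part = wgcna.ModulePartition(
            labels=pd.Series(["I"] * 10, index=m.peptides), min_module_size=2)
        eig = wgcna.module_eigengene(m, part, "I").to_numpy()
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
        # oracle: dominant eigenvector of the sample-by-sample Gram matrix
        evals, evecs = np.linalg.eigh(z.T @ z)
        v1 = evecs[:, -1]
        assert min(np.linalg.norm(eig - v1), np.linalg.norm(eig + v1)) < 1e-8

    def test_unit_norm(self, benchmark_ratios, benchmark_tom):
        _, part = wgcna.cluster_modules(benchmark_tom, min_size=10)
        eig = wgcna.eigengene_matrix(benchmark_ratios, part)
        norms = np.linalg.norm(eig.to_numpy(), axis=1)
        assert np.allclose(norms, 1.0, atol=1e-10)

    def test_explains_more_variance_than_second_component(self):
        rng = np.random.default_rng(12)
        vals = rng.standard_normal((12, 9))
        m = make_ratio_matrix(vals)
        part = wgcna.ModulePartition(
            labels=pd.Series(["I"] * 12, index=m.peptides), min_module_size=2)
        eig = wgcna.module_eigengene(m, part, "I").to_numpy()
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
        var_first = float(((z @ eig) ** 2).sum())
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        var_second = float(((z @ vt[1]) ** 2).sum())
        assert var_first >= var_second

    def test_constant_submatrix_rejected(self):
        m = make_ratio_matrix(np.ones((3, 4)))
        part = wgcna.ModulePartition(
            labels=pd.Series(["I"] * 3, index=m.peptides), min_module_size=2)
        with pytest.raises(ValidationError):
            wgcna.module_eigengene(m, part, "I")


class TestModuleTrait:
    def _design(self, trait_values, samples):
        frame = pd.DataFrame(
            {"condition": ["c"] * len(samples), "time_point": ["24h"] * len(samples),
             "replicate_id": [f"r{i}" for i in range(len(samples))],
             "replicate_kind": ["technical"] * len(samples),
             "control_sample_id": [np.nan] * len(samples)},
            index=pd.Index(samples, name="sample_id"))
        traits = pd.DataFrame({"t": trait_values}, index=frame.index)
        return io_model.StudyDesign(frame=frame, traits=traits, ratio_input=True)

    def test_known_r_and_p(self):
        # construct an eigengene with r = 0.6 against the trait at n = 10
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(10)]
        t = np.array([1.0] * 5 + [0.0] * 5)
        tz = (t - t.mean()) / t.std()
        g = rng.standard_normal(10)
        g -= g.mean()
        g -= (g @ tz) / (tz @ tz) * tz
        g /= g.std()
        e = 0.6 * tz + np.sqrt(1 - 0.36) * g
        eig = pd.DataFrame([e], index=["I"], columns=samples)
        out = wgcna.module_trait(eig, self._design(t, samples))
        row = out.iloc[0]
        assert row["r"] == pytest.approx(0.6, abs=1e-10)
        assert row["p"] == pytest.approx(0.0667, abs=5e-4)
        assert bool(row["selected"])

    def test_r_at_half_not_selected(self):
        samples = [f"s{i}" for i in range(10)]
        rng = np.random.default_rng(1)
        t = np.array([1.0] * 5 + [0.0] * 5)
        tz = (t - t.mean()) / t.std()
        g = rng.standard_normal(10)
        g -= g.mean()
        g -= (g @ tz) / (tz @ tz) * tz
        g /= g.std()
        e = 0.5 * tz + np.sqrt(0.75) * g
        eig = pd.DataFrame([e], index=["I"], columns=samples)
        out = wgcna.module_trait(eig, self._design(t, samples))
        assert not out.iloc[0]["selected"]

    def test_perfect_correlation_selected(self):
        samples = [f"s{i}" for i in range(6)]
        t = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        eig = pd.DataFrame([(t - t.mean()) / t.std()], index=["I"], columns=samples)
        out = wgcna.module_trait(eig, self._design(t, samples))
        assert out.iloc[0]["r"] == pytest.approx(1.0)
        assert out.iloc[0]["p"] == pytest.approx(0.0, abs=1e-12)
        assert bool(out.iloc[0]["selected"])

    def test_zero_variance_trait_untestable(self):
        samples = [f"s{i}" for i in range(5)]
        eig = pd.DataFrame([np.arange(5.0)], index=["I"], columns=samples)
        out = wgcna.module_trait(eig, self._design([1.0] * 5, samples))
        assert not out.iloc[0]["testable"]

    def test_planted_modules_recover_sign(self, benchmark_bundle, benchmark_tom,
                                          benchmark_ratios):
        _, part = wgcna.cluster_modules(benchmark_tom, min_size=10)
        eig = wgcna.eigengene_matrix(benchmark_ratios, part)
        table = wgcna.module_trait(eig, benchmark_bundle["design"])
        truth = benchmark_bundle["truth"]
        pep_truth = truth.module_of_peptide(benchmark_ratios.protein_of)
        for module in part.modules():
            planted = pep_truth.loc[part.members(module)].mode()[0]
            trait, effect = truth.trait_assignment[planted]
            row = table[(table["module"] == module) & (table["trait"] == trait)]
            r = float(row["r"].iloc[0])
            assert np.sign(r) == np.sign(effect)
            assert abs(r) > 0.55 and float(row["p"].iloc[0]) < 0.1


class TestTrimModule:
    def _partition(self, n, label="I"):
        peps = [f"pep{i}" for i in range(n)]
        return wgcna.ModulePartition(
            labels=pd.Series([label] * n, index=peps), min_module_size=2)

    def test_all_above_threshold_keeps_complete_graph(self):
        a = np.full((5, 5), 0.5)
        np.fill_diagonal(a, 0.0)
        tom = tom_from(a)
        res = wgcna.trim_module(tom, self._partition(5), "I", to_min=0.1)
        assert res.n_nodes_after == 5
        assert res.network.n_edges == 10

    def test_all_below_threshold_empties_module(self):
        vals = np.full((4, 4), 0.05)
        np.fill_diagonal(vals, 1.0)
        tom = wgcna.TOMatrix(
            values=pd.DataFrame(vals, index=[f"pep{i}" for i in range(4)],
                                columns=[f"pep{i}" for i in range(4)]),
            protein_of=pd.Series([f"p{i}" for i in range(4)],
                                 index=[f"pep{i}" for i in range(4)]),
            connectivity=pd.Series(np.zeros(4), index=[f"pep{i}" for i in range(4)]))
        res = wgcna.trim_module(tom, self._partition(4), "I", to_min=0.1)
        assert res.n_nodes_after == 0

    def test_equality_survives_trimming(self):
        vals = np.full((3, 3), 0.1)
        np.fill_diagonal(vals, 1.0)
        tom = wgcna.TOMatrix(
            values=pd.DataFrame(vals, index=["a", "b", "c"], columns=["a", "b", "c"]),
            protein_of=pd.Series(["p"] * 3, index=["a", "b", "c"]),
            connectivity=pd.Series(np.zeros(3), index=["a", "b", "c"]))
        part = wgcna.ModulePartition(labels=pd.Series(["I"] * 3,
                                                      index=["a", "b", "c"]),
                                     min_module_size=2)
        res = wgcna.trim_module(tom, part, "I", to_min=0.1)
        assert res.network.n_edges == 3

    def test_retention_matches_direct_filter_oracle(self, benchmark_tom):
        _, part = wgcna.cluster_modules(benchmark_tom, min_size=10)
        module = part.modules()[0]
        res = wgcna.trim_module(benchmark_tom, part, module, to_min=0.1)
        members = sorted(part.members(module))
        sub = benchmark_tom.values.loc[members, members].to_numpy()
        keep = set()
        for i in range(len(members)):
            for j in range(len(members)):
                if i != j and sub[i, j] >= 0.1:
                    keep.add(members[i])
        assert res.n_nodes_after == len(keep)


class TestModuleHubsAndMst:
    def test_star_module_center_tops_both_lists(self):
        from test_topology import star
        hubs = wgcna.module_hubs(star(6), k=3)
        assert hubs.top_hub == "center"
        assert hubs.hubs[0] == "center"
        assert hubs.bottlenecks[0] == "center"

    def test_k_larger_than_module_returns_all_flagged(self):
        from test_topology import star
        hubs = wgcna.module_hubs(star(4), k=10)
        assert len(hubs.hubs) == 4
        assert hubs.truncated

    def test_triangle_mst_keeps_two_cheapest_edges(self):
        vals = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.1], [0.8, 0.1, 1.0]])
        # dissimilarities: ab=0.1, ac=0.2, bc=0.9
        tom = wgcna.TOMatrix(
            values=pd.DataFrame(vals, index=["a", "b", "c"], columns=["a", "b", "c"]),
            protein_of=pd.Series(["p"] * 3, index=["a", "b", "c"]),
            connectivity=pd.Series(np.zeros(3), index=["a", "b", "c"]))
        part = wgcna.ModulePartition(labels=pd.Series(["I"] * 3,
                                                      index=["a", "b", "c"]),
                                     min_module_size=2)
        tree = wgcna.module_mst(tom, part, "I")
        assert {(u, v) for u, v, _ in tree} == {("a", "b"), ("a", "c")}

    def test_equal_dissimilarities_tie_break_deterministic(self):
        vals = np.full((4, 4), 0.5)
        np.fill_diagonal(vals, 1.0)
        idx = ["a", "b", "c", "d"]
        tom = wgcna.TOMatrix(values=pd.DataFrame(vals, index=idx, columns=idx),
                             protein_of=pd.Series(["p"] * 4, index=idx),
                             connectivity=pd.Series(np.zeros(4), index=idx))
        part = wgcna.ModulePartition(labels=pd.Series(["I"] * 4, index=idx),
                                     min_module_size=2)
        t1 = wgcna.module_mst(tom, part, "I")
        t2 = wgcna.module_mst(tom, part, "I")
        assert t1 == t2
        assert [(u, v) for u, v, _ in t1] == [("a", "b"), ("a", "c"), ("a", "d")]

    def test_total_weight_matches_prim_oracle(self, benchmark_tom):
        _, part = wgcna.cluster_modules(benchmark_tom, min_size=10)
        module = part.modules()[0]
        tree = wgcna.module_mst(benchmark_tom, part, module)
        members = sorted(part.members(module))
        assert len(tree) == len(members) - 1
        d = 1.0 - benchmark_tom.values.loc[members, members].to_numpy()
        np.fill_diagonal(d, np.inf)
        assert sum(w for *_, w in tree) == pytest.approx(
            prim_mst_weight(len(members), d), abs=1e-10)

    def test_tiny_module_empty_tree(self, benchmark_tom):
        part = wgcna.ModulePartition(
            labels=pd.Series(["I"], index=[benchmark_tom.peptides[0]]),
            min_module_size=1)
        assert wgcna.module_mst(benchmark_tom, part, "I") == []


class TestSameProteinOverlap:
    def test_same_protein_pairs_have_higher_overlap(self, default_bundle):
        table = default_bundle["table"]
        design = default_bundle["design"]
        ratios = io_model.to_log_ratios(table, design)
        avg = io_model.average_replicates(ratios, design)
        corr = coexpr.pearson_matrix(avg)
        tom = wgcna.topological_overlap(wgcna.soft_adjacency(corr, power=6))
        tv = tom.values.to_numpy()
        prot = tom.protein_of.to_numpy()
        iu, ju = np.triu_indices(len(prot), 1)
        same = prot[iu] == prot[ju]
        same_vals = tv[iu[same], ju[same]]
        rng = np.random.default_rng(6)
        sel = rng.choice(np.flatnonzero(~same), size=4000, replace=False)
        rand_vals = tv[iu[sel], ju[sel]]
        res = mannwhitneyu(same_vals, rand_vals, alternative="greater")
        assert res.pvalue < 0.01


class TestMembershipSignificance:
    def test_peptide_equal_to_eigengene_has_unit_membership(self, benchmark_ratios,
                                                            benchmark_tom,
                                                            benchmark_bundle):
        _, part = wgcna.cluster_modules(benchmark_tom, min_size=10)
        eig = wgcna.eigengene_matrix(benchmark_ratios, part)
        module = part.modules()[0]
        # overwrite one member's profile with the eigengene itself
        m2 = io_model.RatioMatrix(values=benchmark_ratios.values.copy(),
                                  protein_of=benchmark_ratios.protein_of.copy())
        member = part.members(module)[0]
        m2.values.loc[member] = eig.loc[module].to_numpy()
        df, _ = wgcna.membership_significance(
            m2, eig, benchmark_bundle["design"], part, module, "biofuel")
        kme = df.set_index("peptide").loc[member, "module_membership"]
        assert kme == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_trait_gives_zero_significance(self):
        samples = [f"s{i}" for i in range(4)]
        vals = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, -1.0, 1.0, -1.0]])
        m = make_ratio_matrix(vals, samples=samples)
        part = wgcna.ModulePartition(labels=pd.Series(["I", "I"], index=m.peptides),
                                     min_module_size=2)
        eig = wgcna.eigengene_matrix(m, part)
        frame = pd.DataFrame(
            {"condition": ["c"] * 4, "time_point": ["24h"] * 4,
             "replicate_id": list("abcd"), "replicate_kind": ["technical"] * 4,
             "control_sample_id": [np.nan] * 4},
            index=pd.Index(samples, name="sample_id"))
        traits = pd.DataFrame({"t": [1.0, 1.0, 0.0, 0.0]}, index=frame.index)
        design = io_model.StudyDesign(frame=frame, traits=traits, ratio_input=True)
        df, _ = wgcna.membership_significance(m, eig, design, part, "I", "t")
        assert np.allclose(df["peptide_significance"], 0.0, atol=1e-10)

    def test_trait_linked_module_positive_cross_correlation(self, benchmark_ratios,
                                                            benchmark_tom,
                                                            benchmark_bundle):
        _, part = wgcna.cluster_modules(benchmark_tom, min_size=10)
        eig = wgcna.eigengene_matrix(benchmark_ratios, part)
        module = part.modules()[0]
        df, cross = wgcna.membership_significance(
            benchmark_ratios, eig, benchmark_bundle["design"], part, module,
            "biofuel")
        assert len(df) >= 5  # complete-profile members only
        assert cross > 0
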