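"""Co-expression arm: filtering, normalization, adjacency/TOM oracles,
module detection, eigengenes, trait statistics, classification, export."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnmnet import coexpression as cx
from cnmnet.simulate import ExpressionSimSpec, ModuleSpec, simulate_expression_with_traits


def _df(values, prefix="f", cols=None):
    values = np.asarray(values, dtype=float)
    idx = [f"{prefix}{i}" for i in range(values.shape[0])]
    cols = cols or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=idx, columns=cols)


class TestFilterFeatures:
    def test_boundary_nine_of_ten_samples_above_ten_reads(self):
        row = [11] * 9 + [0]
        counts = _df([row, [0] * 10])
        kept = cx.filter_features(counts)
        assert list(kept.index) == ["f0"]

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(0)
        counts = _df(rng.integers(0, 40, size=(20, 12)))
        kept = cx.filter_features(counts, min_count=10, min_fraction=0.9)
        need = math.ceil(0.9 * 12)
        expected = []
        for f in counts.index:
            n_ok = sum(1 for v in counts.loc[f] if v > 10)
            if n_ok >= need:
                expected.append(f)
        assert list(kept.index) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            cx.filter_features(_df([[-1, 2]]))


class TestSizeFactors:
    def test_doubled_sample_gets_double_factor_and_normalizes_away(self):
        a = np.array([100.0, 50.0, 20.0, 400.0])
        counts = _df(np.stack([a, 2 * a], axis=1))
        sf = cx.size_factors(counts)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)
        norm = cx.size_factor_normalize(counts, log2=False)
        np.testing.assert_allclose(norm.iloc[:, 0], norm.iloc[:, 1])

    def test_single_feature_median_of_ratios(self):
        sf = cx.size_factors(_df([[10.0, 20.0]]))
        # geometric mean sqrt(200); ratios 10/g and 20/g -> factors 1:2
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)
        assert sf.iloc[0] == pytest.approx(10 / math.sqrt(200))

    def test_identical_samples_give_unit_factors(self):
        counts = _df(np.tile([[30.0], [70.0]], (1, 4)))
        np.testing.assert_allclose(cx.size_factors(counts), 1.0)

    def test_fallback_to_library_size_when_no_allnonzero_feature(self):
        counts = _df([[0.0, 5.0], [5.0, 0.0]])
        with pytest.warns(UserWarning, match="library-size"):
            sf = cx.size_factors(counts)
        assert sf.prod() == pytest.approx(1.0)  # geometric mean 1


class TestSoftAdjacency:
    def test_perfectly_correlated_pair_has_unit_adjacency(self):
        x = np.arange(6.0)
        adj = cx.soft_adjacency(_df([x, 2 * x + 3]), power=7)
        assert adj.iloc[0, 1] == pytest.approx(1.0)

    def test_known_correlation_raised_to_power(self):
        rng = np.random.default_rng(5)
        expr = _df(rng.normal(size=(4, 30)))
        r = np.corrcoef(expr.values)[0, 1]
        adj = cx.soft_adjacency(expr, power=12)
        assert adj.iloc[0, 1] == pytest.approx(abs(r) ** 12, abs=1e-15)

    def test_matches_bruteforce_pairwise_loop(self):
        rng = np.random.default_rng(1)
        expr = _df(rng.normal(size=(10, 6)))
        adj = cx.soft_adjacency(expr, power=6).values
        x = expr.values
        for i in range(10):
            for j in range(10):
                if i == j:
                    expected = 1.0
                else:
                    expected = abs(stats.pearsonr(x[i], x[j])[0]) ** 6
                assert abs(adj[i, j] - expected) < 1e-12

    def test_zero_variance_feature_warns_and_gets_zero(self):
        expr = _df([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            adj = cx.soft_adjacency(expr, power=2)
        assert adj.iloc[0, 1] == 0.0
        assert adj.iloc[0, 0] == 1.0


class TestTopologicalOverlap:
    def test_identity_adjacency_gives_zero_overlap(self):
        tom = cx.topological_overlap(np.eye(5))
        assert np.allclose(tom - np.eye(5), 0.0)

    def test_two_node_closed_form(self):
        a = np.array([[1.0, 0.8], [0.8, 1.0]])
        tom = cx.topological_overlap(a)
        # k1 = k2 = 0.8, no shared third node: (0 + 0.8)/(0.8 + 1 - 0.8)
        assert tom[0, 1] == pytest.approx(0.8)

    def test_matches_triple_loop_bruteforce(self):
        rng = np.random.default_rng(2)
        r = rng.uniform(0, 1, size=(20, 20))
        a = (r + r.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = cx.topological_overlap(a)
        n = 20
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                k_i = sum(a[i, u] for u in range(n) if u != i)
                k_j = sum(a[j, u] for u in range(n) if u != j)
                expected = (shared + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
                assert abs(tom[i, j] - expected) < 1e-12

    def test_asymmetric_input_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            cx.topological_overlap(a)


class TestDetectModules:
    def _planted(self, seed=0, n_per=40, r_noise=0.2, n_samples=30):
        rng = np.random.default_rng(seed)
        f1, f2 = rng.normal(size=(2, n_samples))
        rows = [f1 + rng.normal(0, r_noise, n_samples) for _ in range(n_per)]
        rows += [f2 + rng.normal(0, r_noise, n_samples) for _ in range(n_per)]
        expr = _df(np.array(rows))
        truth = ["A"] * n_per + ["B"] * n_per
        return expr, truth

    def test_two_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        expr, truth = self._planted()
        tom = cx.topological_overlap(cx.soft_adjacency(expr, 6).values)
        labels = cx.detect_modules(1 - tom, expr, min_module_size=10)
        assert adjusted_rand_score(truth, labels) > 0.9

    def test_min_module_size_above_n_gives_all_grey(self):
        expr, _ = self._planted(n_per=5)
        tom = cx.topological_overlap(cx.soft_adjacency(expr, 6).values)
        with pytest.warns(UserWarning):
            labels = cx.detect_modules(1 - tom, expr, min_module_size=11)
        assert set(labels) == {cx.GREY}

    def test_near_duplicate_modules_are_merged(self):
        # two blocks driven by the same factor with tiny perturbation:
        # eigengene dissimilarity << 0.25 so they must merge
        rng = np.random.default_rng(3)
        f = rng.normal(size=24)
        rows = [f + rng.normal(0, 0.1, 24) for _ in range(40)]
        rows += [f + 0.1 * rng.normal(size=24) + rng.normal(0, 0.1, 24) for _ in range(40)]
        expr = _df(np.array(rows))
        tom = cx.topological_overlap(cx.soft_adjacency(expr, 6).values)
        labels = cx.detect_modules(1 - tom, expr, min_module_size=10, merge_threshold=0.25)
        assert len(set(labels) - {cx.GREY}) == 1

    def test_pure_noise_yields_grey(self):
        rng = np.random.default_rng(4)
        expr = _df(rng.normal(size=(40, 20)))
        tom = cx.topological_overlap(cx.soft_adjacency(expr, 12).values)
        labels = cx.detect_modules(1 - tom, expr, min_module_size=30)
        assert (labels == cx.GREY).mean() > 0.9


class TestModuleEigengenes:
    def test_identical_features_give_their_common_profile(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        expr = _df(np.tile(x, (5, 1)))
        assignment = pd.Series("blue", index=expr.index)
        me = cx.module_eigengenes(expr, assignment)
        r = np.corrcoef(me.loc["blue"], x)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # sign convention: aligned with the mean profile

    def test_latent_factor_recovered(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=30)
        expr = _df([f + rng.normal(0, 0.3, 30) for _ in range(50)])
        me = cx.module_eigengenes(expr, pd.Series("m", index=expr.index))
        assert abs(np.corrcoef(me.loc["m"], f)[0, 1]) > 0.95

    def test_negating_features_negates_eigengene(self):
        rng = np.random.default_rng(1)
        expr = _df(rng.normal(size=(8, 12)))
        assignment = pd.Series("m", index=expr.index)
        me_pos = cx.module_eigengenes(expr, assignment)
        me_neg = cx.module_eigengenes(-expr, assignment)
        np.testing.assert_allclose(me_pos.values, -me_neg.values, atol=1e-10)

    def test_single_feature_module_is_unit_norm_profile(self):
        expr = _df([[1.0, 2.0, 4.0, 3.0]])
        me = cx.module_eigengenes(expr, pd.Series("m", index=expr.index))
        assert np.linalg.norm(me.values) == pytest.approx(1.0)
        assert np.corrcoef(me.values[0], expr.values[0])[0, 1] == pytest.approx(1.0)

    def test_unit_norm_and_grey_excluded(self):
        rng = np.random.default_rng(2)
        expr = _df(rng.normal(size=(10, 8)))
        assignment = pd.Series(["a"] * 5 + [cx.GREY] * 5, index=expr.index)
        me = cx.module_eigengenes(expr, assignment)
        assert list(me.index) == ["a"]
        assert np.linalg.norm(me.loc["a"]) == pytest.approx(1.0)


class TestModuleTraitCorrelation:
    def _me(self, rows, samples=None):
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        samples = samples or [f"s{j}" for j in range(rows.shape[1])]
        return pd.DataFrame(rows, index=[f"mod{i}" for i in range(rows.shape[0])],
                            columns=samples)

    def test_trait_equal_to_eigengene(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=10)
        me = self._me([e])
        traits = pd.DataFrame({"t": e}, index=me.columns)
        out = cx.module_trait_correlation(me, traits)
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0)
        assert out["p_value"].iloc[0] < 1e-9

    def test_t_statistic_against_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.normal(size=30)
            y = 0.7 * x + rng.normal(size=30)
            me = self._me([x])
            traits = pd.DataFrame({f"t{k}": (y if k == 0 else rng.normal(size=30))
                                   for k in range(7)}, index=me.columns)
            out = cx.module_trait_correlation(me, traits)
            row = out[out["trait"] == "t0"].iloc[0]
            r_ref, p_ref = stats.pearsonr(x, y)
            assert row["pearson_r"] == pytest.approx(r_ref, abs=1e-12)
            assert row["p_value"] == pytest.approx(p_ref, rel=1e-9)
            assert row["p_adjusted"] == pytest.approx(min(1.0, p_ref * 7), rel=1e-9)

    def test_bonferroni_monotone_and_capped(self):
        rng = np.random.default_rng(1)
        me = self._me(rng.normal(size=(3, 12)))
        traits = pd.DataFrame(rng.normal(size=(12, 5)),
                              index=me.columns, columns=[f"t{k}" for k in range(5)])
        out = cx.module_trait_correlation(me, traits)
        assert (out["p_adjusted"] >= out["p_value"]).all()
        assert (out["p_adjusted"] <= 1.0).all()

    def test_constant_trait_emits_missing_row(self):
        rng = np.random.default_rng(2)
        me = self._me(rng.normal(size=(1, 8)))
        traits = pd.DataFrame({"const": np.ones(8)}, index=me.columns)
        out = cx.module_trait_correlation(me, traits)
        assert np.isnan(out["pearson_r"].iloc[0])
        assert out["n_samples"].iloc[0] == 8

    def test_missing_values_use_pairwise_complete(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = x.copy()
        y[:3] = np.nan
        me = self._me([x])
        traits = pd.DataFrame({"t": y}, index=me.columns)
        out = cx.module_trait_correlation(me, traits)
        assert out["n_samples"].iloc[0] == 9
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0)


class TestClassifyModules:
    def _row(self, module, trait, r, p_adj):
        return {"module": module, "trait": trait, "pearson_r": r,
                "p_value": p_adj / 6, "p_adjusted": p_adj, "n_samples": 24}

    def test_positive_mass_correlation_is_beneficial(self):
        res = pd.DataFrame([self._row("m", "normalized_ta_mass", 0.6, 0.01)])
        assert cx.classify_modules(res)["m"] == "beneficial"

    def test_positive_central_nuclei_correlation_is_pathogenic(self):
        res = pd.DataFrame([self._row("m", "pct_central_nuclei", 0.6, 0.01)])
        assert cx.classify_modules(res)["m"] == "pathogenic"

    def test_no_significant_correlation_is_unclassified(self):
        res = pd.DataFrame([self._row("m", "normalized_ta_mass", 0.6, 0.5)])
        assert cx.classify_modules(res)["m"] == "unclassified"

    def test_conflicting_evidence_is_unclassified(self):
        res = pd.DataFrame(
            [self._row("m", "normalized_ta_mass", 0.6, 0.01),
             self._row("m", "pct_central_nuclei", 0.6, 0.01)]
        )
        assert cx.classify_modules(res)["m"] == "unclassified"

    def test_invariant_to_row_order(self):
        rows = [
            self._row("a", "normalized_ta_mass", 0.6, 0.01),
            self._row("a", "hanging_time", 0.5, 0.02),
            self._row("b", "pct_small_fibers", 0.7, 0.001),
        ]
        fwd = cx.classify_modules(pd.DataFrame(rows))
        rev = cx.classify_modules(pd.DataFrame(rows[::-1]).reset_index(drop=True))
        pd.testing.assert_series_equal(fwd, rev)

    def test_missing_trait_warns(self):
        res = pd.DataFrame([self._row("m", "normalized_ta_mass", 0.6, 0.01)])
        with pytest.warns(UserWarning, match="missing"):
            cx.classify_modules(res)


class TestExportLayer:
    def test_edge_set_matches_bruteforce_scan(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(0, 1, size=(10, 10))
        t = (r + r.T) / 2
        np.fill_diagonal(t, 1.0)
        tom = pd.DataFrame(t, index=[f"f{i}" for i in range(10)],
                           columns=[f"f{i}" for i in range(10)])
        layer = cx.export_coexpression_layer(tom, 0.15)
        expected = {
            (f"f{i}", f"f{j}")
            for i in range(10)
            for j in range(i + 1, 10)
            if t[i, j] > 0.15
        }
        assert {(a, b) for a, b, _ in layer.edges} == expected
        for a, b, w in layer.edges:
            i, j = int(a[1:]), int(b[1:])
            assert w == pytest.approx(t[i, j])

    def test_threshold_zero_gives_complete_graph(self):
        t = np.full((4, 4), 0.5)
        np.fill_diagonal(t, 1.0)
        tom = pd.DataFrame(t, index=list("abcd"), columns=list("abcd"))
        assert cx.export_coexpression_layer(tom, 0.0).n_edges == 6

    def test_high_threshold_gives_empty_layer(self):
        tom = pd.DataFrame(np.eye(5), index=list("abcde"), columns=list("abcde"))
        assert cx.export_coexpression_layer(tom, 1.0 - 1e-9).n_edges == 0

    def test_threshold_out_of_range_rejected(self):
        tom = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            cx.export_coexpression_layer(tom, 1.0)

    def test_presets_match_published_settings(self):
        assert cx.LAYER_PRESETS["transcriptomic"] == {"power": 10, "threshold": 0.15}
        assert cx.LAYER_PRESETS["proteomic"] == {"power": 12, "threshold": 0.25}
        assert cx.LAYER_PRESETS["metabolomic"] == {"power": 5, "threshold": 0.05}


class TestWGCNAModel:
    def test_fit_recovers_planted_structure_and_classifies(self):
        data = simulate_expression_with_traits(ExpressionSimSpec(rng_seed=11))
        res = cx.WGCNA(data.counts, data.traits).fit()
        assert res.eigengenes.shape[0] >= 2
        assert set(res.modules) - {cx.GREY}
        assert res.module_trait is not None
        assert set(res.classification.unique()) <= {
            "beneficial", "pathogenic", "unclassified"
        }
        text = res.summary()
        assert "modules" in text and "soft power" in text

    def test_results_roundtrip_to_dir(self, tmp_path):
        data = simulate_expression_with_traits(ExpressionSimSpec(rng_seed=11))
        res = cx.WGCNA(data.counts, data.traits).fit()
        res.to_dir(tmp_path)
        modules = pd.read_csv(tmp_path / "modules.tsv", sep="\t", index_col=0)
        assert len(modules) == res.expr.shape[0]
        assert (tmp_path / "module_trait.tsv").exists()

    def test_batch_correction_centers_cohorts(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(5, 8))
        expr = _df(base)
        batches = pd.Series(["c1"] * 4 + ["c2"] * 4, index=expr.columns)
        shifted = expr.copy()
        shifted.iloc[:, 4:] += 10.0  # cohort offset
        corrected = cx.batch_correct(shifted, batches)
        means = corrected.T.groupby(batches).mean()
        np.testing.assert_allclose(means.loc["c1"], means.loc["c2"], atol=1e-10)
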