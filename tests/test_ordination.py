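import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import special_ortho_group

from absanchor import (
    AbsoluteAbundanceTable,
    CLRTransform,
    PCAWithLoadings,
    TaxonCountTable,
    aitchison_distance,
    aitchison_distance_matrix,
    anchor_absolute,
    bray_curtis_matrix,
    clr_transform,
    log_abs_transform,
    pcoa,
    spearman_network,
    taxon_impact,
)
from absanchor.ordination import absolute_pseudocount

positive_rows = st.lists(
    st.lists(st.floats(min_value=0.1, max_value=1e6), min_size=4, max_size=4),
    min_size=2,
    max_size=6,
)


class TestCLR:
    def test_uniform_composition_maps_to_zero(self):
        out = clr_transform(np.array([[1.0, 1.0, 1.0, 1.0]]), pseudocount=0)
        assert out == pytest.approx(np.zeros((1, 4)))

    def test_two_part_hand_example(self):
        out = clr_transform(np.array([[4.0, 1.0]]), pseudocount=0)
        assert out[0] == pytest.approx([np.log(2), -np.log(2)])

    def test_matches_scikit_bio(self):
        from skbio.stats.composition import clr as skbio_clr

        x = np.array([[3.0, 7.0, 11.0, 2.0], [1.0, 1.0, 5.0, 100.0]])
        assert clr_transform(x, pseudocount=0) == pytest.approx(skbio_clr(x))

    @given(rows=positive_rows)
    def test_rows_sum_to_zero_and_scale_invariance(self, rows):
        x = np.array(rows)
        out = clr_transform(x, pseudocount=0)
        assert out.sum(axis=1) == pytest.approx(np.zeros(len(rows)), abs=1e-8)
        scaled = clr_transform(x * 37.5, pseudocount=0)
        assert scaled == pytest.approx(out, abs=1e-8)

    def test_all_zero_sample_flagged_but_valid(self):
        with pytest.warns(UserWarning, match="uniform"):
            out = clr_transform(np.array([[0.0, 0.0, 0.0]]), pseudocount=1)
        assert out == pytest.approx(np.zeros((1, 3)))

    def test_sklearn_pipeline_compatible(self, small_table):
        from sklearn.pipeline import Pipeline

        pipe = Pipeline([("clr", CLRTransform(pseudocount=1.0)), ("pca", PCAWithLoadings())])
        scores = pipe.fit_transform(small_table.counts)
        assert scores.shape == (3, 3)


class TestLogAbsolute:
    def test_zero_load_with_unit_pseudocount(self):
        assert log_abs_transform(np.array([[0.0]]), pseudocount=1.0)[0, 0] == 0.0

    def test_wide_dynamic_range(self):
        out = log_abs_transform(np.array([[1e3, 1e9]]), pseudocount=0.0)
        assert out[0] == pytest.approx([np.log(1e3), np.log(1e9)])

    def test_monotone(self):
        out = log_abs_transform(np.array([[10.0, 20.0, 30.0]]), pseudocount=1.0)
        assert (np.diff(out[0]) > 0).all()

    def test_negative_load_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            log_abs_transform(np.array([[-1.0]]))


class TestAitchison:
    def test_identity_and_scale_invariance(self):
        x = np.array([3.0, 5.0, 9.0])
        assert aitchison_distance(x, x) == 0.0
        assert aitchison_distance(x, 7.0 * x) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_pair(self):
        assert aitchison_distance([1.0, 4.0], [4.0, 1.0]) == pytest.approx(1.9605, abs=1e-3)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same number"):
            aitchison_distance([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_relative_and_absolute_branches_give_identical_distances(self):
        # CLR scale invariance: pseudocount applied on the count scale before
        # anchoring makes relative- and absolute-derived distances identical
        counts = pd.DataFrame(
            {"a": [50, 10, 5], "b": [30, 60, 90], "c": [20, 30, 5]},
            index=["s1", "s2", "s3"],
        )
        table = TaxonCountTable(counts)
        loads = {"s1": 1e9, "s2": 3e10, "s3": 7e8}
        abs_table = anchor_absolute(table, loads)
        d_rel = aitchison_distance_matrix(table.counts, pseudocount=1.0)
        pc = absolute_pseudocount(
            abs_table.total_load.to_numpy(), table.read_depth.to_numpy()
        )
        d_abs = aitchison_distance_matrix(abs_table.loads, pseudocount=pc)
        assert d_abs.to_numpy() == pytest.approx(d_rel.to_numpy(), abs=1e-9)


class TestPCA:
    def test_loadings_reconstruct_covariance(self, rng):
        X = rng.normal(size=(40, 5)) @ rng.normal(size=(5, 5))
        model = PCAWithLoadings().fit(X)
        L = np.asarray(model.loadings_)
        cov = np.cov(X, rowvar=False, ddof=1)
        assert L @ L.T == pytest.approx(cov, abs=1e-8)

    def test_diagonal_covariance_loading_magnitudes(self, rng):
        # features with variances 4 and 1: loading vectors of norm 2 and 1
        n = 100000
        X = np.column_stack([2 * rng.standard_normal(n), rng.standard_normal(n)])
        model = PCAWithLoadings().fit(X)
        norms = np.linalg.norm(np.asarray(model.loadings_), axis=0)
        assert norms == pytest.approx([2.0, 1.0], rel=0.02)

    def test_rank_one_data_has_single_eigenvalue(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([base, 2 * base])
        model = PCAWithLoadings().fit(X)
        assert model.eigenvalues_[1] == pytest.approx(0.0, abs=1e-10)
        L = np.asarray(model.loadings_)
        assert L[1, 0] == pytest.approx(2 * L[0, 0])

    def test_rotation_equivariance(self, rng):
        X = rng.normal(size=(30, 4))
        R = special_ortho_group.rvs(4, random_state=7)
        m1 = PCAWithLoadings().fit(X)
        m2 = PCAWithLoadings().fit(X @ R)
        # eigenvalues are rotation invariant
        assert m2.eigenvalues_ == pytest.approx(m1.eigenvalues_, abs=1e-8)
        # loadings rotate with the data (up to the fixed sign convention)
        L1, L2 = np.asarray(m1.loadings_), np.asarray(m2.loadings_)
        rotated = R.T @ L1
        for j in range(4):
            assert np.minimum(
                np.abs(rotated[:, j] - L2[:, j]).max(),
                np.abs(rotated[:, j] + L2[:, j]).max(),
            ) < 1e-8

    def test_matches_sklearn_pca_scores(self, rng):
        from sklearn.decomposition import PCA

        X = rng.normal(size=(25, 6))
        ours = PCAWithLoadings().fit(X)
        theirs = PCA().fit(X)
        assert np.sort(ours.eigenvalues_)[::-1] == pytest.approx(
            theirs.explained_variance_, abs=1e-9
        )
        s_ours = np.abs(np.asarray(ours.transform(X)))
        s_theirs = np.abs(theirs.transform(X))
        assert s_ours == pytest.approx(s_theirs, abs=1e-8)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            PCAWithLoadings().fit(np.array([[1.0, 2.0]]))


class TestTaxonImpact:
    def test_pythagorean_example(self):
        L = pd.DataFrame({"PC1": [3.0, 0.0], "PC2": [4.0, 0.0]}, index=["a", "b"])
        impact = taxon_impact(L)
        assert impact["a"] == 5.0
        assert impact["b"] == 0.0

    def test_sign_flip_invariance(self):
        L = pd.DataFrame({"PC1": [3.0], "PC2": [-4.0]}, index=["a"])
        assert taxon_impact(L)["a"] == taxon_impact(-L)["a"]

    def test_abs_sum_alternative(self):
        L = pd.DataFrame({"PC1": [3.0], "PC2": [-4.0]}, index=["a"])
        assert taxon_impact(L, method="abs_sum")["a"] == 7.0


class TestDistancesAndPcoa:
    def test_bray_curtis_matches_scipy_and_pcoa_runs(self, rng):
        rel = rng.dirichlet(np.ones(5), size=6)
        d = bray_curtis_matrix(rel)
        assert d.to_numpy().diagonal() == pytest.approx(np.zeros(6))
        scores, eigvals = pcoa(d)
        assert scores.shape == (6, 2)
        assert (eigvals >= -1e-9).all()


class TestSpearmanNetwork:
    def make_table(self, rng):
        n = 12
        base = rng.lognormal(18, 1, size=n)
        loads = pd.DataFrame(
            {
                "follower": base * 2.0,
                "anti": 1e18 / base,
                "noise1": rng.lognormal(15, 1, n),
                "noise2": rng.lognormal(14, 1, n),
                "lead": base,
            },
            index=[f"s{i}" for i in range(n)],
        )
        return AbsoluteAbundanceTable(loads)

    def test_perfect_rank_relations_recovered(self, rng):
        net = spearman_network(self.make_table(rng), top_k=5, fdr=0.05)
        assert net.rho.loc["lead", "lead"] == 1.0
        assert net.rho.loc["lead", "follower"] == pytest.approx(1.0)
        assert net.rho.loc["lead", "anti"] == pytest.approx(-1.0)
        pairs = {frozenset((r.feature_i, r.feature_j)) for r in net.edges.itertuples()}
        assert frozenset(("lead", "follower")) in pairs
        assert frozenset(("lead", "anti")) in pairs

    def test_hand_rank_example(self):
        from scipy.stats import spearmanr

        assert spearmanr([1, 2, 3], [2, 1, 3]).statistic == pytest.approx(0.5)

    def test_total_load_included_and_constant_features_nan(self, rng):
        table = self.make_table(rng)
        table.loads["flat"] = 5.0
        net = spearman_network(table, top_k=6, include_total_load=True)
        assert "total_load" in net.features
        assert np.isnan(net.rho.loc["flat", "lead"])
        assert not (
            (net.edges["feature_i"] == "flat") | (net.edges["feature_j"] == "flat")
        ).any()

    def test_too_few_samples_rejected(self):
        table = AbsoluteAbundanceTable(
            pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}, index=["x", "y"])
        )
        with pytest.raises(ValueError, match="at least 4"):
            spearman_network(table)
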