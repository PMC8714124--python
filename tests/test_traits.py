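"""Specimen trait pipeline: filtering, scaling, PCA, binning, frequencies,
cultural distances and site clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from culturewave.spatial_stats import DistMatrix
from culturewave.traits import (
    TraitsError,
    categorize_scores,
    cluster_sites,
    cultural_distance,
    cultural_pipeline,
    drop_empty_lines,
    filter_specimens,
    l_columns,
    pca_reduce,
    scale_specimens,
    site_trait_frequencies,
)


def _specimens(n=8, n_l=5, rng=None, site_ids=None):
    rng = rng or np.random.default_rng(0)
    df = pd.DataFrame(
        {f"L{i + 1}": rng.uniform(1, 10, n) for i in range(n_l)}
    )
    df.insert(0, "specimen_id", [f"g{i}" for i in range(n)])
    df.insert(1, "site_id", site_ids or ["s1"] * (n // 2) + ["s2"] * (n - n // 2))
    df["total_length"] = rng.uniform(15, 25, n)
    df["total_width"] = rng.uniform(5, 10, n)
    df["area"] = df["total_length"] * df["total_width"] * 0.5
    df["angle"] = rng.uniform(30, 90, n)
    df["retouch_direction_distal"] = (["direct", "inverse"] * n)[:n]
    df["retouch_direction_proximal"] = "direct"
    df["retouch_mode_distal"] = "abrupt"
    df["retouch_mode_proximal"] = "simple"
    df["reliable"] = True
    return df


class TestFilterSpecimens:
    def test_all_pass_is_identity(self):
        df = _specimens()
        out, removed = filter_specimens(df)
        assert len(out) == len(df) and removed == []

    def test_failing_specimen_dropped_and_site_flagged(self):
        df = _specimens(site_ids=["s1"] * 7 + ["solo"])
        df.loc[7, "reliable"] = False
        out, removed = filter_specimens(df)
        assert len(out) == 7
        assert removed == ["solo"]

    def test_all_fail_is_error(self):
        df = _specimens()
        df["reliable"] = False
        with pytest.raises(TraitsError, match="reliability"):
            filter_specimens(df)


class TestScaleSpecimens:
    def test_size_invariance(self):
        """Specimens identical up to size scale to identical rows."""
        df = _specimens(n=4)
        base = df.loc[0, l_columns(df)].to_numpy(dtype=float)
        for i, factor in enumerate([1.0, 2.0, 0.5, 3.0]):
            df.loc[i, l_columns(df)] = base * factor
            df.loc[i, "total_length"] = 20.0 * factor
            df.loc[i, "total_width"] = 8.0 * factor
            df.loc[i, "area"] = 80.0 * factor**2
        out = scale_specimens(df)
        cols = l_columns(df) + ["total_width", "area"]
        assert out[cols].std().max() < 1e-12

    def test_zero_length_names_specimen(self):
        df = _specimens()
        df.loc[2, "total_length"] = 0.0
        with pytest.raises(TraitsError, match="g2"):
            scale_specimens(df)

    def test_zscore_mode_standardises(self):
        out = scale_specimens(_specimens(), mode="zscore")
        cols = l_columns(out)
        assert np.allclose(out[cols].mean(), 0.0, atol=1e-12)
        assert np.allclose(out[cols].std(ddof=0), 1.0, atol=1e-12)


class TestDropEmptyLines:
    def test_zero_column_dropped_single_nonzero_kept(self):
        df = _specimens()
        df["L1"] = 0.0
        df["L2"] = 0.0
        df.loc[3, "L2"] = 4.2
        out = drop_empty_lines(df)
        assert "L1" not in out.columns and "L2" in out.columns

    def test_count_matches_bruteforce_scan(self, rng):
        df = _specimens(n=10, n_l=12, rng=rng)
        zero_cols = rng.choice(l_columns(df), size=4, replace=False)
        df[zero_cols] = 0.0
        out = drop_empty_lines(df)
        expected = sum(
            1 for c in l_columns(df) if (df[c] != 0).any()
        )
        assert len(l_columns(out)) == expected


class TestPcaReduce:
    def test_collinear_data_one_component(self):
        df = _specimens(n=6, n_l=3)
        t = np.linspace(0, 1, 6)
        df["L1"], df["L2"], df["L3"] = 1 + t, 2 + 2 * t, 3 * t
        df["total_length"] = 10 + t
        df["total_width"] = 5 + 5 * t
        df["area"] = 2 + t
        df["angle"] = 40 + t
        res = pca_reduce(df, var_target=0.99)
        assert res.n_components == 1
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_ratios_sum_to_one(self, rng):
        res = pca_reduce(_specimens(n=12, rng=rng))
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_scores_match_eigendecomposition_oracle(self, rng):
        """PCA scores reproduce projection onto covariance eigenvectors."""
        df = _specimens(n=15, n_l=4, rng=rng)
        res = pca_reduce(df, var_target=0.999, standardize=False)
        cols = l_columns(df) + ["total_length", "total_width", "area", "angle"]
        x = df[cols].to_numpy(dtype=float)
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(xc, rowvar=False))
        order = np.argsort(evals)[::-1]
        proj = xc @ evecs[:, order[: res.n_components]]
        # eigenvectors defined up to sign
        for k in range(res.n_components):
            got = res.scores.iloc[:, k].to_numpy()
            assert np.allclose(got, proj[:, k], atol=1e-8) or np.allclose(
                got, -proj[:, k], atol=1e-8
            )

    def test_constant_matrix_rejected(self):
        df = _specimens(n=5)
        cols = l_columns(df) + ["total_length", "total_width", "area", "angle"]
        df[cols] = 1.0
        with pytest.raises(TraitsError, match="constant"):
            pca_reduce(df)


class TestCategorizeScores:
    def test_quartiles_balanced(self, rng):
        scores = pd.DataFrame({"PC1": rng.uniform(0, 1, 40)})
        cats = categorize_scores(scores, n_bins=4)
        counts = cats["PC1"].value_counts()
        assert len(counts) == 4
        assert counts.max() - counts.min() <= 1

    def test_constant_column_single_bin(self):
        scores = pd.DataFrame({"PC1": np.ones(10)})
        with pytest.warns(UserWarning, match="single bin"):
            cats = categorize_scores(scores)
        assert cats["PC1"].nunique() == 1

    def test_boundaries_match_quantiles(self, rng):
        v = rng.normal(size=200)
        cats = categorize_scores(pd.DataFrame({"PC1": v}), n_bins=4)
        qs = np.quantile(v, [0.25, 0.5, 0.75])
        lab = cats["PC1"].to_numpy()
        for i, q in enumerate(qs):
            below = v <= q - 1e-9
            assert set(lab[below]) <= {f"PC1_b{j + 1}" for j in range(i + 1)}


class TestSiteTraitFrequencies:
    def test_single_specimen_one_hot(self):
        cats = pd.DataFrame({"PC1": ["PC1_b2"], "mode": ["abrupt"]})
        freq = site_trait_frequencies(cats, pd.Series(["s1"]))
        assert set(freq.loc["s1"]) == {1.0}

    def test_block_rows_sum_to_one(self, rng):
        n = 30
        cats = pd.DataFrame(
            {
                "PC1": rng.choice(["a", "b", "c"], n),
                "PC2": rng.choice(["x", "y"], n),
            }
        )
        sites = pd.Series(rng.choice(["s1", "s2", "s3"], n))
        freq = site_trait_frequencies(cats, sites)
        for block in ("PC1", "PC2"):
            cols = [c for c in freq.columns if c.startswith(f"{block}=")]
            np.testing.assert_allclose(freq[cols].sum(axis=1), 1.0)


class TestCulturalDistance:
    def test_identical_rows_zero(self):
        freq = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]], index=["a", "b"])
        assert cultural_distance(freq).values[0, 1] == 0.0

    def test_orthogonal_one_hot_sqrt2(self):
        freq = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        assert cultural_distance(freq).values[0, 1] == pytest.approx(np.sqrt(2))

    def test_matches_double_loop(self, rng):
        freq = pd.DataFrame(rng.uniform(0, 1, (5, 7)), index=list("abcde"))
        d = cultural_distance(freq)
        for i in range(5):
            for j in range(5):
                ref = np.sqrt(((freq.iloc[i] - freq.iloc[j]) ** 2).sum())
                assert d.values[i, j] == pytest.approx(ref)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_metric_axioms(self, seed):
        r = np.random.default_rng(seed)
        freq = pd.DataFrame(r.uniform(0, 1, (5, 6)), index=list("abcde"))
        d = cultural_distance(freq).values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestClusterSites:
    def test_identical_sites_merge_first_at_zero(self):
        v = np.array(
            [[0.0, 0.0, 5.0], [0.0, 0.0, 5.0], [5.0, 5.0, 0.0]]
        )
        res = cluster_sites(DistMatrix(v, ("a", "b", "c")))
        assert res.linkage[0, 2] == 0.0
        assert res.merges.loc[0, "members"] == "a|b"

    def test_three_site_merge_order_matches_hand_linkage(self):
        # d(a,b)=1, d(a,c)=4, d(b,c)=6: first merge (a,b) at 1, then c at
        # average linkage (4+6)/2 = 5
        v = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 6.0], [4.0, 6.0, 0.0]])
        res = cluster_sites(DistMatrix(v, ("a", "b", "c")), method="average")
        assert res.linkage[0, 2] == pytest.approx(1.0)
        assert res.linkage[1, 2] == pytest.approx(5.0)

    def test_outlier_site_joins_last(self, rng):
        """A site far from a tight cluster is the last leaf to join."""
        pts = rng.normal(0, 0.2, (5, 3))
        pts[4] += 10.0
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        labels = ("a", "b", "c", "d", "outlier")
        res = cluster_sites(DistMatrix(d, labels))
        assert "outlier" in res.merges.iloc[-1]["members"]
        prev = set(res.merges.iloc[-2]["members"].split("|"))
        assert "outlier" not in prev

    def test_newick_is_parseable_and_complete(self, rng):
        from conftest import random_distmatrix

        d = random_distmatrix(rng, 6, labels=list("abcdef"))
        res = cluster_sites(d)
        assert res.newick.endswith(";")
        for lab in d.labels:
            assert lab in res.newick


class TestPipeline:
    def test_pipeline_on_synthetic_dataset(self, default_dataset):
        _, sites, specimens, _, _ = default_dataset
        A, freq, removed = cultural_pipeline(specimens)
        assert set(A.labels) <= set(sites.site_ids)
        assert ((freq.to_numpy() >= 0) & (freq.to_numpy() <= 1)).all()
        assert A.n == len(freq)
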