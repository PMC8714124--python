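"""Distance matrices, Mantel / partial Mantel and Moran's I."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_distmatrix
from culturewave.io_config import SiteTable
from culturewave.spatial_stats import (
    DegenerateMatrixError,
    DistMatrix,
    PartialMantelEngine,
    chrono_matrix,
    geographic_distance_matrix,
    mantel,
    morans_i,
    partial_mantel,
)


def _sites(coords, mode="planar"):
    import pandas as pd

    df = pd.DataFrame(
        {
            "site_id": [f"s{i}" for i in range(len(coords))],
            "name": "",
            "x": [c[0] for c in coords],
            "y": [c[1] for c in coords],
            "region": "r1",
            "route": "a",
            "cra": 7500.0,
            "cra_error": 50.0,
        }
    )
    return SiteTable(df, mode)


class TestDistMatrix:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]), ("a", "b"))

    def test_roundtrip_csv(self, tmp_path, rng):
        d = random_distmatrix(rng, 5)
        d.write_csv(tmp_path / "d.csv")
        back = DistMatrix.read_csv(tmp_path / "d.csv")
        assert back.labels == d.labels
        np.testing.assert_allclose(back.values, d.values)

    def test_reorder_permutes_consistently(self, rng):
        d = random_distmatrix(rng, 4, labels=list("abcd"))
        r = d.reorder(["d", "b", "a", "c"])
        assert r.values[0, 1] == d.values[3, 1]


class TestGeographicDistance:
    def test_planar_3_4_5(self):
        d = geographic_distance_matrix(_sites([(0, 0), (3, 4)]))
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_coincident_sites_zero(self):
        d = geographic_distance_matrix(_sites([(1, 2), (1, 2), (0, 0)]))
        assert d.values[0, 1] == 0.0

    def test_haversine_one_degree_at_equator(self):
        # closed form: R * pi/180 = 6371 * 0.0174533 = 111.19 km
        d = geographic_distance_matrix(_sites([(0, 0), (1, 0)], mode="lonlat"))
        assert d.values[0, 1] == pytest.approx(111.195, abs=0.01)

    def test_missing_coordinate_rejected(self):
        s = _sites([(0, 0), (3, 4)])
        s.df.loc[0, "x"] = np.nan
        with pytest.raises(ValueError, match="coordinate"):
            geographic_distance_matrix(s)


class TestChronoMatrix:
    def test_equal_dates_zero_matrix(self):
        c = chrono_matrix({"a": 7500.0, "b": 7500.0})
        assert (c.values == 0).all()

    def test_absolute_differences(self):
        c = chrono_matrix([7500.0, 7400.0, 7000.0], labels=["a", "b", "c"])
        iu = c.condensed()
        assert sorted(iu) == [100.0, 400.0, 500.0]

    def test_matches_bruteforce_table(self, rng):
        y = rng.uniform(7000, 8000, size=6)
        c = chrono_matrix(y, labels=[f"s{i}" for i in range(6)])
        for i in range(6):
            for j in range(6):
                assert c.values[i, j] == pytest.approx(abs(y[i] - y[j]))

    def test_missing_date_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            chrono_matrix({"a": 7500.0}, labels=["a", "b"])


def _pearson(x, y):
    return float(np.corrcoef(x, y)[0, 1])


def _exhaustive_mantel_p(A, B, alternative="greater"):
    """Oracle: enumerate all n! joint row/column relabelings of B."""
    n = A.n
    a = A.condensed()
    obs = _pearson(a, B.condensed())
    iu = np.triu_indices(n, 1)
    hits = 0
    total = 0
    for p in itertools.permutations(range(n)):
        bp = B.values[np.ix_(p, p)][iu]
        stat = _pearson(a, bp)
        if alternative == "greater":
            hits += stat >= obs - 1e-12
        else:
            hits += abs(stat) >= abs(obs) - 1e-12
        total += 1
    return hits / total


def _partial_stat_oracle(A, C, B):
    """Residual-on-residual Pearson correlation via least squares."""
    a, c, b = A.condensed(), C.condensed(), B.condensed()
    X = np.column_stack([np.ones_like(b), b])
    ra = a - X @ np.linalg.lstsq(X, a, rcond=None)[0]
    rc = c - X @ np.linalg.lstsq(X, c, rcond=None)[0]
    return _pearson(ra, rc)


def _exhaustive_partial_p(A, C, B):
    n = A.n
    obs = _partial_stat_oracle(A, C, B)
    hits = 0
    total = 0
    for p in itertools.permutations(range(n)):
        Cp = DistMatrix(C.values[np.ix_(p, p)], C.labels)
        stat = _partial_stat_oracle(A, Cp, B)
        hits += stat >= obs - 1e-12
        total += 1
    return hits / total


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        A = random_distmatrix(rng, 6)
        res = mantel(A, A, permutations=99, rng=rng)
        assert res.statistic == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        A = random_distmatrix(rng, 6)
        v = 2.0 * A.values + 5.0
        np.fill_diagonal(v, 0.0)
        B = DistMatrix(v, A.labels)
        res = mantel(A, B, permutations=99, rng=rng)
        assert res.statistic == pytest.approx(1.0)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        for _ in range(3):
            A = random_distmatrix(rng, 4)
            B = random_distmatrix(rng, 4)
            res = mantel(A, B, exact=True)
            assert res.n_perm == 24
            assert res.p_value == pytest.approx(_exhaustive_mantel_p(A, B))

    def test_permutation_p_close_to_exact_for_n5(self, rng):
        A = random_distmatrix(rng, 5)
        B = random_distmatrix(rng, 5)
        exact = mantel(A, B, exact=True).p_value
        approx = mantel(A, B, permutations=4999, rng=rng).p_value
        assert abs(approx - exact) < 0.05

    def test_zero_variance_rejected(self, rng):
        A = random_distmatrix(rng, 5)
        flat = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(DegenerateMatrixError):
            mantel(A, DistMatrix(flat, A.labels), permutations=9, rng=rng)

    def test_relabeling_invariance(self, rng):
        """Simultaneous relabeling of both matrices leaves the statistic
        unchanged."""
        A = random_distmatrix(rng, 6, labels=list("abcdef"))
        B = random_distmatrix(rng, 6, labels=list("abcdef"))
        order = list("fceabd")
        s1 = mantel(A, B, permutations=9, rng=np.random.default_rng(0)).statistic
        s2 = mantel(
            A.reorder(order), B.reorder(order), permutations=9, rng=np.random.default_rng(0)
        ).statistic
        assert s1 == pytest.approx(s2, abs=1e-12)


class TestPartialMantel:
    def test_c_equals_a_gives_one(self, rng):
        A = random_distmatrix(rng, 6)
        B = random_distmatrix(rng, 6, labels=A.labels)
        res = partial_mantel(A, A, B, permutations=99, rng=rng)
        assert res.statistic == pytest.approx(1.0)

    def test_statistic_matches_residual_regression_oracle(self, rng):
        for _ in range(5):
            A = random_distmatrix(rng, 6)
            C = random_distmatrix(rng, 6, labels=A.labels)
            B = random_distmatrix(rng, 6, labels=A.labels)
            res = partial_mantel(A, C, B, permutations=9, rng=rng)
            assert res.statistic == pytest.approx(
                _partial_stat_oracle(A, C, B), abs=1e-10
            )

    def test_exact_p_matches_enumeration_oracle(self, rng):
        A = random_distmatrix(rng, 4)
        C = random_distmatrix(rng, 4, labels=A.labels)
        B = random_distmatrix(rng, 4, labels=A.labels)
        res = partial_mantel(A, C, B, exact=True)
        assert res.p_value == pytest.approx(_exhaustive_partial_p(A, C, B))

    def test_matches_skbio_statistic(self, rng):
        """Independent cross-check of the plain Mantel correlation against
        scikit-bio on the same matrices."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        A = random_distmatrix(rng, 7)
        B = random_distmatrix(rng, 7, labels=A.labels)
        ours = mantel(A, B, permutations=9, rng=rng).statistic
        theirs = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(A.values, A.labels),
            skbio_distance.DistanceMatrix(B.values, B.labels),
            permutations=0,
        )[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_engine_dates_path_equals_matrix_path(self, rng):
        A = random_distmatrix(rng, 6)
        B = random_distmatrix(rng, 6, labels=A.labels)
        y = rng.uniform(7000, 7600, 6)
        C = chrono_matrix(y, labels=A.labels)
        eng = PartialMantelEngine(A, B)
        assert eng.statistic_from_dates(y) == pytest.approx(
            partial_mantel(A, C, B, permutations=9, rng=rng).statistic, abs=1e-12
        )

    def test_constant_dates_not_significant(self, rng):
        A = random_distmatrix(rng, 5)
        B = random_distmatrix(rng, 5, labels=A.labels)
        eng = PartialMantelEngine(A, B)
        res = eng.test_dates(np.full(5, 7500.0), rng)
        assert not res.significant and res.p_value == 1.0


class TestMoransI:
    def test_null_expectation_closed_form(self, rng):
        sites = _sites([(i * 7 % 13, i * 5 % 11) for i in range(13)])
        res = morans_i(rng.normal(size=13), sites, permutations=99, rng=rng)
        assert res.expected == pytest.approx(-1.0 / 12.0)

    def test_gradient_detected(self, rng):
        coords = [(i * 10.0, (i * 3) % 7) for i in range(12)]
        sites = _sites(coords)
        values = np.array([c[0] for c in coords]) + rng.normal(0, 1, 12)
        res = morans_i(values, sites, permutations=999, rng=rng)
        assert res.statistic > res.expected
        assert res.p_value <= 0.05

    def test_type_one_error_calibrated(self, rng):
        """Rejection rate of iid values ≈ alpha over 200 replicates."""
        coords = [(i * 11 % 17, i * 7 % 13) for i in range(10)]
        sites = _sites(coords)
        d = geographic_distance_matrix(sites)
        rejections = 0
        for _ in range(200):
            v = rng.normal(size=10)
            res = morans_i(v, distances=d, permutations=99, rng=rng)
            rejections += res.significant
        assert 0.01 <= rejections / 200 <= 0.10

    def test_constant_values_rejected(self, rng):
        sites = _sites([(0, 0), (1, 0), (0, 1), (1, 1)])
        with pytest.raises(DegenerateMatrixError):
            morans_i(np.ones(4), sites, permutations=9, rng=rng)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=15, deadline=None)
def test_metric_matrices_give_bounded_statistics(seed):
    """|statistic| <= 1 for arbitrary metric inputs (property)."""
    r = np.random.default_rng(seed)
    A = random_distmatrix(r, 5)
    B = random_distmatrix(r, 5, labels=A.labels)
    res = mantel(A, B, permutations=19, rng=r)
    assert -1.0 - 1e-12 <= res.statistic <= 1.0 + 1e-12
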