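"""Distance matrices and permutation statistics.

Three symmetric distance matrices drive the analysis: cultural (A, between
per-site trait-frequency profiles), geographic (B, km) and chronological
(C, absolute calendar-year differences).  The association between A and C
while holding B constant is measured by the first-order partial correlation
of the upper-triangle vectors,

.. math::

    r_{AC \\cdot B} = \\frac{r_{AC} - r_{AB} r_{CB}}
                          {\\sqrt{(1 - r_{AB}^2)(1 - r_{CB}^2)}},

and its significance assessed by jointly permuting the rows and columns of
the hypothesis matrix (C).  Because a joint row/column permutation only
rearranges the off-diagonal entries, the permuted triangles share the mean
and standard deviation of the original, which the implementation exploits to
vectorise the permutation null.

Moran's I with row-standardised inverse-distance weights screens individual
variables for spatial autocorrelation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DistMatrix",
    "MantelResult",
    "MoranResult",
    "DegenerateMatrixError",
    "PartialMantelEngine",
    "geographic_distance_matrix",
    "chrono_matrix",
    "mantel",
    "partial_mantel",
    "morans_i",
]

EARTH_RADIUS_KM = 6371.0


class DegenerateMatrixError(ValueError):
    """A distance matrix has zero variance (or perfect collinearity) where a
    correlation is required."""


@dataclass(frozen=True)
class DistMatrix:
    """Symmetric non-negative square distance matrix with labelled rows."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count must match matrix size")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-8):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < -1e-9):
            raise ValueError("distances must be non-negative")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        v = np.clip(v, 0.0, None)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector (row-major, k=1)."""
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]

    def reorder(self, labels) -> "DistMatrix":
        idx = [self.labels.index(str(l)) for l in labels]
        return DistMatrix(self.values[np.ix_(idx, idx)], tuple(labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="site_id")

    @classmethod
    def read_csv(cls, path) -> "DistMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), tuple(str(c) for c in df.columns))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistMatrix":
        return cls(df.to_numpy(dtype=float), tuple(str(c) for c in df.columns))


@dataclass(frozen=True)
class MantelResult:
    statistic: float
    p_value: float
    n_perm: int
    significant: bool
    alpha: float


@dataclass(frozen=True)
class MoranResult:
    statistic: float
    expected: float
    p_value: float
    n_perm: int
    significant: bool
    alpha: float


def _haversine_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix (km) for degree coordinates."""
    lam = np.radians(lon)
    phi = np.radians(lat)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def geographic_distance_matrix(sites) -> DistMatrix:
    """Pairwise site distances in km.

    Planar coordinate mode uses straight-line Euclidean distance; lon/lat
    mode uses the haversine great-circle distance on a sphere of radius
    6371 km.
    """
    df = sites.df
    coords = df[["x", "y"]].to_numpy(dtype=float)
    if np.any(~np.isfinite(coords)):
        raise ValueError("missing or non-finite site coordinates")
    if sites.coordinate_mode == "planar":
        diff = coords[:, None, :] - coords[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
    elif sites.coordinate_mode == "lonlat":
        d = _haversine_km(coords[:, 0], coords[:, 1])
    else:
        raise ValueError(f"unknown coordinate mode {sites.coordinate_mode!r}")
    return DistMatrix(d, tuple(df["site_id"]))


def chrono_matrix(dates, labels=None) -> DistMatrix:
    """Chronological distance matrix: absolute calendar-year differences.

    ``dates`` may be a mapping site_id -> cal BP year (``labels`` gives the
    output order, default mapping order) or an aligned sequence with
    ``labels`` required.
    """
    if isinstance(dates, dict):
        labels = tuple(labels) if labels is not None else tuple(dates)
        missing = [l for l in labels if l not in dates]
        if missing:
            raise ValueError(f"missing dates for sites: {missing}")
        y = np.asarray([dates[l] for l in labels], dtype=float)
    else:
        y = np.asarray(dates, dtype=float)
        if labels is None:
            raise ValueError("labels required when dates given as a sequence")
        labels = tuple(labels)
    if np.any(~np.isfinite(y)):
        raise ValueError("missing (non-finite) dates")
    return DistMatrix(np.abs(y[:, None] - y[None, :]), labels)


def _check_aligned(*mats: DistMatrix) -> None:
    first = mats[0]
    for m in mats[1:]:
        if m.labels != first.labels:
            raise ValueError("distance matrices must share labels and order")
    if first.n < 4:
        raise ValueError("permutation tests require at least 4 sites")


def _zscore(v: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu = v.mean()
    sd = v.std()
    if sd == 0:
        raise DegenerateMatrixError("distance triangle has zero variance")
    return (v - mu) / sd, mu, sd


def _perm_triangle_index(n: int, perms: np.ndarray) -> np.ndarray:
    """Flat indices of the permuted upper triangle in the original matrix."""
    iu = np.triu_indices(n, 1)
    return perms[:, iu[0]] * n + perms[:, iu[1]]


def _random_perms(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    return np.argsort(rng.random((k, n)), axis=1)


def _pvalue_from_null(null: np.ndarray, observed: float, alternative: str,
                      exact: bool) -> float:
    null = np.asarray(null, dtype=float)
    # tolerance so the identity relabeling counts as a tie despite
    # floating-point summation-order differences
    if alternative == "greater":
        hits = np.sum(null >= observed - 1e-12)
    elif alternative == "two-sided":
        hits = np.sum(np.abs(null) >= abs(observed) - 1e-12)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    if exact:
        return float(hits) / len(null)
    return (float(hits) + 1.0) / (len(null) + 1.0)


def mantel(
    A: DistMatrix,
    B: DistMatrix,
    permutations: int = 999,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    alternative: str = "greater",
    exact: bool = False,
) -> MantelResult:
    """Mantel test: Pearson correlation of the upper triangles of ``A`` and
    ``B``; significance by jointly permuting rows and columns of ``B``.

    ``exact=True`` enumerates all n! relabelings (small n only) and reports
    the exact tail proportion (the identity permutation included, so p > 0).
    """
    _check_aligned(A, B)
    n = A.n
    a = A.condensed()
    b = B.condensed()
    za, _, _ = _zscore(a)
    zb, b_mu, b_sd = _zscore(b)
    m = len(a)
    stat = float(za @ zb) / m

    Bflat = B.values.ravel()
    if exact:
        perms = np.array(list(itertools.permutations(range(n))))
    else:
        if rng is None:
            rng = np.random.default_rng()
        perms = _random_perms(n, permutations, rng)
    idx = _perm_triangle_index(n, perms)
    bp = (Bflat[idx] - b_mu) / b_sd
    null = bp @ za / m
    p = _pvalue_from_null(null, stat, alternative, exact)
    return MantelResult(stat, p, len(perms), p <= alpha, alpha)


class PartialMantelEngine:
    """Reusable partial-Mantel evaluator with ``A`` and ``B`` held fixed.

    Precomputes the standardised triangles of the cultural (A) and geographic
    (B) matrices and their correlation, so that repeatedly testing candidate
    chronological matrices (as the ABC machinery does thousands of times)
    costs only the C-triangle work.
    """

    def __init__(
        self,
        A: DistMatrix,
        B: DistMatrix,
        permutations: int = 999,
        alpha: float = 0.05,
        alternative: str = "greater",
    ):
        _check_aligned(A, B)
        self.labels = A.labels
        self.n = A.n
        self.permutations = int(permutations)
        self.alpha = float(alpha)
        self.alternative = alternative
        self._iu = np.triu_indices(self.n, 1)
        self.za, _, _ = _zscore(A.condensed())
        self.zb, _, _ = _zscore(B.condensed())
        self.m = len(self.za)
        self.r_ab = float(self.za @ self.zb) / self.m
        if abs(self.r_ab) >= 1 - 1e-12:
            raise DegenerateMatrixError("A and B triangles are collinear")
        self._ab_den = math.sqrt(1.0 - self.r_ab**2)

    # -- statistic ---------------------------------------------------------

    def _partial(self, r_ac, r_cb):
        with np.errstate(divide="ignore", invalid="ignore"):
            den = self._ab_den * np.sqrt(np.clip(1.0 - np.square(r_cb), 0.0, None))
            return (r_ac - self.r_ab * r_cb) / den

    def statistic_from_ctri(self, c: np.ndarray) -> float:
        zc, _, _ = _zscore(np.asarray(c, dtype=float))
        r_ac = float(zc @ self.za) / self.m
        r_cb = float(zc @ self.zb) / self.m
        if abs(r_cb) >= 1 - 1e-12:
            raise DegenerateMatrixError("C and B triangles are collinear")
        return float(self._partial(r_ac, r_cb))

    def statistic_from_dates(self, dates: np.ndarray) -> float:
        y = np.asarray(dates, dtype=float)
        return self.statistic_from_ctri(np.abs(y[:, None] - y[None, :])[self._iu])

    # -- permutation test --------------------------------------------------

    def test_ctri(
        self,
        c: np.ndarray,
        rng: np.random.Generator | None = None,
        exact: bool = False,
    ) -> MantelResult:
        c = np.asarray(c, dtype=float)
        zc, c_mu, c_sd = _zscore(c)
        stat = self.statistic_from_ctri(c)
        # full C matrix, for triangle extraction under site permutations
        Cm = np.zeros((self.n, self.n))
        Cm[self._iu] = c
        Cm = Cm + Cm.T
        Cflat = Cm.ravel()
        if exact:
            perms = np.array(list(itertools.permutations(range(self.n))))
        else:
            if rng is None:
                rng = np.random.default_rng()
            perms = _random_perms(self.n, self.permutations, rng)
        idx = _perm_triangle_index(self.n, perms)
        cp = (Cflat[idx] - c_mu) / c_sd
        r_ac = cp @ self.za / self.m
        r_cb = cp @ self.zb / self.m
        null = self._partial(r_ac, r_cb)
        null = np.where(np.isfinite(null), null, -np.inf)
        p = _pvalue_from_null(null, stat, self.alternative, exact)
        return MantelResult(stat, p, len(perms), p <= self.alpha, self.alpha)

    def test_dates(
        self, dates: np.ndarray, rng: np.random.Generator | None = None
    ) -> MantelResult:
        y = np.asarray(dates, dtype=float)
        c = np.abs(y[:, None] - y[None, :])[self._iu]
        if c.std() == 0:
            # all modelled dates equal: no chronological structure to test
            return MantelResult(float("nan"), 1.0, self.permutations, False, self.alpha)
        return self.test_ctri(c, rng)


def partial_mantel(
    A: DistMatrix,
    C: DistMatrix,
    B: DistMatrix,
    permutations: int = 999,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    alternative: str = "greater",
    exact: bool = False,
) -> MantelResult:
    """Partial Mantel test of A vs C controlling for B.

    The statistic is the first-order partial correlation of the triangle
    vectors; the null distribution is built by jointly permuting rows and
    columns of C (the hypothesis matrix) while A and B stay fixed.
    """
    _check_aligned(A, C, B)
    eng = PartialMantelEngine(A, B, permutations, alpha, alternative)
    return eng.test_ctri(C.condensed(), rng=rng, exact=exact)


def morans_i(
    values,
    sites=None,
    distances: DistMatrix | None = None,
    permutations: int = 999,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> MoranResult:
    """Moran's I with row-standardised inverse-distance weights.

    .. math:: I = \\frac{n}{\\sum_{ij} w_{ij}}
              \\frac{\\sum_{ij} w_{ij} z_i z_j}{\\sum_i z_i^2}

    The null expectation is :math:`-1/(n-1)`; the p-value permutes the
    values over locations.
    """
    v = np.asarray(values, dtype=float)
    if distances is None:
        if sites is None:
            raise ValueError("provide either sites or a distance matrix")
        distances = geographic_distance_matrix(sites)
    n = distances.n
    if len(v) != n:
        raise ValueError("value count must match number of sites")
    if n < 4:
        raise ValueError("Moran's I requires at least 4 sites")
    if v.std() == 0:
        raise DegenerateMatrixError("constant values: Moran's I undefined")
    d = distances.values.copy()
    with np.errstate(divide="ignore"):
        w = np.where(d > 0, 1.0 / d, 0.0)
    np.fill_diagonal(w, 0.0)
    rowsum = w.sum(axis=1, keepdims=True)
    if np.any(rowsum == 0):
        raise ValueError("a site has zero weight to every other site")
    w = w / rowsum
    s0 = w.sum()
    z = v - v.mean()
    denom = float(z @ z)
    stat = float(n / s0 * (z @ w @ z) / denom)
    expected = -1.0 / (n - 1)
    if rng is None:
        rng = np.random.default_rng()
    perms = _random_perms(n, permutations, rng)
    zp = z[perms]
    null = n / s0 * np.einsum("pi,ij,pj->p", zp, w, zp) / denom
    if alternative == "greater":
        hits = np.sum(null >= stat)
    elif alternative == "two-sided":
        hits = np.sum(np.abs(null - expected) >= abs(stat - expected))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (float(hits) + 1.0) / (permutations + 1.0)
    return MoranResult(stat, expected, p, permutations, p <= alpha, alpha)
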