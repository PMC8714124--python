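"""From specimen morphometrics to a per-site cultural distance matrix.

The pipeline order is fixed and each stage is a pure function of its input
plus configuration:

1. ``filter_specimens`` — drop specimens failing any reliability flag; sites
   left without specimens are reported for removal from the study.
2. ``scale_specimens`` — remove raw size: divide every linear measure by the
   specimen's total length (area by its square).  A z-score mode is
   available as an alternative normalisation.
3. ``drop_empty_lines`` — discard morphometric L-columns with no presence in
   any retained specimen.
4. ``pca_reduce`` — standardised PCA keeping the smallest number of
   components reaching a cumulative explained-variance target.
5. ``categorize_scores`` — quantile-bin each retained component so numeric
   scores become discrete trait states alongside the categorical retouch
   variables.
6. ``site_trait_frequencies`` — per-site representation value of each trait
   state; within a trait block the frequencies of one site sum to 1.

The cultural distance matrix is the pairwise (default Euclidean) distance
between site frequency rows, and ``cluster_sites`` produces the
average-linkage dendrogram of those distances.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .spatial_stats import DistMatrix

__all__ = [
    "TraitsError",
    "filter_specimens",
    "scale_specimens",
    "drop_empty_lines",
    "PcaResult",
    "pca_reduce",
    "categorize_scores",
    "site_trait_frequencies",
    "cultural_distance",
    "ClusterResult",
    "cluster_sites",
    "cultural_pipeline",
]

_L_RE = re.compile(r"^L\d+$")
METRIC_COVARIATES = ("total_length", "total_width", "area", "angle")
RETOUCH_COLUMNS = (
    "retouch_direction_distal",
    "retouch_direction_proximal",
    "retouch_mode_distal",
    "retouch_mode_proximal",
)
_TRUTHY = {"true", "yes", "y", "ok", "pass", "1", "1.0"}


class TraitsError(ValueError):
    """Trait-pipeline precondition violated."""


def l_columns(df: pd.DataFrame) -> list[str]:
    """Morphometric line-length columns (L1, L2, ...)."""
    return [c for c in df.columns if _L_RE.match(c)]


def reliability_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("reliab")]


def _as_bool(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    return col.astype(str).str.strip().str.lower().isin(_TRUTHY)


def filter_specimens(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Keep specimens passing every reliability flag.

    Returns the filtered table and the ids of sites left with no reliable
    specimen (to be removed from the site list, as incomplete assemblages
    cannot support frequency estimates).
    """
    flags = reliability_columns(df)
    if not flags:
        raise TraitsError("no reliability flag columns found")
    ok = np.ones(len(df), dtype=bool)
    for c in flags:
        ok &= _as_bool(df[c]).to_numpy()
    out = df.loc[ok].reset_index(drop=True)
    if len(out) == 0:
        raise TraitsError("no specimens pass the reliability criteria")
    removed_sites = sorted(set(df["site_id"]) - set(out["site_id"]))
    return out, removed_sites


def scale_specimens(df: pd.DataFrame, mode: str = "length") -> pd.DataFrame:
    """Size normalisation.

    ``length`` mode divides L-measures and total width by the specimen's
    total length, area by total length squared; the angle is already
    scale-free and total length becomes the constant 1.  ``zscore`` mode
    standardises every continuous column instead.
    """
    lc = l_columns(df)
    out = df.copy()
    if mode == "length":
        tl = pd.to_numeric(out["total_length"], errors="raise")
        if (tl <= 0).any():
            bad = out.loc[tl <= 0, "specimen_id"].tolist()
            raise TraitsError(f"non-positive total_length for specimen(s): {bad}")
        out[lc] = out[lc].div(tl, axis=0)
        if "total_width" in out:
            out["total_width"] = out["total_width"] / tl
        if "area" in out:
            out["area"] = out["area"] / tl**2
        out["total_length"] = 1.0
    elif mode == "zscore":
        cols = lc + [c for c in METRIC_COVARIATES if c in out.columns]
        x = out[cols].to_numpy(dtype=float)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        out[cols] = (x - x.mean(axis=0)) / sd
    else:
        raise TraitsError(f"unknown scaling mode {mode!r}")
    return out


def drop_empty_lines(df: pd.DataFrame) -> pd.DataFrame:
    """Remove L-columns that are zero (or missing) in every specimen."""
    lc = l_columns(df)
    vals = df[lc].fillna(0.0)
    empty = [c for c in lc if (vals[c] == 0).all()]
    return df.drop(columns=empty)


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    n_components: int


def pca_reduce(
    df: pd.DataFrame, var_target: float = 0.80, standardize: bool = True
) -> PcaResult:
    """Centred (and by default standardised) PCA over the continuous
    columns; keeps the smallest k with cumulative explained variance
    >= ``var_target``."""
    if not 0 < var_target <= 1:
        raise TraitsError("var_target must lie in (0, 1]")
    cols = l_columns(df) + [c for c in METRIC_COVARIATES if c in df.columns]
    if len(df) < 2:
        raise TraitsError("PCA needs at least two specimens")
    x = df[cols].to_numpy(dtype=float)
    keep = x.std(axis=0) > 0
    if not keep.any():
        raise TraitsError("all continuous columns are constant")
    x = x[:, keep]
    if standardize:
        x = StandardScaler().fit_transform(x)
    else:
        x = x - x.mean(axis=0)
    pca = PCA()
    scores = pca.fit_transform(x)
    ratios = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(ratios), var_target - 1e-12)) + 1
    k = min(k, scores.shape[1])
    out = pd.DataFrame(
        scores[:, :k], index=df.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return PcaResult(out, ratios, k)


def categorize_scores(scores: pd.DataFrame, n_bins: int = 4) -> pd.DataFrame:
    """Quantile-bin each score column into categorical trait states.

    Ties collapsing a bin boundary merge adjacent bins (with a warning); a
    constant column yields a single state.
    """
    if n_bins < 2:
        raise TraitsError("n_bins must be at least 2")
    out = {}
    for col in scores.columns:
        v = scores[col]
        if v.nunique() == 1:
            warnings.warn(f"{col}: constant scores collapsed to a single bin")
            out[col] = pd.Series([f"{col}_b1"] * len(v), index=v.index)
            continue
        binned = pd.qcut(v, q=n_bins, duplicates="drop", labels=False)
        if binned.nunique() < n_bins:
            warnings.warn(f"{col}: tied quantiles merged adjacent bins")
        out[col] = binned.map(lambda b: f"{col}_b{int(b) + 1}")
    return pd.DataFrame(out, index=scores.index)


def site_trait_frequencies(
    cats: pd.DataFrame, site_ids: pd.Series
) -> pd.DataFrame:
    """Per-site representation values of every trait state.

    ``cats`` holds one categorical column per trait block (binned component
    scores and retouch variables).  The output has one row per site and one
    column per ``block=state``; within each block a site's values sum to 1.
    """
    if len(cats) != len(site_ids):
        raise TraitsError("cats and site_ids must align")
    sid = pd.Series(site_ids).astype(str).reset_index(drop=True)
    cats = cats.reset_index(drop=True)
    blocks = []
    for col in cats.columns:
        tab = pd.crosstab(sid, cats[col].astype(str), normalize="index")
        tab.columns = [f"{col}={lvl}" for lvl in tab.columns]
        blocks.append(tab)
    freq = pd.concat(blocks, axis=1).fillna(0.0)
    freq.index.name = "site_id"
    return freq.sort_index()


def cultural_distance(freq: pd.DataFrame, metric: str = "euclidean") -> DistMatrix:
    """Pairwise distance between site frequency rows (Matrix A)."""
    if len(freq) < 2:
        raise TraitsError("cultural distance needs at least two sites")
    d = squareform(pdist(freq.to_numpy(dtype=float), metric=metric))
    return DistMatrix(d, tuple(str(s) for s in freq.index))


@dataclass(frozen=True)
class ClusterResult:
    linkage: np.ndarray
    labels: tuple[str, ...]
    newick: str
    merges: pd.DataFrame

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]


def _newick(node, labels: tuple[str, ...], parent_height: float) -> str:
    length = max(parent_height - node.dist, 0.0)
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.6g}"
    left = _newick(node.left, labels, node.dist)
    right = _newick(node.right, labels, node.dist)
    return f"({left},{right}):{length:.6g}"


def cluster_sites(d: DistMatrix, method: str = "average") -> ClusterResult:
    """Agglomerative clustering of sites on their cultural distances.

    Returns the SciPy linkage matrix, a Newick string with merge-height
    branch lengths, and a merge table (height + members per merge).
    """
    z = hierarchy.linkage(d.condensed(), method=method)
    tree = hierarchy.to_tree(z)
    newick = _newick(tree, d.labels, tree.dist) + ";"
    n = d.n
    members: dict[int, list[str]] = {i: [d.labels[i]] for i in range(n)}
    rows = []
    for i, (a, b, h, _) in enumerate(z):
        grp = members[int(a)] + members[int(b)]
        members[n + i] = grp
        rows.append({"merge": i + 1, "height": h, "members": "|".join(sorted(grp))})
    return ClusterResult(z, d.labels, newick, pd.DataFrame(rows))


def cultural_pipeline(
    specimens: pd.DataFrame,
    var_target: float = 0.80,
    n_bins: int = 4,
    scale_mode: str = "length",
    metric: str = "euclidean",
) -> tuple[DistMatrix, pd.DataFrame, list[str]]:
    """Run the full trait pipeline: filter, scale, drop empty lines, PCA,
    categorise, site frequencies, cultural distances.

    Returns (cultural DistMatrix, frequency matrix, removed site ids).
    """
    filtered, removed = filter_specimens(specimens)
    scaled = scale_specimens(filtered, mode=scale_mode)
    trimmed = drop_empty_lines(scaled)
    scores = pca_reduce(trimmed, var_target=var_target).scores
    cats = categorize_scores(scores, n_bins=n_bins)
    for col in RETOUCH_COLUMNS:
        if col in trimmed.columns:
            cats[col] = trimmed[col].astype(str).reset_index(drop=True)
    freq = site_trait_frequencies(cats, trimmed["site_id"])
    return cultural_distance(freq, metric=metric), freq, removed
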