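"""Posterior summaries of the final particle.

Origin probabilities are accepted-draw frequencies per site.  Regional and
route aggregates correct for unequal group sizes: the summed probability of
a group is divided by the number of sites producing it, and the corrected
scores are renormalised to sum to 1.  For double-origin runs the same logic
applies to unordered origin pairs (same-group pairs included), dividing by
the number of site pairs that can realise each group pair.

The expansion-rate posterior is summarised by a maximum-likelihood Gamma
fit and its highest-posterior-density (HPD) interval — the narrowest
interval holding the requested mass under the fitted density.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "origin_posterior",
    "aggregate_groups",
    "aggregate_pairs",
    "HpdResult",
    "r_hpd",
    "convergence_summary",
    "posterior_summary",
]


def origin_posterior(records: Sequence) -> pd.Series:
    """Per-site origin probability: frequency among accepted records.

    Double-origin records contribute both members of their unordered pair,
    so the probabilities still sum to 1.
    """
    if not records:
        raise ValueError("empty particle")
    counts: dict[str, int] = {}
    total = 0
    for rec in records:
        for site in rec.origins:
            counts[site] = counts.get(site, 0) + 1
            total += 1
    probs = pd.Series(counts, dtype=float).sort_index() / total
    probs.index.name = "site_id"
    return probs


def aggregate_groups(site_probs: pd.Series, mapping: Mapping[str, str]) -> pd.Series:
    """Size-corrected group (region/route) probabilities.

    raw_g = sum of the group's site probabilities divided by the group's
    site count; the corrected scores are renormalised to sum to 1.  The
    group size counts every mapped site, including those that never appear
    among the accepted origins.
    """
    missing = [s for s in site_probs.index if s not in mapping]
    if missing:
        raise ValueError(f"sites missing from group mapping: {missing}")
    sizes: dict[str, int] = {}
    for g in mapping.values():
        sizes[g] = sizes.get(g, 0) + 1
    if any(v == 0 for v in sizes.values()):
        raise ValueError("empty group in mapping")
    raw: dict[str, float] = {g: 0.0 for g in sizes}
    for site, p in site_probs.items():
        raw[mapping[site]] += p
    corrected = {g: raw[g] / sizes[g] for g in raw}
    total = sum(corrected.values())
    if total <= 0:
        raise ValueError("all group probabilities are zero")
    out = pd.Series({g: v / total for g, v in corrected.items()}).sort_index()
    out.index.name = "group"
    return out


def _pair_key(a: str, b: str) -> str:
    return "-".join(sorted((a, b)))


def aggregate_pairs(
    records: Sequence,
    mapping: Mapping[str, str],
    corrected: bool = True,
) -> pd.Series:
    """Unordered group-pair probabilities from double-origin records.

    Each record's unordered origin pair maps to an unordered group pair
    (same-group pairs included).  With ``corrected=True`` the summed
    probability of a group pair is divided by the number of unordered site
    pairs (repeats allowed) that can realise it — |g||h| for distinct
    groups, |g|(|g|+1)/2 within a group — then renormalised.
    """
    if not records:
        raise ValueError("empty particle")
    sizes: dict[str, int] = {}
    for g in mapping.values():
        sizes[g] = sizes.get(g, 0) + 1
    groups = sorted(sizes)
    keys = [_pair_key(a, b) for a, b in combinations_with_replacement(groups, 2)]
    raw = {k: 0.0 for k in keys}
    for rec in records:
        if len(rec.origins) != 2:
            raise ValueError("aggregate_pairs requires double-origin records")
        g1, g2 = mapping[rec.origins[0]], mapping[rec.origins[1]]
        raw[_pair_key(g1, g2)] += 1.0
    total = float(len(records))
    raw = {k: v / total for k, v in raw.items()}
    if corrected:
        weights = {}
        for a, b in combinations_with_replacement(groups, 2):
            if a == b:
                npairs = sizes[a] * (sizes[a] + 1) / 2
            else:
                npairs = sizes[a] * sizes[b]
            weights[_pair_key(a, b)] = raw[_pair_key(a, b)] / npairs
        total_w = sum(weights.values())
        if total_w <= 0:
            raise ValueError("all pair probabilities are zero")
        raw = {k: v / total_w for k, v in weights.items()}
    out = pd.Series(raw).sort_index()
    out.index.name = "group_pair"
    return out


@dataclass(frozen=True)
class HpdResult:
    low: float
    high: float
    mass: float
    shape: float
    rate: float  # Gamma rate = 1/scale

    def as_tuple(self) -> tuple[float, float]:
        return self.low, self.high


def r_hpd(r_samples, mass: float = 0.95) -> HpdResult:
    """Gamma-fit HPD interval for the expansion-rate posterior.

    A Gamma distribution is fitted by maximum likelihood (location fixed at
    zero); the narrowest interval containing ``mass`` of the fitted density
    is found by numeric search over the lower endpoint.  For shapes <= 1
    the density is monotone decreasing, so the interval starts at zero.
    """
    v = np.asarray(r_samples, dtype=float)
    if len(v) < 30:
        raise ValueError("need at least 30 samples for a stable Gamma fit")
    if np.any(v <= 0):
        raise ValueError("rate samples must be positive")
    if v.std() == 0:
        raise ValueError("degenerate (zero-variance) rate samples")
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    shape, _, scale = stats.gamma.fit(v, floc=0)
    dist = stats.gamma(shape, scale=scale)
    if shape <= 1:
        return HpdResult(0.0, float(dist.ppf(mass)), mass, shape, 1.0 / scale)

    def width(lo: float) -> float:
        return dist.ppf(dist.cdf(lo) + mass) - lo

    res = optimize.minimize_scalar(
        width, bounds=(0.0, float(dist.ppf(1 - mass))), method="bounded"
    )
    lo = float(res.x)
    return HpdResult(lo, float(dist.ppf(dist.cdf(lo) + mass)), mass, shape, 1.0 / scale)


def convergence_summary(particles: Sequence[Sequence]) -> pd.DataFrame:
    """Per-stage table of the rate posterior: mean, sd and central 80%/95%
    intervals, with a flag marking stages whose sd failed to shrink."""
    if len(particles) < 2:
        raise ValueError("need at least two particles")
    rows = []
    prev_sd = None
    for i, recs in enumerate(particles, start=1):
        r = np.asarray([rec.r for rec in recs], dtype=float)
        sd = float(r.std(ddof=1)) if len(r) > 1 else 0.0
        rows.append(
            {
                "stage": i,
                "n": len(r),
                "mean_r": float(r.mean()),
                "sd_r": sd,
                "q10": float(np.quantile(r, 0.10)),
                "q90": float(np.quantile(r, 0.90)),
                "q025": float(np.quantile(r, 0.025)),
                "q975": float(np.quantile(r, 0.975)),
                "sd_shrinking": prev_sd is None or sd <= prev_sd + 1e-12,
            }
        )
        prev_sd = sd
    return pd.DataFrame(rows)


def posterior_summary(
    result,
    region_map: Mapping[str, str],
    route_map: Mapping[str, str],
    hpd_masses: Sequence[float] = (0.80, 0.95),
    pair_correction: bool = True,
) -> dict:
    """JSON-ready posterior summary of one kernel's ABC result."""
    final = result.final
    site_probs = origin_posterior(final)
    out: dict = {
        "kernel": result.kernel,
        "n_accepted": len(final),
        "site_probs": {k: float(v) for k, v in site_probs.items()},
        "region_probs": {
            k: float(v) for k, v in aggregate_groups(site_probs, region_map).items()
        },
        "route_probs": {
            k: float(v) for k, v in aggregate_groups(site_probs, route_map).items()
        },
    }
    if len(final[0].origins) == 2:
        out["region_pair_probs"] = {
            k: float(v)
            for k, v in aggregate_pairs(final, region_map, pair_correction).items()
        }
        out["route_pair_probs"] = {
            k: float(v)
            for k, v in aggregate_pairs(final, route_map, pair_correction).items()
        }
    r = result.r_samples()
    out["r_hpd"] = {}
    for m in hpd_masses:
        h = r_hpd(r, m)
        out["r_hpd"][f"{m:g}"] = {"low": h.low, "high": h.high,
                                  "shape": h.shape, "rate": h.rate}
    out["convergence"] = convergence_summary(result.particles).to_dict(orient="records")
    return out
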