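"""Wave-of-advance expansion model.

A dispersal episode starts at an origin site at calendar date ``t`` (cal BP)
and advances as a constant-speed front of rate ``r`` (km/yr) along
straight-line distances, so the modelled arrival date at site *i* is

.. math:: y_i = t - o_i / r,

with :math:`o_i` the distance from the origin in km.  Larger cal BP values
are older, so arrival dates decrease with distance from the origin.  With
two origins each site takes the oldest (largest) of the two candidate
arrival dates; the origins share a single rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spatial_stats import DistMatrix

__all__ = ["ExpansionParams", "arrival_dates_single", "arrival_dates_double", "arrival_dates"]


@dataclass(frozen=True)
class ExpansionParams:
    """One candidate dispersal scenario: origin site index(es), start
    date(s) in cal BP (one per origin) and a shared expansion rate."""

    origins: tuple[int, ...]
    ts: tuple[float, ...]
    r: float

    def __post_init__(self) -> None:
        origins = tuple(int(o) for o in self.origins)
        ts = tuple(float(t) for t in self.ts)
        object.__setattr__(self, "origins", origins)
        object.__setattr__(self, "ts", ts)
        if len(origins) not in (1, 2):
            raise ValueError("one or two origins supported")
        if len(ts) != len(origins):
            raise ValueError("one start date per origin required")
        if self.r <= 0:
            raise ValueError("expansion rate must be positive")


def arrival_dates_single(params: ExpansionParams, D: DistMatrix) -> np.ndarray:
    """Modelled arrival dates (cal BP) for a single-origin expansion."""
    if len(params.origins) != 1:
        raise ValueError("expected exactly one origin")
    (o,), (t,) = params.origins, params.ts
    return t - D.values[o, :] / params.r


def arrival_dates_double(params: ExpansionParams, D: DistMatrix) -> np.ndarray:
    """Modelled arrival dates for a double-origin expansion: at each site
    the oldest of the two front arrivals is kept."""
    if len(params.origins) != 2:
        raise ValueError("expected exactly two origins")
    cand = np.stack(
        [t - D.values[o, :] / params.r for o, t in zip(params.origins, params.ts)]
    )
    return cand.max(axis=0)


def arrival_dates(params: ExpansionParams, D: DistMatrix) -> np.ndarray:
    """Dispatch on the number of origins."""
    if len(params.origins) == 1:
        return arrival_dates_single(params, D)
    return arrival_dates_double(params, D)
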