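"""Radiocarbon calibration and calendar-date sampling.

A conventional radiocarbon age (CRA, in uncalibrated 14C yr BP) is converted
into a discrete probability density over calendar years (cal BP, larger =
older) by comparing it against a calibration curve.  The density at calendar
year :math:`\\theta` is proportional to the Normal density of the measured CRA
at mean :math:`\\mu(\\theta)` with standard deviation
:math:`\\sqrt{\\sigma_{lab}^2 + \\sigma_{curve}(\\theta)^2}`, normalised over
the grid — the standard intercept-free ("probabilistic") calibration used by
rcarbon, OxCal and calib.

The module also provides random sampling of a single calendar year from a
calibrated density (the date-randomisation device used when a single year per
site is needed) and highest-density intervals (HDI).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "CalibrationError",
    "CalCurve",
    "CalDensity",
    "read_calcurve",
    "write_calcurve",
    "calibrate",
    "sample_cal_date",
    "hdi",
]

#: conventional two-sigma coverage used for reported calibrated ranges
TWO_SIGMA_MASS = 0.954


class CalibrationError(ValueError):
    """A date cannot be calibrated against the supplied curve."""


@dataclass(frozen=True)
class CalCurve:
    """Calibration curve: calendar grid ``theta`` (cal BP), curve 14C age
    ``mu`` and curve error ``sigma`` at each knot.

    The grid must be strictly monotone; it is stored ascending.  Values
    between knots are linearly interpolated, the standard practice for
    published curves.
    """

    theta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if not (theta.ndim == mu.ndim == sigma.ndim == 1):
            raise ValueError("curve columns must be one-dimensional")
        if not (len(theta) == len(mu) == len(sigma)):
            raise ValueError("curve columns must have equal length")
        if len(theta) < 2:
            raise ValueError("curve needs at least two knots")
        d = np.diff(theta)
        if np.all(d < 0):  # stored youngest-last; flip to ascending
            theta, mu, sigma = theta[::-1], mu[::-1], sigma[::-1]
        elif not np.all(d > 0):
            raise ValueError("calendar grid must be strictly monotone")
        if np.any(sigma < 0):
            raise ValueError("curve errors must be non-negative")
        object.__setattr__(self, "theta", theta.copy())
        object.__setattr__(self, "mu", mu.copy())
        object.__setattr__(self, "sigma", sigma.copy())

    @property
    def span(self) -> tuple[float, float]:
        """(youngest, oldest) calendar year covered, cal BP."""
        return float(self.theta[0]), float(self.theta[-1])

    def at(self, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated (mu, sigma) at the requested calendar years."""
        grid = np.asarray(grid, dtype=float)
        return (
            np.interp(grid, self.theta, self.mu),
            np.interp(grid, self.theta, self.sigma),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CalCurve):
            return NotImplemented
        return (
            np.array_equal(self.theta, other.theta)
            and np.array_equal(self.mu, other.mu)
            and np.array_equal(self.sigma, other.sigma)
        )


@dataclass(frozen=True)
class CalDensity:
    """Discrete normalised probability distribution over calendar years."""

    theta: np.ndarray
    p: np.ndarray
    grid_step: float = field(default=1.0)

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if theta.shape != p.shape or theta.ndim != 1:
            raise ValueError("theta and p must be equal-length vectors")
        if np.any(p < 0):
            raise ValueError("probability mass must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probability mass must sum to 1")
        if len(theta) > 1 and not np.all(np.diff(theta) > 0):
            raise ValueError("calendar grid must be strictly increasing")
        object.__setattr__(self, "theta", theta.copy())
        object.__setattr__(self, "p", p.copy())

    def mean(self) -> float:
        """Probability-weighted mean calendar age (cal BP)."""
        return float(np.sum(self.theta * self.p))

    def mode(self) -> float:
        return float(self.theta[int(np.argmax(self.p))])


def _parse_table(text: str) -> np.ndarray:
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        try:
            vals = [float(x) for x in parts[:3]]
        except ValueError:
            continue  # header row
        if len(vals) == 3:
            rows.append(vals)
    if not rows:
        raise CalibrationError("no numeric rows found in calibration curve file")
    return np.asarray(rows, dtype=float)


def read_calcurve(path) -> CalCurve:
    """Read a 3-column (cal BP, 14C age, error) curve table.

    Accepts the published ``.14c`` layout: comma- or whitespace-separated,
    ``#`` comment lines and an optional header row are ignored.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        arr = _parse_table(fh.read())
    return CalCurve(arr[:, 0], arr[:, 1], arr[:, 2])


def write_calcurve(curve: CalCurve, path) -> None:
    buf = io.StringIO()
    buf.write("# cal BP,14C age,error\n")
    for t, m, s in zip(curve.theta, curve.mu, curve.sigma):
        buf.write(f"{t:.17g},{m:.17g},{s:.17g}\n")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def calibrate(
    cra: float,
    cra_error: float,
    curve: CalCurve,
    grid_step: float = 1.0,
    trim: float = 1e-15,
) -> CalDensity:
    """Calibrate a conventional radiocarbon age against ``curve``.

    Parameters
    ----------
    cra, cra_error
        Measured 14C age and its one-sigma laboratory error (yr).
    grid_step
        Calendar-grid resolution in years (default 1).
    trim
        Cells with mass below this value at the tails are dropped (the
        density is renormalised); keeps the support compact.
    """
    if cra_error <= 0:
        raise CalibrationError("cra_error must be positive")
    lo, hi = curve.span
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    mu, sig = curve.at(grid)
    sd = np.hypot(cra_error, sig)
    z = np.abs(cra - mu) / sd
    if z.min() > 10:
        raise CalibrationError(
            f"date {cra}±{cra_error} lies entirely off the calibration curve"
        )
    dens = norm.pdf(cra, loc=mu, scale=sd)
    total = dens.sum()
    p = dens / total
    keep = p > trim
    i0 = int(np.argmax(keep))
    i1 = len(p) - int(np.argmax(keep[::-1]))
    grid, p = grid[i0:i1], p[i0:i1]
    p = p / p.sum()
    return CalDensity(grid, p, grid_step=grid_step)


def sample_cal_date(density: CalDensity, rng: np.random.Generator) -> float:
    """Draw one calendar year (cal BP) from a calibrated density."""
    cum = np.cumsum(density.p)
    u = rng.random()
    idx = int(np.searchsorted(cum, u * cum[-1]))
    idx = min(idx, len(density.theta) - 1)
    return float(density.theta[idx])


def hdi(density: CalDensity, mass: float = TWO_SIGMA_MASS) -> list[tuple[float, float]]:
    """Highest-density region: the smallest set of grid cells whose total
    mass reaches ``mass``, merged into closed intervals (ascending cal BP).

    Cells are accumulated greedily in order of decreasing mass; ties are
    broken by grid position, so the result is deterministic.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    order = np.argsort(-density.p, kind="stable")
    cum = np.cumsum(density.p[order])
    k = int(np.searchsorted(cum, mass - 1e-12)) + 1
    cells = np.sort(order[:k])
    intervals: list[tuple[float, float]] = []
    start = prev = cells[0]
    for c in cells[1:]:
        if c == prev + 1:
            prev = c
            continue
        intervals.append((float(density.theta[start]), float(density.theta[prev])))
        start = prev = c
    intervals.append((float(density.theta[start]), float(density.theta[prev])))
    return intervals


def intervals_overlap(
    a: list[tuple[float, float]], b: list[tuple[float, float]]
) -> bool:
    """True when any closed interval of ``a`` intersects any of ``b``.

    Touching endpoints count as overlap ("to any extent").
    """
    for lo1, hi1 in a:
        for lo2, hi2 in b:
            if max(lo1, lo2) <= min(hi1, hi2):
                return True
    return False
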