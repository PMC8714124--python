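"""Rejection + sequential Monte Carlo acceptance over (origin, t, r).

The observed summary is not a single number but a distribution
:math:`S_o` of significant partial-Mantel statistics obtained by repeatedly
resampling one calendar date per site from its calibrated density.  A
candidate dispersal scenario (origin site(s), start date(s) drawn from the
origin's calibrated density, rate r ~ U(prior)) is simulated through the
expansion model, its modelled chronological matrix tested against the fixed
cultural (A) and geographic (B) matrices, and accepted when the statistic is
significant and falls inside the current quantile window of :math:`S_o`.

Stage 1 is a plain rejection sampler with the interquartile window
(Q1, Q3); the three SMC stages resample a record from the previous particle,
perturb the rate with a transition kernel (strict: U(0.9r, 1.1r); relaxed:
U(r-1, r+1), both clipped to the prior support), redraw the start date(s)
from the calibrated density and re-simulate, with windows tightening to
(P30, P70), (P35, P65) and (P40, P60).  No importance weights are used —
the scheme is plain accept/resample with shrinking windows.  Draw caps turn
non-convergence into a diagnostic error instead of an endless loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .calibration import CalDensity, sample_cal_date
from .expansion import ExpansionParams, arrival_dates
from .io_config import RunConfig
from .spatial_stats import DistMatrix, PartialMantelEngine

__all__ = [
    "AbcError",
    "SimRecord",
    "SummaryDistribution",
    "observed_summary",
    "simulate_one",
    "rejection_stage",
    "smc_step",
    "run_abc",
    "run_all",
    "AbcResult",
]

logger = logging.getLogger("culturewave")


class AbcError(RuntimeError):
    """Acceptance failed to reach its target within the draw cap."""

    def __init__(self, message: str, accepted: int = 0, draws: int = 0):
        rate = accepted / draws if draws else 0.0
        super().__init__(f"{message} (accepted {accepted}/{draws} draws, rate {rate:.4f})")
        self.accepted = accepted
        self.draws = draws
        self.acceptance_rate = rate


@dataclass(frozen=True)
class SimRecord:
    """One accepted (or candidate) simulation draw."""

    origins: tuple[str, ...]
    ts: tuple[float, ...]
    r: float
    statistic: float
    p_value: float
    significant: bool
    stage: int


@dataclass(frozen=True)
class SummaryDistribution:
    """The observed summary S_o: significant partial-Mantel statistics under
    calibrated-date resampling."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) == 0:
            raise ValueError("summary distribution must be a non-empty vector")
        object.__setattr__(self, "values", v.copy())

    @property
    def n(self) -> int:
        return len(self.values)

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.values, q))

    def window(self, pair: Sequence[float]) -> tuple[float, float]:
        lo, hi = pair
        return self.quantile(lo), self.quantile(hi)

    def mean(self) -> float:
        return float(self.values.mean())


def _density_sampler(densities: Mapping[str, CalDensity], labels: Sequence[str]):
    """Precompute per-site cumulative masses for fast date draws."""
    thetas = [densities[l].theta for l in labels]
    cums = [np.cumsum(densities[l].p) for l in labels]

    def sample_all(rng: np.random.Generator) -> np.ndarray:
        u = rng.random(len(labels))
        return np.array(
            [
                th[min(int(np.searchsorted(c, ui * c[-1])), len(th) - 1)]
                for th, c, ui in zip(thetas, cums, u)
            ]
        )

    def sample_site(i: int, rng: np.random.Generator) -> float:
        th, c = thetas[i], cums[i]
        idx = min(int(np.searchsorted(c, rng.random() * c[-1])), len(th) - 1)
        return float(th[idx])

    return sample_all, sample_site


def observed_summary(
    A: DistMatrix,
    B: DistMatrix,
    densities: Mapping[str, CalDensity],
    cfg: RunConfig,
    rng: np.random.Generator,
) -> SummaryDistribution:
    """Build S_o: draw one calendar date per site from its calibrated
    density, form the chronological matrix, run the partial Mantel test, and
    keep the statistic when significant, until ``n_summary`` values are
    collected (or the draw cap aborts with a no-signal diagnostic)."""
    engine = PartialMantelEngine(A, B, cfg.n_perm, cfg.alpha)
    sample_all, _ = _density_sampler(densities, engine.labels)
    cap = cfg.draw_cap_factor * cfg.n_summary
    values: list[float] = []
    draws = 0
    while len(values) < cfg.n_summary:
        if draws >= cap:
            raise AbcError(
                "observed summary: too few significant draws — "
                "the data carry no chronology-culture signal",
                accepted=len(values),
                draws=draws,
            )
        draws += 1
        res = engine.test_dates(sample_all(rng), rng)
        if res.significant:
            values.append(res.statistic)
    logger.info("observed summary built: n=%d from %d draws", len(values), draws)
    return SummaryDistribution(np.asarray(values))


def simulate_one(
    engine: PartialMantelEngine,
    B: DistMatrix,
    params: ExpansionParams,
    rng: np.random.Generator,
    stage: int = 0,
) -> SimRecord:
    """Simulate one candidate: expansion model -> modelled dates ->
    simulated chronological matrix -> partial Mantel statistic."""
    y = arrival_dates(params, B)
    res = engine.test_dates(y, rng)
    return SimRecord(
        origins=tuple(engine.labels[o] for o in params.origins),
        ts=params.ts,
        r=params.r,
        statistic=res.statistic,
        p_value=res.p_value,
        significant=res.significant,
        stage=stage,
    )


def _perturb_r(
    r: float, kernel: str, prior: tuple[float, float], rng: np.random.Generator
) -> float:
    if kernel == "strict":
        lo, hi = 0.9 * r, 1.1 * r
    elif kernel == "relaxed":
        lo, hi = r - 1.0, r + 1.0
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return float(np.clip(rng.uniform(lo, hi), prior[0], prior[1]))


def rejection_stage(
    engine: PartialMantelEngine,
    B: DistMatrix,
    densities: Mapping[str, CalDensity],
    s_o: SummaryDistribution,
    cfg: RunConfig,
    rng: np.random.Generator,
) -> list[SimRecord]:
    """Stage 1: plain rejection sampling from the priors.

    Origins are uniform over the actual sites (repeats allowed for two
    origins), start dates come from the origin's calibrated density, and
    r ~ U(prior).  A draw is accepted when significant and strictly inside
    the first quantile window of S_o.
    """
    n = engine.n
    lo, hi = s_o.window(cfg.windows[0])
    _, sample_site = _density_sampler(densities, engine.labels)
    cap = cfg.draw_cap_factor * cfg.n_particle
    accepted: list[SimRecord] = []
    draws = 0
    while len(accepted) < cfg.n_particle:
        if draws >= cap:
            raise AbcError("rejection stage draw cap reached",
                           accepted=len(accepted), draws=draws)
        draws += 1
        origins = tuple(int(i) for i in rng.integers(0, n, size=cfg.n_origins))
        ts = tuple(sample_site(o, rng) for o in origins)
        r = float(rng.uniform(*cfg.prior_r))
        rec = simulate_one(engine, B, ExpansionParams(origins, ts, r), rng, stage=1)
        if rec.significant and lo < rec.statistic < hi:
            accepted.append(rec)
    logger.info("rejection stage: %d accepted from %d draws", len(accepted), draws)
    return accepted


def smc_step(
    prev: list[SimRecord],
    window: Sequence[float],
    kernel: str,
    engine: PartialMantelEngine,
    B: DistMatrix,
    densities: Mapping[str, CalDensity],
    s_o: SummaryDistribution,
    cfg: RunConfig,
    rng: np.random.Generator,
    stage: int,
) -> list[SimRecord]:
    """One SMC stage: resample a record from the previous particle, perturb
    r with the transition kernel (clipped to the prior), keep the origins,
    redraw start dates from the calibrated densities, re-simulate, accept
    inside the tightened window."""
    if not prev:
        raise AbcError("previous particle is empty")
    lo, hi = s_o.window(window)
    label_to_idx = {l: i for i, l in enumerate(engine.labels)}
    _, sample_site = _density_sampler(densities, engine.labels)
    cap = cfg.draw_cap_factor * cfg.n_particle
    accepted: list[SimRecord] = []
    draws = 0
    while len(accepted) < cfg.n_particle:
        if draws >= cap:
            raise AbcError(f"SMC stage {stage} draw cap reached",
                           accepted=len(accepted), draws=draws)
        draws += 1
        src = prev[int(rng.integers(0, len(prev)))]
        origins = tuple(label_to_idx[o] for o in src.origins)
        r = _perturb_r(src.r, kernel, cfg.prior_r, rng)
        ts = tuple(sample_site(o, rng) for o in origins)
        rec = simulate_one(engine, B, ExpansionParams(origins, ts, r), rng, stage=stage)
        if rec.significant and lo < rec.statistic < hi:
            accepted.append(rec)
    logger.info("SMC stage %d: %d accepted from %d draws", stage, len(accepted), draws)
    return accepted


@dataclass(frozen=True)
class AbcResult:
    """Particles and provenance of one kernel's full run."""

    kernel: str
    particles: tuple
    s_o: SummaryDistribution
    log: dict = field(default_factory=dict)

    @property
    def final(self) -> list[SimRecord]:
        return list(self.particles[-1])

    def r_samples(self, stage: int = -1) -> np.ndarray:
        return np.asarray([rec.r for rec in self.particles[stage]])


def run_abc(
    A: DistMatrix,
    B: DistMatrix,
    densities: Mapping[str, CalDensity],
    cfg: RunConfig,
    rng: np.random.Generator,
    kernel: str | None = None,
    s_o: SummaryDistribution | None = None,
) -> AbcResult:
    """Full scheme for one kernel: build S_o (unless supplied), run the
    rejection stage and one SMC step per remaining window."""
    kernel = kernel or (cfg.kernels[0])
    if s_o is None:
        s_o = observed_summary(A, B, densities, cfg, rng)
    engine = PartialMantelEngine(A, B, cfg.n_perm, cfg.alpha)
    particles = [rejection_stage(engine, B, densities, s_o, cfg, rng)]
    for stage, window in enumerate(cfg.windows[1:], start=2):
        particles.append(
            smc_step(particles[-1], window, kernel, engine, B, densities,
                     s_o, cfg, rng, stage)
        )
    log = {
        "kernel": kernel,
        "n_stages": len(particles),
        "windows": [list(w) for w in cfg.windows],
        "window_bounds": [list(s_o.window(w)) for w in cfg.windows],
        "s_o_mean": s_o.mean(),
        "s_o_n": s_o.n,
    }
    return AbcResult(kernel, tuple(tuple(p) for p in particles), s_o, log)


def run_all(
    A: DistMatrix,
    B: DistMatrix,
    densities: Mapping[str, CalDensity],
    cfg: RunConfig,
    rng: np.random.Generator,
) -> dict[str, AbcResult]:
    """Run every configured kernel against a shared observed summary."""
    s_o = observed_summary(A, B, densities, cfg, rng)
    return {
        k: run_abc(A, B, densities, cfg, rng, kernel=k, s_o=s_o)
        for k in cfg.kernels
    }
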