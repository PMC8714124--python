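# culturewave

Origin-point and dispersal-route inference from cultural trait distances,
radiocarbon chronology and geography, for a spreading cultural/economic
package — the motivating case is the Neolithic arrival in the Iberian
Peninsula, traced through the stylistic morphometry of geometric microliths
(trapeze/triangle/segment arrowheads) at the earliest dated sites of four
fluvial basins.

The package is for archaeologists and quantitative researchers who want to
ask: *given how similar the artefact assemblages of dated sites are, and
how far apart the sites lie, which dispersal scenarios are consistent with
the chronology?*

## The method

Three symmetric distance matrices over the n study sites: cultural **A**
(between per-site trait-state frequency profiles), geographic **B** (km),
chronological **C** (|calendar-year differences|).  The summary statistic
is the partial Mantel correlation of culture with chronology, controlling
geography,

    r_AC·B = (r_AC − r_AB·r_CB) / √((1 − r_AB²)(1 − r_CB²)),

assessed by jointly permuting rows and columns of C.  Because each site's
calendar age is a calibrated *density*, not a number, the observed
statistic is itself a distribution S_o: one calendar year is resampled per
site per draw, and the significant statistics are collected (n = 1000 by
default).

Candidate dispersals follow a wave-of-advance model: an origin site o,
start date t drawn from o's calibrated density, and front speed
r ~ U(1, 5) km/yr give modelled arrival dates

    y_i = t − d(o, i)/r

(two origins: each site keeps the older candidate date).  A sequential ABC
scheme — one rejection stage accepting significant simulated statistics
inside (Q1, Q3) of S_o, then three resample-perturb stages with windows
tightening to (P40, P60) and a strict (±10%) or relaxed (±1 km/yr)
transition kernel on r — yields particles of accepted (origin, t, r)
draws.  Origin frequencies, size-corrected region/route aggregates and a
Gamma-fit highest-density interval for r summarise the posterior.

A first-class synthetic-data module generates site tables,
pseudo-radiocarbon measurements (inverted through the calibration curve
plus lab noise) and specimen trait tables in which trait divergence grows
with arrival-time difference — so the whole pipeline, from CSV to
posterior, is testable against a known ground truth without any download.

## Worked example

```python
import numpy as np
from culturewave import (
    RunConfig, Scenario, generate_dataset, calibrate, site_inclusion_filter,
    geographic_distance_matrix, run_abc, origin_posterior, aggregate_groups, r_hpd,
)
from culturewave.traits import cultural_pipeline

scn = Scenario(seed=6)                      # 13 sites, origin "Cen", r = 2 km/yr
sites, specimens, curve, truth = generate_dataset(scn)

densities = {s.site_id: calibrate(s.cra, s.cra_error, curve)
             for s in sites.df.itertuples()}
sites = site_inclusion_filter(sites, densities)

A, freq, removed = cultural_pipeline(specimens)   # Matrix A (cultural)
labels = [s for s in sites.site_ids if s in A.labels]
A, sites = A.reorder(labels), sites.subset(labels)
B = geographic_distance_matrix(sites)             # Matrix B (km)
densities = {k: densities[k] for k in labels}

cfg = RunConfig(seed=10006, n_summary=300, n_particle=300, n_perm=199, n_origins=2)
result = run_abc(A, B, densities, cfg, cfg.rng())

site_probs = origin_posterior(result.final)
region_probs = aggregate_groups(site_probs, sites.region_map())
route_probs = aggregate_groups(site_probs, sites.route_map())
hpd = r_hpd(result.r_samples(), 0.95)

print(f"observed summary: mean {result.s_o.mean():.3f} over {result.s_o.n} draws")
print(f"top origin sites: {site_probs.sort_values(ascending=False).head(3).round(3).to_dict()}")
print(f"region posterior: {region_probs.round(3).to_dict()}")
print(f"route posterior:  {route_probs.round(3).to_dict()}")
print(f"r 95% HPD: [{hpd.low:.2f}, {hpd.high:.2f}] km/yr (true r = {truth['true_r']})")
```

prints

```
observed summary: mean 0.345 over 300 draws
top origin sites: {'Cen': 0.403, 'Tor': 0.247, 'Bar': 0.128}
region posterior: {'ebro': 0.066, 'guadalquivir': 0.335, 'northeast': 0.172, 'xuquer': 0.427}
route posterior:  {'north_mediterranean': 0.49, 'pyrenees': 0.084, 'south': 0.426}
r 95% HPD: [0.37, 3.55] km/yr (true r = 2.0)
```

Reading the output: resampling calibrated dates gives significant
culture–chronology partial correlations averaging 0.345; the accepted
dispersal scenarios put the most origin mass on the true origin site
("Cen"), its basin ("xuquer") and its route ("north_mediterranean"); and
the Gamma-fit 95% highest-density interval for the front speed covers the
true 2 km/yr.  Site-level modal identification is not reliable in general
— the origin posterior should be read as a regional spread signal (see
`docs/methods.md` for why).

The same workflow is available from the shell:

```bash
culturewave synth --seed 6 --out data/        # synthetic dataset + truth.json
culturewave run --config cfg.yml --out out/   # accepted.csv + posterior.json
culturewave mantel A.csv C.csv --control B.csv
```

## Layout

| path | contents |
| --- | --- |
| `src/culturewave/io_config.py` | table/config I/O, site-inclusion filter |
| `src/culturewave/calibration.py` | radiocarbon calibration, date sampling, HDI |
| `src/culturewave/traits.py` | specimen pipeline → frequencies → Matrix A, clustering |
| `src/culturewave/spatial_stats.py` | distance matrices, Mantel / partial Mantel, Moran's I |
| `src/culturewave/expansion.py` | wave-of-advance arrival model |
| `src/culturewave/abc_smc.py` | observed summary, rejection + SMC stages |
| `src/culturewave/posterior.py` | origin/region/route posteriors, Gamma HPD |
| `src/culturewave/synthetic_data.py` | ground-truth scenario generator, recovery experiment |
| `docs/methods.md` | model, assumptions, parameters, limitations |
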