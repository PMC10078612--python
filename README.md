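# traitsync

Spatial synchrony of fitness-related traits in wild populations.

Long-term nest-box monitoring of hole-nesting passerines (blue tits, great
tits, pied flycatchers) produces decades of brood records — laying dates,
clutch sizes, fledgling numbers — for populations scattered across Europe.
A recurring question in population ecology is whether the year-to-year
fluctuations of such traits rise and fall *together* across populations
(spatial synchrony), and whether a spatially correlated environmental
driver such as spring temperature (a Moran effect) is responsible.
`traitsync` implements that analysis end to end: brood filtering and annual
aggregation, detrending and normalization, parametric correlogram
estimation by maximum likelihood, parametric-bootstrap uncertainty, and
climate-driver attribution by residualization.

## Model

Let ỹ<sub>it</sub> be the detrended, normalized annual average trait value
of population *i* in year *t*.  The populations available in year *t* are
modelled as

&nbsp;&nbsp;&nbsp;&nbsp;Ỹ<sub>t</sub> ~ MVN(0, Σ<sub>t</sub>),

where Σ<sub>t</sub> has unit diagonal and off-diagonal elements given by a
Gaussian correlogram in the distance d<sub>ij</sub> (km) between
populations:

&nbsp;&nbsp;&nbsp;&nbsp;ρ(d) = ρ<sub>∞</sub> + (ρ<sub>0</sub> − ρ<sub>∞</sub>) · exp(−d² / 2l²).

* **ρ<sub>0</sub>** — correlation as distance → 0 (1 − ρ<sub>0</sub> is a
  nugget of purely local variability);
* **ρ<sub>∞</sub>** — the distance-independent regional floor;
* **l** (km) — the SD of the Gaussian kernel: the characteristic distance
  over which fluctuations remain correlated.

Because site coverage varies among years, the total log-likelihood is the
sum of annual MVN log-densities over each year's available populations; it
is maximized numerically under 0 ≤ ρ<sub>∞</sub> ≤ ρ<sub>0</sub> ≤ 1 with a
multi-start quasi-Newton search.  Uncertainty comes from a parametric
bootstrap: panels are simulated from the fitted model on the observed
availability pattern and refitted; medians and 2.5/97.5 percentiles over
replicates are reported.  Climate attribution regresses each population's
annual averages on its own February–May climate means, normalizes the
residuals, refits the model, and reports the drop in the fitted correlogram.

## Worked example

Simulate a 31-site study with known synchrony and recover the parameters:

```python
import traitsync as ts

truth = ts.SynchronyParams(rho0=0.8, rho_inf=0.263, l=247.0)
study = ts.simulate_study(ts.SimulationScenario(n_sites=31, n_years=30, truth=truth, seed=7))

est, loglik = ts.fit_synchrony(study.latent, study.distances)
print(f"rho0={est.rho0:.3f} rho_inf={est.rho_inf:.3f} l={est.l:.0f} km")

fit = ts.parametric_bootstrap(est, study.latent.mask, study.distances, B=200, seed=1, loglik=loglik)
lo, hi = fit.ci95["rho0"]
print(f"median rho0={fit.median.rho0:.3f}  95% CI [{lo:.3f}, {hi:.3f}]")
```

Output:

```
rho0=0.819 rho_inf=0.281 l=226 km
median rho0=0.823  95% CI [0.761, 0.873]
```

The point estimate lands close to the simulation truth (0.800, 0.263,
247 km): local correlation ~0.82, a regional floor ~0.28 that persists at
any distance, and correlation decaying over a couple hundred kilometres.
The bootstrap interval for ρ<sub>0</sub> covers the truth.

The same analysis runs from the shell on CSV inputs (brood records, site
coordinates, daily or annual climate series):

```bash
traitsync simulate --seed 3 --out-dir sim/ --emit-broods
traitsync preprocess --broods sim/broods.csv --trait laying_date --min-years 5 --out panel.csv
traitsync bootstrap --panel panel.csv --sites sim/sites.csv -B 2000 --seed 1 --out fit.json
```

`traitsync run --config pipeline.yaml` executes every species × trait cell
(fit report JSON, correlogram CSV, pairwise-correlation CSV, figures, and a
climate comparison per configured climate variable) with a reproducible
run manifest:

```yaml
broods_path: data/broods.csv
sites_path: data/sites.csv
climate_paths:
  mean_temperature: data/temperature_daily.csv
traits: [laying_date, clutch_size, fledgling_number]
min_years: 9
bootstrap_reps: 2000
seed: 1
out_dir: results/
```

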