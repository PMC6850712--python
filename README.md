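# mbhv — model-based hypervolumes for grouped ecological data

Ecologists summarize the joint behaviour of several niche axes or ecosystem
properties as an *n*-dimensional hypervolume. When the variables are jointly
multivariate normal, a natural parametric hypervolume is the 95% confidence
ellipsoid of the fitted distribution. But ecological surveys are rarely
simple random samples: plots sit inside squares, sites inside catchments.
Pooling such nested data mixes between-group mean differences into the
estimated covariance and systematically inflates the hypervolume.

`mbhv` estimates **model-based hypervolumes** from a hierarchical
multivariate normal model with group random intercepts:

```
Y_i | group k ~ MVN(mu_k, Sigma)        mu_{j,k} ~ N(0, eps)
```

so that the shared within-group covariance `Sigma` — the object the
hypervolume is built from — is separated from group-level shifts. The prior
on the precision `Omega = Sigma^{-1}` is Wishart with rate equal to the
pooled raw-data covariance `Sigma_R` and `J + 1` degrees of freedom; the
intercept prior variance `eps` is fixed at 10,000 (weakly informative on
centered data). Both full conditionals are conjugate, so the posterior is
sampled by an exact two-block Gibbs scheme (no tuning, no external MCMC
runtime). Setting the number of groups to one gives the *empirical*
(structure-blind) model for comparison.

The package provides:

- `mbhv.data` — CSV loading/validation of grouped observations, centering,
  pooled covariance;
- `mbhv.inference` — Gibbs samplers for both models, Gelman–Rubin
  diagnostics, posterior summaries, ensemble archives;
- `mbhv.geometry` — ellipsoid semi-axes and volume, analytic and
  Monte-Carlo probability-of-inclusion tests, truncated-normal sampling
  inside a hypervolume, pairwise overlap and containment;
- `mbhv.simstudy` — a synthetic-data generator for nested designs and a
  simulation engine measuring the relative volume error
  `(estimated − true)/true` of both estimators;
- `mbhv.cli` — the `mbhv` command with `fit`, `compare`, `include`,
  `simulate` and `fixtures` subcommands.

## Worked example

Simulate a nested design (3 variables, 4 groups of 10, between-group
variance 2), fit both models, and compare volumes:

```python
import numpy as np
from mbhv import (SimulationScenario, simulate_grouped_dataset, center,
                  fit_structured, fit_empirical, FitConfig, posterior_mean_volume,
                  true_volume, gelman_rubin, hypervolume_from_ensemble, overlap)

scenario = SimulationScenario(n_dims=3, n_groups=4, n_per_group=10,
                              between_var=2.0, seed=1)
data = simulate_grouped_dataset(scenario, rep_index=0)
centered, transform = center(data)

config = FitConfig(n_iterations=10_000, n_burnin=5_000, n_chains=3, thin=10, seed=1)
model = fit_structured(centered, config, centering=transform)
empirical = fit_empirical(centered, config, centering=transform)

truth = true_volume(scenario)
print(f"true within-group volume : {truth:.2f}")
print(f"model-based volume       : {posterior_mean_volume(model):.2f}")
print(f"empirical volume         : {posterior_mean_volume(empirical):.2f}")
print(f"max R-hat (model fit)    : {gelman_rubin(model).max():.3f}")

ov = overlap(hypervolume_from_ensemble(model),
             hypervolume_from_ensemble(empirical), n_points=50_000, seed=1)
print(f"overlap model/empirical  : {ov.overlap:.3f} (MC se {ov.mc_se:.4f})")
```

Output:

```
true within-group volume : 64.71
model-based volume       : 53.47
empirical volume         : 91.41
max R-hat (model fit)    : 1.002
overlap model/empirical  : 0.923 (MC se 0.0008)
```

The generating within-group ellipsoid has volume 64.7. The model-based fit
lands near it (53.5 — a single 40-observation replicate), while the
structure-blind fit, which absorbs the group shifts into `Sigma`, inflates
the volume to 91.4. The R-hat near 1 confirms the three chains mixed.

The same workflow from the shell:

```sh
mbhv fixtures --out fx --seed 1
mbhv fit --data fx/grouped_j3_k4.csv --variables x1,x2,x3 --group group \
         --iterations 10000 --burnin 5000 --out fit-model
mbhv fit --data fx/grouped_j3_k4.csv --variables x1,x2,x3 --group group \
         --model empirical --iterations 10000 --burnin 5000 --out fit-emp
mbhv compare fit-model/ensemble.npz fit-emp/ensemble.npz --out compare.json
mbhv include fit-model/ensemble.npz fit-emp/ensemble.npz \
         --points new_plots.csv --out inclusion.csv
```

`include` reports, per new observation, its density `q` under the fitted
distribution, the probability of inclusion `p` (the posterior-summarized
fraction of the distribution less dense than the point), and an
inside/outside decision at the 0.05 threshold — with two archives it also
classifies each point as belonging to the first, the second, both or
neither hypervolume.

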