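# ftleforage

Tools for linking **submesoscale aggregative surface-current features** to the
habitat selection, feeding-site selection and feeding rates of a diving,
lunge-feeding marine predator observed with biologging tags.

The motivating system is blue whales foraging over the California Current:
multi-sensor tags record 1 Hz depth, individual lunge-feeding events and GPS
fixes, while coastal HF-radar networks measure surface currents hourly at
~6 km. Fronts and eddy boundaries that aggregate prey are ephemeral and
poorly captured by velocity snapshots, so the package characterises them with
the **backward-in-time finite-time Lyapunov exponent (FTLE)**: tracers seeded
at 10x the velocity-grid resolution are advected backward 48 h with an
adaptive Runge–Kutta–Fehlberg scheme, and the flow map Φ gives

    FTLE = ln λ_max((∇Φ)ᵀ ∇Φ) / (2|T|)        [day⁻¹]

whose ridges mark attracting transport structures. Dive-level foraging data
are then confronted with the FTLE fields at three levels:

- **habitat selection** (third order): whale-encountered FTLE vs 10:1
  time-matched background samples, compared with a one-sided *weighted*
  two-sample Kolmogorov–Smirnov test (individuals weighted equally per
  deployment; permutation p-value);
- **feeding-site selection** (fourth order): the probability that a dive is
  a feeding dive regressed on FTLE (binomial GEE with individuals as
  correlation groups and a serially decaying working correlation), tested
  against correlated-random-walk null tracks and 24/48/96/192 h time-shifted
  tracks;
- **feeding intensity**: a supervised four-state transition model
  (non-feeding, light, moderate, heavy feeding, split at the 25th/75th
  percentile ranks of each individual's dive-cycle feeding rates) with
  FTLE-dependent multinomial-logit transitions; its stationary probabilities
  π(x) and the weighted state feeding rates give the estimated overall
  feeding rate Σ π_state(x) · rate_state across the FTLE range.

A first-class synthetic-data module generates analytic benchmark flows with
known FTLE (uniform, saddle, double gyre), degraded gappy/noisy grids, and
simulated whale deployments whose feeding couples to FTLE through known
coefficients — so every stage of the pipeline is testable without any data
download. See `docs/methods.md` for the full model description and the
numerical policies.

## Worked example

Simulate four 4-day deployments over a synthetic FTLE series and run the
three analyses (about a minute on one CPU):

```python
import numpy as np, pandas as pd
from ftleforage.synthetic import (WhaleSimSpec, simulate_whale_deployments,
                                  gen_random_ftle_series)
from ftleforage.biologging import compute_feeding_rates, normalize_and_label_states
from ftleforage.habitat import compute_weights, sample_background, weighted_ks_test
from ftleforage.sites import fit_feeding_model
from ftleforage.feeding_hmm import (fit_transition_model,
                                    weighted_state_feeding_rates,
                                    estimate_feeding_rate_curve)

x = np.linspace(-123.5, -121.5, 41); y = np.linspace(35.0, 37.0, 41)
times = np.datetime64("2017-09-01T00") + np.arange(24 * 8).astype("timedelta64[h]")
series = gen_random_ftle_series(x, y, times, corr_time_hours=12.0, seed=42,
                                geographic=True)
deps = simulate_whale_deployments(WhaleSimSpec(n_individuals=4,
                                               duration_days=4.0, seed=7), series)
dives = pd.concat([normalize_and_label_states(compute_feeding_rates(d.dives))
                   for d in deps], ignore_index=True)

fit = fit_feeding_model(dives)                      # GEE logit: feeding ~ FTLE
model = fit_transition_model(dives)                 # 4-state transition model
```

Output of the full script (tests/ and `scripts/acceptance.py` run the same
computations):

```
4 deployments, 1770 dives, 45% feeding
habitat selection: weighted K-S D = 0.011, p = 0.898 (no location selection encoded by the generator)
feeding model: logit slope on FTLE = 1.04 +/- 0.27 (p = 1.4e-04)
state feeding rates (light, moderate, heavy): 11.0, 30.0, 63.7 lunges h^-1
estimated overall feeding rate at the 5th/50th/95th pct of encountered FTLE (-0.54/0.13/0.88 day^-1): 8.8/14.3/25.7 lunges h^-1 (+191% from 5th to 95th)
```

Reading the numbers: the default generator couples feeding *intensity* to
FTLE but places the simulated track independently of it, so the
use-availability test correctly reports no habitat selection (D ≈ 0, large
p) while the feeding-probability slope is strongly positive and the
estimated overall feeding rate rises across the encountered-FTLE range —
feeding intensity increasing with feature strength, as encoded.

## Command line

```bash
ftleforage synth field --config flow.yaml --seed 1 --out fields/
ftleforage ftle --field fields/double_gyre.nc --horizon -48 --refine 10 --out ftle.nc
ftleforage dives --depth depth.csv --gps gps.csv --lunges lunges.csv --ftle ftle.nc --out dives.csv
ftleforage select regional --dives dives.csv --ftle ftle.nc --ratio 10 --seed 1 --out ks.csv
ftleforage select sites --dives dives.csv --ftle ftle.nc --nulls crw,shift --seed 1 --out fits.csv
ftleforage hmm --dives dives.csv --states 4 --out curve.csv
```

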