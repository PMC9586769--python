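# hawkespd

Pharmacodynamic drug-effect modelling on monitored vital signs with a
Hawkes-style self-exciting intensity, Haar MODWT feature extraction, and
Granger-causality target selection.

## The problem

In intensive care, a drug given at discrete times (e.g. repeated heparin
doses) leaves a delayed, cumulative imprint on continuously monitored
variables such as heart rate.  Each administration takes effect after a lag,
rises to a peak, decays slowly, and overlaps with the effects of earlier
doses.  `hawkespd` models this directly: it treats the administrations as a
marked point process and the monitored variable as the realization of a
self-exciting intensity

```
lambda(t) = mu(t) + sum_{t_i < t} gamma(t - t_i, d_i)
mu(t)     = a0 + b0 sin(alpha0 t + beta0)
gamma(u, d) = 1 / (a1 + b1 e^{-kappa1 (m1 + d) a2})
              * u^{kappa2 - 1} e^{-b2 u} / (b2^{kappa2} Gamma(kappa2))
```

The sinusoid `mu` captures the slow physiological baseline; the kernel
`gamma` multiplies a saturating dose sigmoid by a Gamma-shaped lag profile
(zero at lag 0, peak at `(kappa2 - 1)/b2` minutes, exponential decay).  The
kernel is also available as the proper unit-mass Gamma density
(`normalized=True`), the convention used throughout the simulation-study
helpers — see `docs/methods.md` for why.

Because raw vital signs mix measurement noise, disease trend and drug
response, the model is not fit to the raw series.  A Haar maximal-overlap
discrete wavelet transform (MODWT) decomposes the series into full-length
detail (`d1..dJ`) and scale (`s1..sJ`) coefficient series; a Granger
F-test of the lagged dose series against every component picks the one the
drug most significantly predicts; and the 11-parameter vector
`theta = (a0, b0, alpha0, beta0, a1, b1, kappa1, m1, a2, kappa2, b2)` is
estimated on that component by bounded multi-start quasi-Newton least
squares, reported with `R^2 = (SST - SSE)/SST` and the Pearson correlation.

Intended users: biostatisticians and clinical-data researchers who want an
interpretable dose-response trend model for regularly sampled monitoring
data with event-time drug records.

## Worked example

```python
import numpy as np
from hawkespd import (make_icu_like_fixture, haar_modwt, dose_mark_series,
                      select_target_variable, fit, FitConfig)

# a synthetic data set shaped like the motivating ICU extract:
# 812 one-minute heart-rate-scale samples, 63 doses of 25 units
series, schedule = make_icu_like_fixture(seed=7)

W = haar_modwt(series, J=4)                       # d1..d4, s1..s4
marks = dose_mark_series(schedule, series)        # doses on the sampling grid
target, label, table = select_target_variable(W, marks, m=4)
print("selected component:", label)

result = fit(target, schedule, FitConfig(seed=7))
print(f"R^2 = {result.r_squared:.3f}")
print(f"Pearson corr = {result.pearson_corr:.3f} (p = {result.pearson_p:.2g})")
print("theta_hat =", np.round(result.params.to_vector(), 3))
```

Output:

```
selected component: s4
R^2 = 0.716
Pearson corr = 0.846 (p = 1.4e-223)
theta_hat = [70.075  0.638  1.     0.81  25.017  5.005  0.505 -1.    5.005 12.106  0.349]
```

The level-4 smooth carries the drug-driven trend, so it wins the Granger
selection; the fitted baseline level (70.1) and angular frequency (1.00
rad/min) recover the generating truth, while the kernel parameters are only
weakly identified (several trade off against each other without changing
the fitted curve — see the methods note).  `R^2` is computed against the
noisy component; the Pearson correlation of 0.85 says the fitted intensity
tracks most of the component's rises and drops.

The same pipeline is available from the shell:

```sh
hawkespd simulate --seed 7 --out sim/          # series.csv, events.csv, truth.json
hawkespd decompose --series sim/series.csv     # W matrix CSV
hawkespd granger --series sim/series.csv --events sim/events.csv
hawkespd fit --series sim/series.csv --events sim/events.csv
hawkespd sweep --kind noise --out noise.csv    # best-R^2 vs noise variance
hawkespd pipeline --simulate --seed 7 --out out/   # everything, plus report.json
```

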