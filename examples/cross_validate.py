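"""Compare estimation approaches by leave-one-out cross-validation.

Each site is removed in turn and predicted from the rest; bias, RMSPE and
95%-interval coverage are computed on the log scale.  Compares the Bayesian
spatial fit, plug-in REML, non-spatial OLS and the adjusted dispersion-model
baseline.  Takes a couple of minutes (60 MCMC refits).
"""

import airfusion as af

cfg = af.SyntheticConfig(extent_m=(0.0, 10_000.0, 0.0, 10_000.0),
                         n_tubes=52, n_monitors=8, n_colocated=4, seed=3)
sites, _ = af.generate_dataset(cfg)
spec = af.CovariateSpec(include_source=True)

rows = []
for method in ("mcmc", "reml", "ols"):
    rows.append(af.loocv(sites, spec, fit_method=method, seed=11))
rows.append(af.pcm_baseline(sites))

print(f"{'model':>14s} {'bias':>8s} {'rmspe':>8s} {'coverage%':>10s}")
for s in rows:
    print(f"{s.model:>14s} {s.bias:8.4f} {s.rmspe:8.4f} {s.coverage_pct:10.1f}")

print("\nThe spatial fits beat the non-spatial ones mainly through the")
print("co-located and near-neighbour sites; Bayesian intervals are a bit")
print("wider (closer to nominal 95%) than plug-in REML because they carry")
print("the parameter uncertainty into prediction.")
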