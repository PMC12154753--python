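"""Centile curves and worm-plot data for model inspection.

Reference charts display centiles of the healthy distribution across
age at a fixed height; the 5th centile is the LLN curve. Worm plots are
per-age-bin detrended QQ plots of quantile residuals — a well-specified
model leaves every worm flat and centered on zero. Both operations emit
plot-ready tables rather than figures, so any plotting stack can render
them.
"""

import numpy as np

from spirolms import (
    CohortSpec,
    ModelSpec,
    TermSpec,
    centile_curves,
    fit_gamlss,
    generate_cohort,
    load_ise,
    quantile_residuals,
    worm_plot_data,
)

curves = centile_curves(
    load_ise("male"), "fvc", centiles=(0.05, 0.5, 0.95),
    age_grid=np.arange(20, 71, 10), height_policy="median",
)
print("male FVC centiles at height 174 cm (L):")
print(curves.round(2).to_string(index=False))

cohort = generate_cohort(CohortSpec(n=2001, female_fraction=2000 / 2001, seed=31))
cohort = cohort[cohort["sex"] == "female"]
fit = fit_gamlss(
    cohort,
    ModelSpec(family="BCCG", index="fvc",
              mu=TermSpec(("intercept", "log_height", "log_age")),
              sigma=TermSpec(("intercept",)), nu=TermSpec(("intercept",))),
)
resid = quantile_residuals(fit, cohort)
wp = worm_plot_data(resid, cohort["age_years"].to_numpy(), n_bins=4)
print("\nworm centering per age bin (should be ~0 for a good fit):")
print(
    wp.groupby("bin")
    .agg(age_lo=("age_lo", "first"), age_hi=("age_hi", "first"),
         mean_deviation=("deviation", "mean"))
    .round(3)
    .to_string()
)
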