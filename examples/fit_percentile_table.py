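"""Recovering skew-normal parameters from a percentile summary table.

Health agencies publish covariate distributions as percentile tables
rather than microdata. This script builds a synthetic 9-point table from
known parameters (location 25, scale 6, shape 5 — a plausible BMI-like
covariate), fits the skew-normal by grouped maximum likelihood, and
compares against the nested normal model.
"""

from dichoteff import SNParams, compare_to_normal, percentiles_from_params

truth = SNParams(location=25.0, scale=6.0, shape=5.0)
table = percentiles_from_params(
    truth, [0.01, 0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95, 0.99], label="synthetic BMI"
)
print("input table (percentile -> value):")
for p, v in zip(table.percentiles, table.values):
    print(f"  {p:5.2f} -> {v:7.3f}")

fit, verdict = compare_to_normal(table)
print(
    f"\nfitted SN:  location={fit.params.location:.3f}  "
    f"scale={fit.params.scale:.3f}  shape={fit.params.shape:.3f}"
)
print(f"true SN:    location={truth.location:.3f}  scale={truth.scale:.3f}  shape={truth.shape:.3f}")
print(f"max |fitted CDF - percentile|: {fit.max_cdf_dev:.2e} ({verdict['sn_fit_quality']})")
print(
    f"normal submodel max CDF deviation: {verdict['normal_max_cdf_dev']:.3f} "
    f"({verdict['normal_fit_quality']}); preferred model: {verdict['preferred']}"
)
print(
    "\nThe skew-normal reproduces the table essentially exactly, while the "
    "best normal fit misses the tabulated percentiles by several points of "
    "probability — the signature of genuinely skewed data."
)
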