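"""Monte-Carlo corroboration of the closed-form efficiency.

Simulates trials at the reference design (100 per arm, treatment effect
15, covariate slope 20, residual SD 30), fits the full / restricted /
partially-restricted OLS models to each replicate, and estimates D from
the regression-slope estimator. The analytic value should fall inside
the 95% CI for most grid cells.
"""

from dichoteff import SNParams, TrialDesign, simulation_study

design = TrialDesign(n_total=200, gamma=15.0, beta=20.0, sigma_eps=30.0)
study = simulation_study(
    design,
    shapes=[2.0, 10.0],
    tau_grid=[0.3, 0.5, 0.7],
    n_reps=200,
    seed=11,
)

cols = ["shape", "tau", "D_analytic", "D_hat", "ci_low", "ci_high", "covered"]
print(study[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))

print(
    f"\n{study['covered'].sum()} of {len(study)} confidence intervals cover "
    "the analytic D. Each row compares the closed-form efficiency with the "
    "slope of the partial precision gain regressed on the full precision "
    "gain across 200 simulated trials."
)
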