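"""Full gradient analysis on a synthetic environmental-filtering study.

Simulates a 24-species pool sampled at five sites (0-3500 m from an
effluent source, 3 dates x 3 seasons) with environmental filtering acting
on the functional axis near the source, then runs the complete inference:
alpha sweep, per-site mean effect sizes with bootstrap CIs, and Rao's
quadratic entropy at the optimal alpha.
"""

from fpdiv import PipelineConfig, ScenarioSpec, run_pipeline, simulate_bundle

bundle = simulate_bundle(ScenarioSpec(scenario="filtering", seed=42))
config = PipelineConfig(seed=42, n_tree_boot=200, n_mantel=999)
result = run_pipeline(
    bundle["traits"], bundle["alignment"], bundle["communities"], config
)

print(f"Mantel r (FDist vs PDist) = {result.mantel.r:.4f}, p = {result.mantel.p:.4f}")
print("\noptimal blend weight per season (argmax adjusted R^2 of ES ~ distance):")
for season, alpha in result.sweep.optimal_alpha.items():
    best = result.sweep.scan.query("season == @season")["adj_r2"].max()
    print(f"  {season:7s} alpha* = {alpha:5.3f}  (adj R^2 = {best:.3f})")

print("\nper-site mean effect size with 95% bootstrap CI:")
print(result.site_es.to_string(index=False, float_format=lambda v: f"{v:7.3f}"))

rao = result.rao.groupby("site", sort=True)["rao_q"].mean()
print("\nmean Rao's quadratic entropy per site:")
print(rao.to_string(float_format=lambda v: f"{v:.3f}"))
print(
    "\nNegative mean ES with CI below zero at the near-source sites is the"
    "\nsignature of environmental filtering; diversity (Rao's Q) is"
    "\ncorrespondingly depressed near the source."
)
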