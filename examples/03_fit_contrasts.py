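"""The full pipeline on the bundled fixture: posteriors and contrasts.

Runs prior tuning -> per-cohort intercept-only binomial-logit posteriors
(MCMC: 4 chains x 2000 iterations, 4000 kept draws, split-R-hat gated)
-> posterior contrasts, then prints the published-style proportions table
and the headline rows.  With the quadrature engine the same run is fully
deterministic; swap engine="quadrature" to see it.
"""

from rule48 import paper_run_config, render_table, run_pipeline

bundle = run_pipeline(paper_run_config(seed=20231122))

worst_rhat = max(f.convergence.rhat for f in bundle.fits if f.convergence)
print(f"models fitted: {len(bundle.fits)}; worst split-R-hat: {worst_rhat:.4f}\n")

text, _ = render_table(bundle, "proportions")
print(text)

by = {(c.variable, c.scale): c for c in bundle.contrasts}
print("\nheadlines:")
for variable, scale, unit in (
    ("lateral hit to head", "pp", "pp"),
    ("body checks to head", "pp", "pp"),
    ("lateral hit to head", "per_100_games", "/100 games"),
    ("overall", "per_100_games", "/100 games"),
):
    c = by[(variable, scale)]
    direction = c.pm_negative if c.mean_diff < 0 else c.pm_positive
    print(
        f"  {variable:22s} {c.mean_diff:+6.1f} {unit:10s} "
        f"90% CrI ({c.cri90[0]:+.1f}, {c.cri90[1]:+.1f})  "
        f"PM(direction)={100 * direction:.1f}%"
    )

# Reading the headlines: lateral hits to the head fell by ~19 pp of the
# event share (and ~0.6/100 games) after the rule change, with essentially
# all posterior mass on a reduction, while overall concussion incidence
# *rose* by ~2/100 games — consistent with better detection, not safety.
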