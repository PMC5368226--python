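"""Simulate graded rejection behaviour and recover the generating model.

Simulates the 2 (order) x 2 (violation mode) x 4 (item type) design under
the feature-additive logistic response model, summarizes rejection rates
per cell, runs the analysis battery, and checks that the trial-level
logistic regression recovers the generating coefficients.
"""

from aglearn import behavior, stats

spec = behavior.ResponseModelSpec()          # published coefficient defaults
design = behavior.ExperimentDesign(participants_per_cell=200)
trials = behavior.simulate_trials(spec, design, seed=42)
print(f"simulated {len(trials)} trials "
      f"({design.participants_per_cell} participants/cell x 36 trials)")

rates = behavior.summarize_rates(trials)
cell = rates.query("order == 'di_repetition' and violation_mode == 'presence'")
print("\nrejection rates, /di/-first order, presence violations:")
print(cell[["item_class", "mean_rejection", "se_between"]].to_string(index=False))
# The graded pattern: grammatical items are rarely rejected, single
# violations at intermediate rates, double violations most often - unlike
# the all-or-none pattern a conjunction-rule learner would produce.

pm = behavior.participant_means(trials)
g = pm.query("order=='di_repetition' and violation_mode=='presence' "
             "and item_class=='grammatical'")["rejected"]
res = stats.one_sample_t_vs_chance(g)
print(f"\ngrammatical vs chance (50%): t({res.df:.0f}) = {res.statistic:.2f}, "
      f"p_bonf = {res.p_adjusted:.2g}, d = {res.effect_size:.2f}, "
      f"{res.direction} chance")

print("\nlogistic recovery (generating -> estimate +- SE):")
generating = dict(zip(behavior.PREDICTORS, spec.coefficients()))
for c in stats.fit_rejection_logistic(trials):
    print(f"  {c.name:42s} {generating[c.name]:+.2f} -> "
          f"{c.estimate:+.2f} +- {c.se:.2f}")
# With ~29k trials every estimate lands close to the coefficient that
# generated the data, validating the analysis pipeline end to end.
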