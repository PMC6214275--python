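"""Full reduced-scale experiment: build -> simulate -> reconstruct -> census
-> null models -> aggregated Z-scores.

Three trials of 300 s trains, transfer entropy at kappa = 0.2 with 20 null
randomisations per trial (about 4-5 minutes on one CPU). Prints the
aggregated dyadic transformation Z-scores whose sign pattern is the
analysis's headline result: preservation transformations overrepresented,
conversions underrepresented, direction reversal (2->2*) and recurrence
gain (2->3) near random.
"""

import spikeplex as sp
from spikeplex.pipeline import run_trial, trial_seeds

config = sp.reduced_profile(seed=1, kappas=(0.2,))
config.methods = ("te",)

trials = []
for ts in trial_seeds(config):
    print(f"running trial with seed {ts} ...")
    trials.append(run_trial(config, ts))

bundle = sp.aggregate(trials, config)
stats = bundle.stats[("te", 0.2)]
print("\naggregated dyadic Z-scores (mean +/- sd over 3 trials):")
for name, mean, sd in zip(
    sp.DYAD_TRANSFORMATIONS, stats.dyadic_z_mean, stats.dyadic_z_sd
):
    print(f"  {name:6s} {mean:8.2f} +/- {sd:.2f}")
print("\npositive preservation rows (1->1, 2->2, 3->3) and negative conversion "
      "rows mean the functional layer follows the synaptic structure far "
      "beyond chance; 2->2* and 2->3 stay near random.")
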