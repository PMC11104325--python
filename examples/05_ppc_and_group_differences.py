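"""Posterior predictive checks and posterior group differences.

Fits the dual-learning-rate power model to both simulated groups, overlays
observed and model-predicted accuracy/RT trial bins, and prints the
posterior group-difference table (control minus gambling) with 95% HDIs,
P(diff > 0) and directed Bayes factors.
"""

import pandas as pd

from rlddm import diagnostics, inference, models, task
from rlddm.inference import MCMCConfig

spec = models.get_model("RLDDM8")
schedule = task.generate_task_schedule(seed=0)
fits, datasets = {}, {}
for group in ("control", "gambling"):
    data, _ = task.simulate_group(task.group_presets(group), 10, spec, schedule,
                                  seed=17, group=group)
    datasets[group] = data
    fits[group] = inference.fit_hierarchical(
        spec, models.preprocess_rts(data),
        mcmc=MCMCConfig.short(burn=1200, keep=600), seed=19)

ppc = diagnostics.posterior_predictive_bins(
    fits["control"], spec, datasets["control"], bin_width=10, n_draws=200, seed=1)
print("control group, observed vs predicted accuracy per 10-trial bin:")
print(ppc.table[["bin", "obs_acc", "pred_acc_mean", "pred_acc_lo", "pred_acc_hi"]].round(3).to_string(index=False))

diff = diagnostics.group_difference_summary(fits["control"], fits["gambling"])
cols = ["parameter", "m_diff", "hdi95_lo", "hdi95_hi", "p_diff_gt0", "dbf"]
with pd.option_context("display.width", 120):
    print("\ngroup differences (control - gambling):")
    print(diff[cols].round(3).to_string(index=False))
print("\nA positive t0 difference means the gambling preset responds with shorter")
print("non-decision times. At this reduced scale (10 subjects, short chains) the")
print("drift-scaling contrast is noisy — its HDI is wide — which is why the full")
print("workflow relies on recovery checks before interpreting group differences.")
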