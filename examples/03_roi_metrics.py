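"""Full single-run analysis: ROI time course, cycle average, recovery fit.

Prints the two headline metrics — maximal change (peak of the cycle-averaged
percent-change R2* time course) and recovery change (peak minus the fitted
end-of-recovery value) — next to the injected ground truth.
"""

import numpy as np

from musclebold import DEFAULT_TRUTH
from musclebold.pipeline import run_synthetic

res = run_synthetic("fast", seed=3, snr=50.0, muscles=("soleus", "gastrocnemius"))

cols = ["muscle", "maximal_change", "recovery_change", "recovery_change_normalized",
        "tau", "converged"]
print(res.metrics[cols].round(3).to_string(index=False))

truth = DEFAULT_TRUTH["soleus"]
expected_rec = truth.deficit * (1 - np.exp(-120.0 / truth.tau))
print(f"\ninjected soleus truth: A = {truth.amplitude}% of baseline R2*, "
      f"tau = {truth.tau} s,")
print(f"implied recovery change D(1 - e^(-120/tau)) = {expected_rec:.3f}%")
print("\nMaximal change tracks oxygen utilisation during the 90 s contraction block;")
print("recovery change tracks replenishment over the 120 s rest that follows.")
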