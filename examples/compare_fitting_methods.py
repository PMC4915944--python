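"""Fast PSE-variance fit vs trial-level maximum likelihood on the same data.

The fast method uses ~1/N of the data (one PSE + one variance per condition
instead of every trial) and runs in seconds; the trial-level method maximizes
the Bernoulli likelihood of all ~10,000 responses.  Both should recover
priors with the same shape: density decreasing with speed, in the same rank
order at the knot speeds.
"""

import time

import numpy as np

import speedprior as sp
from speedprior.fitting import FitConfig, fit_full_likelihood, fit_model, reconstruct_prior

observer = sp.ObserverSpec()
dataset = sp.generate_dataset(observer, sp.build_design(), master_seed=11)
trials = sp.experiment.trials_to_frame(dataset)
print(f"dataset: {len(dataset.staircases)} staircases, {len(trials)} trials")

t0 = time.time()
fast = fit_model(sp.pse_summary(dataset), FitConfig())
t_fast = time.time() - t0

t0 = time.time()
full = fit_full_likelihood(trials, FitConfig())
t_full = time.time() - t0

knots = np.array([1.0, 4.0, 8.0, 12.0])
print(f"\nfast PSE-variance fit ({t_fast:.1f} s):   prior density {np.round(reconstruct_prior(fast.observer.prior, knots), 4)}")
print(f"trial-level ML fit    ({t_full:.1f} s):   prior density {np.round(reconstruct_prior(full.observer.prior, knots), 4)}")
print("\nSame rank order of density at 1, 4, 8, 12 deg/s -> the cheap summary-")
print("statistics method preserves the structure of the extracted prior.")
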