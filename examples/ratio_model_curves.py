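"""Temporal-filter ratio model: perceived speed vs contrast and speed.

Evaluates the band-pass / low-pass filter-ratio front end at the three
experimental contrasts over a range of speeds (2 cycles/deg grating), with
the fitted filter constants and with the original literature constants.
With the fitted constants the output tracks true speed closely except at low
speeds, where raising contrast *lowers* the output -- the opposite of the
Thompson effect, which is why the front end helps the combined model at low
speeds only.
"""

import numpy as np

import speedprior as sp

speeds = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 12.0])
contrasts = (0.03, 0.15, 0.95)

for label, params in [
    ("fitted constants", sp.RatioParams()),
    ("literature constants", sp.RatioParams.literature()),
]:
    print(f"\n{label}: tau1={params.tau1}, tau2={params.tau2}, k={params.k}")
    header = "speed(deg/s)" + "".join(f"   c={c:<5g}" for c in contrasts)
    print(header)
    for v in speeds:
        outs = [sp.ratio_output(params, v, c, sf=2.0) for c in contrasts]
        print(f"{v:12.1f}" + "".join(f"   {o:7.3f}" for o in outs))

print(
    "\nWith the fitted constants, columns agree at high speeds (near-veridical"
    "\noutput, ~10% above true speed) and diverge at low speeds, where the"
    "\n95%-contrast output drops below the 3%-contrast output."
)
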