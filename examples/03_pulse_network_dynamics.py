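"""Watch the intersecting cortical model fire, neuron by neuron.

A single isolated neuron driven by stimulus S = 0.5 with decay factors
f = 0.9, g = 0.8, threshold amplitude h = -1 and initial threshold 5:
its activation F climbs geometrically while the threshold E decays, the
first pulse fires at iteration 6, and the negative h keeps it firing
from then on.  On a full frame the same race happens per pixel, ordered
by stimulus, which is what turns the network into a segmenter.
"""

import numpy as np

from spermseg import ICMParams, run_icm

params = ICMParams(f=0.9, g=0.8, h=-1.0, n_iterations=10)
stimulus = np.array([[0.5]])
_, history = run_icm(stimulus, params)

print("iter  pulse")
for k, pulse in enumerate(history, start=1):
    print(f"{k:4d}  {int(pulse[0, 0])}")

first = next(k for k, p in enumerate(history, start=1) if p[0, 0])
print(f"\nfirst firing at iteration {first}; fires at every iteration after "
      "(h < 0 keeps the threshold below the activation).")
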