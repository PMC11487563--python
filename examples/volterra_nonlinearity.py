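"""Quantify nonlinearity as a function of stimulus spacing with Volterra kernels.

The first-order kernel is the impulse response; the second-order kernel is
the change in the response caused by a preceding stimulus (saturation /
refractoriness at short SOAs).  The variance fraction carried by the
second-order kernel measures how far a design strays from linearity.
"""

import numpy as np

from boldhrf import design, hdm

p = hdm.HDMParams(beta=0.6)
lags = np.arange(0.0, 16.1, 0.75)
k1 = hdm.volterra_kernel1(p, lags)
K2 = hdm.volterra_kernel2(p, lags)
print(f"first-order kernel peak: {k1.max():.3f}% at "
      f"{lags[np.argmax(k1)]:.1f} s")
print(f"second-order kernel extreme: {K2.min():.3f}% "
      f"(max |K2|/|K1| = {np.abs(K2).max() / np.abs(k1).max():.2f})")

rng = np.random.default_rng(1)
seq = design.generate_msequence(8)
msequence_onsets = design.build_event_timing(seq, rng=rng).onsets
for label, onsets in [
    ("fixed 2.25 s SOA ", np.arange(0.0, 120.0, 2.25)),
    ("m-sequence design", msequence_onsets),
    ("fixed 20.25 s SOA", np.arange(0.0, 600.0, 20.25)),
]:
    frac = hdm.second_order_variance_fraction(onsets, p)
    print(f"{label}: second-order variance fraction {frac:.1%}")
# Dense fixed-SOA designs are the most nonlinear; long SOAs approach the
# linear-convolution regime the basis-set models assume.
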