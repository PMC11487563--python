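"""Fit the four-parameter amplitude/latency model to individual HRF curves.

The template is the first singular vector of a participants-by-bins FIR
matrix; each individual's curve is matched by warping it in time
(offset t0, scaling t1) and scaling it in amplitude (offset a0, gain a1).
"""

import numpy as np

from boldhrf import basis, nlf

rng = np.random.default_rng(3)
canon = basis.two_gamma_hrf(basis.TwoGammaParams(), step_s=1.0)

# a toy cohort: delayed and damped variants of a common shape, plus noise
curves = []
truth = []
for _ in range(30):
    t0 = rng.uniform(-1.0, 1.5)
    t1 = rng.uniform(0.8, 1.3)
    a1 = rng.uniform(0.5, 2.0)
    template0 = nlf.HRFTemplate(curve=canon, step_s=1.0)
    y = a1 * nlf.warp_template(template0, t0, t1)
    curves.append(y + 0.03 * rng.standard_normal(len(y)))
    truth.append((t0, t1, a1))

template = nlf.make_template(np.stack(curves), step_s=1.0)
print(f"group template (SVD of the cohort) peaks at "
      f"{template.times[np.argmax(template.curve)]:.0f} s")
corrs = [nlf.fit_nlf(template, y)[1] for y in curves]
print(f"template fit correlations: median {np.median(corrs):.3f}, "
      f"min {np.min(corrs):.3f}")

# parameter recovery is only meaningful against the generating template
known = nlf.HRFTemplate(curve=canon, step_s=1.0)
print("fits against the generating shape (a1, t0, t1) vs truth:")
errs = []
for y, (t0, t1, a1) in zip(curves, truth):
    p, corr = nlf.fit_nlf(known, y)
    errs.append((abs(p.t0 - t0), abs(p.t1 - t1)))
for y, (t0, t1, a1) in list(zip(curves, truth))[:3]:
    p, corr = nlf.fit_nlf(known, y)
    print(f"  fit ({p.a1:4.2f}, {p.t0:+5.2f}, {p.t1:4.2f})  "
          f"truth ({a1:4.2f}, {t0:+5.2f}, {t1:4.2f})  corr {corr:.3f}")
errs = np.array(errs)
print(f"median |latency offset error| {np.median(errs[:, 0]):.2f} s, "
      f"median |latency scaling error| {np.median(errs[:, 1]):.3f}")
# t0 captures a rigid delay of the whole response; t1 a proportional
# stretch — the two ways a response can be 'late'.
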