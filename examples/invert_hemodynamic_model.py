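"""Bayesian inversion of one participant's ROI timeseries.

Variational Laplace estimates the neural efficacy and the two vascular
rates (vasoactive-signal decay and blood transit) from a single run, with
Gaussian priors on a log-deviation scale around decay 0.64 Hz and transit
1.02 Hz.
"""

import numpy as np

from boldhrf import design, glm, vl

rng = np.random.default_rng(8)
seq = design.generate_msequence(8)
events = design.build_event_timing(seq, rng=rng)
model = vl.HDMModel(onsets=events.onsets, tr_s=1.97, n_scans=261)

# ground truth: a middle-aged participant with faster decay, slower transit
theta_true = np.array([0.7, 0.30, -0.20])
truth = model.params_from_theta(theta_true)
print(f"truth:  efficacy {truth.beta:.2f}, decay {truth.kappa:.3f} Hz, "
      f"transit {truth.transit_rate:.3f} Hz")

dct = glm.dct_highpass_set(261, 1.97)
y = model.predict(theta_true) + dct[:, 1] * 2.0 + 0.3 * rng.standard_normal(261)
post = vl.vl_fit(y, model, nuisance=dct)

rates = vl.posterior_rates_in_hz(post)
sd = np.sqrt(np.diag(post.covariance))
print(f"fitted: efficacy {rates['beta']:.2f} (sd {sd[0]:.2f}), "
      f"decay {rates['kappa']:.3f} Hz, transit {rates['transit_rate']:.3f} Hz")
print(f"free energy {post.free_energy:.1f} after "
      f"{len(post.free_energy_trace)} accepted steps "
      f"(converged: {post.converged})")
# The posterior covariance (not just the means) is what the group-level
# empirical-Bayes model consumes.
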