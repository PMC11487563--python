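"""Build the rapid event-related design: m-sequence, jittered onsets, trial types.

The stimulus schedule is one period of a degree-8 maximal-length shift-register
sequence: 255 slots at a base SOA of 2 s, half of them null, giving realised
SOAs from 2 s upward that sample the hemodynamic response efficiently.  Each
stimulus slot gets a uniform 0.1-0.3 s jitter, and 8 of the 128 trials become
unimodal catch trials.
"""

import numpy as np

from boldhrf import design

seq = design.generate_msequence(degree=8)
ac = design.msequence_autocorrelation(seq)
print(f"sequence period: {len(seq)} elements, {seq.sum()} stimuli")
print(f"off-peak autocorrelation: min {ac[1:].min()}, max {ac[1:].max()}")

rng = np.random.default_rng(0)
events = design.build_event_timing(seq, base_soa_s=2.0, jitter_low_s=0.1,
                                   jitter_high_s=0.3, rng=rng)
events = design.assign_trial_types(events, rng=rng)
soas = np.diff(events.onsets)
types, counts = np.unique(events.trial_types.astype(str), return_counts=True)
print(f"{len(events)} events over {events.onsets[-1]:.1f} s")
print(f"SOA range: {soas.min():.2f} to {soas.max():.2f} s")
print("trial types:", {str(t): int(c) for t, c in zip(types, counts)})
# The -1 off-peak autocorrelation means every SOA occurs as dictated by the
# shift-register recursion, so overlapping responses can be unmixed by a
# linear model with near-optimal efficiency.
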