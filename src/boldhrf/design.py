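"""Rapid event-related designs driven by maximal-length shift-register sequences.

Fast event-related fMRI experiments schedule stimuli and null events using a
binary m-sequence, whose flat power spectrum and near-ideal autocorrelation
make the stimulus-onset-asynchrony (SOA) distribution efficient for estimating
the shape of the hemodynamic response.  This module generates the sequence
itself, converts it to jittered event timings, and assigns trial types
(frequent audiovisual trials plus rare unimodal "catch" trials).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EventSequence",
    "generate_msequence",
    "build_event_timing",
    "assign_trial_types",
    "DEFAULT_TAPS",
]

#: Primitive feedback polynomials (tap sets) per register degree.  Any
#: primitive polynomial yields a maximal sequence; these are conventional
#: choices.  Degree 8 uses taps {8, 6, 5, 4}.
DEFAULT_TAPS: dict[int, tuple[int, ...]] = {
    2: (2, 1),
    3: (3, 2),
    4: (4, 3),
    5: (5, 3),
    6: (6, 5),
    7: (7, 6),
    8: (8, 6, 5, 4),
    9: (9, 5),
    10: (10, 7),
    11: (11, 9),
    12: (12, 11, 10, 4),
    13: (13, 12, 11, 8),
    14: (14, 13, 12, 2),
    15: (15, 14),
    16: (16, 15, 13, 4),
}

TRIAL_TYPES = ("audiovisual", "visual_only", "auditory_only")


@dataclass(frozen=True)
class EventSequence:
    """Typed, jittered stimulus onsets for one scanning run.

    Onsets are seconds from the first scan; each onset is its sequence slot
    time (slot index times the base SOA) plus a per-trial uniform jitter.
    """

    onsets: np.ndarray
    durations: np.ndarray
    trial_types: np.ndarray
    jitters: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", np.asarray(self.durations, dtype=float))
        object.__setattr__(self, "trial_types", np.asarray(self.trial_types, dtype=object))
        if self.jitters is None:
            object.__setattr__(self, "jitters", np.zeros_like(onsets))
        else:
            object.__setattr__(self, "jitters", np.asarray(self.jitters, dtype=float))
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        if onsets.size and onsets[0] < 0:
            raise ValueError("event onsets must be non-negative")
        if len(self.durations) != len(onsets) or len(self.trial_types) != len(onsets):
            raise ValueError("onsets, durations and trial_types must have equal length")

    def __len__(self) -> int:
        return len(self.onsets)


def generate_msequence(degree: int, taps: tuple[int, ...] | None = None) -> np.ndarray:
    """Generate one period of a maximal-length binary shift-register sequence.

    Parameters
    ----------
    degree
        Register length ``d``; the sequence has period ``2**d - 1`` with
        ``2**(d-1)`` ones.
    taps
        Feedback tap positions (1-based, must form a primitive polynomial).
        Defaults to a known primitive set for the degree.

    Returns
    -------
    ndarray of 0/1 ints, length ``2**degree - 1``.

    Raises
    ------
    ValueError
        If the degree is out of range or the taps are not primitive (detected
        by the register returning to its seed state before the full period).
    """
    if not (2 <= degree <= 16):
        raise ValueError(f"degree must be in [2, 16], got {degree}")
    if taps is None:
        taps = DEFAULT_TAPS[degree]
    taps = tuple(sorted(set(int(t) for t in taps), reverse=True))
    if not taps or max(taps) > degree or min(taps) < 1 or degree not in taps:
        raise ValueError(f"taps {taps} invalid for degree {degree}")

    period = 2**degree - 1
    state = np.ones(degree, dtype=int)  # seed: all ones
    seed = state.copy()
    out = np.empty(period, dtype=int)
    for i in range(period):
        out[i] = state[-1]
        fb = 0
        for t in taps:
            fb ^= state[t - 1]
        state = np.concatenate(([fb], state[:-1]))
        if i < period - 1 and np.array_equal(state, seed):
            raise ValueError(
                f"taps {taps} are not primitive for degree {degree}: "
                f"period {i + 1} < {period}"
            )
    if not np.array_equal(state, seed):
        raise ValueError(f"taps {taps} are not primitive for degree {degree}")
    return out


def msequence_autocorrelation(seq: np.ndarray) -> np.ndarray:
    """Periodic autocorrelation of the +/-1 coded sequence at all lags.

    For a maximal sequence this equals the period at lag 0 and -1 at every
    other lag.
    """
    x = 2 * np.asarray(seq, dtype=float) - 1
    n = len(x)
    return np.array([np.dot(x, np.roll(x, -k)) for k in range(n)])


def build_event_timing(
    seq: np.ndarray,
    base_soa_s: float = 2.0,
    jitter_low_s: float = 0.1,
    jitter_high_s: float = 0.3,
    rng: np.random.Generator | None = None,
    duration_s: float = 0.0,
) -> EventSequence:
    """Convert a binary sequence into jittered event onsets.

    Sequence element ``k`` equal to one yields an event at ``k * base_soa_s``
    plus a uniform jitter in ``[jitter_low_s, jitter_high_s]``; null elements
    yield no event, so the realised SOAs are multiples of the base SOA (plus
    jitter differences).
    """
    if base_soa_s <= 0:
        raise ValueError("base_soa_s must be positive")
    if not (0 <= jitter_low_s <= jitter_high_s):
        raise ValueError("need 0 <= jitter_low_s <= jitter_high_s")
    if rng is None:
        rng = np.random.default_rng()
    seq = np.asarray(seq)
    slots = np.flatnonzero(seq == 1)
    jit = rng.uniform(jitter_low_s, jitter_high_s, size=len(slots))
    onsets = slots * base_soa_s + jit
    return EventSequence(
        onsets=onsets,
        durations=np.full(len(slots), float(duration_s)),
        trial_types=np.array(["audiovisual"] * len(slots), dtype=object),
        jitters=jit,
    )


def assign_trial_types(
    events: EventSequence,
    counts: dict[str, int] | None = None,
    rng: np.random.Generator | None = None,
) -> EventSequence:
    """Randomly assign trial types with fixed counts.

    Defaults mirror the sensorimotor paradigm: of 128 trials, 120 are
    audiovisual and 4 each are visual-only / auditory-only catch trials,
    intermixed at uniformly random positions.
    """
    n = len(events)
    if counts is None:
        if n != 128:
            raise ValueError(
                "default counts (120/4/4) require 128 events; pass counts explicitly"
            )
        counts = {"audiovisual": 120, "visual_only": 4, "auditory_only": 4}
    unknown = set(counts) - set(TRIAL_TYPES)
    if unknown:
        raise ValueError(f"unknown trial types: {sorted(unknown)}")
    total = sum(counts.values())
    if total != n:
        raise ValueError(f"counts sum to {total} but there are {n} events")
    if rng is None:
        rng = np.random.default_rng()
    labels = np.concatenate(
        [np.full(counts.get(t, 0), t, dtype=object) for t in TRIAL_TYPES]
    )
    rng.shuffle(labels)
    return replace(events, trial_types=labels)
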