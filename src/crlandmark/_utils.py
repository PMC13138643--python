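"""Small shared helpers: step functions and RNG plumbing."""

from __future__ import annotations

import numpy as np


class StepFunction:
    """Right-continuous step function f(t) = values[k] for times[k] <= t < times[k+1].

    ``baseline`` is the value for t < times[0].
    """

    def __init__(self, times, values, baseline=0.0):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if times.size > 1 and np.any(np.diff(times) < 0):
            raise ValueError("times must be sorted ascending")
        self.times = times
        self.values = values
        self.baseline = float(baseline)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], self.baseline)
        return out if out.ndim else float(out)

    def left_limit(self, t):
        """f(t-): the value just before t."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], self.baseline)
        return out if out.ndim else float(out)


def _stable_key(k) -> int:
    # hash() is process-salted for str; crc32 is stable across runs
    import zlib

    if isinstance(k, (int, np.integer)):
        return int(k) % (2**31)
    return zlib.crc32(str(k).encode()) % (2**31)


def spawn_rng(seed, *key):
    """Derive an independent Generator from a master seed and a string/int key path."""
    ss = np.random.SeedSequence([int(seed)] + [_stable_key(k) for k in key])
    return np.random.default_rng(ss)
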