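"""Intensity transforms between linear and log-compressed initial pressure.

Initial pressure spans several orders of magnitude, so the networks regress
the log-compressed field p0' = log10(1 + p0) and predictions are expanded
back with p0 = 10^p0' - 1. Negative network outputs are clipped to zero at
expansion time.
"""

from __future__ import annotations

import numpy as np

__all__ = ["log_compress", "log_expand"]


def log_compress(p0: np.ndarray) -> np.ndarray:
    """p0' = log10(1 + p0); monotone, maps 0 to 0."""
    p0 = np.asarray(p0)
    if np.any(p0 < 0):
        raise ValueError("initial pressure must be nonnegative")
    return np.log10(1.0 + p0)


def log_expand(p0_log: np.ndarray, clip_negative: bool = True) -> np.ndarray:
    """Inverse transform p0 = 10^p0' - 1.

    Network estimates can dip below zero; by default they are clipped so the
    expanded pressure stays nonnegative.
    """
    p0_log = np.asarray(p0_log)
    if clip_negative:
        p0_log = np.maximum(p0_log, 0.0)
    elif np.any(p0_log < 0):
        raise ValueError("log-compressed pressure must be nonnegative")
    return 10.0**p0_log - 1.0
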