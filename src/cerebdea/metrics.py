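"""Tracking-error metrics: windowed RMS learning curves and steady-state RMS."""

from __future__ import annotations

import numpy as np

__all__ = ["windowed_rms", "steady_state_rms"]


def windowed_rms(e: np.ndarray, window_s: float, fs: float) -> np.ndarray:
    """RMS of e over consecutive non-overlapping windows of window_s seconds.

    Returns floor(len(e) / (window_s * fs)) values; a trailing partial window
    is discarded.
    """
    e = np.asarray(e, dtype=float)
    w = int(round(window_s * fs))
    if w < 1 or w > len(e):
        raise ValueError(f"window of {window_s} s does not fit series of "
                         f"{len(e) / fs} s")
    n_win = len(e) // w
    trimmed = e[: n_win * w].reshape(n_win, w)
    return np.sqrt(np.mean(trimmed**2, axis=1))


def steady_state_rms(
    e: np.ndarray, fs: float, final_span_s: float = 320.0, window_s: float = 20.0
) -> float:
    """Mean of the windowed RMS error over the final final_span_s seconds."""
    e = np.asarray(e, dtype=float)
    n_tail = int(round(final_span_s * fs))
    if n_tail > len(e):
        raise ValueError(f"series shorter than final span {final_span_s} s")
    return float(np.mean(windowed_rms(e[-n_tail:], window_s, fs)))
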