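"""Small discrete-time filter primitives shared across modules.

All filters run sample-by-sample at a fixed rate (50 Hz by default) and keep
their own state, so the control loop can interleave them freely.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FirstOrderFilter", "VectorOnePole"]


class FirstOrderFilter:
    """Scalar first-order IIR filter  y_k = a1*y_{k-1} + b0*x_k + b1*x_{k-1}.

    Written in the delay-operator convention H(q) = (b0 + b1 q^-1)/(1 - a1 q^-1),
    which covers both the brainstem filter B_L and the reference model M.
    """

    def __init__(self, b0: float, b1: float = 0.0, a1: float = 0.0) -> None:
        if abs(a1) >= 1.0:
            raise ValueError(f"unstable pole a1={a1}; |a1| must be < 1")
        self.b0 = float(b0)
        self.b1 = float(b1)
        self.a1 = float(a1)
        self.reset()

    def reset(self) -> None:
        self._y = 0.0
        self._x = 0.0

    @property
    def dc_gain(self) -> float:
        return (self.b0 + self.b1) / (1.0 - self.a1)

    def step(self, x: float) -> float:
        y = self.a1 * self._y + self.b0 * x + self.b1 * self._x
        self._x = x
        self._y = y
        return y

    def filter(self, x: np.ndarray) -> np.ndarray:
        """Filter a whole sequence (resets nothing; continues from state)."""
        out = np.empty(len(x), dtype=float)
        for k, xk in enumerate(x):
            out[k] = self.step(float(xk))
        return out


class VectorOnePole:
    """Bank of identical one-pole filters applied elementwise to a vector.

    Used for eligibility filtering: every parallel-fibre signal is passed
    through its own copy of the reference model, sharing coefficients but not
    state.
    """

    def __init__(self, b0: float, a1: float, dim: int) -> None:
        if abs(a1) >= 1.0:
            raise ValueError(f"unstable pole a1={a1}")
        self.b0 = float(b0)
        self.a1 = float(a1)
        self.dim = int(dim)
        self._y = np.zeros(self.dim)

    def reset(self) -> None:
        self._y[:] = 0.0

    def step(self, x: np.ndarray) -> np.ndarray:
        if x.shape != (self.dim,):
            raise ValueError(f"expected shape ({self.dim},), got {x.shape}")
        self._y *= self.a1
        self._y += self.b0 * x
        return self._y.copy()
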