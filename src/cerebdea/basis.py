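"""Granular-layer analogue: input recoding, alpha-function basis, whitening.

The mossy-fibre input (an efference copy of the previous motor command) is
expanded in three stages before it reaches the adaptive weights:

1. **Input recoding** — a bank of threshold-linear (rectifier) elements with
   increasing thresholds, plus one untransformed linear channel.  This gives
   the adaptive filter a piecewise-linear basis in the *amplitude* of the
   command, which is what lets it synthesise a nonlinear compensation.
2. **Alpha filter bank** — each recoded channel is filtered by a set of
   alpha-function filters alpha(t) ~ (t/T^2) exp(-t/T) with log-spaced time
   constants, giving a compact basis over *time* (delays growing
   logarithmically, as in granular-layer processing).
3. **Decorrelation** — a whitening matrix Q, estimated once from a batch of
   filter outputs by singular value decomposition, maps the (highly
   correlated) bank outputs onto uncorrelated, unit-power parallel-fibre
   signals.  Equalising power across fibres is what lets a single scalar
   learning rate drive all weights at their maximal stable speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InputRecoder",
    "AlphaBasis",
    "DecorrelationMatrix",
    "alpha_kernel",
    "log_spaced_time_constants",
    "estimate_decorrelation",
]


@dataclass
class InputRecoder:
    """Threshold-linear expansion of a scalar command.

    Produces ``nu + 1`` channels: channel 0 is the raw command, channel j
    (j >= 1) is ``max(u - sigma[j-1], 0)``.  With ``nu = 0`` the recoder is a
    pure pass-through and the downstream adaptive filter is linear.
    """

    nu: int = 0
    sigma: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.nu < 0:
            raise ValueError(f"nu must be >= 0, got {self.nu}")
        if self.sigma.shape != (self.nu,):
            raise ValueError(
                f"sigma must have length nu={self.nu}, got {self.sigma.shape}"
            )
        if self.nu > 1 and not np.all(np.diff(self.sigma) > 0):
            raise ValueError(f"thresholds must be strictly increasing: {self.sigma}")

    @property
    def n_channels(self) -> int:
        return self.nu + 1

    def __call__(self, u_prev: float) -> np.ndarray:
        if not np.isfinite(u_prev):
            raise ValueError(f"non-finite command {u_prev}")
        q = np.empty(self.nu + 1)
        q[0] = u_prev
        if self.nu:
            np.maximum(u_prev - self.sigma, 0.0, out=q[1:])
        return q


def input_recoding(recoder: InputRecoder, u_prev: float) -> np.ndarray:
    """Functional alias for :meth:`InputRecoder.__call__`."""
    return recoder(u_prev)


def log_spaced_time_constants(t_min: float, t_max: float, n_f: int) -> np.ndarray:
    """Geometrically spaced time constants from t_min to t_max inclusive."""
    if n_f < 1:
        raise ValueError("n_f must be >= 1")
    if n_f == 1:
        return np.array([t_min], dtype=float)
    return np.geomspace(t_min, t_max, n_f)


def alpha_kernel(T: float, dt: float, horizon: float) -> np.ndarray:
    """Sampled alpha-function impulse response, normalised to unit DC gain.

    The continuous kernel is alpha(t) ~ (t/T^2) exp(-t/T), peaking at t = T.
    The discrete version uses the impulse-invariant double pole
    lam = exp(-dt/T): h[n] = (1-lam)^2/lam * n * lam^n, whose infinite sum is
    exactly 1.  A horizon shorter than 5*T truncates a non-negligible tail and
    triggers a warning.
    """
    if T <= 0 or dt <= 0:
        raise ValueError("T and dt must be > 0")
    if horizon < 5.0 * T:
        warnings.warn(
            f"horizon {horizon} s < 5*T = {5 * T} s truncates the alpha kernel",
            stacklevel=2,
        )
    lam = np.exp(-dt / T)
    n = np.arange(int(round(horizon / dt)) + 1)
    return (1.0 - lam) ** 2 / lam * n * lam**n


class AlphaBasis:
    """Recursive alpha filter bank: every input channel through every filter.

    Each filter is the second-order recursion
    ``y_k = 2*lam*y_{k-1} - lam^2*y_{k-2} + (1-lam)^2 * x_{k-1}`` with
    ``lam = exp(-dt/T)`` — the impulse-invariant realisation of the alpha
    kernel, normalised to unit DC gain so that constant commands map to
    constant fibre levels.  Output ordering is channel-major: the n_f outputs
    of channel 0 (shortest to longest T), then channel 1, and so on.
    """

    def __init__(self, T: np.ndarray, dt: float, n_channels: int) -> None:
        self.T = np.asarray(T, dtype=float)
        if self.T.ndim != 1 or np.any(self.T <= 0):
            raise ValueError("T must be a 1-D array of positive time constants")
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.dt = float(dt)
        self.n_f = len(self.T)
        self.n_channels = int(n_channels)
        self.lam = np.exp(-self.dt / self.T)[:, None]  # (n_f, 1)
        self.gain = (1.0 - self.lam) ** 2
        self.reset()

    @property
    def dim(self) -> int:
        """Total output dimension (channels x filters)."""
        return self.n_channels * self.n_f

    def reset(self) -> None:
        self._y1 = np.zeros((self.n_f, self.n_channels))
        self._y2 = np.zeros((self.n_f, self.n_channels))
        self._x1 = np.zeros(self.n_channels)

    def step(self, q: np.ndarray) -> np.ndarray:
        if q.shape != (self.n_channels,):
            raise ValueError(
                f"expected {self.n_channels} channels, got shape {q.shape}"
            )
        y = 2.0 * self.lam * self._y1 - self.lam**2 * self._y2 + self.gain * self._x1
        self._y2 = self._y1
        self._y1 = y
        self._x1 = np.asarray(q, dtype=float).copy()
        # channel-major flattening: (n_f, C) -> (C, n_f) -> flat
        return y.T.reshape(-1).copy()


def filter_bank_step(basis: AlphaBasis, q: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`AlphaBasis.step`."""
    return basis.step(q)


@dataclass
class DecorrelationMatrix:
    """Whitening transform for the filter-bank outputs.

    ``Q`` is the symmetric (ZCA) whitening matrix of the estimation batch:
    on that batch the transformed signals have identity sample covariance.
    """

    Q: np.ndarray
    mean: np.ndarray
    fitted: bool = False

    @property
    def dim(self) -> int:
        return self.Q.shape[0]

    def __call__(self, g: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("decorrelation matrix has not been fitted")
        return self.Q @ g

    @classmethod
    def identity(cls, dim: int) -> "DecorrelationMatrix":
        return cls(Q=np.eye(dim), mean=np.zeros(dim), fitted=True)


def estimate_decorrelation(
    batch: np.ndarray, floor_rel: float = 1e-9
) -> DecorrelationMatrix:
    """Estimate a whitening matrix from a batch of filter outputs by SVD.

    Parameters
    ----------
    batch : array, shape (n_samples, dim)
        Filter-bank outputs collected over time; should be generated by
        exciting the bank with commands of the same statistics as the task.
    floor_rel : float
        Singular values below ``floor_rel * s_max`` are floored there (a ridge
        against rank deficiency, e.g. a rectified channel that never fired).

    Returns
    -------
    DecorrelationMatrix with ``cov(Q @ g) = I`` on the batch to ~1e-6 for
    well-conditioned batches.
    """
    batch = np.asarray(batch, dtype=float)
    if batch.ndim != 2:
        raise ValueError("batch must be 2-D (samples x dim)")
    n, dim = batch.shape
    if n < 10 * dim:
        warnings.warn(
            f"batch of {n} samples is small for dimension {dim}; "
            "whitening may be poorly conditioned",
            stacklevel=2,
        )
    mean = batch.mean(axis=0)
    centred = batch - mean
    # SVD of the scaled data matrix: singular values are sqrt of cov eigenvalues
    _, s, Vt = np.linalg.svd(centred / np.sqrt(n - 1), full_matrices=False)
    if np.any(s < 1e-8 * s[0]):
        warnings.warn(
            f"{int(np.sum(s < 1e-8 * s[0]))} near-zero-variance channel(s); "
            "singular-value floor applied",
            stacklevel=2,
        )
    s = np.maximum(s, floor_rel * s[0])
    # symmetric (ZCA) whitening keeps channels aligned with their sources
    Q = Vt.T @ np.diag(1.0 / s) @ Vt
    return DecorrelationMatrix(Q=Q, mean=mean, fitted=True)


def decorrelate(Q: DecorrelationMatrix, g: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`DecorrelationMatrix.__call__`."""
    return Q(g)
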