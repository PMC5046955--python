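"""Adaptive-filter cerebellum: weighted parallel-fibre sum with LMS learning.

The Purkinje-cell analogue outputs ``z = w . p + bias`` where ``p`` are the
whitened parallel-fibre signals.  The weights follow the covariance (LMS)
rule driven by the tracking error ``e = x - y`` delivered by the climbing
fibre, in power-normalised form:

    w  <-  w - beta * dt * e * p_tilde / (1 + |p_tilde|^2)

where ``p_tilde`` are the fibre signals filtered through the reference model
M (eligibility filtering).  Passing the basis through M before correlating it
with the error aligns the timing of credit assignment with the desired
closed-loop dynamics; with this sign convention the update descends the
squared-error surface, because z adds to the motor command and the plant gain
is positive.  The normalisation by instantaneous eligibility power is the
classical NLMS safeguard: whitening equalises fibre power only on the
estimation batch, and in closed loop occasional large excursions of the
whitened basis would otherwise destabilise learning at this rate.
"""

from __future__ import annotations

import logging

import numpy as np

from ._filters import VectorOnePole

__all__ = ["CerebellarFilter"]

log = logging.getLogger(__name__)


class CerebellarFilter:
    """Adaptive linear filter over parallel-fibre signals.

    Parameters
    ----------
    dim : int
        Number of parallel fibres, ``(nu + 1) * n_f``.
    beta : float
        Learning rate of the covariance rule (per mm of error per second).
        ``beta = 0`` freezes the weights.
    bias : float
        Fixed additive constant on the output z (not learned).
    m_num, m_pole : float
        Reference-model coefficients ``M(q) = m_num / (1 - m_pole q^-1)``
        used for eligibility filtering; must match the loop's M.
    """

    def __init__(
        self,
        dim: int,
        beta: float = 8.0,
        bias: float = 0.0,
        m_num: float = 0.18,
        m_pole: float = 0.82,
    ) -> None:
        if dim < 1:
            raise ValueError("dim must be >= 1")
        if beta < 0:
            raise ValueError("beta must be >= 0")
        self.dim = int(dim)
        self.beta = float(beta)
        self.bias = float(bias)
        self.w = np.zeros(self.dim)
        self._elig = VectorOnePole(b0=m_num, a1=m_pole, dim=self.dim)
        self.n_frozen = 0

    def reset(self) -> None:
        self.w[:] = 0.0
        self._elig.reset()
        self.n_frozen = 0

    def output(self, p: np.ndarray) -> float:
        """Purkinje-cell output z = w . p + bias."""
        if p.shape != (self.dim,):
            raise ValueError(f"expected {self.dim} fibres, got shape {p.shape}")
        return float(self.w @ p) + self.bias

    def eligibility_step(self, p: np.ndarray) -> np.ndarray:
        """Advance the per-fibre reference-model filters; return p_tilde."""
        return self._elig.step(p)

    def lms_update(self, e: float, p_tilde: np.ndarray, dt: float) -> None:
        """Normalised covariance-rule update; no-op when beta == 0."""
        if not np.isfinite(e) or not np.all(np.isfinite(p_tilde)):
            self.n_frozen += 1
            log.warning("non-finite error/eligibility at update; learning frozen "
                        "for this sample (count=%d)", self.n_frozen)
            return
        if self.beta == 0.0:
            return
        self.w -= (self.beta * dt * e / (1.0 + p_tilde @ p_tilde)) * p_tilde
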