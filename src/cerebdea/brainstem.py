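"""Brainstem model: linear filter plus piecewise-linear recruitment element.

The brainstem is the fixed (or slowly plastic) approximate inverse of the
plant.  It is a cascade of

* a linear filter ``B_L(q) = (0.66 - 0.48 q^-1)/(1 - 0.82 q^-1)`` (stable,
  unit DC gain) that approximately inverts the plant's linear dynamics
  through the reference model, and
* a memoryless piecewise-linear element built from rectifier units,

      u = g_0 * v + sum_j g_j * max(v - rho_j, 0),

  the engineering analogue of motor-unit recruitment: as the drive v grows,
  units with progressively higher thresholds switch in and change the local
  slope, so a suitable gain profile approximates the inverse of the plant's
  static nonlinearity.

With a nonzero transfer rate ``zeta`` the gains are plastic: they follow the
Hebbian correlation of the cerebellar drive z with the recruitment basis
activations, which slowly transfers compensation learned by the cerebellum
into the brainstem ("transfer of training", as observed in vestibulo-ocular
reflex adaptation).  Negative drive passes through the linear term only; the
task is unipolar so no negative-side recruitment exists.
"""

from __future__ import annotations

import logging

import numpy as np

from ._filters import FirstOrderFilter

__all__ = ["BrainstemModel"]

log = logging.getLogger(__name__)

#: B_L(q) = (0.66 - 0.48 q^-1) / (1 - 0.82 q^-1)
BL_NUM = (0.66, -0.48)
BL_POLE = 0.82


class BrainstemModel:
    """Linear brainstem filter followed by a recruitment nonlinearity.

    Parameters
    ----------
    gains : array, length m+1
        ``gains[0]`` multiplies v itself; ``gains[j]`` (j >= 1) multiplies the
        rectified copy ``max(v - rho[j-1], 0)``.
    rho : array, length m
        Recruitment thresholds, strictly increasing with ``rho[0] = 0`` (same
        units as v, i.e. target-displacement mm).
    zeta : float
        Transfer-of-training rate; 0 keeps the gains fixed.
    transfer_rule : {"simple", "decorrelated"}
        "simple" is the plain Hebbian rule dg_j = zeta*z*mu_j*dt.
        "decorrelated" subtracts the neighbouring activation for j >= 2
        (dg_j = zeta*z*(mu_j - mu_{j-1})*dt), partially decorrelating the
        overlapping rectifier basis; both give very similar closed-loop
        behaviour.
    """

    def __init__(
        self,
        gains: np.ndarray,
        rho: np.ndarray,
        zeta: float = 0.0,
        bl_num: tuple[float, float] = BL_NUM,
        bl_pole: float = BL_POLE,
        transfer_rule: str = "simple",
    ) -> None:
        self.gains = np.asarray(gains, dtype=float).copy()
        self.rho = np.asarray(rho, dtype=float)
        if self.rho.ndim != 1 or self.gains.ndim != 1:
            raise ValueError("gains and rho must be 1-D")
        if len(self.gains) != len(self.rho) + 1:
            raise ValueError(
                f"need len(gains) == len(rho) + 1, got {len(self.gains)} "
                f"and {len(self.rho)}"
            )
        if len(self.rho) and self.rho[0] != 0.0:
            raise ValueError(f"rho[0] must be 0, got {self.rho[0]}")
        if len(self.rho) > 1 and not np.all(np.diff(self.rho) > 0):
            raise ValueError(f"thresholds must be strictly increasing: {self.rho}")
        if zeta < 0:
            raise ValueError("zeta must be >= 0")
        if transfer_rule not in ("simple", "decorrelated"):
            raise ValueError(f"unknown transfer rule {transfer_rule!r}")
        self.zeta = float(zeta)
        self.transfer_rule = transfer_rule
        self._bl = FirstOrderFilter(b0=bl_num[0], b1=bl_num[1], a1=bl_pole)
        self.n_frozen = 0

    @property
    def m(self) -> int:
        """Number of recruitment (rectifier) terms."""
        return len(self.rho)

    def reset(self) -> None:
        self._bl.reset()
        self.n_frozen = 0

    def linear_step(self, r_plus_z: float) -> float:
        """One sample of the linear brainstem filter B_L."""
        return self._bl.step(r_plus_z)

    def basis(self, v: float) -> np.ndarray:
        """Recruitment basis activations mu_j: mu_0 = v, mu_j = max(v - rho_j, 0)."""
        mu = np.empty(self.m + 1)
        mu[0] = v
        if self.m:
            np.maximum(v - self.rho, 0.0, out=mu[1:])
        return mu

    def recruitment(self, v: float) -> float:
        """Piecewise-linear output u = gains . basis(v) (continuous in v)."""
        return float(self.gains @ self.basis(v))

    def nonlinearity_curve(self, v: np.ndarray) -> np.ndarray:
        """Evaluate the recruitment map on an array of drives (for plotting)."""
        return np.array([self.recruitment(float(vi)) for vi in np.asarray(v)])

    def transfer_update(self, z: float, v: float, dt: float) -> None:
        """Cerebellum-driven gain plasticity; identity when zeta == 0."""
        if self.zeta == 0.0:
            return
        if not np.isfinite(z) or not np.isfinite(v):
            self.n_frozen += 1
            log.warning("non-finite cerebellar drive; transfer frozen for this "
                        "sample (count=%d)", self.n_frozen)
            return
        mu = self.basis(v)
        if self.transfer_rule == "simple":
            self.gains += self.zeta * z * dt * mu
        else:
            delta = mu.copy()
            delta[2:] = mu[2:] - mu[1:-1]
            self.gains += self.zeta * z * dt * delta
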