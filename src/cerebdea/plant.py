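"""Synthetic Hammerstein model of a dielectric elastomer actuator (DEA).

The simulated plant is a cascade of a memoryless static nonlinearity (SNL,
the supralinear voltage-to-displacement map of the elastomer) and a linear
dynamic system (LDS, a first-order lag with ~100 ms time constant), with two
measurement-level effects layered on top:

* *creep* — a slow multiplicative growth of the response amplitude over tens
  of minutes, modelled as a saturating-exponential output gain; and
* *sensor noise* — additive Gaussian noise with the repeatability of a laser
  displacement sensor (0.02 mm), applied to the measurement only.  The true
  displacement is retained alongside the noisy reading so tracking accuracy
  can be quantified independently of the sensor.

Two SNL families are provided.  :class:`SplineSNL` (the default calibration)
is a monotone spline identified from the recruitment-style inverse map used
by the fixed nonlinear controller: approximately linear at 1/3 mm/V over the
lower half of the displacement range, with the supralinear knee concentrated
around 1 mm so that commands of roughly 0-4.3 V span 0-1.8 mm.
:class:`StaticNonlinearity` is a plain monotone quadratic useful for
analytically tractable experiments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "StaticNonlinearity",
    "SplineSNL",
    "LinearDynamics",
    "CreepProcess",
    "HammersteinPlant",
    "LinearPlant",
]

log = logging.getLogger(__name__)

DEFAULT_TAU = 0.1
DEFAULT_DT = 0.02
DEFAULT_NOISE_SD = 0.02
DEFAULT_KAPPA_MAX = 0.12
DEFAULT_TAU_C = 600.0

#: displacement knots (mm) and command knots (V) of the default calibration.
#: The command column interpolates between the linear-brainstem line (3 V/mm)
#: and the identified piecewise-linear inverse map, with the slope break
#: placed near 1 mm where the reference distribution has most of its mass.
SNL_KNOTS_D = (0.0, 0.255, 0.51, 0.765, 1.02, 1.25, 1.5, 1.785, 2.1)
SNL_KNOTS_U = (0.0, 0.806, 1.76, 2.46, 3.02, 3.42, 3.70, 3.98, 4.30)
DEFAULT_U_MAX = 4.3


@dataclass
class StaticNonlinearity:
    """Monotone quadratic voltage-to-displacement map d(V) = c1*V + c2*V^2.

    Strictly increasing on [0, u_max] (c1 > 0, c2 >= 0), hence invertible
    there in closed form.
    """

    c1: float = 0.20
    c2: float = 0.10
    u_max: float = 3.4

    def __post_init__(self) -> None:
        if self.c1 <= 0:
            raise ValueError(f"c1 must be > 0, got {self.c1}")
        if self.c2 < 0:
            raise ValueError(f"c2 must be >= 0, got {self.c2}")
        if self.u_max <= 0:
            raise ValueError(f"u_max must be > 0, got {self.u_max}")

    @property
    def d_max(self) -> float:
        """Displacement at the command ceiling (mm)."""
        return self(self.u_max)

    def __call__(self, V: float) -> float:
        """Steady-state displacement (mm) for command voltage V."""
        if not 0.0 <= V <= self.u_max:
            raise ValueError(f"command {V} V outside [0, {self.u_max}] V")
        return self.c1 * V + self.c2 * V * V

    def inverse(self, d: float) -> float:
        """Command voltage producing steady-state displacement d (mm)."""
        if not 0.0 <= d <= self.d_max + 1e-12:
            raise ValueError(f"displacement {d} mm outside [0, {self.d_max:.4g}] mm")
        # stable form of the positive quadratic root (no cancellation as c2->0)
        return 2.0 * d / (self.c1 + math.sqrt(self.c1 * self.c1 + 4.0 * self.c2 * d))


class SplineSNL:
    """Monotone-spline static nonlinearity (the default DEA calibration).

    Forward and inverse maps are monotone PCHIP interpolants through the
    calibration knots, so ``inverse`` is exact to interpolation accuracy and
    the round trip is consistent to ~1e-9.
    """

    def __init__(
        self,
        knots_d=SNL_KNOTS_D,
        knots_u=SNL_KNOTS_U,
        u_max: float = DEFAULT_U_MAX,
    ) -> None:
        d = np.asarray(knots_d, dtype=float)
        u = np.asarray(knots_u, dtype=float)
        if d.shape != u.shape or d.ndim != 1 or len(d) < 3:
            raise ValueError("knots must be two equal-length 1-D arrays")
        if not (np.all(np.diff(d) > 0) and np.all(np.diff(u) > 0)):
            raise ValueError("knots must be strictly increasing")
        if d[0] != 0.0 or u[0] != 0.0:
            raise ValueError("map must pass through the origin")
        if u_max <= 0:
            raise ValueError("u_max must be > 0")
        self.knots_d = d
        self.knots_u = u
        self.u_max = float(u_max)
        self._fwd = PchipInterpolator(u, d, extrapolate=True)
        self._inv = PchipInterpolator(d, u, extrapolate=True)

    @property
    def d_max(self) -> float:
        return float(self._fwd(self.u_max))

    def __call__(self, V: float) -> float:
        if not 0.0 <= V <= self.u_max:
            raise ValueError(f"command {V} V outside [0, {self.u_max}] V")
        return float(self._fwd(V))

    def inverse(self, d: float) -> float:
        if not 0.0 <= d <= self.d_max + 1e-12:
            raise ValueError(f"displacement {d} mm outside [0, {self.d_max:.4g}] mm")
        # PCHIP forward and inverse interpolants are not exact inverses
        # between knots; polish with a few Newton steps on the forward map.
        u = float(self._inv(min(d, self.d_max)))
        for _ in range(4):
            u = min(max(u, 0.0), self.u_max)
            f = float(self._fwd(u)) - d
            df = float(self._fwd.derivative()(u))
            if df <= 0:
                break
            step = f / df
            u -= step
            if abs(step) < 1e-12:
                break
        return min(max(u, 0.0), self.u_max)


def snl_eval(snl, V: float) -> float:
    """Steady-state displacement for command V (works for either SNL type)."""
    return snl(V)


def snl_invert(snl, d: float) -> float:
    """Command producing steady-state displacement d."""
    return snl.inverse(d)


@dataclass
class LinearDynamics:
    """Unit-DC-gain one-pole lag, pole exp(-dt/tau)."""

    tau: float = DEFAULT_TAU
    dt: float = DEFAULT_DT
    state: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.dt <= 0:
            raise ValueError("tau and dt must be > 0")
        self.pole = math.exp(-self.dt / self.tau)

    def reset(self) -> None:
        self.state = 0.0

    def step(self, v: float) -> float:
        self.state = self.pole * self.state + (1.0 - self.pole) * v
        return self.state


@dataclass
class CreepProcess:
    """Multiplicative amplitude drift gain(t) = 1 + kappa_max*(1 - exp(-t/tau_c)).

    Monotone nondecreasing from 1 toward 1 + kappa_max; emulates the slow
    growth of DEA response amplitude under sustained stimulation.
    """

    kappa_max: float = DEFAULT_KAPPA_MAX
    tau_c: float = DEFAULT_TAU_C
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa_max < 0 or self.tau_c <= 0:
            raise ValueError("kappa_max must be >= 0 and tau_c > 0")

    def reset(self) -> None:
        self.t = 0.0

    def gain(self, t: float | None = None) -> float:
        if t is None:
            t = self.t
        return 1.0 + self.kappa_max * (1.0 - math.exp(-t / self.tau_c))

    def advance(self, dt: float) -> float:
        """Advance internal time and return the gain at the new time."""
        self.t += dt
        return self.gain()


@dataclass
class HammersteinPlant:
    """SNL -> LDS cascade with creep gain and measurement noise.

    One call to :meth:`step` advances the plant by one sample: the command is
    clipped to the admissible range, mapped through the static nonlinearity,
    filtered by the lag, scaled by the creep gain and finally corrupted by
    sensor noise.  Noise affects the measurement only, never the internal
    state; the noiseless displacement of the last step is kept in
    :attr:`x_true`.  With ``noise_sd = 0`` and ``kappa_max = 0`` the plant is
    deterministic.
    """

    snl: object = field(default_factory=SplineSNL)
    lds: LinearDynamics = field(default_factory=LinearDynamics)
    creep: CreepProcess = field(default_factory=CreepProcess)
    noise_sd: float = DEFAULT_NOISE_SD
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.reset()

    @property
    def u_max(self) -> float:
        return self.snl.u_max

    @property
    def dt(self) -> float:
        return self.lds.dt

    def reset(self) -> None:
        self.lds.reset()
        self.creep.reset()
        self._rng = np.random.default_rng(self.rng_seed)
        self.n_clipped = 0
        self.x_true = 0.0

    def step(self, u: float) -> float:
        """Drive the plant with command u (V); return measured displacement (mm)."""
        u_c = min(max(u, 0.0), self.snl.u_max)
        if u_c != u:
            self.n_clipped += 1
            if self.n_clipped in (1, 100, 10000):
                log.debug("command %.3f V clipped to [0, %.2f] V (count=%d)",
                          u, self.snl.u_max, self.n_clipped)
        v_star = self.snl(u_c)
        x = self.lds.step(v_star)
        x *= self.creep.advance(self.lds.dt)
        self.x_true = x
        if self.noise_sd > 0:
            x += self.noise_sd * self._rng.standard_normal()
        return x


class LinearPlant:
    """First-order LTI plant with transfer function b0 / (a0 - a1 q^-1).

    Mainly useful for exact-inverse experiments: with the defaults
    (0.18 / (0.66 - 0.48 q^-1)) the cascade of the standard linear brainstem
    filter with this plant equals the reference model, so a unit-gain
    controller is perfect by construction and the cerebellum has nothing
    left to learn.
    """

    def __init__(self, b0: float = 0.18, a0: float = 0.66, a1: float = 0.48,
                 noise_sd: float = 0.0, rng_seed: int = 0,
                 dt: float = DEFAULT_DT) -> None:
        if abs(a1 / a0) >= 1.0:
            raise ValueError("unstable plant pole")
        self.b0, self.a0, self.a1 = float(b0), float(a0), float(a1)
        self.noise_sd = float(noise_sd)
        self.rng_seed = int(rng_seed)
        self.dt = float(dt)
        self.u_max = None  # no clipping
        self.reset()

    def reset(self) -> None:
        self._x = 0.0
        self._rng = np.random.default_rng(self.rng_seed)
        self.x_true = 0.0

    def step(self, u: float) -> float:
        self._x = (self.a1 / self.a0) * self._x + (self.b0 / self.a0) * u
        self.x_true = self._x
        x = self._x
        if self.noise_sd > 0:
            x += self.noise_sd * self._rng.standard_normal()
        return x
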