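# Methods

`cerebdea` simulates closed-loop displacement control of a dielectric
elastomer actuator (DEA, an electroactive-polymer "artificial muscle") by a
cerebellar-inspired adaptive-inverse controller, and reproduces a six-way
comparison of control schemes on a common synthetic plant.  This note
records the model, its parameters, and the numerical and design choices
behind the implementation.

## Control architecture

The controller copies the organisation of the vestibulo-ocular reflex:

* a **brainstem** pathway — a fixed linear filter
  `B_L(q) = (0.66 − 0.48 q⁻¹)/(1 − 0.82 q⁻¹)` (stable, unit DC gain)
  followed by a memoryless piecewise-linear *recruitment* element
  `u = g₀v + Σⱼ gⱼ·max(v − ρⱼ, 0)` — which implements an approximate
  inverse of the plant; and
* a **cerebellum** — an adaptive linear filter over a fixed nonlinear basis
  — connected recurrently: it receives an efference copy of the motor
  command `u` and adds its output `z` to the reference before the brainstem,
  `v = B_L(r + z)`.

A reference model `M(q) = 0.18/(1 − 0.82 q⁻¹)` defines the target response
`y = M r`; the climbing-fibre teaching signal is the tracking error
`e = x − y` between measured displacement and target.  At convergence the
composite controller approximates the plant inverse through `M`, and the
cerebellum holds an incremental plant model (whatever the brainstem gets
wrong).

The cerebellar basis is built in three stages from the efference copy
`u_{k−1}`:

1. **threshold-linear recoding** into ν+1 channels (one raw channel plus
   rectifiers at thresholds σ, the granular-layer analogue of
   threshold-linear granule-cell responses);
2. an **alpha-function filter bank** per channel, kernels
   `α(t) ∝ (t/T²)e^{−t/T}` with n_f = 4 time constants log-spaced from
   0.1 to 0.5 s, realised as unit-DC-gain second-order recursions
   (impulse-invariant, double pole `exp(−dt/T)`); and
3. a **whitening matrix Q** estimated once by SVD from a batch of bank
   outputs, giving uncorrelated, unit-power parallel-fibre signals.

Learning rules:

* **Cerebellum (LMS / covariance rule, power-normalised).**
  `w ← w − β·dt·e·p̃ / (1 + ‖p̃‖²)` with β = 8 and eligibility signals
  `p̃ = M(p)` (each fibre filtered through the reference model, aligning
  the timing of credit assignment).  The normalisation by instantaneous
  eligibility power is the classical NLMS safeguard: the whitening equalises
  fibre power only on the estimation batch, and in closed loop occasional
  large excursions of the whitened basis at this learning rate would
  otherwise drive weight bursting — transient instabilities of the
  recurrent loop in which large cerebellar outputs act as large loop gains.
  With normalisation all six schemes learn stably at the same β.
* **Brainstem (transfer of training).**  `gⱼ ← gⱼ + ζ·z·μⱼ·dt` with
  μ₀ = v, μⱼ = max(v − ρⱼ, 0) and ζ = 0.01 (scheme six only; ζ = 0
  elsewhere).  This Hebbian correlation of cerebellar drive with
  recruitment-basis activity slowly moves compensation learned by the
  cerebellum into the brainstem, keeping `z` small.  A variant that
  subtracts the neighbouring activation (`Δgⱼ ∝ z(μⱼ − μⱼ₋₁)` for j ≥ 2),
  partially decorrelating the overlapping rectifier basis, is available via
  `transfer_rule="decorrelated"`; both give very similar closed-loop
  behaviour.

Per-sample order of operations, loop timing (the efference copy is the
*previous* command, avoiding an algebraic loop), and a divergence guard
(abort when |e| exceeds 10× the reference range for a full second) are
described in `cerebdea.loop`.

## The synthetic plant

The DEA is a Hammerstein cascade: static nonlinearity (SNL) → first-order
lag → multiplicative creep gain → additive sensor noise.

| parameter | default | units | rationale |
|---|---|---|---|
| SNL | monotone spline, see below | mm vs V | calibrated from the printed inverse map |
| τ (lag) | 0.1 | s | step response settles in ≈300 ms |
| dt | 0.02 | s | 50 Hz sampling |
| κ_max (creep) | 0.12 | — | visible drift without linearising the task (below) |
| τ_c (creep) | 600 | s | drift develops over tens of minutes |
| noise sd | 0.02 | mm | laser-sensor repeatability |
| u_max | 4.3 | V | admissible command ceiling (pre-amplification volts) |

**SNL calibration.**  The only quantitative information available about the
modelled actuator's static map is indirect: (i) the displacement task spans
0.1–1.8 mm with commands of order 3 V; (ii) the fixed linear brainstem
(slope 3 V/mm) tracks well when the reference is kept below 1 mm, so the
map must be approximately linear at ~1/3 mm/V over its lower range; and
(iii) the identified 8-term recruitment map (gains 0.92, 2.38, 1.07, −1.92,
−0.78, −0.11, −0.12, −0.045, 0 at thresholds 0–1.785 mm) is an
*approximate* inverse of the true map.  The default SNL is a monotone PCHIP
spline through knots chosen to satisfy all three constraints at once: the
command knots blend the 3 V/mm line with the printed piecewise map over the
lower range, then break to a shallower inverse slope (~1 V/mm) just above
1 mm — inside the window covered by the cerebellar thresholds
σ = 2.18–3.38 V — and meet the printed map again near the top
(u(1.785) ≈ 3.98 V vs 4.13 V printed).  The printed recruitment map
therefore retains a genuine ±0.1–0.25 V identification error against the
"true" plant, exactly the situation the fixed-brainstem schemes are meant
to face.  An earlier candidate — a plain quadratic d = 0.2·V + 0.1·V²
(kept available as `StaticNonlinearity`) — was rejected because its inverse
slope at the origin (5 V/mm) contradicts the printed brainstem gains
(g₀+g₁ = 3.0–3.3 V/mm) and makes the fixed nonlinear brainstem a *worse*
inverse than the plain linear one, inverting the scheme comparison.

**Creep magnitude.**  κ_max = 0.12 rather than a larger value: because
creep multiplies the output, a gain approaching 1.3 shifts the whole
operating range so far down the command axis that by the end of a run the
task no longer engages the supralinear region at all — every scheme then
looks linear and the comparison degenerates.  At 0.12 the drift is clearly
visible (it drives the cerebellar-output growth in the zeta = 0 schemes)
while the task stays nonlinear throughout.

**Error reporting.**  The sensor noise enters the feedback path (learning
sees the noisy measurement), but reported tracking errors are computed on
the true displacement (`SimulationResult.e_true`, the default for
`steady_state_rms`).  The published steady-state errors (down to 0.011 mm)
lie *below* the 0.02 mm sensor repeatability, so they can only refer to
noiseless displacement; quoting measured-error RMS would add the sensor
variance (+0.02 mm in quadrature) to every number.  The measured-error
series is retained (`e`, and `measured=True` in the metric methods).

## Reference signal

White Gaussian noise, 2nd-order Butterworth low-pass at 1 Hz, affinely
rescaled so the realised minimum/maximum equal the target range (0.1–1.8 mm
full, 0.1–1.0 mm reduced); a 10 s pre-roll absorbs the filter transient.
Exact-range rescaling was chosen over statistical scaling for
reproducibility.  Note a consequence of min/max rescaling of Gaussian
noise: the amplitude *distribution* concentrates around mid-range
(sd ≈ 0.2 mm about a 0.95 mm mean for the full task), so extreme
displacements are rare and steady-state RMS weights the mid-range shape of
the plant map far more than its extremes.

## Whitening protocol

Q is estimated from a 120 s open-loop pre-run: the untrained brainstem is
driven by a fresh reference realisation (independent seed), the resulting
commands excite the recoder and alpha bank, the first 2 s are discarded as
warm-up, and Q is the symmetric (ZCA) whitening matrix of the collected
batch.  Singular values are floored at 1% of the largest
(`SchemeConfig.q_floor`): the discarded directions carry <0.01% of the
batch variance each, and whitening them exactly would amplify
batch-specific noise by factors of 10³–10⁴.  Q is then frozen for the
learning run; one Q is fitted per run.  `estimate_decorrelation` itself
defaults to a near-exact floor (1e−9) and satisfies cov(Qg) = I to 1e−6 on
any well-conditioned batch.

## PID baseline

The comparison scheme is a parallel-form PID on the tracking error with a
clamped integrator, acting at the same 50 Hz with a one-sample compute
delay.  Gains were tuned once by grid search minimising steady-state RMS on
the secant-linearised plant (gain d_max/u_max ≈ 0.49 mm/V), subject to a
12 dB gain margin and 45° phase margin; the 12 dB budget is not cosmetic —
the true plant's small-signal slope spans roughly 2× around the secant, so
6 dB is consumed by linearisation error before any safety margin.  The
frozen result is kp = 4, ki = 100, kd = 0.  Without the margin constraint
the grid drifts to very high integral gain, which on this idealised
one-pole plant out-tracks every adaptive scheme — a regime with no margin
against the gain spread and no hardware plausibility.

## Metrics

Windowed RMS error uses non-overlapping 20 s windows (45 points over a
900 s run); the steady-state figure is the mean of windowed RMS over the
final 320 s.  The element-count sweep re-runs the nonlinear-cerebellum
scheme for ν = 0…8 with thresholds spread evenly over [2.18, 3.38] V
(ν = 5 recovers the standard thresholds) under a shared seed, and reports
the smallest ν within 10% of the ν = 8 error.

## What the synthetic study does and does not show

The generator emulates the phenomenology that drives the control problem —
supralinear static map, 100 ms lag, slow creep, sensor noise — not the
electromechanics of a real DEA.  Hysteresis, temperature sensitivity,
inter-sample variability and failure modes are absent, so passing tests
demonstrate properties of the *algorithm* under the modelled difficulty,
not performance guarantees on hardware.  Quantitative steady-state errors
depend on the plant calibration, which is reconstructed (see above) rather
than identified from data; the observed values agree with the published
ones within about a factor of two for most schemes, and the comparison is
most faithful at the level of its qualitative claims: a nonlinear basis
(in cerebellum or brainstem) is required for full-range tracking, creep
forces unbounded cerebellar output unless transfer of training unloads it
into the brainstem, and transfer leaves the learned recruitment curve
approximating the plant's inverse.

Known residual discrepancies, with the cause as we understand it:

* The linear scheme (one) degrades less, relative to the nonlinear schemes,
  than published.  Two structural reasons: the min/max-rescaled Gaussian
  reference rarely visits the extremes where a linear controller fails
  hardest, and a linear-filter cerebellum plus command clipping inside the
  recurrent loop is more expressive than a static-gain analysis suggests.
* Scheme six's transfer (ζ = 0.01) converges the recruitment gains well
  inside the heavily-visited range but leaves the top thresholds
  (ρ ≥ 1.275 mm, visited a few percent of the time) under-trained after
  900 s, so its error does not quite fall below scheme five's and the
  learned inverse deviates above ~1.3 mm.
* With the 0.02 mm noise in the feedback path, adaptive-scheme errors
  bottom out near 0.025–0.03 mm (learning misadjustment plus creep
  tracking); the two published 0.011 mm figures are therefore reproduced
  only to a factor of ~2.2–2.7.

## Numerical details

* All filters are realised as explicit per-sample recursions with owned
  state; runs are bit-exactly reproducible for a given seed (reference,
  plant noise and whitening pre-run draw from independent streams spawned
  from the run seed).
* The spline SNL inverse polishes the interpolated inverse with Newton
  steps on the forward map (round trip ≤ 1e−8 mm); the quadratic SNL
  inverts in closed form.
* Commands are clipped to [0, u_max] at the loop level and again inside the
  plant; the efference copy is the clipped command actually issued.
* Non-finite errors or fibre signals freeze learning for that sample and
  log a diagnostic rather than poisoning the weights.
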