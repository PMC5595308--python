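# Methods

## Model structure and assumptions

The channel is represented by four independent four-state voltage-sensor
chains (S ⇌ D ⇌ A ⇌ X per domain) coupled through a single interaction:
charge immobilization, in which the DIII deactivation rate β₃(V) is
multiplied by the fraction of DIV sensors *not* fast-inactivated. The
16-dimensional occupancy ODE is therefore linear at fixed voltage except for
that one bilinear term. The tetrameric form trades the 4⁴ = 256-state
expanded Markov chain for 16 states; the cost is that inter-sensor
cooperativity beyond the DIII–DIV term is assumed to be absorbed into the
empirically fitted rates.

Assumptions worth stating explicitly:

* **DI ≡ DII.** The first two sensors share identical rate laws; the
  parameter-fitting module enforces this as an equality constraint after
  every search step.
* **Charge bookkeeping.** Only D ⇌ A carries gating charge. DIII and DIV
  fluxes are weighted 1.5× relative to DI/DII, giving 20/20/30/30 % charge
  shares on a complete transfer. S ⇌ D and A ⇌ X are charge-silent even
  though some of their rates are voltage-dependent; this is a deliberate
  simplification of the synthesis rule, not an oversight.
* **Pore rule.** `P_open = A_DI·A_DII·A_DIII·(1 − I_DIV)`. The alternative
  that also requires DIV activation (`pore_rule="product4"`) is available
  but rejected as the default: it collapses the persistent-current fractions
  by two orders of magnitude and roughly halves the acidosis shift of the
  CF/EK conductance midpoint, both in clear conflict with the behaviour the
  parameter sets are meant to express.
* **Voltage clamp.** The command is piecewise constant; the membrane sees an
  exponentially filtered version with time constant `clamp_tau` (default
  0.05 ms, configurable, τ → 0 supported). The default mimics a fast
  cut-open clamp; the value is a package choice, as no settling constant is
  tabulated.

## Coupling and topology options

Two printed forms of the immobilization coupling coexist; both are
implemented and the choice is recorded in every trajectory's metadata:

* `coupling="text"` (default): deactivation flux `β₃·(1 − I_DIV)·A_DIII`.
* `coupling="table"`: the literal occupancy difference `β₃·(A_DIII −
  I_DIV)`, floored at zero. Its stationary state is solved in closed form
  from flux balance, with a boundary branch for the regime where the floor
  is active (S/D drain completely).

The DIV inactivated state's exit path is likewise configurable:

* `div_recovery="chain"` (default): the literal chain, I → A at the constant
  rate FR only. This is the printed model definition, but it makes recovery
  from fast inactivation voltage-independent and slow (τ = 1/FR = 500 ms for
  CF at pH 7.4) — far slower than the few-to-tens-of-ms,
  hyperpolarization-accelerated recovery sodium channels show.
* `div_recovery="deactivation"`: adds I → D at the voltage-dependent β₄
  rate, i.e. the inactivated sensor may deactivate directly. This restores
  millisecond-scale recovery (τ ≈ 1/β₄: ~1 ms at −130 mV, ~40 ms at −90 mV)
  and counts the I → D flux as inward gating charge at the DIV weight, since
  it moves the sensor down across the charge-carrying step. The added edge
  breaks detailed balance (the DIV graph becomes a cycle), so its stationary
  state is computed as a linear-system null vector rather than by the
  chain recursion.

None of the headline quantities (persistent currents, GV/QV midpoints and
their shifts) is sensitive to this choice — they are governed by forward
inactivation and activation — so the default stays with the literal chain
and the recovery-time-course example opts into `"deactivation"`.

## Numerics

* Integration: `scipy.integrate.solve_ivp` with BDF, rtol 1e-8 / atol 1e-10
  defaults (configurable). The system is stiff: α₁ approaches 2×10⁵ ms⁻¹ at
  +60 mV while relaxation rates sit near 10⁻⁵ ms⁻¹.
* Output sampling: 0.02 ms (50 kHz-equivalent) by default; slow protocols
  use coarser grids. After each protocol segment the per-domain occupancies
  are renormalised to sum to one, which keeps conservation drift below
  1e-9 over multi-segment sweeps.
* Equilibria: per-domain stationary distributions are closed form (detailed
  balance along the chain, with explicit handling of irreversible and
  disconnected bonds using the "reachable from rest" convention); the
  DIII ← DIV coupling is resolved by fixed-point iteration, which settles in
  two passes because DIV is autonomous.
* Peak detection: signed extremum after a blanking window of 3·clamp_tau
  (the clamp-settling period), after a 0.1 ms boxcar that emulates the
  10 kHz recording filter; without it, single-sample noise spikes bias the
  peak of noisy sweeps.
* Conductance conversion G = I_peak/(V − E_rev) excludes steps within 5 mV
  of the reversal potential, where the near-zero driving force amplifies
  noise without bounding information. E_rev defaults to +58 mV (Nernst,
  96 mM/9.6 mM sodium at 293 K).
* Curve fits are bounded nonlinear least squares (`scipy.optimize`) with
  time constants and Hill coefficients in log space and a fixed-seed
  3-start multi-start for the exponential and Hill problems. Biexponential
  fits with a tau ratio under 1.5 are flagged degenerate rather than
  rejected.

## Parameter search

The two-stage search (generational GA, then coordinate-wise hill climbing)
operates on named rate-law coefficients (`alpha3.term0.amplitude`, …) in
log₁₀ space, reflecting the ten-decade spread of the rate table. GA
defaults: population 24, tournament size 3, BLX-α crossover (α = 0.25),
log-normal mutation σ = 0.15 decades, 2 elites. Hill climbing probes each
coordinate ±step on a shrinking schedule (0.1 → 0.003 decades) and accepts
only improvements, so its result never degrades the GA's. The objective is
the RMS deviation between peak-normalised simulated and target current
families; normalisation removes g_max as a nuisance parameter. These
operator choices are package defaults — no published hyper-parameters exist
to match — and everything is configurable and seeded.

The recovery benchmark (×2-perturbed DIII amplitudes, five-sweep GV target
on a 0.05 ms grid, rtol 1e-6) converges in ≈200 objective evaluations and
recovers both coefficients within ~1 %; the problem sizes were chosen to
keep a full run in the order of a minute on one CPU.

## Synthetic recordings

`synth` adds white Gaussian noise, ohmic leak (`g_leak·V`) and exponential
capacitive transients at each command step, then corrects with P/N
subtraction using N channel-free pulses scaled to 1/N — an idealisation of
the real procedure in two ways: the sub-pulses contain *no* channel current
at all (real sub-threshold pulses may gate a little charge), and the noise
is white (no 1/f or line components). Noiseless corrections are therefore
exact by linearity, and noisy corrected traces carry the predicted
(1 + N)·sd² per-sample variance. What passing these tests shows is that the
estimators tolerate realistic noise amplitudes and artifact shapes; it does
not certify behaviour against correlated noise, series-resistance error, or
endogenous currents, none of which are emulated.

## Known limitations

* The conductance midpoint of the CF parameter sets shifts by ≈6.5 mV
  between pH 7.4 and 6.0 under every analysis variant tried (coupling form,
  clamp τ 0–0.5 ms, fit window), larger than the ≈4 mV the experiments
  report for that construct; the CF/EK sets reproduce their ≈8.5 mV shift
  well. The package reports what the rate table produces.
* Proton block of maximal conductance is not part of the model (pH enters
  only through the separate rate tables), so absolute current amplitudes do
  not fall at pH 6.0 the way recorded currents do; analyses here are
  normalised, where this cancels.
* Under the default `chain` topology, recovery from fast inactivation is
  unrealistically slow (see above). Use `div_recovery="deactivation"` for
  recovery-kinetics work.
* Only the four printed conditions are parameterised; there is no pH 7.0
  column and no temperature scaling of rates (temperature enters only the
  Boltzmann fit).
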