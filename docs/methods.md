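# Methods

## Relaxation model

The system is a two-state binding equilibrium E + L ⇌ EL observed by
tryptophan fluorescence after a rapid (nanosecond) temperature jump. For a
small perturbation of a single bimolecular step, the relaxation toward the
new equilibrium is exponential with rate

    k_obs = k_on ([E]_free + [L]_free) + k_off,

free concentrations taken at the post-jump temperature. Observed transients
additionally contain a slower phase from conformational exchange that is
not coupled to binding, so each transient is modeled as

    F(t) = F₀ [1 + A_fast (1 − e^(−k_fast t)) + A_slow (1 − e^(−k_slow t))] + ε(t),

with i.i.d. Gaussian noise ε of standard deviation `noise_sd·F₀`. Rising
saturating exponentials are used because heating promotes dissociation and
thereby relieves Trp quenching (the signal increases after the jump);
amplitudes are signed, so decaying phases are representable.

## Binding equilibrium

`binding.adjust_kd` moves a calorimetric dissociation constant from its
reference temperature with the integrated van 't Hoff relation at constant
association enthalpy ΔH (ITC sign convention; R = 1.98720425×10⁻³ kcal
mol⁻¹ K⁻¹). A ΔC_p hook exists but defaults to zero: ITC reports K_d and ΔH,
and over a 7 °C jump the curvature term is negligible relative to the other
uncertainties. `binding.free_concentrations` solves the mass-action
quadratic for [EL] through the numerically stable product form
(2·E_t·L_t)/(b + √(b² − 4·E_t·L_t)), which avoids cancellation when
K_d ≪ totals; mass conservation and the K_d residual hold to 1×10⁻⁹
relative (property-tested).

## Transient processing

Processing follows the standard free-Trp-reference protocol:

1. **Reference subtraction.** The free-tryptophan reference transient is
   resampled onto the sample grid, scaled so its pre-jump intensity matches
   the sample's (scale recorded in the output metadata), and subtracted.
   This removes the intrinsic Trp temperature response *including* the
   baseline it carries, leaving a pure kinetic-change trace near zero.
2. **Normalization.** Samples are scaled so the pre-jump window mean equals
   100, i.e. the trace reads as percent of initial fluorescence. When a
   reference was subtracted, the corrected trace is instead expressed as
   percent of the sample's own pre-jump intensity and offset to start at
   100, landing both paths on the same scale. The pre-jump window is the
   first 1 % of points (configurable); the divisor and window are recorded
   in metadata so the correction is auditable.
3. **Double-exponential fit.** Unweighted least squares
   (`scipy.optimize.curve_fit`) of baseline + two rising exponentials, with
   a floating baseline. Initial guesses come from two-stage log-time
   peeling: the slow tail is log-linear-fitted on the late third of the
   trace, subtracted, and the residual fitted on the early third. Rates are
   reported sorted descending with standard errors from the fit covariance.
   Degenerate cases are flagged rather than hidden: near-zero amplitudes
   ("not identifiable"), k_fast/k_slow < 1.5 ("rate collapse"), and a time
   window shorter than 3/k_slow. Replicates are fitted individually (one
   row per transient), matching a design in which the pooled statistics are
   formed over all n = concentrations × replicates fits.

## Concentration-dependence analysis

For each converged fit, the free-concentration sum at the final temperature
is computed from the configured binding parameters. Each phase's Pearson r
against that sum is compared with two-tailed critical values

    r_crit = t_c / √(t_c² + DF),  DF = n − 2,

at 99 %/90 %/80 % confidence (0.505/0.337/0.265 at DF = 23). Two-tailed
quantiles are used because they reproduce all three reference thresholds;
one-tailed quantiles do not. Verdicts: r ≥ r_crit(99 %) → dependent;
r_crit(99 %) > r ≥ r_crit(90 %) → weakly dependent; otherwise independent.
Any negative r is classified independent — a binding step cannot slow down
with increasing free concentration, so a negative sample correlation is
noise. An independent oracle for the thresholds (r² ~ Beta(½, DF/2) under
the null) is kept in the tests.

k_on and k_off are the slope and intercept of an unweighted OLS line of
k_fast against the concentration sum; they are withheld entirely when the
fast phase classifies as independent, since the regression would then have
no mechanistic meaning. K_d(kinetic) = k_off/k_on. Slow rates are pooled
with the arithmetic mean and the sample (n−1) standard deviation.

## Equilibrium characterization

* **Band integration** is trapezoidal with linear interpolation at the band
  edges (matching a 327–353 nm bandpass exactly even on a coarse grid);
  complex intensities are reported as percent of the apoenzyme integral.
* **Temperature series** are normalized to 1 at the lowest temperature and
  the normalized free-Trp reference is subtracted, so the output is a
  change-in-intensity series that is exactly 0 at the lowest temperature.
  The alternative subtract-then-normalize order is available behind a flag;
  normalize-then-subtract is the default because it makes the correction
  independent of the two series' absolute scales.
* **Melt fitting** uses a four-parameter logistic (two baselines, midpoint
  T_m, width). Fits are flagged non-converged when the optimizer fails,
  T_m falls outside the measured range, or the transition amplitude is not
  resolved above 4× the residual RMS (a flat curve has no midpoint).
* **Relative activity** is the ratio of early-time OLS slopes of 340 nm
  absorbance traces; the default window is the first 10 % of points or the
  longest early segment with R² ≥ 0.99, whichever is shorter (minimum 3
  points).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:
five ligand concentrations up to 200 μM at 100 μM enzyme, five replicates,
a 29→36 °C jump, a fast phase obeying the relaxation line, a
concentration-independent slow phase, an intrinsic Trp background that
steps down on heating, and i.i.d. Gaussian noise. Key defaults and their
rationale:

| parameter | default | rationale |
|---|---|---|
| k_on | 31 μM⁻¹ s⁻¹ | representative folate association rate |
| k_off | 1100 s⁻¹ | representative dissociation rate |
| k_slow | 400 s⁻¹ | representative conformational rate, ≥2× separated from every realized k_fast |
| K_d(ref), ΔH | 4.7 μM at 29 °C, −10 kcal/mol | calorimetric K_d; the enthalpy is a placeholder typical of exothermic folate binding and must be user-supplied for real data |
| amp_fast, amp_slow | +0.10, +0.08 | equilibrium folate binding quenches the Trp signal by roughly half, so a dissociation-driven post-jump change of order 10 % is realistic and gives the signal-to-noise under which the 5×5 design recovers rates to a few percent |
| noise_sd | 0.01 | 1 % of the pre-jump intensity, a typical photomultiplier noise floor |
| time grid | 1000 log-spaced points, 1 μs–10 ms | resolves rates from ~10² to ~10⁶ s⁻¹; the grid is post-jump only, the heating step being effectively instantaneous |
| ligand_totals | 25–200 μM | a titration bracketing the enzyme concentration; no zero-ligand sample, since the study design is a binary-complex titration |

Not modeled: photophysics (excimers, FRET), instrument response,
correlated detector noise, photobleaching, and any coupling between the
slow phase and concentration. Passing recovery tests therefore demonstrate
the *estimator's* correctness under the assumed noise model, not robustness
to every artifact of real instruments.

## Problem sizes and numerical choices

The standard analyses run 25 transient fits of 1000 points each; the
repeated-recovery check averages 20 such titrations, and melt-recovery
statistics use 100 noisy curves — sizes chosen so the full suite completes
in seconds while estimator bias stays well below the reported tolerances.
Fit rates are bounded below by 0.01/t_span to keep the optimizer away from
degenerate zero-rate solutions; ties between phases are resolved by sorting
rates descending after the fit. Seeded `numpy.random.default_rng` streams
drive all noise; per-sample seeds derive from one master seed via
`numpy.random.SeedSequence`, so datasets are byte-reproducible.

## Known limitations

* The double-exponential fit assumes well-separated phases; the generator
  enforces a ≥2× separation, and closer rates trigger a warning rather
  than a refusal.
* The van 't Hoff correction is constant-ΔH; for jumps much larger than a
  few degrees, or proteins with large ΔC_p of binding, supply `delta_Cp`.
* The correlation classification treats fits as independent observations;
  replicate correlation (e.g. shared sample preparation) is not modeled.
* Per-point fit weights are not supported: transients carry no per-point
  uncertainty estimates in this protocol.
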