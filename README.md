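# trelax

Analysis of laser temperature-jump (T-jump) fluorescence relaxation kinetics
for a two-state enzyme–ligand binding system with coupled conformational
exchange, together with the equilibrium characterization that accompanies
such a study (emission-band integration, CD thermal melts, relative
activity).

The package is written for biophysicists analyzing tryptophan-probed T-jump
transients of enzymes such as dihydrofolate reductase (DHFR) binding folate:
single-Trp variants report local environment changes, and the relaxation
after a nanosecond heating pulse carries both the ligand binding/unbinding
step and slower conformational motions.

## The model

A rapid jump from 29 to 36 °C perturbs the binding equilibrium
E + L ⇌ EL. Each fluorescence transient is corrected for the intrinsic
temperature response of tryptophan (measured on free Trp), normalized to
100 at its initial intensity, and fit to a double exponential

```
F(t) = F₀ + A_fast (1 − e^(−k_fast t)) + A_slow (1 − e^(−k_slow t))
```

For a single bimolecular binding step, chemical relaxation theory gives

```
k_fast = k_on ([E]_free + [L]_free) + k_off
```

with the free concentrations evaluated at the post-jump temperature using
the van 't Hoff-adjusted calorimetric K_d. Across a titration, each phase
is classified by the significance of its Pearson correlation r with the
free-concentration sum (two-tailed critical values
r_crit = t_c/√(t_c² + DF), e.g. 0.505 at 99 % confidence for DF = 23). A
concentration-dependent fast phase is regressed to give k_on (slope) and
k_off (intercept), hence K_d = k_off/k_on; the concentration-independent
slow phase is pooled into a single mean rate. Equilibrium-side routines
integrate Trp emission bands (percent-of-apoenzyme quenching), fit
sigmoidal CD melts for T_m, and compute relative activity from 340 nm
NADPH absorbance slopes.

Because no raw transients are deposited for such studies, the package
includes a first-class synthetic-data module that generates transients,
reference traces, spectra, melts and activity traces with known ground
truth, so the whole pipeline is testable end to end.

## Worked example

`examples/03_full_titration_analysis.py` simulates the standard design —
five folate concentrations up to 200 μM at 100 μM enzyme, five replicates,
1 % noise — fits all 25 transients and runs the concentration-dependence
analysis:

```
n = 25 fits, DF = 23
critical r: 0.505 (99%), 0.337 (90%), 0.265 (80%)
fast phase: r = 0.963 -> dependent
slow phase: r = -0.197 -> independent
k_on  = 30.5 +/- 1.8 uM^-1 s^-1   (true 31)
k_off = 1147 +/- 137 s^-1        (true 1100)
Kd from rates = 37.7 uM vs ITC 4.7 uM (ratio 8.0: ...)
pooled slow rate = 404 +/- 46 s^-1 (true 400)
```

The fast phase clears the 99 % significance threshold (binding-coupled);
the slow phase does not (a conformational event), so its 25 rates are
pooled. The kinetic K_d exceeding the calorimetric one signals that the
fast phase is convolved with conformational change rather than being pure
binding. The other examples cover the binding equilibrium
(`01_binding_equilibrium.py`), a single transient fit
(`02_fit_one_transient.py`) and the equilibrium characterization
(`04_equilibrium_characterization.py`).

A thin CLI wraps the same stages for shell use:

```bash
trelax simulate --outdir data --seed 1 --label wt
trelax fit-transients --datadir data --out fits.csv
trelax analyze --fits fits.csv --config analysis.yaml --outdir out
trelax equilibrium --config equilibrium.yaml --outdir out
```

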