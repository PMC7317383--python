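# Methods

## Signal model

The package models N exchanging proton pools coupled to water.  Mobile
pools carry (Mx, My, Mz); semisolid pools carry Mz only plus an
absorption lineshape.  All magnetizations are normalized to water's
equilibrium value, so the water pool has m0r = 1 and the semisolid m0r
is the pool size ratio (PSR).  Exchange is water-centric (no
solute–solute coupling) and obeys detailed balance,
k_water→s = k_s→water · m0r_s.  Transverse water magnetization exchanges
with mobile solutes only; the semisolid pool has no transverse state to
receive it.

During RF irradiation the state evolves as dM/dt = (R_L + W)M − R_L·M0.
W contains, per mobile pool, the 2πΔ precession block (Δ = Δω − δs,
converted from ppm at the configured centre frequency, 127.7 MHz by
default) and the ±ω1 y↔z nutation; per semisolid pool it contains
−π·ω1²·g(Δ, T2M) on the diagonal.  Lineshapes (units: seconds,
normalized to unit integral over angular frequency):

* Lorentzian: (T2/π) / (1 + (2πΔT2)²)
* Gaussian: (T2/√(2π)) · exp(−(2πΔT2)²/2)
* super-Lorentzian: the orientation average
  ∫₀^{π/2} sinθ √(2/π) (T2/|3cos²θ−1|) exp(−2(2πΔT2/(3cos²θ−1))²) dθ,
  evaluated with a fixed 512-point Gauss–Legendre rule.

The super-Lorentzian diverges on resonance; for |Δ| below a configurable
1 kHz cutoff it is replaced by a cubic in |Δ| anchored at samples in
[1, 1.5] kHz, the standard qMT practice.  The cap deliberately removes
the integrable on-resonance spike; at T2M = 10 µs that spike carries
about 2% of the lineshape's area, so the *capped* curve integrates to
≈0.98 while the functional form itself integrates to 1.

### Pulsed steady state

One acquisition shot is: saturation train (t_m) → spoil → gap (t_s) →
spoil + instantaneous excitation (flip α, semisolid z scaled by cos α)
→ readout/recovery (t_r) → spoil.  Spoiling zeroes transverse
components; because the spoiler precedes the excitation, the sin α
transverse entries of the excitation matrix act on zero and the readout
duration is folded into t_r (a 2D spoiled-gradient-echo readout is short
relative to the shot).  Free intervals relax toward equilibrium under
R_L alone.  Every interval is an affine map M → AM + c; the periodic
steady state is the fixed point of the composed cycle, obtained by one
linear solve, and the reported signal is the water Mz immediately before
excitation normalized by its value at the reference offset (800 ppm).
A singular cycle matrix is reported as a non-convergent sequence
configuration rather than silently regularized.

The shaped train enters through its continuous-wave equivalent pulse:
the constant amplitude with the same mean-square ω1 (average power) as
the train over the full period including gaps.  For a Gaussian pulse the
shape is truncated at ±3σ (σ = duration/6) and the flip angle fixes the
peak via γ∫B1 dt.  An average-amplitude CWEP mode is available.  Matrix
exponentials use scaling-and-squaring with Padé approximation
(`scipy.linalg.expm`).

### Time-stepped oracle

`simulate_zspectrum_timestepped` integrates the same equations with the
shaped B1(t) sampled piecewise-constant (dt ≤ pulse_dur/50), keeps
off-resonance precession during intra-train gaps (no spoiler fires
inside the train), composes one shot into a single affine map and
iterates shots to a 1e-8 shot-to-shot tolerance.  In the
block-pulse/100%-duty limit it agrees with the closed form to better
than 1e-6, which validates both code paths against each other.

**CWEP validity.**  At the reference settings (fifty 20-ms Gaussian
pulses, 50% duty, 180° per-pulse flip) the CWEP spectrum tracks the
shaped-pulse oracle to < 0.01 absolute Z for |Δω| ≥ 1 ppm.  Inside
±1 ppm the per-pulse rotations partially invert water and interfere
coherently across gaps — physics an average-power reduction cannot
represent — and the discrepancy grows to ≈0.16 near ±0.4 ppm.  The
deviation is dt-converged and is made worse, not better, by spoiling
between pulses.  Conclusions drawn from the model inside ±1 ppm of
water rest on the CWEP approximation, not on the shaped-pulse physics.

## Fitting

Per voxel the normalized spectrum is fit by maximizing a Gaussian
posterior: additive Gaussian noise on the normalized signal times
priors on the free parameters.  Positive parameters (m0r, k, T2) are
estimated on the log scale with log-normal priors; B0 is linear.
Defaults: one decade (sd of ln-value = ln 10) on m0r and k, half a
decade on T2, N(0, 0.1 ppm) on B0.  Pool T1 values are fixed — water
T1 to the observed T1 map where supplied — and the relative transmit
field scales both the saturation amplitude and the excitation flip.
Optimization is Levenberg–Marquardt on the stacked (whitened data +
prior) residual with three starts jittered within the priors (fixed
seed); posterior sds are Laplace approximations from the Gauss–Newton
Hessian at the optimum, delta-transformed back to natural units.  When
the noise sd is not supplied it is re-estimated once from the data
residuals, floored at 5e-4 (the reproducibility level of a normalized
spectrum) so that priors are never swamped on noiseless inputs.

For two-pool and MT-containing analyses the package also provides a
qMT-anchored prior set (`qmt_informative_priors`): 0.15 decade (≈±40%)
on the semisolid exchange rate and T2M, whose in-vivo and gel ranges are
well characterised, and half a decade on PSR.  With single-power
saturation data the product m0r·k is identified but the factors are
not; with fully diffuse priors a two-pool fit of CEST-contaminated data
can ride this ridge to nonphysical PSR values, so the bootstrap and
recovery experiments use the anchored set.  The derived CEST quantity
reported throughout is MTR\*: the difference at the pool offset between
an idealized one-pool and two-pool spectrum (water T1/T2 = 1.0 s/140 ms;
amide 1 s/10 ms; NOE 1 s/5 ms) simulated with the fitted (m0r, k) under
the same scheme, in percent.  MTR\* depends on the identified flux and
is stable where m0r and k separately are not.

T1 estimation supports magnitude inversion-recovery
(|a(1 − 2e^{−TI/T1})|) and variable-flip-angle spoiled-gradient-echo
fits.

## Pool templates and synthetic data

`brain_7pool` (white-matter-like, super-Lorentzian semisolid):

| pool | δ (ppm) | T1 (s) | T2 | m0r | k→water (1/s) |
|---|---|---|---|---|---|
| water | 0 | 1.0 | 70 ms | 1 | — |
| amide | +3.5 | 1.0 | 10 ms | 0.005302 | 30 |
| creatine | +2.0 | 1.0 | 10 ms | 0.001 | 1000 |
| NOE ×3 | −1.75/−2.5/−3.5 | 1.0 | 2 ms | 0.005 each | 20 |
| semisolid | −2.34 | 1.0 | 10 µs | 0.20 | 20 |

Shifts, rates and T2 values are standard literature conventions: slow
base-catalysed amide exchange, fast guanidinium exchange (~1000 1/s,
hence invisible at these low powers), a slow broad aliphatic NOE band,
and a 20% semisolid fraction with its line displaced upfield of water.
The amide fraction is fixed so that the idealized amide MTR\* under the
reference scheme is 11.0%, a representative white-matter effect size.
`brain_5pool_hydroxyl` adds a +1.0 ppm pool exchanging at 2000 1/s.
Fitting templates centre the semisolid line at 0 ppm (two-pool qMT
convention); the truth-vs-template mis-centring is deliberately part of
the "mis-modelled semisolid pool" mechanism under study.

`bsa_agarose` maps tube concentrations linearly onto pools: BSA (% w/v)
→ amide and NOE fractions (9% BSA ≡ the brain amide fraction; NOE 1.5×
amide), agarose → a Gaussian-lineshape semisolid fraction (0.03 per %)
and both onto water relaxation rates.  This calibration is a synthetic
convention chosen once for realism — zero concentration gives zero pool
fraction and all maps are monotone — not a measured relation; tests
built on it demonstrate *recovery of a known monotone design*, not
agreement with any particular protein preparation.  Phantom images are
simulated voxel-wise with optional smooth second-order-polynomial B0
(bounded amplitude, default 0.05 ppm) and B1 (mean 1, default ±5%)
fields and seeded Gaussian noise on the normalized signal (default sd
0.005, a typical 3 T SNR).  What the generator does not emulate:
Rician noise, partial volume at tube edges, motion, drift, and
coil/readout effects — so passing recovery tests show correctness of
the estimator under its own noise model, not robustness to real
acquisition artefacts.

Acquisition schedules mirror the reference protocols: a 36-point
uniform ±5 ppm grid plus MT offsets {7.5, 15, 30, 60, 100} ppm at 180°
and 540° (simulation), and a 41-point asymmetric ±4.5 ppm grid densified
near ±3.5 ppm with the same MT offsets at 184°/540° (in-vivo-like); each
carries 800-ppm reference points per power.

## Experiments

* **Seven-pool underfitting** (`run_seven_pool_bias`): simulate the
  seven-pool truth noiselessly on the simulation schedule, fit water +
  amide + semisolid with the default priors, report fitted vs true PSR
  and amide MTR\*.  Deterministic given the seed.
* **Offset-removal bootstrap** (`run_bootstrap_experiment`): four-pool
  truth (6% BSA / 0.65% agarose), 20 noisy replicates at sd 0.005;
  two-pool fits at nested pseudo-random CEST subsets of 41/31/21/11/1
  offsets (MT and reference points always retained, removal uniform
  without replacement, subsets nested so the trend is interpretable),
  with the full-data B0 posterior as the B0 prior for reduced fits,
  against a qMT-only fit.  Summaries: per-count PSR, |mean bias| vs
  qMT-only, and rank-sum p-values.
* **Concentration correlations**: six-tube variable-BSA series fit with
  the four-pool model at ROI-mean noise (sd 0.001); fitted amide MTR\*
  regressed on concentration (R², slope-t p via ordinary least
  squares).  Wilcoxon rank-sum comparisons use the exact distribution
  for small untied samples and the tie-corrected normal approximation
  otherwise.

Problem sizes (50 recovery replicates, 20 bootstrap replicates, 6
tubes, 100 random systems in the fixed-point sweep) were chosen so the
whole suite runs in minutes on a single core while keeping Monte-Carlo
error well below the asserted margins.

## Known limitations

* Single-power saturation data leave m0r and k individually weakly
  identified; point estimates of PSR from MT-contaminated fits depend
  visibly on prior width.  MTR\* is the robust derived quantity.
* The CWEP closed form is quantitatively wrong within ±1 ppm of water
  at 180°-class pulse trains (see above).
* In the offset-removal experiment the |bias| of the two-pool PSR is
  *not* monotone in the number of retained CEST offsets under these
  synthetic conditions: with many retained offsets the single broad
  semisolid line must compromise across conflicting clean and
  contaminated points, while with ~11–21 retained offsets the narrow
  amide/NOE dips can be absorbed with little resistance, so the bias
  peaks at intermediate counts.  Every CEST-containing subset remains
  strongly significantly biased relative to the qMT-only fit.
* Gradient/diffusion effects, imperfect spoiling, relaxation during the
  excitation pulse, dipolar-order (Provotorov) saturation and Rician
  noise are out of scope.
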