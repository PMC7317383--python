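# cestqmt

Quantitative modelling of **chemical exchange saturation transfer (CEST)**
and **magnetization transfer (MT)** MRI from a single generalized N-pool
Bloch–McConnell model — and the machinery to show how *underfitting* (too
few CEST pools, or a mis-modelled semisolid pool) biases both the CEST
effect sizes and the qMT parameters.

It is written for quantitative-MRI researchers who fit pulsed-saturation
Z-spectra: people who want PSR, k_MF and T2M on the same footing as the
qMT literature while also estimating amide and NOE exchange effects, and
who need to know when a simplified model corrupts those numbers.

## The model

Each proton pool is either *mobile* (full (Mx, My, Mz) magnetization) or
*semisolid* (Mz only, with an absorption lineshape g(Δ, T2M) —
Lorentzian, Gaussian, or super-Lorentzian).  Exchange is water-centric
with detailed balance k_FS = k_SF·M0,rS.  The coupled equations are
linear, dM/dt = (R_L + W)M − R_L·M0, with R_L holding relaxation and
exchange and W the RF terms: 2πΔ precession and ω1 = γB1 nutation for
mobile pools, and the saturation rate π·ω1²·g(Δ, T2M) for semisolid
pools.

A pulsed acquisition shot is the sequence *saturation train (t_m) → spoil
→ gap (t_s) → excitation (α) → readout/recovery (t_r)*.  The shaped
train is reduced to its continuous-wave equivalent pulse (CWEP, matched
average power), each interval becomes an affine map on the state vector,
and the **periodic steady state is the exact fixed point of the composed
cycle**, obtained by one linear solve.  A time-stepped integrator that
plays out the shaped B1(t) directly serves as the verification oracle.

On top of the forward model:

* **Voxel-wise MAP fitting** with Gaussian/log-normal priors (Laplace
  posterior sds), observed-T1 and relative-B1 maps as per-voxel priors,
  and a common B0 offset per voxel.  Variants: `cest_mt` (all pools
  simultaneously), `qmt_fix` (two-stage: water+semisolid from the
  |Δω| > 5 ppm points, then fixed while fitting the CEST pools), and a
  merged NOE+MT two-pool reduction.
* **MTR\*** — the idealized two-pool CEST effect size computed from a
  fitted (m0r, k) pair, the quantity that stays identified when m0r and
  k individually do not.
* **Digital phantoms** — BSA/agarose tube series and brain-like
  multi-pool templates with smooth B0/B1 field maps and seeded noise.
* **Bias experiments** — seven-pool truth vs three-pool fit, and the
  CEST-offset-removal bootstrap of the two-pool qMT analysis.

## Worked example

```python
import numpy as np
from cestqmt import *

system   = make_pool_system("brain_7pool").without("creatine", "noe1", "noe2")
scheme   = SaturationScheme(sat_flip_deg=180.0, exc_flip_deg=7.0)
schedule = sim_schedule()          # ±5 ppm CEST grid + 7.5–100 ppm MT points
z = simulate_zspectrum(system, scheme, schedule)
for off in (-3.5, 3.5, 15.0):
    i = int(np.argmin(np.abs(schedule.offsets_ppm - off)))
    print(f"Z({schedule.offsets_ppm[i]:+.2f} ppm) = {z.values[i]:.3f}")
print(f"MTR*(amide) = {mtr_star(0.005302, 30.0, scheme, 3.5):.1f} %")

est = fit_spectrum(z, schedule, FitConfig(system=system, scheme=scheme))
print(f"fitted PSR = {100*est.psr:.2f} %  (truth 20.00 %)")
print(f"fitted k_MF = {est.system.get('semisolid').k_to_water:.1f} /s")
```

prints

```
Z(-3.57 ppm) = 0.789
Z(+3.57 ppm) = 0.784
Z(+15.00 ppm) = 0.915
MTR*(amide) = 11.0 %
fitted PSR = 20.00 %  (truth 20.00 %)
fitted k_MF = 20.0 /s
```

The Z values are the steady-state water signal at the amide (+3.5 ppm),
NOE (−3.5 ppm) and MT (15 ppm) sampling points, normalized by the
800-ppm reference.  MTR\* = 11.0% is the idealized amide effect size for
this white-matter-like system, and the matched-model fit recovers the
20% semisolid pool size ratio and its exchange rate exactly.  Fitting
the *same* data with a model that omits the NOE pools is what biases
PSR, k_MF, T2M and MTR\* — run `cestqmt bias-sim --out report.json` to
reproduce that experiment end to end.

A command-line surface (`cestqmt simulate|fit|mtrstar|bootstrap|phantom|bias-sim`)
wraps the same functions for NIfTI stacks, plain-text schedules and YAML
pool configurations.

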