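# ecsastro

Quantitative pipelines for two classic measurements of brain-tissue
micro-architecture and astrocyte physiology:

1. **Real-time iontophoresis (RTI / TMA⁺ method).**  A micropipette
   releases tetramethylammonium (TMA⁺) into tissue with a current pulse;
   an ion-selective microelectrode (ISM) 50–100 µm away records the
   concentration transient.  Fitting the transient with a point-source
   diffusion model yields the extracellular-space (ECS) **volume fraction
   α**, the **tortuosity λ** (λ² = free / apparent diffusion coefficient)
   and the **non-specific uptake rate k′** (s⁻¹).  These parameters track
   how much cells swell or shrink during, e.g., a high-K⁺ challenge.
2. **3D confocal morphometry.**  Fluorescent (EGFP) astrocytes are imaged
   as z-stack time series; projection, registration, photobleaching
   correction and Isodata segmentation turn each stack into a soma area
   Ss, and isotropic scaling gives the normalized soma volume
   **Vs ∝ Ss³ᐟ²**, expressed in % of the pre-treatment baseline.

Since such recordings come from animal experiments, a first-class
synthetic-data module generates both kinds of input with known ground
truth — diffusion voltage traces at the standard protocol (200 nA / 24 s
step on a 20 nA bias, 0.1 mM TMA⁺ background) and astrocyte z-stack
phantoms (0.41 × 0.41 × 0.5 µm voxels) that swell up to ~340% with
bleaching, drift and shot noise — so every stage of the analysis can be
validated end to end.

## The model

The concentration increment around a point source switched on at t = 0
in a porous medium is

```
C(r,t) = (Q λ²)/(8π D α r) · [ e^{+rλ√(k′/D)} erfc( rλ/(2√(Dt)) + √(k′t) )
                             + e^{−rλ√(k′/D)} erfc( rλ/(2√(Dt)) − √(k′t) ) ]
```

with source strength Q = I·n/(zF) (I: step current, n: electrode
transport number, F: Faraday constant).  A finite pulse is the
superposition of an on- and a delayed off-solution.  In free medium
(α = 1, λ = 1, k′ = 0) this reduces to C = Q/(4πDr)·erfc(r/(2√(Dt))), the
basis of the agar calibration that determines n and D before each tissue
measurement.  Tissue curves are then fitted for (α, λ, k′) by a bounded
Nelder–Mead simplex on the sum of squared residuals.  ISM voltages map to
concentrations through the Nikolski (Nicolsky–Eisenmann) equation
V = v0 + slope·log₁₀(c + interference), fitted per electrode from a
five-standard series (0.1–10 mM).

An independent radial finite-difference solver (`ecsastro.radial_fd`)
cross-checks the closed form against the underlying PDE
∂C/∂t = (D/λ²)∇²C − k′C + (Q/α)δ(r).

## Worked example

```python
import numpy as np
from ecsastro import (DiffusionParams, fit_tissue, preprocess_curve)
from ecsastro.synthetic_data import (CurveSimConfig, DEFAULT_CALIBRATION,
                                     simulate_diffusion_trace)

truth = DiffusionParams(alpha=0.19, lam=1.6, kprime=5e-3, D=1.2e-5,
                        n_transport=0.35)
cfg = CurveSimConfig(params_true=truth, noise_sigma_rel=0.02, seed=5)
trace = simulate_diffusion_trace(cfg)                       # voltage trace
curve = preprocess_curve(trace.voltage_mV, trace.times,
                         DEFAULT_CALIBRATION, cfg.source, t_on=0.0)
res = fit_tissue(curve, n=0.35, D=1.2e-5)
print(f"alpha={res.params.alpha:.3f} lambda={res.params.lam:.3f} "
      f"k'={res.params.kprime:.2e}")
# alpha=0.190 lambda=1.600 k'=4.93e-03
```

The fitted α = 0.190 is the fraction of tissue volume occupied by the
extracellular space (the generating truth was 0.19); λ = 1.60 says TMA⁺
diffuses (1.6)² ≈ 2.6× slower than in free solution; k′ ≈ 5×10⁻³ s⁻¹ is
the first-order loss of tracer from the ECS.

The experiment-level drivers under `analysis/` run the full study on
synthetic data (electrode calibration → agar calibration → high-K⁺
challenge on α → astrocyte swelling) and write tidy tables under
`results/`.  For example `python analysis/03_tissue_diffusion.py` prints

```
ctrl: alpha 0.189 -> 0.127 at 20 min (drop 33%), washout end 0.185 (recovery 94% of deficit)
sod1: alpha 0.194 -> 0.169 at 20 min (drop 13%), washout end 0.224 (recovery 219% of deficit)
```

i.e. the control group loses about a third of its ECS volume at the peak
of the 50 mM K⁺ challenge while the mutant group loses 13%, and the
mutant group overshoots its initial ECS volume during washout.

There is also a thin CLI (`ecsastro simdata|rti|morpho|report`) for
running the same steps on CSV traces and TIFF stacks from the shell.

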