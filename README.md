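# dcedot

Dynamic contrast-enhanced diffuse optical tomography (DCE-DOT) in 2-D:
simulate frequency-domain near-infrared measurements on arbitrarily shaped
phantoms, reconstruct absorption maps with four analysis methods, and
quantify how accurately each method recovers contrast-enhancement kinetics.

## The problem

Diffuse optical tomography recovers tissue absorption (μa) and reduced
scattering (μs′) from boundary measurements of multiply scattered light.
Because the inverse problem is severely ill-posed, absolute images are noisy
and quantitatively unreliable. Two remedies are studied here together:

* **differential (DCE) imaging** — inject a near-infrared absorber
  (e.g. indocyanine green), reconstruct every time frame, and subtract the
  pre-injection baseline image, cancelling model and instrument errors that
  are common to both frames; and
* **anatomical priors** — constrain the inversion with a region map from a
  co-registered high-resolution modality (MR-like masks here), penalising
  within-region variation of the solution.

The package reproduces the computational core of that comparison: which
combination of data type, coupling handling and prior yields enhancement
estimates that are *linear* in contrast-agent concentration and therefore
trustworthy kinetics.

## Model

Light transport is the frequency-domain diffusion equation on a 2-D domain,

∇·[D∇Φ] − (μa + iω/c_n)Φ = −q₀,  D = 1/[3(μa+μs′)],

with the Robin boundary condition Φ + 2AD ∂Φ/∂n = 0 and measured flux
φ = Φ/2A (A ≈ 2.95 for a tissue–air index mismatch of 1.4). It is solved by
linear-triangle FEM; 8 sources and 8 detectors in a fan-beam geometry give
64 amplitude + 64 phase data per frame. Images are found by
Levenberg–Marquardt iteration

X⁽ᵐ⁺¹⁾ = X⁽ᵐ⁾ + (JᵀJ + λR)⁻¹ Jᵀε,

with the adjoint-method Jacobian J, residual ε in log-amplitude/phase space,
and R either the identity or LᵀL built from region labels
(L_ii = 1, L_ij = −1/N_r within a region, 0 across regions). Four analysis
methods are dispatched:

| Method | data | unknowns | prior |
|---|---|---|---|
| 1 | 64 log-amp + 64 phase | μa and μs′ | identity |
| 2 | 64 log-amp | μa (μs′ from a global fit) | identity |
| 3 | 64 log-amp | μa + 16 optode coupling gains | identity/block |
| 4 | 64 log-amp | μa | region LᵀL |

Raw data are referenced to the forward model with a homogeneous-phantom
calibration, F_cal = F_meas / F_homo_meas × F_homo_forw.

## Worked example

```python
import numpy as np
from dcedot import phantoms, recon, dce
from dcedot.forward import forward_measurements
from dcedot.workflow import ExperimentConfig, build_case

cfg_exp = ExperimentConfig(shapes=("circle",), same_mesh=True,
                           amplitude_cv=0, phase_sd_deg=0, recon_edge_mm=2.0)
case = build_case(cfg_exp, "circle")          # mask -> mesh -> optodes
cfg = cfg_exp.forward_config()
maps = phantoms.make_phantom_series(case.spec, case.gen_mesh)   # B0..B8
frames = [forward_measurements(case.gen_mesh, m, case.gen_layout, cfg)
          for m in maps]
homog = recon.fit_homogeneous(frames[0], case.recon_mesh, case.recon_layout, cfg)
res = recon.reconstruct(frames[-1], case.recon_mesh, case.recon_layout, 4,
                        cfg, homogeneous_init=homog)
roi = dce.roi_from_prior(case.recon_mesh, 1)
w = case.recon_mesh.node_areas()[roi]
print(f"homogeneous fit: mua={homog[0]:.4f}, musp={homog[1]:.3f}")
print(f"B8 inclusion mean mua: {np.sum(w*res.map.mua[roi])/w.sum():.4f}")
```

prints

```
homogeneous fit: mua=0.0100, musp=0.600
B8 inclusion mean mua: 0.0799
```

i.e. the global fit recovers the background (μa = 0.01 mm⁻¹,
μs′ = 0.6 mm⁻¹) and the region-prior reconstruction recovers the
highest-contrast inclusion (true μa = 0.08 mm⁻¹) to 0.15%. The same
pipeline without the prior (methods 1–3) recovers ≈ 0.04 mm⁻¹ — the
partial-volume underestimation the prior is there to fix.

The full studies are available from the CLI:

```
dcedot study-phantom --out runs/linearity     # contrast-linearity comparison
dcedot study-icg --out runs/icg               # 32-frame bolus kinetics
dcedot report --results runs/linearity
```

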