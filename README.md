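# eprredox

Accelerated 3D electron-paramagnetic-resonance (EPR) redox imaging in
Python: golden-mean sparse sampling of spectral projections,
compressed-sensing (FISTA, L1 + total-variation) and filtered
back-projection reconstruction, and voxelwise nitroxyl decay-rate mapping,
validated end-to-end on digital phantoms.

## The problem

Nitroxyl radicals such as ¹⁵N-labelled perdeuterated Tempone (¹⁵N-PDT) lose
their EPR signal when reduced to EPR-silent hydroxylamines, so the voxelwise
decay rate *k* of the signal, from fitting

&nbsp;&nbsp;&nbsp;&nbsp;*S*(*t*) = *A*₀ e^(−*k t*),

maps the reducing capacity (redox status) of tissue — elevated in tumors.
Short-lifetime probes decay in minutes, which leaves no time for the
thousands of spectral projections a conventional 3D continuous-wave EPR
image needs.  Two ingredients recover the lost time:

1. **Golden-mean sampling.**  Gradient directions follow the deterministic
   two-golden-means schedule on the sphere (φ₁ = 1/λ², φ₂ = 1/λ with
   λ³ = λ² + 1), whose every prefix is quasi-uniform, so a measured set of
   2048 projections can be retrospectively truncated to any smaller count.
2. **Compressed sensing.**  Each volume is reconstructed by solving

   &nbsp;&nbsp;&nbsp;&nbsp;x̂ = argmin_x ‖*C R x* − *y*‖₂² + λ₁‖x‖₁ + λ₂ TV(x),

   where *R* is the 3D Radon (plane-integral) transform over the acquired
   directions, *C* the convolution with the first-derivative lineshape and
   *y* the observed spectra, solved with a monotone FISTA (four outer
   iterations, TV-denoising + soft-thresholding prox).  Filtered
   back-projection (second-derivative filter, cosine window) is the
   conventional reference.

The package is aimed at EPR imaging groups who want to prototype sparse
acquisition schedules and reconstruction/kinetics pipelines against
simulated ground truth before touching a spectrometer.

## Worked example

Simulate noisy spectral projections of the ten-pillar solution phantom
(3 mm pillars, 1.06 mL total) and reconstruct with both methods:

```python
from eprredox import (
    LineshapeModel, ScanProtocol, golden_mean_directions, pillar_phantom,
    simulate_spectra, fista_reconstruct, fbp_reconstruct, nrmse, mae, ssim,
)
from eprredox.cs import preset
from eprredox.forward import noise_sd_for_snr

phantom = pillar_phantom(matrix=48, fov=37.5)
directions = golden_mean_directions(256)
protocol = ScanProtocol(includes_zero_gradient=False)  # 1.5 mT sweep, 40 mT/m
line = LineshapeModel()                                # Lorentzian, 0.073 mT pp

clean = simulate_spectra(phantom, directions, line, protocol)
sd = noise_sd_for_snr(clean.spectra, snr=50.0)
data = simulate_spectra(phantom, directions, line, protocol, noise_sd=sd, seed=0)

cs_vol = fista_reconstruct(data, preset("phantom", matrix=48, fov=37.5), line)
fbp_vol = fbp_reconstruct(data, line, matrix=48, fov=37.5)

for name, recon in [("CS ", cs_vol), ("FBP", fbp_vol)]:
    print(f"{name}  NRMSE={nrmse(phantom, recon):.3f}  "
          f"MAE={mae(phantom, recon):.3f}  SSIM={ssim(phantom, recon):.3f}")
```

which prints

```
CS   NRMSE=0.133  MAE=0.042  SSIM=0.574
FBP  NRMSE=1.499  MAE=0.173  SSIM=0.083
```

At 256 of 2048 projections the CS reconstruction is already close to the
ground-truth phantom (errors dominated by the ~1.8 mm intrinsic blur of the
0.073 mT linewidth at 40 mT/m), while FBP is swamped by noise-amplified
streak artifacts — the reason sparse schedules need the regularized
reconstruction.

The same pipelines are scriptable from the shell:

```bash
eprredox simulate --phantom pillar --n-projections 256 --matrix 48 --out proj.h5
eprredox cs  --input proj.h5 --preset phantom --matrix 48 --out cs.nii
eprredox fbp --input proj.h5 --matrix 48 --out fbp.nii
eprredox assess --ref cs.nii --recon fbp.nii
eprredox experiment --matrix 64 --out-dir results/
```

Decay-rate mapping (`eprredox decay`, or `eprredox.kinetics.fit_decay_map`)
fits the exponential voxel by voxel over a reconstructed time series, after
`renormalize_series` restores the inter-frame amplitude scale from the
double-integrated spectral amplitudes.

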