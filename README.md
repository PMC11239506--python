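# wfdecon

Deconvolution and spot analysis for 3D widefield fluorescence microscopy,
aimed at FISH-style experiments where the signals of interest are crowded,
(near-)diffraction-limited dots — single transcripts in smFISH, DNA loci in
oligo-probe DNA FISH.

Widefield optics collect out-of-focus light from the whole specimen, so
dense dot patterns blur into haze and individual signals become hard to
count. `wfdecon` addresses this with four pieces that work together:

1. **PSF calculator** — the scalar Born-Wolf model of an aberration-free
   objective,

       h(r, z) = | ∫₀¹ J₀(k·NA·r·ρ) · exp(−i·k·z·ρ²·NA²/(2·nᵢ)) · ρ dρ |²,
       k = 2π/λ_em,

   rasterized by *integrating over the lateral extent of each sensor
   pixel* (a 7×7 Gauss-Legendre grid per pixel square) rather than
   sampling pixel centers, via a precomputed radial table with Lanczos-3
   interpolation. Needs only NA, immersion index, emission wavelength and
   pixel sizes.

2. **Deconvolution** — Richardson-Lucy with a positivity constraint,
   scaled-heavy-ball momentum (β_k = (k−1)/(k+2)), and missing-data
   boundary handling: the object is estimated on an extended grid
   (image + PSF − 1) and everything outside the observed region Ω is
   treated as missing information, with the weighted update
   x_{k+1} = (x_k / w) · Hᵀ[1_Ω · y / (H x_k)], w = Hᵀ1_Ω.
   This suppresses edge artifacts, survives axially cropped objects, and
   makes seamless tiling possible. The iteration count is the only
   parameter.

3. **Tiling** — arbitrarily large images processed in overlapping lateral
   tiles streamed through float32 scratch files, blended with linear
   ramps that sum to one; memory scales with the tile, not the image.

4. **Simulation + dot detection** — an exact in-silico smFISH generator
   (pixel-integrated Gaussian blobs, Poisson + Gaussian noise) and a
   detector for diffraction-limited dots: strict 6-connectivity local
   maxima, intensity or difference-of-Gaussians ranking, sub-pixel
   refinement, FWHM, ring-sampled contrast-to-noise ratio, 260 nm
   nearest-neighbor matching, and KDE-based auto-thresholding.

See `docs/methods.md` for the model details and numerical choices.

## Worked example (Python API)

```python
import numpy as np
from wfdecon import *

p = OpticalParams(na=1.45, ni=1.515, lambda_em=460.0, dxy=130.0, dz=130.0)
psf = pixel_integrated_psf(p, (41, 41, 31))
print(f"PSF 41x41x31: sum={psf.data.sum():.6f}, peak={psf.data.max():.5f}")

spec = SimulationSpec(shape=(128, 128, 16), n_dots=150, snr=10.0, seed=7)
gt, noisy = simulate_stack(spec, psf)
print(f"amplitude for SNR 10: {amplitude_for_snr(10.0, spec, psf):.0f}")

est, info = shb_iterate(noisy, psf, DeconvConfig(n_iter=50, method="shb"))
print(f"data-fit objective: {info['objective'][0]:.3g} -> {info['objective'][-1]:.3g}")

for name, img in (("raw", noisy), ("deconvolved", VolumeImage(est, (130.0,) * 3))):
    tab = detect(img, mode="dog", params=DetectParams(voxel=(130.0,) * 3))
    rec, prec = recall_against_truth(tab.positions()[:150], gt.positions, (130.0,) * 3)
    print(f"{name:12s} recall {rec:.2f}  precision {prec:.2f}")
```

Output:

```
PSF 41x41x31: sum=1.000000, peak=0.01318
amplitude for SNR 10: 67738
data-fit objective: 2.71e+05 -> 1.06e+05
raw          recall 0.97  precision 1.00
deconvolved  recall 1.00  precision 0.99
```

Reading it: the PSF is unit-sum with a small peak (widefield optics
spread a point's light over the whole volume); at SNR 10 a blob needs
amplitude ≈ 6.8e4 for its blurred peak to stand 10 noise-sigmas above
the background; 50 accelerated iterations reduce the Poisson data-fit
objective ~2.5×; and on this mid-density condition detection on the
deconvolved stack recovers every true dot while the raw stack already
misses a few. The gap widens sharply with crowding and noise.

## Command line

```sh
wfdecon psf-bw --NA 1.45 --ni 1.515 --lambda 460 --resxy 130 --resz 130 \
        --size-x 81 --size-z 79 psf.tif
wfdecon deconvolve --iter 100 [--method shb|rl] [--tilesize 512 --tilepad 40] \
        [--out-format u16|f32] psf.tif image.tif
wfdecon simulate --ndots 1600 --snr 5 --seed 1 --out-dir sim/
wfdecon dots detect --mode dog image.tif --out dots.tsv
wfdecon dots match --radius-nm 260 a.tsv b.tsv
wfdecon bench grid --snr 5,10,20,40 --ndots 100,400,800,1600 --seeds 5 --out grid.tsv
```

Every run writes a `.log.txt` beside its output with all parameters and,
for 16-bit output, the intensity rescale factor needed to undo the
encoding. Exit codes: 0 success, 2 usage error, 3 data error.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the crowded-smFISH detection benchmark from scratch: five
synthetic 255×255×40 stacks (1,600 dots each, SNR 5, seeds derived from
`--seed`), each deconvolved with 100 accelerated iterations using the
same Born-Wolf PSF that blurred it, dots detected and the top 1,600
matched to the true positions at 260 nm. It writes the mean recall (%)
on the deconvolved stacks and on the raw stacks as JSON. Expect roughly
10–15 minutes on one CPU.
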