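# rotoloc

3D super-resolution localization from single 2D images taken through an
engineered, rotating point spread function (PSF).

## The problem

Placing a phase mask in the Fourier plane of a 4f relay behind a wide-field
fluorescence microscope reshapes the PSF so that its form encodes depth:
with a double-helix mask, the image of a point emitter is a pair of lobes
that rotates about its midpoint as the emitter moves through focus. A
single camera frame then carries full 3D information — but the PSFs of
nearby emitters overlap and cannot be fit by simple Gaussian models, so
recovering emitter coordinates at useful densities requires a deconvolution
approach rather than per-spot fitting. `rotoloc` implements that recovery
end to end, for any phase mask that produces a z-dependent PSF, and ships a
synthetic-data generator so phase-mask designs can be benchmarked without a
microscope.

## The method

The imaging model treats the unknown emitter distribution as a sparse,
nonnegative 3D voxel image `x` and the 3D PSF as a matrix `A`; the camera
records only the focal slice of their convolution,

    y = S(A ⊗ x) + noise,

where `S` selects the z = 0 plane (a one-hot selection vector `T` over z).
The pipeline has four stages:

1. **PSF simulation** (`rotoloc.optics`) — scalar Fourier optics: pupil
   disk × mask phase × high-NA defocus phase, FFT, squared modulus. A
   built-in double-helix mask is generated from a Laguerre–Gauss mode
   superposition; measured or custom masks load from TIFF/CSV.
2. **Sparse deconvolution** (`rotoloc.admm`) — the convex program
   `min ½‖S(A⊗x) − y‖² + λ‖x‖₁, x ≥ 0` solved by ADMM with splitting
   variables for the observed slice and the L1 term (penalties μ = 1,
   ν = 20, 1000 iterations, all subproblems in closed form via FFTs).
3. **Sub-grid refinement** (`rotoloc.refine`) — voxel blobs become
   candidates; a joint linear least squares over first-order Taylor
   expansions of each candidate's PSF in (x, y, z) returns continuous
   coordinates and intensities.
4. **False-positive rejection** (`rotoloc.mlfilter`) — a logistic
   regression trained on labeled simulations at the user's own optical
   configuration scores each localization (intensity, fit residual, blob
   statistics, crowding); the acceptance threshold is chosen on held-out
   data to cap the false-positive rate at 5%.

`rotoloc.bench` measures recall (matched true emitters / all true
emitters), false-positive rate (unmatched localizations / all
localizations) and per-axis error SDs as a function of emitter density.

## Worked example

```python
import numpy as np
from rotoloc import (
    OpticalConfig, build_psf_stack, double_helix_mask, simulate_frame,
    ADMMParams, localize_frame, match_localizations, compute_metrics,
)
from rotoloc.bench import subtract_background

config = OpticalConfig()                      # NA 1.45 oil, 580 nm, 100 nm px
stack = build_psf_stack(config, double_helix_mask(config))

# one synthetic frame: 15 emitters at 0.4 per um^2, 3000 photons each
frame, truth = simulate_frame(0.403, stack, field_px=61, seed=3007,
                              fixed_count=15)
locs = localize_frame(subtract_background(frame), stack,
                      ADMMParams(log_every=0))
match = match_localizations(locs, truth)
recall, fp = compute_metrics(match)
print(f"{len(truth)} emitters, {match.n_matched} matched, recall {recall:.0f}%")
errs = np.std(match.errors_nm, axis=0, ddof=1)
print(f"error SD (x, y, z): {errs[0]:.1f}, {errs[1]:.1f}, {errs[2]:.1f} nm")
```

prints

```
15 emitters, 15 matched, recall 100%
error SD (x, y, z): 4.9, 5.2, 7.4 nm
```

i.e. every emitter in this frame is recovered, with nanometer-scale lateral
precision and (as expected for depth encoded in lobe rotation) roughly
double the error in z. The unfiltered localization list also contains many
low-mass spurious candidates; training and applying the threshold model
(`rotoloc.train_from_simulation`, `rotoloc.apply_threshold`) removes them —
see the CLI below or `scripts/acceptance.py`.

The same pipeline is available from the shell:

```bash
rotoloc psf      --out psf.tif --calibration rotation.csv
rotoloc simulate --density 0.4 --frames 10 --seed 1 --out frames.tif
rotoloc train    --seed 1 --out model.json
rotoloc localize --frames frames.tif --model model.json --out results/
rotoloc benchmark --densities 0.2,0.4,0.7,1.0 --frames 20 --seed 7 \
                  --model model.json --out report/
```

## Scope

Scalar-diffraction PSF models only (no vectorial/polarization effects);
single-frame recovery (no joint multi-frame solve); no GPU path; no motion
blur or structured background in the generator.
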