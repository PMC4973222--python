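# Methods

This note records the models, conventions and numerical choices behind
`rotoloc`, and what the synthetic benchmarks do and do not demonstrate.

## Optical model

The PSF engine is scalar Fourier optics. The pupil is a uniform disk out to
the NA cutoff (no apodization — the illumination profile at the Fourier
plane is taken as flat). A point emitter displaced by `z` from focus
multiplies the pupil by the angular-spectrum defocus phase

    φ_z(ρ) = (2π n / λ) · z · sqrt(1 − (NA·ρ/n)²),

with ρ the pupil radius normalized to the aperture edge; the detector-plane
intensity is |F{pupil · e^{iφ_mask} · e^{iφ_z}}|². The pupil grid is sized
so that the FFT of the pupil is sampled exactly at the recovery grid's
lateral step (`aperture_radius_px = N·NA·Δx/λ`), which removes any
image-space resampling. This scalar model ignores polarization and
high-NA vectorial effects; at NA 1.45 those change fine PSF detail but not
the two-lobe/rotation structure the method relies on.

**Sign convention.** An emitter at +z (toward the coverslip) projects the
PSF slice computed at defocus −z onto the detector. This is fixed once in
`render_frame`/`emitter_kernel` and covered by a consistency test; nothing
else in the code may re-decide it.

**Double-helix mask.** The built-in mask is the phase (phase-only
projection) of an equal-energy sum of Laguerre–Gauss modes with indices
(p, l) = (j, j·charge_step), j = 0…n_modes−1 (defaults 4 modes, step 2).
Modes on a line of slope 2 in the modal plane form a rotating beam, and
adjacent charges differing by 2 interfere into two azimuthal lobes. The
mode waist is 0.30 of the aperture radius: a one-time design choice made by
scanning the generator's own conformance properties (two separable lobes on
every slice, monotone lobe rotation, linear-fit R² > 0.99 over the axial
range); larger waists rotate faster but lose lobe separability at the range
edges. The resulting mask rotates ≈ 90°/μm, linear to R² ≈ 0.998 over
±1 μm.

**Rotation calibration.** Per-slice lobe orientation is the angle of the
line through the two lobe centroids (intensity-weighted, 5×5 windows around
the two strongest separated maxima of the lightly smoothed slice), defined
modulo 180° and unwrapped along z. Slices without two separable lobes are
excluded with a warning. Because the pupil is parameterized by NA only, the
rotation–z response is a property of the objective; the relay's beam radius
`r` and focal length `f` enter only the magnification formulas
(`M_lat = C·n·f/r` with configurable constant `C`, `M_ax = M_lat²/n`),
which are exposed with their formula metadata so a calibrated constant can
be substituted.

## Forward simulation

`render_frame` places the z-interpolated PSF slice (linear between the two
bracketing planes) at each emitter's continuous lateral position using the
Fourier shift theorem for the sub-pixel part. The camera model is
`gain · Poisson(signal + background) + N(0, read_noise²)`, seeded and
bit-reproducible.

Default study conditions (stored in every frame's provenance): 3000
photons/emitter median (lognormal, σ_log = 0.25), 10 photons/px uniform
background, gain 1, read noise 1 count, 100 nm pixels, axial range 2 μm
sampled every 50 nm (41 planes). Emitter z is drawn over the central 80% of
the axial range so that near-edge emitters remain refinable; lateral
positions keep a 3 px margin. These are the conditions under which the
quoted benchmark behavior holds; brighter/dimmer samples shift every curve.

What the generator does *not* emulate: motion blur during exposure,
structured/cellular background, PSF aberration mismatch between calibration
and sample, pixel-response nonuniformity, EMCCD excess noise. Passing
benchmarks therefore demonstrate the recovery mathematics under the stated
noise model, not robustness to those real-data effects; in particular,
recovery on measured frames is only as good as the match between the
simulated and the experimental PSF.

## Sparse deconvolution (ADMM)

The recovery program is the penalized form

    min_x  ½‖S(A ⊗ x) − y‖² + λ‖x‖₁,  x ≥ 0,

with circular 3D convolution. The constrained formulation (fidelity within
a noise tolerance ε) is retained as metadata only; λ is the user-facing
knob, defaulting to `2·σ_bg·‖A_focus‖₂` with σ_bg taken from the known
noise model or a MAD estimate of the frame.

Splitting: `u0` stands for the observed slice of `A⊗x`, `u1` for `x` under
the L1 + nonnegativity term; scaled duals η0, η1; penalties μ = 1, ν = 20;
update order x → u0 → u1 → duals from `x = u1 = 0, u0 = y`; 1000 iterations
by default with an optional residual-based early stop (off by default).
All subproblems are exact:

* **x-update.** In the lateral Fourier domain the normal matrix per
  frequency is `ν·I + μ·v·vᴴ` with `v` the across-plane transfer vector —
  a rank-one correction solved by Sherman–Morrison. Working per z-plane
  with 2D FFTs is algebraically identical to transforming z as well (the
  z-DFT is unitary and the slice-selection operator is what couples
  planes), so no 3D transform is needed.
* **u0-update.** `(y + μ(s + η0))/(1 + μ)` — quadratic fidelity is assumed
  (Poisson fidelity would break the closed forms).
* **u1-update.** Nonnegative soft threshold at λ/ν, i.e. the prox of
  λ‖·‖₁ + ι_{≥0}.

Boundary handling: the frame is reflect-padded by half the PSF lateral
support (then to an FFT-friendly size) and the solution cropped back;
circular convolution otherwise aliases emitters across edges. The returned
grid is `u1` (nonnegative and sparse by construction; equal to x at
convergence). The hot loop runs in single precision (memory-bandwidth
bound); the modular update functions preserve double precision and are the
ones exercised by the optimality oracles (subproblem gradients < 1e-8
relative; converged objective within 0.5% of an independent
bound-constrained solver on 8×8×3 instances).

## Candidate extraction and refinement

Voxels above 2% of the grid maximum form the candidate support; the
support is split into one basin per local maximum (watershed, minimum peak
separation 2 voxels). Plain connected components were tried first and
merged genuinely distinct nearby emitters through low-amplitude bridges;
splitting at every maximum keeps them apart at the cost of extra spurious
candidates, which is deliberate — rejection is the classifier's job.

Refinement linearizes the detector template of each candidate i,

    y ≈ Σ_i I_i·H_i + (I_i dx_i)·∂H_i/∂x + (I_i dy_i)·∂H_i/∂y + (I_i dz_i)·∂H_i/∂z,

and solves for all candidates jointly by linear least squares over the
union of 21×21 px candidate windows. Partial derivatives are central
differences of the *rendered* template (1 nm laterally, one 50 nm plane
axially), which keeps the sign conventions identical to the forward model
by construction. Offsets are the ratio of the fitted products to the fitted
intensity; moves are clipped to one grid step per pass (flagged when
clipped) and the system is re-linearized for up to 5 passes or until moves
fall below 1 nm. Numerical safeguards, each visible in the output:

* a small column-equilibrated ridge (α = 1e-4 relative) damps the huge
  cancelling coefficients that near-collinear candidate columns otherwise
  produce; bias on well-conditioned fits is ~1e-4 relative, far below the
  0.1% intensity tolerance of the noiseless oracle;
* candidates whose refined positions converge within 80 nm lateral /
  160 nm axial are duplicates of one emitter — the stronger is kept and
  the system re-solved;
* non-positive fitted intensity flags the localization but keeps it for
  the classifier.

## False-positive rejection

Features per localization (fixed order; photons and blob mass on a log1p
scale because they span decades and a pathological fit can inflate them):
fitted photons, window RMS residual, deconvolved blob mass, blob voxel
count, refinement offset in grid-step units, distance to the nearest other
candidate, local background (window-border median).

The classifier is an L2-regularized logistic regression — auditable,
deterministic, and sufficient for seven features; the classifier kind is a
config option, not a claim that nothing better exists. Training data are
self-generated simulations at the user's optical configuration across
0.2–1.0 emitters/μm², labeled by greedy matching against ground truth
(lateral radius 100 nm, axial 200 nm). A seeded 2:1 split fits the model
and selects the decision threshold on the held-out third: the cut
maximizing recall subject to a held-out false-positive rate ≤ 5% among
accepted localizations. The threshold lives on the logit scale
(probabilities saturate for well-separated classes). The operating point
deliberately favors purity: a missed emitter costs measuring time, a false
positive distorts the recovered structure. Models carry a provenance hash
and refuse application to a mismatched feature definition.

## Benchmarking

Matching is greedy in ascending anisotropic distance
`sqrt((Δx²+Δy²)/100² + Δz²/200²) ≤ 1` (radii ≈ 3× the low-density error
SDs, so matching does not dominate the metrics), with a deterministic
tie-break; an exhaustive-assignment oracle confirms greedy optimality at
small n. Recall = matched truths / all truths; FP rate = unmatched
localizations / all localizations; per-axis SDs are pooled over frames
(per-frame medians would be noisier at the frame counts used). Seeds for
per-frame simulation derive from the master seed by fixed offsets, so
reports are bit-reproducible.

Problem sizes: the density sweep runs 48×48 px fields (23 μm²) with
12 frames per density at 0.2/0.4/0.7 μm⁻² and 20 at 1.0 μm⁻²; the
15-emitter worked configuration uses a 61×61 px field so that 15 emitters
are exactly 0.4 μm⁻². These sizes keep a full sweep near ten minutes on
one CPU while leaving ≥ 50 matched pairs per density for the SD estimates;
the field size does not enter the per-μm² metrics, only their variance.

Without the threshold stage the raw localization list is dominated by
low-mass spurious candidates (FP ≈ 70% at all densities — the direct
consequence of permissive extraction), so the density trend of the
*final* pipeline is the thresholded row; the unthresholded row is reported
for the with/without comparison.

## Known limitations

* Phase masks whose PSFs lack two separable lobes need a different
  orientation statistic than the lobe-pair angle (the second-moment
  principal axis degrades gracefully but is not exposed as an option).
* The z-encoding is ambiguous modulo the lobe period for |rotation| > 90°;
  the solver disambiguates through lobe shape, but precision degrades near
  the axial range edges.
* Threshold models are configuration-specific by design; there is no
  transfer across optical configurations.
* Recovery quality assumes the simulated and actual PSF match; no
  aberration retrieval is included.
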