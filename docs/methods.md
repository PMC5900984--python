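# Methods

`dwiphantom` analyzes pulsed-gradient spin-echo (PGSE) diffusion-weighted MRI
of cell-mimicking hollow-microsphere phantoms: a packed bed of micron-scale
water-filled polymer spheres immersed in water, imaged as an annular
cross-section alongside a water-only control tube. This note records the
models, the numerical choices, and what the synthetic data generator does and
does not emulate.

## Signal model

A PGSE measurement is (G, δ, Δ) with diffusion weighting
b = γ²G²δ²(Δ − δ/3) for ideal rectangular pulses (γ defaults to the proton
value 2.6752218744×10⁸ rad s⁻¹ T⁻¹ and is configurable). b is always
recomputed from the timing parameters; b-values supplied in a protocol table
are cross-checked (warning above 2% disagreement) but never used numerically,
because stated b-values and stated gradient amplitudes from scanner exports
frequently disagree with the rectangular-pulse formula (effective gradient
calibration and pulse shape are rarely documented).

The normalized two-compartment signal is

    S/S0 = f_i · S_i(R, D) + (1 − f_i) · S_e(D, f_i)

* **Restricted compartment** `S_i`: diffusion inside an impermeable sphere of
  radius R under the Gaussian phase distribution (GPD) approximation — a
  series over modes α_m = x_m/R, where x_m is the m-th positive root of
  x J′₃⁄₂(x) − ½ J₃⁄₂(x) = 0 (first root ≈ 2.081576). Roots are located by a
  0.1-step sign scan and bisection to 10⁻¹⁰ (robustness over speed; they are
  computed once and cached). The series uses 20 roots by default with
  term-based truncation at 10⁻⁸ relative; going from 20 to 50 roots changes
  the signal by < 10⁻⁶ over the reference protocols for R ≤ 25 µm.
* **Hindered compartment** `S_e = exp(−b·D/(1 + f_i/2))`: extracellular
  diffusivity reduced by the tortuosity factor 1 + f_i/2. The tortuosity form
  is asserted, not derived; simulating its validity would require packed
  many-sphere substrates, which are out of scope.
* One diffusivity D is shared by both compartments (the same fluid is inside
  and outside the spheres). No T2 weighting, no exchange, no direction
  dependence (spherical symmetry); TE-dependent amplitude differences between
  Δ acquisitions are removed by per-Δ normalization rather than modeled.

Units: R in µm, D in µm²/ms, b in s/mm² (b·D·10⁻³ is the dimensionless
exponent); all internal computation converts to SI.

## Monte-Carlo oracle

The GPD expression is an approximation, so it is validated against an
independent random-walk simulation that shares no code with the series:
walkers take Gaussian steps (per-axis SD √(2·D·dt)), are reflected specularly
at the sphere boundary (mirror about the tangent plane at the crossing point,
iterated for multiple reflections), and accrue phase through the literal
finite-δ rectangular waveform, so the simulation probes the full GPD
expression rather than the narrow-pulse limit. The time step obeys
√(6·D·dt) ≤ R/20 (hard error above R/10) and is snapped to an integer number
of steps per millisecond so pulse edges fall on the step grid. A
rejection-step boundary rule is available to cross-validate the reflection
rule. Positions are held in float32 (µm scale, round-off ~10⁻⁶ µm — far below
the step length); phases accumulate in float64. At 10⁵ walkers the
Monte-Carlo and GPD signals agree to ≤ 0.02 across R ∈ {2.5, 5, 10} µm and
Δ ∈ {12, 45} ms at D = 2 µm²/ms; the largest deviation (~0.011 at R = 10 µm,
Δ = 45 ms, strong gradients) is genuine GPD approximation error, not
simulation noise.

## Noise model and ADC estimation

Magnitude images carry Rician noise. The Gaussian SD is estimated from a
signal-free background ROI as σ = S_bg·√(2/π); S_noise defaults to the same
ROI mean (a separate noise ROI can be supplied), and SNR = (mean b=0 signal
in the analysis ROI)/σ.

ADC maps are fitted per voxel by maximizing the Rician likelihood of the
observed magnitudes with mean S0·exp(−b·ADC·10⁻³) and scale σ (Nelder-Mead,
started from the log-linear least-squares estimate; log I₀ evaluated via the
exponentially-scaled Bessel function for stability). S0 is a free parameter.
ADC is constrained to [0, 4] µm²/ms: at very low SNR the unbounded Rician
likelihood has heavy-tailed maxima in which all high-b signal is attributed
to noise, and a plausible physical range (free water at room temperature is
~2.1 µm²/ms) is imposed in the same spirit as the microstructure constraint
box. Voxels pinned at either limit are flagged. ROI summaries use the median.

## Microstructure fitting

Whole-ROI analysis averages raw voxel signals over the ROI, normalizes each
Δ group to its G = 0 scan, and discards entries whose raw signal is strictly
below 2·S_noise (Rician-floor mitigation; equality retains the point; the
order normalize-then-average is available by configuration). Because
averaging and normalization destroy the single-Rician distribution of the
data, the model is fitted by least squares, not Rician ML.

The fit minimizes the SSE between observed normalized signals and the model
over (R, f_i, D) — or (R, f_i) with D fixed, typically to the median
free-water ADC at the shortest diffusion time — inside the constraint box
0.1 ≤ R ≤ 25 µm, 0.01 ≤ f_i ≤ 1, 0.1 ≤ D ≤ 3 µm²/ms. Nelder-Mead operates on
a smooth logistic reparameterization of the box so the simplex is
unconstrained; 100 starting points are drawn uniformly in the box from a
seeded generator and the lowest objective wins. Convergence tolerances are
10⁻⁸ on simplex spread and objective spread, 2000 iterations per start.
Parameters within 1% of a constraint are flagged at-bound. The simplex loop
is JIT-compiled (numba) with the same algorithm, coefficients, initial
simplex and termination rule as scipy's implementation; the scipy path is
retained behind `engine="scipy"` and the two are cross-checked in the tests.
Voxelwise fitting runs the same machinery per voxel and reports at-bound
fractions and median ± IQR with and without at-bound voxels.

The (R, f_i) pair is intrinsically poorly conditioned at realistic SNR:
larger spheres at higher volume fraction produce signals close to smaller
spheres at lower volume fraction. At a signal-level SNR of 25 roughly a fifth
of single realizations have their global SSE minimum at the R lower bound.
This is a property of the model and protocol, not of the optimizer — it is
why whole-ROI averaging, the fixed-D mode, and bootstrap uncertainty matter.

## Bootstrap uncertainty

Precision of whole-ROI fits is assessed with a residual bootstrap stratified
by diffusion time: because SNR differs across Δ (TE grows with Δ), residuals
are exchangeable only within a Δ stratum, and each replicate adds to every
fitted value a residual resampled with replacement from its own stratum only.
Each of B = 1000 replicates (B = 200 in the scaled-down validation runs) is
refitted with a 10-start search (the point estimate as a warm start plus 9
random starts; the full 100-start search is a config switch and was verified
not to change coverage). 95% CIs are the 2.5%/97.5% quantiles using the
(B+1)p plotting position, the bootstrap-literature convention. Pearson
correlations across replicates expose the degeneracy directions; ρ(R, f_i) is
strongly positive on near-degenerate data.

Two defaults extend the plain resample-the-residuals recipe and can be
switched off: residuals are leverage-corrected (divided by √(1 − h_i), with
leverages from the Jacobian of the linearized model at the point estimate)
before resampling, because raw least-squares residuals from 9 points and 3
parameters understate the noise SD; and the global √(n/(n−p)) factor is
available as a simpler alternative. With these defaults, 95% CIs on R cover
the truth in ~85% of matched-noise synthetic datasets — still slightly below
nominal, which is expected: percentile intervals centered on a bound-truncated,
non-Gaussian estimator cannot reach nominal coverage, and noise entering
through the G = 0 normalization is invisible to residuals. Under the full
Rician raw-signal pipeline, coverage is lower still (~65–75% measured); the
bootstrap quantifies fit precision, and its intervals should not be read as
calibrated frequentist coverage on strongly degenerate fits.

## Synthetic phantom generator

The generator emulates the imaging experiment the estimators are built for:
a 30×30 mm field of view, 128×128 matrix, 10×1 mm axial slices; an annular
phantom cross-section (inner/outer diameters 1.8/3 mm) with a free-water
core, and a disjoint water-only control tube (radius 2.1 mm, the bore of a
5 mm NMR tube). Phantom voxels follow the two-compartment model (defaults
R = 5.2 µm, f_i = 0.35, D = 2.0 µm²/ms — the independently characterized
sphere radius and a packing-plausible volume fraction); water voxels decay
mono-exponentially at D_free = 2.0 µm²/ms (room-temperature water). The
phantom's b = 0 amplitude is 0.65 of the water amplitude, reflecting reduced
water content in the sphere-packed material; this is also what makes
intensity-based segmentation of phantom vs free water possible. TE growth
with Δ is emulated by a mono-exponential amplitude factor with T2 = 85 ms,
chosen so that a phantom SNR of 25 at Δ = 12 ms (TE 21.3 ms) falls to ≈ 17 at
Δ = 45 ms (TE 54.3 ms), matching the SNR ratio of the two acquisitions on a
7 T preclinical system. Noise is Rician: √((S+n₁)² + n₂²) with seeded
Gaussian draws. Ground truth is homogeneous by default — the spread seen in
voxelwise fits on real data is dominated by fit imprecision, not structural
heterogeneity — with optional truncated-Gaussian jitter on (R, f_i) for
voxelwise experiments.

What the generator does **not** emulate: partial-volume voxels at region
boundaries, compartmental T2 differences, membrane exchange, time-dependent
extracellular diffusivity, sphere-size distributions, clumping/aggregation of
spheres, wall thickness (spheres are modeled as filled, impermeable), ghosting
or drift artifacts. Passing recovery tests on synthetic data therefore
demonstrates estimator correctness under the model's own assumptions, not
accuracy on real phantom data — on the real system, R is overestimated
(unmodeled exchange, T2 and pore effects are candidate explanations), which
is precisely the kind of bias this package's simulation tools are meant to
help dissect.

## Segmentation

The phantom ROI is extracted from the b = 0 image in two intensity steps:
Otsu's threshold separates the tubes from background, then free-water voxels
are removed at the midpoint between the phantom-material and water intensity
modes (class medians after an Otsu split of the foreground). The manual
touch-up of the original workflow is replaced by an optional mask that
overrides or intersects the automatic label; thresholds are recorded in the
result. On synthetic data the automatic phantom label overlaps truth with
Dice ≥ 0.95; real-data segmentation quality is not claimed.

## Pipeline and reproducibility

`run_full_pipeline` chains: protocol validation → segmentation (or supplied
labels) → noise estimation (background eroded in-plane to avoid tube-edge
partial volumes) → per-Δ Rician ML ADC maps for phantom and control →
fixed-D selection (median control-water ADC at the shortest Δ) → ROI
averaging, normalization, 2·S_noise filtering → all-free and fixed-D fits →
stratified bootstrap → reports. A protocol-subset refit excluding the longest
diffusion time is a config switch. Every random draw descends from the config
seed; reports (CSV/JSON, uncompressed NIfTI maps) contain no paths or
timestamps and are byte-identical across identical runs.

## Problem sizes used in validation

The test suite runs the Monte-Carlo comparison at 10⁵ walkers, the stochastic
recovery on 50 synthetic image datasets (64×64, 3 slices, ~60 annulus voxels,
ROI-averaged before fitting), the coverage study at 100 signal-level datasets
× B = 200, and the pipeline checks on reduced grids (64–128 in-plane, 2
slices); the acceptance script uses the full 128×128×10 geometry with
B = 1000. These sizes were chosen to give sampling error well inside the
tolerances being checked. At ROI-signal SNR as low as 25 (no spatial
averaging) single-realization fits are bimodal — roughly a quarter pin R at
the lower constraint — so summaries of unaveraged low-SNR fits are reported
with at-bound fractions rather than trusted medians.

## Known limitations

* GPD is an approximation; its error grows with gradient strength and radius
  (measured ~0.011 signal units at R = 10 µm, Δ = 45 ms, G ≈ 150 mT/m).
* Percentile residual-bootstrap CIs under-cover on degenerate fits (above).
* The Rician ML ADC assumes unaveraged single-coil magnitude data.
* The mean-based ROI average is sensitive to mask errors at region edges;
  segmentation quality directly propagates into the whole-ROI fit.
* The stereological π/4 wall-thickness correction assumes random planar
  sections through spherical shells; it is provided as arithmetic, with the
  sampling assumptions left to the user.
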