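# dwiphantom

Two-compartment diffusion-MRI analysis for cell-mimicking microsphere
phantoms, with a synthetic phantom-image generator and a Monte-Carlo
random-walk oracle.

## The problem

Hollow polymer microspheres packed in water mimic the restricted and hindered
water diffusion of tumor tissue, giving a physical test object for
diffusion-weighted MRI (DW-MRI) microstructure methods: unlike free-water
phantoms, their apparent diffusion coefficient (ADC) depends on the diffusion
time, and their signal is described by a biophysical model with a known
ground truth (sphere radius from electron microscopy, volume fraction from
CT). This package implements the analysis chain for such phantoms —
acquisition bookkeeping, forward models, estimators, uncertainty — for
researchers validating DW-MRI microstructure pipelines on preclinical
scanners, plus the synthetic-data machinery to test every stage without
scanner data.

## The model

For a pulsed-gradient spin-echo (PGSE) measurement with gradient amplitude
G, pulse duration δ and separation Δ (b = γ²G²δ²(Δ − δ/3)), the normalized
signal is a mixture of restricted and hindered pools sharing one diffusivity:

    S/S0 = f_i · S_i + (1 − f_i) · S_e

    S_i = exp(−2γ²G² Σ_m [α_m²(α_m²R² − 2)]⁻¹ ·
            [2δ/(α_m²D) + (−2 + 2e^{−α_m²Dδ} + 2e^{−α_m²DΔ}
             − e^{−α_m²D(Δ−δ)} − e^{−α_m²D(Δ+δ)}) / (α_m⁴D²)])

    S_e = exp(−b·D / (1 + f_i/2))

where S_i is the Gaussian-phase-distribution (GPD) signal for diffusion
restricted in an impermeable sphere of radius R (α_m R are the roots of
x J′₃⁄₂(x) − ½J₃⁄₂(x) = 0) and 1 + f_i/2 is the tortuosity factor of the
extracellular space at sphere volume fraction f_i.

Estimation follows standard practice for magnitude MR data: noise σ from a
background ROI (σ = S_bg√(2/π)), maximum-likelihood Rician ADC mapping,
per-Δ normalization to the G = 0 scan, exclusion of signals below 2·S_noise,
constrained 100-start Nelder-Mead fitting of (R, f_i, D) (optionally with D
fixed to the free-water ADC), and a Δ-stratified residual bootstrap for
confidence intervals and parameter correlations. A vectorized random-walk
simulator (specular reflection inside the sphere, literal finite-δ phase
integration) serves as an independent check of the GPD series.

## Worked example

Simulate a phantom dataset with known truth (R = 5.2 µm, f_i = 0.35,
D = 2.0 µm²/ms, phantom SNR 25) and analyze it:

```python
import dwiphantom as dp

adc_p, micro_p = dp.make_reference_protocols()
protocol = dp.Protocol(tuple(adc_p.measurements) + tuple(micro_p.measurements))
geometry = dp.build_geometry()                      # 128x128, 10 slices, annulus + control tube
dataset = dp.simulate_dataset(geometry, protocol, snr=25.0, seed=1)

cfg = dp.PipelineConfig(seed=1, bootstrap_B=1000)
bundle = dp.run_full_pipeline(cfg, dataset=dataset)

adc = bundle["adc"]["median"]
free = bundle["fits"]["all-free"]
print(f"phantom ADC: {adc['phantom'][12.0]:.3f} (Δ=12 ms) "
      f"vs {adc['phantom'][45.0]:.3f} (Δ=45 ms) µm²/ms")
print(f"water   ADC: {adc['control_water'][12.0]:.3f} vs "
      f"{adc['control_water'][45.0]:.3f} µm²/ms")
print(f"fit: R = {free['R']:.2f} µm  f_i = {free['f_i']:.3f}  "
      f"D = {free['D']:.3f} µm²/ms  (R² = {free['r_squared']:.4f})")
print(f"95% CI on R: [{free['ci_lower']['R']:.2f}, {free['ci_upper']['R']:.2f}], "
      f"ρ(R, f_i) = {free['correlations']['R_f_i']:.2f}")
```

prints

```
phantom ADC: 1.037 (Δ=12 ms) vs 0.720 (Δ=45 ms) µm²/ms
water   ADC: 1.998 vs 2.006 µm²/ms
fit: R = 5.19 µm  f_i = 0.358  D = 2.030 µm²/ms  (R² = 1.0000)
95% CI on R: [5.10, 5.26], ρ(R, f_i) = 0.61
```

The phantom region shows the diffusion-time dependence that free water lacks
(ADC falls from 1.04 to 0.72 µm²/ms as Δ grows from 12 to 45 ms, while the
control tube stays at 2.0); the whole-ROI fit recovers the simulated
microstructure (R = 5.2 µm, f_i = 0.35, D = 2.0), and the bootstrap
correlation exposes the well-known R–f_i degeneracy (larger spheres at higher
volume fraction resemble smaller spheres at lower volume fraction).

A CLI mirrors the library (`dwiphantom simulate | segment | fit-adc |
fit-micro | bootstrap | stability | run | predict`); see `dwiphantom --help`.

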