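# flimspec

Frequency-domain fluorescence lifetime imaging (FD-FLIM) reconstruction with
protoporphyrin IX (PpIX) spectroscopic co-validation.

## The problem

5-ALA-induced PpIX fluorescence guides the resection of high-grade gliomas,
but in low-grade gliomas and weakly infiltrated brain the red PpIX emission
is outweighed by tissue autofluorescence and invisible to the surgeon.
Because PpIX has a long fluorescence lifetime (16.4 ns in solution) compared
with brain autofluorescence (~0.8–2 ns), even weak PpIX admixtures raise the
*apparent* lifetime measured by FD-FLIM. `flimspec` implements the full
analysis chain that quantifies this effect:

1. **Reconstruction** — a lock-in amplifier demodulates the emission into a
   per-pixel phase Θ and amplitude R; after phase calibration, the lifetime
   is τ = tan(Φ)/(2π f_mod) with f_mod = 10 MHz.
2. **Spectral decomposition** — for spatially registered emission spectra
   (590–740 nm), an OLS baseline fitted to the PpIX-free anchor windows
   600–610 nm and 720–730 nm splits the counts at the 635 nm peak into
   S_PpIX (above the line) and S_Autofl (the line), giving the relative PpIX
   signal contribution RSC = S_PpIX / (S_Autofl + S_PpIX).
3. **Correlation model** — a fifth-order polynomial of lifetime on RSC
   (6 coefficients, DOF = n − 6) with two-sided 95 % Student-t confidence and
   prediction bands,
   CI = t·σ̂·√(1/n + (x₀−x̄)²/Σ(xᵢ−x̄)²), PI = t·σ̂·√(1 + 1/n + …),
   plus regime classification (RSC < 0.25: autofluorescence-level lifetimes;
   0.25–0.85: PpIX invisible but lifetime raised; ≥ 0.85: visibly fluorescent).
4. **Cohort statistics** — per-specimen pixel subsampling normalized to the
   smallest specimen, group summaries, KS shape checks after median/IQR
   standardization, and one-sided (greater) Mann–Whitney U tests of each
   tumor group against the non-pathological control, starred at
   0.05/0.01/0.005.
5. **Visualization** — log₂-scaled jet colorization between 1 and 16 ns,
   grayscale intensity rendering, HSL/YPbPr chrominance–luminance blending
   of lifetime color onto structural images, and SSIM comparison.

Since no instrument data ship with the package, a first-class synthetic-data
module generates two-fluorophore phasor phantoms, matched emission spectra
with exact target RSC, and labelled cohorts; every stage is tested against it.

## Worked example

```python
import numpy as np
import flimspec as fs

# a phantom: left half pure autofluorescence (1.6 ns), right half a PpIX
# mixture whose apparent lifetime is 13 ns
labels = np.zeros((64, 64), int); labels[:, 32:] = 1
scene = fs.PhantomScene(label_map=labels, region_params={
    0: fs.RegionParams(alpha_ppix=0.0, tau_auto_ns=1.6),
    1: fs.RegionParams(alpha_ppix=fs.alpha_for_apparent_lifetime(13.0)),
})
frame = fs.render_demod_frame(scene, fs.NoiseModel(phase_jitter_scale=0.05, seed=0))
tau_map, intensity = fs.reconstruct(frame, fs.CalibrationModel(0.0))
print(np.nanmedian(tau_map.tau[:, :32]), np.nanmedian(tau_map.tau[:, 32:]))
# 1.6005100091171038 13.003897590239143

# an emission spectrum with 37 % PpIX contribution at 635 nm
spectrum = fs.synth_spectrum(0.37)
decomp = fs.compute_rsc(spectrum, fs.fit_baseline(spectrum))
print(decomp.rsc)          # 0.37
print(fs.classify_regime(decomp.rsc))  # 'B'  (raised lifetime, no visible fluorescence)
```

The two median lifetimes recover the generator's regions to within the phase
noise, the RSC round-trips exactly on noiseless spectra, and 0.37 falls in
regime B — the working range where FD-FLIM sees PpIX the eye cannot.

The full pipeline (generate → reconstruct → decompose → correlate → stats →
blend) runs from the shell:

```bash
flimspec run --seed 7 --out demo_run   # writes CSVs, plots, blends, manifest
flimspec validate demo_run/run_manifest.json
```

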