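# lungdce

Quantitative analysis of 4D dynamic contrast-enhanced (DCE) lung perfusion
MRI, built on indicator-dilution theory, with a synthetic phantom
generator and an in-silico repeat-injection experiment.

## The problem

4D perfusion MRI tracks a contrast bolus through the lungs (here: 24
volumes at 1.47 s/volume, injection 5 s after scan start) and quantifies
regional perfusion by deconvolving each voxel's tissue curve against the
arterial input function (AIF) from the pulmonary trunk:

    C_t(t) = f · (C_a ⊛ R)(t)

* **PBF** = 6000 · height of the flow-scaled residue f·R  [ml/min/100ml]
* **PBV** = 100 · ∫C_t / ∫C_a                             [ml/100ml]
* **MTT** = 60 · PBV / PBF (central volume theorem)       [s]

Such measurements are attractive for monitoring regional lung function in
COPD, but repeat injections are problematic: contrast from a previous
injection (serum elimination half-life ≈ 1.6 h) is still circulating
~32 min later (≈ 79% of one dose's steady-state concentration), and the
MRI signal grows sub-linearly with concentration. The concentrated
arterial signal is dampened more than the dilute tissue signal, so a
linear signal-to-concentration conversion inflates second-injection PBV
and PBF while the measured AIF barely changes — a measurement bias that
can masquerade as, or obscure, real physiology. `lungdce` implements the
full quantification pipeline, the phantom with known ground truth, and
the 2-day × 2-injection experiment that isolates this mechanism.

Intended users: researchers in quantitative perfusion imaging who want a
tested, reproducible reference pipeline and a sandbox for repeat-dose
bias, correction schemes, and regional repeatability statistics.

## Worked example

`examples/` holds one narrative script per capability. The headline one:

```bash
python examples/04_repeat_injection_bias.py
```

```
scheduled residual fraction (of one dose's steady state):
  day 1, injection 1: 0
  day 1, injection 2: 0.794
  day 2, injection 1: 6.9e-05
  day 2, injection 2: 0.794

whole-lung PBV: injection 1 19.91, injection 2 20.59 ml/100ml (+3.4%)
subjects with inflated PBV at injection 2: 20/20 subject-days
measured AIF integral change: -4.5% (the AIF looks stable while the tissue estimates shift)
region-pooled Wilcoxon (PBV, injection 1 vs 2): p = 2.40e-38
```

True perfusion is identical at both injections; the +3.4% PBV shift in
every subject-day is pure measurement bias from residual contrast plus
signal saturation, while the AIF scalar moves by only a few percent in
the other direction. After 24 h less than 0.005% of a dose remains, so
elimination kinetics produce no day-to-day effect.

The other examples: `01_simulate_phantom.py` (phantom + ground truth with
the gravity-dependent dorsal>ventral gradient), `02_quantify_perfusion.py`
(automatic AIF detection, deconvolution, per-region recovery within a few
percent at 2% noise), `03_regional_stats.py` (regional MAD heterogeneity,
gradient contrasts, Bland–Altman and Wilcoxon test–retest comparisons).

A thin CLI wraps the same library: `lungdce simulate|quantify|regions|
compare|experiment` (see `--help`; every run writes provenance and
checksummed manifests).

## Library map

| module | contents |
|---|---|
| `lungdce.phantom` | seeded 4D phantoms: gamma-variate AIF, discrete compartment tissue curves, saturating signal map, residual baseline, noise |
| `lungdce.kinetics` | signal→concentration (linear / saturation-corrected), bolus-arrival detection, elimination kinetics |
| `lungdce.aif` | automatic pulmonary-trunk detection, AIF extraction |
| `lungdce.deconv` | Toeplitz convolution matrix, truncated-SVD deconvolution, matched-filter PBF read-out, MTT/PBF/PBV maps |
| `lungdce.regions` | left/right split, six equal-volume regions per lung, vessel exclusion, regional medians |
| `lungdce.stats` | Bland–Altman, exact Wilcoxon signed-rank, regional MAD, gradient contrasts, the paired study table |
| `lungdce.experiment` | carryover schedule, the 2-day × 2-injection simulation, mechanism report |
| `lungdce.io` / `lungdce.cli` | NIfTI/CSV/JSON plumbing, provenance, subcommands |

See `docs/methods.md` for the model, parameter defaults and their
rationale, numerical choices, and known limitations.

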