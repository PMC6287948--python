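# Methods

`lungdce` implements quantitative analysis of 4D dynamic contrast-enhanced
(DCE) lung perfusion MRI on indicator-dilution theory, together with a
synthetic-data generator and an in-silico repeat-injection experiment that
demonstrates how residual circulating contrast agent combined with signal
nonlinearity biases repeated perfusion measurements.

## Tracer-kinetic model

A voxel's tissue concentration curve is the convolution of the arterial
input function (AIF) with a flow-scaled residue function,

    C_t(t) = f · (C_a ⊛ R)(t),      f = PBF / 6000   [1/s],

where R(τ) is the fraction of tracer still inside the voxel τ seconds after
an idealized instantaneous arterial input (R(0)=1, non-increasing). The
three perfusion parameters follow from the shape and amplitude of f·R and
the curve integrals:

* **PBF** (pulmonary blood flow, ml/min/100ml) = 6000 · height of f·R;
* **PBV** (pulmonary blood volume, ml/100ml) = 100 · ∫C_t / ∫C_a over the
  common post-arrival window;
* **MTT** (mean transit time, s) = 60 · PBV / PBF (central volume theorem).

PBV is taken from the integral ratio rather than f·∫R because it is less
sensitive to regularization bias; the equivalence of the two in the ideal
case is a test, not an assumption. MTT is defined through the central
volume theorem; the area/height read-out of the residue is retained as a
diagnostic (`area_height_mtt`) and agrees within discretization tolerance
on clean data.

### Discretization

All curves live on the frame grid (interval `dt`, default 1.47 s). The
convolution is discretized with the rectangle rule, giving a
lower-triangular Toeplitz system `A x = c_t`, `A[i,j] = dt·C_a[i−j]`. The
residue kernel is the exact discrete solution of the single-compartment
washout, `R[j] = (1 − dt/MTT)^j`, rather than a naive sample of
`exp(−τ/MTT)`: at this temporal resolution (dt/MTT ≈ 0.3) only the
discrete kernel satisfies both `R[0] = 1` (height → PBF) and
`dt·ΣR = MTT` (area ratio → PBV) simultaneously, so the central volume
identity holds exactly on the grid. The kernel requires `MTT ≥ dt`;
generation refuses ground truth that violates it. Trunk→tissue transit
delays are quantized to whole frames for the same reason (a fractional
shift is not representable in this discretization).

## Synthetic phantom

The generator emulates the study acquisition: 24 volumes at 1.47 s/volume
(35.28 s), contrast injected 5 s after scan start, bolus reaching the
pulmonary trunk ~3 s later, so 5–8 baseline frames depending on transit
time. Components:

* **Geometry** — two box lungs and a central pulmonary-trunk block on a
  32×32×16 grid (x: left→right, y: ventral→dorsal, z: cranio→caudal),
  voxel 9×9×15 mm. Regions are generated with the same equal-volume
  partitioner used by the analysis.
* **AIF** — gamma-variate first pass, `a·(t/tp)^α·exp(α(1−t/tp))` with
  α = 3, tp = 4 s, peak amplitude 1 (arbitrary concentration units), plus
  an optional recirculation bump. Frame values are averaged over each
  frame interval, so the frame during which the bolus arrives shows a
  partial-volume sliver.
* **Ground truth** — per-region PBF/PBV with a gravity-dependent gradient
  (dorsal ≈ +50% PBV vs ventral, with a longer dorsal MTT) and a mild
  apico-basal gradient; base values PBF 220 ml/min/100ml, PBV 18 ml/100ml
  (MTT ≈ 4.9 s) sit in the range reported for COPD lungs. Tissue curves
  are built by the same discrete convolution the estimator inverts, so the
  noise-free linear phantom is exactly recoverable. An optional smooth
  ventral→dorsal gradient mode scales PBF and PBV jointly per voxel
  (preserving MTT), and an optional vessel mode plants voxels at 5×
  parenchymal PBV.
* **Signal model** — `S = s0·(1 + c/(1 + β·c))`, a rational saturation
  map: monotone, concave, linear for β = 0, asymptote `s0·(1+1/β)`. One
  parameter expresses the nonlinearity mechanism and gives a clean linear
  limit; the full spoiled-gradient-echo equation is deliberately not
  modelled (no relaxivity or sequence calibration exists, and all
  downstream ratios are invariant to the absolute concentration scale).
  Default β = 0.3 dampens the arterial peak by ~23%, chosen together with
  the steady-state scale (below) so that the simulated AIF stability and
  tissue bias reproduce the qualitative pattern the method is built to
  study.
* **Residual contrast** — a prior injection's leftover concentration is a
  constant baseline during the ≤37 s acquisition (elimination half-life of
  hours ≫ scan length). `residual_fraction` is expressed relative to one
  dose's fully mixed steady-state concentration, set to 0.04 of the bolus
  peak: a first-pass bolus is roughly 25× more concentrated than the same
  dose after complete mixing (dose delivered in ~3 s of cardiac output vs
  the whole blood pool). Tissue inherits the residual scaled by its blood
  volume fraction (PBV/100).
* **Noise** — additive Gaussian, clipped at zero, default SD 2% of the
  baseline signal. Rician noise would be the physical choice for magnitude
  MRI; the bias mechanism under study does not depend on the noise law, so
  the simpler model is used and documented as a swap point.

## Signal conversion and arrival detection

Concentration is relative enhancement `(S − S0)/S0` with S0 the per-voxel
mean over pre-arrival frames (≥3 required). The default **linear** mode
ignores saturation deliberately — it mirrors the class of quantification
software whose bias is under study. The **corrected** mode inverts the
rational map given known β and, optionally, a known pre-bolus baseline
concentration map (e.g. predicted from the injection schedule and the
elimination half-life); with both, the inversion is exact. This is an
idealized upper bound on nonlinearity corrections: in practice β and the
residual are only approximately known.

Bolus arrival is the first frame where the trunk-mean signal exceeds the
running baseline mean + k·SD (k = 3) for two consecutive frames; the
2-frame persistence rejects single-frame spikes, and an SD floor keeps the
threshold meaningful on noise-free data. A global arrival is used rather
than per-voxel arrival because the acquisition's temporal footprint (5–8
baseline frames) is a global property; per-voxel delay estimation is out
of scope.

## AIF detection

Voxels in the search volume are scored by peak enhancement × earliness
(rank of the peak frame, earliest best); exactly the top 1% of scorers
(at least 10) are kept and the largest 26-connected component becomes the
trunk. The AIF is the mean curve over that component — a structure, not a
single voxel — and its reported scalar is the trapezoidal integral of the
*converted* concentration curve from arrival to scan end. Detection fails
loudly below 10 voxels or without any enhancement.

## Deconvolution and the PBF read-out

Each acquisition's Toeplitz system is solved once by truncated SVD:
singular values below `truncation_frac·σ_max` (default 0.15, the canonical
bolus-tracking choice, configurable) are zeroed and the pseudo-inverse is
applied to all lung voxels in a single matrix product.

Two well-known artifacts of this regularizer matter at lung temporal
resolution: hard truncation flattens the residue's sharp peak
(underestimating flow by 10–20% at dt/MTT ≈ 0.3), and reading the height
as a per-voxel maximum inflates it under noise (an order statistic over
~19 noisy samples). The default read-out therefore uses a **matched
filter**: the tissue transit delay is identified once per acquisition by
shape-matching delayed model residues against the voxel-median residue,
and each voxel's regularized residue is projected onto the truncated
reconstruction of a unit-height compartment residue at that voxel's MTT,
iterated 4× through the central volume theorem (the projection varies
smoothly with MTT, so the fixed point is stable). On noise-free
model-consistent data the projection is exact at any truncation; at 2%
noise it removes both biases and leaves region-median errors within ~±5%
(PBF) across seeds. Assumptions: monoexponential residue and an
approximately uniform transit delay at this frame rate — both true of the
phantom by construction, stated model approximations for real lungs. The
plain maximum read-out remains available (`pbf_mode="peak_max"`, and in
the per-voxel API `params_from_residue`).

Voxels with non-positive PBF or PBV are flagged invalid, not raised;
whole-acquisition failures (no bolus, degenerate AIF, arrival beyond half
the frames) raise typed errors.

## Regional analysis

Each lung (the two largest connected components, left/right by centroid)
is cut into six regions — upper/middle/lower along z, each split
front/back along y — using whole voxel planes at the cumulative-count
positions nearest 1/3, 2/3 (z) and 1/2 (y), ties toward the lower index.
Cuts by voxel count rather than geometric midplane honour the uniform-
volume requirement; outer slabs deviate from a third by at most half a
plane, and the middle slab absorbs both cut errors (≤1.5 planes pairwise
spread — the price of prescribing both cuts independently). Large-vessel
exclusion removes voxels above a PBV percentile (default 95th) plus a
1-voxel dilation; vessels are blood-filled so apparent blood volume is the
natural criterion. Summaries are per-region and whole-lung medians over
valid voxels.

## Repeatability statistics

* **Bland–Altman**: mean difference, SD (n−1), limits mean ± 1.96·SD.
* **Wilcoxon signed-rank**: zero differences dropped, ties mid-ranked;
  exact two-sided p by convolution of the rank-sum distribution for n ≤ 12
  (scipy's exact mode refuses ties, hence the in-house path, verified
  against full sign-flip enumeration), normal approximation with tie
  correction otherwise.
* **MAD** follows the study's definition — the median over the 12 regions
  of |region median − whole-lung median| per parameter — not the
  conventional median absolute deviation from the median.
* **Gradient contrasts**: dorsoventral = mean(back) − mean(front);
  apicobasal = mean(upper) − mean(lower) with the middle slabs excluded.
* Contrasts pool region-level pairs across subjects by default (each
  region is a data point), with whole-lung pairing available.

## The repeat-injection experiment

`ExperimentDesign` encodes the protocol: two injections of equal dose
32 min apart on each of two consecutive days, elimination half-life 1.6 h
(a 4.2 h impaired-clearance variant ships as
`impaired_renal_design()`). The carryover schedule sums, over all prior
doses, `0.5^(elapsed/T½)`: ≈0.794 of a dose at the second injection of a
day, <0.005% the next morning. True perfusion is held fixed across all
four cells — the simulation models no oxygen physiology, which is exactly
what lets it isolate the measurement bias; a per-subject lognormal factor
(CV 15%, PBF and PBV jointly, preserving MTT ≥ dt) provides inter-subject
variation.

The mechanism, quantitatively: the residual raises the pre-bolus baseline.
In linear mode the measured enhancement of the concentrated, saturated
arterial signal shrinks (concavity plus baseline division) by ~4–5% in
integral at residual 0.79, while the dilute, nearly linear tissue signal
shrinks by <1%. PBV — the tissue/arterial integral ratio — is therefore
inflated at the second injection, and PBF follows through the
deconvolution, while the reported AIF scalar changes little. Because both
errors are smooth in the residual fraction, the bias is monotone over
residual ∈ [0, 0.8]. Note the structural consequence: with
baseline-subtracted relative enhancement and a concave signal map, the
PBV inflation can never exceed the AIF dampening — the bias is real,
directionally robust in every simulated subject, but of the same few-
percent order as the AIF change, not an order of magnitude larger. The
saturation itself contributes a residual-independent bias floor (~+16%
PBV at β = 0.3) that cancels in injection-1 vs injection-2 contrasts.

The corrected conversion with the scheduled residual supplied removes the
residual-induced component entirely in simulation; this is the idealized
ceiling for the nonlinearity corrections proposed in the literature.

## Problem sizes and numerical choices

Default grids (32×32×16×24, ~6,300 lung voxels) quantify in well under a
second, so the shipped experiments use the full study design (10 subjects
× 4 acquisitions). Tolerances used in the validation suite: noise-free
recovery within 5% per region, 2%-noise recovery within 10%,
consistent-system inversion to <1e-8, AIF integral stability within 5% at
cohort level. Degenerate inputs (all-constant series, empty masks,
single-plane lungs, all-zero differences) raise typed validation errors;
ties in partitioning and ranking are broken deterministically, and every
pipeline stage is bit-reproducible under a fixed seed.

## Known limitations

* Concentration units are arbitrary (no relaxivity/sequence calibration);
  only ratios and within-artifact comparisons are meaningful.
* The phantom has piecewise-constant regional truth, box anatomy, no
  breathing motion (the protocol is breath-held), no k-space view-sharing
  simulation, no T2*/susceptibility or extravasation/leakage kinetics —
  passing tests show correctness of the quantification machinery under
  the stated model, not robustness to real-lung deviations from it.
* The matched-filter PBF read-out assumes the monoexponential residue
  family; strongly dispersed or multi-compartment voxels would be read
  with residual bias (the raw maximum mode is the fallback).
* The day-1→day-2 parameter shifts reported in the motivating literature
  are *not* reproduced by elimination kinetics alone (<0.005% carryover);
  the experiment deliberately leaves that discrepancy unexplained rather
  than model effects (renal impairment, extravasation) for which no
  quantitative description exists.
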