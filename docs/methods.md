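# Methods

## The classification problem

Two classes of ¹H NMR spectra share peak positions but differ in peak
intensity, concentrated in the sugar region δ 3.50–6.00 ppm where
glucose/fructose/sucrose resonate; the geo-authentic class has the *lower*
sugar signal on a TSP-referenced scale. The pipeline classifies a spectrum
by the texture of its rendered trace image rather than by the raw vector,
which compresses tens of thousands of points into a 10-dimensional,
rotation- and gray-shift-invariant descriptor.

## Synthetic data generator

`nmrlbp.synth` simulates this structure directly:

* **Lineshape.** Each resonance is a unit-height Lorentzian
  `w² / ((δ−c)² + w²)` scaled by its amplitude — the natural NMR lineshape.
  J-coupling multiplets, solvent lineshapes, phase/baseline artifacts and
  vendor formats are deliberately out of scope.
* **Peak table.** 17 fixed, fabricated peaks spanning the aliphatic
  (0.8–3.1 ppm), sugar (3.5–5.5 ppm; the strongest amplitudes, 28–70 a.u.)
  and aromatic (6.5–9.0 ppm) regions. Real assignment positions for yam
  metabolites are not published, so centers are documented constants chosen
  to populate the three regions realistically.
* **Class effect.** Non-authentic samples multiply amplitudes of peaks
  centered in the sugar region by `class_ratio` (default 1.5 — a strong but
  plausible concentration difference for the discriminating sugars).
* **Biological spread.** Each peak amplitude is jittered per sample by a
  unit-mean lognormal factor with coefficient of variation
  `intensity_cv = 0.1`.
* **Noise.** Additive Gaussian noise with SD 0.7 a.u. = 1 % of the largest
  base amplitude.
* **Axis.** 2048 points over δ 0.50–9.50, stored descending (display
  convention). 2048 points keep every stage fast while leaving ≥ 1.6
  spectrum points per image column after solvent excision; printed
  dimensions of real instrument exports (tens of thousands of points) are
  acquisition-specific and not emulated.
* **Sample sizes.** 70 geo-authentic + 70 non-authentic, a realistic field
  collection for this kind of authentication survey.
* **Determinism.** One `numpy` Generator seeded from `SynthParams.seed`
  (default 101) produces bit-identical datasets.

What passing tests on this simulator do *not* show: robustness to baseline
drift, phasing errors, chemical-shift miscalibration, peak-position
variation, or unbalanced classes — none of which the generator emulates.

## Preprocessing

Crop to δ 0.50–9.50 (regime 1); additionally excise δ 3.28–3.34 and
δ 4.6–5.2 (regimes 2–3). All intervals are closed on both ends (symmetric,
simplest to state and test). Excised points are deleted, not zero-filled:
vectors shorten, and the renderer draws the retained segments contiguously.
No normalization (TSP scaling, integral normalization) is applied.

## Rendering

A minimal deterministic rasterizer: black 1-px 4-connected trace on white,
1156 × 600 px, no axes/ticks/text/anti-aliasing — texture features must not
encode plotting chrome. Columns follow decreasing ppm; each column takes the
*maximum* intensity in its bin (peak-preserving), empty columns are linearly
interpolated, and consecutive column rows are joined by vertical runs.
Intensity 0 maps to the bottom row and the ceiling to the top, clipping
outside [0, ceiling].

**Intensity ceiling.** The default is the *dataset-global* maximum: spectra
referenced to a common internal standard live on one absolute scale, and the
class signal here *is* an absolute sugar-region intensity difference.
Per-spectrum-max scaling (available via `RenderSpec`) makes each image
invariant to global rescaling of its spectrum, but in doing so removes most
of the class signal — on the default simulation the largest per-feature
standardized class difference drops from |d| ≈ 9.5 to ≈ 2–3 and exp3
accuracy from 100 % to roughly 81–95 % depending on the classifier. Use
per-spectrum scaling only when absolute intensities are not comparable
across samples.

## riu2 LBP

Neighbor i of a pixel sits at angle 2πi/p counter-clockwise from the
+column axis on a circle of radius r (defaults r = 1, p = 8). Non-integer
positions are resolved by bilinear interpolation in lerp form
(`a + f·(b−a)`), which is exact on locally constant patches — this
guarantees, bit for bit, that constant regions produce the all-ones pattern.
Exact integer positions use raw pixel values. The threshold is s(x) = 1 ⇔
x ≥ 0, so ties count as 1 and a constant image maps to code p (some LBP
implementations break ties the other way). Patterns with ≤ 2 circular
transitions are coded by their count of set bits; all others share code
p + 1. Border pixels of width ⌈r⌉ are skipped rather than padded (padding
would inject artificial edge texture). Histograms are frequency-normalized
by default so vectors are comparable across image sizes.

Verified invariances: exact equality under 90°/180°/270° rotation and under
constant gray shifts; agreement with an exhaustive brute-force oracle on all
256 patterns and with an independent third-party implementation on random
images; codomain size p + 2 for p ∈ {4, 6, 8, 12}.

## Classification and evaluation

* **KNN** — Euclidean majority vote, default k = 5 (the parameter is not
  prescribed; k = 1 is used in self-consistency tests). Vote ties (even k)
  fall to the tied class with the smaller summed neighbor distance, then to
  label sort order — a documented deterministic rule.
* **Decision tree** — axis-aligned binary partitioning, Gini impurity,
  unlimited depth, min leaf 1, fixed seed.
* **Linear SVM** — soft margin, C = 1.0 by default (the linear kernel
  leaves only C); on separable toys the fitted (w, b) satisfies the margin
  property y(wᵀx+b) ≥ 1 − 1e−6 at large C.
* **Folds** — per-class shuffle followed by a single round-robin deal
  across classes: per-class fold sizes differ by ≤ 1 and overall sizes are
  as even as possible (140 balanced samples → five folds of exactly 28,
  14 + 14).
* **Metrics** — ACC = (TP+TN)/total·100, SEN = REC·100 = TP/(TP+FN)·100,
  PRE = TP/(TP+FP), F1 = 2·PRE·REC/(PRE+REC); any 0/0 is defined as 0 and
  logged. The positive class is geo-authentic. Headline numbers are pooled
  over the concatenated test folds (a 140-sample pooled confusion makes
  two-decimal percentages exact multiples of 1/140); fold means are also
  reported. Wall time covers training + prediction only and is
  hardware-dependent, hence reported but never asserted.

## k-means and projections

Lloyd iterations from k distinct random data points (kept deliberately
simple rather than k-means++; the seed is exposed). Empty clusters are
re-seeded from the point farthest from its assigned center. Inertia is
non-increasing by construction and the result is a fixed point up to the
tolerance. Projections: per-sample mean vs *population* STD (divisor n — a
descriptive statistic of the sample's own vector; the sample-STD variant is
a one-line change), or two feature columns. When the feature pair is drawn
at random, constant (structurally zero) LBP columns are skipped — several
riu2 codes never occur on line-trace images.

Under the default strong effect both the raw mean/STD projection and the
LBP-pair projection cluster perfectly (Rand index 1.0); the LBP pair's
advantage becomes strict at weaker effect sizes (e.g. class ratio 1.2),
which is how the property is tested.

## Problem sizes used in checks

The full 70 + 70 dataset at default settings is used for the headline
pooled-accuracy computation and the regime-ordering check. Monte-Carlo
properties (sugar-region class effect, null-effect chance-level accuracy)
run 20 seeds at reduced size (8–10 samples per class, 512-point axis) —
the properties are size-independent and this keeps the suite fast.

## Known limitations

* The simulator's peak table is fabricated; absolute accuracies on it do
  not transfer to real yam spectra, only the relative behavior of the
  pipeline stages does.
* The renderer is one of many possible spectrum-to-image conventions; other
  renderers (axes, anti-aliasing, different scaling) shift LBP histograms
  by systematic amounts. `RenderSpec` exposes the knobs needed to match an
  external renderer.
* Binary classification only; no hyperparameter search, no non-linear
  kernels, no probability calibration.
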