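# Methods

This note records the models, defaults and numerical choices behind the
package, and what the synthetic data do and do not establish.

## Compound library and mass arithmetic

The annotation fixture (`data/table1.tsv`) holds 68 phenolic metabolites
with formula, published deprotonated exact mass, MS² fragment list
(`mz:relative-intensity` pairs, percent of base peak), retention time,
compound class, reference-standard flag and species distribution
letters (A = *S. hercynicus* … E = *J. maritima*). Monoisotopic [M−H]⁻
masses are computed from a five-element table (C 12.000000,
H 1.0078250319, N 14.0030740052, O 15.9949146221, S 31.97207069) minus a
proton (1.007276 Da); this reproduces the published values to better
than 3 ppm for 67 of 68 compounds. Two source quirks are preserved
rather than repaired: compound 18's published mass (337.1500 for
C₁₆H₁₈O₈) disagrees with its formula by 169 ppm, so the fixture carries
both the published and the recomputed value; and compound 48's published
mass is one final-digit ulp above the exact value (595.1669 printed vs
595.16684 computed, 0.17 ppm). The abundance fixture
(`data/table2.tsv`) is the published 51-compound × 5-species matrix,
row-normalized to 0–100 with 0 meaning not detected.

## Synthetic LC-MS runs

The generator emulates the acquisition actually used for the extracts:
negative-mode full scans over *m/z* 100–1000 with data-dependent MS² of
the library compounds at their library retention times. Each planted
compound contributes a Gaussian chromatographic peak whose analytical
area equals its ground-truth abundance. Defaults, with reasoning:

| parameter | default | why |
|---|---|---|
| peak sigma | 0.015 min | a typical UHPLC peak width; crucially, narrow enough to resolve the closest same-mass isomer pair in the retention ladder (rutin vs isorhamnetin-*O*-pentosylhexoside, 0.09 min apart), which the study's chromatography demonstrably resolved |
| scan interval | 0.3 s | Orbitrap-class full-scan rate; ≈ 6 points per sigma |
| RT span | 0–13 min | covers all 68 library retention times |
| RT drift sd | 0.02 min | run-level offset (the whole gradient shifts together) plus a per-compound jitter at one fifth of that sd; drift in practice is dominated by the shared component |
| *m/z* jitter | 3 ppm | well inside the 15 ppm screening gate, as for a calibrated Orbitrap |
| fragment intensity CV | 0.10 | multiplicative noise on MS² intensities |
| decoys | 20 per run | random precursors kept ≥ 25 ppm from every library mass, so a decoy passing the screen would indicate a logic error rather than bad luck |

The source reports no noise magnitudes; these are package choices. A
`low_noise` preset (drift 0.005 min, jitter 1 ppm, CV 0.02) defines the
recovery conditions used by the acceptance checks. DDA scheduling is
simplified to one MS² scan at each peak apex plus up to two more within
±1 sigma — enough to exercise scan grouping; Top-N scheduling, isotope
patterns and chimeric spectra are not modelled. Ground-truth abundances
default to the published normalized matrix rescaled to areas (1000 area
units per normalized point), preserving its zero pattern.

Because generation is a pure function of (library, truth, settings,
species, seed) and the writers use fixed formatting, identical seeds
give byte-identical MGF/TSV files.

## Screening

The four gates follow the published criteria exactly; where the source
is silent the choices are:

- **Fragment tolerance** reuses the precursor rule (15 ppm with a
  0.0010 Da floor): one consistent mass-accuracy model.
- **Fragment recall** is reference-anchored — matched reference ions
  over reference ions with relative intensity ≥ 1% (the floor guards
  against trace ions) — and strictly greater than 2/3.
- **Intensity error** is an absolute difference in base-peak-normalized
  percentage points. Both query and reference are renormalized to their
  own base peak first; a few published fragment lists top out below
  100%, and without renormalization those compounds could never pass
  their own reference spectrum.
- **Scan grouping** merges passed scans within 0.1 min of the best match
  (the source does not define "same chromatographic peak" numerically).
  The published averaging formula divides the intensity-weighted sum by
  the scan count N, which does not return an *m/z* unless the weights
  average to one; the standard intensity-weighted mean (divide by
  Σ intᵢ) is implemented instead.
- A scan that passes for two targets is kept for both: annotation is
  per-target in targeted screening. In practice the intensity gate
  separates the co-eluting same-mass acylquinic-acid isomer pairs
  (their base peaks differ), and retention time separates the rest.

## Quantification

XICs are extracted per scan as the summed intensity within the mass
tolerance of the target, restricted to a ±0.03 min (2 sigma) window
around the annotated apex, and integrated by the trapezoidal rule. The
narrow window is what makes the closest same-mass neighbours in the
retention ladder (0.06 min apart) independent; the uniform ~4.6% tail
truncation cancels exactly in row normalization. Optional
window-minimum baseline subtraction is available but off by default —
the synthetic MS¹ has no baseline offset, and subtracting the window
minimum from a clean Gaussian biases its area. A compound counts as
detected in a species iff it has at least one passed screening match
and positive integrated area; normalization is per compound across
species (max-scaling only — zeros appear only for non-detections, so no
min-max shift is applied).

## Clustering and PCA

Clustering operates on the normalized 0–100 matrix directly (no
per-row z-scaling). Ward.D2 is implemented by hand via the
Lance–Williams recurrence on squared Euclidean distances, with ties in
merge cost broken toward the lexicographically smallest label pair for
platform-independent dendrograms; scipy's `linkage(..., "ward")` serves
as an independent oracle in the tests (agreement checked through
cophenetic distances on random matrices up to n = 12). PCA defaults to
centered, unscaled — the variables already share the 0–100 scale — with
a `scale` switch; cos² of an observation on a component is its squared
score over its squared distance to the centroid, summing to 1 over all
retained components. The number of compound-side clusters in the
published heatmap depends on an unstated cut height and is treated as a
visualization choice, not a pinned result.

## Morphometrics

The generator draws multivariate-normal samples per species (counts
rounded to integers, truncated at 1 — note rounding slightly attenuates
count-character correlations, so the generator exposes a `discretize`
switch). The default profiles are synthetic: they encode only the
qualitative structure reported for the taxa — root diameter (X₁)
separating the genera; leaf width (X₄) homogeneous within *Senecio* and
separating the two *Jacobaea*; bract/ray/disc counts (X₆, X₈, X₁₀)
mutually positively correlated and negatively correlated with stem
height (X₂); capitula count (X₁₂) at ~45 %CV against ~12 %CV elsewhere —
with magnitudes chosen as botanically plausible. The raw measurements
live in an appendix without a machine-readable deposit, so the split-
dependent published error counts ("all but one" of 15) are not
desk-reproducible; the package instead reports accuracy distributions
over 50 seeded 80/20 splits.

Best-subset selection is exhaustive over the 4095 non-empty subsets.
Since the original used a regression-subsets routine on a classification
problem without stating the response coding, the species response is
one-hot coded and RSS summed over the indicators; metrics are reported
on a per-response scale so the classical identities hold (the full
model's Cp is p+1), and Wilks' Λ per subset is reported alongside as the
classification-native ranking. The BIC optimum is the default chosen
subset.

LDA is first-principles: discriminant directions are eigenvectors of
the generalized problem B v = λ W v normalized to vᵀSw v = 1 (at most
classes − 1 of them, signs fixed so the largest-magnitude coefficient
is positive), and prediction minimizes Mahalanobis distance to the
class means under the pooled covariance minus 2·log prior. Priors are
equal (balanced design, 15 plants per species). Predictions and scores
(up to sign) are invariant to affine rescaling of any input variable.

## What the synthetic data do not show

Passing recovery tests demonstrates the correctness of the screening /
integration / normalization logic under the stated noise model, not
performance on real chromatograms: co-elution beyond the library's own
retention ladder, baseline drift, in-source fragmentation (the likely
reason one three-species compound is absent from the published
abundance matrix), detector saturation and isotope interference are all
outside the model. Likewise the morphometric generator reproduces the
reported qualitative structure, not the real per-species means, so LDA
accuracies describe the synthetic regime only.

## Problem sizes

Default checks use the five-species run set (~200 planted peaks plus
100 decoys), 51-compound matrices, 75-plant tables, and 50 LDA split
replicates; the full suite and the acceptance script each complete in
well under a minute on one core.
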