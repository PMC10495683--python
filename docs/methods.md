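# Methods

## Scope

`simplemux` processes sequential chromogenic immunohistochemistry (IHC)
experiments in which one tissue section is stained, imaged, and chemically
erased over several rounds — hematoxylin counterstain plus one AEC-revealed
antigen per acquisition — and merges the rounds into a single aligned
multi-channel image. It also implements the matching label-free DIA
(data-independent acquisition) quantitation chain used to compare the
proteomes of microdissected tissue structures. Everything is exercised on
ground-truthed synthetic data; the generators are first-class, tested code.

## Colour deconvolution

Brightfield chromogens attenuate light multiplicatively, so stain
contributions combine approximately linearly in optical density
(Beer–Lambert): `OD_c = -log10(I_c / I0_c)` per RGB channel `c`, with `I0`
the background white point. Each stain is a unit 3-vector of relative
absorbances; stacking hematoxylin, AEC, and an orthogonal residual
(normalised cross product of the first two) gives an invertible 3×3 stain
matrix `M`. A pixel's OD row vector decomposes as `od = c · M`; the
concentrations are `c = od · M⁻¹`, with negative solutions clipped to zero
and the clipped fraction reported as QC (a high fraction indicates a
mismatched stain basis).

Numerical choices:

* Default stain vectors are the published colour-deconvolution values,
  hematoxylin (0.650, 0.704, 0.286) and AEC (0.274, 0.679, 0.680),
  normalised at load; both are overridable in the study manifest. They are
  a documented default, not a claim about any particular scanner.
* Default background is `I0 = (255, 255, 255)`; `estimate_background`
  offers a per-channel percentile estimate (default 99th) floored at 1.
* Zero intensities are floored to 1 before the log, bounding OD at
  `-log10(1/255) ≈ 2.407` against a 255 background.
* The tiled path (`unmix_tiled`) streams `tile × tile` blocks and is
  bit-identical to whole-image processing because every operation is
  pixel-wise; only the three float64 output planes are whole-image buffers.

## Registration

Rounds differ by a near-rigid 2-D transform (re-coverslipping, restage).
Given ≥ 3 manually paired landmarks, the affine `p_ref = A·p_mov + t` is the
least-squares minimiser, solved via SVD (`numpy.linalg.lstsq`) rather than
normal equations — manual points often cluster, and the normal equations
square the condition number. No outlier rejection is applied (pairs are
curated by a human); residuals above 5 px are logged as suspect. With
exactly 3 non-collinear pairs the fit interpolates exactly. Warping samples
the moving image at `T⁻¹(p_ref)` with bilinear interpolation for intensity
and concentration images (nearest available; integer images round-trip
bit-exactly under nearest). Coordinates are (x, y), 0-based, origin
top-left, x rightward, y downward, in every module.

## Assembly

Each acquisition is unmixed; its AEC concentration map becomes that
antigen's channel, warped into the reference frame through the transform
fitted from its control points. Design choices:

* One acquisition = one antigen; two antibodies applied in the same
  staining round appear as two acquisitions sharing a `round_index`.
* The hematoxylin channel comes from the reference acquisition only and is
  never warped: the counterstain is re-applied every cycle and the
  reference defines the frame. Hematoxylin maps of other rounds are
  discarded.
* Every round registers directly to the reference (no round-to-round
  chaining), avoiding error accumulation.
* Channel order: hematoxylin, then antigens by (round, acquisition order).

Export is a float32 multi-channel OME-TIFF via `tifffile`. Channel name and
display colour use the native OME Channel attributes; the staining round
and antibody text ride in the free-text `Fluor` attribute
(`round=<n>;antibody=<text>`) because the OME schema has no slot for a
chromogenic staining-round integer. The composite renderer normalises each
channel to [0, 1] at a configurable percentile (default 99th), multiplies
by its display colour and sums additively.

The carryover QC statistic estimates incomplete chromogen erasure: the
median of `later/earlier` over pixels where the earlier channel exceeds a
positivity threshold. It assumes the two antigens occupy mostly disjoint
tissue patterns; where patterns overlap, genuine later-round signal
inflates the estimate, so it is an upper bound there.

## DIA quantitation

The rollup follows the standard top-N convention: peptide quantity per
sample = sum of its 3 most intense precursors (all if fewer); protein
quantity = mean over retained peptides, keeping at most the 10 peptides
with the highest cross-sample mean (lexicographic tie-break for
determinism) and requiring at least 2 distinct peptides (single-hit
proteins are excluded). The published parameters state the top-3 and
min-2/max-10 rules but not the aggregation operators; sum-then-mean is this
package's documented choice and is isolated in one function.

Global normalization median-centres samples in log2 space: each sample is
scaled so its median log2 quantity equals the grand median of the
per-sample medians. Missing values (below the detection limit) stay
missing; no imputation.

Differential abundance uses Welch's t-test on log2 quantities per protein
with Benjamini–Hochberg FDR across tested proteins, and the decision rule
FDR ≤ 0.05 AND |log2 FC| ≥ 0.58 (fold change ≥ 1.5; `round(log2 1.5, 2) =
0.58`). The upstream tooling this emulates scores differential abundance
with a Bayesian model whose internals are not public; this package
implements the stated decision thresholds behind the same interface and
makes no claim of reproducing that model's posterior scores. Proteins with
fewer than two observed values in either group are reported `tested =
False` rather than dropped. The localization summary takes the protein list
and a protein→categories table (four-term vocabulary: nuclear, cytosol,
plasma_membrane, extracellular_matrix) and reports overlapping category
percentages plus the percentage with ≥ 2 localizations.

## Synthetic generators

The phantom emulates the acquisition cycle, not histology: nuclei are
Gaussian blobs (shared hematoxylin field), antigen patterns are smooth
parametric fields (blob / ring / scattered, plus half-frame confined
variants whose disjoint support the carryover QC assumes). Per acquisition
the generator composes hematoxylin + antigen AEC + carryover × the previous
acquisition's AEC (immediate-predecessor only, emulating the erase–restain
cycle), mixes through the stain matrix, converts to 8-bit RGB, observes the
scene through the inverse of that acquisition's true affine, and adds
Gaussian camera noise. Defaults: 192×192 px, 60 nuclei, the five-marker
panel CD31/SFTPC (round 1), RAGE/ACTA2 (round 2), TUBB4B (round 3),
rotation ≤ 3°, translation ≤ 8 px, scale deviation ≤ 2%, noise σ = 2
intensity levels, carryover 0.05 — small misalignments and modest noise, as
for a well-behaved slide scanner. Control points are true landmark pairs
with i.i.d. Gaussian jitter (default σ = 0.5 px) emulating manual clicking,
so the true transform's residual RMSE concentrates at σ√2.

The DIA study generator draws log-normal intensities from a protein /
peptide / precursor hierarchy: protein baseline N(20, 2²) in log2 units
(~10⁶ median raw intensity), peptide and precursor response offsets (σ = 1
and 0.5), a per-(protein, sample) biological term (σ = 0.3) shared by the
protein's precursors — this keeps the protein-level within-group variance
from vanishing under peptide averaging — and technical noise (σ = 0.5).
Peptide counts are 1 + Poisson(2.5), so ~8% of proteins are single-hit and
exercise the exclusion rule; precursor counts are 1 + Poisson(1). Planted
effects multiply group-B intensities by `2^fc` (default |fc| = 2, random
sign) on a chosen fraction of proteins. Intensities below the detection
limit (default 2¹⁵, ~1–2% of measurements) are recorded missing, emulating
below-detection-threshold dropout.

What the generators do not emulate — and therefore what passing tests do
not demonstrate about real data: tissue texture and stain inhomogeneity,
non-affine deformation (folds, tears), illumination gradients,
intensity-dependent (heteroscedastic) MS noise, interference/co-elution,
and shared-peptide protein inference. Results on phantoms bound the
algorithmic error, not the biological one.

## Problem sizes and tolerances

Tests and the acceptance script use desk-scale problems chosen as the
smallest sizes at which the measured statistics stabilise: 192×192 phantoms
(the processing is resolution-independent and pixel-wise or landmark-based),
200 Monte-Carlo replicates for the control-point jitter calibration
(tolerance 5% on the σ√2 prediction), 100–200 null studies of 2000 proteins
for false-discovery behaviour, and randomized ≤ 20-protein tables against a
brute-force rollup oracle (agreement to 1e-12 relative). The noiseless
unmix/mix round trip is asserted at 1e-6; 8-bit quantisation bounds the
noiseless phantom recovery error at ~0.05 OD through the inverse stain
matrix. Tiled-vs-whole equivalence is asserted bit-exact, not approximate.

## Known limitations

* Stain vectors are fixed inputs; no automatic stain estimation,
  flat-field correction, or > 3-stain unmixing.
* Registration is a single global affine per round; no nonlinear warps or
  multiresolution refinement, and no automatic (intensity-based) matching.
* OME-TIFF export is single-resolution (no pyramids); very large slides
  should be unmixed tiled and assembled downstream.
* The differential test is a two-group Welch t; no covariates, paired
  designs, or shrinkage variance estimators.
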