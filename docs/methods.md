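# Methods

`atquant` reimplements, as a tested pipeline, the image-analysis and assay
arithmetic used to quantify synaptic puncta and amyloid-beta in array
tomography of human brain tissue, together with a synthetic serial-section
generator that provides ground truth for every stage.

## The imaging model

Array tomography images ribbons of ultrathin (70 nm) resin sections.  A
field of view is imaged at the same location on 15–30 sequential sections
in up to three channels: a pre-synaptic marker (synaptophysin, `SYP`), a
post-synaptic marker (PSD95) and an amyloid-beta conformational antibody
(`OC`).  Because section thickness is far below the axial diffraction
limit, reconstructing objects across sections gives sub-diffraction axial
resolution: a genuine protein cluster ("punctum") reappears on at least
two consecutive sections, while staining specks and section artefacts do
not.  That observation drives the noise rule at the heart of the
segmentation stage.

The processing chain is:

1. **Background removal.** Each section's smooth background is estimated
   with a median filter and subtracted (clamped at zero).  The default
   radius is 10 px (window 21 px ≈ 2 µm at the default 0.1 µm pixel
   size).  The window must be large relative to the punctum footprint
   *including* the crowding of neighbouring puncta: with windows only a
   few times the punctum diameter, the local median inside dense neuropil
   is raised by the puncta themselves and the filter subtracts signal
   (measured as tens of counts at a 13 px window versus ~2 counts at
   21 px on the default simulation).  For integer-valued (camera ADU)
   sections the median uses the histogram-based rank filter, which is an
   order of magnitude faster at these window sizes; fractional input
   falls back to the exact sliding-window median.
2. **Rigid registration.** Translation-only alignment, the dominant mode
   of ribbon misalignment.  Shifts between neighbouring sections of one
   reference channel (default `SYP`) are estimated by subpixel phase
   cross-correlation, compounded against a middle reference section, and
   applied identically to every channel.  Registration runs *after*
   background subtraction: a stationary background gradient is a strong
   zero-shift attractor for any correlation-based estimator.  Neighbour
   estimates below 0.1 px are snapped to zero so an already-aligned stack
   registers as an exact no-op instead of accumulating estimation noise
   across sections.  All channels are cropped to the common valid field;
   density and burden denominators downstream use the cropped volume so
   edge-fill voxels never bias them.  Accuracy is photon-limited: on the
   default 256×256 px simulation the worst per-section error over 20
   seeds is ≈0.2 px; substantially smaller fields degrade this.
   Rotation is out of scope (translation-only by design).
3. **Segmentation.** Per-section auto-local thresholding: a voxel is
   foreground iff its intensity strictly exceeds a local statistic plus an
   offset.  The default statistic is the local mean over a 32 px window;
   Niblack and Phansalkar are selectable, and the method with its
   parameters is recorded as provenance in every mask and output table.
   Thresholding is 2D per section (staining intensity varies section to
   section).  3D objects are then maximal connected components under full
   26-connectivity (puncta drift laterally between sections; diagonal
   continuity must not split objects), and every component confined to a
   single section is removed.  No minimum-area filter is applied by
   default; the single-section rule is the only noise filter.
4. **Quantification.** Per channel: object count, density (objects per
   mm³ of analysed volume), burden (% of analysed volume that is
   foreground; a per-section area-% variant is also exposed for 2D
   readouts).  Per ordered channel pair (A, B): the percentage of
   A-objects whose own volume overlaps B's foreground by at least 25%
   (inclusive; the denominator is always the tested object's volume, so
   the relation is deliberately asymmetric).  Synaptic pairing: pre/post
   objects whose unweighted voxel centroids (physical µm,
   anisotropic-aware) lie within 0.5 µm (inclusive), matched one-to-one
   greedily by ascending distance with lexicographic id tie-breaks.
   Greedy matching is deterministic and, at biological puncta spacing,
   attains the exact maximum-cardinality minimum-distance matching (the
   test suite verifies this against an enumeration oracle on small
   instances).  Percentages over an empty object set are errors, not
   zeros — "no synapses" must not masquerade as "no colocalization".

The three decision thresholds live in one `PairingCriteria` object:
overlap ≥ 0.25 (inclusive), centroid distance ≤ 0.5 µm (inclusive), and
the downstream pathology binarization at ratio > 2 (strict).  Boundary
behaviour of each is pinned by tests at the exact threshold value.

## The synthetic generator

`simulate_roi` emulates what the acquisition produces, with a manifest of
everything true.  Defaults are the package's standing model of moderately
dense adult human neuropil at this resolution and are not tuned per run:

| parameter | default | rationale |
|---|---|---|
| field | 256×256 px × 20 sections (0.1, 0.1, 0.07 µm voxels) | protocol-scale ROI (~917 µm³) |
| pre/post density | 0.25 /µm³ each | 2.5×10⁸ per mm³, the order reported for synaptic puncta in aged human cortex |
| A-beta blob density | 0.05 /µm³ | sparse pathology channel |
| punctum half-max radius | 0.2 ± 0.05 µm (min 0.1) | diffraction-limited spot; diameter ≥ 2 sections so true puncta always span ≥ 2 sections |
| amplitude | 400 ± 40 counts over background 50 | 16-bit-scale camera counts, shot-noise-limited |
| pairing fraction | 0.3 at offsets ≤ 0.3 µm | constructed pairs sit safely inside the 0.5 µm criterion |
| post↔A-beta coloc fraction | 0.3 | A-beta blob concentric with the post punctum, radius ≥ 1.1× |
| jitter | integer, ≤ 3 px per section | ribbon misalignment; subpixel mode available |
| specks | 5 per section per channel | single-section noise the 2-section rule must remove |

Puncta are isotropic 3D Gaussians sampled at voxel centres; "true volume"
is the voxel set within the half-maximum radius, which is unambiguous for
both the Gaussian render and the hard-edged `solid` render used for
exactness checks (with `solid` blobs, any threshold between background
and amplitude reproduces the truth mask bit-for-bit, so noise-free runs
recover counts and burden exactly).  Unpaired post-synaptic puncta are
rejection-sampled to stay ≥ 0.7 µm from every pre-synaptic centroid, and
independent A-beta blobs ≥ 0.5 µm from post centroids, so the constructed
pairing and colocalization fractions are also the true fractions
recoverable under the criteria — without the exclusion, chance
proximity at these densities would add a few percent of "accidental"
pairs that the manifest could not label.  Jitter vectors are normalized
so the middle (reference) section is zero, matching the registration
convention.  A single seed expands into fixed, append-only substreams per
channel and stage, so adding a channel or stage never perturbs another's
draws.  The generator does **not** model optical PSF physics, spectral
bleed-through, ribbon curvature, plaque morphology, or intensity
correlations between channels; passing recovery tests therefore
demonstrates correctness of the measurement chain on well-specified
input, not robustness to every property of real tissue.

The pipeline's default segmentation offset (190 counts) is the package's
calibration for this amplitude scale: thresholding at roughly half the
nominal punctum peak makes segmented volumes track the half-maximum truth
definition.  On real data the offset is a per-dataset choice; every
output records the value used.

## What recovery looks like at the default conditions

Counts are biased a few percent low because nearby puncta merge into one
26-connected component (the pipeline deliberately does no watershed
splitting); the merge rate is a property of the density, not of the
implementation, and is binomially noisy seed to seed.  Recovery
assertions are therefore made on seed aggregates: mean relative error
across ≥ 20 seeds within ±15% for density and burden, and per-seed 95%
binomial confidence intervals covering the configured pairing and
colocalization fractions for at least 80% of seeds (nominal coverage
95%).  Registration recovery is asserted as worst per-section error
≤ 0.5 px over 20 seeds of integer jitter.

## Assay and effects arithmetic

* BCA normalization: `raw (pg/ml) × dilution / total protein (mg/ml)` →
  pg analyte per mg total protein.  Below-detection values are explicit
  left-censored records, excluded from ratios with a warning, never
  imputed as zero (no imputation rule is defensible without the assay's
  limit of detection).
* A-beta 42/40 ratio, unit-free given matching units; a pM ↔ pg/ml helper
  takes the isoform's molecular weight from the caller rather than
  hard-coding peptide masses.
* Relative expression by 2^−ΔΔCt against a housekeeping gene (GAPDH by
  default) and a control condition.
* LDH cytotoxicity: `100 × sample / assay maximum`.
* Control normalization in percent (control ↦ 100) and subtraction
  (control ↦ 0) modes; binary pathology readout strictly > 2-fold.
* Spearman's rho as Pearson correlation of mid-ranks; constant vectors
  and n < 3 are errors.  p-values and all mixed-model fitting (GLMM /
  LMEM with Tukey post-hoc) are deliberately out of scope: the package
  ends at `export_model_table`, a verified tidy CSV with covariate
  columns (`age, sex, brain_region, apoe, pathology`) ready for external
  statistics software.  The fold-binarization accepts either per-ROI or
  per-case aggregated inputs; which was used is the caller's record.

## Numerical choices and degenerate inputs

Thresholding uses strict `>` against statistic + offset; even windows are
promoted to the next odd size.  Local statistics use reflected image
boundaries.  Voxel centres sit at `(index + 0.5) × spacing`.  Stacks
outside the 15–30 section protocol range load with a warning rather than
an error (the range is a protocol property, not a validity condition).
Featureless registration references raise, naming the section.  Zero
analysed volume, empty object lists for percentages, non-positive
controls, protein or LDH maxima, and mismatched genes in ΔΔCt are all
explicit errors.  Everything stochastic flows from a single integer seed;
identical config + seed reproduces every CSV byte-for-byte.

## Problem sizes

Tests and the acceptance script use 256×256 px × 16–20 section fields,
20-seed recovery batches, and brute-force oracle instances of ≤ 32×32×4
voxels, ≤ 8 objects per side, and n ≤ 12 — sizes at which the oracles are
exhaustively checkable while the simulated conditions remain at protocol
scale.
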