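# Methods

This note documents the model choices, parameters, numerical conventions and
known limitations of the `lungcbir` retrieval engine.

## Inputs and label dialect

The engine consumes three co-registered 3-D voxel grids: a lung mask
(0 background, 1 right lung, 2 left lung), a finding-label volume, and the CT
volume in Hounsfield units, with physical spacing in mm (NIfTI in/out via
nibabel). The finding-label dialect is fixed by the shipped schema
(`lungcbir/data/findings_schema.json`): codes 1–26 are the parenchymal
finding categories in a documented order; 0/27/28 are reserved for
background, airway and vessel. Airway and vessel voxels lie inside the lung
mask but are not findings: they count in region volumes (denominators) and
never in finding percentages. The schema also fixes the 11-group coarse
regrouping used on wide regions and the lesion definition (all findings
except normal lung and borderline-normal; 24 of 26).

Axis convention is declared, not inferred: axis 0 cranio-caudal (index
increasing caudally), axis 1 antero-posterior (increasing dorsally), axis 2
medio-lateral in either direction. Volumes are voxel count × voxel volume,
reported in mL. No resampling is performed; grids are used as given.

## Region hierarchy

Four levels, 33 regions: whole lung / per-lung / thirds / thirds ×
antero-posterior halves × medio-lateral inner:outer. Stated volume ratios:
upper:middle:lower 1:1:1, ventral:dorsal 1:1, inner:outer 1:2.

Design choices made where the geometry was genuinely open:

* **Nested, not global, cuts.** Each split is computed within its parent
  region, so every level exactly refines the previous one and the 24-region
  naming is the product of the 6-region naming.
* **Whole-slice cuts with deviation-minimizing indices.** A cut is a plane
  between grid slices; indices are chosen by exhaustive search to minimize
  the maximum absolute deviation between achieved and target cumulative
  volume fractions, ties broken toward the smaller index. This is exact,
  deterministic and resolution-robust; the achieved ratio deviates from the
  target by at most one slice's voxel mass.
* **Inner/outer as a medio-lateral volume cut,** with "inner" the slab on
  the mediastinal side of each lung (the side facing the whole-lung
  centroid), not a distance-from-pleura peel. A pleural-distance band would
  also be defensible; the axis cut was chosen because it composes with the
  other two axis cuts into a clean product partition and needs no surface
  extraction. Mirroring a volume along the medio-lateral axis maps
  inner→inner, outer→outer by construction.

The partition is stored as a single level-3 label map (codes 1–24); every
coarser region is a fixed union of level-3 codes, which makes disjointness,
nesting and volume conservation structural rather than incidental.

## Features

Per level-3 region (30 features): the 26 per-finding volume fractions, region
volume (mL), mean and variance of CT (HU, HU²), lesion fraction. Per coarse
region (12 features): the 11 grouped fractions plus volume. Conventions:

* Fraction denominators are **all** lung-mask voxels of the region, airway
  and vessel included, so Σ of the 26 fractions may be < 1.
* CT mean/variance run over all region voxels (airway/vessel included) —
  whether the upstream convention excludes them is unknowable from the
  printed material; including them is the simpler, documented choice.
* Variance is population variance (divide by N).
* Fractions live on [0, 1], never percent. This matters: the feature-weight
  constant 300 makes a percent scale degenerate (the weight would sit at its
  floor for any nonzero percentage), which supports the [0, 1] reading.
* Empty regions yield all-zero features with a logged warning instead of an
  error, so degenerate masks remain usable.

## Normalization

Each (region, feature) slot is z-scored with the mean and population
standard deviation of that slot over all registered cases. Degenerate slots
(deviation 0, i.e. constant across the database) map to z = 0, which
removes them from every distance; deviations below 1e-12 (relative) are
snapped to exact zero so floating-point cancellation cannot resurrect a
constant slot. A query is normalized with the database's statistics and is
never included in them, matching the leave-one-out protocol. Statistics are
recomputed explicitly, not incrementally, for reproducibility.

## Similarity

Per level k ∈ {0,1,2,3} with M_k regions and N_k features:

    S_k = Σ_m wr(m) · √( Σ_n wf(m,n) · (fc − fq)² )

* **Area weight** wr(p) = 1/(1+exp(−5.0·(p−0.5))), p = the **query's** raw
  regional lesion proportion. Diseased regions of the query dominate.
* **Feature weight** wf(p) = 1.5/(1+exp(300.0·p)) + 0.25, p = the
  **candidate's** raw finding proportion (fine level) or group proportion
  (coarse levels — the coarse features are group sums, so the group sum is
  the natural argument). It boosts findings rare in the candidate; range
  (0.25, 1.0]. The coarse volume feature is not a finding and carries
  wf = 1 (configurable). At the fine level the four non-fraction features
  (volume, CT mean, CT variance, lesion fraction) form a second, unweighted
  block under its own square root, sharing the region's area weight.
* **Level weights** normalize region count and feature dimensionality so the
  four levels contribute comparably: ws_k = 1/(M_k·√N_k) for k ≤ 2 and
  ws_3 = 1/(24·(√26+√4)). With these, a uniform unit z-difference in every
  slot contributes exactly equally per level (a tested identity). Only the
  intent of the level weights is externally fixed; this concrete choice is a
  package decision, overridable in `SimilarityConfig`.

Lower S_total means more similar — the formulas are weighted Euclidean
distances, and ranking is ascending with lexicographic case-id tie-breaks.
The measure is deliberately **asymmetric** (wr follows the query, wf the
candidate); the test suite asserts the asymmetry on a constructed pair
rather than "fixing" it. All similarity constants (5.0, 0.5, 1.5, 300.0,
0.25) default to their standard values and are configurable.

## Synthetic cohorts

The generator emulates upstream segmenter output: two jittered ellipsoidal
lungs (default grid 64³ at 1 mm isotropic — large enough for a clean 33-way
partition, seconds per case), a sprinkle of airway (0.5%) and vessel (2%)
voxels, then per-finding blob growth. Each finding has a target whole-lung
fraction and a spatial prior over the 24 level-3 regions built from per-zone
multipliers; blob centers are sampled region-wise from the prior and grown
6-connected through remaining normal-lung voxels until the target count is
met exactly (or the lung saturates, with a warning). CT values are sampled
i.i.d. per voxel from a per-finding normal HU model (e.g. normal lung
−850 ± 40, GGO −600 ± 70, consolidation +40 ± 50, emphysema −950 ± 25).
All randomness flows from one seed; identical seeds give byte-identical
volumes.

Six phenotypes are shipped as configuration (not clinical truth claims):
`uip_like` (honeycombing 12% + reticulation 10% + traction bronchiectasis +
GGO, basal/peripheral/dorsal prior; ILD, with-UIP), `nsip_like` (GGO-dominant,
basal; ILD, without-UIP), `op_like` (peripheral consolidation; ILD,
without-UIP), `emphysema_like` (upper-zone centrilobular emphysema 18% +
hyperlucency; non-ILD, without-UIP), `nodular_like` (mid-zone nodules and
bronchiectasis; non-ILD, without-UIP), and `normal`. Target fractions were
chosen once at magnitudes typical of moderately extensive disease.

What the generator does **not** emulate: realistic lung shape and lobar
anatomy, parenchymal texture, scanner/kernel effects, spatial correlation of
CT noise, co-occurring findings at lesion borders, or inter-patient
variability beyond ellipsoid jitter and blob randomness. Passing tests
therefore show the *pipeline* is correct and that retrieval separates
phenotypes whose regional finding statistics differ; they are not evidence
about retrieval quality on real HRCT.

## Evaluation

Leave-one-out: each labeled case in turn is the query; normalization
statistics are recomputed over the remaining cases (cheap at desk scale);
the top-5 are retrieved and concordance = matching labels / 5. Cases without
a label on the chosen axis take no part in the run (neither as query nor
candidate), since concordance is undefined for them. Summaries use
population deviations, a normal-approximation 95% CI (mean ± 1.96·sd/√n; a
t-quantile CI would also be defensible — the construction is a documented
choice), pooled accuracy as the query-weighted mean over both labels, and
Student's equal-variance two-sample t-test (Welch behind a flag). Two
degenerate t-test outcomes are fixed by convention: identical constant
groups → t = 0, p = 1; disjoint constant groups → |t| = ∞, p = 0.

## Problem sizes and numerical notes

The test suite and the acceptance script run cohorts of up to 60 cases
(3 phenotypes × 20) on 64³ grids and oracle comparisons over ≥100 randomized
case pairs — sizes chosen so a full run completes in well under a minute per
stage while still exercising every code path at realistic dimensionality.
Oracle-equivalence assertions use 1e-9 relative tolerance (sums of hundreds
of float64 terms); closed-form single-difference identities use 1e-12;
integer recounts are exact. CT variance is clamped at 0 against cancellation.
The cut-index search is exhaustive (the slabs per split are ≤ 3 and slice
counts small), so no optimizer tolerance is involved.

## Known limitations

* The 33-region geometry assumes roughly conventional patient orientation
  encoded in the declared axis convention; volumes in other orientations
  must be reoriented upstream.
* The inner/outer axis-cut reading and the concrete ws values are
  documented package decisions; other readings (pleural-distance bands,
  other level weights) would change absolute S_total values, though the
  ws choice only rescales levels monotonically.
* Retrieval is exhaustive O(database size) per query; no approximate
  nearest-neighbour index is provided (desk-scale databases only).
* The two upstream finding classes excluded from the 26-category dialect are
  not modelled; label volumes containing codes outside the schema are
  rejected.
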