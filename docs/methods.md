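# Methods

This note documents the models, defaults and numerical choices behind
`perilesion`, and what the synthetic-data validation does and does not
demonstrate about real IMC data.

## Data model

One row per segmented cell: identifiers (`cell_id`, `sample_id`,
`roi_id`, `group` ∈ {Control, ONJ, Tonsil}), centroid coordinates in μm
(per-ROI frame, origin top-left, y increasing downward, matching raster
indexing), one whole-cell mean intensity per panel marker, and optional
nuclear-compartment channels (`nuc_<marker>`).  Tissue regions are an
integer raster (1 = epithelium, 2 = stroma, 3 = vessel, 0 = background)
with a physical pixel size.  Groups outside the three known labels are
rejected at load time (fail fast on mislabelled inputs).

A `transform_state` tag (raw → winsorized → arcsinh) moves only
forward, so a table cannot be double-transformed or gated on the wrong
scale.

## Preprocessing

Per marker, never across markers: winsorize at the 0.1th and 99.5th
percentiles, then `asinh(x / cofactor)` with cofactor 5 (both values are
the cytometry-standard choices for IMC ion counts).  Two deliberate
choices:

* **Quantile definition.** The winsorization quantile defaults to the
  nearest order statistic (`numpy` method `"nearest"`) rather than
  linear interpolation.  With any interpolating definition,
  winsorization is not idempotent — after clipping, the interpolated
  quantile of the clipped vector moves strictly inward again (e.g.
  `[0, 1]` at 5/95% → `[0.05, 0.95]` → `[0.095, 0.905]`) — whereas an
  exact order statistic makes it a true projection.  Idempotence is the
  property a clipping step should have; interpolation remains available
  via the `method` parameter.
* **Pooling scope.** Quantiles pool all cells in the run per marker
  (stable for small ROIs); `per_roi=True` computes them within each
  ROI instead.

## Region assignment and signed distance

Cells are points; a cell belongs to the region under its centroid
pixel.  The signed distance to a region is the Euclidean distance to
the nearest boundary pixel, negative inside (flippable via
`inside_negative`).  Boundary pixels are region pixels 4-adjacent to a
non-region pixel, with the raster edge counting as outside.  Distances
come from a Euclidean distance transform evaluated at the cell's pixel,
which agrees with the exact point-to-boundary-pixel distance to within
one pixel diagonal — the tolerance all geometry tests use.

## Gating

Marker positivity is a strict `intensity > threshold` test on the
arcsinh scale, using the nuclear channel where the panel requires it
(YAP1, whose activity is nuclear localisation).  Thresholds per marker:

* **gmm2 (default):** two-component Gaussian mixture; the cut is the
  equal-posterior crossing between the component means (solved by
  bracketed root-finding on the weighted log-density ratio).
* **Degenerate guard:** if a component weight falls below 0.02 or the
  means are closer than 0.1, the fit is declared degenerate and the
  threshold falls back to the midpoint of the 10th/90th percentiles,
  flagged in the log.  This fallback presumes a roughly balanced
  bimodal marker; for a marker that is genuinely rare-positive it lands
  inside the negative population, so the synthetic defaults keep every
  gating marker's positive fraction comfortably above the 2% guard.
* **fixed:** user-supplied overrides always win.

Classification is rule-based and deterministic.  Rules support
`all` (every listed marker positive), `any` (at least one), `none`
(all negative); within a level the highest-priority matching rule wins,
and priorities must be unique per level.  The shipped default hierarchy
(`src/perilesion/data/gating_default.toml`):

* **Level 1** priority immune > endothelial > epithelial > fibroblast >
  functional; no match ⇒ `unclassified`.  "Functional" means
  lineage-negative with at least one functional marker positive — the
  realization chosen here for a basic type that is otherwise
  under-specified.  The immune-first priority keeps infiltrating immune
  cells immune and defers their co-expressed compartment to level 3.
* **Level 2** (immune only): Treg (CD4⁺FoxP3⁺) > exhausted T
  (PD1⁺ and CD4/CD8⁺) > BnT (CD20⁺ and CD4/CD8⁺) > M2 (CD68⁺CD163⁺) >
  macrophage > B > CD4 T > CD8 T > NK > DC; no match ⇒ `immune-other`.
* **Level 3**: immune cells co-expressing epithelial (E-cad, EGFR,
  PanCK), endothelial (CD31, Podoplanin) or fibroblast (CD90, aSMA,
  FSP1) markers become `immune-in-<compartment>`, precedence
  epithelial > endothelial > fibroblast.
* **Level 4**: non-exclusive flags — proliferation ⇐ Ki67 ∨ pERK,
  apoptosis ⇐ BNIP3, autophagy ⇐ Caveolin, pro-inflammatory ⇐ pNFκB,
  migration ⇐ IntegrinB1, transcriptional ⇐ pSTAT3 (pSTAT3 chosen as
  the transcriptional-activity readout; configurable).  No flag ⇒
  `non-functional`.  A dominant-state reduction (fixed order
  proliferation > apoptosis > autophagy > pro-inflammatory > migration >
  transcriptional) exists for single-colour visualisation only.

## Spatial statistics

For types a, b in a rectangular ROI window W:

    K̂_ab(r) = |W|/(n_a n_b) Σ_i Σ_j e_ij 1[d_ij ≤ r]

over ordered pairs; for a = b self-pairs are excluded and the
denominator is n(n−1).  The translation edge correction weighs each
pair by e_ij = |W| / ((w−|Δx|)(h−|Δy|)); it has a closed form on
rectangles and is therefore checkable against a brute-force oracle to
1e−9 relative error (isotropic correction is out of scope).  The
interaction score u = √(K̂/π) − r is 0 in expectation under CSR.

Scoring rules: radii 50 and 100 μm are always both computed; a pair is
`valid = False` (u = NaN) in an ROI where either type has fewer than
`min_count = 10` cells, since L estimates from a handful of points are
wildly unstable (this also encodes the convention of leaving very rare
types blank).  Per-sample scores are n_a·n_b-weighted means over valid
ROIs; samples with no valid ROI are dropped and logged.

Group inference is a two-sided Wilcoxon rank-sum on per-sample scores
with BH adjustment across all pairs within one radius (radii are
reported separately, hence separate families).  This replaces the
mixed-model inference of the R package commonly used for this analysis:
with biological replicates as the unit and ROIs pre-aggregated, the
rank-sum test is the package's primary test everywhere, which keeps the
spatial contrast consistent with the composition analysis.  Pairs with
fewer than 3 samples per group get p = NA and leave the BH family.

Small-sample caveat: u is a concave function of K̂, so with few points
per ROI E[u] < 0 under CSR (at K̂ = 0 the score saturates at −r).  The
CSR calibration checks therefore run at ~300 points per type; sparse
types are protected by `min_count` instead.

## Differential statistics

Per-sample proportions (ROIs pooled first; denominator = all cells in
the stratum, including unclassified) or per-sample positive fractions.
Wilcoxon rank-sum primary (exact by enumeration when n+m ≤ 14 without
ties, else normal approximation with tie and continuity correction),
Welch t confirmatory, BH within each analysis table, stars at
0.05/0.01/0.001.  Tests never run on per-cell values — per-cell testing
is pseudoreplication and is deliberately not offered.  Comparisons with
fewer than 3 samples per group report NA.

Note that proportions are compositional: planting an increase in one
type necessarily dilutes the shares of the others, which can surface as
opposite-signed "effects" in unshifted types.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults define the
study conditions everything else is validated under.

* **Geometry.** 1000×1000 μm windows at 1 μm/pixel (matching IMC's 1 μm
  ablation resolution), an epithelial band of depth 250 μm along the
  top edge with a sinusoidally undulating junction, and 3
  non-overlapping vessel disks (r = 40 μm) inside the stroma.
* **Cohort.** 8 Control + 6 ONJ individuals, 2–5 ROIs each.  Overall
  density 1.2e−3 cells/μm² (≈1200 cells/mm²) in Control, ×1.25 in ONJ.
* **Composition.** Region-specific type mixtures (epithelium dominated
  by epithelial cells, stroma by fibroblasts with a broad immune
  infiltrate, vessels by endothelium; all ten immune subtypes present;
  DC kept rare to exercise the min-count invalid path; 4% all-negative
  "unclassified" filler everywhere).  Every gating marker's pooled
  positive fraction is kept above ~3% so the mixture-threshold
  degeneracy guard does not trigger spuriously; this is why the
  endothelial pool is half lymphatic (Podoplanin⁺LYVE1⁺).
* **Intensity model.** Positive population lognormal(meanlog ln 10,
  sdlog 0.4), background lognormal(meanlog ln 0.3, sdlog 0.4) — about
  3.5 log-sd of separation, i.e. high but imperfect per-marker
  classification, the regime cytometry gating actually operates in.
  Functional markers are positive at per-type baseline rates (Ki67
  0.15, PD1 0.02, others ~0.10); defining markers with probability 1.
  Nuclear YAP1 lives in `nuc_YAP1`; the whole-cell YAP1 column carries
  background only.  A noise-free variant (zero log-sd, PD1 baseline 0
  so the exhausted-T definition stays unambiguous) supports
  exact-recovery tests.
* **Spatial modes.** CSR by default; planted attraction uses a Thomas
  process (parents at κ = λ/μ, μ = 20 offspring, σ = 15 μm), planted
  avoidance a hard-core dart-throwing process.  Thomas offspring are
  truncated to the region, so realized clustered-type proportions run
  somewhat below the planted intensity (e.g. planted 6% realizes ≈5%)
  and are substantially more variable per sample than CSR types.
* **Planted effects (defaults).** Treg proportion 0.02 → 0.06, Treg
  CSR → Thomas in ONJ, Ki67 positivity 0.15 → 0.30, pNFκB 0.10 → 0.25,
  density ×1.25.  `PlantedEffects.null()` removes all of them.
* **Determinism.** All draws flow from one seed through spawned
  substreams; identical seed ⇒ identical cohort, identical pipeline
  CSV bytes.

### What the synthetic validation shows — and does not

Passing tests demonstrate that the estimators are exact, the tests are
calibrated, and planted effects of realistic size are recovered through
the full pipeline.  The generator does **not** simulate raw pixel
images, segmentation errors, spillover/isotope interference, batch
effects, spatially varying marker intensity, or cell shapes (cells are
centroids); conclusions about robustness to those phenomena cannot be
drawn from these tests.

## Problem sizes used in tests and the acceptance script

Heavy checks run on scaled-down replicates of the same design —
400–500 μm windows at 2 μm/pixel, densities 2.5–4e−3, 1–3 ROIs — sizes
chosen so the full validation completes in minutes on one CPU while
keeping every per-ROI type count in the regime the estimators assume.
Specifically: estimator oracle on ≤500-point configurations; CSR/
Thomas/hard-core calibration over 200 simulations (~300 points per
type); null type-I error over 500 two-ROI cohorts; mode-switch power
over 50 cohorts; gating recovery over 50 four-sample cohorts (~4500
cells each, CSR placement so the planted Treg fraction is not
confounded by cluster-count noise); the acceptance script uses the same
designs with slightly smaller replicate counts.

## Known limitations

* The translation correction loses reliability for r approaching half
  the window size (warned, not blocked).
* The GMM threshold assumes a two-population marker; rare-positive
  markers (<2% positive) hit the prescribed percentile-midpoint
  fallback, which is a poor cut for them — supply fixed overrides in
  that situation.
* Level-3 infiltration relies on marker co-expression and cannot
  distinguish true infiltration from segmentation spillover; the
  generator plants co-expression directly, so this ambiguity is not
  modelled.
* The Wilcoxon exact path requires tie-free data; per-sample
  proportions from large cohorts are effectively tie-free, but heavily
  discretised inputs silently use the approximate path.
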