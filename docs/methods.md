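# Methods

This note documents the measurement conventions, the synthetic-scene
models, the numerical choices, and the limitations of `gliaquant`. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Segmentation and geometry conventions

Images are single-channel 8-bit planes with a square pixel calibration
(µm/px). Thresholding keeps pixels in the **inclusive** window
`[low, high]`; no shade or flat-field correction is applied first. The
defaults are 30–255 for glial/cell channels and 20–255 for plaque
channels. Connected components use **8-connectivity**, chosen so thin
diagonal processes of ramified cells stay attached to their soma; regions
below a minimum size (30 px for cells, 20 px for plaques, both
configurable) are discarded, and surviving regions are labeled in raster
order of their first pixel, a deterministic tie-break.

The convex hull is taken over the cloud of **pixel corners** (each
foreground pixel contributes its four corners). Consequences:

* a single pixel has hull area exactly 1 px², so a hull is never
  degenerate;
* axis-aligned filled rectangles score form factor exactly 1;
* a 1×N bar's Feret diameter is √(N² + 1) px — the corner-cloud caliper;
* a rasterized disk of radius r scores a form factor slightly below 1,
  with a discretization deficit that decays roughly as 0.8/r (≈ 0.97 at
  r = 20 px, within 2% of 1 for r ≥ 50 px). This is inherent to comparing
  a pixel count against an outline-polygon hull area and matches how
  outline-based hulls behave in interactive analysis tools.

The Feret (maximum caliper) diameter is the largest pairwise distance over
hull vertices; the hull has few vertices, so the all-pairs computation is
exact and cheap. Tests cross-check it against a rotating-calipers sweep
and a brute-force scan of the full corner cloud.

## Morphometry

Form factor = pixel area / hull area, in (0, 1]. Cells touching the image
border are excluded by default because truncated hulls bias the ratio
upward; a flag re-includes them. Touching or overlapping cells are **not**
split (no watershed): the generator guarantees separation, and real scenes
with touching cells are outside this stage's validated domain. Group
summaries report mean/SD/SEM/n; inference is one-way ANOVA with Tukey HSD
(α = 0.05). Groups with zero pooled variance return a `degenerate` flag
rather than a p-value.

## Plaque-associated activation

The neighborhood of a plaque is the disk of diameter 8 × Feret centered on
its pixel-center centroid; disk membership is by pixel centers within the
radius, inclusive. "Overlapping plaques are excluded" is interpreted as
overlapping **neighborhood disks** — stricter than mask overlap, because
the measured quantity lives in the neighborhood; both members of each
overlapping pair are flagged, and a mask-overlap mode is available. The
default background reference is the complement of the union of all
neighborhood disks eroded by 5 px; an explicit ROI can be supplied. Halo
intensity is Σ max(I − background mean, 0) over in-disk pixels with raw
value in the glial threshold window — an integrated, background-corrected
quantity in arbitrary 8-bit units. Whether the source convention
integrated or averaged intensity is not recorded anywhere we could verify;
the integrated form is declared and validated by simulation recovery, not
by published fit coefficients.

Per-group regression is ordinary least squares of halo intensity on plaque
area. Slope differences against a reference group use the pooled model
`y ~ area + group + area:group` (reference-coded); each non-reference
group's p-value is the Wald test of its interaction coefficient. No
multiplicity correction is applied across groups, matching the
reference-vs-each reporting style; a Bonferroni adjustment can be applied
by the caller. All non-excluded plaques enter the analysis; per-animal
subsampling (e.g. 15–20 plaques per section) is not enforced.

## SGZ neurogenesis

Inputs are vector annotations — soma points and dendrite polylines — not
raw pixels: the counting procedure this stage reproduces is manual, and
automated dendrite tracing is a different problem. Linear density counts
positions within a 20 µm band (default; the membership band is not a
published value) of the SGZ trace and divides by arc length in mm.
Laminar counts: b counts primary paths with ≥ 1 crossing of the mid-GCL
line, c counts secondary paths with ≥ 1 crossing of the outer-GCL edge; a
path crossing a line several times counts **once** (the declared rule for
re-crossing dendrites). Ratios b/a and c/b are returned as `None`, not 0,
when the denominator is zero. Double-labeled BrdU⁺DCX⁺ cells count toward
both markers' densities.

## Signature screens

Fold values are signed ratios, with downregulation stored as the negative
mirrored fold (−2.7, not 0.37). Fold cutoffs are inclusive (≥ 2, ≤ −2);
score thresholds are strict ("exceeding 80" keeps > 80). Gene symbols
match case-insensitively with whitespace stripped, through a packaged
alias table of known typographical variants (Carl3→Calr3, R1f→Rlf,
Rio1→Riok1, Igbo-V7183→Igh-V7183, Atpla2→Atp1a2, Parkar1b→Prkar1b, plus
case/space variants); where running text and tables disagree, the tables
are authoritative. Venn regions are exact and disjoint; inclusion–
exclusion over the regions reconstructs each group's set size, which the
tests assert. The packaged score table covers perturbagen classes only;
compound-level (PC) intersections depend on data not fully published, so
they are supported by the same operations but not validated against
printed counts.

## Metabolic indices

HOMA-IR takes glucose in mM and insulin in U/mL as printed in the source
formula; unit conversion is the caller's responsibility. OGTT AUC is the
**total** trapezoidal integral over the full sampled window (endpoints are
not published; the full window is assumed), with an incremental
(baseline-subtracted, clipped at zero) option.

## Synthetic scenes: what they emulate and what they do not

One integer seed drives a named pseudorandom stream per scene component,
so adding a component never perturbs existing draws, and identical
spec + seed is bit-identical. Object placement is rejection sampling with
a retry cap; infeasible packings raise an explicit error.

**Microglia** are a soma disk (default 8 µm radius at 0.5 µm/px) plus 5
jittered-random-walk branches (default 30 µm long, 2 µm wide) rasterized
at intensity 200 on a zero background; `activation` retracts branches by a
fraction, moving cells from ramified toward amoeboid. Defaults were chosen
so the two modes straddle the form-factor range reported for cultured
amoeboid vs ramified microglia (≈ 0.35–0.65). Not modeled: process
tortuosity and varicosities, touching cells, intensity gradients.

**Plaques** are radial-falloff blobs (value 255 at center, 0 at radius
5–10 µm). The glial channel paints, inside each plaque's neighborhood
disk, clustered blobs whose total excess over the uniform background
(value 10, below the glial threshold) equals β₁·area + β₀ + N(0, σ), with
defaults β₁ = 633.8, β₀ = 276,179 — the vehicle-group operating point of
the halo model. Two details make recovery exact on 8-bit rasters: the
halo law is applied to the **measured** plaque area (plaques are
rasterized, detected with the pipeline's own segmentation, then painted),
and the integer-quantized target spreads its remainder one count per
pixel, so painted excess matches the target to < 1 a.u. `sigma_for_r2`
calibrates σ to a desired regression R² given the area distribution; the
record-level sampler `sample_halo_records` draws (area, intensity) pairs
from the same model without rasterization, keeping large regression
simulations cheap. Not modeled: PSF, Poisson shot noise, background
texture, 3-D structure.

**SGZ scenes** place somata at even arc spacing (with jitter) along a
sinusoidally wobbled 2 mm trace; crossing fractions for primaries and
secondaries are applied as global rounded counts, so generated truth is an
exact integer triple (a, b, c). **Signature tables** assign synthetic
genes to designed Venn regions with folds drawn outside/inside the cutoff
bands. **Metabolic cohorts** draw per-animal fasting values from group
normals (NCD ≈ 7 mM / 12 U/mL; HFSTZ ≈ 15 mM / 25 U/mL — typical for
chow-fed vs high-fat + streptozotocin mice) and OGTT curves that rise to a
peak at 30 min and decay exponentially; the HFSTZ decay near 0 reproduces
the impaired return to baseline. n = 6 per group by default, matching the
cohort sizes of the study design the generator emulates.

Because the generator omits noise sources real microscopy has, passing
recovery tests demonstrates the **correctness of the measurement chain**
(geometry, masking, background correction, statistics), not robustness to
stain variability, optical blur or annotation error.

## Problem sizes and numerical choices

Default scenes are 640² px (microglia, 0.5 µm/px) and 768² px (plaques,
1 µm/px) with 5–6 objects — small enough that the full suite runs in well
under a minute while each stage still measures multiple objects per scene.
Simulation studies in the tests and acceptance script use 300 replicates
for confidence-interval coverage, 500 for the null rejection rate of the
slope-difference test, and 100 rasterized scenes for slope-bias
estimation; these sizes put the Monte-Carlo standard error comfortably
inside the asserted bands. OLS fits guard degenerate inputs explicitly:
zero variance in x raises, constant y returns a flat fit with R² = 0, and
collinear pooled designs raise before fitting.

## Known limitations

* No watershed splitting of touching cells; no 3-D/z-stack geometry
  (confocal stacks are assumed maximum-projected upstream).
* Halo intensities are arbitrary 8-bit integrated units; comparisons
  across acquisitions require identical exposure settings, which the
  package does not verify.
* The published fit coefficients and group means that parameterize the
  generator come from real tissue; desk-scale synthetic scenes validate
  directions of effect and estimator calibration, not those absolute
  values.
* The connectivity-scoring and enrichment algorithms that produce the
  screening tables are upstream services; only their tabular outputs are
  consumed.
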