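# Methods

## What the pipeline models

An imaging flow cytometer records, for every event ("object"), a small
spatially registered multichannel image. For erythroblastic-island (EBI)
analysis the informative events are multicellular: a central macrophage in
contact with at least three CD71+ nucleated erythroblasts, sometimes with
CD11b+ myeloid satellite cells attached at the periphery. The pipeline
turns each event image into scalar features, gates events hierarchically,
and applies an explicit rule set where an analyst would otherwise inspect
images by eye. Everything downstream of the image is deterministic given a
configuration, so every number in the outputs is reproducible from a seed.

## Synthetic cohorts

No public IFC datasets of native EBIs exist, so cohorts are simulated. The
generator is first-class, tested code: its ground-truth tables are the
reference for all recovery statistics.

**Geometry.** Cells are rasterized on a 128 px frame at 0.33 µm/px (a 60×
imaging-flow objective). Erythroblasts are disks of radius 5–8 px,
myeloid cells 4–6 px; each nucleated cell carries a concentric DNA disk at
0.55× its radius. Macrophages are either *stellate* — a disk core
(9–14 px) with 4–7 tapered radial arms (12–26 px, jittered angles) — or
*round* — a core disk scaled 1.25× with mild low-order radial wobble
(SD 6 % per harmonic), because real rounded cells are never perfect
circles. An island places the macrophage at the frame centre and rings the
erythroblasts so each footprint overlaps the core by 2.5–4 px; satellites
attach outside a host erythroblast. A loose cluster is a bent chain with
the macrophage at one end: connected in brightfield, but failing both the
≥ 3-contact and the centrality criteria. Configured geometry that cannot
fit the frame raises immediately, naming the offending parameter.

**Staining.** Each (cell class, channel) pair has a mean level, a per-cell
CV (default 0.15), and a pattern: `uniform` over the footprint,
`membranous` (a 2-px perimeter band — CD71, Ter119, CD11b), or `patchy`
(random blobs covering a configured fraction of the footprint — CD169 at
0.4, matching its irregular, non-continuous appearance on island
macrophages). F4/80, VCAM-1 and rat CD163 are painted uniform: in the
source imagery these stains fill the macrophage rather than resolving as a
thin ring. Tissue presets encode the biology of interest: FL draws round
macrophages with probability 0.85 vs 0.10 in BM; BM attaches ≥ 1 CD11b+
satellite to 80 % of islands vs 5–10 % in FL/SP; FL omits CD169; ratBM
expresses CD163 and no CD169; the VCAM-1+/F4/80-low cluster class is most
frequent in FL (0.15) and stressed spleen (0.08), rarest in steady-state BM
(0.03). Class mixes, levels and rates are ordinary config fields — the
presets are defaults, not constants.

**Noise.** Observed = Poisson(signal) + background (4 AU) + Gaussian read
noise (SD 2 AU), clipped at zero; each term can be switched off
independently, which the oracle tests use.

**What the generator does not emulate** — and hence what passing recovery
tests do and do not show: optical point-spread blur, flow-core vibration,
spectral crosstalk, chromatic misregistration, 3-D occlusion, debris
adhering to islands, and biological shape diversity beyond
disk/stellate/wobbly-round. Recovery scores near 1.0 on these cohorts
demonstrate that the rules are implemented correctly and separate the
planted classes under the stated noise; they are an upper bound on, not an
estimate of, real-instrument performance.

## Masking and features

Masks use Otsu's threshold (deterministic, testable by exhaustive search),
radius-1 morphological closing and hole filling; the object mask keeps only
the largest 8-connected component (brightfield events are single blobs),
while marker masks keep all blobs (patchy stains are legitimately
multi-blob). Conventions fixed once: pixel centres at integer (row, col),
origin top-left; 8-connected foreground / 4-connected background; a mask's
centroid is the unweighted mean of its pixel coordinates; the boundary is
the set of largest-component pixels 8-adjacent to background, with
distances measured from the full-mask centroid. A zero-variance channel
yields an empty, flagged mask rather than an exception.

**Circularity** is mean(d)/SD(d) over boundary-pixel distances d.
"Variation" is taken as the population SD, which makes the statistic
dimensionless and scale-free up to rasterization (the suite asserts < 5 %
change on doubling an ellipse; note a *perfect* disk's SD is pure
rasterization noise, so scale-freeness is only meaningful for shapes with
real boundary variation). If SD < 1e-9 px the value is capped at 100. At
least 8 boundary pixels are required.

**Similarity** is ln((1+ρ)/(1−ρ)) — twice the Fisher z-transform — with ρ
clipped to ±(1 − 1e-6), capping |S| at ≈ 14.5. The transform is symmetric
in the channel pair, invariant under positive affine rescaling, and flips
sign under negation; all three are asserted on random images, and the
closed form is checked at a constructed ρ = 0.8 (S = ln 9 ≈ 2.197). The
default region is the whole-object brightfield mask: the least biased
choice when asking whether two stains decorate the same cell within an
event, and configurable. Zero variance in either channel makes S undefined
(NaN + flag), excluded from summaries.

**Intensity** = Σ pixel − (median of off-object pixels) × area;
**mean pixel** is the plain mean over the region with no background
subtraction — it is the quantity used for positivity calls, because patchy
stains need not produce a clean image.

## Gating

Gates form a tree evaluated top-down; membership requires the parent.
Interval bounds are half-open `[lo, hi)` so adjacent gates partition an
axis exactly. The default tree is root → multiplets (brightfield area ≥ 50,
interpreted as µm² and converted through pixel_size²; both the unit choice
and the conversion are config-visible) → the CD71 × macrophage-marker
double-positive gate (F4/80 for mouse, CD163 for rat). Intensity cuts are
drawn graphically by analysts, so the defaults here are data-driven: the
0.99 quantile of the integrated intensity among negative controls —
planted singlets/debris lacking the marker when truth is available,
otherwise all objects below the multiplet area cut. A cohort with no
controls at all gets the column minimum (gate keeps everything) with a
warning; fixed thresholds can always be supplied.

## Classification

Nuclei are regional maxima of the Gaussian-smoothed DNA channel (σ = 2 px,
min separation 5 px) above the DNA positivity threshold; each seeds a
watershed basin grown on distance-from-seed inside the object mask, and the
basin is the cell's working footprint. Per-cell marker positivity accepts
the mean pixel over the footprint, over its 2-px perimeter band, *or* over
a 3-px shell just outside it. The shell matters: when cells overlap, a
central cell's true boundary — where membrane stains sit — lies largely
outside its own basin, in the neighbours' territory, and basin-interior
sampling alone would blind the classifier to ring staining on exactly the
cell it most needs to phenotype.

Positivity thresholds default to background median + k·MAD with k = 6,
estimated per object from off-mask pixels (fixed overrides per channel are
accepted). The inclusive bound (mean pixel = threshold ⇒ positive) is part
of the contract. Contact between cells is footprint overlap or 8-adjacency
after 1-px dilation, since island cells overlap considerably and
adjacency-only would under-count. Centrality is 1 − (distance from cell
centroid to cluster centroid)/(equivalent radius √(area/π)), with
θ_c = 0.5; competing central candidates are resolved by highest
centrality, then highest macrophage-marker mean pixel, with an ambiguity
flag recorded. CD71+/DNA− cells (reticulocytes) never count toward the
≥ 3-erythroblast requirement — nucleation is the testable criterion.
Co-expression calls use S ≥ 1.0 (configurable) for "consistent";
undefined S propagates. The CD11b call uses the 2-px perimeter band alone,
matching its membranous biology, and the central macrophage is reported
separately from the satellite count.

## Statistics

Wilcoxon rank-sum, two-tailed, mid-ranks for ties. The exact branch runs
at combined n ≤ 12 by full enumeration (C(12,6) = 924 assignments —
instant) with p = min(1, 2·min(P(W ≤ w), P(W ≥ w))); larger samples use
the normal approximation with tie correction and 0.5 continuity
correction, computed via erfc to keep deep-tail precision. Two identical
samples give p = 1. The two branches agree within 0.02 at n = 6 + 6 and
the normal branch's type-I error is calibrated within 3 SE of 0.05 over
1000 null replicates. Significance is α = 0.05 with no multiple-testing
correction — a deliberate mirror of common practice in this setting, and a
known limitation. Proportions carry the binomial SE √(p̂(1−p̂)/n).

## Problem sizes

Recovery statistics use a 500-object default-noise BM cohort; the
FL-vs-BM shape contrast uses 100 islands per arm; the analysis drivers use
150 objects per preset; statistical calibration uses 1000 replicates at
n = 20 + 20. These sizes give 3-SD binomial bands of a few percent on every
reported proportion while keeping a full run in minutes on one CPU.

## Known limitations

* The generator's simplifications listed above; in particular, Similarity
  values on simulated islands (≈ 4.3 / 0.8 / −0.5 for continuous / patchy /
  disjoint co-expression against F4/80) are cleaner than instrument data,
  where blur and crosstalk compress the ordering.
* Watershed footprints are nucleus-Voronoi territories, not true cell
  outlines; counts are robust but per-cell morphology (e.g. cell-level
  circularity of non-central cells) is not attempted.
* The classifier's centrality score assumes roughly convex clusters; ring-
  or chain-shaped multiplets are handled (they fail centrality) but exotic
  topologies have not been explored.
* Gate thresholds derived without ground truth fall back to a sub-area
  control pool, which assumes singlets dominate below the area cut.
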