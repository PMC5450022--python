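# Methods

## Scope and design

`emtconv` implements the computational core of a live-cell
fibroblast-to-neuron conversion study: morphology-rule classification
and lineage tracing of hourly time-lapse movies, population/lineage
kinetics, signed EMT/metabolism signature scores, and the
EMT-microarray meta-analysis procedure. Real acquisitions are replaced
by synthetic generators with complete ground truth, so every stage has
an oracle. The package is a library first (importable API plus
narrative `examples/`); the `emtconv` CLI is a thin wrapper over
`emtconv.pipeline` for shell use.

## Morphology

Cells are connected components (8-connectivity) of a label or binary
image. Features per component:

- **centroid**: unweighted mean of member pixel coordinates
  (0-based, row/col, origin top-left);
- **perimeter**: scikit-image's weighted line-segment estimator over
  4-connected border transitions;
- **length/width**: ellipse-equivalent axes, 4·√(eigenvalues) of the
  population covariance of pixel coordinates, each floored at 1 px (a
  single pixel has unit extent); this is moments-based, not a bounding
  box, so it is rotation-robust and testable against an exact
  eigendecomposition oracle;
- **neurite count**: the mask is skeletonized; the soma is the largest
  inscribed disc (centered at the maximum of the Euclidean distance
  transform); an endpoint (skeleton pixel with ≤ 1 skeleton neighbour)
  counts as a neurite tip when its geodesic distance along the
  skeleton from the soma disc exceeds `min_neurite_len` (default 5 px,
  diagonal steps cost √2). How the original tracing software measured
  neurites and nuclei in light-field images is not recorded anywhere;
  the skeleton-endpoint and inscribed-disc constructions are this
  package's operational definitions;
- **nucleus-to-cytosol**: nucleus pixels inside the mask over the
  remaining (cytosol) pixels.

Classification applies three ordered rules, first match wins, matching
how the classes are reported as disjoint: neuron-like (L/W > 5 and
≥ 2 neurites), then shrunken (L/W < 1.5, area < `area_small`,
N:C > 0.2), then MEF-like (area > `area_large`, N:C < 0.1), else
unclassified. "Small" and "large" sizes have no published pixel value
and no physical pixel scale exists, so `area_small`/`area_large` are
config thresholds (defaults 300/700 px², calibrated once against the
synthetic archetype area distributions, which are well separated:
shrunken ≈ 140 px², MEF-like ≈ 1500 px²). Rules needing the nucleus
simply cannot fire when no nucleus channel is present.

Marker overlap between predicted neuron-like cells and
marker-positive truth is Jaccard (100·|∩|/|∪|) — the strictest
symmetric reading of "overlap" — with recall against the marker set
reported alongside. Two empty sets agree vacuously (100%, flagged).

## Tracking

Frame linking is greedy mutual-nearest-neighbour on centroid distance
within a gate (default 5× the motion step SD when the generator config
is known, else 50 px), iterated until no new mutual pairs emerge; ties
break on (distance, lower label). It mirrors the closest-cell logic of
manual tracing and is deterministic; a Hungarian minimum-cost
assignment is kept as a test oracle, and on well-separated frames the
two provably agree. After identity linking:

1. an unmatched source with ≥ 2 unmatched targets within the division
   radius (default 2× mean major-axis length) becomes a division to
   the two nearest;
2. a *second-chance pass* re-links remaining unmatched sources and
   targets (mutual nearest within min(2·gate, division radius)) so a
   single oversized step is not split into a death plus an appearance;
3. a *division rescue*: a remaining unmatched target near a linked
   source is interpreted as the second daughter of a division whose
   first daughter captured the identity link. The true parent sits
   near the midpoint of its daughters, so the chosen source is the one
   whose distances to the two candidate daughters are most nearly
   equal.

Remaining unmatched sources are disappearances, unmatched targets
appearances. "Untraceable" is operationalized as "no identity link":
migration then uses the distance to the globally closest cell in the
next frame, flagged as imputed; the last frame yields an explicitly
absent value, never 0.

Lineage forests concatenate identity links into tracks and branch at
divisions; every observation belongs to exactly one node, and an id
linked twice aborts with the offending frame named.

## Kinetics

- Doubling time: Td = 24 / log₂(N(t+24)/N(t)), undefined (None) without
  growth.
- Day *d* covers frames [24d, 24(d+1)); class compositions are
  censused at the last frame of each day and percentages are over all
  surviving cells.
- A conversion event is the first frame along a root-to-leaf path
  where the class switches into the target and persists ≥ 3 observed
  frames (default; hourly frames make single-frame switches noise), a
  run cut short only by the movie end still counting. Events attach to
  the node where the run starts, so post-conversion divisions do not
  multiply events. Mode: **high-mitosis** if ≥ 1 division (config
  `mitosis_threshold`) occurred in the 24 h preceding the conversion,
  else **low-mitosis**; no numeric cutoff is published, and the
  one-recent-division default encodes "immediately after one round of
  mitosis". The mode summary reports founders, mean emergence hour and
  the percent of final-frame target cells descending from each mode.
- Grid sampling divides the picture into k×k (default 5×5) equal
  fields and picks per field the cell nearest the field center (ties:
  lower label).
- Parameter-recovery estimators: per-class division probability =
  detected divisions by parent class over cell-frame exposures;
  per-class motion SD = per-axis SD of identity-link displacements.

## Scores

All scores use
`(Σ log₂FC up-genes − Σ log₂FC down-genes) / n_used`.
Genes absent from the input are excluded from numerator and
denominator alike — "genes used" is read as genes actually used; a
divide-by-all-signature-genes mode is selectable. Raw (linear) inputs
are converted as log₂((x+1)/(control+1)); the unit pseudocount is this
package's choice as none is published. Symbols are case-normalized
(upper for human, capitalized for mouse) and an alias table
(Snai2→Slug, etc.) is applied for the qPCR score. The six qPCR genes
are fixed (up: Cdh2, Fn1, Slug, Zeb1; down: Epcam, Ocln). The 130-gene
human EMT signature is cited from prior work and not printed anywhere,
so the shipped `emt_signature_synthetic.gmt` is a synthetic stand-in
and any GMT with `*_UP`/`*_DOWN` sets can be supplied — the signature
is configuration, not code. The metabolism GMT ships representative
KEGG00190/KEGG00010 member subsets. Homolog mapping goes through a
curated two-column TSV (no network access); unmapped symbols are
returned, never dropped, and conflicting rows fail loudly.

## Meta-analysis

Per dataset: replicates of each non-control treatment are averaged on
the linear scale, divided by the single shared control mean, and
log₂-transformed; log₂-intensity inputs are exponentiated first and
declared log₂-vs-control inputs pass through (idempotence).
Non-positive control means fail naming the gene. Datasets are
outer-merged on official symbols after alias rewriting; duplicate
symbols collapse by mean with a logged warning; missingness is
preserved, never imputed, and every fraction reports its basis count.
"Up-regulated" defaults to fold change > 1.5× (log₂FC > 0.585),
configurable — chosen because the Stat3 effect is described as a
modest 150–200% rise. "Strongly induced EMT" is the top quartile of
per-column EMT scores; no published cutoff exists.

## Synthetic movie generator

Frames are uint16 label images (pixel value = global cell id) with an
aligned nucleus stack; this isolates tracking/feature logic from
segmentation, which is not the contribution under test. Three
archetypes are rendered from per-archetype parameter distributions:
an ellipse body (area, aspect ratio, orientation drawn per cell at
birth), a nucleus as the exact `frac`-quantile elliptical core (so the
N:C ratio is exact by construction), and, for neuron-like cells, 2–4
one-to-three-pixel rays anchored near the soma poles so the
elongation survives measurement. `render_archetype(check=True)`
measures each candidate with the morphology module and redraws until
the archetype's rule contract holds (error if impossible) — the
closed loop behind the noise-free recovery tests. In movies, neuron-
like cells are always contract-checked (they define marker truth);
the other archetypes keep their drawn noise, whose defaults place
them 3–4 SD inside their rule boundaries.

Dynamics: isotropic Gaussian random-walk steps with true mirror
reflection at the field margin; per-frame per-archetype division and
apoptosis probabilities; conversions scheduled as waves — a fraction
of initial lineages converts inside a frame window, either
*with-mitosis* (forced division, both daughters the target archetype)
or *without-mitosis* (in-place switch), the fate carried by the whole
lineage. Daughters are placed on opposite sides of the parent at 0.55×
their bounding-box diagonal — adjacent but non-overlapping, a clean
geometric division signature. Placement stamps masks onto the canvas;
an overlap triggers a deterministic spiral search for the smallest
freeing nudge (overcrowding raises an error naming the frame). All
randomness flows from one `numpy` Generator seeded by the config:
identical config + seed is byte-identical.

Default demo conditions: 60 initial MEFs on a 1400×1400 field, 36
hourly frames, MEF division probability 0.065/frame, conversion waves
totalling 65% of lineages to neuron-like (mostly with-mitosis) and 12%
to shrunken — producing ≥ 300 final cells (typically 420–500) with a
final composition dominated by neuron-like cells. Sizes are pixels
throughout; no physical scale is assumed.

What the generator does *not* emulate: phase-contrast/light-field
appearance, segmentation errors, touching cells, focus drift, cells
entering the field, gap occlusions. Passing tests therefore certify
the measurement, classification, tracking and bookkeeping logic on
clean segmentations — not robustness to segmentation noise.

## Synthetic compendium generator

Each of n (default 30) datasets carries an EMT strength
s ~ Uniform(0.2, 2). Gene effects (log₂): up-signature
Normal(+a·s, σ), down-signature Normal(−a·s, σ) with a = 1, σ = 0.3;
Stat3 ~ Normal(0.8, 0.2) independent of s — a universal, modest
(~150–200%) rise, under which the expected fraction of datasets
exceeding 1.5× is the Normal tail P(log₂FC > 0.585) ≈ 86%, consistent
with "more than 70%"; Sox2 and the projection markers ~
Normal(max(0, s−1), 0.3) — a threshold response active only in
strongly induced datasets. Values are emitted as linear replicate and
control columns (3 + 3, multiplicative log₂-noise SD 0.02) so the
meta-analysis arm must itself do the averaging and normalization that
the procedure prescribes.

## Numerical choices and degenerate inputs

- 1-pixel masks: length = width = 1, neurite count 0.
- Empty frames: empty observation lists, flagged empty census rows —
  never exceptions.
- Both overlap sets empty: 100% by convention, flagged vacuous.
- Ties everywhere break deterministically on (distance, lower label).
- Seeds derived from the CLI/config seed stay below 2³¹.

## Test-scale choices

The default suite simulates one demo movie (~470 final cells, 36
frames), three pooled recovery replicates (120 initial cells, 30
frames each; pooling three seeds puts the binomial noise of division
counts well inside the 15% recovery tolerance), and several small
event-topology movies; the whole suite runs in about three minutes on
one CPU.

## Known limitations

- The tracker closes no gaps over missing frames and does not
  re-identify cells after long occlusion; appearances are explicit
  records, not errors.
- The division rescue can, in principle, misread a genuine mid-field
  appearance next to a linked cell as a division; with closed-field
  synthetic movies appearances only arise from tracking faults, where
  the rescue strictly helps (link accuracy ≥ 99% at demo densities).
- Mode labels (high/low-mitosis) describe the observed division
  history, so an in-place conversion inside a fast-dividing lineage is
  legitimately labelled high-mitosis.
- The shipped EMT signature and KEGG subsets are synthetic stand-ins
  for licensing-external gene lists; analyses of real data should
  supply their own GMT files.
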