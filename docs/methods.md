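# Methods

This note records the models, conventions and numerical choices behind
`explantkit`, in the spirit of a methods appendix: what each component
assumes, which knobs matter, and what the synthetic benchmarks do and do
not demonstrate.

## Image pipeline

**Thresholding.** Foreground is `intensity > local_mean(window) + offset`
with a square local-mean window (default 101 px) and an additive offset
(default 2000 on the 16-bit scale). A local-mean rule adapts to shading
gradients but deliberately suppresses the interior of regions much larger
than the window — the explant body therefore survives mainly as a dense
rim. Connected components below 64 px are treated as specks. The window
must comfortably exceed the neurite width (a few pixels) and stay below
the body diameter; the offset should sit several noise standard
deviations above zero. Both are exposed because real acquisitions differ
in background texture.

**Body segmentation.** Opening with a disk of radius 4 px removes all
thin (neurite-scale) structure; components smaller than a quarter of the
largest dense component are discarded; closing (radius 15 px) plus hole
filling consolidates the rim into a solid region, whose largest connected
component is the body. The projected area is the pixel count times the
squared pixel size. On synthetic images the intersection-over-union
against the true body polygon exceeds 0.9 (typically ≈ 1.0).

**Skeleton graph.** The outgrowth (mask minus a 2 px dilation of the
body) is skeletonized; skeleton pixels with ≠ 2 neighbors, and pixels in
contact with the body, become node pixels; 8-connected node-pixel
clusters become graph nodes (endpoints, junctions, body-contact "start"
nodes); maximal node-free pixel runs become edges of a multigraph (two
nodes may be joined by several distinct skeleton paths, and fused
fascicles can produce cycles — both are kept). Edge length is the chain
code: orthogonal steps cost 1 and diagonal steps √2 pixel units.

**Spur pruning.** Terminal edges shorter than `min_spur` (default 10 µm)
whose inner endpoint is a junction are removed, and any resulting
degree-2 node is fused so the surviving path is seamless; sweeps iterate
to a fixpoint, making the operation idempotent. Start nodes are never
pruned.

**Lengths.** An ending's length is the geodesic distance along the graph
to its nearest start node (multi-source Dijkstra on the chain-code
weights; ties between parallel edges resolve to the shorter edge, then
the smaller key). The *reported* length re-measures the routed pixel
trace after an endpoint-preserving moving-average smoothing (window
7 px) and adds the small Euclidean gap between the start node and the
body rim. The raw chain code overestimates digital straight lines by up
to 8 % (≈ 5.5 % averaged over orientations) — a classical digitization
bias — so summing 1/√2 steps cannot meet a ±5 % length budget; smoothing
the trace removes the staircase and brings per-ending errors to well
under 2 % in the median. `total_length` remains the plain sum of
chain-code edge lengths (exact conservation: it equals the sum over
edges by construction). Endings in components with no start node are
measured from their component's node nearest the body centroid and
flagged `disconnected`; the body-facing endpoint of such a fragment is
not counted as an ending. The median of an empty length list is reported
as missing, never 0.

**Conventions.** 0-based (row, col) coordinates, origin top-left;
8-connectivity throughout.

## Direction analysis

Each ending contributes the bearing of the vector from its assigned
start point (nearest by geodesic, not the body centroid) to the ending:
0° points to the top of the image and angles increase clockwise (90° =
right). The sign convention is a package choice — only the reference
axis is fixed by the measurement design — and is documented wherever
angles are emitted. Angles pool across explants; histograms use 36
half-open 10° bins. One-sample uniformity uses the Rayleigh test
(Z = n·R̄² with the classical second-order series for the p-value; the
approximation is excellent for n ≥ 10 and is cross-checked against an
independent implementation in the tests). The two-sample comparison uses
Watson's U², which is invariant to a common rotation, with a seeded
permutation null (999 permutations by default); the p-value uses the
add-one rule.

## DAB immunoreactivity

A pixel is DAB-positive when it lies in the include-minus-exclude ROI
and its RGB value is within a Euclidean tolerance (default 40) of one of
the trained brown reference shades. The default shade set is a brown
ramp at IR 60–240 in steps of 30; shade training mirrors interactive
histology software, and stain-vector deconvolution is a deliberate
non-goal. IR of a pixel is 255 − round(0.299 R + 0.587 G + 0.114 B),
anchoring 0 = no staining and 255 = saturated; the mean over positive
pixels is the ROI's IR. An empty mask reports IR 0 with an explicit
`no_positive_pixels` flag (a convention; real panels always stain). The
proprietary metric of commercial tools cannot be reproduced exactly —
only the 0/255 anchors and the ordering behavior are asserted.

## Stimulation model

Pulse trains are charge-balanced biphasic rectangles: amplitude (µA),
phase duration (µs), interphase gap (µs), rate (Hz), an optional
minutes-scale on/off raster, and run length (hours). Charge per phase is
amplitude × phase duration; "total charge" sums the single-phase
magnitude over delivered pulses (the biphasic pair nets zero, so the net
is useless for dose comparisons); duty fraction is on/(on+off) with the
continuous pattern as the off → 0 limit. The interphase gap enters the
period-fit validation but not the charge (no current flows in the gap).
No ramping is modeled. The catalog holds the five study patterns
(10/100/500/1000 µA continuous, 1000 µA 1-min-on/2-min-off; 30 µs,
2.1 µs, 1000 Hz, 72 h). Evaporation QC converts the plate weight-loss
difference to per-well volume at 1 g/mL and reports grams and percent of
the 400 µL working volume.

## Study statistics

Outcomes are skewed, so everything is median-based and nonparametric.
Fold change is computed **per explant** (value ÷ control median), then
summarized by group medians — figures plot per-explant points, and for
group medians the per-explant and ratio-of-medians conventions coincide
up to interpolation. The neurotrophin design normalizes to the single
global control; the stimulation design normalizes each plate to its own
unstimulated in-plate controls (a plate without controls is a hard
error). Equal-share pooling balances cochlear turns by seeded
subsampling without replacement to the smallest turn's n, optionally per
treatment group. Quartiles use linear interpolation between order
statistics; whiskers clip to the most extreme data points within 1.5 IQR
of the box (Tukey convention), points beyond are listed as outliers.

Multi-group testing: Kruskal–Wallis omnibus (tie-corrected, χ²
approximation) with Dunn's z for each group against the control only,
Bonferroni-corrected over that family alone — comparing every group with
every other would correct far more aggressively than the design needs.
If all values are identical the omnibus p is 1 and no post-hoc runs.
Pairwise designs use the two-sided Mann–Whitney U with Holm–Šídák
step-down (sorted raw p, adjusted_(i) = 1 − (1 − p_(i))^(m−i+1), running
maximum). In the simulation-based calibration of the neurotrophin chain,
"rejection" is the omnibus Kruskal–Wallis decision at α = 0.05: the
omnibus is the chain's gatekeeper, whereas the Bonferroni family-wise
rate over correlated comparisons is intentionally conservative and has
no single nominal level to calibrate against.

## Synthetic data generator

The generator defines the conditions under which the pipeline is
validated.

**Explant images.** The body is an ellipse (default) or annular-sector
wedge of given area (default 40 000 µm², a few hundred µm across) at the
image center; default frame 2048² at 0.5 µm/px (a 40× air objective
context). Neurites are polylines grown from body-boundary start points
in 5 µm steps with Gaussian per-step heading jitter (default 4°);
branching is Bernoulli per step with probability scaled to 50 µm of
growth; each terminal path's root-to-tip target length is log-normal
(median parameterization — the printed study medians plug in directly;
default median 316 µm, log-sd 0.45). Branch children draw a fresh
root-to-tip length and extend beyond their branch point, so endings
exceed start points as observed in culture. Growth stops at the frame
margin (the realized length then enters the ground truth). Direction
modes: uniform, von Mises, or near-regular spacing ("spaced") for
well-separated benchmark neurites. Optional fasciculation shares an
initial trunk among one start point's neurites (off by default for
ground-truth clarity; shared trunks count once in total length).
Channel 0 carries speckled nuclei inside the body, channel 1 body plus
neurites at a signal level of 20 000 over background 1000 with Gaussian
noise (sd 200), optional Poisson. Identical specs (which include the
seed) give bit-identical output.

What the image generator does **not** emulate: stitching artifacts,
shading fields, out-of-focus fascicle blur, crossing-dominated dense
outgrowth, somata leaving the body. Benchmarks on it therefore
demonstrate the geometric correctness of the measurement chain, not its
robustness to every acquisition pathology; with dense, wandering
neurites (higher jitter) tips that collide with another fiber are
absorbed and endings are under-counted by several percent.

**DAB sections.** Positive regions are a Gaussian-random-field
threshold inside the ROI at exactly the requested area quantile; stained
pixels take the brown whose IR matches the target (white→brown blend for
IR ≤ 177, brown→black beyond), with per-pixel shade jitter (sd 6). The
realized IR is recomputed from the emitted image.

**Study tables.** Outcomes are log-normal with the group median as
location. A shared latent "vigor" couples endings and length (loading
0.7, matching the observed 0.7–0.8 rank correlation between neurite
number and median length); total length ≈ endings × median length ×
small noise and branch points ≈ 0.85 × endings, so the
endings/branch/total family is almost perfectly correlated, as in real
data. Default log-sds: 0.55 (endings) and 0.35 (lengths). Litter effects
are shared log-shifts (sd 0.12) over litters of 36 explants assigned by
random permutation across groups; the stimulation design adds shared
per-plate log-effects (the component in-plate normalization removes) and
fills each plate half with controls. Covariates (sex, side, age P6/P7,
weight ≈ N(3.8, 0.35) g) have zero effect; the projected area carries a
mild positive link to vigor and a mild negative link to weight.

## Benchmark problem sizes

The test suite validates ground-truth recovery on twenty 2048² images of
30–60 well-separated neurites (ending counts within ±5 % in aggregate;
matched per-ending lengths: median absolute relative error and mean
signed error both within ±5 %), null calibration of the neurotrophin
chain on 1000 simulated studies of 4 groups × 3 turns × 10 explants, and
Rayleigh p-value uniformity over 200 samples of n = 1000. These sizes
make the whole suite run in a few minutes on one core while keeping the
Monte-Carlo standard errors comfortably inside the asserted bands.

## Known limitations

* Fascicle-shared trunk length is counted once in `total_length`, not
  once per member neurite; tools that assign trunks per neurite will
  report larger totals.
* The skeleton cannot separate neurites that merge for long stretches;
  such geometry is attributed to whichever path is geodesically shorter.
* Litter structure is generated but not modeled in the statistics
  (no mixed-effects layer); the testing chain treats explants as
  exchangeable, as the original nonparametric analysis does.
* The microscope pixel size is a configuration default (0.5 µm/px), not
  a measured fact; all µm quantities scale linearly with it.
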