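# explantkit

Quantification toolkit for spiral ganglion neuron (SGN) explant outgrowth
studies. Cultured explants of the auditory nerve regrow neurites radially
onto the dish; treatments (neurotrophins such as BDNF and NT-3, or
charge-balanced electrical stimulation delivered through cochlear-implant
style electrodes) change how many fibers sprout and how far they grow.
`explantkit` implements the full desk side of such a study for researchers
in auditory neuroscience and neural-prosthesis development:

* **skeleton-graph morphometry** — an explant micrograph (nuclear +
  neuronal-marker channel) is adaptively thresholded, the explant body is
  delineated, and the outgrowth is skeletonized and converted into a
  spatial graph. From the graph: the number of neurite endings *E*
  (degree-1 nodes), branch points (degree ≥ 3), start points (fascicles
  exiting the body), per-ending root-to-tip geodesic lengths
  *ℓᵢ = d_G(endingᵢ, nearest start)*, the median and longest length, total
  outgrowth length, and the projected body area;
* **growth-direction statistics** — per-neurite bearings relative to the
  vertical image axis (0° = up, clockwise), 10° polar histograms, the
  Rayleigh test of circular uniformity (Z = n·R̄²) and a permutation
  Watson U² two-sample comparison;
* **DAB immunoreactivity** — positive-pixel classification by trained
  brown reference shades inside include-minus-exclude ROIs, and mean
  immunoreactivity IR = 255 − luminance on a 0 (no staining) – 255
  (saturation) scale;
* **stimulation charge accounting** — biphasic pulse trains (phase
  duration 30 µs, interphase gap 2.1 µs, 1000 Hz), duty cycle of
  minutes-scale on/off rasters, per-phase and total delivered charge, and
  plate evaporation QC arithmetic;
* **study statistics** — per-explant fold changes x/median(control)
  against a global or an in-plate control, equal-share pooling of cochlear
  turns, Kruskal–Wallis with Dunn's post-hoc (Bonferroni over the
  group-vs-control family), groupwise Mann–Whitney with Holm–Šídák
  step-down, Spearman correlation matrices and Tukey box summaries;
* **a ground-truthed synthetic generator** — explant images with exact
  vector geometry, DAB sections with known positive fraction and stain
  intensity, and explant-level study tables with log-normal outcomes,
  litter/plate variance components and zero-effect covariates, so the
  entire chain is testable without microscopy data.

## Worked example

Simulate one explant image with known geometry and re-measure it:

```python
import numpy as np
from explantkit.synthetic_data import ExplantImageSpec, DirectionSpec, generate_explant_image
from explantkit.image_pipeline import analyze_image

spec = ExplantImageSpec(
    n_start_points=40, neurites_per_start=(1, 1), branch_probability=0.0,
    heading_jitter_deg=1.5, direction=DirectionSpec(kind="spaced"), seed=2,
)
image, truth = generate_explant_image(spec)          # (2, 2048, 2048) uint16
mask, body, graph, metrics = analyze_image(image[1], spec.pixel_size_um)
print("truth endings:", truth.n_endings, "recovered:", metrics.n_endings)
print("median length  truth: %.1f µm  recovered: %.1f µm"
      % (np.median(truth.lengths_um), metrics.median_length_um))
```

```
truth endings: 40 recovered: 40
median length  truth: 288.9 µm  recovered: 288.1 µm
```

All 40 neurite endings are found, and the recovered median root-to-tip
length agrees with the generator's ground truth to a fraction of a
percent (per-ending lengths are typically within a few percent; see
docs/methods.md for the error model).

The same chain is available from the shell:

```sh
explant simulate --seed 2 --out sim/
explant analyze sim/explant_seed2.tif --pixel-size 0.5 --out out/
explant direction out/endings.csv
explant stim
```

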