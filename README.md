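# cometkit

Analysis of **comet assay** (single-cell gel electrophoresis) micrographs,
built around a study of sperm degradation in female spider crabs
(*Maja brachydactyla*), which store sperm in seminal receptacles for months
before fertilisation. The package answers two questions:

1. **Image analysis** — given a fluorescence micrograph of SYBR-stained
   nucleoids, find each cell, split it into the bright near-circular *head*
   and the dimmer *tail* of migrated (fragmented) DNA, decide whether the
   cell is damaged (tailed) or intact (head-only), and quantify the damage.
2. **Statistics** — given per-female damage and viability measurements
   against sperm storage time, characterise the temporal decline.

## Methods at a glance

**Segmentation** runs in four stages: morphological opening/closing
(noise), global thresholding with hysteresis (candidate regions; the lower
of a three-class Otsu split seeds regions that extend down to just above
background), region-restricted thresholding with shape gates — area window,
circularity 4πA/P², convexity A/A_hull — (head), and convex hull of the
smoothed region minus the head (tail). A four-feature CART decision tree
(head/tail area ratio, head position along x, mean head and tail
intensities) separates tailed comets from head-only cells, and comets with
an implausible head/tail area ratio or a migration axis not parallel to the
electrophoresis direction (+x) are discarded.

**Quantification** uses the *tail moment*

    TM = L_tail × ( DNA_tail / (DNA_head + DNA_tail) )

with background-subtracted integrated intensities as DNA mass and the tail
length `L_tail` in pixels; higher values mean more DNA degradation.

**Statistics**: tie-corrected Spearman rank correlation, and a
one-breakpoint segmented (broken-line) regression

    y = β₀ + β₁·x + β₂·(x − ψ)₊,   continuous at the breakpoint ψ,

estimated by Muggeo-style iterative linearization with SSE-guarded steps and
multi-start grid initialization. Slope confidence intervals come from the
converged working model; adjusted R² counts four estimated parameters.

Because the study's original micrographs are not distributed, the package
includes a **synthetic scene generator** that renders comets with exact
ground truth (masks, tail length, tail-DNA fraction), so every pipeline
stage is benchmarked against known truth. The 30-female table of storage
times and viability percentages ships with the package.

## Worked example

Generate a synthetic scene, segment it, score it against ground truth, and
fit the viability statistics — all from the shell:

```sh
cometkit synth --seed 7 --n 8 --out scene
cometkit segment --image scene/image.tif --out project.json --metrics metrics.csv
cometkit evaluate --pred project.json --truth scene/gt.json --out report.json
cometkit stats --out fit.json
```

`report.json` from this exact run:

```json
{
 "n_truth": 8,
 "n_predicted": 7,
 "detection_rate_percent": 87.5,
 "mean_iou_head": 0.9469,
 "mean_iou_tail": 0.9055
}
```

Seven of the eight simulated comets were found (one dim cell was missed);
matched heads and tails overlap their ground-truth masks with mean
intersection-over-union 0.95 and 0.91. `metrics.csv` holds one row per
accepted comet, e.g. a damaged cell with 51% of its DNA in an 86 px tail
scores tail moment `86 × 0.509 ≈ 43.7`, while a head-only cell scores 0.

`fit.json` (from the packaged female table):

```json
{
 "spearman_r": -0.9109,
 "breakpoint": 4.2209,
 "slope1": -13.3039,
 "slope2": -4.6031,
 "adj_r_squared": 0.7655
}
```

Viability correlates strongly and negatively with storage time
(Spearman r = −0.911): it falls by about 13.3 percentage points per month
until roughly 4.2 months, then by about 4.6 per month thereafter.

The same operations are available as a library:

```python
from cometkit import (SynthConfig, generate_assay_image, segment_image,
                      match_and_evaluate, load_female_table, fit_segmented)

image, truth = generate_assay_image(SynthConfig(seed=7, n_comets=8))
predicted = [s for s in segment_image(image) if s.accepted]
print(match_and_evaluate(predicted, truth).detection_rate)

records = load_female_table()
fit = fit_segmented([r.storage_time for r in records],
                    [r.viability for r in records])
print(fit.breakpoint, fit.slope1, fit.slope2)
```

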