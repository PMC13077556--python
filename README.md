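# cryoev

Automated characterization of extracellular vesicles (EVs) and
co-isolating particles in defocused cryo-EM micrographs: supervised
per-pixel segmentation of lipid bilayers, lipoproteins and ice
artifacts, followed by Hough circle detection and size-distribution
measurement — paired with a synthetic micrograph simulator that
provides per-particle ground truth, so every stage of the pipeline is
testable without microscope data.

## Who this is for

EV researchers and cryo-EM facility staff who need objective,
reproducible particle counts and size distributions from large
automatically acquired image sets. The defining image feature of an EV
is its lipid bilayer — two dark leaflets ~4 nm apart, resolvable at
strong underfocus — which distinguishes vesicles from dense
lipoprotein discs (HDL ~7–12 nm, LDL ~18–25 nm, VLDL ~30–70 nm) and
other non-vesicular particles that co-isolate with EVs.

## What it computes

1. **Simulation** (`cryoev.simulate`): seeded synthetic micrographs at
   the standard acquisition geometry (0.55 nm/px, ~32 e/Å² dose, one
   2 µm carbon hole per field) containing bilayer rings, dense
   lipoprotein discs, exomere-like ~45 nm particles, irregular ice
   blobs, a hole-rim arc, background gradients and dose-dependent
   shot noise — each with exact per-particle ground truth.
2. **Preprocessing** (`cryoev.preprocess`): percentile 8-bit
   normalization, frequency-domain bandpass (passband 2–50 px feature
   sizes), 4× mean-pool binning (0.55 → 2.2 nm/px), 3×3 median
   despeckling.
3. **Segmentation** (`cryoev.segment`): a trainable per-pixel
   classifier (`PixelClassifier`, an MLP over a multiscale filter-bank
   feature stack, one independent binary model per structure class),
   and a deterministic `RingMatchedFilter` bilayer detector
   (normalized cross-correlation with the double-leaflet ring template
   over a radius sweep).
4. **Detection and sizing** (`cryoev.detect`): edge/skeleton outlines,
   a Hough circle transform over radii 6–100 px with vote scores
   normalized so a complete ideal ring scores 1 and an arc covering a
   fraction α of a circle scores ≈ α (thresholds 0.8 for circles, 0.5
   for rings — partial bilayer predictions are still sized correctly),
   area-equivalent diameters d = 2√(A/π) for filled particles,
   rule-based artifact exclusion (hole rim, border, ice overlap), and
   median/SD/count/histogram size distributions.
5. **Evaluation** (`cryoev.evaluate`): greedy centroid/radius matching
   against ground truth, precision/recall/F1 and detection accuracy
   tp/(tp+fp+fn), per-class diameter bias and RMSE.

## Worked example

```python
from dataclasses import replace
import numpy as np
from cryoev.pipeline import PipelineConfig, process_micrograph, vesicle_scene
from cryoev.detect import size_distribution
from cryoev.simulate import simulate_micrograph, dataset_seeds

cfg = PipelineConfig()
scene = vesicle_scene(ev_density=40, image_shape=(1024, 1024), hole_rim=True)
records = []
for s in dataset_seeds(1, 10):
    micrograph, truth = simulate_micrograph(replace(scene, seed=s))
    recs, binned_px = process_micrograph(micrograph, cfg, truth=truth)
    records += recs

dist = size_distribution(records)
print(f"n={dist.count} median={dist.median:.1f} nm sd={dist.sd:.1f} nm")
```

prints

```
n=130 median=66.0 nm sd=19.1 nm
```

— 130 vesicles detected across ten simulated fields whose true
diameters are lognormal with median 60 nm: the sample median of the
truth draw in these ten fields is 64.4 nm, and the Hough-recovered
median of 66.0 nm tracks it to within one binned pixel's worth of
diameter (4.4 nm at 2.2 nm/px radius quantization). Per-matched-particle
bias over the same run is −0.33 nm.

The same pipeline is available from the shell:

```bash
cryoev run --n 10 --seed 1 --out runs/demo
cryoev simulate --n 5 --seed 7 --out sim/
cryoev preprocess --bandpass 50,2 --bin 4 sim/ pre/
cryoev size --mode rings --hough 6,100,0.5 --pixel-size 2.2 masks/ sized/
```

## Limitations

- Radius resolution of Hough sizing is 1 binned pixel (2.2 nm at the
  default geometry); no sub-pixel refinement is attempted.
- Area-based sizing merges touching particles into one component.
- Sizes of vesicles larger than ~200 nm are biased in real data by
  flattening in thin ice; the pipeline reports projected sizes and does
  not correct for this.
- The simulator is phenomenological (no CTF/optics model); see
  `docs/methods.md` for what passing tests do and do not establish
  about real micrographs.
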