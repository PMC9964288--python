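# waterscape

Space–psychology–behavior landscape-aesthetic evaluation of waterfront green
spaces, as a reusable, tested Python pipeline.

The package computes:

- **Spatial dimension** — twelve formula-defined indicators from categorical
  land-cover rasters (Shannon diversity, Pielou evenness, hemeroby
  disturbance, patch fragmentation), elevation/surface grids (terrain
  position, profile curvature, green volume, relief amplitude) and panoramic
  images (layer superposition, opponent-channel colorfulness, sky fraction,
  canopy density); min–max normalization, horizontal / vertical /
  three-dimensional / overall composites, and exact (dynamic-programming)
  natural-breaks grading.
- **Psychological dimension** — pluggable review sentiment scoring on a 0–10
  scale (transparent lexicon scorer by default), per-park emotional values,
  relative evaluation rates and relative emotional values, the rate–emotion
  OLS regression, and five-sense word frequencies.
- **Behavioral dimension** — thermal means and low/sub/high grading of
  heat-map snapshots, Gaussian visitor kernel densities (mass-conserving),
  3-class density grades, and behavior-observation summaries.
- **Coupling–coordination model** — coupling index C, coordination index T,
  coupling coordination degree D = √(C·T) with its 10-level ladder, for any
  2- or 3-subsystem combination.
- **Synthetic scenes** — `waterscape.synthetic_data` generates every input
  the pipeline consumes (rasters, panoramas, reviews, heat snapshots,
  visitor points) with known ground truth, deterministically per seed.

Reference per-park tables from the source study ship as plain-CSV fixtures
under `waterscape/data` (see `waterscape.fixtures.load_table`).

## CLI

```bash
# generate a 3-park synthetic scene
waterscape --seed 7 --outdir scene synth --parks 3

# run everything (indicators, composites, sentiment, behavior, coupling)
waterscape --outdir results all scene

# or individual stages
waterscape --outdir results spatial scene
waterscape --outdir results psych scene
waterscape --outdir results behavior scene
waterscape --outdir results couple scene
```

Global flags: `--config` (YAML/JSON run configuration mirroring
`waterscape.core_io.RunConfig`), `--seed`, `--outdir`, `--log-level`.

## Layout

- `src/waterscape/core_io.py` — raster/CSV I/O, `RunConfig`, pipeline driver
- `src/waterscape/landcover_metrics.py` — C1–C4, C11
- `src/waterscape/terrain_metrics.py` — C7, C8, C10, C12
- `src/waterscape/image_metrics.py` — C5, C6, C9
- `src/waterscape/aggregation.py` — normalization, composites, natural breaks
- `src/waterscape/sentiment_analysis.py` — emotional values and regression
- `src/waterscape/behavior_metrics.py` — thermal, kernel density, observation
- `src/waterscape/coupling_model.py` — C, T, D and the coordination ladder
- `src/waterscape/synthetic_data.py` — ground-truth scene generator
- `tests/` — unit, property (hypothesis) and acceptance suites
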