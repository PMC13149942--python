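# spikescan

Digital phenotyping of wheat spike photographs: from a single-spike image
on a blue backdrop (or a synthetic phantom with exact ground truth) to a
per-spike "digital certificate" and a relational phenotype store.

The pipeline:

1. **phantom** — synthetic spike images (kite or smooth-lanceolate body,
   thin awn strokes, optional color chart, known mm-per-pixel scale) with
   exact 4-class ground-truth masks; pure function of (spec, seed).
2. **segmentation** — classical hue-window + morphological-thickness
   segmentation into background / chart / body / awns; scale and affine
   color calibration from the chart; loader for externally produced masks.
3. **morphometry** — the 19 morphological features: spike axis, 7 outline
   descriptors + awn area, and the 11-parameter symmetrized quadrangle
   (kite) model.
4. **colorimetry** — mean color components in RGB / Lab / HSV / YCrCb
   (12 per region) and the 3 dominant colors (seeded k-means, k = 3) for
   body and awns.
5. **texture** — 10 GLCM and 6 GLRM features over the body region.
6. **certificate** — per-spike frontal/lateral blocks of 24 features
   (11 quadrangle + 7 outline + body RGB + awn RGB, with awn area carried
   alongside), Welch / Mann-Whitney group comparisons with optional
   Benjamini-Hochberg correction, and kite-model figure rendering with a
   5x magnified width axis.
7. **datastore** — an 11-table SQLite schema (5 uploaded-block tables:
   Collection, Plant with exactly 20 fields, Environment, Spike, Image;
   6 extracted-block tables keyed by Image), transactional CSV batch
   import with row-level rejection reporting, feature export, and
   frequency summaries.

## Test

```sh
python -m pytest -q tests/
```

The suite is fully synthetic — every fixture is generated at test time by
the phantom module, which is itself first-class, tested code.

## CLI

```sh
spikescan phantom --seed 3 --out ph/                  # synthetic image + truth mask + spec
spikescan segment ph/phantom.png --out mask.png
spikescan calibrate ph/phantom.png mask.png --mm-per-px 0.2 --out cal.json
spikescan features ph/phantom.png --mask mask.png --cal cal.json \
    --spike-id s1 --view frontal --out feats/s1_frontal.json
spikescan certificate feats/ --out certs.json
spikescan compare certsA.json certsB.json --block frontal
spikescan render certs.json --block frontal --out fig.svg
spikescan db init spikes.db
spikescan db import spikes.db manifest.csv --images images/
spikescan db stats spikes.db --group-by country_of_origin --top 10
spikescan db export spikes.db --out export/
```

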