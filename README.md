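# retinaquant

Quantification toolkit for retinal cryosection experiments:

- **Synthetic data with exact ground truth** (`retinaquant.synthetic`):
  confocal-like layered sections (DAPI nuclei, a PCNA-positive subset,
  L-plastin leukocytes, optional TUNEL/HuC/D channels) with PSF blur and
  Poisson + Gaussian noise, plus qPCR Ct tables with programmed per-group
  fold changes, reference-gene loading drift and non-detect behaviour.
- **Imaging core** (`retinaquant.imaging`): named-channel z-stack model with
  OME-TIFF / plain TIFF (+ YAML sidecar) I/O, polygon/polyline ROIs
  (structured text, minimal ImageJ `.roi` reader), shoelace area and
  curvilinear length.
- **Colocalization counting** (`retinaquant.counting`): per-plane
  preprocessing (unsharp mask, Gaussian blur, optional edge step), a
  threshold ensemble (Otsu / multi-Otsu / local mean, majority-vote
  combination), 15 px² small-object exclusion before and after the binary
  AND of two channel masks, 8-connected component counting inside a polygon
  ROI or polyline band, densities per mm² / per mm; manual-rule scoring
  (nuclear-overlap and surround rules) for marker-positive cells.
- **qPCR quantification** (`retinaquant.qpcr`): technical-replicate collapse
  with explicit non-detect policy, reference-gene stability screening
  (2^(Ct range) fold scale), Livak ddCt fold changes against a calibrator
  group.
- **Group statistics** (`retinaquant.stats`): Welch's unequal-variance t-test
  (optional permutation p-value), tie-corrected Kruskal–Wallis, Conover–Iman
  post hoc with Holm/Bonferroni adjustment.
- **Pipeline + CLI** (`retinaquant.pipeline`, `retinaquant.cli`):
  YAML-configured end-to-end runs (simulate → count → qPCR → stats →
  report), deterministic given the root seed.

## CLI

```sh
# simulate a section (stack + ground truth CSVs)
retinaquant simulate --config scene.yaml --seed 3 --out simdir/

# count colocalized objects, normalized to the ROI
retinaquant count --stack simdir/stack.ome.tif --channels DAPI,PCNA \
    --roi roi.txt --out counts.csv --qc-dir qc/

# ddCt fold changes with a reference-gene screen
retinaquant qpcr --table ct.csv --target ascl1a --reference 18s \
    --calibrator treatment=saline,dpi=4 --screen 18s,bact2 --out folds.csv

# group statistics on a long-format CSV
retinaquant stats --counts counts.csv --value density --by line \
    --test kw-conover --adjust holm --out stats.csv

# full experiment from one YAML config; then a text summary
retinaquant run --config run.yaml --out outdir/
retinaquant report --dir outdir/
```

ROI files are plain text (`label:`/`kind:` lines followed by `row col`
vertex pairs, 0-based pixel coordinates); ImageJ `.roi` polygons/polylines
are also read. Pixel size is always explicit (stack metadata or
`--pixel-size`), never defaulted.

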