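# fibrilmpl

Mass-per-unit-length (MPL) densitometry for filamentous assemblies in
dark-field TEM micrographs, calibrated against an in-image standard of known
MPL (e.g. tobacco mosaic virus, 131 kDa/nm).

In dark-field imaging the recorded intensity is approximately proportional
to local projected mass, so the ratio of a fibril's background-corrected
intensity to that of a co-imaged standard yields its MPL with no detector
calibration and no pixel-size input:

```
mpl = (I_fibril - B_fibril) / (I_std - B_std) * K
```

Per 1-px axial step along each user-selected segment, the sampler measures a
perpendicular band of `w` bilinear samples plus two flanking background
bands of the same width (default 2 px gap); `B` is the mean of the two
background sums. The calibration pools the corrected slice sums of every
standard selection; slice MPLs are aggregated per fibril and pooled across
fibrils, and all outputs are plain-text TSV.

## CLI

Selections are plain TSV (`kind  label  x0  y0  x1  y1  width`, `#`
comments, optional header; coordinates are 0-based pixel centers), or an
equivalent JSON mirror. Curved fibrils are handled by chaining short
segments with suffixed labels.

```sh
# render the three-bar validation phantom (+ its selection file)
fibrilmpl simulate -o phantom --noise-sd 25 --seed 1

# calibrated measurement: per-slice, summary, and histogram TSVs
fibrilmpl measure phantom.tif phantom_selections.tsv -o run --k 131 --gap 2

# band-width robustness sweep on a phantom bar
fibrilmpl sweep -o sweep.tsv --target A --wmin 20 --wmax 40 --noise-sd 0

# consecutive-difference noise statistics
fibrilmpl fluctuation phantom.tif phantom_selections.tsv -o fluct.tsv
```

The measurement path is fully deterministic; randomness exists only in the
synthetic phantom generators and is always seeded.

Notes on conventions:

- Slices whose band samples fall partly outside the image are dropped, not
  zero-padded. Width below the true filament width causes systematic MPL
  underestimation; choose `w` comfortably above the apparent width.
- The summary emits pooled (all-slice) statistics and per-fibril-mean
  statistics side by side, with SD and SEM explicitly labelled.
- Negative per-slice MPLs on noisy background are retained (clipping would
  bias means upward).

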