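# Methods

This note documents the models, conventions and numerical choices behind
`paramlens`, in the order data flows through the package.

## Sweeps and data records

A sweep is defined by a list of parameter specs `(name, lo, hi, n_samples)`,
a list of input images, and a plugin. Each spec is sampled **uniformly and
endpoint-inclusively**: sample `i` is the convex combination
`lo·(1−t) + hi·t` with `t = i/(n−1)`. This form (rather than `lo + i·step`)
makes the endpoints exact and gives a symmetric interval an exactly-zero
midpoint — important because corrective parameters sampled an odd number of
times should have a sample that is *exactly* "no change" (the 6th of 11
samples on `[−0.5, 0.5]` is 0.0, not 1e−17).

The grid is the Cartesian product of the per-parameter samples, enumerated
with the **last parameter varying fastest**; the enumeration index is the
`record_id`. Fixing the order makes record ids stable across runs, so two
runs of the same configuration and seed produce byte-identical
`records.csv` files. Plugin failures abort the sweep (with the failing
record id, image index and parameter values) rather than skip: a silently
sparse grid would corrupt every downstream analysis.

A persisted sweep is a directory: `manifest.json` (specs, plugin settings,
seed, output-image references), `records.csv` (one row per record,
parameter columns left of measure columns, mirroring the tabular view), and
`images/rec<id>_in<i>_ch<k>.png`. Floats are serialised with Python's
shortest round-trip `repr`, so read-back is bit-faithful; the reader
cross-checks the CSV row count against the JSON record count and rejects
version mismatches. Input images passed in memory are persisted under
`inputs/` so renders remain reproducible from the directory alone.

## Colour deconvolution and the corrective parameters

**Model.** For transmitted light, optical density is additive across dyes:
`OD = D · S`, where `D` (per pixel) holds per-stain densities and the rows
of `S` are the stains' unit absorbance vectors in OD(R,G,B) space.
`rgb_to_od` computes `−log10(clamp(I, ε, I0)/I0)` per channel with
`ε = I0/255` (one count on the 8-bit scale), so saturated-dark pixels map to
a large finite density instead of infinity. Deconvolution computes
`D̂ = OD · S⁻¹` per pixel.

**Default stain vectors.** The H&E calibration of Ruifrok & Johnson,
normalised to unit length: hematoxylin `(0.650, 0.704, 0.286)`, eosin
`(0.072, 0.990, 0.105)`. Both are overridable per sweep.

**Corrective parameterisation.** The two corrections `p1`, `p2` are
rotation angles (radians) applied to the stain-1 and stain-2 vectors
*within the plane spanned by the two base vectors*, followed by
renormalisation; `p1 = p2 = 0` reproduces the base matrix exactly. Rotation
was chosen over per-component additive deltas because it is a
one-parameter-per-stain family with an exact identity at 0 and no
renormalisation ambiguity; the parameterisation is confined to
`build_deconv_matrix` so an alternative family can be swapped in. For a
two-stain model the third matrix row is the normalised cross product of the
two (corrected) stain rows — the standard complement for three-channel
deconvolution. The builder refuses (nearly) collinear stain pairs and
matrices with condition number above 1e8.

**Quality measures.** `m1`/`m4` are the percentage of negative
stain-1/stain-2 coefficients over all pixels; `m2`/`m5` their mean;
`m3`/`m6` their **population** standard deviation. With no negatives, mean
and sd are 0 by convention. Statistics use the raw (unclamped) coefficients
— negative values are the object of study — but values in `[−1e−12, 0)`
count as zero: deconvolving an exact forward mixture with its own matrix
leaves float residue of order 1e−16 OD at zero-density pixels, which is
roundoff, not a negative stain contribution (real mismatch negatives are
~1e−2 OD). The per-stain *viewables* written as output images clamp
coefficients to ≥ 0 and re-expose them through Beer–Lambert
(`I0 · 10^(−c·v)`, rounded half-up to uint8); clamping affects display only.

## Nuclei-detection fixture

A deliberately plain five-parameter detector in the CellProfiler mould:
Gaussian smooth (`smoothing_sigma`, px) → fixed threshold
(`lower_threshold`, intensity) → fill holes up to `hole_fill` px diameter →
8-connected components → keep components whose equivalent diameter (the
diameter of the circle with the component's area) lies in
`[min_diameter, max_diameter]`. The count of survivors is the output
measure; the output image is the input with 1-px inner boundaries of kept
components set to 255. It exists to exercise the sweep/table workflow on a
counting task with ground truth, not to compete with real segmentation —
touching nuclei are not declumped, which is why the synthetic generator
enforces non-overlapping disks.

## Synthetic data

`generate_structured_densities` builds per-stain density fields from
Gaussian bumps at uniform random positions: many small dense bumps for the
hematoxylin-like stain (nuclei, default 40 bumps, σ = 4 px, peak 0.9 OD) and
few broad bumps for the eosin-like stain (cytoplasm/connective tissue,
default 12 bumps, σ = 22 px, peak 0.6 OD). Each stain's field is rescaled so
its peak equals its amplitude: overlapping bumps must not push total OD
beyond what transmitted light at 8-bit scale can resolve, and peak densities
of 0.6–0.9 OD are the realistic staining range. `generate_two_stain_image`
renders `I = I0 · 10^(−D·S)` with optional additive Gaussian intensity noise
(default sd 0, so oracle tests are exact), clipped to `[0, I0]`.

`generate_nuclei_image` places non-overlapping bright disks (default
diameter 10 px, intensity 200 on background 20) by rejection sampling with
at most 10,000 attempts (separation ≥ diameter + 4 px, no border clipping)
and returns the image with its ground-truth count and centers.

The default test image size is 256×256 — large enough for dozens of
well-separated objects, small enough that a full 11×11 sweep over two
images runs in seconds; the generators take any shape, including the
1000×1000 typical of scanned histology tiles. What passing tests on these
inputs show: the algebra of the pipeline (mixing → deconvolution →
measures) and the detector's parameter response are correct. What they do
not show: robustness to real tissue texture, scanner colour profiles,
uneven illumination, or touching nuclei — none of which the generators
emulate.

## Table operations

All operations are pure functions on an immutable `ResultTable` (records +
ordering + visible set + sort keys + selection).

* **Nested sort** (`multi_sort`): clicking key `k` appends it to the sort
  keys; the ordering is the lexicographic ascending sort over the
  accumulated keys, so earlier keys form contiguous bins that the new key
  reorders internally. Ties on the full key tuple break by `record_id`,
  making every ordering deterministic. Ascending is the fixed direction.
* **Smart sort**: scores each parameter by the mean of `|Pearson r|`
  against every measure column over the *visible* records, with `r = 0`
  when either column is constant (no association rather than undefined);
  the winner becomes the sole sort key. Ties break toward the leftmost
  parameter column. A `variance_weighted` variant weights each measure's
  `|r|` by that measure's variance share, for the reading of "aggregate
  correlation" that emphasises measures which actually vary; the unweighted
  mean is the default. Only the single top-ranked parameter is sorted on —
  ranking-and-sorting by all parameters imposes a hierarchy users then have
  to undo.
* **Context selection**: the maximal contiguous run, in the current visible
  ordering, of records sharing the cursor record's exact value in the
  cursor column. Exact float equality is safe here because grid values are
  shared sampled constants, never recomputed.
* **Filters** compose by intersection with the current visible set, keep
  the ordering, and prune the selection; `clear_filters` resets.
* **Coverage strips** divide each column's full domain into 100 display
  bins; a bin is covered when any selected record's value falls in it, and
  adjacent covered bins merge. Point values therefore widen to one bin; a
  constant column's degenerate domain is fully covered or empty.

## Rendering

Renders are composed directly into uint8 arrays (no font/chrome
dependencies), so identical state yields byte-identical PNGs. The table
view allots 48 px per column with parameters left of measures, a colour
header band, and a per-column strip showing the visible records' domain
coverage; total height is `n_visible · row_height + 17` px of fixed chrome.
Bar encoding is used when `row_height > 4` px, otherwise a per-column
polyline through the per-row value positions (over-plotting accepted).
Cell values map linearly onto the column's `[min, max]`; constant columns
render at mid-scale rather than erroring.

The image grid shows input images on top (each repeated over its block of
output-channel columns) and one row per selected record, in selection
order. Each output image is blended as `α·output + (1−α)·input` with
round-half-up quantisation, so `α ∈ {0, 1}` reproduce the source images bit
for bit. ROI crop applies to input and output alike before blending;
magnification is nearest-neighbour and applied last. A side panel draws the
selection's coverage strips. `render_single_record` emits one record's row
composed by the same path, so it equals the corresponding grid row exactly
— the static analogue of a hover preview.

SVG output of the table view is structural (one mark per cell) with no
bit-level claims; PNG is the contract-bearing format.

## Known limitations

* The deconvolution plugin assumes exactly two stains; three-stain models
  work at the matrix level but have no sweep plugin.
* The smart-sort statistic is Pearson-based; monotone nonlinear
  relationships are under-weighted (a rank variant would be a natural
  extension).
* The nuclei detector has no declumping; counts on overlapping objects
  undercount by design.
* Renders target reproducibility, not typography: no text labels are drawn.
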