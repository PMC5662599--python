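# Methods

## The measurement problem

Single-chain FRET biosensors for RHOA place donor (CFP) and acceptor
(citrine-YFP) on one polypeptide, so the two fluorophores are equimolar in
every pixel and the acceptor/donor emission ratio reports local GTPase
activation with no bleed-through correction. In migrating cells such as
trunk neural crest cells, RHOA activity is spatially organized: high and
persistent in the cytoplasm at the cell rear, lower and fluctuating in the
protrusive front. `fretpolar` turns two-channel time-lapse stacks into the
quantities used to describe that organization — per-pixel activation maps,
back/front FRET indices and their ratio, fixed region-pair (A/B) series
with repolarization detection, line-scan profiles, protrusion-angle
statistics and migration metrics — and ships a generator that produces the
same data with known ground truth so every stage is testable.

## Ratiometric processing chain

Per frame and channel:

1. **Background subtraction.** Background = median of a user-supplied
   background region, or, when absent, of the pixels below a triangle
   threshold of the full-frame histogram (pixels without significant cell
   signal). The corrected frame is clipped at zero.
2. **Cell masks.** The donor+FRET sum (better signal-to-noise than either
   channel and insensitive to FRET efficiency) is thresholded — Otsu by
   default — and connected components smaller than `min_object_area`
   (default 50 px) are dropped; each surviving component is one cell.
3. **Windowed ratio.** For every mask pixel, ratio = (Σ FRET)/(Σ donor)
   over a `window_size` square window intersected with the mask, times a
   scale factor of 1000. The default window is 3×3, the smallest window
   that realizes sum-based noise suppression; pixels whose window carries
   no donor signal are undefined.
4. **Low-tail exclusion.** The dimmest 5% of defined pixels — ranked by
   summed-channel intensity, since the purpose is to remove low-intensity
   pixels whose ratio is noise-dominated — are discarded:
   exactly ⌊qN/100⌋ pixels, ties at the cut broken by (row, column) raster
   order so the operation is deterministic.
5. **Smoothing and normalization.** A Gaussian filter of width 2 pixels is
   applied, reading *width* as 2σ (σ = 1 px); smoothing is mask-aware
   (normalized convolution), so undefined pixels carry zero weight and no
   signal leaks across the mask edge. Values are then divided by the
   defined minimum so the lower scale value is exactly 1.0. Normalization
   is per frame and per cell.

Two numerical details are deliberate. The windowed sums are accumulated as
shifted arrays in raster order, which makes the result bit-identical to a
naive per-pixel double loop. And because both the 3×3 window and the σ=1
Gaussian mix pixels across the back/front divide, the half-contrast of a
sharply polarized cell is biased low by roughly 2% at the default cell
size (semi-major axis 8 µm); with `window_size=1` and `gaussian_width=0`
the chain is exactly unbiased. This is a spatial-resolution trade-off of
the prescribed filtering, not an estimator defect, and it is far inside
the 10% band the noisy-recovery checks use.

## Polarity statistics

The *FRET index* of a region is defined as the mean of the defined
normalized ratio pixels in that region (the underlying publications do not
write the formula; mean over the region is the simplest consistent
choice). The cell is split into back and front halves by the line through
the axis centroid perpendicular to the front direction; the front
direction comes either from an annotation or from the track's net
displacement over a `lookahead` of 1 frame (15 min). Halves with fewer
than 10 defined pixels yield an undefined record with a reason code. The
back/front ratio is exactly reciprocal under a 180° axis flip and
invariant under any common rescaling of the image.

Region-pair (A/B) series use two regions fixed in the lab frame — suited
to a stationary cell undergoing a front–back switch — and the
repolarization frame is estimated as the first frame whose B/A value lies
on the opposite side of 1 from the series start.

Line scans sample the image by bilinear interpolation every `step`
(default one pixel) along the polyline's arclength, averaging
`averaging_width` = 3 parallel samples spaced one pixel apart
perpendicular to the local direction. Profile correlation linearly
resamples two profiles onto a common normalized-position grid (0 = leading
edge, 1 = perinuclear) and reports Pearson r with the sample count.

Heat maps align cells on a common time base (nearest-neighbour fill) and
order rows by descending time-mean as a lightweight stand-in for
clustering.

## Protrusions

A protrusion is an actin extension reaching strictly more than 4.5 µm
beyond the cell body. The body is recovered by morphological opening with
a disc of `body_opening_radius` = 3 µm (configurable); candidates are
connected components of mask−body touching the body. Length is the
maximum Euclidean distance from component pixels to the body, minus one
pixel: the distance transform measures to the nearest body pixel *centre*
and overshoots the body boundary by up to a pixel, and the subtraction
keeps a rasterized arm of exactly 4.5 µm from being pushed over the
strict threshold by discretization. Length is the tip's reach beyond the
body boundary, not arm arclength — rasterization-stable and true to
"extension beyond the cell body". The protrusion direction is base→tip,
the angle to the subsequent migration direction is folded to [0°, 180°]
(the published polar plots are half-roses), and the default histogram bin
is 20°.

## Motility

For a track sampled at strictly increasing times: total distance = sum of
step lengths (µm); net displacement = straight-line origin-to-end
distance; duration in hours; net speed = net displacement / duration and
total speed = total distance / duration (µm/h); persistence = net
displacement / total distance ∈ [0, 1]. "Net" speed is read as dividing
the straight-line displacement (consistent with the separately reported
total speed); a stationary track gets persistence 1.0 by convention, with
a warning. Tracks are not smoothed before metric computation.

## Synthetic data: what it emulates and what it does not

The movie generator renders an elliptical cell (semi-major 8 µm, aspect
0.8, smooth sigmoid edge) migrating at `migration_speed` along
`migration_direction`, imaged at 0.16 µm/pixel every 15 min. The
activation field is `activation_back` (default 2.0) in the rear half and a
sinusoid around `activation_front_mean` (default 1.0, amplitude 0.3,
period 8 frames) in the front half — a polarized cell with a fluctuating
front. Donor = edge profile × 1000 counts + 100 counts background; the
FRET channel is activation × (donor − background) + background, so with
noise disabled the background-corrected channel ratio on the mask *is* the
activation field. Noise is per-channel Poisson on the expected counts plus
Gaussian read noise (sd 5 counts) — the standard camera model. Optional
`repolarization_frame` flips the back/front assignment and reverses the
migration direction mid-movie. Ground truth (masks, activation fields,
centroid track, front axes, exact back/front ratio) is returned alongside.

Default problem sizes: movies of 16 frames at 256×256 (a 4-hour segment
of high-magnification ratio imaging; recovery and repolarization checks
use 2- and 28-frame movies), random walks of 64 steps (the 16-hour
motility condition). The signal-to-noise regime is a free choice — the
source acquisitions publish no background or noise statistics — picked
once as a realistic confocal operating point.

What the generator does *not* model: optics (no PSF), photobleaching,
multi-cell fields or collisions, membrane texture, and protrusions on the
moving cell (star masks with arms of known length and angle are a separate
fixture for the protrusion rule). Passing tests therefore demonstrate
correctness of the quantification chain under a known forward model, not
robustness to segmentation-hostile real imagery.

## Known limitations

- The back/front halving by a straight line through the centroid is a
  stated substitute for hand-drawn regions of interest, which are not
  recoverable from the source description.
- Protrusion detection parameters of the original ADAPT-based analysis are
  unrecoverable; the opening-based operator here keeps only the 4.5 µm
  retention rule verbatim.
- Whether "Gaussian filter of width 2 pixels" means σ, FWHM or kernel
  diameter is ambiguous; width = 2σ is this package's reading and is
  configurable.
- The pipeline is single-cell per movie in the orchestrated runner
  (largest detected component); the library functions accept any number
  of cells per frame.
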