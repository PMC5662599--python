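# fretpolar

Quantification of front–rear cell polarity from ratiometric FRET
biosensor time-lapse imaging, with protrusion-angle and cell-motility
statistics and a synthetic-data generator with full ground truth.

The package is written for the analysis of migrating cells — the
motivating system is trunk neural crest cells expressing a single-chain
RHOA biosensor — where the question is how GTPase activation is organized
along the front–rear axis: persistently high at the cell rear, lower and
fluctuating in the protrusive front, and re-localizing when the cell
reverses direction.

## What it computes

**Activation maps.** For a single-chain sensor, donor (CFP) and acceptor
are equimolar per pixel, so activation is read out ratiometrically with no
bleed-through term. Per frame: local background subtraction; cell masks
from the thresholded donor+FRET sum; windowed ratio
R(x) = 1000 · Σ_w F / Σ_w D over a 3×3 window within the mask; exclusion
of the dimmest 5% of pixels; mask-aware Gaussian smoothing (width 2 px,
σ = 1) and normalization so the minimum defined value is 1.0.

**Polarity indices.** The FRET index of a region is the mean normalized
ratio over its defined pixels. Splitting the mask by the line through the
centroid perpendicular to the front direction u (from annotation or from
the subsequent migration displacement) gives

    back/front ratio = mean{R(x) : (x−c)·u < 0} / mean{R(x) : (x−c)·u ≥ 0}

plus the total index over the whole cell, fixed region-pair (A/B) series
with detection of the frame where B/A crosses 1 (repolarization), line
scans with Pearson profile correlation, and per-cell heat maps over time.

**Protrusions.** Actin extensions reaching strictly more than 4.5 µm
beyond the cell body (recovered by morphological opening) are protrusions;
the angle between each protrusion and the subsequent migration direction
is folded to [0°, 180°] and histogrammed in 20° bins.

**Motility.** Per track: total distance (µm), net displacement, net and
total speed (µm/h), and persistence = net displacement / total distance.

The synthetic generator renders a migrating elliptical cell with a known
polarized activation field (rear level 2.0, fluctuating front around 1.0),
Poisson shot noise and Gaussian read noise, optional mid-movie
repolarization, star masks with arms of known length/angle, and
persistent-random-walk trajectories — so every stage can be checked
against ground truth. See `docs/methods.md` for the full model.

## Worked example

```python
import fretpolar as fp

params = fp.SyntheticCellParams(n_frames=4, rng_seed=42)
movie, truth = fp.generate_polarized_cell_movie(params)

cell, ratio, qc = fp.process_frame(movie.donor_frames[0], movie.fret_frames[0])[0]
print(f"background estimate (donor): {qc['background_donor']:.1f} counts")
print(f"defined ratio pixels:        {qc['defined_pixels']}")

track = fp.trajectory_from_ground_truth(truth)
axis = fp.derive_axis_from_track(track, frame=0)
rec = fp.back_front_indices(ratio, cell, axis, movie.pixel_size)
print(f"back index:  {rec.back_index:.3f}")
print(f"front index: {rec.front_index:.3f}")
print(f"back/front FRET index ratio: {rec.back_front_ratio:.3f}"
      f"   (ground truth {truth.true_back_front_ratio[0]:.3f})")

walk = fp.generate_trajectory(fp.RandomWalkParams(rng_seed=1))
s = fp.summarize_track(walk)
print(f"persistence: {s.persistence:.3f}   net speed: {s.net_speed:.2f} um/h"
      f"   total speed: {s.total_speed:.2f} um/h")
```

prints

```
background estimate (donor): 100.1 counts
defined ratio pixels:        5993
back index:  2.057
front index: 1.049
back/front FRET index ratio: 1.962   (ground truth 2.000)
persistence: 0.785   net speed: 4.71 um/h   total speed: 6.00 um/h
```

The back index ~2 and front index ~1 recover the generator's polarized
activation field; the ratio of 1.96 against a truth of 2.00 reflects the
small blur the prescribed 3×3 window and Gaussian filter introduce across
the back/front divide. The random walk (64 steps of 1.5 µm at 15-min
intervals, 20° turning spread) migrates at 6 µm/h total speed with
persistence 0.79.

A config-driven CLI wraps the same chain:

```sh
fretpolar run-all --config config.yaml     # synthesis → ratio → polarity →
                                           # protrusions → motility + manifest
```

with subcommands `simulate`, `ratio`, `polarity`, `protrusions`,
`motility` for stage subsets. Outputs are CSV/TIFF/PNG in a fresh
timestamped run directory with SHA-256 hashes recorded in
`manifest.json`.

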