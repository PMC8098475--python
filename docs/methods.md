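# Methods

## Thickness model

Both estimators treat electron attenuation as a single-exponential law
in thickness. For zero-loss filtered pairs,

    D = λ · ln(I / I_zl) − C,

with λ the *apparent* inelastic mean free path and C the vacuum
zero-offset; for aperture-limited scattering (ALS),

    D = λ_ALS · ln(I_0 / I).

The constants are operational, not physical: they absorb aperture
size, detector response, sample composition and magnification regime,
which is why the registry keys them by voltage, regime (LM vs M/SA)
and method, and why the package offers refitting rather than claiming
transferable physical mean free paths.

Registry defaults (nm):

| voltage | regime | method | λ    | C  |
|--------:|--------|--------|-----:|---:|
| 200     | M/SA   | filter | 305  | 4  |
| 200     | LM     | filter | 485  | 35 |
| 300     | M/SA   | filter | 435  | 1  |
| 300     | LM     | filter | 805  | 65 |
| 200     | LM     | ALS    | 600  | 0  |
| 300     | LM     | ALS    | 1750 | 0  |

C is defined by the observation that an empty hole reads a small
positive apparent thickness with the filter method; subtracting the
fitted offset sets that reading to zero. ALS profiles carry C = 0 by
construction because the vacuum reference I_0 is itself measured
inside an empty hole, absorbing the same effect.

## Calibration fits

All λ fits are least squares with C held fixed, i.e. a through-origin
regression of (D + C) on the log-attenuation. C comes first, from
vacuum holes (C = λ·mean lnr, floored at 0 with a warning when
negative); the two-step scheme keeps the vacuum zero exact, which is
the defining property of C. When a table carries both vacuum and ice
holes, the CLI iterates the two steps to their joint fixed point.
A single usable sample yields the one-point solution (D + C)/lnr with
undefined standard error; uncertainties are ordinary least-squares
standard errors, no bootstrap. Negative thickness readings are kept
raw internally (clamping is a display/selection concern) so the fits
stay unbiased.

The synthetic calibration generator draws hole thicknesses uniformly
over 20–200 nm by default. The range matters: with n samples of
thickness noise σ_D, the λ standard error is σ_D/√(Σ lnr²), and a
20–200 nm span makes 20 samples at σ_D = 5 nm determine every registry
λ to better than 1%. A narrow span (say 10–70 nm) would leave λ = 305
determined only to ~2.4% — the wide span reflects that calibration
sessions deliberately include thick squares.

## Counting statistics and the measurement radius

Per-hole thickness uses the ratio of mean intensities over a disk of
`radius_fraction` times the hole radius. For Poisson counting with N
total counts in the disk (unfiltered plane), the thickness error is

    σ_D ≈ λ · sqrt[(1 + e^{(D+C)/λ}) / N].

At the calibrated survey conditions — 10.7 counts/px/s, 1 s exposure,
144.6 Å pixels — an R1.2/1.3-style hole (0.6 µm radius ≈ 41.5 px)
collects ≈ 5.8·10⁴ counts over its full disk, giving σ_D ≈ 1.85 nm at
D = 30 nm; at half the radius the disk shrinks fourfold and σ_D grows
to ≈ 3.7 nm. The conservative default `radius_fraction = 0.5` stays
well clear of the hole edge and suits higher-magnification work where
counts are plentiful; at survey magnification the radius should be
enlarged toward the full hole, which is what the end-to-end accuracy
tests do. Because detected centers are snapped to the refined lattice
(see below), even the full-hole disk stays inside the hole.

Two averaging conventions coexist deliberately: the cursor-style
`local_thickness` averages the *ratio image* over a box and applies
the formula to the averaged ratio, while per-hole measurement applies
the formula to the *ratio of mean intensities*. They agree on uniform
regions but differ under noise and gradients; both are kept because
both are the native conventions of the interactive and the batch
workflow respectively.

The count-rate guard compares the mean unfiltered rate against the
camera ceiling (K2: 10 counts/px/s, inclusive) and warns without
aborting — the reference acquisition itself ran at 10.7 counts/px/s,
so a blocking guard would reject the very conditions the constants
were calibrated under. The K2 counts-per-electron factor is 10.7/12.9;
the K3 factor defaults to 1.0 and its ceiling to 40 counts/px/s
(roughly scaling with its faster frame rate) — both are calibration
knobs, not measured constants.

## Image processing

* MRC2014 I/O is built on gemmi (modes 0/1/2/6 read, mode 2 written);
  the pixel size comes from the map cell. Exposure time and slit state
  have no standard MRC field and are carried in a header label;
  foreign files default to 1 s with a warning.
* Binning is block *mean* pooling, so every intensity ratio — and
  therefore the thickness formula — commutes with binning. Fourfold
  binning is the default for the displayed map, mirroring the survey
  acquisition it emulates.
* The ratio image is median-filtered (3×3 default, reflected edges)
  before the log; filtering the ratio rather than the raw planes is a
  choice, exposed as `apply_median`/`median_kernel`.
* Registration is rigid translation only (the energy shift displaces
  the filtered image; it does not rotate or scale it), estimated by
  phase correlation with sub-pixel refinement and applied by bilinear
  resampling; border pixels that entered from outside become NaN.
  Sub-pixel interpolation order is bilinear by design — at counting
  noise levels higher-order interpolation buys nothing.
* Invalid pixels (non-positive counts, wrapped borders) carry NaN and
  are excluded from every statistic and classification.

## Hole detection

Holey films are periodic, so detection is posed as lattice estimation
plus template matching rather than free blob search:

1. basis vectors from the two shortest non-collinear peaks of the
   image autocorrelation (sub-pixel parabolic refinement; peaks must
   reach 10% of the central value — genuine lattices reach ~70%,
   structureless images stay below ~5%);
2. hole radius and an initial origin from Otsu-thresholded connected
   components (median equivalent radius of interior blobs);
3. origin and basis jointly refined by least squares against the blob
   centroids;
4. candidate centers from normalized cross-correlation with a disk
   template, snapped to the nearest lattice node (residual < 0.35 of
   the spacing), best score per node;
5. final centers are the refined lattice nodes, which is what makes
   them sub-pixel accurate under counting noise.

Holes within an edge margin (hole radius + 2 px by default) of the
border, or whose surround is far darker than support film (grid bar),
are flagged `edge` and excluded from targeting by default.

## Selection, grouping, export

Selection clamps negative readings to zero and applies the window
inclusively ("20–40 nm" is read as a closed interval); `invalid` and
`edge` flags always block selection and are reported separately in the
summary. Re-selection re-applies the same rule to stored values
without re-measurement and is idempotent.

Grouping tiles the lattice-index plane greedily into pattern-sized
blocks anchored at the minimal selected index; a group holds only
selected holes (skipped positions leave the group partial), every
selected hole lands in exactly one group, and the anchor is the member
nearest the group centroid. Navigator export writes one autodoc item
per hole ordered by id — stage coordinates through an affine
pixel→µm transform (default: pixel-size scaling), thickness rounded
to 0.1 nm in the Note, Acquire = 1 for selected holes, and a color
index (0 within, 1 below, 2 above, 3 flagged). The parser accepts
CRLF; round trips are lossless at the 0.1 nm Note precision, which
also means a hole lying within 0.05 nm of a window bound can change
class after a store/re-select cycle.

## What the simulator does and does not emulate

Emulated: the periodic hole lattice (with rotation and border
clipping), a spatially varying thickness field, the exponential
zero-loss attenuation including the empty-hole offset C (modelled
phenomenologically as constant extra attenuation in the filtered
channel — no physical claim), a support film darker than the holes
(uniform transmission 0.5), an empty-hole intensity 2% above open
vacuum, the filtered-image shift, and independent per-pixel Poisson
noise seeded from a single scene seed (identical seeds give
bit-identical images).

Not emulated: carbon texture, grid-bar shadowing beyond the film mask,
particles, CTF/defocus effects, beam-induced motion, contamination,
gain/defect artifacts, coincidence-loss nonlinearity. Passing tests
therefore demonstrate correctness of the estimators and the targeting
logic under ideal counting statistics, not robustness to every
real-microscope artifact; in particular the detector's perfect
recall/precision on simulated scenes should be read as a property of
clean periodic films.

Default scene conditions mirror the calibrated 200 kV survey setup:
10.7 counts/px/s incident rate, 1 s exposure, 144.6 Å pixels, λ = 305
nm / C = 4 nm, holes of 0.6 µm radius on a 2.5 µm pitch. Test problem
sizes are 1024² images (~25 holes) for exactness checks, one 4096²
scene (529 holes) for the noisy-accuracy check, and twenty 2048²
scenes for detection quality — large enough for ≥100-hole statistics
while keeping the suite in a few minutes.

## Known limitations

* λ and C stability over time is not modelled; the registry records a
  free-text source per profile and refitting is the supported remedy.
* The magnification-dependent energy-shift values affect acquisition,
  not computation, and are treated as pass-through metadata.
* No contamination or targeting-mismatch detection: a few percent of
  selected holes may still fail in practice for reasons outside the
  thickness model.
* The ALS path shares all downstream machinery but has no dedicated
  forward simulator; its tests are constructed analytically.
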