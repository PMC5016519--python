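# Methods

This note records the statistical models behind `locquant`, the defaults
and the reasoning behind them, the numerical conventions that make results
reproducible to the digit, and the limits of what the synthetic-data tests
demonstrate.

## Data model and units

A localization table is a list of rows (x, y, frame, photons?).
Coordinates are always nanometres internally; densities are per µm².  All
unit conversion happens at the I/O boundary.  Observation windows are
axis-aligned rectangles with half-open membership `[min, max)` on both
axes, so a tiling of windows partitions the plane without double counting.

The rapidSTORM text dialect is parsed from its commented XML-like header
when present (column roles from `identifier`, coordinate units from
`unit`, micrometres converted); without a header, columns are taken
positionally as x, y, frame, intensity and coordinates are **assumed to be
nanometres**.  That assumption is a convention, not something the format
guarantees — exports configured in camera pixels must be converted by the
user (a typical EMCCD pixel is ~130–160 nm, so the error would be obvious
in any density).

Rows with non-finite or non-integral values are skipped with a logged
count rather than aborting: real exports contain fit failures, and a
hard error would make whole acquisitions unusable for one bad row.

## Sliding-window density

A circular window (default diameter 1 µm) moves on a square grid (default
step 100 nm).  Only windows lying entirely inside the analysis region are
evaluated; no partial-window area correction is attempted, which avoids
edge bias at the cost of a (diameter/2)-wide unanalyzed margin.  Counts
use a strict `distance < radius` comparison.  Summaries report median,
mean and quartiles; quantiles use linear interpolation between order
statistics (`numpy.quantile` default), so the toy example {1,2,3,4,5} →
(q25, median, q75) = (2, 3, 4) is exactly reproducible.  The standard
error of the median is a seeded 1000-resample bootstrap — there is no
closed form worth defending for the median of correlated window values,
and the bootstrap makes the definition explicit.

A two-fold overlapping membrane (e.g. a lamellipodium projected into 2D)
doubles the expected count in every window, so the ratio of median window
densities between a double and a single layer is 2; this is both a test
and the practical diagnostic for choosing single-membrane regions.

## Blink calibration

**Grouping.**  Localizations are grouped into per-fluorophore tracks by a
deterministic greedy frame-ordered centroid linkage: processing rows in
frame order (stable within a frame), each localization joins the nearest
open track whose running centroid lies within the tracking radius
(distance ≤ r; ties to the lowest track index) and whose last member is
within the temporal gap allowance (default: the whole stack), otherwise it
opens a new track.  A Kalman-filter tracker could be substituted, but the
calibration statistic — the mean track length at the plateau radius —
depends on the radius and the gap allowance, not on a motion model
(the emitters are immobile); the linkage is validated against ground truth
on synthetic scenes, where it recovers the true partition exactly for
well-separated fluorophores.  The linkage is O(n · tracks); fine for
reference samples (hundreds of localizations per region), not intended
for dense fields, which are not meaningful calibration inputs anyway.

**Conversion factor.**  The mean track length versus radius (swept
1–160 nm in 1 nm steps) rises to a plateau once the radius covers the
localization scatter; the saturation level is read at the fixed radius
50 nm and its SE is the standard error of the track lengths there.  An
alternative `window_mean` read-out (mean over 40–80 nm) is available; the
fixed read-out is the default because it has no extra free parameter.
With per-fluorophore blink counts Poisson(µ) conditioned on ≥ 1 (an
undetected fluorophore contributes nothing), the expected factor is
µ/(1−e^−µ): 5.034 at µ = 5, a +0.7 % shift from the unconditional mean.
Two small biases are documented and accepted rather than corrected:
nearby fluorophores occasionally merge into one track (≈ +1 % at
2 fluorophores/µm² and r = 50 nm), and a fluorophore whose scatter is
split never occurs in practice at σ = 8 nm and r = 50 nm
(P(|offset| > 50 nm) < 10⁻⁸).

**Precision.**  Tracks of length ≥ 3 ("length > 2") are aligned to their
centers of mass and the offsets pooled.  Because each track's own centroid
is subtracted, offsets have variance σ²(L−1)/L; the default estimator is
the exactly shrinkage-corrected pooled standard deviation
σ̂² = Σ d² / Σ_t (L_t − 1), which involves no binning.  A least-squares
Gauss fit to the marginal histograms (bin width 2 nm) is retained as an
option for parity with how such distributions are displayed; it carries
no shrinkage correction and sits a few percent low.

**Molecular density** is the quotient localization density / conversion
factor, reported at full precision and rounded to integer for table
display, with optional first-order propagation of the two independent
SEs.  Reference check: 350/6.7 → 52, 625/5.0 → 125, 1520/4.4 → 345,
1536/5.5 → 279 fluorophores/µm².

## Ripley's h

The estimator is the bare windowed subset form

    K̂(d) = A · Σᵢ Σⱼ k(i, j) / (m (n − 1)),
    h(d) = √(K̂(d)/π) − d,

with i over a uniform random subset of m test localizations (default
min(500, n), drawn without replacement, seeded), j over all n, and
k(i,j) = 1 iff the pair distance is strictly positive and strictly less
than d.  The strict-zero rule means identical coordinates (ground-truth
duplicates, or a table accidentally concatenated with itself) contribute
nothing and cannot blow up the statistic.  The square-root transform is
what makes h ≡ 0 in expectation under CSR and puts h in nm; a form
without the radical is dimensionally inconsistent (area × count /
length²·count − length) and cannot be zero under CSR, so the radical is
treated as part of the definition.  The normalization m(n−1) implies the
double sum counts ordered (test, any-other) pairs, which is what is
implemented.

**Edge effects.**  No edge correction (Ripley weights, toroidal wrap) is
applied to the sum itself.  Test points near the boundary see truncated
discs, which biases h downward at large d by ≈ d(√γ̄(d) − 1), where γ̄ is
the mean in-window disc fraction — about −21 nm at d = 500 nm in a
5 × 5 µm² window, far beyond any Monte-Carlo error.  The optional *guard
buffer* restricts test points (not the counted neighbors) to the interior
at least d_max from the boundary, which makes E[K̂] = πd² exact for every
grid distance; the CSR-zero validation therefore runs with the guard on.
The guard is off by default so that the default output is the bare
estimator; for 5 × 5 µm² regions and d up to 800 nm the guard discards
the outer ~50 % of candidate test points, which is affordable at m = 500.

**Envelopes and comparison.**  Replicate curves (the protocol uses five
regions from independent cells) are aggregated pointwise; the 95 %
interval is mean ± t₀.₉₇₅,ᵣ₋₁ · SE (Student-t, since r is ~5).  Peak
extraction takes the grid argmax of the mean within a search range, ties
toward smaller d, with a flag when the maximum sits on the range boundary
(a monotone curve has no interior peak).  Null comparison flags grid
points where an observed mean leaves a null envelope's band and reports
contiguous excursion intervals.  Distance grid default: 10–800 nm in
10 nm steps, covering the blink-peak scale (20–30 nm) and the
membrane-deformation range (30–800 nm).

## Synthetic generators

All generators take an integer seed (or a shared `numpy` generator) and
are bit-reproducible.  What they emulate, and what they deliberately do
not:

* **CSR** — homogeneous Poisson at a given intensity; frames i.i.d.
  uniform over the stack (default 20,000 frames).
* **Neyman–Scott** — Poisson parents in the window buffered by 5σ,
  Poisson(µ) offspring per parent (conditioned ≥ 1 by default), isotropic
  Gaussian scatter σ, offspring clipped to the window.  The buffering +
  clipping keeps the process stationary inside the window instead of
  depleting clusters at the edge.  Defaults µ = 5, σ = 8 nm — the
  experimentally calibrated blink statistics.  Parent intensity can be
  set directly or matched so the *localization* density equals a target
  (the default matching mode, since experiments report localization
  densities).  Purely spatial: frames are 0.
* **Blinking scene** — the diluted reference regime: fluorophores uniform
  at a given density (default 2/µm², i.e. ~10 loc/µm², safely below the
  20 loc/µm² isolation threshold), truncated-Poisson blink counts,
  Gaussian scatter, frames drawn uniformly *without replacement* per
  fluorophore.  Blinking is temporally uniform, not bursty: real
  fluorophores emit in bursts with characteristic off times, but the
  calibration stage groups across the whole stack, so burst structure is
  irrelevant to everything tested here.  Off-time-based corrections would
  need a kinetic model and are out of scope.
* **Double membrane** — two independent CSR layers superposed.
* **Vesicle field** — CSR background plus discs of fixed radius, each
  with an exact number of uniform localizations; disc centers are kept
  one radius inside the window so the deterministic count is exact.

No camera noise, PSF shape, drift, or detection inhomogeneity is
simulated.  Consequently, passing parameter-recovery tests shows the
*analysis* is correct and unbiased under the stated point-process
assumptions; it does not certify behavior under drift, bursty kinetics,
or spatially varying detection efficiency in real data.

**Ground truth.**  Cluster-type generators return the fluorophore
positions and the row indices belonging to each fluorophore.  Fluorophores
whose localizations were all clipped at the window edge are dropped from
the truth (with a count), so every retained fluorophore has ≥ 1 row.

## Problem sizes and seeds

The validation suite runs at the protocol's own scales: 5 × 5 µm²
regions; CSR at 1000 loc/µm² (n ≈ 25,000) with m = 500 and 20 replicates
for the CSR-zero check; Neyman–Scott matched to 625 loc/µm² with 5
replicates for the peak check; 16 reference scenes at 2 fluorophores/µm²
(~800 tracks, ~3,500–4,000 aligned offsets) for the calibration
recovery, which puts the conversion-factor SE near 0.08 and the σ SE
near 0.1 nm.  Every stochastic step is seeded; the full suite and the
acceptance script each complete in well under a minute of compute per
heavy test on a single CPU.

## Known limitations

* The greedy linkage is order-dependent by construction (deterministic,
  but not permutation-invariant within a frame); at reference-sample
  densities this is immaterial.
* The mean-track-length curve is non-decreasing in radius for nested
  greedy grouping on fixed data; this is verified empirically per seed
  rather than proven, since pathological configurations could in
  principle re-partition non-monotonically.
* Printed ± values on molecular densities in published tables mix
  propagation and cell-to-cell spread in ways that are generally not
  reconstructible; `locquant` reports first-order propagation of the two
  SEs it actually has and makes no claim beyond that.
* Ripley analysis assumes stationarity inside each region; regions should
  be chosen visually homogeneous (and under the nucleus, to avoid double
  membranes) before the statistic is informative.
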