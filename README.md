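# locquant

Quantitative analysis of single-molecule localization microscopy (SMLM /
*d*STORM) coordinate data: localization-density mapping, fluorophore-blink
calibration, molecular-density estimation, and spatial statistics with
Ripley's h function benchmarked against simulated null models.

## The problem

A *d*STORM measurement of a labeled plasma membrane yields a list of
localizations — fitted (x, y) positions of single emitting fluorophores, one
per camera frame.  Two properties of the photophysics complicate any
quantitative reading of that list:

1. **Over-counting.**  Each fluorophore blinks several times during the
   acquisition, so one molecule produces several localizations.  The
   localization density (loc/µm²) therefore overestimates the molecular
   density.
2. **Self-clustering.**  The repeated localizations of one fluorophore
   scatter around its true position with the localization precision σ
   (~8 nm), so even randomly placed molecules *look* clustered on that
   length scale.

`locquant` implements the standard correction workflow:

* **Density maps** — a sliding circular window (diameter 1 µm, step 100 nm)
  gives local localization densities; the median over a region quantifies
  labeling efficiency, and a 2× median ratio betrays a two-fold overlapping
  membrane projected into 2D.
* **Blink calibration** — on a diluted reference sample
  (< 20 loc/µm², isolated fluorophores), localizations are grouped into
  per-fluorophore tracks across the whole stack.  The mean track length
  versus tracking radius (swept 1–160 nm) saturates; the plateau (read at
  50 nm) is the **conversion factor** — localizations per fluorophore.
  Aligning tracks of length ≥ 3 to their centers of mass and fitting the
  pooled offsets estimates the experimental precision σx, σy.
* **Molecular density** — localization density ÷ conversion factor, with
  first-order error propagation.
* **Ripley's h** — with K̂(d) = A·ΣᵢΣⱼ k(i,j) / (m(n−1)), where i runs over a
  random subset of m ≈ 500 test localizations, j over all n, and
  k(i,j) = 1 iff 0 < dist(i,j) < d,

      h(d) = √(K̂(d)/π) − d

  is zero in expectation under complete spatial randomness (CSR).  Observed
  curves are compared with envelopes from matched **Poisson** (CSR) and
  **Neyman–Scott** simulations; the latter models blinking (Poisson parents,
  on average ~5 Gaussian-scattered offspring at σ = 8 nm), so an h peak at
  d ≈ 20–30 nm that the Neyman–Scott null reproduces is blinking, not
  biology.
* **Synthetic scenes** — seeded generators for CSR fields, Neyman–Scott
  clusters, frame-resolved blinking fluorophores, double membranes, and
  vesicle-like disc artifacts, with ground truth for parameter-recovery
  tests.

## Worked example

```python
import numpy as np
import locquant as lq

region = lq.Region.square(5000.0)          # 5 x 5 um^2 window
rng = np.random.default_rng(0)

# 16 diluted reference scenes: 2 fluorophores/um^2, ~5 blinks each, sigma = 8 nm
scenes = [lq.simulate_blinking_scene(2.0, 5.0, 8.0, 20_000, region, rng)[0]
          for _ in range(16)]
calib = lq.BlinkCalibrationModel(scenes).fit()
print(calib.summary())
```

```
Blink calibration
=============================================
scenes pooled:            16
localizations:            4106
tracks at plateau radius: 806  (r = 50 nm)
---------------------------------------------
conversion factor:    5.09 ± 0.08  loc/fluorophore
sigma_x:              8.07  nm
sigma_y:              8.41  nm
aligned offsets:    3955  (from 718 tracks, length >= 3)
=============================================
```

The fitted conversion factor recovers the generating blink statistics
(Poisson mean 5 conditioned on detection ⇒ 5.034 expected) and the σ
estimates recover the simulated 8 nm precision.  Converting a measured
localization density of 350 ± 30 loc/µm²:

```python
print(calib.molecular_density(350.0, density_se=30.0))
# 69 ± 6 fluorophores/µm² (68.70)
```

Ripley analysis of blinking-cluster fields matched to 625 loc/µm²:

```python
params = lq.NeymanScottParams.from_localization_density(625.0)
tables = [lq.simulate_neyman_scott(params, region, rng)[0] for _ in range(5)]
ripley = lq.RipleyModel(tables, region).fit(seed=rng)
print(ripley.summary())
```

```
Ripley h analysis
=============================================
replicate regions:  5
localizations:      [15414, 15317, 15651, 15559, 15799]
test subset m:      [500, 500, 500, 500, 500]
distance grid:      10..800 nm
peak of mean h:     29.69 nm at d = 20 nm
=============================================
```

The mean h peaks at d ≈ 20 nm — the localization-precision scale — which is
exactly the blinking artifact the Neyman–Scott null is designed to flag.

## Command line

The same stages are exposed as a CLI:

```bash
locquant simulate --kind blinking --seed 1 --out ref.csv
locquant calibrate ref.csv --out-curve sweep.csv
locquant density data.csv --region 0,5000,0,5000
locquant mdensity --density 350 --factor 6.7       # -> 52 fluorophores/µm²
locquant ripley r1.csv r2.csv r3.csv --m 500
locquant nulls --density 625 --seed 2
locquant run config.yaml                            # full pipeline + manifest
```

`locquant run` consumes a YAML config (all parameters default to the
standard protocol values), writes per-stage CSV/JSON artifacts and a
manifest with seeds, versions, and the config hash.

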