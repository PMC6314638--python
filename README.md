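# chromemo

Analysis pipeline for continuous-report chromatic memory experiments on a
circular hue locus.  Starting from trial-by-trial (target angle, response
angle) records, the pipeline produces:

- per-(player, target) circular summaries with a k-SD outlier filter and
  per-cell gaussianity checks (`chromemo.circstats`);
- trigonometric-series fits of the mean-error profile Δ(t) and the variance
  profile σ²(t) by weighted least squares (equivalent to Gaussian maximum
  likelihood), with chi-square p-value model-order selection and exact
  coefficient covariances (`chromemo.errormodel`);
- attractor and repulsor colors — zeros of Δ(t) crossed with negative /
  positive slope — screened for significance against the coefficient
  covariance ellipsoid, plus cohort-level location-uniformity KS tests
  (`chromemo.attractors`);
- the Fisher-information profile J(t) of the Gaussian response model, Fisher
  distances, prominent extrema, term-decomposition ratios, and the
  mnemonically uniform rescaling s(t) under which J is constant
  (`chromemo.fisher`).

Two support modules make the whole pipeline runnable without human data:

- `chromemo.simulate` — synthetic players with unbiased, categorical or
  mixed response strategies, configurable bias/variance profiles, and a
  null-cohort generator for false-positive calibration;
- `chromemo.locus` — a physically defined stimulus locus: quadratic screen
  calibration from primary spectra (synthetic primaries included),
  iso-intensity maximally saturated closed curve with equal spectral-energy
  steps, CIE xy reporting.

## CLI

The `chromemo` entry point exposes the stages as subcommands:

```sh
# simulate a cohort, write responses.csv
chromemo simulate --strategy mixed --players 11 --seed 1 --out responses.csv

# per-player fits, attractor screen, Fisher profile, uniform scale
chromemo fit responses.csv --player p00
chromemo attractors responses.csv --player p00 --samples 10000 --seed 0
chromemo fisher responses.csv --player p00 --export profile.csv
chromemo scale responses.csv --player p00 --out scale.csv

# full report bundle (summaries, fits, attractors, profiles, run log)
chromemo report --responses responses.csv --seed 1 --out bundle/

# physical color locus from synthetic (or measured) primary spectra
chromemo locus --colors 743 --out locus.csv
```

Response tables are CSV (canonical) or XLSX (read-only) with columns
identifying player, target (angle or index) and response (angle or bar
position); headers are auto-detected.  All angles are radians in (−π, π].

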