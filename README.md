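# ddcqa — difference-detail-curve image quality assessment for CT

`ddcqa` is a library and command-line tool for assessing **low-contrast
detectability** in abdominal CT using **difference-detail curves (DDCs)**.
It targets medical physicists doing phantom-based quality assurance and
dose/image-quality protocol optimisation, where MTF-style metrics break
down for iterative reconstruction and the clinically relevant question is:
*what is the lowest contrast an observer still sees, as a function of object
size?*

The package covers the whole measurement chain:

* a geometric/material model of a modular body phantom whose 80 mm epoxy
  **DDC modules** hold 30 randomly placed contrast rods — every combination
  of six diameters (3, 4, 5, 6, 8, 9 mm) and five nominal contrasts
  (16, 32, 48, 64, 80 HU above the ~60 HU epoxy base), in an iodine
  (contrast-agent) or sucrose (native) variant;
* a synthetic CT simulator (partial-volume rasterisation, Gaussian PSF,
  dose-scaled white noise, kV-dependent iodine response) with full ground
  truth, plus a psychometric simulated observer, so the pipeline is testable
  without a scanner or human readers;
* automated contrast verification: template registration, the 5 px disc ROI
  erosion, rod/background statistics, linearity, energy-response and drift
  analytics;
* click-session evaluation producing DDC curves and the log-linear model fit;
* bootstrap standard errors of the fit parameters versus observer-panel size.

## The model

For object diameter *s* the minimal detected contrast is modelled as

    E[Δ_min HU(s)] = α + β ln s

— the logarithmic form expected from Weber/Fechner-type psychophysical laws.
With several observers *i*, observer bias is modelled as

    E[Δ_min HU(s)] = (α + αᵢ′) + (β + βᵢ′) ln s,   Σᵢ αᵢ′ = Σᵢ βᵢ′ = 0,

fitted by least squares under the sum-to-zero constraints. Robustness to
panel size is quantified by a bootstrap: *m* resamples of *k* ≤ *n* curves
are drawn with replacement, each refitted with the pooled model, and the
standard deviation of the *m* estimates (1/(m−1) divisor) is the standard
error of α and β at panel size *k*.

## Worked example

```python
from ddcqa import (generate_layout, simulate_volume, AcquisitionSettings,
                   register_template, load_reference_curves,
                   fit_observer_bias, bootstrap_se)
from ddcqa.roi import rod_statistics, measure_contrasts

# simulate a 120 kV / 9 mGy scan of a randomised module, rotated by 5 deg
layout = generate_layout(seed=1)
settings = AcquisitionSettings(kv=120, ctdi_vol_mgy=9.0, n_slices=3)
volume, truth = simulate_volume(layout, settings, seed=1, rotation_deg=5.0)

transform = register_template(volume, layout)      # recovers the pose
rod_stats, bg_stats = rod_statistics(volume, layout, transform)
meas = measure_contrasts(layout, rod_stats, bg_stats, settings)

# fit the observer-bias model to the bundled five-observer reference curves
fit = fit_observer_bias(load_reference_curves())
boot = bootstrap_se(load_reference_curves(), k=5, m=100_000, seed=1)
```

prints (via the obvious `print` statements):

```
recovered rotation: 4.99 deg
rod 9 mm / 16 HU -> measured 15.2 HU
background: 60.1 +/- 10.6 HU
alpha = 118.70 HU, beta = -33.75 HU per ln(mm)
observer offsets alpha_i': -45.0, +33.8, +17.3, -14.3, +8.1
bootstrap SE (k=5): se(alpha) = 14.55, se(beta) = 5.84
```

Reading this: the registered, eroded ROI measurement recovers the 16 HU rod
to within the noise (15.2 HU at ~10.6 HU pixel noise); the five-observer
reference fit says a 9 mm object needs about `118.7 − 33.75·ln 9 ≈ 44 HU`
to be seen, and a full five-observer panel pins α to about ±15 HU. The
negative offset −45.0 belongs to the best observer, who sees lower contrasts
than the panel average.

The same pipeline is available from the shell:

```sh
ddc simulate --seed 9 --out scan/
ddc analyze  --volume scan/ --layout scan/layout.json --out meas.csv
ddc verify   --measurements meas.csv --out verify.json
ddc observe  --truth scan/truth --noise-sigma 8 --observers 5 --seed 2 --out curves.csv
ddc fit      --curves curves.csv --out fit.json
ddc bootstrap --curves curves.csv -k 3 -m 100000 --seed 1 --out boot.json
ddc report   --curves curves.csv --fit fit.json --out ddc.png
```

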