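# beamtune

A commissioning toolkit for the four MLC/source parameters of a TPS
photon-beam model, written for medical physicists who tune VMAT beam models
and for anyone who wants the tuning arithmetic to be testable offline.

Modern TPS beam models for MLC-equipped linacs expose four knobs:

* **σX, σY** — effective target spot sizes (mm), the widths of the Gaussian
  smoothing applied to the primary-photon fluence at the isocenter plane.
  They broaden the calculated penumbra in the crossline (leaf-travel) and
  inline directions.
* **DLG** — dosimetric leaf gap (mm), an effective widening of every
  MLC-defined gap that accounts for transmission through rounded leaf ends.
* **T** — MLC transmission, the closed-leaves / open-field dose ratio.

`beamtune` implements one complete tuning methodology:

1. **Spot size from penumbras.** 20–80% penumbras (100% at the central
   axis) are extracted from profile scans of five MLC-defined square fields
   (0.5–4 cm). σ is scanned from 0 to 2 mm in 0.2 mm steps and the optimum
   is the zero crossing of the mean signed calculated-minus-measured
   penumbra deviation.
2. **Transmission** as the measured closed/open ratio.
3. **DLG from asynchronous oscillating sweeping-gap (aOSG) tests.** A
   battery of 15 plans (gaps 10/20/30 mm × tongue-and-groove fractions
   0/0.25/0.5/0.75/1) is delivered; the model DLG is scanned from 0 to
   3.4 mm and the optimum minimizes the mean absolute relative dose
   difference. The classic synchronous sweeping-gap extrapolation
   (DLG = −x-intercept of the transmission-corrected reading vs gap line)
   is computed for comparison: because synchronous sweeps are blind to
   tongue-and-groove losses, the aOSG optimum exceeds it whenever the TPS
   mismodels the TG effect.
4. **Taguchi L27 sensitivity analysis** of small-field output factors: the
   four parameters at three levels each on the standard L27(3¹³) orthogonal
   array, with the DLG×σX and DLG×σY interactions estimable, per-field-size
   ANOVA at α = 1%, effect amplitudes, and 3×3 interaction surfaces.
5. **Gamma-index plan QA**: global 3%/2 mm gamma with a 10% low-dose
   threshold, verdicts at the universal 95% tolerance and 90% action limits.

A closed-form synthetic dose engine (erf-edged profiles and apertures, an
affine sweeping-gap dose law with a tongue-and-groove loss term, a
product-of-edges output-factor model) stands in for both the linac and the
TPS, so the whole pipeline runs offline against a known ground truth. The
engine is declared synthetic throughout: it reproduces the qualitative
behaviour of a rounded-leaf MLC beam model, not any commercial algorithm.

## Worked example

Generate a noise-free synthetic input set with ground truth
σX = 0.7 mm, σY = 0.35 mm, DLG = 0.55 mm, T = 1.26%, then commission:

```bash
$ beamtune simulate --out demo --noise-cv 0 --detector-sigma 0 --seed 7
wrote fixture set; config: demo/config.yaml

$ beamtune commission demo/config.yaml
tuned parameters:
  sigma_x_mm: 0.6999
  sigma_y_mm: 0.3477
  dlg_aosg_mm: 0.5
  dlg_sweeping_mm: 0.55
  transmission: 0.0126
gamma [synthetic-plan]: 100.0% -> pass
```

The spot sizes come back within interpolation error of the truth, the
sweeping-gap DLG is exact (the engine's dose law is exactly affine), the
aOSG DLG lands on the nearest 0.1 mm grid point, and the transmission ratio
is exact. With `--tg-loss-calculated` larger than `--tg-loss-measured` the
aOSG DLG rises above the sweeping-gap value — the signature of a TPS that
overestimates tongue-and-groove losses. `--out report.json` writes the full
machine-readable report, including the deviation and cost curves for every
grid evaluation.

The same stages are available individually (`tune-spot`, `tune-dlg`,
`sweeping-dlg`, `transmission`, `doe`, `gamma`), and as library functions
(`beamtune.tune_spot_size`, `beamtune.tune_dlg`, `beamtune.gamma_map`, …).

## Layout

```
src/beamtune/
  params.py     parameter containers and validity ranges
  engine.py     synthetic closed-form dose engine (linac + TPS stand-in)
  profiles.py   penumbra extraction, spot-size tuning
  dlg.py        aOSG battery, DLG tuning, sweeping-gap + transmission estimators
  doe.py        Taguchi L27, responses, effects, ANOVA, interaction surfaces
  gamma.py      global 2D gamma index and QA verdicts
  io.py         CSV / text-grid / DICOM RT Dose readers and writers, config
  pipeline.py   end-to-end commission driver and fixture generation
  cli.py        the `beamtune` command
docs/methods.md   model equations, defaults, numerical choices, limitations
```
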