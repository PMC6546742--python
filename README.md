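# photokin

Kinetic analysis of time-resolved spectroscopy for molecular photoswitches:

- **kinetics** — closed-form first-order branching photokinetics convolved
  with a Gaussian instrument response (exponential ⊗ Gaussian via the
  scaled complementary error function), with a numeric ODE fallback for
  near-degenerate rates, and a builder for the excited-state cascade
  S2 → S1 → {hot Z, E}.
- **targetfit** — global/target analysis of ΔA(time, wavelength) matrices:
  SVD rank estimation, variable-projection fitting of lifetimes / time zero /
  IRF width / branch fractions with species-associated difference spectra
  (SADS) eliminated analytically each iteration, plus decay-associated
  spectra (DAS) fits and a kinetic branching-yield estimate.
- **anisotropy** — pump–probe anisotropy r = (I∥ − I⊥)/(I∥ + 2I⊥) and
  isotropic signal (I∥ + 2I⊥)/3 from polarized pairs, with a
  rise-times-decay model fit.
- **relaxation** — single-exponential half-life fits, Eyring regression of
  ln(k/T) on 1/T with ΔH‡/ΔS‡ covariance, ΔG‡(T) with error propagation,
  Eyring rate ↔ Gibbs-energy conversion, photo-acceleration ratios and
  photostationary-state fractions.
- **spectra** — absorption peak detection with parabolic refinement,
  Z/E band-separation (Δλmax) analysis, Beer–Lambert utilities.
- **synthkit** — seeded, deterministic generators for every input the
  pipeline consumes (TA matrices, polarized pairs, decay traces, rate
  series, spectra, NMR integral series), with ground truth embedded in
  metadata for recovery tests.
- **dataio / cli** — wide-CSV TA format, two-column trace/spectrum/rate
  CSVs with explicit units and `#`-comment metadata, plus a `photokin`
  command-line interface.

## CLI

```sh
photokin simulate   --config sim.yaml --seed 7 --out run/   # synthetic TA matrix
photokin fit-target run/ta.csv --config fit.yaml --out fit/  # target analysis
photokin fit-das    run/ta.csv --n-components 3 --out das/   # DAS fit
photokin anisotropy par.csv perp.csv --out aniso/            # r(t) + fit
photokin halflife   trace.csv --out hl/                      # exponential decay
photokin eyring     rates.csv --temperature 298 --out eyr/   # ΔH‡, ΔS‡, ΔG‡
photokin pss        --integral-z 35 --integral-e 65 --out p/ # PSS fraction
photokin bandsep    --z-max 429 --e-max 515 --e-max 552 --out bs/
```

Every run writes its outputs plus `provenance.json` (config echo, seed,
package version) and a `run.log` into the output directory. Config files
are YAML; see `tests/test_cli.py` for complete examples of the simulate
and fit-target configuration blocks.

## File formats

- TA matrix: wide CSV, header `time_<unit>,<nm>,<nm>,...`, one row per
  delay; `#polarization:` and `#truth:`/`#key:` comment lines carry
  metadata. Units: fs, ps, ns, us, ms, s, min.
- Decay trace: `time_<unit>,signal`. Spectrum: `wavelength_nm,absorbance`.
  Rate series: `T_K,k_per_s[,k_se[,condition]]`.
- All numerics with 9 significant digits, UTF-8, LF; decimal points only.
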