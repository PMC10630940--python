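# amorphotrack

Analysis toolkit for the physical stability and release behaviour of
amorphous drugs, in bulk and confined in mesoporous matrices (silica,
alumina). It covers the full measurement-analysis chain used in broadband
dielectric spectroscopy (BDS), nonisothermal differential scanning
calorimetry (DSC) and dissolution testing:

- **Dielectric spectra** — data model and CSV I/O for complex permittivity
  series; parallel-capacitor composition/deconvolution of drug-filled porous
  membranes; loss-peak normalization for master curves.
- **Relaxation fitting** — Havriliak–Negami (HN) superpositions with a
  dc-conductivity term; closed-form loss-peak times; the one-sided Fourier
  transform of the KWW (stretched-exponential) function evaluated by
  oscillatory quadrature with tail acceleration; coupling-model test for a
  Johari–Goldstein assignment of secondary relaxations.
- **Relaxation maps** — tau(T) assembly, VFT and Arrhenius fits, the glass
  transition at tau_alpha = 100 s, and detection of the confinement-induced
  crossover (VFT above, quasi-isochoric Arrhenius branch below a kink).
- **Thermal analysis** — DSC thermogram I/O, extraction of glass-transition
  steps (midpoint convention), crystallization/melting peaks (maximum
  convention), double-event reports across heating rates, and Kissinger
  activation-energy regression.
- **Dissolution** — release-model fitting (first-order, logarithmic,
  rise-and-decay, constant) with AICc selection and classification into
  prolonged release / spring-and-crash / flat; profile metrics and ranking.
- **Synthetic data** — generators for every input above with planted ground
  truth (bulk and confined scenario presets, core/interfacial dynamics, MWS
  polarization, Kissinger-consistent exotherms, Gibbs–Thomson melting
  depression), so each analysis stage is validated by parameter recovery.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (parameter-recovery
tolerances, oracle equivalences, false-positive rates, determinism); the
other files are per-module unit and property tests.

## Command line

```bash
# generate synthetic measurements for a preset scenario
amorphotrack simulate --preset bulk_apz --kind dsc --rate 10 --out dsc.csv

# analysis stages
amorphotrack deconvolve --input total.csv --matrix-eps 3.8 --fill 0.27 --out api.csv
amorphotrack fit-hn --input api.csv --processes 1 --conductivity --window 1e-1:1e6 --out fits.json
amorphotrack fit-vft --fits fits.json
amorphotrack detect-crossover --fits fits.json
amorphotrack dsc-events --input dsc.csv
amorphotrack kissinger --points points.csv
amorphotrack dissolution --input profile.csv

# full chain: generate -> deconvolve -> fit -> map -> Tg/crossover -> KWW/CM
#             -> DSC events -> Kissinger -> dissolution class -> report
amorphotrack run-scenario --scenario native_sio2 --seed 1 --outdir out/
```

Scenario presets: `bulk_apz`, `native_sio2`, `silanized_sio2`, `aao`.
`run-scenario` writes a JSON report, a markdown summary and the resolved
YAML config; reports are byte-identical for a fixed config and seed.

## File formats

- `bds-v1`: CSV `temp_K,freq_hz,eps_real,eps_imag` (or `time_h` leading
  column for isothermal series).
- `dsc-v1`: `# rate_K_min:` / `# exo_up:` metadata lines, then
  `temp_K,heat_flow`.
- `diss-v1`: CSV `time_min,conc_mg_ml`.

Complex permittivity follows eps\* = eps' − i·eps''; a lossy matrix constant
is therefore passed with a negative imaginary part (e.g. `3.8-0.05j`).
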