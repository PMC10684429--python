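# goodph

Non-invasive pH determination from Raman spectra of MOPS-buffered aqueous
systems. The buffer itself is the pH indicator: the protonated (MOPSH) and
deprotonated (MOPS⁻) species have distinct Raman bands in the 2700–3100 cm⁻¹
window, so a hard-model fit of a mixture spectrum yields their weight ratio,
a single ratiometric calibration factor maps it to a concentration ratio,
and the pH follows from the temperature-dependent pKa of MOPS:

    pH = pKa(T) + log10(c_MOPS⁻ / c_MOPSH),
    pKa(T) = 814.077/T + 9.865 − 0.9501·ln(T)   (T in kelvin)

Because the readout is a weight *ratio*, global intensity scale (laser
power, focus) and additive linear baselines cancel, and no activity
coefficients are needed inside the working range (~pH 6–8).

## Modules

- `goodph.spectra_io` — Raman spectra as CSV or a JCAMP-DX subset
  (XYPOINTS / XYDATA); canonical increasing-axis representation; cropping.
- `goodph.hard_model` — pseudo-Voigt peaks, pure-component and composite
  mixture models, JSON (de)serialization, and the variable-projection
  mixture fitter (non-negative weights + linear baseline solved linearly,
  free water-peak parameters optimized nonlinearly).
- `goodph.model_building` — direct pseudo-Voigt peak fitting of pure
  spectra, and complemental hard modeling (CHM) to extract a solute model
  from a binary aqueous spectrum given a known water model.
- `goodph.ph_probe` — pKa(T), ratio↔pH algebra, ratiometric calibration
  (origin-constrained least squares for k), prediction, RMSE and
  leave-one-out cross-validation; extended Debye–Hückel diagnostics
  (simulation-only, never used in prediction).
- `goodph.synthetic` — ground-truth simulators: MOPS speciation and
  titration (validated against a full charge-balance bisection oracle),
  NaCl ionic-strength series, Michaelis–Menten acidification kinetics
  (penicillin G hydrolysis), and forward-synthesized noisy spectra from
  deterministic fixture peak tables.
- `goodph.cli` — the `goodph` command.

## CLI

```sh
# synthetic data (deterministic under --seed)
goodph simulate titration --seed 1 --out run1/
goodph simulate salt --seed 1 --initial-ph 7.0 --out salt/
goodph simulate enzyme --seed 1 --out rxn/

# model building
goodph build-model --spectrum pure.csv --n-peaks 3 --name solute --out solute.json
goodph build-model --spectrum binary.csv --water-model water.json --out solute.json

# calibrate / predict / monitor / evaluate
goodph calibrate --spectra run1/ --reference ref.csv --model run1/composite.json \
    --temperature 35C --out calib.json
goodph predict --spectrum s.csv --calib calib.json --temperature 35C
goodph monitor --spectra rxn/ --calib calib.json --temperature 25C --out ph.csv
goodph evaluate --pred ph.csv --ref truth.csv
```

Temperatures are accepted as `35C` or `308.15K`. Exit codes: 0 success,
1 validation/runtime failure, 2 usage error.

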