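# cardiopore

Simulation and analysis of high-density microelectrode-array (HD-MEA)
recordings of spontaneously beating cardiomyocyte cultures, built around
electroporation-mediated intracellular-like access:

- **`synth_cardiomyocyte`** — ground-truth membrane voltage: closed-form
  action-potential (AP) templates (product of two sigmoids with an exact
  90%-repolarization point), spontaneous beat schedules, multiplicative
  drug modulation with per-cell lognormal dispersion.
- **`synth_interface`** — cell–electrode interface: logistic
  electroporation-outcome model driven by delivered charge density, seal
  quality and stimulation-unit loading; exponential pore resealing; linear
  mixing of intracellular (scaled AP) and extracellular (scaled dV/dt)
  components; amplifier offsets, noise, saturation; multichannel
  `Recording` assembly with streaming segments.
- **`recording_io`** — HDF5/NPZ recording containers, CSV feature tables,
  run manifests with stable config hashes.
- **`waveform_pipeline`** — beat detection (robust MAD threshold), offset
  correction, snippet classification (intracellular-like iff peak
  amplitude > 500 µV **and** width > 25 ms, strict), selection and
  averaging of three consecutive beats taken ≥ 9 s after poration end (or
  after offset-drift stabilization), amplitude normalization.
- **`ap_features`** — AP amplitude, APD90, depolarization time (linear
  interpolation at threshold crossings), field-potential amplitude,
  culture synchrony.
- **`study_stats`** — pulse-train arithmetic (2·phase + IPI per biphasic
  cycle), electrode geometry, electroporation yield per repeat, repeat
  summaries, percent changes, a self-contained exact/asymptotic
  Mann–Whitney U test, and drug-response reports against the last
  baseline.
- **`cli_app`** — `cardiopore simulate | analyze | report`.

## CLI

```bash
cardiopore simulate --config cfg.yaml --seed 1 --out runs/sim
cardiopore analyze runs/sim/recording_*.h5 --config cfg.yaml --out runs/ana
cardiopore report runs/ana/features.csv --config cfg.yaml --out runs/rep
```

Configs are YAML with sections `culture`, `array`, `protocol`,
`classifier`, `session`; unknown keys are rejected with a list of the
offending entries. Defaults reproduce the optimized protocol (1 Vpp,
200 µs phase, 1 ms IPI, 25,000 pulses, 200 randomly selected 4 µm
electrodes). Every command writes a run manifest; identical config + seed
give byte-identical CSV outputs.

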