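# glyrfluct

Fluctuation analysis of glycinergic whole-cell currents, with seeded
synthetic-data generators standing in for raw recordings. The package
implements the full quantitative pipeline used to characterize glycinergic
dysfunction in a hyperekplexia model:

- **`glyrfluct.syntrace`** — generators with recorded ground truth:
  ensemble currents from N independent two-state channels (exact-jump
  Gillespie simulation of the ensemble open count, resampled onto the trace
  grid), slowly ramped agonist applications, Poisson trains of
  biexponential miniature-IPSC waveforms in Gaussian noise, Hill
  dose-response tables, and tonic currents abolished by a blocker step.
- **`glyrfluct.minis`** — miniature-IPSC detection with a sliding
  optimally-scaled biexponential template (amplitude threshold in units of
  the robust baseline noise SD), 10–90% rise / 90–10% decay kinetics,
  overlap / slow-rise / rough-decay acceptance filters, and per-recording
  summaries (kinetic means require ≥ 20 accepted events).
- **`glyrfluct.fluctuation`** — stationary noise analysis: windowed
  variance–mean pairs from the DC trace and a band-passed AC copy,
  background subtraction, parabolic fit `σ²(I) = I_u·I − I²/N_c` for the
  unitary current and channel count, the linear low-occupancy fallback
  `I_u = σ²/I`, and the open probability `P_o = I_peak/(I_u·N_c)`.
- **`glyrfluct.spectra`** — one-sided net power spectra (Welch, < 200 Hz)
  and single/double Lorentzian fits; `τ = 1/(2π·f_c)`, with the
  power-weighted `τ_w` for two components and an F-test for model choice.
- **`glyrfluct.pharm`** — peak-current measurement, Hill dose–response
  fits for EC50, and tonic-inhibition quantification (holding-current and
  band-passed variance shift around an annotated blocker application).
- **`glyrfluct.behavior`** — escape-behavior contingency statistics
  (largest-remainder percentages, pairwise per-category 2×2 χ² without
  continuity correction) with the published count table as a packaged
  fixture, plus an in-silico restriction digest (TG^CA) for genotyping.
- **`glyrfluct.cli`** — the `glyrfluct` command-line tool and the
  simulate→detect→noise→spectrum→dose→tonic pipeline with JSON reports.

Traces are uniformly sampled currents in pA (inward negative) and
round-trip through a commented CSV format and an equivalent HDF5 layout.

## CLI

```sh
glyrfluct simulate minis --event-rate 1 --amp-mean 40 --duration 60 --seed 7 --out train.csv
glyrfluct detect train.csv --out events.csv
glyrfluct simulate ensemble --n-channels 100 --unitary-current 2 --k-open 200 \
    --k-close 200 --duration 60 --seed 1 --out ensemble.csv
glyrfluct noise ramp.csv --control 0:5 --out fit.json
glyrfluct spectrum ensemble.csv --drug 20:60 --control 0:20 --out psd.json
glyrfluct dose table.csv --out dose.json
glyrfluct tonic tonic.csv --drug strychnine --out shift.json
glyrfluct behavior counts.csv --out stats.json
glyrfluct digest seq.fasta --site TGCA
glyrfluct run experiment.yaml
glyrfluct compare out/wt/report.json out/mut/report.json --metric ec50_um
```

Every simulator requires an explicit `--seed`; runs are bit-reproducible
and reports log the seed and a configuration hash.

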