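# proteospike

Analysis toolkit for the electrical activity of proteinoid microspheres —
thermal proteins that self-assemble into micrometre-scale spheres and emit
voltage spikes, including distinct responses when alphabet characters are
projected onto the sample as light patterns.

The package turns raw potential (mV) or temperature (°C) time series into
per-character response profiles and the derived characterizations a study of
this substrate needs:

- **Spike analysis** — baseline removal (moving median, linear fit or
  pre-stimulus mean), peak detection by topographic prominence, inter-spike
  periods, and seven-number summaries (quartiles Q1/Q2/Q3, mean, max, min,
  SD) of amplitudes and periods.
- **Character recognition** — the threshold rule ŷᵢ = i iff Aᵢ > A_th and
  Pᵢ > P_th (else *reject*), a 26×26 confusion matrix with a separate reject
  tally, accuracy, per-class precision and recall, and a nearest-profile
  classifier for end-to-end synthetic recognition.
- **Boolean gates** — min-max normalization of the 26 mean amplitudes and
  periods, then AND / OR / NOT / NAND / NOR gates at thresholds (T_A, T_P)
  with strict inequalities.
- **Morphology** — Gaussian-kernel KDE of microsphere diameters,
  f(x) = (1/nw) Σᵢ φ((x − Xᵢ)/w) with Scott's-rule bandwidth w = σ̂·n^(−1/5),
  and box statistics with Tukey fences Q1 − 1.5·IQR / Q3 + 1.5·IQR.
- **Spectral** — zero-phase Butterworth low-/high-pass filtering and
  periodogram power spectra in dB.
- **Synthetic data** — a seeded generator producing spiking recordings whose
  amplitude and inter-spike-interval distributions are log-normal and
  moment-matched to any row of the packaged per-character profile table, so
  every stage is testable without lab recordings.

A reference table of published per-character amplitude and period statistics
(26 characters × 7 summary statistics each) ships with the package.

## Worked example

```python
import proteospike as ps

table = ps.load_profile_table()            # packaged reference profiles

# simulate a letter-D recording and recover its profile
cfg = ps.GeneratorConfig.from_profile(table["D"], duration=10.0,
                                      sampling_interval=5.0, seed=2)
rec, events = ps.simulate_recording(cfg, n_events=60)
est = ps.profile_character(rec, label="D")
print(f"estimated amplitude mean: {est.amplitude.mean:.2f} mV "
      f"(reference {table['D'].amplitude.mean} mV)")
print(f"estimated period mean: {est.period.mean:.0f} s "
      f"(reference {table['D'].period.mean} s)")
print("classified as:", ps.nearest_profile_classify(est, table))

gt = ps.gates_from_profiles(table)         # default thresholds T_A = T_P = 1
print({g: gt.count(g) for g in ("AND", "OR", "NOT", "NAND", "NOR")})
```

prints

```
estimated amplitude mean: 16.95 mV (reference 17.26 mV)
estimated period mean: 11969 s (reference 11755.72 s)
classified as: D
{'AND': 0, 'OR': 0, 'NOT': 26, 'NAND': 26, 'NOR': 26}
```

The estimated moments recover the generator's configured values to within
sampling error (60 events), the nearest-profile classifier identifies the
letter, and the gate evaluation reproduces the reference characterization:
no character exceeds both normalized thresholds (AND = OR = 0) while every
character falls below at least one of them (NOT = NAND = NOR = 26).

The same stages are available from the shell:

```bash
proteospike simulate --letter D --n-events 60 --sampling-interval 5 \
    --seed 7 --out d.csv
proteospike profile --input d.csv --label D --out d_profile.csv
proteospike gates --out gates.csv
proteospike full --seed 1 --amplitude-threshold 10 --period-threshold 8000 \
    --outdir out/
```

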