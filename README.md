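# ecgdesk

Desk-scale analysis of single-lead (Lead-I-equivalent, 125 Hz) ECG
recordings: signal-quality filtering, P/QRS/T delineation with the eight
standard interval/rate measurements, a residual CNN-RNN multilabel
diagnosis network over 20 diagnostic items, a cardiovascular health score
with passive-alert rules, and a seeded synthetic-ECG generator with
analytic ground truth that serves as the test substrate for everything
else.

## Modules

| Module | What it does |
| --- | --- |
| `ecgdesk.signal_quality` | 50-Hz low-pass + 60-Hz notch (high-frequency noise), 0.67-Hz high-pass + moving-average baseline removal, flat-line / lead-off detection, `clean()` chain |
| `ecgdesk.delineation` | Energy-based QRS detection, beat-level P/T delineation, P duration / PR / QRS / QT / QTc / T duration / atrial & ventricular rate, HRV (SDNN, RMSSD, pNN50), average beat, RR scatter |
| `ecgdesk.diagnosis` | 32-layer (8 stages x 4, kernel 16) pre-activation residual 1-D CNN + GRU + sigmoid head, multilabel over 20 items; binary reverse-lead variant; training (Adam, BCE), inference, per-item metric suite. Implemented in NumPy with explicit backprop — no deep-learning framework required |
| `ecgdesk.health` | Built-in risk table (categories + critical values), `score_from_items` (100 minus summed deductions, floored at 0), two passive-alert rules, retrospective report |
| `ecgdesk.synthetic` | Gaussian-bump morphology ECG generator, 9 rhythm classes, HF-noise / baseline-wander artifacts, polarity reversal, labelled datasets with exact fiducial ground truth |
| `ecgdesk.io` / `ecgdesk.pipeline` / `ecgdesk.cli` | WFDB (format-16 subset) + CSV I/O, end-to-end pipeline, CLI |

## CLI

```sh
ecgdesk simulate --out data/ --n 10 --rhythm normal_sinus --seed 1
ecgdesk clean --in data/rec00000.hea --out clean.csv
ecgdesk delineate --in data/rec00000.hea --out waves.json
ecgdesk measure  --in data/rec00000.hea --out measurements.json
ecgdesk hrv --in data/rec00000.hea
ecgdesk train --manifest data/manifest.csv --model-out model --epochs 5
ecgdesk diagnose --in data/rec00000.hea --model model
ecgdesk evaluate --manifest data/manifest.csv --model model
ecgdesk score --items AF,PVC
ecgdesk alerts --scores 95,89,84,84
ecgdesk report --manifest data/manifest.csv
ecgdesk run --in data/rec00000.hea --out result.json
```

Records are WFDB pairs (`.hea`/`.dat`, single signal, format 16) or CSV
with a `time_s,amplitude_mV` header; non-125-Hz input is resampled with a
logged notice. Distinct CLI exit codes map to error classes (see
`ecgdesk/errors.py`).

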