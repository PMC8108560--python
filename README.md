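# sleeptes

Analysis pipeline for studies of slow-oscillation transcranial electrical
stimulation (TES) during sleep: does weak scalp stimulation delivered during
stable N2 sleep increase the duration of deep (N3) sleep and slow-wave
(0.5–1 Hz) EEG power?

Because no raw recordings from such studies are publicly deposited, the
package pairs the analysis pipeline with a synthetic polysomnography (PSG)
generator whose defaults match the study conditions, so every stage of the
pipeline is testable end to end without any download. The per-subject summary
tables of one published study are shipped as CSVs and their printed
statistics are reproduced exactly.

## What is in the box

| Module | Purpose |
| --- | --- |
| `sleeptes.synthetic` | Overnight hypnogram Markov chain, stage-conditioned EEG synthesis, TES artifact injection, configurable N3-enhancement effect |
| `sleeptes.psg_io` | EDF writer/reader, hypnogram and schedule CSVs, bipolar derivations, scalp region map |
| `sleeptes.protocol` | Stable-N2 trigger, 5×300-s stimulation blocks with 60-s rests, pause/resume bookkeeping, epoch exclusion masks, immediate and spectral analysis windows |
| `sleeptes.stager` | Sleep staging: a from-scratch numpy 1-D CNN (five-stage softmax, Adam, best-validation checkpointing) and a calibrated rule-based scorer |
| `sleeptes.metrics` | Whole-night stage minutes, percent of total sleep time, immediate-window stage seconds — all honoring exclusion masks |
| `sleeptes.spectral` | Clean-segment selection, Tukey taper + concatenation, Welch slow-wave band power, per-region and relative (%) power |
| `sleeptes.stats` | Two-condition repeated-measures ANOVA (F = t²), Wilcoxon signed-rank with exact small-sample p, Pearson r, paired contrasts |
| `sleeptes.pipeline` / `sleeptes.cli` | Study orchestration, published-table statistics, tidy CSV outputs, `sleeptes` command-line entry point |

## Worked example

```python
from sleeptes import (HypnogramModel, StageSignalModel, simulate_hypnogram,
                      simulate_recording, preprocess, rule_based_stager,
                      evaluate)

MONTAGE = ("C3", "C4", "M1", "M2", "EOGL", "EOGR", "EMG")

hyp = simulate_hypnogram(HypnogramModel(), n_epochs=240, seed=7)
rec = simulate_recording(hyp, StageSignalModel(), montage=MONTAGE, seed=7)
scored = rule_based_stager(preprocess(rec))
print(evaluate(scored, hyp).kappa)
```

prints `0.994...` — the rule-based scorer recovers the generator's stages
almost perfectly. The `examples/` directory walks each capability:

```text
examples/01_simulate_and_stage.py   # generator -> EDF round-trip -> staging
examples/02_protocol_windows.py     # trigger, pause handling, analysis windows
examples/03_spectral_analysis.py    # regional slow-wave band power, pre vs post
examples/04_paired_statistics.py    # published tables + a synthetic study
```

Running `examples/04_paired_statistics.py` reproduces the published
statistics from the shipped tables:

```text
n3_minutes      F(1,9) =  9.06 (p = 0.015);  T =  5.0 (p = 0.012, greater)
n3_percent      F(1,9) = 10.76 (p = 0.010);  T =  5.0 (p = 0.010, greater)
immediate_n3_s  F(1,8) =  2.01 (p = 0.194);  T =  7.0 (p = 0.070, greater)
immediate_n2_s  F(1,8) =  0.68 (p = 0.435);  T = 11.0 (p = 0.360, two-sided)
```

## Command line

```bash
sleeptes stats                                  # published-table statistics
sleeptes simulate --seed 3 --out data/          # synthetic EDF + CSV file sets
sleeptes stage --edf data/subject01_sham.edf --out scored.csv
sleeptes metrics --hypnogram h.csv --schedule s.csv
sleeptes spectral --edf night.edf --schedule s.csv --out power.csv
sleeptes run-all --out results/                 # full synthetic study
```

`simulate` and `run-all` accept `--config study.yaml`; any `StudyConfig`
field can be set there (see `examples/study_config.yaml`).

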