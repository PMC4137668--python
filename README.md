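# ftcdlat

Functional transcranial Doppler (fTCD) language-laterality analysis:
from two-channel cerebral blood-flow-velocity recordings with trial
markers to a per-subject laterality index (LI), left / bilateral / right
classification, split-half reliability, cohort-level statistics, and a
population mixture model of left-brain bias — plus a synthetic session
generator so the whole pipeline runs on simulated data.

## What it does

- **`ftcdlat.recording`** — `Recording` data model, the plain-text
  `.ftcd.tsv` dialect (header `#fs=<Hz> subject=<id>`, columns
  `time_s left right marker`), and anti-aliased downsampling to the
  25 Hz analysis rate.
- **`ftcdlat.epochs`** — marker-locked epoching of the 30 s trial
  (12 s silent watching / cue / 10 s talking / 8 s rest), dropout &
  spiking screening with single-point repair, per-channel normalization
  to mean 100, heart-cycle integration (per-beat averaging), extreme
  value rejection, and baseline correction — in that fixed order.
- **`ftcdlat.laterality`** — grand-average left−right difference, peak
  search in the 4–14 s post-cue period of interest, per-epoch LIs over a
  2 s window at the peak, SE / 95% CI, CI-based categorization
  (≥ 12 accepted trials required), odd/even split LIs.
- **`ftcdlat.stats`** — Pearson and linear-by-linear (trend) chi-square,
  one/two-sample t, one-way ANOVA, Mann–Whitney, Pearson/Spearman
  correlations, odd/even intraclass correlation (ICC(A,1) with F-based
  CI), Edinburgh handedness quotient, reaching-task LQ, language-status
  classification and the principal-component language composite.
- **`ftcdlat.popmodel`** — mixture of a 90:10 left-biased low-risk
  majority and an unbiased high-risk minority: analytic expectations,
  Monte-Carlo sampling, twin concordance, expected case-control tables
  and trend-test power.
- **`ftcdlat.simulate`** — session generator (pulsatile cardiac
  waveform, task-locked lateralized response calibrated so the noise-free
  pipeline recovers the requested true LI, artifact injection with
  ground-truth logs) and cohort generator with subgroup labels.
- **`ftcdlat.cli`** — `simulate`, `process`, `cohort-stats`, `popmodel`
  subcommands.

## CLI

```sh
# simulate a 24-trial session with a true LI of 3
ftcdlat simulate --seed 1 --true-li 3 --subject kid1 --out data/

# run the analysis pipeline (downsamples to 25 Hz automatically)
ftcdlat process data/kid1.ftcd.tsv --out results/

# cohort statistics from per-subject summaries + outcome labels
ftcdlat cohort-stats --summary results/summary.csv \
    --outcomes outcomes.csv --out results/

# population mixture model expectations and replicate tables
ftcdlat popmodel --p-risk 0.2 --replicates 2000 --seed 1 --out results/
```

Defaults can be overridden with `--config file.toml` using sections
`[epoching]`, `[simulate]`, `[popmodel]`; unknown keys are rejected.
Exit codes: 0 success, 2 configuration error, 3 data error.

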