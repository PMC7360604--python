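# pupilstress

Analysis pipeline for acute-stress effects on cognitive emotion regulation:
pupillometry preprocessing down to per-condition AUCg summaries, salivary
endocrine and affect scoring, and a mixed-design repeated-measures ANOVA
engine — exercised end to end on a synthetic-study generator that emulates
the experimental design, so no raw data download is needed.

## What's inside

| Module | Purpose |
| --- | --- |
| `pupilstress.simulate` | Synthetic 2 (stress/control) × 3 (MALE/FELU/FEOC) studies: 30 Hz binocular pupil traces with arousal + cognitive-effort dilation components, blinks/spikes, 4-timepoint cortisol/alpha-amylase series, DAS affect ratings, per-trial arousal/valence/success ratings |
| `pupilstress.pupil` | Eye averaging → 6 Hz zero-phase FIR smoothing → event-locked segmentation → 1.5–9 mm range filter → dilation-speed MAD outlier filter → blink-gap handling (> 100 ms discards, shorter gaps linearly interpolated) → 300 ms baseline correction → AUCg over 2–5 s → per-condition aggregation |
| `pupilstress.endocrine` | Baseline-to-peak deltas, DAS negative-affect scores, Welch t from summary statistics (mean/SEM/n) |
| `pupilstress.stats` | Split-plot mixed ANOVA (Type III, any number of crossed between factors), Greenhouse–Geisser epsilon, Mauchly's test, Bonferroni post-hocs, Lilliefors/Levene assumption checks, Pearson correlations, difference scores |
| `pupilstress.pipeline` / `pupilstress.cli` | `simulate → preprocess → summarize → test` orchestration with YAML config, CSV tables and a JSON run report |

## CLI

```bash
pupilstress simulate --seed 1 --out data/            # synthetic study tables
pupilstress preprocess --data data/ --out pre/       # QC + AUCg tables
pupilstress summarize --data data/ --out sum/        # delta + group summaries
pupilstress run-all --config run.yaml                # everything + report.json
pupilstress report --run run_out/
```

Example `run.yaml`:

```yaml
outdir: run_out
study:
  n_per_cell: 10
  seed: 42
  artifact_params:
    blink_rate_hz: 0.1
preprocess:
  mad_multiplier: 16
  min_valid: 5
```

## Notes and known caveats

- The published FEOC delta-cortisol and male delta-amylase t statistics do
  not reconcile with the printed group means/SEMs at two-decimal precision
  (the printed values presumably come from unrounded data); they are not
  targeted.
- The dilation-speed filter thresholds at median + k·MAD per trial
  (k ∈ [6, 30], default 16). On a perfectly noiseless trace MAD ≈ 0 and the
  deterministic dilation ramp itself is flagged — keep sample noise on when
  simulating data destined for the preprocessing pipeline.
- `mean_aucg` is a signed trapezoidal integral (mm·s) relative to the
  post-baseline-correction zero line; `ln_aucg` uses ln(x + shift) with a
  shared shift of 1 − min(x) when any value is non-positive.
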