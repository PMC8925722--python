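# pupilrl

Behavioral models, competitive-game environments, and pupillometry
regression analyses for two-choice decision tasks in head-fixed rodents —
with a synthetic-data module so every stage is testable without recordings.

## What's inside

- **`pupilrl.envs`** — the exploitative matching-pennies computer opponent
  (nine conditional left-probability estimates over choice and
  choice-outcome histories, exact binomial tests, counter choice), the
  block-structured two-armed bandit (0.7:0.1 reward probabilities, 10-hit
  arming, 1/11 switch probability), and the trial-timing generator
  (truncated-exponential ITI with penalty draws).
- **`pupilrl.agents`** — five trial-by-trial decision models (win-stay
  lose-switch, Q-learning, forgetting Q-learning, differential Q-learning,
  and the hybrid forgetting-Q + choice-kernel model) with latent-variable
  trajectories (action values, choice kernels, reward prediction error,
  choice-kernel error).
- **`pupilrl.fitting`** — constrained maximum-likelihood fitting with
  multi-start optimization and BIC model comparison. The likelihood uses a
  vectorized forward pass (linear-filter recursions), tested against the
  per-trial reference loop.
- **`pupilrl.behavior_metrics`** — three-choice pattern entropy,
  running-entropy session truncation, reward rate, preference switches,
  psychometric curves.
- **`pupilrl.simulation`** — closed-loop agent-vs-environment simulation
  and reward-rate sweeps over the relative choice-kernel weight.
- **`pupilrl.pupil`** — pupil-trace preprocessing (4-Hz lowpass, 3-scaled-MAD
  outlier masking, 10-min moving-window z-score), trial-aligned
  baseline-subtracted responses in 100-ms bins on [-3, 5] s, three
  regression designs (observable, action-selection, value-updating),
  per-bin OLS with across-session significance-fraction and chi-square
  summaries, RPE-sign split, and two-eye coefficient correlation.
- **`pupilrl.synthetic_data`** — generators for behavioral sessions with
  known parameters and pupil traces with planted regression structure.

## CLI

```bash
pupilrl simulate --env mp --params params.yaml --trials 500 --sessions 20 --seed 1 --out sims/
pupilrl fit --model fq_rpe_ck --sessions 'sims/session_*.csv' --restarts 10 --seed 1 --out fit.yaml
pupilrl compare --sessions 'sims/session_*.csv' --out bic.csv
pupilrl summarize --sessions 'sims/session_*.csv' --out summary.csv
pupilrl sweep --env mp --grid 0:1:11 --reps 20 --trials 500 --seed 1 --out sweep.csv
pupilrl synth behavior --spec spec.yaml --seed 1 --out data/
pupilrl synth pupil --session data/session_000.csv --spec pupil.yaml --model-params fit.yaml --out trace.csv
pupilrl pupil preprocess --trace trace.csv --events events.csv --out z.csv
pupilrl pupil regress --trace trace.csv --events events.csv --session s.csv \
    --model-params fit.yaml --model observable --out coefs.csv
```

Session files are CSV with columns
`trial,choice,outcome,computer_choice,cue_time,response_time`
(choices `L`/`R`/`MISS`); traces are `time_s,diameter`; events are
`trial,cue_time_s`; model parameters and generator specs are YAML.

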