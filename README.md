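# prl-qlearn

Reinforcement-learning analysis pipeline for two-choice **probabilistic
reversal learning (PRL)** data: trial-by-trial Q-learning models with a
choice-stickiness term, exhaustive grid-search maximum-likelihood fitting,
model comparison, conventional reversal-learning measures, and the
correlation analysis that links the two — plus a task/agent simulator so the
whole pipeline can be exercised and validated without external data.

## What it implements

**Task.** Two options, one designated "correct" and rewarded on 80 % of
choices (the other on 20 %); the designation flips after 8 consecutive
correct choices; sessions run up to 200 trials. The simulator reproduces
this environment and generates cohorts with a group × sex × phase design so
group-level parameter shifts can be planted and recovered.

**Models.** Delta-rule value learning `Q ← Q + α (r − Q)` for the chosen
option, softmax choice over `Q/β` with an additive stickiness bonus `κ`
toward the previous choice. Three nested variants:

| name     | free parameters                 |
|----------|---------------------------------|
| `M_ab`   | α, β                            |
| `M_abk`  | α, β, κ                         |
| `M_a2bk` | α_rew, α_non-rew, β, κ          |

**Fitting.** Exhaustive grid search per session per model; α on
[0.001, 1] step 0.05, β on [0.005, 5] step 0.15, κ on [−1, 1] step 0.1.
Ties break to the first point in lexicographic grid order. The grid
evaluation is vectorised (the Q trajectory only depends on the learning-rate
axes) so a full 4-parameter fit of a 500-trial session takes ~2.5 s on one
CPU.

**Comparison.** Log-likelihood ratio `d = 2 (LL₂ − LL₁)`, pseudo-r²
(0 = chance, 1 = perfect prediction), and BIC in its log-evidence form
`LL − (k/2) log m` (larger is better; `classical_bic` converts to the
−2LL + k log m convention). Winner = best mean BIC across sessions.

**Conventional measures.** Win-stay and lose-shift percentages split by
previous-response correctness, trials to criterion, proportion correct, and
perseverative responses after reversals.

**Statistics.** Pearson correlations between fitted parameters and
conventional measures on per-subject session means, Shapiro–Wilk normality
screening, and Benjamini–Hochberg FDR control at q = 0.05.

## CLI

Every stage is a subcommand of `prl-qlearn`:

```sh
prl-qlearn simulate --design design.yaml --seed 1 --out sessions.csv
prl-qlearn io validate sessions.csv
prl-qlearn io filter --max-reversals 4 --sessions-per-phase 3 sessions.csv filtered.csv
prl-qlearn fit --model M_ab --model M_abk --model M_a2bk filtered.csv fits.csv
prl-qlearn compare --out comparison.csv fits.csv
prl-qlearn measures --fits fits.csv --model M_a2bk --out measures.csv filtered.csv
prl-qlearn correlate --fdr 0.05 --out corr.csv measures.csv
prl-qlearn run config.yaml --out rundir     # everything end to end
```

`run` consumes a single YAML config:

```yaml
seed: 1
task: {p_reward_correct: 0.8, p_reward_incorrect: 0.2, reversal_criterion: 8, max_trials: 200}
cohort:
  n_per_cell: 8
  sessions_per_phase: 3
  phases: [pre_stress, post_stress]
  default_params: {alpha_rew: 0.451, alpha_nonrew: 0.451, beta: 0.305, kappa: 0.0}
  overrides:
    - {group: MS, sex: female, kappa: 0.3}   # plant a stickiness shift
# input: sessions.csv                        # alternatively: skip simulation
filters: {max_reversals: 4, sessions_per_phase: 3}
models: [M_ab, M_abk, M_a2bk]
q0: 0.5
fdr: 0.05
```

The run directory contains `sessions.csv`, `sessions_filtered.csv`,
`fits.csv`, `comparison.csv`, `measures.csv`, `corr.csv`, `normality.csv`,
a `recovery_report.csv` (true vs. fitted parameters, simulation mode only)
and a `manifest.json` that reproduces the run byte-for-byte.

## File formats

Trial logs are plain CSV, one row per trial:

```
subject_id,group,sex,phase,session_index,trial_index,chosen_side,correct_side,rewarded,reversal_index
```

Sides are `L`/`R`, rewards `0`/`1`, `reversal_index` counts completed
contingency flips. Measure tables are one row per subject-session with
missing values written as `NA`.
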