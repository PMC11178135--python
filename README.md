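# igtsim

Agent-based simulation, parameter fitting, and block-trajectory analysis of
choice behaviour in the Iowa Gambling Task (IGT).

The model is deliberately small. On each of 100 trials an agent:

1. converts values into choice probabilities with the **matching rule**
   (`p_i = v_i / Σv`, values rectified at a small floor so the ratio stays
   defined when learning drives them negative) — or optionally **softmax**;
2. draws a card from the chosen deck (fixed gain, Bernoulli loss);
3. forms a subjective net gain `Gn = gain·Gs − loss·Ls`, weighting the
   (max-gain-normalized) payoffs by its gain sensitivity `Gs` and loss
   sensitivity `Ls`;
4. updates the chosen deck's value with the linear-operator rule
   `V ← M·V + (1−M)·Gn`, where `M` is the memory factor.

All values start at 0.25. The package adds everything needed to study and
recover the `(M, Gs, Ls)` triple:

| module              | what it does                                                             |
| ------------------- | ------------------------------------------------------------------------ |
| `igtsim.task`       | deck/task configuration, outcome sampling, max-gain normalization        |
| `igtsim.agent`      | parameters, net gain, value update, matching/softmax choice rules        |
| `igtsim.engine`     | single-agent runs with full trial logs, vectorized multi-agent runs, the 9×9×9 grid sweep |
| `igtsim.fitting`    | rejection fitting on fifth-block preference, multi-start Nelder–Mead on the 5-block SSE (common random numbers), replica re-simulation |
| `igtsim.summaries`  | power-function (`y = a·x^b`) rate-of-change fits, Q1/Q2/Q3 quartile subgroups, block-mean correlation/RMSE |
| `igtsim.cohort`     | synthetic two-group cohorts with known ground-truth parameters and lapse noise |

## Command line

A single `igt` entry point with five subcommands:

```bash
# one agent, full trial log
igt simulate -m 0.9 -g 0.1 -l 0.5 --seed 1 --out trials.csv

# full parametric sweep (729 combinations x 50 agents), optional heat grid
igt sweep --grid-step 0.1 --n-agents 50 --seed 1 --out sweep.csv --plot sweep.png

# synthetic cohort: per-subject trial logs, targets.csv, truth.csv
igt generate --seed 7 --out-dir cohort/

# recover (M, Gs, Ls) per subject
igt fit --targets cohort/targets.csv --method rejection --tolerance 0.01 \
        --seed 2 --out fits.csv
igt fit --targets cohort/targets.csv --method nelder-mead --seed 2 --out fits.csv

# per-subject power fits + subgroups; pass --prefs twice to compare cohorts
igt summarize --prefs cohort/targets.csv --out summary.csv --json-out cohort.json
```

Task and cohort designs are plain JSON/YAML files (see
`src/igtsim/data/default_task.json` and `igtsim.cohort.load_cohort_spec`).

## Notes on behaviour

- The matching rule's handling of negative values is not uniquely
  determined by the model statement; this implementation rectifies values
  at `1e-3` for the probability computation only. Sweep extremes depend on
  this choice.
- Deck labels follow the source convention (A/B flagged advantageous) even
  though A/B have negative expected raw value under the listed payoffs;
  the flag is exposed on `DeckSpec` so users can relabel.
- Parameter recovery from a 5-point block trajectory is weakly identified;
  the Nelder–Mead fitter uses multiple starts and wide initial simplices
  because its common-random-number objective is piecewise constant.
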