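# domhier

Dominance-hierarchy inference from pairwise contests, and the statistics
linking social rank to stress outcomes in laboratory mice.

Rodent labs measure social rank with the **tube test**: two cagemates meet
in a narrow tube and the mouse that retreats loses. Running every pair of a
four-mouse cage in a round robin, session after session, yields a contest
ledger from which a hierarchy can be reconstructed — and that hierarchy
predicts how each animal responds to chronic stress. `domhier` implements
the full analysis path:

* **Rank inference** — David's Scores over a session window, quartile rank
  classes (dominant / intermediate / subordinate), daily standings with a
  tournament-linearity flag, hierarchy stability, steepness, and rank
  mobility.
* **Stress-outcome scores** — social-interaction (SI) ratio with the
  susceptible/resilient classification, active-coping score, wound score,
  and vigilance.
* **Group statistics** — outlier filtering within rank x stress cells,
  Pearson correlations with Fisher-z CIs, Student t-tests, 2x2 chi-square,
  two-way factorial ANOVA (Type-III, sum-to-zero coding) with
  Sidak-adjusted within-rank contrasts, and one-way ANOVA with Tukey-style
  contrasts.
* **Synthetic cohorts** — a logistic latent-ability (Bradley–Terry-type)
  tournament generator with winner-effect and session-jitter dynamics,
  plus rank-linked stress-outcome generators for the chronic social defeat
  (CSDS), chronic variable stress (CVS), dyad-recombination and
  rank-mobility designs, so the entire pipeline is testable end to end
  without animal data.

## The core statistic

For animals with win proportions `P_ij` (wins of *i* over *j* divided by
their contests), David's Score is

    w_i  = Σ_j P_ij            l_i  = Σ_j P_ji
    w2_i = Σ_j P_ij · w_j      l2_i = Σ_j P_ji · l_j
    DS_i = w_i + w2_i − l_i − l2_i

Wins over strong opponents count for more than wins over weak ones. In a
tetrad with every pair contested, DS spans [−6, 6]; the quartile cutoffs
classify `DS > 3` as dominant and `DS < −3` as subordinate. The normalized
score `NormDS_i = DS_i/N + (N−1)/2 ∈ [0, N−1]`, ordered and regressed on
rank position 1..N, gives hierarchy **steepness** (1 = perfectly despotic,
0 = flat).

## Worked example

```python
from domhier import RunConfig, SimConfig, characterize, simulate_tournament

cohort = simulate_tournament(SimConfig(n_cages=12, seed=42))
report = characterize(cohort.ledger, RunConfig())
```

Running `python examples/characterize_hierarchy.py` prints:

```
cages:            12
stable cages:     25%   (4 consecutive identical sessions at the end of testing)
linear days:      99%   (win counts form a strict order, no 3-cycles)
mean steepness:   0.95   (1 = perfectly despotic, 0 = flat)

one cage in detail:
animal   ds  norm_ds rank_class
 C01.1 -6.0     0.00        SUB
 C01.2  1.0     1.75        INT
 C01.3 -1.0     1.25        INT
 C01.4  6.0     3.00        DOM
```

Cage C01 is a perfectly resolved hierarchy: the top animal won every
contest of the window (DS = +6, dominant), the bottom animal lost every
one (DS = −6, subordinate), and the middle two sit in the intermediate
band. The other examples cover each study design:

| script | what it shows |
| --- | --- |
| `examples/characterize_hierarchy.py` | stability, linearity, steepness, DS classes |
| `examples/rank_and_defeat_outcomes.py` | social defeat: SUB/INT deficits, dominants spared |
| `examples/emergent_rank_cvs.py` | non-social stress: emergent rank predicts SI, pre-stress rank does not |
| `examples/recombination_dyads.py` | losing dominance after re-pairing costs resilience |
| `examples/behavior_scores.py` | SI ratio, coping, wound, vigilance scores |

A thin CLI wraps the same workflows:

```bash
domhier simulate --out cohort/ --seed 7
domhier characterize --ledger cohort/ledger.csv --out report/
domhier stress --ledger cohort/ledger.csv --behavior cohort/behavior.csv \
    --design csds --out stress_report/
```

## Data formats

Contest ledgers are long-format CSV, one contest per row, with columns
`day,cage,animal_a,animal_b,winner`; behavior tables are CSV keyed by
`cage,animal` with measurement columns (interaction-zone times, coping
event counts, wound observations, vigilance seconds, warm-corner
occupancy) and a `CTRL`/`STRESS` condition label. The loader rejects any
row violating a ledger invariant and names the row. Run configuration is
a JSON document (unknown keys rejected).

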