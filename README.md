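# cervicost

Decision-tree cost-effectiveness analysis of Pap-smear **collection
devices** for the South African national cervical-cancer screening
programme, focused on HIV-infected women.

## The problem

Conventional cervical cytology is only as good as the specimen on the
slide: a smear without endocervical cells has sampled the transformation
zone poorly and its sensitivity for dysplasia drops sharply.  The wooden
elongated-tip (Aylesbury) spatula — the device on public tender at under
$0.02 — yields endocervical cells on roughly half of smears; the plastic
Cervex-Brush ("broom", ≈ $0.22) samples ecto- and endocervix
simultaneously and raises that to over 80 %.  Whether the 10× more
expensive device pays for itself depends on what happens to an inadequate
smear:

* **Guidelines (intended) practice** — a negative smear lacking
  endocervical cells, or an unsatisfactory smear, triggers a recall for
  immediate retesting.  Inadequate smears then cost money (repeat visits,
  repeat cytology) and lose women from care when they never return.
* **Typical practice** — only unsatisfactory smears are repeated; a
  negative inadequate smear becomes a final result.  Inadequate smears
  then cost *diagnoses*: false negatives in women screened because they
  are at high risk.

`cervicost` implements both decision trees for an annual cohort of
HIV-infected women (screening volume × HIV-positive fraction), costs every
completed smear (outpatient visit + laboratory cytology + device, 2014
USD, provider perspective), and propagates parameter uncertainty with a
paired 10,000-trial Monte Carlo probabilistic sensitivity analysis (PSA).
An individual-level microsimulation of the identical branch logic serves
as a brute-force oracle for the closed-form cohort expectations, and as a
generator of synthetic laboratory-style slide records.

## The model in brief

For a woman with true state *s* ∈ {negative, ASC-US, LSIL, HSIL}, one
smear with a device whose endocervical-cell probability is *e* is

* reported **abnormal** with probability
  `p_sat · [e·sens_endo + (1−e)·sens_no_endo(s)]` for diseased states
  (grade-split sensitivity when endocervical cells are absent) and
  `p_sat · (1 − specificity)` for negative women;
* a **final negative** or a **recall**, according to the practice rules
  above.

A recalled woman re-enters with probability `q = p_return ·
p_repeat_given_return` and is otherwise lost to care.  With per-round
probabilities (a, f, r) the terminal distribution is a geometric sum; with
the default cap of one repeat smear (`max_rounds=2`),

```
P(detected) = a·(1 + rq),  P(final negative) = f·(1 + rq),
P(lost)     = r·(1 − q) + rq·r,   E[smears] = 1 + rq.
```

Programme cost is `n · E[smears] · (visit + lab + device)`; the headline
metric is the **cost per HSIL case detected**, compared between devices as
the difference of the two ratios (a conventional ICER is available
separately).

## Worked example

```bash
cervicost run --n-trials 10000 --seed 1 -o out/
```

prints (abridged):

```
Guidelines (intended practice) — 10000 Monte Carlo trials, seed 1
Metric                                   Spatula           Broom          Diff     %
Annual programme cost             $ 6,258,013.40  $ 5,517,768.86 $ -740,244.53  -12%
Cost per woman screened                  $ 16.98         $ 14.97       $ -2.01  -12%
Cost per HSIL case detected              $ 79.47         $ 64.92      $ -14.54  -18%
HSIL smears detected                      78,950          85,147         6,198   +8%
No diagnosis (lost to care)               56,920          14,345       -42,576  -75%

Typical practice — 10000 Monte Carlo trials, seed 1
Annual programme cost             $ 4,971,862.59  $ 5,046,796.46   $ 74,933.87   +2%
Cost per HSIL case detected              $ 79.27         $ 64.85      $ -14.42  -18%
HSIL smears detected                      62,943          78,006        15,064  +24%
False negative smears reported           113,988          82,272      -31,717  -28%
```

Reading: under guidelines practice the broom **dominates** — it saves the
programme about $0.74 M/year (≈ $2 per woman) by avoiding repeat smears
*and* detects ~6,200 more HSIL cases, i.e. about $14.5 saved per HSIL case
detected.  Under typical practice the broom costs ~$75 k/year more (the
device premium) but detects ~15,000 additional HSIL cases and averts
~32,000 false-negative reports, still lowering the cost per HSIL detected
by about $14.

Other entry points:

```bash
cervicost params                      # the full input registry (means, 95 % bounds)
cervicost simulate --device broom --n-women 100000 -o records.csv
```

and as a library:

```python
from cervicost import default_registry, run_psa
res = run_psa(default_registry(), "guidelines", n_trials=10_000, seed=1)
print(res.summary())
```

## Layout

| Module | Contents |
| --- | --- |
| `cervicost.parameters` | parameter registry (packaged YAML), interval→SD, sampling |
| `cervicost.tree` | branch probabilities, recall-loop absorption, cohort expectations |
| `cervicost.economics` | costing, incremental comparison, dominance, ICER |
| `cervicost.psa` | paired Monte Carlo engine, mean/CI summaries |
| `cervicost.microsim` | individual-level simulator, tallies, parameter recovery |
| `cervicost.report` / `cervicost.cli` | run orchestration, tables, manifest, CLI |

See `docs/methods.md` for the full model description, parameter table
semantics, numerical choices and known limitations.
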