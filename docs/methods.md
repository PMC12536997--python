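# Methods note

This note records the modelling assumptions, parameter conventions and
numerical choices behind `cholecea`, including the places where the inputs
were ambiguous and a design decision had to be made.

## Model structure

Both care strategies (conventional inpatient care; acute day surgery with
remote monitoring) share a fixed two-level chance tree:

* **root** — the cholecystectomy is completed laparoscopically
  (`p_lap` = 0.97) or converted to open surgery (complement, 0.03);
* **laparoscopic node** — no complication (`p_lap_no_comp` = 0.94) or a
  minor complication (`p_lap_minor` = 0.06);
* **open node** — no complication (0.88), minor complication (0.08),
  major complication (0.01) or perioperative mortality (0.02).

That yields six terminal states per strategy. Each terminal carries a payoff
bundle (cost in 2023 AU$, inpatient bed days, utility weight); rollback is
the probability-weighted expectation, and an independent path-enumeration
routine serves as the test oracle for it. QALYs are utility × 1-year
horizon, with the mortality state fixed at 0 QALYs (its cost and bed days
are still counted). The tree depth is deliberately fixed: the engine
validates and rolls back this structure rather than arbitrary trees.

The strategies differ only in the two uncomplicated-laparoscopy terminals:
under day surgery these carry the same-day procedure cost, the remote
monitoring program cost and a 1-day stay; every complicated pathway uses the
same inpatient payoffs in both arms. Consequently the base-case QALY totals
are identical across strategies and the QALY comparison is a pure cost
difference at the point estimate.

## Parameters

Inputs live in `src/cholecea/data/table1.yaml`. Conventions:

* **Units.** Costs in 2023 AU$ per patient (a US$ display column uses a
  fixed 0.66 rate); lengths of stay in bed days; utilities on the 0–1 scale;
  probabilities per surgical episode.
* **Row count.** 23 rows are *variable* (enter the sensitivity analyses):
  5 branch probabilities, 5 utilities, 7 lengths of stay, 6 costs. The
  three "no complication / not converted" branches are stored for
  readability but flagged as complements — they are determined by their
  siblings through node renormalization, so sweeping them independently
  would double-count. The mortality utility is fixed at 0.
* **Shared rows.** A payoff that takes the same value in both arms (all
  utilities; the complicated-pathway costs and stays) is stored once with
  `strategy: shared` and a list of the (strategy, state) terminals it
  applies to, instead of duplicated per arm.
* **Derived costs.** The same-day procedure cost is the inpatient
  laparoscopy cost divided by a 1.38 inpatient:day-surgery cost ratio
  (AU$11,300 / 1.38 ≈ AU$8,188, rounded to the dollar); the monitoring
  program is budgeted at 50% of the resulting saving
  (0.5 × (11,300 − 8,188) ≈ AU$1,556). `derive_day_surgery_costs` performs
  the derivation and the fixture values are tested against it. The
  monitoring cost is given a deliberately wide plausible range
  (AU$500–5,000) because the program is costed by assumption, not observed.
* **Missing ranges** default to base ± 50% (`default_range_fraction`),
  clipped to [0, 1] for probabilities and utilities, and are filled in at
  file-load time. A row whose low = high = base therefore means "known
  exactly" and becomes a point mass everywhere downstream.

### Chance-node normalization

The open-surgery branch probabilities are stated as 0.88/0.08/0.01/0.02,
which sum to 0.99. Rather than silently absorbing the deficit into one
branch, the engine renormalizes every chance node proportionally
(`normalize_chance_probabilities`), and applies the *same* rule in the base
case, the one-way sweeps and the PSA. An all-zero or negative node is an
error, not a renormalization candidate.

## Incremental analysis

Conventional care is the reference; effects are **bed days saved**
(reference minus comparator stay, so the reference scores 0) or **QALYs
gained**. For willingness to pay λ:

* per-strategy NMB = λ·effect − cost; INMB = λ·Δeffect − Δcost;
* the comparison is classified as dominant (saves effect-units and money),
  dominated, trade-off, or undefined when Δeffect = 0 with Δcost ≠ 0;
* an ICER is reported only for trade-offs (elsewhere it is NaN with a
  verbal label), and the ceiling test treats ICER = λ as acceptable
  (boundary inclusive).

## One-way sensitivity analysis

Each of the 23 variable rows is swept to its low and high bound while all
others stay at base, recording INMB at both endpoints. Probability sweeps
insert the perturbed raw value and renormalize the **whole node**
proportionally — the same normalization as everywhere else — so that a
sweep whose bounds are collapsed to the base value reproduces the base-case
INMB exactly, even on the 0.99-sum node. (Renormalizing only the siblings
would break that invariant there.) Shared rows are perturbed in both arms
simultaneously; rows appearing identically in both arms therefore produce
zero-width bars, and exactly 7 of the 23 bars have non-zero width. Bars are
sorted by descending width with ties broken by name; "influential" defaults
to a width exceeding 1% of |base INMB|.

## Probabilistic sensitivity analysis

Distribution families follow parameter roles: beta for probabilities and
utilities, modified-PERT (shape 4, on the low–base–high range) for lengths
of stay, gamma for costs — all moment-matched.

* **Probability SDs.** The reported dispersion column for probabilities is
  not usable on the probability scale (most entries exceed the Bernoulli
  bound √(m(1−m)), and the feasible ones imply U-shaped betas contradicting
  their own 95% ranges). All probability betas therefore use the
  range-implied SD (high − low)/4; this substitution is logged per
  parameter at run time.
* **Utility and cost SDs** are used as reported (all utility betas are
  feasible; gammas accept any positive SD). An infeasible utility SD would
  fall back to the range-implied value, again logged.
* **Correlation structure.** Probability rows are drawn once per iteration
  and applied to both arms (both arms face the same patient mix). Shared
  payoff rows are drawn **independently per arm** — each arm gets its own
  replicate of the same distribution — which is what gives the QALY
  difference a non-degenerate distribution despite identical point
  estimates.
* **Reproducibility.** Every (parameter, arm) pair gets its own RNG
  substream, keyed as `SeedSequence([seed, crc32(name|arm)])`. Results are
  bitwise reproducible for a given seed, and adding a parameter to the
  table does not reshuffle the draws of existing ones.
* **Vectorization.** The per-draw rollback is evaluated in closed form over
  whole draw arrays; a test rebuilds the trees draw by draw and confirms
  agreement to 1e-9 relative tolerance. 5,000 draws run in well under a
  second.

"Probability cost-effective" is the strict fraction of draws with
INMB(λ) > 0; CEACs evaluate it on a grid (default: 101 points from 0 to
twice the headline threshold, which always contains the headline value).

A side effect of the PERT choice worth knowing: the PERT mean
(low + 4·base + high)/6 sits above the mode for the right-skewed stay
ranges, so PSA mean bed days (≈3.16 vs 1.49) sit slightly above the
base-case rollback values (3.157 and 1.334).

## Synthetic model generator

`generate_model(SyntheticModelConfig(...))` builds random but
structurally valid parameter tables on the same six-state tree: Dirichlet
branch probabilities per node (first branch flagged as the complement),
per-strategy stay/cost/utility rows with ranges base ± a configurable
variance fraction. It exists to test the machinery, not the clinical
question:

* `variance_fraction=0` collapses every distribution to a point mass, so a
  PSA must reproduce the deterministic rollback to ~1e-12 — an exact
  end-to-end oracle;
* `known_answer_model()` has hand-computable expectations (cost 300,
  2 bed days, 0.7 QALYs in both arms) checked exactly;
* a harness rolls 1,000 random models through both rollback and path
  enumeration and requires agreement.

Passing these shows the engine computes the stated expectations correctly
for any table of this shape; it says nothing about whether the clinical
inputs themselves are right.

## Numerical and degenerate-case choices

* Beta moment fits with sd² ≥ m(1−m) raise `InfeasibleMomentsError` rather
  than clamping silently; sd = 0 is a point mass.
* PERT with low = high is a point mass; samples are clipped only by the
  distribution's own support, never post-hoc.
* A single-draw PSA yields degenerate 0/1 CEAC probabilities rather than an
  error.
* Currency derivations round to the whole dollar; everything downstream is
  float.
* Tornado ties (equal widths) break alphabetically for deterministic
  output.

## Limitations

* The tree is static over a 1-year horizon: no readmission dynamics, no
  discounting (irrelevant at 1 year), no patient heterogeneity beyond the
  branch probabilities.
* The QALY arm difference at the point estimate is zero by construction;
  the QALY CEAC reflects sampled utility uncertainty only and should be
  read as secondary to the bed-day outcome.
* The monitoring program cost is an assumption (a budget share of the
  day-surgery saving), not an observed price; its wide sensitivity range is
  the honest expression of that.
* The probability dispersion column had to be replaced wholesale by
  range-implied SDs (see above); reported and modelled uncertainty for
  probabilities therefore differ by design.
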