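# Methods

This note documents the models implemented by `thermotrace`, their
assumptions, the defaults and why they were chosen, and what the
synthetic-data validation does and does not demonstrate.

## The experimental system being modeled

One *microcosm* is a sealed sediment + medium bottle. The design crossed
three 10-day temperature pretreatments (+4 °C unfrozen control, −20 °C,
−80 °C) with three replicates. After pretreatment every bottle was
pasteurized (+80 °C, killing vegetative cells but not endospores) and
incubated at +50 °C; amplicon libraries were taken immediately after
pasteurization (day 0) and after 7 days (day 7). Dormant thermophilic
endospores that survived pretreatment germinate and grow at +50 °C, so
viable *thermospores* appear as OTUs that jump from (near) undetectable
to percent-level relative abundance between the paired libraries.

## Thermospore calling

An OTU qualifies **in a microcosm** when three criteria hold in that
microcosm's day-0/day-7 pair, and an OTU is a thermospore when it
qualifies in at least one microcosm:

| criterion | default | notes |
|---|---|---|
| abundance floor | day-7 fraction > 0.005 | strict inequality |
| fold change | day-7/day-0 fraction ≥ 10 | see zero-handling below |
| significance | Bonferroni-adjusted two-sided Fisher exact p < 0.001 | family = all OTUs in the pair |

Design choices where the procedure was genuinely open:

- **Pairing.** "The corresponding pre-incubation library" is read as the
  same bottle's day-0 library; replicates are never pooled. A fold change
  needs its own baseline, and bottle-to-bottle variability is itself a
  finding of the study system.
- **Conjunction per pair.** All three criteria must hold in the *same*
  pair. Evaluating, say, the abundance floor in one replicate and the
  fold change in another would let unrelated noise combine into a call.
- **Zero day-0 counts.** OTUs absent at day 0 are the expected signal
  (germination from below the detection limit) and must not be lost to
  division by zero. The fold-change denominator defaults to 0.5 reads at
  the day-0 depth — the largest abundance indistinguishable from zero is
  just under one read, and half a read is the natural sub-detection mass.
  An OTU absent at both timepoints has fold change 0, not ∞.
- **Fisher exact test.** p is the sum of hypergeometric probabilities of
  all 2×2 tables with the observed margins whose probability is at most
  the observed table's, with a relative tie tolerance of 1e-7 so that
  floating-point noise cannot flip the inclusion of an exactly tied
  table. When every table in the support is as extreme as observed, p is
  exactly 1. The implementation uses a cached log-factorial table; tests
  compare it against an exact integer-arithmetic enumeration oracle
  (exhaustively for small totals, sampled up to margins of 200) and
  against an independent library implementation.
- **Bonferroni family.** The family size is the number of OTUs in the
  table, applied per microcosm pair — the correction a per-comparison
  differential-abundance tool applies.
- **Detection vs. qualification.** For per-microcosm summary counts and
  the pretreatment Venn partition, a thermospore counts as *detected* in
  any microcosm where its day-7 fraction reaches the detection floor
  (default 0.05 %, half the smallest value printed in the study's
  per-OTU table). When the input is the printed abundance table itself
  (which has no counts), detection is "non-zero cell", since blanks in
  that table encode non-detection.

The calling criteria are monotone in the thresholds: raising the
abundance floor or fold minimum, or lowering α, can only remove calls.

## Embedded per-OTU abundance fixture

The study's per-OTU day-7 relative abundance table (22 thermospore OTUs ×
9 microcosms, one decimal place, in percent) is embedded as a TSV
fixture with blanks encoded as exact 0 and values stored internally as
fractions. Reconstruction from this fixture reproduces the printed
per-microcosm counts (15, 11, 14 / 16, 9, 10 / 8, 12, 11), the Venn
partition (total 22; 12 in all three groups; 1 unfrozen-control-only;
6 frozen-only, 2 of those −80 °C-only), and the 14 % mean abundance of
the dominant sulfate-reducer OTU over its 7 detected microcosms. Summed
per-microcosm abundances agree with the printed totals only to rounding
(each cell is rounded to one decimal before summing).

## Electron-balance stoichiometry

Complete oxidation of CxHyOz to CO₂ and H₂O transfers `4x + y − 2z`
electrons; sulfate → sulfide accepts 8. The expected drawdown of a
substrate mix is Σ cᵢeᵢ/8, giving 8.75 mM for the six 1 mM organic acids
(70 electron-mM) and 10.25 mM with 1 mM ethanol. Compositions are those
of the neutral (protonated) molecules.

The geochemistry simulator advances pools at a fixed timestep (default
0.25 d over 21 d):

- Each scheduled substrate follows a **logistic depletion window**
  (lag, duration, terminal fraction consumed), rescaled to start and end
  exactly at the window edges, applied multiplicatively to the pool so
  that material produced mid-window is consumed by the remaining
  schedule. The terminal fraction below 1 models replicates where a
  substrate was never removed. Lags shift uniformly with a pretreatment
  offset, which delays but cannot change the terminal drawdown.
- **Reaction rules** route a configured fraction of each consumed mole
  through partial transformations — succinate → propionate + CO₂ (0 e⁻),
  lactate → acetate (4 e⁻), butyrate → 2 acetate (4 e⁻),
  ethanol → acetate (4 e⁻) — with the remainder completely oxidized.
  Rules must balance electrons exactly (reactant electrons = product
  electrons + released electrons), which makes the terminal drawdown
  path-independent: any chain of rules ending in CO₂ releases the
  complete-oxidation electron count. A rule can be flagged fermentative,
  in which case its electrons are tallied separately and consume no
  sulfate (the study could not attribute the earliest consumption to
  sulfate reduction with certainty).
- Sulfate is decremented by exactly ⅛ of the electrons released, so
  8 × drawdown = cumulative electrons and total carbon (pools + CO₂) are
  conserved to machine precision at every step — these are asserted in
  tests at 1e-9.
- Optional Gaussian measurement noise (default off) is added *after* the
  mass balance and clipped at zero; values are flagged against the assay
  detection limits (sulfate 0.1 mM, organic acids 2.5 µM). Invariants are
  stated on the noise-free trajectories.

The default microcosm configuration reproduces the qualitative observed
dynamics: formate/lactate first, stoichiometric succinate → propionate
conversion, propionate and butyrate next, an acetate overshoot to ~4 mM
(fed by lactate and butyrate incomplete oxidation on top of the initial
1 mM) followed by late acetate depletion, and an onset delay growing
with pretreatment harshness. Ethanol is present in the medium but left
unconsumed by default: the observed 7–9 mM drawdown brackets the 8.75 mM
six-acid expectation, not the 10.25 mM including ethanol, and whether
ethanol was consumed is not established.

## Synthetic community generator

The generator emulates the statistical structure the caller assumes, with
known ground truth:

- **Background community** (default 300 OTUs): an abundant log-normal
  core (σ = 0.8) holding most of the mass, plus a *rare tail* (default
  half of the background OTUs) with log-uniform absolute fractions of
  5e-6–5e-5 — i.e. straddling one read at 45,000-read depth. Two
  components are needed because a single log-normal cannot reproduce the
  observed direction of diversity change: day-0 evenness must be high
  (so the bloom *lowers* inverse Simpson) while a substantial
  sub-detection tail must exist (so compositional compression *lowers*
  observed richness and Chao1). Dead or dormant background DNA persists
  through pasteurization, so day-0 libraries stay background-dominated.
- **Thermospore seed bank** (default 20 OTUs): day-0 seed fractions
  uniform in [1e-5, 5e-5], anchored to the study's statement that
  pre-incubation abundances of the key genus averaged below 0.005 %.
- **Survival**: Bernoulli per OTU per microcosm (all spores of an OTU in
  a bottle live or die together) — the simplest mechanism that generates
  the observed between-replicate variability. Three default classes
  mirror the observed phenotypes: freeze-robust (0.95/0.95/0.9 for
  +4/−20/−80 °C), freeze-sensitive (0.95/0.8/0.15; the pattern of the
  dominant sulfate-reducer OTU, lost at −80 °C), and freeze-revealed
  (0.1/0.85/0.85; enriched only after freezing relieves competition).
  An optional fractional-survival mode binomially thins the viable seed
  across a configurable number of virtual spores instead.
- **Growth**: log-uniform factors of 200–5000 per OTU over the 7-day
  incubation; non-survivors keep factor 1. Day-7 compositions are
  renormalized products of day-0 fractions and factors. At these
  defaults the day-7 thermospore fraction lands around 35–50 % of reads,
  inside the observed 36–61 % band.
- **Sequencing**: one multinomial draw per library at 45,000 reads
  (matching the study's ~44,900 average); the column sum is exact.
- **Reproducibility**: RNG streams are keyed per microcosm via
  `SeedSequence(seed, spawn_key=(pretreatment, replicate))`, so adding
  replicates never perturbs earlier draws, and identical configurations
  are bit-identical.

What validation on this generator shows: the calling criteria recover
≥ 95 % of surviving thermospores whose true day-7 fraction exceeds the
abundance floor, with zero background false positives across 20 studies
(Bonferroni holding the family-wise error at 0.001). What it does not
show: robustness to PCR/primer bias, chimeras, OTU-clustering artifacts,
compositional correlations among background OTUs, or partial-germination
kinetics — none of which are modeled. Misses are concentrated exactly at
the floor (true fraction a hair above 0.5 %, sampled below), which is the
irreducible cost of a sharp threshold under multinomial noise.

## Diversity and ordination

- **Chao1** uses the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)),
  defined even when no doubletons exist; it is always ≥ observed
  richness. (The source study's diversity table prints richness larger
  than Chao1, which that estimator cannot produce — the columns appear
  transposed — so those printed values are not reproduction targets.)
- **Distances** are computed on relative abundances by default, matching
  the compositional framing of the per-OTU table; raw-count input is
  accepted by the pairwise function.
- **NMDS** minimizes Kruskal stress-1, √(Σ(d̂−d)²/Σd²), alternating
  pool-adjacent-violators monotone regression (disparities d̂ over the
  rank order of the input dissimilarities) with gradient descent on the
  configuration, halving the step until stress decreases; defaults are
  20 random starts in [−1,1]^k, 300 iterations, convergence at stress
  improvement < 1e-6. Stress is non-increasing within a run, and the
  reported stress is exactly recomputable from the returned (centered)
  coordinates. Pairs with *exactly zero* input dissimilarity get a zero
  disparity after regression: otherwise, at small n, rank-order stress
  is trivially minimized without collocating duplicate samples. Like all
  NMDS, small-n ordinations can reach near-zero stress whenever the rank
  order is realizable; stress values are comparable only at similar n.
- **ANOSIM** uses mid-ranks for tied distances,
  R = (r̄_between − r̄_within)/(M/2), and a label-permutation p-value that
  includes the observed statistic in the tally — p ≥ 1/(permutations+1)
  by construction. The implementation is cross-checked against
  scikit-bio's.
- **Kruskal–Wallis** delegates to scipy (tie-corrected H, χ² p-value)
  with the convention that fully degenerate data (all values identical)
  gives H = 0, p = 1, which scipy rejects rather than defines.
- **No rarefaction** is applied before diversity computation; all
  simulated libraries have identical depth, and a depth-standardization
  step would be a no-op there.

## Problem sizes and tolerances

Default test and acceptance runs use: 20 synthetic studies of 320 OTUs ×
18 libraries at depth 45,000 for recovery; exhaustive Fisher sweeps for
table totals ≤ 40 plus 1,000–2,000 sampled tables with margins ≤ 200;
geochemistry at dt = 0.25 d over 21 d. Conservation invariants are
asserted at 1e-9 (observed error ~1e-14); Fisher agreement at 1e-9
relative; stress recomputation at 1e-9.

## Known limitations

- The original study's raw libraries are not inputs; its published
  diversity values, NMDS stress (0.076) and ANOSIM R (0.42, p = 0.011)
  are data-dependent and are replaced by direction-of-change and
  invariant checks on synthetic data.
- The geochemistry simulator is a mass-balance generator, not a kinetic
  model: no thermodynamics, pH, growth yield, or isotopes.
- Taxonomy is carried as annotation only; calling never filters on it.
- The Fisher implementation enumerates the full conditional support; for
  margins far beyond sequencing-library sizes a saddlepoint or mid-p
  variant would be preferable.
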