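# Model and methods

## The model

`complevo` simulates a population of `S` binary haplotypes of length `N`
evolving by discrete, non-overlapping generations of fitness-proportional
selection and per-position mutation (a Wright–Fisher-type model). Its purpose
is to study how **genetic complementation** — sharing of gene products among
genomes co-packaged in groups, as in viral coinfection — changes the ability
of a population to traverse rugged fitness landscapes, and how that benefit
fares against **genetic parasites** (defective interfering-particle-like
genomes) under random versus kin group formation.

### Fitness landscapes

Fitness comes from a genotype → fitness map, either

* an explicit **two-locus table** over {00, 01, 10, 11}. The shipped fixture
  (`fig2a_landscape()`) is the minimal valley model `f00=0.2, f01=f10=0,
  f11=1`: a local peak at 00, a global peak at 11, and lethal single-mutant
  intermediates, so a lone lineage can cross only by a simultaneous double
  mutation; or
* a random **NK landscape**: each of `N` sites contributes a value from a
  table of `2^(K+1)` entries indexed by its own state and the states of `K`
  random partner sites. Contributions are i.i.d. uniform on [0, 1] (the
  canonical NK choice), aggregated by the arithmetic mean, and by default
  normalized by the maximum over all `2^N` genotypes so the global optimum
  has fitness exactly 1. `K = 0` is purely additive; `K = N − 1` is an
  uncorrelated House-of-Cards landscape. Ruggedness (strict local-peak count)
  increases with `K`. Landscapes are exhaustively enumerable (guarded at
  `N ≤ 20`) and serializable to JSON for exact reproducibility.

A consequence of mean-aggregated uniform contributions worth keeping in mind:
genotype fitness values concentrate (CLT), so after normalization the
second-best genotype typically exceeds 0.95 of the maximum and local optima
sit high. Valleys are therefore shallow relative to the two-locus fixture,
which deliberately has lethal intermediates. See "Known limitations".

### Groups and complementation rules

The population is partitioned into `G = S/m` groups of exactly `m`. Group
fitness `f_g` follows one of four rules:

* **full trans**: the maximum fitness over every genotype that can be
  assembled by choosing, at each locus, an allele carried by some member
  covering that locus (one intact gene copy suffices);
* **average trans**: the expected fitness when each locus's allele is drawn
  with probability equal to its frequency among covering members (gene
  dosage matters). Implemented by a per-locus weighted expansion over the
  `2^N` genotypes; it equals the brute-force average over all `m^N` ordered
  member choices by linearity, and the enumeration is kept in the package as
  an independent reference implementation;
* **full cis / average cis**: no cross-genome mixing — the maximum or the
  mean of the members' own fitness values (conformational-epistasis regime);
* **none**: `m = 1`, the basic non-interacting model (all rules coincide).

Selection draws offspring in two stages, `P_g = f_g / Σ_j f_j` over groups and
`P_{i|g} = β_i / Σ_k β_k` within a group, with `β_i = 1` for helpers and
`β_i = β_C` (default 5) for parasites.

### Parasites

Each helper converts to a parasite with probability `α_C` per generation.
Conversion deletes the first `I` positions, `I ~ Uniform{1..N}`; deletions are
heritable and irreversible. Deleted positions contribute nothing to allele
pools; surviving positions still donate alleles (a partially deleted genome
complements partially). A group of parasites only has fitness 0, and by
default so does a group in which some locus is covered by no member — a gene
product nobody encodes cannot be complemented (`uncovered_locus_policy =
"lethal"`; the alternative treats the missing gene as allele 0). In cis rules
a parasite's own fitness is 0. Parasites are selectively neutral within an
all-helper or all-parasite group; in mixed groups they take the share
`β_C/(β_C + m − 1)` per draw.

Two useful analytic anchors for the two-locus model with random pairs, both
confirmed numerically: while helpers are monomorphic, a rare parasite's
per-generation growth factor is `2β_C/(1+β_C)`, and the stable parasite
fraction is `(β_C−1)/(β_C+1)`. Because mean population fitness is capped at
`(1 − p²) · f_max` once a fraction `p` of parasites is present (all-parasite
pairs have zero fitness), runs in which parasites equilibrate above
`p ≈ 0.224` can never reach the 0.95 threshold: whether a population crosses
is a race between adaptation and invasion.

### Group formation

* **random**: the `S` selected offspring are pooled and repartitioned
  uniformly at random each generation.
* **kin**: each offspring group descends from a single parental group drawn
  fitness-proportionally with replacement (prolific lineages found several
  groups); its `m` members are drawn with replacement from that group using
  the member weights. This models collective transmission (vesicles,
  occlusion bodies, cell-to-cell spread). Member draws are with replacement,
  so within-lineage diversity decays by drift on a timescale of ~`m`
  generations — matching the transient intra-group diversity peaks the model
  is meant to display.

### Generation cycle and observables

Per generation: evaluate all `f_g` → record observables → reproduce/regroup →
convert helpers to parasites → mutate every non-deleted position with
probability `α`. The snapshot precedes reproduction so the founder state is
generation 0, and the stopping rule (`mean fitness > threshold`, default
0.95) tests the recorded value. Mean population fitness is the mean of `f_g`
over groups (equal-sized groups make this the individual-weighted mean).
Conversion-before-mutation is the default order (a new parasite's surviving
loci can still mutate); the alternative order is a config switch and is
empirically indistinguishable at the default rates.

Observables per generation: mean fitness, parasite fraction, intra-group
diversity (fraction of positions per group with ≥ 2 of the tri-states
helper-0 / helper-1 / parasite; a parasite occupies the parasite state at
every position by default), mean Hamming distance to the global optimum
(deleted positions count as mismatches by default), per-genotype frequencies
(two-locus runs), and optionally the **mutation-effect scan**: the mean, over
every (individual, non-deleted position) pair, of the change in that
individual's group fitness when the single allele is flipped and reverted.
The scan is side-effect-free, `O(m·N)` vectorized fitness evaluations per
generation, and can be capped to the first `mutation_scan_max_groups` groups
(group order is exchangeable), with the subset size recorded.

All randomness in a run flows from one `numpy` Generator seeded by
`run_seed`; (config, seed) determines the trajectory bit-for-bit. Replicate
`r` of an experiment uses `base_seed + r`, so conditions are seed-paired.
If every group has fitness zero (possible when all groups are parasite-only),
selection falls back to uniform over groups rather than extinction, keeping
`S` constant; the generation is flagged in the trajectory.

## Default parameters

| Parameter | Default | Meaning |
|---|---|---|
| `S` | 10 000 | population size (haplotypes) |
| `m` | 2 | group size (multiplicity of coinfection) |
| `alpha` | 0.001 | per-position mutation probability per generation |
| `alpha_C` | 0.001 | helper → parasite conversion probability per generation |
| `beta_C` | 5 | parasite intra-group selection weight (helpers = 1) |
| `fitness_threshold` | 0.95 | mean-fitness stopping rule (normalized landscapes) |
| `max_generations` | 10 000 | generation cap; runs that never cross are censored |

These are the canonical study conditions; experiment presets carry them, and
the CLI/test harness scales `S`, replicates and caps down for speed.

## Statistical conventions

Experiment summaries report the mean and SEM (sample SD / √n) of
generations-to-threshold over uncensored replicates, plus the censored count
and fraction — censored runs are never silently dropped. Where a single-number
comparison of means is needed (the parasite-advantage sweep), censored runs
are imputed at the generation cap; this lower-bounds the true mean and is
conservative for declaring a grouped condition faster than the baseline.

## Scales used in the shipped tests and acceptance script

Stochastic checks run at reduced scale chosen for statistical stability:
two-locus comparisons at `S = 2000` with 30 replicates (caps 1500–5000
generations), the NK group-size sweep at `S = 2000` with 25 landscape-paired
replicates, and exploration runs at `S = 1000`, `α = 5·10⁻⁴`, 150
generations with the mutation scan enabled. The acceptance script's
parasite-advantage sweep uses `S = 2000`, 30 replicates and a cap of 2000
generations per run.

## What the synthetic data does and does not emulate

All inputs are generated by the package itself (two-locus tables, seeded NK
landscapes, monomorphic or random founders); there is no external data. The
model abstracts coinfection into fixed-size groups (no explicit cells or
multiplicity-of-infection distribution), has no recombination, spatial
structure, or within-host dynamics, and treats fitness as a static genotype
map. Passing tests therefore demonstrate properties of this idealized
dynamics, not of any particular virus.

## Known limitations

* **Parasite invasion is fast under the literal selection formulas.** With
  random groups the invasion growth factor `2β_C/(1+β_C)` exceeds 1 for any
  `β_C > 1`, so whether a population reaches the fitness threshold is a
  knife-edge race against adaptation; at the scales used here the grouped
  advantage survives parasites only for `β_C` near 1, and populations that
  lose the race are permanently censored. Kin structure robustly rescues
  adaptation (parasites never establish).
* **Mean-aggregated uniform NK landscapes have shallow valleys.** Lone
  (`m = 1`) populations escape their local optima within ~10²–10³
  generations via simultaneous double mutations, so on these landscapes
  kin-structured complementation — whose beneficial alleles are neutral
  within groups and pay an ~`1/m` establishment penalty — shows no
  group-size advantage. The advantage is large and monotone in `m` on the
  two-locus valley fixture under both grouping modes, and on K=4 landscapes
  under random grouping. The NK contribution distribution and aggregation
  are exposed through the landscape API precisely because this choice, which
  the standard NK formulation fixes, controls the depth of valleys and hence
  how much there is for complementation to rescue.
* Group size is constant and uniform; `m` must divide `S`.
* The diversity metric and the Hamming observer each have one deliberate
  ambiguity resolution (parasite state at all positions; deleted positions
  as mismatches), both switchable in the config.
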