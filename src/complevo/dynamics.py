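"""Wright–Fisher-style generation updates and multi-generation runs.

Each generation proceeds as: group-fitness evaluation → observer snapshot →
fitness-proportional reproduction with regrouping → helper-to-parasite
conversion → per-position allele mutation.  The observer snapshot is taken
*before* reproduction, so the generation-0 (founder) state is recorded and
the stopping rule tests the recorded mean fitness.

Reproduction draws ``S`` offspring in proportion to group fitness and, within
a group, to the member weights (helpers 1, parasites ``beta_C``).  Two
group-formation regimes are supported:

* ``random`` — the ``S`` selected offspring are pooled and repartitioned
  uniformly at random into ``G = S/m`` fresh groups each generation.
* ``kin`` — each offspring group descends from a single parental group drawn
  fitness-proportionally (with replacement, so prolific groups can found
  several offspring groups); its ``m`` members are drawn from that parental
  group only.  This models collective transmission (vesicles, occlusion
  bodies, cell-to-cell spread) in which interacting genomes are siblings.

All randomness comes from one ``numpy`` Generator seeded by
``config.run_seed``; a (config, seed) pair fully determines the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import observers
from .group_fitness import population_group_fitness, population_member_weights
from .landscapes import _LandscapeBase, genotype_index
from .population import Population, SimulationConfig, init_population

__all__ = [
    "SelectionWeights",
    "TrajectoryRecord",
    "RunResult",
    "compute_selection_weights",
    "reproduce",
    "apply_parasite_conversion",
    "mutate",
    "step",
    "run",
]


@dataclass(frozen=True)
class SelectionWeights:
    """Group selection probabilities and normalized within-group member weights."""

    group_probs: np.ndarray  # (G,), sums to 1
    member_probs: np.ndarray  # (G, m), each row sums to 1
    group_fitness: np.ndarray  # (G,) raw f_g
    degenerate: bool = False  # True when total fitness was 0 (uniform fallback)


@dataclass
class TrajectoryRecord:
    """Per-generation observables, measured on the pre-reproduction state."""

    generation: int
    mean_fitness: float
    parasite_fraction: float
    intragroup_diversity: float
    mean_hamming_to_optimum: float
    mean_mutation_effect: float | None = None
    degenerate_selection: bool = False
    genotype_frequencies: dict | None = None

    def to_row(self) -> dict:
        row = {
            "generation": self.generation,
            "mean_fitness": self.mean_fitness,
            "parasite_fraction": self.parasite_fraction,
            "intragroup_diversity": self.intragroup_diversity,
            "mean_hamming_to_optimum": self.mean_hamming_to_optimum,
            "mean_mutation_effect": self.mean_mutation_effect,
            "degenerate_selection": self.degenerate_selection,
        }
        if self.genotype_frequencies is not None:
            row.update({f"freq_{k}": v for k, v in self.genotype_frequencies.items()})
        return row


def compute_selection_weights(population: Population, landscape: _LandscapeBase,
                              rule: str, beta_C: float,
                              uncovered_locus_policy: str = "lethal",
                              group_fitness: np.ndarray | None = None) -> SelectionWeights:
    """Selection probabilities ``P_g = f_g / sum_j f_j`` plus member weights.

    When every group has fitness 0 (possible once all groups are
    parasite-only) selection falls back to uniform over groups, keeping the
    population size constant; the condition is flagged.
    """
    fg = group_fitness
    if fg is None:
        fg = population_group_fitness(population, landscape, rule,
                                      uncovered_locus_policy=uncovered_locus_policy)
    total = fg.sum()
    if total > 0:
        pg = fg / total
        degenerate = False
    else:
        pg = np.full(population.G, 1.0 / population.G)
        degenerate = True
    return SelectionWeights(group_probs=pg,
                            member_probs=population_member_weights(population, beta_C),
                            group_fitness=fg, degenerate=degenerate)


def reproduce(population: Population, weights: SelectionWeights, grouping: str,
              rng: np.random.Generator,
              return_parent_groups: bool = False):
    """Draw ``S`` offspring and form the next generation's groups.

    Offspring copy their parent's alleles and deletion state.  See the module
    docstring for the ``random`` and ``kin`` regimes.  With
    ``return_parent_groups`` the parental group index of each offspring group
    (kin) or of each individual (random) is also returned, for lineage tests.
    """
    s, m, g_count = population.S, population.m, population.G
    if grouping == "random":
        q = (weights.group_probs[:, None] * weights.member_probs).ravel()
        parents = rng.choice(s, size=s, p=q)
        parent_groups = parents // m
    elif grouping == "kin":
        parent_group_of_group = rng.choice(g_count, size=g_count, p=weights.group_probs)
        w = weights.member_probs[parent_group_of_group]  # (G, m)
        cw = np.cumsum(w, axis=1)
        u = rng.random((g_count, m))
        member = np.minimum((u[:, :, None] >= cw[:, None, :]).sum(axis=2), m - 1)
        parents = (parent_group_of_group[:, None] * m + member).ravel()
        parent_groups = parent_group_of_group
    else:
        raise ValueError(f"unknown grouping mode {grouping!r}")
    offspring = Population(population.alleles[parents].copy(),
                           population.deletion_count[parents].copy(),
                           m, population.generation + 1)
    if return_parent_groups:
        return offspring, parent_groups
    return offspring


def apply_parasite_conversion(population: Population, alpha_C: float,
                              rng: np.random.Generator) -> Population:
    """Convert each helper to a parasite with probability ``alpha_C``.

    On conversion the deletion extent ``I`` is drawn uniformly from
    ``{1, ..., N}`` and the first ``I`` positions are marked deleted;
    surviving alleles are retained and parasites never revert.  Modifies and
    returns ``population``.
    """
    if alpha_C <= 0:
        return population
    helpers = population.deletion_count == 0
    convert = helpers & (rng.random(population.S) < alpha_C)
    n_new = int(convert.sum())
    if n_new:
        population.deletion_count[convert] = rng.integers(1, population.N + 1, size=n_new)
    return population


def mutate(population: Population, alpha: float, rng: np.random.Generator) -> Population:
    """Flip every non-deleted position independently with probability ``alpha``.

    Deleted positions are untouched.  Modifies and returns ``population``.
    """
    if alpha <= 0:
        return population
    flips = rng.random(population.alleles.shape) < alpha
    flips &= ~population.deleted_mask
    np.bitwise_xor(population.alleles, flips.astype(np.uint8), out=population.alleles)
    return population


def _snapshot(population: Population, config: SimulationConfig,
              weights: SelectionWeights) -> TrajectoryRecord:
    track_freqs = config.track_genotype_frequencies
    if track_freqs is None:
        track_freqs = population.N == 2
    freqs = None
    if track_freqs:
        helpers = ~population.is_parasite
        counts = np.bincount(genotype_index(population.alleles[helpers]),
                             minlength=2**population.N)
        labels = ["".join(map(str, g.tolist()))
                  for g in config.landscape.all_genotypes()]
        freqs = dict(zip(labels, (counts / population.S).tolist()))
    mean_effect = None
    if config.measure_mutation_effects:
        scan = observers.mutation_effect_scan(
            population, config.landscape, config.rule,
            uncovered_locus_policy=config.uncovered_locus_policy,
            max_groups=config.mutation_scan_max_groups)
        mean_effect = scan.mean_effect
    return TrajectoryRecord(
        generation=population.generation,
        mean_fitness=float(weights.group_fitness.mean()),
        parasite_fraction=observers.parasite_fraction(population),
        intragroup_diversity=observers.intragroup_diversity(
            population, parasite_all_positions=config.diversity_parasite_all_positions),
        mean_hamming_to_optimum=observers.mean_hamming_to_optimum(
            population, config.landscape,
            count_deleted_as_mismatch=config.hamming_count_deleted_as_mismatch),
        mean_mutation_effect=mean_effect,
        degenerate_selection=weights.degenerate,
        genotype_frequencies=freqs,
    )


def step(population: Population, config: SimulationConfig,
         rng: np.random.Generator) -> tuple[Population, TrajectoryRecord]:
    """Advance one generation; the record reflects the pre-reproduction state.

    Mean population fitness is the mean of ``f_g`` over groups; with equal
    group sizes this equals the individual-weighted mean, and for ``m = 1``
    it is the mean individual fitness of the basic model.
    """
    weights = compute_selection_weights(
        population, config.landscape, config.rule, config.beta_C,
        uncovered_locus_policy=config.uncovered_locus_policy)
    record = _snapshot(population, config, weights)
    nxt = reproduce(population, weights, config.grouping, rng)
    if config.conversion_before_mutation:
        if config.parasites_enabled:
            apply_parasite_conversion(nxt, config.alpha_C, rng)
        mutate(nxt, config.alpha, rng)
    else:
        mutate(nxt, config.alpha, rng)
        if config.parasites_enabled:
            apply_parasite_conversion(nxt, config.alpha_C, rng)
    return nxt, record


@dataclass
class RunResult:
    """Trajectory plus final state of one simulation run."""

    records: list
    final_population: Population
    config: SimulationConfig
    reached_threshold: bool
    generations_to_threshold: int  # observers.CENSORED when never crossed

    @property
    def trajectory(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.records])


def run(config: SimulationConfig) -> RunResult:
    """Run a full simulation from the founder population.

    Stops at the first recorded generation whose mean fitness strictly
    exceeds ``config.fitness_threshold``, or after ``max_generations``
    generations, whichever comes first.
    """
    rng = np.random.default_rng(config.run_seed)
    population = init_population(config, rng)
    records: list[TrajectoryRecord] = []
    reached = False
    hit_generation = observers.CENSORED
    while True:
        weights = compute_selection_weights(
            population, config.landscape, config.rule, config.beta_C,
            uncovered_locus_policy=config.uncovered_locus_policy)
        records.append(_snapshot(population, config, weights))
        if records[-1].mean_fitness > config.fitness_threshold:
            reached = True
            hit_generation = population.generation
            break
        if population.generation >= config.max_generations:
            break
        population = reproduce(population, weights, config.grouping, rng)
        if config.conversion_before_mutation:
            if config.parasites_enabled:
                apply_parasite_conversion(population, config.alpha_C, rng)
            mutate(population, config.alpha, rng)
        else:
            mutate(population, config.alpha, rng)
            if config.parasites_enabled:
                apply_parasite_conversion(population, config.alpha_C, rng)
    return RunResult(records=records, final_population=population, config=config,
                     reached_threshold=reached, generations_to_threshold=hit_generation)
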