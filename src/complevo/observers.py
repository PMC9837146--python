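"""Observers: the measured quantities of a simulation.

These functions are pure measurements on a population (plus landscape):
time-to-threshold extraction, intra-group diversity, parasite fraction,
mean Hamming distance to the global optimum, and the exhaustive single-flip
mutation fitness-effect scan.  None of them mutate the population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .group_fitness import population_group_fitness
from .landscapes import _LandscapeBase
from .population import Population

__all__ = [
    "CENSORED",
    "generations_to_threshold",
    "intragroup_diversity",
    "parasite_fraction",
    "mean_hamming_to_optimum",
    "MutationEffectScan",
    "mutation_effect_scan",
]

#: Marker returned when a trajectory never crosses the fitness threshold.
CENSORED = -1


def generations_to_threshold(trajectory, threshold: float) -> int:
    """First generation whose mean fitness strictly exceeds ``threshold``.

    ``trajectory`` is a trajectory DataFrame (or anything with ``generation``
    and ``mean_fitness`` columns).  Returns :data:`CENSORED` (-1) if the
    threshold is never crossed.
    """
    frame = pd.DataFrame(trajectory)
    if frame.empty:
        raise ValueError("trajectory is empty")
    hit = frame.loc[frame["mean_fitness"] > threshold, "generation"]
    return int(hit.iloc[0]) if len(hit) else CENSORED


def intragroup_diversity(population: Population,
                         parasite_all_positions: bool = True) -> float:
    """Mean fraction of polymorphic positions within groups.

    At each position every member carries one of three states — helper-0,
    helper-1 or parasite — and a position is polymorphic within a group when
    at least two distinct states occur.  With
    ``parasite_all_positions=False`` only a parasite's deleted positions are
    classified as the parasite state; its surviving positions count as
    helper alleles.
    """
    g, m, n = population.G, population.m, population.N
    state = population.alleles.astype(np.int8)
    if parasite_all_positions:
        state[population.is_parasite] = 2
    else:
        state[population.deleted_mask] = 2
    state = state.reshape(g, m, n)
    polymorphic = state.max(axis=1) != state.min(axis=1)
    return float(polymorphic.mean())


def parasite_fraction(population: Population) -> float:
    """Fraction of the population that is a genetic parasite."""
    return float(population.is_parasite.mean())


def mean_hamming_to_optimum(population: Population, landscape: _LandscapeBase,
                            count_deleted_as_mismatch: bool = True) -> float:
    """Mean Hamming distance from each individual to the global optimum.

    Ties for the optimum resolve to the lexicographically smallest genotype
    (with a warning).  A parasite's deleted positions count as mismatches by
    default — a deleted gene is maximally far from a functional allele —
    or can be masked out of both numerator and denominator.
    """
    f = landscape.fitness_vector
    if (f == f.max()).sum() > 1:
        warnings.warn("global optimum is not unique; using the lexicographically smallest",
                      stacklevel=2)
    opt = landscape.global_optimum
    mismatch = population.alleles != opt[None, :]
    deleted = population.deleted_mask
    if count_deleted_as_mismatch:
        mismatch = mismatch | deleted
        return float(mismatch.sum(axis=1).mean())
    mismatch = mismatch & ~deleted
    per_ind = mismatch.sum(axis=1) / np.maximum((~deleted).sum(axis=1), 1)
    return float(per_ind.mean() * population.N)


@dataclass(frozen=True)
class MutationEffectScan:
    """Result of the exhaustive single-flip fitness-effect scan."""

    generation: int
    mean_effect: float
    flip_count: int
    groups_scanned: int


def mutation_effect_scan(population: Population, landscape: _LandscapeBase,
                         rule: str, uncovered_locus_policy: str = "lethal",
                         max_groups: int | None = None) -> MutationEffectScan:
    """Average fitness effect of every possible single-allele flip.

    For each individual and each of its non-deleted positions, the allele is
    flipped, the individual's *group* fitness is recomputed, and the
    difference (after minus before) is recorded; the flip is then reverted.
    The returned mean averages over all ``sum(N - deletion_count)`` flips.
    ``max_groups`` caps the number of groups scanned (the first ``max_groups``
    groups; group order is exchangeable), recorded in the result.

    The scan is side-effect-free: the population is left bit-identical.
    """
    m, n = population.m, population.N
    if max_groups is not None and max_groups < population.G:
        sub = Population(population.alleles[: max_groups * m].copy(),
                         population.deletion_count[: max_groups * m].copy(),
                         m, population.generation)
    else:
        sub = population
    g_count = sub.G
    base = population_group_fitness(sub, landscape, rule,
                                    uncovered_locus_policy=uncovered_locus_policy)
    covered = ~sub.deleted_mask
    total = 0.0
    count = 0
    rows_base = np.arange(g_count) * m
    for k in range(m):
        rows = rows_base + k
        for locus in range(n):
            valid = covered[rows, locus]
            if not valid.any():
                continue
            flipped = sub.alleles.copy()
            flipped[rows, locus] ^= 1
            trial = Population(flipped, sub.deletion_count, m, sub.generation)
            fg = population_group_fitness(trial, landscape, rule,
                                          uncovered_locus_policy=uncovered_locus_policy)
            diff = fg - base
            total += float(diff[valid].sum())
            count += int(valid.sum())
    mean = total / count if count else 0.0
    return MutationEffectScan(generation=population.generation, mean_effect=mean,
                              flip_count=count, groups_scanned=g_count)
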