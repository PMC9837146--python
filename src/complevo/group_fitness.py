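"""Group fitness under the four genetic-complementation rules.

Trans-complementation pools gene products across the genomes co-packaged in
a group: group fitness is computed over the set of genotypes that can be
assembled by choosing, at every locus, an allele carried by *some* member
whose genome covers that locus.  ``full`` trans takes the fittest assembled
combination (one intact gene copy suffices); ``average`` trans takes the
expected fitness when each locus's allele is drawn in proportion to its
frequency among covering members (gene dosage determines the phenotype).

Cis-complementation excludes trans-action: only the actual member sequences
matter.  ``full`` cis is the fitness of the best member, ``average`` cis the
mean over all members.

Parasites (defective genomes with their first ``I`` positions deleted)
contribute alleles to trans pools only at their surviving positions, have
individual fitness 0 in cis rules, and a group consisting solely of
parasites has fitness 0.  By default a locus covered by *no* member also
nullifies group fitness — a gene product nobody encodes cannot be
complemented; the ``zero_allele`` policy instead treats such a locus as
carrying allele 0.

The module exposes both a per-group API (:func:`trans_fitness`,
:func:`cis_fitness`, ...) and the vectorized whole-population evaluator
:func:`population_group_fitness` used by the dynamics hot loop.  A direct
enumeration over all ``m**N`` member choices is kept as an independent
reference implementation (:func:`trans_fitness_bruteforce`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .landscapes import _LandscapeBase, genotype_index
from .population import Group, Population

__all__ = [
    "AllelePoolTable",
    "allele_pools",
    "trans_fitness",
    "cis_fitness",
    "trans_fitness_bruteforce",
    "member_weights",
    "group_fitness",
    "population_group_fitness",
    "population_member_weights",
]


@dataclass(frozen=True)
class AllelePoolTable:
    """Per-locus allele counts among members whose genome covers the locus."""

    count_one: np.ndarray  # (N,) members carrying allele 1 at the locus
    coverage_count: np.ndarray  # (N,) members covering (not deleted at) the locus

    @property
    def count_zero(self) -> np.ndarray:
        return self.coverage_count - self.count_one

    @property
    def freq_one(self) -> np.ndarray:
        """Frequency of allele 1 among covering members; 0 where uncovered."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(self.coverage_count > 0,
                         self.count_one / np.maximum(self.coverage_count, 1), 0.0)
        return f


def allele_pools(group: Group) -> AllelePoolTable:
    """Count alleles per locus over the group's non-deleted member positions."""
    alleles = group.alleles  # (m, N)
    covered = np.arange(group.N) >= group.deletion_counts[:, None]  # (m, N)
    return AllelePoolTable(
        count_one=(alleles * covered).sum(axis=0),
        coverage_count=covered.sum(axis=0),
    )


def _single_group_population(group: Group) -> Population:
    return Population(group.alleles, group.deletion_counts, m=group.m)


def trans_fitness(group: Group, landscape: _LandscapeBase, mode: str,
                  uncovered_locus_policy: str = "lethal") -> float:
    """Group fitness under trans-complementation (``mode`` full or average)."""
    if mode not in ("full", "average"):
        raise ValueError("mode must be 'full' or 'average'")
    rule = "full_trans" if mode == "full" else "average_trans"
    fg = population_group_fitness(_single_group_population(group), landscape, rule,
                                  uncovered_locus_policy=uncovered_locus_policy)
    return float(fg[0])


def cis_fitness(group: Group, landscape: _LandscapeBase, mode: str) -> float:
    """Group fitness under cis-complementation (``mode`` full or average).

    Parasites count as individual fitness 0; average cis averages over all
    ``m`` members including parasites.
    """
    if mode not in ("full", "average"):
        raise ValueError("mode must be 'full' or 'average'")
    rule = "full_cis" if mode == "full" else "average_cis"
    fg = population_group_fitness(_single_group_population(group), landscape, rule)
    return float(fg[0])


def trans_fitness_bruteforce(group: Group, landscape: _LandscapeBase, mode: str,
                             uncovered_locus_policy: str = "lethal") -> float:
    """Trans-complementation fitness by direct enumeration of member choices.

    Every ordered assignment of a donor member to each locus (``m**N``
    combinations) is enumerated; assignments using a deleted position are
    discarded.  ``full`` returns the maximum fitness over realizable
    combinations, ``average`` the mean with multiplicity (each surviving
    ordered assignment weighted equally), which coincides with per-locus
    frequency weighting by linearity.  Reference implementation; quadratic in
    ``m**N`` and meant for small groups.
    """
    if (group.deletion_counts > 0).all():  # parasites only
        return 0.0
    alleles = group.alleles
    covered = np.arange(group.N) >= group.deletion_counts[:, None]
    if uncovered_locus_policy == "lethal" and not covered.any(axis=0).all():
        return 0.0
    values = []
    for choice in itertools.product(range(group.m), repeat=group.N):
        g = np.empty(group.N, dtype=np.uint8)
        ok = True
        for locus, member in enumerate(choice):
            if covered[member, locus]:
                g[locus] = alleles[member, locus]
            elif uncovered_locus_policy == "zero_allele" and not covered[:, locus].any():
                g[locus] = 0
            else:
                ok = False
                break
        if ok:
            values.append(landscape.fitness_vector[genotype_index(g)])
    if not values:
        return 0.0
    return float(max(values) if mode == "full" else np.mean(values))


def member_weights(group: Group, beta_C: float) -> np.ndarray:
    """Within-group selection weights: helper 1, parasite ``beta_C``, normalized."""
    w = np.where(group.deletion_counts > 0, float(beta_C), 1.0)
    return w / w.sum()


def group_fitness(group: Group, landscape: _LandscapeBase, rule: str,
                  uncovered_locus_policy: str = "lethal") -> float:
    """Dispatch on the rule string used throughout the configuration."""
    if rule == "full_trans":
        return trans_fitness(group, landscape, "full", uncovered_locus_policy)
    if rule == "average_trans":
        return trans_fitness(group, landscape, "average", uncovered_locus_policy)
    if rule == "full_cis":
        return cis_fitness(group, landscape, "full")
    if rule == "average_cis":
        return cis_fitness(group, landscape, "average")
    if rule == "none":
        if group.m != 1:
            raise ValueError("rule 'none' requires singleton groups")
        return cis_fitness(group, landscape, "full")
    raise ValueError(f"unknown complementation rule {rule!r}")


# --- vectorized whole-population evaluation (dynamics hot path) -----------

def population_group_fitness(population: Population, landscape: _LandscapeBase,
                             rule: str,
                             uncovered_locus_policy: str = "lethal") -> np.ndarray:
    """Fitness of every group in ``population``, shape ``(G,)``.

    Equivalent group-by-group to :func:`group_fitness` but evaluated in a
    handful of array operations over all groups at once.
    """
    if rule not in ("full_trans", "average_trans", "full_cis", "average_cis", "none"):
        raise ValueError(f"unknown complementation rule {rule!r}")
    if population.N != landscape.N:
        raise ValueError(f"population genome length {population.N} does not match landscape N={landscape.N}")
    s, n = population.alleles.shape
    m, g_count = population.m, population.G
    fvec = landscape.fitness_vector
    parasite = population.is_parasite
    all_parasite = parasite.reshape(g_count, m).all(axis=1)

    if rule in ("full_cis", "average_cis", "none"):
        idx = genotype_index(population.alleles)
        fi = fvec[idx].astype(float)
        fi[parasite] = 0.0
        fi = fi.reshape(g_count, m)
        fg = fi.max(axis=1) if rule in ("full_cis", "none") else fi.mean(axis=1)
        fg[all_parasite] = 0.0
        return fg

    covered = ~population.deleted_mask  # (S, N)
    cov = covered.reshape(g_count, m, n)
    n_cov = cov.sum(axis=1)  # (G, N)
    n_one = (population.alleles.astype(np.int64) * covered).reshape(g_count, m, n).sum(axis=1)
    uncovered_any = (n_cov == 0).any(axis=1)
    genos = landscape.all_genotypes()  # (2**N, N)
    bits = genos.astype(bool)

    if rule == "full_trans":
        has_one = n_one > 0
        has_zero = n_one < n_cov
        if uncovered_locus_policy == "zero_allele":
            has_zero = has_zero | (n_cov == 0)
        feasible = np.where(bits[None, :, :], has_one[:, None, :], has_zero[:, None, :]).all(axis=2)
        fg = np.where(feasible, fvec[None, :], -np.inf).max(axis=1)
        fg[~feasible.any(axis=1)] = 0.0
        fg = np.maximum(fg, 0.0)
    else:  # average_trans
        with np.errstate(invalid="ignore", divide="ignore"):
            p_one = np.where(n_cov > 0, n_one / np.maximum(n_cov, 1), 0.0)
        weights = np.ones((g_count, genos.shape[0]))
        for locus in range(n):
            weights *= np.where(bits[None, :, locus], p_one[:, locus:locus + 1],
                                1.0 - p_one[:, locus:locus + 1])
        fg = weights @ fvec

    if uncovered_locus_policy == "lethal":
        fg[uncovered_any] = 0.0
    fg[all_parasite] = 0.0
    return fg


def population_member_weights(population: Population, beta_C: float) -> np.ndarray:
    """Normalized within-group member weights for every group, shape ``(G, m)``."""
    w = np.where(population.is_parasite, float(beta_C), 1.0).reshape(population.G, population.m)
    return w / w.sum(axis=1, keepdims=True)
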