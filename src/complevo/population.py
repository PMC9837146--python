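"""Population containers and simulation configuration.

A population holds ``S`` individuals partitioned into ``G = S / m`` groups of
equal size ``m``.  Individuals are binary haplotypes that are either *helpers*
(intact genomes) or *genetic parasites*: defective genomes whose first ``I``
positions (``1 <= I <= N``) are deleted, in the manner of defective
interfering particles.  Deleted positions retain placeholder allele values
internally, but every fitness and diversity computation masks them; the
contract, not the representation, is binding.

For speed the population is stored as flat arrays (``alleles`` with shape
``(S, N)`` and a per-individual ``deletion_count``), with group ``g``
occupying rows ``g*m`` to ``(g+1)*m - 1``.  :class:`Individual` and
:class:`Group` are lightweight views used by the per-group API and by tests.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .landscapes import Genotype, _LandscapeBase, as_genotype

__all__ = [
    "Individual",
    "Group",
    "Population",
    "SimulationConfig",
    "init_population",
    "COMPLEMENTATION_RULES",
    "GROUPING_MODES",
]

COMPLEMENTATION_RULES = ("full_trans", "average_trans", "full_cis", "average_cis", "none")
GROUPING_MODES = ("random", "kin")


@dataclass
class Individual:
    """One haplotype: allele vector plus parasite deletion extent.

    ``deletion_count == 0`` marks a helper; a parasite has its first
    ``deletion_count`` positions deleted (no usable allele there).
    """

    genotype: Genotype
    deletion_count: int = 0

    def __post_init__(self) -> None:
        self.genotype = as_genotype(self.genotype)
        n = self.genotype.size
        if not 0 <= self.deletion_count <= n:
            raise ValueError(f"deletion_count must lie in [0, {n}]")

    @property
    def is_parasite(self) -> bool:
        return self.deletion_count > 0

    @property
    def deleted_mask(self) -> np.ndarray:
        return np.arange(self.genotype.size) < self.deletion_count


@dataclass
class Group:
    """An ordered collection of ``m`` individuals sharing a group fitness."""

    members: list
    cached_fitness: float | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a group must have at least one member")
        n = {ind.genotype.size for ind in self.members}
        if len(n) != 1:
            raise ValueError("all group members must share the same genome length")

    @property
    def m(self) -> int:
        return len(self.members)

    @property
    def N(self) -> int:
        return self.members[0].genotype.size

    @property
    def alleles(self) -> np.ndarray:
        return np.stack([ind.genotype for ind in self.members])

    @property
    def deletion_counts(self) -> np.ndarray:
        return np.array([ind.deletion_count for ind in self.members])


class Population:
    """``S`` individuals in ``G = S/m`` groups, stored as flat arrays."""

    def __init__(self, alleles: np.ndarray, deletion_count: np.ndarray, m: int,
                 generation: int = 0):
        alleles = np.asarray(alleles, dtype=np.uint8)
        deletion_count = np.asarray(deletion_count, dtype=np.int64)
        if alleles.ndim != 2:
            raise ValueError("alleles must be a (S, N) matrix")
        s, n = alleles.shape
        if s % m != 0:
            raise ValueError(f"group size m={m} does not divide S={s}")
        if deletion_count.shape != (s,):
            raise ValueError("deletion_count must have one entry per individual")
        if ((deletion_count < 0) | (deletion_count > n)).any():
            raise ValueError("deletion_count out of range")
        self.alleles = alleles
        self.deletion_count = deletion_count
        self.m = int(m)
        self.generation = int(generation)

    @property
    def S(self) -> int:
        return self.alleles.shape[0]

    @property
    def N(self) -> int:
        return self.alleles.shape[1]

    @property
    def G(self) -> int:
        return self.S // self.m

    @property
    def is_parasite(self) -> np.ndarray:
        return self.deletion_count > 0

    @property
    def deleted_mask(self) -> np.ndarray:
        """(S, N) boolean mask of deleted positions (prefix deletions)."""
        return np.arange(self.N) < self.deletion_count[:, None]

    def copy(self) -> "Population":
        return Population(self.alleles.copy(), self.deletion_count.copy(),
                          self.m, self.generation)

    def group(self, g: int) -> Group:
        sl = slice(g * self.m, (g + 1) * self.m)
        return Group([Individual(self.alleles[i].copy(), int(self.deletion_count[i]))
                      for i in range(sl.start, sl.stop)])

    def groups(self) -> Iterator[Group]:
        for g in range(self.G):
            yield self.group(g)

    # --- snapshot format (tabular text, one row per individual) ----------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": np.repeat(np.arange(self.G), self.m),
            "alleles": ["".join(map(str, row.tolist())) for row in self.alleles],
            "is_parasite": self.is_parasite.astype(int),
            "deletion_count": self.deletion_count,
        })

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, m: int, generation: int = 0) -> "Population":
        alleles = np.array([[int(c) for c in s] for s in frame["alleles"]], dtype=np.uint8)
        return cls(alleles, frame["deletion_count"].to_numpy(), m, generation)

    @classmethod
    def from_csv(cls, path_or_buf, m: int, generation: int = 0) -> "Population":
        if isinstance(path_or_buf, str):
            frame = pd.read_csv(path_or_buf, dtype={"alleles": str})
        else:
            frame = pd.read_csv(io.TextIOWrapper(path_or_buf) if isinstance(path_or_buf, io.RawIOBase)
                                else path_or_buf, dtype={"alleles": str})
        return cls.from_frame(frame, m, generation)


@dataclass
class SimulationConfig:
    """All parameters of one simulation run.

    Defaults follow the canonical parameterization of the model: population
    size ``S = 10000``, per-position mutation probability ``alpha = 0.001``,
    helper-to-parasite conversion probability ``alpha_C = 0.001`` per
    generation, parasite intra-group selective advantage ``beta_C = 5``
    (helpers have weight 1), and a mean-fitness stopping threshold of 0.95
    on normalized landscapes.
    """

    landscape: _LandscapeBase
    S: int = 10_000
    m: int = 2
    alpha: float = 0.001
    alpha_C: float = 0.001
    beta_C: float = 5.0
    rule: str = "full_trans"
    grouping: str = "random"
    initial_genotype: str | Sequence[int] = "random"
    fitness_threshold: float = 0.95
    max_generations: int = 10_000
    run_seed: int = 0
    parasites_enabled: bool = True
    measure_mutation_effects: bool = False
    #: cap on groups scanned per generation by the mutation-effect observer
    mutation_scan_max_groups: int | None = None
    #: apply helper->parasite conversion before allele mutation within a generation
    conversion_before_mutation: bool = True
    #: a locus no group member covers makes group fitness 0 ("lethal");
    #: alternative "zero_allele" treats the missing gene as allele 0
    uncovered_locus_policy: str = "lethal"
    #: classify every position of a parasite as the "parasite" state in the
    #: intra-group diversity metric (False: only deleted positions)
    diversity_parasite_all_positions: bool = True
    #: count a parasite's deleted positions as mismatches to the optimum
    hamming_count_deleted_as_mismatch: bool = True
    #: record per-genotype frequencies (two-locus runs); None = auto (N == 2)
    track_genotype_frequencies: bool | None = None

    def __post_init__(self) -> None:
        if self.S <= 0 or self.m <= 0:
            raise ValueError("S and m must be positive")
        if self.S % self.m != 0:
            raise ValueError(f"group size m={self.m} must divide S={self.S}")
        if not 0.0 <= self.alpha <= 1.0 or not 0.0 <= self.alpha_C <= 1.0:
            raise ValueError("alpha and alpha_C must lie in [0, 1]")
        if self.beta_C < 1.0:
            raise ValueError("beta_C must be >= 1 (helpers have weight 1)")
        if self.rule not in COMPLEMENTATION_RULES:
            raise ValueError(f"rule must be one of {COMPLEMENTATION_RULES}; got {self.rule!r}")
        if self.grouping not in GROUPING_MODES:
            raise ValueError(f"grouping must be one of {GROUPING_MODES}; got {self.grouping!r}")
        if self.rule == "none" and self.m != 1:
            raise ValueError("rule 'none' models non-interacting sequences and requires m = 1")
        if self.uncovered_locus_policy not in ("lethal", "zero_allele"):
            raise ValueError("uncovered_locus_policy must be 'lethal' or 'zero_allele'")
        if self.max_generations < 0:
            raise ValueError("max_generations must be non-negative")
        if not isinstance(self.initial_genotype, str) or self.initial_genotype != "random":
            # eager validation of an explicit founder genotype
            as_genotype(self.initial_genotype, self.landscape.N)

    @property
    def N(self) -> int:
        return self.landscape.N

    @property
    def G(self) -> int:
        return self.S // self.m

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


def init_population(config: SimulationConfig, rng: np.random.Generator | None = None) -> Population:
    """Initial population: ``S`` helpers at the founder genotype, in ``G`` groups.

    With ``initial_genotype="random"`` a single founder genotype is drawn
    uniformly from all ``2**N`` genotypes and shared by every individual, so
    each run starts monomorphic at a random position in the landscape.
    """
    n = config.landscape.N
    if isinstance(config.initial_genotype, str) and config.initial_genotype == "random":
        if rng is None:
            rng = np.random.default_rng(config.run_seed)
        founder = rng.integers(0, 2, size=n).astype(np.uint8)
    else:
        founder = as_genotype(config.initial_genotype, n)
    alleles = np.tile(founder, (config.S, 1))
    return Population(alleles, np.zeros(config.S, dtype=np.int64), config.m, generation=0)
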