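"""Fitness landscapes over binary genotypes.

Two concrete landscape families are provided:

* :class:`TwoLocusLandscape` — an explicit fitness table over the four
  genotypes of a two-locus, two-allele system (00, 01, 10, 11), used for the
  minimal valley-crossing model.
* :class:`NKLandscape` — a random NK landscape over ``N`` binary sites in
  which the fitness contribution of each site depends on its own state and
  on the states of ``K`` randomly chosen epistatic partner sites.  ``K = 0``
  gives a purely additive landscape; ``K = N - 1`` gives an uncorrelated
  ("House of Cards") landscape.  Increasing ``K`` increases ruggedness, i.e.
  the number of local fitness peaks.

Genotypes are fixed-length 0/1 vectors.  The first element of the vector is
the first locus, which is also the most significant bit when a genotype is
rendered as a string or converted to an integer index, so the string ``"10"``
denotes allele 1 at the first locus and allele 0 at the second.

Both landscape classes expose a dense ``fitness_vector`` over all ``2**N``
genotypes (landscapes are kept exhaustively enumerable, guarded at
``N <= 20``), which is what the simulation dynamics consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Genotype",
    "as_genotype",
    "genotype_index",
    "genotype_from_index",
    "TwoLocusLandscape",
    "NKLandscape",
    "LandscapeSummary",
    "make_two_locus",
    "generate_nk",
    "genotype_fitness",
    "summarize_landscape",
    "landscape_to_json",
    "landscape_from_json",
]

#: Maximum number of sites for which exhaustive genotype enumeration is allowed.
MAX_ENUMERABLE_N = 20

Genotype = np.ndarray


def as_genotype(alleles: Sequence[int] | str | np.ndarray, n: int | None = None) -> Genotype:
    """Coerce ``alleles`` (sequence, 0/1 string, or array) to a genotype vector.

    Raises ``ValueError`` if any element is not exactly 0 or 1, or if the
    length does not match ``n`` when given.
    """
    if isinstance(alleles, str):
        alleles = [int(c) for c in alleles]
    arr = np.asarray(alleles)
    if arr.ndim != 1:
        raise ValueError("genotype must be a one-dimensional allele vector")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("genotype alleles must be exactly 0 or 1")
    if n is not None and arr.size != n:
        raise ValueError(f"genotype length {arr.size} does not match landscape N={n}")
    return arr.astype(np.uint8)


def genotype_index(alleles: np.ndarray) -> np.ndarray | int:
    """Integer index of genotype(s): first locus is the most significant bit."""
    arr = np.asarray(alleles, dtype=np.int64)
    n = arr.shape[-1]
    powers = 1 << np.arange(n - 1, -1, -1, dtype=np.int64)
    out = arr @ powers
    return int(out) if out.ndim == 0 else out

def genotype_from_index(index: int, n: int) -> Genotype:
    """Inverse of :func:`genotype_index`."""
    bits = (index >> np.arange(n - 1, -1, -1)) & 1
    return bits.astype(np.uint8)


def _all_genotypes(n: int) -> np.ndarray:
    """All 2**n genotypes as a (2**n, n) uint8 matrix, in index order."""
    idx = np.arange(2**n, dtype=np.int64)
    return ((idx[:, None] >> np.arange(n - 1, -1, -1)) & 1).astype(np.uint8)


class _LandscapeBase:
    """Shared behaviour: dense fitness vector, optimum lookup, evaluation."""

    N: int
    fitness_vector: np.ndarray  # (2**N,), read-only by convention

    @property
    def genotype_count(self) -> int:
        return 2**self.N

    def all_genotypes(self) -> np.ndarray:
        """All genotypes of this landscape, cached, shape ``(2**N, N)``."""
        cached = getattr(self, "_all_genotypes_cache", None)
        if cached is None:
            cached = _all_genotypes(self.N)
            object.__setattr__(self, "_all_genotypes_cache", cached)
        return cached

    def fitness(self, genotype: Sequence[int] | str | np.ndarray) -> float:
        g = as_genotype(genotype, self.N)
        return float(self.fitness_vector[genotype_index(g)])

    @property
    def global_optimum_index(self) -> int:
        """Index of the fittest genotype (lexicographically smallest on ties)."""
        return int(np.argmax(self.fitness_vector))

    @property
    def global_optimum(self) -> Genotype:
        return genotype_from_index(self.global_optimum_index, self.N)

    @property
    def max_fitness(self) -> float:
        return float(self.fitness_vector[self.global_optimum_index])


@dataclass(frozen=True)
class TwoLocusLandscape(_LandscapeBase):
    """Explicit fitness table over the four two-locus genotypes.

    ``fitness_table`` maps the genotype strings ``"00"``, ``"01"``, ``"10"``,
    ``"11"`` to non-negative fitness values; at least one must be positive.
    """

    fitness_table: dict
    N: int = field(default=2, init=False)

    def __post_init__(self) -> None:
        keys = {"00", "01", "10", "11"}
        if set(self.fitness_table) != keys:
            raise ValueError("fitness_table must have exactly the keys 00, 01, 10, 11")
        values = [float(self.fitness_table[k]) for k in sorted(keys)]
        if any(v < 0 for v in values):
            raise ValueError("fitness values must be non-negative")
        if all(v == 0 for v in values):
            raise ValueError("at least one fitness value must be positive")
        vec = np.array([self.fitness_table[k] for k in ("00", "01", "10", "11")], dtype=float)
        object.__setattr__(self, "fitness_vector", vec)


@dataclass(frozen=True)
class NKLandscape(_LandscapeBase):
    """Random NK landscape.

    The raw fitness of a genotype is the arithmetic mean over the ``N`` sites
    of that site's contribution, looked up in a per-site table of
    ``2**(K + 1)`` values drawn uniformly on [0, 1] and indexed by the state
    of the site itself (most significant bit) followed by the states of its
    ``K`` epistatic partner sites.  When normalized (the default), all fitness
    values are divided by the raw maximum over every genotype so the global
    optimum has fitness exactly 1.
    """

    N: int
    K: int
    neighborhoods: np.ndarray  # (N, K) int partner indices, focal site excluded
    contribution_tables: np.ndarray  # (N, 2**(K+1)) floats in [0, 1]
    seed: int | None = None
    normalization_constant: float = 1.0  # max raw fitness; 1.0 when unnormalized

    def __post_init__(self) -> None:
        if not 0 <= self.K <= self.N - 1:
            raise ValueError(f"K must lie in [0, N-1]; got K={self.K}, N={self.N}")
        nb = np.asarray(self.neighborhoods, dtype=np.int64).reshape(self.N, self.K)
        tables = np.asarray(self.contribution_tables, dtype=float).reshape(
            self.N, 2 ** (self.K + 1)
        )
        for i in range(self.N):
            row = nb[i]
            if len(set(row.tolist())) != self.K or i in row:
                raise ValueError(f"neighborhood of site {i} must be {self.K} distinct non-focal sites")
        object.__setattr__(self, "neighborhoods", nb)
        object.__setattr__(self, "contribution_tables", tables)
        object.__setattr__(self, "fitness_vector", self._enumerate())

    def _enumerate(self) -> np.ndarray:
        if self.N > MAX_ENUMERABLE_N:
            raise ValueError(f"N={self.N} exceeds the enumeration guard ({MAX_ENUMERABLE_N})")
        genos = _all_genotypes(self.N)  # (2**N, N)
        raw = np.zeros(genos.shape[0], dtype=float)
        k = self.K
        for i in range(self.N):
            # table index: focal bit first (MSB), then partner bits in order
            idx = genos[:, i].astype(np.int64) << k
            for j, p in enumerate(self.neighborhoods[i]):
                idx |= genos[:, p].astype(np.int64) << (k - 1 - j)
            raw += self.contribution_tables[i, idx]
        raw /= self.N
        return raw / self.normalization_constant

    @classmethod
    def generate(cls, N: int, K: int, seed: int, normalize: bool = True) -> "NKLandscape":
        if not 0 <= K <= N - 1:
            raise ValueError(f"K must lie in [0, N-1]; got K={K}, N={N}")
        if normalize and N > MAX_ENUMERABLE_N:
            raise ValueError(f"normalization requires exhaustive enumeration; N <= {MAX_ENUMERABLE_N}")
        rng = np.random.default_rng(seed)
        others = np.array([[j for j in range(N) if j != i] for i in range(N)])
        neighborhoods = np.empty((N, K), dtype=np.int64)
        for i in range(N):
            neighborhoods[i] = rng.choice(others[i], size=K, replace=False)
        tables = rng.random((N, 2 ** (K + 1)))
        raw = cls(N=N, K=K, neighborhoods=neighborhoods, contribution_tables=tables, seed=seed)
        if not normalize:
            return raw
        c = raw.max_fitness
        return cls(
            N=N, K=K, neighborhoods=neighborhoods, contribution_tables=tables,
            seed=seed, normalization_constant=c,
        )


@dataclass(frozen=True)
class LandscapeSummary:
    genotype_count: int
    global_optimum: str
    global_optimum_fitness: float
    local_peak_count: int


def make_two_locus(f00: float, f01: float, f10: float, f11: float) -> TwoLocusLandscape:
    """Build a two-locus landscape from the four genotype fitness values."""
    return TwoLocusLandscape({"00": f00, "01": f01, "10": f10, "11": f11})


def generate_nk(N: int, K: int, seed: int, normalize: bool = True) -> NKLandscape:
    """Generate a random NK landscape; the same seed yields the same landscape."""
    return NKLandscape.generate(N, K, seed, normalize=normalize)


def genotype_fitness(landscape: _LandscapeBase, genotype) -> float:
    """Fitness of one genotype under ``landscape`` (length-checked)."""
    return landscape.fitness(genotype)


def summarize_landscape(landscape: _LandscapeBase) -> LandscapeSummary:
    """Exhaustive characterization: optimum and strict local-peak count.

    A local peak is a genotype strictly fitter than all of its ``N``
    single-flip (Hamming-1) neighbors; a flat landscape therefore has no
    peaks under this definition.
    """
    if landscape.N > MAX_ENUMERABLE_N:
        raise ValueError(f"landscape too large to enumerate (N > {MAX_ENUMERABLE_N})")
    f = landscape.fitness_vector
    n = landscape.N
    idx = np.arange(f.size)
    is_peak = np.ones(f.size, dtype=bool)
    for b in range(n):
        is_peak &= f > f[idx ^ (1 << b)]
    opt = landscape.global_optimum
    return LandscapeSummary(
        genotype_count=f.size,
        global_optimum="".join(map(str, opt.tolist())),
        global_optimum_fitness=landscape.max_fitness,
        local_peak_count=int(is_peak.sum()),
    )


# --- serialization ---------------------------------------------------------

def landscape_to_json(landscape: _LandscapeBase) -> str:
    """Serialize a landscape to a JSON document sufficient to rebuild it exactly."""
    if isinstance(landscape, TwoLocusLandscape):
        doc = {"type": "two_locus",
               "fitness_table": {k: float(v) for k, v in landscape.fitness_table.items()}}
    elif isinstance(landscape, NKLandscape):
        doc = {
            "type": "nk",
            "N": landscape.N,
            "K": landscape.K,
            "seed": landscape.seed,
            "neighborhoods": landscape.neighborhoods.tolist(),
            "contribution_tables": landscape.contribution_tables.tolist(),
            "normalization_constant": landscape.normalization_constant,
        }
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot serialize landscape of type {type(landscape)!r}")
    return json.dumps(doc)


def landscape_from_json(text: str) -> _LandscapeBase:
    doc = json.loads(text)
    if doc["type"] == "two_locus":
        return TwoLocusLandscape(doc["fitness_table"])
    if doc["type"] == "nk":
        return NKLandscape(
            N=doc["N"], K=doc["K"],
            neighborhoods=np.array(doc["neighborhoods"], dtype=np.int64),
            contribution_tables=np.array(doc["contribution_tables"], dtype=float),
            seed=doc.get("seed"),
            normalization_constant=doc.get("normalization_constant", 1.0),
        )
    raise ValueError(f"unknown landscape type {doc.get('type')!r}")
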