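"""Genotypes, the genotype-phenotype map, Gaussian fitness, mutation and recombination.

An individual's genome has two heritable classes of genes:

* a **weight vector** ``a`` of length ``n_a`` — gene *j* has real-valued
  effect magnitude ``a_j``;
* a **contribution matrix** ``c`` of shape ``(n_traits, n_a)`` — entry
  ``c_ij`` routes the effect of weight gene *j* onto trait *i*.  Each entry
  is an independently mutating gene.

Phenotypes are the linear read-out ``z_i = sum_j c_ij * a_j``, so the amount
of pleiotropy of a weight gene is itself encoded in (and evolves through)
the contribution matrix.

Fitness is a product of independent Gaussian functions, one per trait, each
with variance one around a moving optimum: ``w(z) = exp(-sum_i
(z_i - opt_i)^2 / 2)``.  Log-fitness is additively separable across traits,
i.e. there is no correlational selection within a generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = [
    "Genotype",
    "Phenotype",
    "ModelParams",
    "compute_phenotype",
    "phenotypes",
    "fitness",
    "fitness_array",
    "mutate",
    "recombine",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the population model.

    With the defaults (``N=1000``, ``n_a=4``, ``n_traits=4``) the expected
    number of new mutations per generation (= N births) is
    ``n_a * mu_a * N = 5`` for weight genes and
    ``n_traits * n_a * mu_c * N = 5`` for contribution genes.

    Parameters
    ----------
    N
        Population size (constant over time).
    n_traits
        Number of traits under selection.
    n_a
        Number of weight genes.
    mu_a
        Mutation probability per weight gene per birth.
    mu_c
        Mutation probability per contribution gene per birth.
    mut_var
        Variance of the Gaussian mutational effect (mean zero); shared by
        both gene classes.
    sexual
        If True, reproduction draws two fitness-weighted parents and the
        offspring is assembled by free recombination before mutation.
    selection_var
        Variance of the Gaussian fitness function per trait.  The model is
        defined with this fixed at 1; it is exposed for completeness.
    selection
        If False, fitness is ignored when choosing parents (neutral Moran
        model); fitness values are still computed for reporting.
    """

    N: int = 1000
    n_traits: int = 4
    n_a: int = 4
    mu_a: float = 1.25e-3
    mu_c: float = 3.125e-4
    mut_var: float = 0.5
    sexual: bool = False
    selection_var: float = 1.0
    selection: bool = True

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.n_traits < 1 or self.n_a < 1:
            raise ValueError("n_traits and n_a must be positive")
        for name in ("mu_a", "mu_c"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mut_var <= 0:
            raise ValueError("mut_var must be positive")
        if self.selection_var <= 0:
            raise ValueError("selection_var must be positive")

    @property
    def n_genes(self) -> int:
        """Total genome size: n_a weight genes + n_traits*n_a contribution genes."""
        return self.n_a + self.n_traits * self.n_a

    def with_(self, **kw: Any) -> "ModelParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "N": self.N, "n_traits": self.n_traits, "n_a": self.n_a,
            "mu_a": self.mu_a, "mu_c": self.mu_c, "mut_var": self.mut_var,
            "sexual": self.sexual, "selection_var": self.selection_var,
            "selection": self.selection,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


@dataclass
class Genotype:
    """One individual's heritable state: weight vector ``a`` and contribution matrix ``c``."""

    a: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        self.c = np.asarray(self.c, dtype=np.float64)
        if self.a.ndim != 1:
            raise ValueError("a must be a 1-D vector")
        if self.c.ndim != 2:
            raise ValueError("c must be a 2-D matrix")
        if self.c.shape[1] != self.a.shape[0]:
            raise ValueError(
                f"dimension mismatch: a has {self.a.shape[0]} genes but "
                f"c has {self.c.shape[1]} columns"
            )
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.c))):
            raise ValueError("genotype entries must be finite")

    @property
    def n_a(self) -> int:
        return self.a.shape[0]

    @property
    def n_traits(self) -> int:
        return self.c.shape[0]

    def copy(self) -> "Genotype":
        return Genotype(self.a.copy(), self.c.copy())


@dataclass
class Phenotype:
    """Trait values of one individual."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.z.ndim != 1:
            raise ValueError("z must be a 1-D vector")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("phenotype must be finite")


def compute_phenotype(g: Genotype) -> Phenotype:
    """Map a genotype to its phenotype, ``z_i = sum_j c_ij a_j``."""
    return Phenotype(g.c @ g.a)


def phenotypes(a: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorised genotype-phenotype map for a whole population.

    Parameters
    ----------
    a
        Array of shape ``(N, n_a)``.
    c
        Array of shape ``(N, n_traits, n_a)``.

    Returns
    -------
    Array of shape ``(N, n_traits)``.
    """
    a = np.asarray(a, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    if a.shape[0] != c.shape[0] or a.shape[1] != c.shape[2]:
        raise ValueError(f"incompatible population arrays: a {a.shape}, c {c.shape}")
    return np.einsum("nij,nj->ni", c, a)


def fitness(z: Phenotype | np.ndarray, opt: np.ndarray, selection_var: float = 1.0) -> float:
    """Gaussian fitness of one phenotype around the optimum ``opt``.

    ``w = exp(-sum_i (z_i - opt_i)^2 / (2 * selection_var))`` — always in
    (0, 1], equal to 1 exactly at the optimum, and multiplicative across
    traits.
    """
    zv = z.z if isinstance(z, Phenotype) else np.asarray(z, dtype=np.float64)
    opt = np.asarray(opt, dtype=np.float64)
    if zv.shape != opt.shape:
        raise ValueError(f"phenotype and optimum lengths differ: {zv.shape} vs {opt.shape}")
    return float(np.exp(-np.sum((zv - opt) ** 2) / (2.0 * selection_var)))


def fitness_array(z: np.ndarray, opt: np.ndarray, selection_var: float = 1.0) -> np.ndarray:
    """Vectorised fitness for phenotype rows ``z`` of shape ``(N, n_traits)``."""
    z = np.asarray(z, dtype=np.float64)
    opt = np.asarray(opt, dtype=np.float64)
    if z.shape[1] != opt.shape[0]:
        raise ValueError("phenotype and optimum lengths differ")
    return np.exp(-np.sum((z - opt[None, :]) ** 2, axis=1) / (2.0 * selection_var))


def mutate(g: Genotype, params: ModelParams, rng: np.random.Generator) -> Genotype:
    """Return a mutated copy of ``g``; the input is not modified.

    Each weight gene mutates independently with probability ``mu_a`` and each
    contribution gene with probability ``mu_c``; a mutated allele is the
    parental value plus a Normal(0, mut_var) draw.
    """
    a = g.a.copy()
    c = g.c.copy()
    sd = float(np.sqrt(params.mut_var))
    hits_a = rng.random(a.shape) < params.mu_a
    n_hits = int(hits_a.sum())
    if n_hits:
        a[hits_a] += rng.normal(0.0, sd, size=n_hits)
    hits_c = rng.random(c.shape) < params.mu_c
    n_hits = int(hits_c.sum())
    if n_hits:
        c[hits_c] += rng.normal(0.0, sd, size=n_hits)
    return Genotype(a, c)


def recombine(p1: Genotype, p2: Genotype, rng: np.random.Generator) -> Genotype:
    """Free recombination: every gene comes from either parent with probability 1/2."""
    if p1.a.shape != p2.a.shape or p1.c.shape != p2.c.shape:
        raise ValueError("parents have different genome dimensions")
    take_a = rng.random(p1.a.shape) < 0.5
    take_c = rng.random(p1.c.shape) < 0.5
    return Genotype(
        np.where(take_a, p1.a, p2.a),
        np.where(take_c, p1.c, p2.c),
    )
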