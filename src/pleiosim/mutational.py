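"""Mutational variance-covariance (M-matrix) estimation by single-mutation perturbation.

The per-mutation change in trait (co)variance, M*, is estimated by sampling
individuals from a replicate's recorded snapshots, applying one mutation to
one gene, and recording the phenotype before (z) and after (z'); with
dz = z' - z,

    M*_ii = Var(dz_i) + 2 Cov(dz_i, z_i)
    M*_ij = Cov(dz_i, dz_j) + Cov(z_i, dz_j) + Cov(dz_i, z_j)

which are the exact finite-sample identities for Var(z'_i) - Var(z_i) and
Cov(z'_i, z'_j) - Cov(z_i, z_j) over the same draws.  Weight-gene (a-class)
and contribution-gene (c-class) mutations are tracked separately: only
a-genes can be pleiotropic (one a-gene feeds every trait through its column
of c), while a c-gene touches a single trait.  The total mutational matrix
weights each class by its genomic mutation supply:

    M_tot = n_a * mu_a * M*_a + (n_traits * n_a) * mu_c * M*_c

(the 4 / 16 weighting at the default gene counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import ModelParams
from .moran import SimulationRecord
from .quantgen import VCVMatrix

__all__ = [
    "MutationalMoments",
    "sample_mutational_moments",
    "total_mutational_matrix",
]


@dataclass
class MutationalMoments:
    """Per-single-mutation change in the trait (co)variance matrix for one gene class."""

    M_star: np.ndarray
    gene_class: str
    n_samples: int
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.gene_class not in ("a", "c"):
            raise ValueError("gene_class must be 'a' or 'c'")
        self.M_star = np.asarray(self.M_star, dtype=np.float64)

    def to_frame(self, replicate: int | str = "") -> pd.DataFrame:
        n = self.M_star.shape[0]
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        return pd.DataFrame(
            {
                "replicate": replicate,
                "label": "mutational",
                "gene_class": self.gene_class,
                "trait_i": i.ravel() + 1,
                "trait_j": j.ravel() + 1,
                "value": self.M_star.ravel(),
            }
        )


def _moments(z: np.ndarray, dz: np.ndarray) -> np.ndarray:
    """M* from sampled (z, dz) pairs via plain sample covariances (denominator n)."""
    n_traits = z.shape[1]
    both = np.concatenate([z, dz], axis=1)
    C = np.cov(both, rowvar=False, bias=True)
    Czz = C[:n_traits, n_traits:]          # Cov(z_i, dz_j)
    Cdd = C[n_traits:, n_traits:]          # Cov(dz_i, dz_j)
    return Cdd + Czz + Czz.T


def sample_mutational_moments(
    record: SimulationRecord,
    gene_class: str,
    n_samples: int,
    rng: np.random.Generator | None = None,
    snapshot: int | None = None,
) -> MutationalMoments:
    """Estimate M* for one gene class by perturbing sampled individuals.

    Each draw picks an individual uniformly with replacement (pooling all
    snapshots unless ``snapshot`` fixes one), picks one gene uniformly within
    the class, and adds a Normal(0, mut_var) effect to that allele.  The
    phenotype change is computed analytically from the genotype-phenotype
    map — an a_j perturbation of size d shifts z by d * c[:, j]; a c_ij
    perturbation shifts z_i by d * a_j — so the stored populations are never
    modified.
    """
    if gene_class not in ("a", "c"):
        raise ValueError("gene_class must be 'a' or 'c'")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if record.n_snapshots < 1:
        raise ValueError("record has no snapshots")
    rng = np.random.default_rng() if rng is None else rng

    if snapshot is None:
        A = record.snapshot_a.reshape(-1, record.snapshot_a.shape[-1])
        C = record.snapshot_c.reshape(-1, *record.snapshot_c.shape[-2:])
    else:
        A = record.snapshot_a[snapshot]
        C = record.snapshot_c[snapshot]
    M, n_a = A.shape
    n_traits = C.shape[1]

    idx = rng.integers(0, M, n_samples)
    a = A[idx]                      # (n, n_a)
    c = C[idx]                      # (n, n_traits, n_a)
    z = np.einsum("nij,nj->ni", c, a)
    delta = rng.normal(0.0, np.sqrt(record.params.mut_var), n_samples)

    dz = np.zeros_like(z)
    if gene_class == "a":
        j = rng.integers(0, n_a, n_samples)
        dz = c[np.arange(n_samples), :, j] * delta[:, None]
    else:
        i = rng.integers(0, n_traits, n_samples)
        j = rng.integers(0, n_a, n_samples)
        dz[np.arange(n_samples), i] = a[np.arange(n_samples), j] * delta

    prov = f"rep{record.replicate_id}/" + (
        "pooled-snapshots" if snapshot is None else f"snapshot{snapshot}"
    )
    return MutationalMoments(_moments(z, dz), gene_class, n_samples, prov)


def total_mutational_matrix(
    Ma: MutationalMoments, Mc: MutationalMoments, params: ModelParams
) -> VCVMatrix:
    """Combine per-class M* matrices into the total mutational matrix M_tot."""
    if Ma.gene_class != "a" or Mc.gene_class != "c":
        raise ValueError("expected an a-class and a c-class MutationalMoments, in that order")
    if Ma.M_star.shape != Mc.M_star.shape:
        raise ValueError("class matrices have different shapes")
    mat = params.n_a * params.mu_a * Ma.M_star + (
        params.n_traits * params.n_a
    ) * params.mu_c * Mc.M_star
    return VCVMatrix(mat, "mutational", f"{Ma.provenance}|{Mc.provenance}")
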