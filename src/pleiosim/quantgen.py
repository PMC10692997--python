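"""Genetic (co)variance estimation and its decomposition.

Three views of the trait variance-covariance structure of a population:

* **total** — the plain covariance matrix of phenotypes across individuals
  (there is no environmental noise in the model, so phenotypic variance is
  entirely genetic);
* **pleiotropy / LD** — alleles are permuted among individuals
  independently at every locus, which destroys linkage disequilibrium but
  leaves each locus's allele frequencies and effects intact; the covariance
  of the shuffled population is the pleiotropy component and the remainder
  (total minus shuffled) is the linkage-disequilibrium component;
* **additive** — for sexual populations, midparent-offspring regression:
  random couples produce recombinant (unmutated) offspring, the heritability
  of trait *i* is the OLS slope of mean-offspring on midparent, and the
  additive (co)variance is that slope times the trait's phenotypic variance.

Per-snapshot matrices are averaged over a replicate's recorded time points;
treatment comparisons use Welch two-sample t-tests on per-replicate means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import phenotypes
from .moran import Population, SimulationRecord

__all__ = [
    "VCVMatrix",
    "ReplicateSummary",
    "total_vcv",
    "shuffle_decompose",
    "additive_vcv",
    "summarize_replicate",
    "compare_treatments",
    "offdiag_mean",
    "diag_mean",
]

LABELS = ("total", "pleiotropy", "LD", "additive", "mutational")


@dataclass
class VCVMatrix:
    """A labelled traits-by-traits (co)variance matrix."""

    matrix: np.ndarray
    label: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        self.matrix = np.asarray(self.matrix, dtype=np.float64)

    @property
    def n_traits(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self, replicate: int | str = "") -> pd.DataFrame:
        """Tidy long form: one row per matrix entry."""
        n = self.n_traits
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        return pd.DataFrame(
            {
                "replicate": replicate,
                "label": self.label,
                "trait_i": i.ravel() + 1,
                "trait_j": j.ravel() + 1,
                "value": self.matrix.ravel(),
            }
        )


def offdiag_mean(m: np.ndarray) -> float:
    """Mean of the off-diagonal entries of a square matrix."""
    m = np.asarray(m)
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least 2 traits for an off-diagonal mean")
    return float((m.sum() - np.trace(m)) / (n * (n - 1)))


def diag_mean(m: np.ndarray) -> float:
    return float(np.mean(np.diag(m)))


def _pop_arrays(snapshot: Population | tuple) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(snapshot, Population):
        return snapshot.a, snapshot.c
    a, c = snapshot
    return np.asarray(a), np.asarray(c)


def total_vcv(snapshot: Population | tuple, provenance: str = "") -> VCVMatrix:
    """Total genetic variance-covariance matrix of the individuals present.

    Population covariance (denominator N) of the phenotype rows.
    """
    a, c = _pop_arrays(snapshot)
    if a.shape[0] < 2:
        raise ValueError("need at least 2 individuals for a covariance matrix")
    z = phenotypes(a, c)
    return VCVMatrix(np.cov(z, rowvar=False, bias=True), "total", provenance)


def shuffle_decompose(
    snapshot: Population | tuple,
    n_shuffles: int = 1,
    rng: np.random.Generator | None = None,
    provenance: str = "",
) -> tuple[VCVMatrix, VCVMatrix]:
    """Split the total (co)variance into pleiotropy and linkage-disequilibrium parts.

    Every locus (each weight gene and each contribution gene independently)
    is permuted among individuals; the covariance matrix of the shuffled
    population estimates the pleiotropy component, averaged over
    ``n_shuffles`` independent shuffles.  The LD component is defined as
    total minus pleiotropy, so the three matrices satisfy
    ``pleiotropy + LD = total`` exactly.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    a, c = _pop_arrays(snapshot)
    N, n_a = a.shape
    n_traits = c.shape[1]
    if N < 2:
        raise ValueError("need at least 2 individuals")

    total = total_vcv((a, c), provenance)
    acc = np.zeros((n_traits, n_traits))
    for _ in range(n_shuffles):
        sa = np.empty_like(a)
        for j in range(n_a):
            sa[:, j] = a[rng.permutation(N), j]
        sc = np.empty_like(c)
        for t in range(n_traits):
            for j in range(n_a):
                sc[:, t, j] = c[rng.permutation(N), t, j]
        z = phenotypes(sa, sc)
        acc += np.cov(z, rowvar=False, bias=True)
    pleio = acc / n_shuffles
    ld = total.matrix - pleio
    return (
        VCVMatrix(pleio, "pleiotropy", provenance),
        VCVMatrix(ld, "LD", provenance),
    )


def additive_vcv(
    snapshot: Population | tuple,
    n_pairs: int = 1000,
    n_offspring_per_pair: int = 10,
    rng: np.random.Generator | None = None,
    provenance: str = "",
    symmetrize: bool = True,
) -> tuple[VCVMatrix, np.ndarray, np.ndarray]:
    """Additive (co)variance by midparent-offspring regression.

    ``n_pairs`` couples are drawn uniformly with replacement (mate choice
    ignores fitness).  Each couple's offspring are free recombinants of the
    parental genomes, without mutation, averaged over
    ``n_offspring_per_pair`` draws.  For trait *i* the heritability is the
    OLS slope of mean-offspring trait *i* on midparent trait *i* (= V_A/V_P:
    the midparent-offspring covariance and the midparent variance each carry
    a factor 1/2) and the additive variance is that slope times the
    phenotypic variance of the trait; the (i, j) covariance entry uses the
    slope of offspring trait *j* on midparent trait *i* times the variance
    of the trait used for the midparent.

    Returns the additive :class:`VCVMatrix` (symmetrised average of the raw
    estimator by default), the raw asymmetric matrix, and the per-trait
    heritability vector.  Traits with zero midparent variance get NaN
    entries — reported as missing, never as zero.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    if n_offspring_per_pair < 1:
        raise ValueError("n_offspring_per_pair must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    a, c = _pop_arrays(snapshot)
    N, n_a = a.shape
    n_traits = c.shape[1]

    i1 = rng.integers(0, N, n_pairs)
    i2 = rng.integers(0, N, n_pairs)
    z = phenotypes(a, c)
    mid = 0.5 * (z[i1] + z[i2])

    # free recombination, vectorised over pairs x offspring
    K = n_offspring_per_pair
    mask_a = rng.random((n_pairs, K, n_a)) < 0.5
    off_a = np.where(mask_a, a[i1][:, None, :], a[i2][:, None, :])
    mask_c = rng.random((n_pairs, K, n_traits, n_a)) < 0.5
    off_c = np.where(mask_c, c[i1][:, None, :, :], c[i2][:, None, :, :])
    off_z = np.einsum("pkij,pkj->pki", off_c, off_a).mean(axis=1)  # (n_pairs, n_traits)

    var_mid = mid.var(axis=0)       # population (1/n) denominators throughout
    var_trait = z.var(axis=0)       # phenotypic variance of each trait
    raw = np.full((n_traits, n_traits), np.nan)
    h2 = np.full(n_traits, np.nan)
    # a genetically uniform trait gives var_mid ~ 0 up to rounding noise
    tiny = 100 * np.finfo(float).eps * np.maximum(1.0, (mid**2).mean(axis=0))
    ok = var_mid > tiny
    if ok.any():
        mid_c = mid - mid.mean(axis=0)
        off_c_ = off_z - off_z.mean(axis=0)
        cross = (mid_c.T @ off_c_) / n_pairs  # Cov(mid_i, off_j)
        slopes = cross[ok, :] / var_mid[ok, None]
        raw[ok, :] = slopes * var_trait[ok, None]
        h2[ok] = np.diag(cross)[ok] / var_mid[ok]
    mat = 0.5 * (raw + raw.T) if symmetrize else raw
    return VCVMatrix(mat, "additive", provenance), raw, h2


@dataclass
class ReplicateSummary:
    """Time-averaged matrices and the fitness series of one replicate."""

    replicate_id: int
    matrices: dict[str, VCVMatrix]
    mean_fitness: np.ndarray | None = None
    fitness_generations: np.ndarray | None = None
    per_snapshot: dict[str, np.ndarray] | None = None  # label -> (S, k, k)
    heritability: np.ndarray | None = None

    def matrix(self, label: str) -> np.ndarray:
        return self.matrices[label].matrix

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [m.to_frame(self.replicate_id) for m in self.matrices.values()],
            ignore_index=True,
        )


def summarize_replicate(
    record: SimulationRecord,
    *,
    n_shuffles: int = 1,
    additive: bool | None = None,
    n_pairs: int = 1000,
    n_offspring_per_pair: int = 10,
    rng: np.random.Generator | None = None,
    keep_snapshots: bool = False,
) -> ReplicateSummary:
    """Apply the estimators to every snapshot and average elementwise over time.

    The additive estimator runs only for sexual-model records (override with
    ``additive=``).
    """
    if record.n_snapshots < 1:
        raise ValueError("record has no snapshots")
    rng = np.random.default_rng() if rng is None else rng
    if additive is None:
        additive = record.params.sexual

    labels = ["total", "pleiotropy", "LD"] + (["additive"] if additive else [])
    per = {lab: [] for lab in labels}
    h2s = []
    for s in range(record.n_snapshots):
        snap = (record.snapshot_a[s], record.snapshot_c[s])
        prov = f"rep{record.replicate_id}/gen{record.snapshot_generations[s]}"
        tot = total_vcv(snap, prov)
        pleio, ld = shuffle_decompose(snap, n_shuffles, rng, prov)
        per["total"].append(tot.matrix)
        per["pleiotropy"].append(pleio.matrix)
        per["LD"].append(ld.matrix)
        if additive:
            add, _, h2 = additive_vcv(
                snap, n_pairs, n_offspring_per_pair, rng, prov
            )
            per["additive"].append(add.matrix)
            h2s.append(h2)

    prov = f"rep{record.replicate_id}/time-averaged"
    matrices = {
        lab: VCVMatrix(np.mean(np.stack(ms), axis=0), lab, prov)
        for lab, ms in per.items()
    }
    return ReplicateSummary(
        replicate_id=record.replicate_id,
        matrices=matrices,
        mean_fitness=record.mean_fitness,
        fitness_generations=record.fitness_generations,
        per_snapshot={lab: np.stack(ms) for lab, ms in per.items()} if keep_snapshots else None,
        heritability=np.nanmean(np.stack(h2s), axis=0) if h2s else None,
    )


Selector = str | tuple[int, int] | Callable[[np.ndarray], float]


def _select(matrix: np.ndarray, statistic: Selector) -> float:
    if callable(statistic):
        return float(statistic(matrix))
    if statistic == "offdiag_mean":
        return offdiag_mean(matrix)
    if statistic == "diag_mean":
        return diag_mean(matrix)
    if isinstance(statistic, tuple) and len(statistic) == 2:
        return float(matrix[statistic])
    raise ValueError(f"unknown statistic selector {statistic!r}")


def compare_treatments(
    groupA: Sequence[ReplicateSummary],
    groupB: Sequence[ReplicateSummary],
    label: str = "total",
    statistic: Selector = "offdiag_mean",
    alternative: str = "two-sided",
) -> dict:
    """Welch two-sample t-test on a matrix summary across replicates.

    Returns the t statistic, Welch degrees of freedom, p-value, group means
    and the ratio of group means (A / B).  Degenerate groups (both with zero
    variance) are reported as a failure, not a fabricated p-value.
    """
    if len(groupA) < 2 or len(groupB) < 2:
        raise ValueError("need at least 2 replicates per group")
    xa = np.array([_select(s.matrix(label), statistic) for s in groupA])
    xb = np.array([_select(s.matrix(label), statistic) for s in groupB])
    out = {
        "label": label,
        "statistic": repr(statistic),
        "n_a": len(xa),
        "n_b": len(xb),
        "mean_a": float(xa.mean()),
        "mean_b": float(xb.mean()),
        "ratio": float(xa.mean() / xb.mean()) if xb.mean() != 0 else float("nan"),
    }
    if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
        if np.allclose(xa.mean(), xb.mean()):
            # identical degenerate groups: no evidence of difference
            out.update(t=0.0, df=float(len(xa) + len(xb) - 2), p=1.0, error=None)
        else:
            out.update(t=np.nan, df=np.nan, p=np.nan,
                       error="zero within-group variance in both groups")
        return out
    res = stats.ttest_ind(xa, xb, equal_var=False, alternative=alternative)
    out.update(t=float(res.statistic), df=float(res.df), p=float(res.pvalue), error=None)
    return out
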