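"""Experiment batteries: regime comparisons, block modularity, and the
fixed-pleiotropy evolvability transplant.

The transplant assay asks whether the pleiotropy structure a population
evolved under one pattern of environmental change helps it adapt to another.
After phase 1, each replicate's contribution matrix is frozen at the modal
allele per locus (stopping further evolution of pleiotropy), the population
is copied once per test regime, and each copy evolves for phase 2 under
unbounded optima with contribution-gene mutation switched off.  Mean fitness
is recorded every ten generations and each replicate is summarised by its
mean fitness over the last tenth of phase 2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import ModelParams
from .environment import EnvironmentSpec
from .moran import Population, SimulationRecord, run_batch, run_replicate
from .mutational import MutationalMoments, sample_mutational_moments, total_mutational_matrix
from .quantgen import (
    ReplicateSummary,
    compare_treatments,
    offdiag_mean,
    summarize_replicate,
)

__all__ = [
    "ExperimentDesign",
    "FitnessTrajectory",
    "fix_pleiotropy",
    "evolvability_assay",
    "run_full_battery",
    "block_pair_means",
]

logger = logging.getLogger(__name__)

REGIMES = ("correlated", "independent", "block_correlated")


@dataclass(frozen=True)
class ExperimentDesign:
    """Scale and structure of a full experiment grid."""

    N: int = 1000
    n_traits: int = 4
    n_a: int = 4
    blocks: tuple[tuple[int, ...], ...] = ((0, 1), (2, 3))
    phase1_generations: int = 5000
    phase2_generations: int = 2000
    n_replicates: int = 500
    sexual: bool = False
    mu_a: float = 1.25e-3
    mu_c: float = 3.125e-4
    mut_var: float = 0.5
    step_size: float = 0.2
    period_generations: int = 10
    n_shuffles: int = 1
    mutational_samples: int = 1_000_000

    def __post_init__(self) -> None:
        flat = sorted(i for b in self.blocks for i in b)
        if flat != list(range(self.n_traits)):
            raise ValueError("blocks must partition the trait indices")

    @property
    def n_genes(self) -> int:
        return self.n_a + self.n_traits * self.n_a

    def params(self) -> ModelParams:
        return ModelParams(
            N=self.N, n_traits=self.n_traits, n_a=self.n_a,
            mu_a=self.mu_a, mu_c=self.mu_c, mut_var=self.mut_var,
            sexual=self.sexual,
        )

    def env(self, pattern: str, bounded: bool = True) -> EnvironmentSpec:
        return EnvironmentSpec(
            pattern=pattern,
            blocks=self.blocks if pattern == "block_correlated" else (),
            step_size=self.step_size,
            period_generations=self.period_generations,
            bounded=bounded,
        )

    @classmethod
    def full_scale(cls, **kw) -> "ExperimentDesign":
        """The full-scale design: N=1000, 5,000 + 2,000 generations, 500 replicates."""
        return cls(**kw)

    @classmethod
    def eight_trait(cls, **kw) -> "ExperimentDesign":
        """Block variant with eight traits and 72 genes (8 weight + 64 contribution)."""
        kw.setdefault("n_traits", 8)
        kw.setdefault("n_a", 8)
        kw.setdefault("blocks", ((0, 1, 2, 3), (4, 5, 6, 7)))
        return cls(**kw)

    @classmethod
    def desk_scale(cls, **kw) -> "ExperimentDesign":
        """Reduced design for a single workstation: directional, not quantitative."""
        kw.setdefault("N", 200)
        kw.setdefault("phase1_generations", 1000)
        kw.setdefault("phase2_generations", 500)
        kw.setdefault("n_replicates", 20)
        kw.setdefault("mutational_samples", 100_000)
        return cls(**kw)

    @classmethod
    def smoke(cls, **kw) -> "ExperimentDesign":
        """Minimal design that exercises every code path and table schema."""
        kw.setdefault("N", 50)
        kw.setdefault("phase1_generations", 50)
        kw.setdefault("phase2_generations", 30)
        kw.setdefault("n_replicates", 2)
        kw.setdefault("mutational_samples", 1000)
        return cls(**kw)

    def to_dict(self) -> dict:
        return {
            "N": self.N, "n_traits": self.n_traits, "n_a": self.n_a,
            "blocks": [list(b) for b in self.blocks],
            "phase1_generations": self.phase1_generations,
            "phase2_generations": self.phase2_generations,
            "n_replicates": self.n_replicates, "sexual": self.sexual,
            "mu_a": self.mu_a, "mu_c": self.mu_c, "mut_var": self.mut_var,
            "step_size": self.step_size,
            "period_generations": self.period_generations,
            "n_shuffles": self.n_shuffles,
            "mutational_samples": self.mutational_samples,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        d = dict(d)
        d["blocks"] = tuple(tuple(b) for b in d.get("blocks", ((0, 1), (2, 3))))
        return cls(**d)


@dataclass
class FitnessTrajectory:
    """Mean-fitness series of one replicate, summarised over the last tenth."""

    replicate_id: int
    generations: np.ndarray
    mean_fitness: np.ndarray

    @property
    def summary(self) -> float:
        """Mean fitness over the final 10% of the recorded series."""
        n = self.generations.shape[0]
        tail = max(1, int(round(n * 0.1)))
        return float(self.mean_fitness[-tail:].mean())


def fix_pleiotropy(population: Population) -> Population:
    """Freeze every contribution locus at its modal allele value.

    Alleles are real numbers but arise as discrete mutational lineages, so
    exact-value frequencies are meaningful.  Ties are broken in favour of
    the value carried by the lowest-indexed individual.  Weight vectors are
    untouched.  The caller is responsible for running the resulting
    population with ``mu_c = 0`` so pleiotropy stays fixed.
    """
    if population.N < 1:
        raise ValueError("population is empty")
    a = population.a.copy()
    c = population.c.copy()
    N, n_traits, n_a = c.shape
    for t in range(n_traits):
        for j in range(n_a):
            col = c[:, t, j]
            values, first, counts = np.unique(col, return_index=True, return_counts=True)
            best = counts.max()
            tied = np.flatnonzero(counts == best)
            winner = values[tied[np.argmin(first[tied])]]
            c[:, t, j] = winner
    return Population(a, c, population.optimum.copy(),
                      selection_var=population.selection_var)


def evolvability_assay(
    phase1_records: dict[str, Sequence[SimulationRecord]],
    test_regimes: dict[str, EnvironmentSpec],
    phase2_generations: int,
    master_seed: int,
    fitness_every: int = 10,
) -> dict[tuple[str, str], list[FitnessTrajectory]]:
    """3x3 (or RxT) transplant: fix pleiotropy, copy per test regime, evolve on.

    Every ancestral replicate is pleiotropy-fixed once; all its copies start
    from identical genotypes.  Phase 2 runs with ``mu_c = 0`` under the given
    (normally unbounded) test regimes from the zero optimum.
    """
    for name, spec in test_regimes.items():
        if spec.bounded:
            logger.warning("test regime %r is bounded; the transplant normally runs unbounded", name)
    seed_rng = np.random.default_rng(master_seed)
    results: dict[tuple[str, str], list[FitnessTrajectory]] = {
        (anc, test): [] for anc in phase1_records for test in test_regimes
    }
    for anc, records in phase1_records.items():
        for rec in records:
            fixed = fix_pleiotropy(rec.final_population())
            params2 = rec.params.with_(mu_c=0.0)
            n_events = phase2_generations * params2.N
            for test, spec in test_regimes.items():
                sub = int(seed_rng.integers(2**31))
                rec2 = run_replicate(
                    params2, spec, n_events, sub,
                    replicate_id=rec.replicate_id,
                    initial=fixed.copy(),
                    init_optimum=np.zeros(params2.n_traits),
                    snapshot_gens=[phase2_generations],
                    fitness_every=fitness_every,
                )
                results[(anc, test)].append(
                    FitnessTrajectory(
                        rec.replicate_id, rec2.fitness_generations, rec2.mean_fitness
                    )
                )
    return results


def block_pair_means(matrix: np.ndarray, blocks: Sequence[Sequence[int]]) -> dict:
    """Mean covariance over within-block and between-block off-diagonal pairs."""
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    block_of = {}
    for b, members in enumerate(blocks):
        for i in members:
            block_of[i] = b
    within, between = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (within if block_of[i] == block_of[j] else between).append(matrix[i, j])
    return {"within": float(np.mean(within)), "between": float(np.mean(between))}


@dataclass
class BatteryResult:
    """All outputs of one full experiment grid run."""

    design: ExperimentDesign
    seed: int
    summaries: dict[str, list[ReplicateSummary]]
    mutational: dict[str, dict[str, list[MutationalMoments]]]  # regime -> class -> reps
    fitness: dict[tuple[str, str], list[FitnessTrajectory]]
    tests: dict
    failures: dict[str, int]

    def vcv_table(self) -> pd.DataFrame:
        frames = []
        for regime, sums in self.summaries.items():
            for s in sums:
                df = s.to_frame()
                df.insert(0, "regime", regime)
                frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def mutational_table(self) -> pd.DataFrame:
        frames = []
        for regime, classes in self.mutational.items():
            for cls, reps in classes.items():
                for r, mom in enumerate(reps):
                    df = mom.to_frame(r)
                    df.insert(0, "regime", regime)
                    frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def fitness_table(self) -> pd.DataFrame:
        rows = []
        for (anc, test), trajs in self.fitness.items():
            for tr in trajs:
                for g, wbar in zip(tr.generations, tr.mean_fitness):
                    rows.append(
                        {"ancestral": anc, "test": test, "replicate": tr.replicate_id,
                         "generation": int(g), "mean_fitness": float(wbar)}
                    )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.vcv_table().to_csv(out / "vcv_matrices.csv", index=False)
        self.mutational_table().to_csv(out / "mutational_matrices.csv", index=False)
        self.fitness_table().to_csv(out / "fitness_trajectories.csv", index=False)
        with open(out / "tests.json", "w") as fh:
            json.dump(self.tests, fh, indent=2, default=float)
        with open(out / "design.json", "w") as fh:
            json.dump({"design": self.design.to_dict(), "seed": self.seed,
                       "failures": self.failures}, fh, indent=2)


def run_full_battery(
    design: ExperimentDesign,
    seed: int,
    out_dir: str | Path | None = None,
    regimes: Sequence[str] = REGIMES,
    run_evolvability: bool = True,
) -> BatteryResult:
    """Run the full grid: phase-1 batches per regime, all analyses, the transplant.

    Replicates that fail are logged and excluded with an explicit count,
    never imputed.
    """
    params = design.params()
    n_events = design.phase1_generations * design.N
    words = np.random.SeedSequence(seed).generate_state(len(regimes) + 2, np.uint64)
    regime_seeds = {r: int(s % (2**31)) for r, s in zip(regimes, words)}
    analysis_seed = int(words[-2] % (2**31))
    evo_seed = int(words[-1] % (2**31))

    records: dict[str, list[SimulationRecord]] = {}
    summaries: dict[str, list[ReplicateSummary]] = {}
    mutational: dict[str, dict[str, list[MutationalMoments]]] = {}
    failures: dict[str, int] = {}
    arng = np.random.default_rng(analysis_seed)
    for regime in regimes:
        logger.info("phase 1: %s (%d replicates x %d events)",
                    regime, design.n_replicates, n_events)
        batch = run_batch(params, design.env(regime), design.n_replicates,
                          n_events, regime_seeds[regime])
        good, sums, mut_a, mut_c = [], [], [], []
        n_fail = 0
        for rec in batch:
            try:
                sums.append(summarize_replicate(rec, n_shuffles=design.n_shuffles, rng=arng))
                mut_a.append(sample_mutational_moments(
                    rec, "a", design.mutational_samples, arng))
                mut_c.append(sample_mutational_moments(
                    rec, "c", design.mutational_samples, arng))
                good.append(rec)
            except Exception:
                n_fail += 1
                logger.exception("replicate %d in regime %s failed; excluded",
                                 rec.replicate_id, regime)
        records[regime] = good
        summaries[regime] = sums
        mutational[regime] = {"a": mut_a, "c": mut_c}
        failures[regime] = n_fail

    tests: dict = {}
    if "correlated" in summaries and "independent" in summaries:
        for label in ("total", "pleiotropy", "LD"):
            tests[f"{label}_covariance_corr_vs_indep"] = compare_treatments(
                summaries["correlated"], summaries["independent"], label, "offdiag_mean")
            tests[f"{label}_variance_corr_vs_indep"] = compare_treatments(
                summaries["correlated"], summaries["independent"], label, "diag_mean")
        for cls in ("a", "c"):
            for stat, name in ((offdiag_mean, "covariance"), (np.trace, "variance")):
                va = [float(stat(m.M_star) if stat is offdiag_mean else np.mean(np.diag(m.M_star)))
                      for m in mutational["correlated"][cls]]
                vb = [float(stat(m.M_star) if stat is offdiag_mean else np.mean(np.diag(m.M_star)))
                      for m in mutational["independent"][cls]]
                from scipy import stats as _st
                res = _st.ttest_ind(va, vb, equal_var=False)
                tests[f"mutational_{cls}_{name}_corr_vs_indep"] = {
                    "mean_a": float(np.mean(va)), "mean_b": float(np.mean(vb)),
                    "t": float(res.statistic), "p": float(res.pvalue),
                }
    if "block_correlated" in summaries:
        for label in ("total", "pleiotropy", "LD"):
            pair = [block_pair_means(s.matrix(label), design.blocks)
                    for s in summaries["block_correlated"]]
            within = np.array([p["within"] for p in pair])
            between = np.array([p["between"] for p in pair])
            from scipy import stats as _st
            res = _st.ttest_ind(within, between, equal_var=False)
            entry = {
                "within_mean": float(within.mean()), "between_mean": float(between.mean()),
                "ratio": float(within.mean() / between.mean()) if between.mean() != 0 else float("nan"),
                "t": float(res.statistic), "p": float(res.pvalue),
            }
            if "independent" in summaries:
                indep = np.array([offdiag_mean(s.matrix(label))
                                  for s in summaries["independent"]])
                r1 = _st.ttest_ind(within, indep, equal_var=False)
                r2 = _st.ttest_ind(between, indep, equal_var=False)
                entry["within_vs_independent"] = {
                    "ratio": float(within.mean() / indep.mean()) if indep.mean() != 0 else float("nan"),
                    "t": float(r1.statistic), "p": float(r1.pvalue),
                }
                entry["between_vs_independent"] = {
                    "t": float(r2.statistic), "p": float(r2.pvalue),
                }
            tests[f"{label}_block_within_vs_between"] = entry

    fitness: dict[tuple[str, str], list[FitnessTrajectory]] = {}
    if run_evolvability:
        test_specs = {r: design.env(r, bounded=False) for r in regimes}
        fitness = evolvability_assay(
            records, test_specs, design.phase2_generations, evo_seed)
        cell_means = {
            f"{anc}->{test}": float(np.mean([t.summary for t in trajs]))
            for (anc, test), trajs in fitness.items()
        }
        tests["evolvability_cell_mean_fitness"] = cell_means

    result = BatteryResult(design, int(seed), summaries, mutational, fitness,
                           tests, failures)
    if out_dir is not None:
        result.write(out_dir)
    return result
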