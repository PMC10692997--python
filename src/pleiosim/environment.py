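"""Trajectories of moving trait optima under three patterns of environmental change.

Every ``period_generations`` generations each trait optimum takes a step of
``+step_size`` or ``-step_size`` with equal probability.  The three regimes
differ only in how the steps are coupled across traits:

* ``correlated`` — one coin toss drives every trait (the optimum walks along
  the main diagonal of trait space);
* ``independent`` — one coin toss per trait;
* ``block_correlated`` — traits are partitioned into blocks; one coin toss
  per block, shared by the traits inside it.

In the bounded case the optimum lives on the lattice
``{lower, lower+step, ..., upper}``; at a boundary it stays put with
probability 1/2 and moves one step inward with probability 1/2, a "lazy
reflection" that makes the stationary distribution of the walk uniform over
the lattice.  Marginally, each trait performs the same one-dimensional walk
in all three regimes — only the cross-trait coupling differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnvironmentSpec",
    "OptimumTrajectory",
    "step_optimum",
    "make_trajectory",
    "bounded_walk_transition_matrix",
]

PATTERNS = ("correlated", "independent", "block_correlated")

_LATTICE_TOL = 1e-9


@dataclass(frozen=True)
class EnvironmentSpec:
    """How the optimum moves: coupling pattern, step size, period and bounds."""

    pattern: str = "correlated"
    blocks: tuple[tuple[int, ...], ...] = ()
    step_size: float = 0.2
    period_generations: int = 10
    bounded: bool = True
    bounds: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}, got {self.pattern!r}")
        if self.step_size < 0:
            raise ValueError("step_size must be >= 0")
        if self.period_generations < 1:
            raise ValueError("period_generations must be >= 1")
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError("bounds must satisfy lower < upper")
        if self.bounded and self.step_size > 0:
            ratio = (hi - lo) / self.step_size
            if abs(ratio - round(ratio)) > _LATTICE_TOL:
                raise ValueError(
                    "(upper - lower) must be an integer multiple of step_size "
                    "so the bounded lattice is well defined"
                )

    def trait_blocks(self, n_traits: int) -> tuple[tuple[int, ...], ...]:
        """The groups of traits whose steps share one coin toss."""
        if self.pattern == "correlated":
            return (tuple(range(n_traits)),)
        if self.pattern == "independent":
            return tuple((i,) for i in range(n_traits))
        blocks = tuple(tuple(b) for b in self.blocks)
        flat = sorted(i for b in blocks for i in b)
        if flat != list(range(n_traits)):
            raise ValueError(
                f"blocks {blocks} do not partition trait indices 0..{n_traits - 1}"
            )
        return blocks

    def to_dict(self) -> dict:
        return {
            "pattern": self.pattern,
            "blocks": [list(b) for b in self.blocks],
            "step_size": self.step_size,
            "period_generations": self.period_generations,
            "bounded": self.bounded,
            "bounds": list(self.bounds),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnvironmentSpec":
        d = dict(d)
        d["blocks"] = tuple(tuple(b) for b in d.get("blocks", ()))
        d["bounds"] = tuple(d.get("bounds", (-1.0, 1.0)))
        return cls(**d)


@dataclass
class OptimumTrajectory:
    """Pre-drawn optimum positions, one row per generation."""

    optima: np.ndarray  # (n_generations, n_traits)
    spec: EnvironmentSpec

    @property
    def n_generations(self) -> int:
        return self.optima.shape[0]

    @property
    def n_traits(self) -> int:
        return self.optima.shape[1]

    def epoch_optima(self) -> np.ndarray:
        """Optimum per environmental epoch (one row per ``period_generations`` span)."""
        p = self.spec.period_generations
        return self.optima[::p].copy()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.optima,
            columns=[f"trait_{i + 1}" for i in range(self.n_traits)],
        )
        df.insert(0, "generation", np.arange(self.n_generations))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_on_lattice(opt: np.ndarray, spec: EnvironmentSpec) -> None:
    lo, hi = spec.bounds
    if np.any(opt < lo - _LATTICE_TOL) or np.any(opt > hi + _LATTICE_TOL):
        raise ValueError(f"optimum {opt} outside bounds [{lo}, {hi}]")
    if spec.step_size > 0:
        k = (opt - lo) / spec.step_size
        if np.any(np.abs(k - np.round(k)) > 1e-6):
            raise ValueError(
                f"optimum {opt} is off the step lattice (lower={lo}, step={spec.step_size})"
            )


def step_optimum(
    opt: np.ndarray, spec: EnvironmentSpec, rng: np.random.Generator
) -> np.ndarray:
    """Apply one environmental change to ``opt`` and return the new optimum.

    One +/-``step_size`` coin toss is drawn per coupling block (all traits for
    the correlated pattern, one per trait for independent, one per declared
    block otherwise).  In bounded mode a block sitting on a boundary stays
    with probability 1/2 and moves one step inward with probability 1/2.
    """
    opt = np.asarray(opt, dtype=np.float64)
    if spec.bounded:
        _check_on_lattice(opt, spec)
    if spec.step_size == 0:
        return opt.copy()
    new = opt.copy()
    lo, hi = spec.bounds
    step = spec.step_size
    for block in spec.trait_blocks(opt.shape[0]):
        v = opt[block[0]]
        coin = rng.random() < 0.5
        if spec.bounded and v >= hi - _LATTICE_TOL:
            dv = 0.0 if coin else -step
        elif spec.bounded and v <= lo + _LATTICE_TOL:
            dv = 0.0 if coin else step
        else:
            dv = step if coin else -step
        for i in block:
            new[i] = opt[i] + dv
    if spec.bounded:
        np.clip(new, lo, hi, out=new)
    return new


def make_trajectory(
    spec: EnvironmentSpec,
    n_generations: int,
    init: np.ndarray,
    rng: np.random.Generator,
) -> OptimumTrajectory:
    """Pre-draw a full optimum trajectory, one optimum per generation.

    The optimum is ``init`` for generations ``0 .. period-1`` and changes at
    every later generation divisible by ``period_generations``.
    Deterministic given the generator state.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    init = np.asarray(init, dtype=np.float64)
    if spec.bounded:
        _check_on_lattice(init, spec)
    out = np.empty((n_generations, init.shape[0]), dtype=np.float64)
    cur = init.copy()
    for g in range(n_generations):
        if g > 0 and g % spec.period_generations == 0:
            cur = step_optimum(cur, spec, rng)
        out[g] = cur
    return OptimumTrajectory(out, spec)


def bounded_walk_transition_matrix(spec: EnvironmentSpec) -> np.ndarray:
    """Exact transition matrix of the one-trait bounded optimum walk.

    States are the lattice points ``lower, lower+step, ..., upper``.  Interior
    states move one step either way with probability 1/2; boundary states stay
    or move inward with probability 1/2 each.  The stationary distribution of
    this chain is uniform over the lattice.
    """
    if not spec.bounded or spec.step_size <= 0:
        raise ValueError("transition matrix is defined for the bounded, moving walk")
    lo, hi = spec.bounds
    n = int(round((hi - lo) / spec.step_size)) + 1
    P = np.zeros((n, n))
    for s in range(n):
        if s == 0:
            P[s, s] = 0.5
            P[s, s + 1] = 0.5
        elif s == n - 1:
            P[s, s] = 0.5
            P[s, s - 1] = 0.5
        else:
            P[s, s - 1] = 0.5
            P[s, s + 1] = 0.5
    return P
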