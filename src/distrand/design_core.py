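"""Exact allocation-probability tables for multi-intervention randomization designs.

A trial evaluates K candidate interventions at once, with each participant
receiving a subset of them:

* ``distributive`` — exactly k of the K interventions, drawn at random;
* ``capped_factorial`` — any subset of at most k interventions;
* ``full_factorial`` — any subset (independent coin per intervention);
* ``controlled_distributive`` — distributive plus an intervention-free
  control arm with a specified probability;
* ``parallel`` — classical multi-arm trial, one intervention per patient
  plus a shared control arm (1:1 between each intervention and control);
* ``separate`` — K independent two-arm trials (see
  :func:`separate_trials_tables`).

Enumerating all 2**K (or ``C(K, k)``) arms explicitly is wasteful when most
interventions are exchangeable.  Only the "interesting" interventions —
those with a presumed non-null effect and/or an unbalanced allocation
probability — need explicit combinatorial treatment; the remaining
interventions enter through the distribution of *how many* of them are
drawn.  The table therefore has one row per combination of interesting
interventions:

    p'(X_I)   product of per-intervention draw probabilities over the
              interesting subset,
    p''(X_I)  probability that the uninteresting draws complete the arm to
              a feasible total (exactly k allocations for distributive, at
              most k for capped factorial, anything for full factorial),
    p'''      = p' * p'',
    p(X_I)    = p''' normalized to sum to one.

Rows whose completion is impossible (too many or too few allocations) get
probability zero through the convention C(Y, y) = 0 for y < 0 or y > Y.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError

#: Hard cap on K; 0.5**K stays far from double-precision underflow below this.
MAX_INTERVENTIONS = 64


class DesignKind(str, Enum):
    DISTRIBUTIVE = "distributive"
    CAPPED_FACTORIAL = "capped_factorial"
    FULL_FACTORIAL = "full_factorial"
    CONTROLLED_DISTRIBUTIVE = "controlled_distributive"
    PARALLEL = "parallel"
    SEPARATE = "separate"


_NEEDS_K_PER_PATIENT = {
    DesignKind.DISTRIBUTIVE,
    DesignKind.CAPPED_FACTORIAL,
    DesignKind.CONTROLLED_DISTRIBUTIVE,
}


@dataclass(frozen=True)
class DesignSpec:
    """Declarative description of a randomization design.

    Parameters
    ----------
    kind
        One of :class:`DesignKind` (or its string value).
    K
        Number of candidate interventions (2 <= K <= 64).
    k
        Number of interventions per patient: exact for distributive /
        controlled distributive, a maximum for the capped factorial.
        Ignored (may be None) for full factorial, parallel and separate.
    alloc_probs
        Per-intervention allocation probability p_i in (0, 1); 0.5 means a
        balanced allocation.  Defaults to all 0.5.
    control_fraction
        Probability c in [0, 1) of the intervention-free arm; only
        meaningful for the controlled distributive design.
    """

    kind: DesignKind
    K: int
    k: int | None = None
    alloc_probs: tuple[float, ...] | None = None
    control_fraction: float = 0.0

    def __post_init__(self) -> None:
        kind = DesignKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if not 2 <= int(self.K) <= MAX_INTERVENTIONS:
            raise ValueError(f"K must be in [2, {MAX_INTERVENTIONS}], got {self.K}")
        object.__setattr__(self, "K", int(self.K))
        if kind in _NEEDS_K_PER_PATIENT:
            if self.k is None:
                raise ValueError(f"design kind {kind.value!r} requires k")
            if not 1 <= int(self.k) <= self.K:
                raise ValueError(f"k must satisfy 1 <= k <= K, got k={self.k}, K={self.K}")
            object.__setattr__(self, "k", int(self.k))
        if self.alloc_probs is not None:
            probs = tuple(float(p) for p in self.alloc_probs)
            if len(probs) != self.K:
                raise ValueError("alloc_probs must have length K")
            if not all(0.0 < p < 1.0 for p in probs):
                raise ValueError("alloc_probs must all lie in (0, 1)")
            object.__setattr__(self, "alloc_probs", probs)
        c = float(self.control_fraction)
        if not 0.0 <= c < 1.0:
            raise ValueError("control_fraction must lie in [0, 1)")
        if c > 0.0 and kind is not DesignKind.CONTROLLED_DISTRIBUTIVE:
            raise ValueError("control_fraction > 0 only valid for controlled_distributive")
        object.__setattr__(self, "control_fraction", c)

    @property
    def probs(self) -> np.ndarray:
        """Allocation probabilities as a length-K array (default 0.5)."""
        if self.alloc_probs is None:
            return np.full(self.K, 0.5)
        return np.asarray(self.alloc_probs, dtype=float)

    def to_dict(self) -> dict:
        d = {"kind": self.kind.value, "K": self.K}
        if self.k is not None:
            d["k"] = self.k
        if self.alloc_probs is not None:
            d["alloc_probs"] = list(self.alloc_probs)
        if self.control_fraction:
            d["control_fraction"] = self.control_fraction
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        return cls(
            kind=d["kind"],
            K=d["K"],
            k=d.get("k"),
            alloc_probs=tuple(d["alloc_probs"]) if d.get("alloc_probs") else None,
            control_fraction=d.get("control_fraction", 0.0),
        )


@dataclass(frozen=True)
class InterestingSet:
    """The interventions that need explicit combinatorial enumeration.

    ``indices`` are 1-based intervention labels (matching the X_1..X_K
    column convention); an intervention is interesting when it has a
    presumed non-null effect and/or an unbalanced allocation probability.
    """

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise ValueError("interesting indices must be unique")
        if any(i < 1 for i in idx):
            raise ValueError("interesting indices are 1-based (>= 1)")
        object.__setattr__(self, "indices", idx)

    @property
    def L(self) -> int:
        return len(self.indices)

    def validate_against(self, spec: DesignSpec) -> None:
        if any(i > spec.K for i in self.indices):
            raise ValueError("interesting indices exceed K")

    @classmethod
    def detect(cls, spec: DesignSpec, effects=None) -> "InterestingSet":
        """Automatic detection: unbalanced allocation and/or named in an
        effect rule.  ``effects`` may be an EffectSpec or None."""
        probs = spec.probs
        idx = {i + 1 for i in range(spec.K) if probs[i] != 0.5}
        if effects is not None:
            idx |= set(effects.interventions())
        return cls(tuple(sorted(idx)))


@dataclass(frozen=True)
class AllocationTable:
    """Exact per-combination allocation probabilities.

    One row per combination of interesting interventions (lexicographic,
    intervention ``interesting.indices[0]`` as the fastest-varying bit),
    plus at most one explicit control row (controlled distributive).
    The parallel design stores arms directly: one all-zero control row and
    one one-hot row per intervention (here the interesting set is all K).
    """

    spec: DesignSpec
    interesting: InterestingSet
    X: np.ndarray                      # (n_rows, L) uint8 allocation indicators
    l: np.ndarray                      # number of interesting allocations per row
    p_prime: np.ndarray
    p_dprime: np.ndarray
    p_tprime: np.ndarray
    p_final: np.ndarray
    is_control: np.ndarray             # explicit intervention-free control arm
    success_prob: np.ndarray | None = None

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def L(self) -> int:
        return self.X.shape[1]

    def with_success(self, success: np.ndarray) -> "AllocationTable":
        success = np.asarray(success, dtype=float)
        if success.shape != (self.n_rows,):
            raise ValueError("success vector length mismatch")
        return replace(self, success_prob=success)

    def row_sets(self) -> list[frozenset[int]]:
        """Allocated interesting-intervention labels per row."""
        labels = np.asarray(self.interesting.indices)
        return [frozenset(labels[self.X[r].astype(bool)]) for r in range(self.n_rows)]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"X_{i}": self.X[:, j] for j, i in enumerate(self.interesting.indices)}
        cols.update(
            l=self.l,
            p_prime=self.p_prime,
            p_dprime=self.p_dprime,
            p_tprime=self.p_tprime,
            p_final=self.p_final,
            is_control=self.is_control.astype(int),
        )
        if self.success_prob is not None:
            cols["success_prob"] = self.success_prob
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# elementary probabilities


def partial_draw_prob(X_I: Sequence[int], alloc_probs_subset: Sequence[float]) -> float:
    """Probability of drawing exactly the pattern ``X_I`` over the interesting
    interventions: prod_i [X_i p_i + (1 - X_i)(1 - p_i)].

    The empty product (L = 0) is 1.
    """
    x = np.asarray(X_I, dtype=float)
    p = np.asarray(alloc_probs_subset, dtype=float)
    if x.shape != p.shape:
        raise ValueError("X_I and alloc_probs_subset must have equal length")
    if x.size and not np.all((p > 0) & (p < 1)):
        raise ValueError("allocation probabilities must lie in (0, 1)")
    return float(np.prod(x * p + (1 - x) * (1 - p)))


def uninteresting_count_distribution(
    spec: DesignSpec, interesting: InterestingSet
) -> np.ndarray:
    """Distribution of the number of allocations among the K - L
    uninteresting interventions.

    Computed by drawing them one at a time and convolving (exact for
    arbitrary, possibly unbalanced, allocation probabilities); reduces to
    Binomial(K - L, 0.5) when all are balanced.  Returns a vector over
    counts 0..K-L summing to 1 (the empty convolution is ``[1.0]``).
    """
    interesting.validate_against(spec)
    probs = spec.probs
    others = [i for i in range(spec.K) if (i + 1) not in interesting.indices]
    dist = np.array([1.0])
    for i in others:
        p = probs[i]
        new = np.zeros(dist.size + 1)
        new[:-1] += dist * (1 - p)
        new[1:] += dist * p
        dist = new
    return dist


def completion_prob(
    l: int,
    spec: DesignSpec,
    interesting: InterestingSet,
    count_dist: np.ndarray | None = None,
) -> float:
    """Probability p''(X_I) that the uninteresting draws complete an arm
    with ``l`` interesting allocations to a feasible total.

    distributive / controlled distributive
        P(exactly k - l uninteresting allocations); 0 when k - l < 0 or
        k - l > K - L (too many or too few allocations).
    capped_factorial
        P(at most k - l uninteresting allocations).
    full_factorial
        1 (any number allowed).
    """
    L = interesting.L
    if not 0 <= l <= L <= spec.K:
        raise ValueError("need 0 <= l <= L <= K")
    kind = spec.kind
    if kind is DesignKind.FULL_FACTORIAL:
        return 1.0
    if kind not in _NEEDS_K_PER_PATIENT:
        raise ValueError(f"completion probability undefined for design kind {kind.value!r}")
    if count_dist is None:
        count_dist = uninteresting_count_distribution(spec, interesting)
    need = spec.k - l
    if kind is DesignKind.CAPPED_FACTORIAL:
        if need < 0:
            return 0.0
        return float(count_dist[: need + 1].sum())
    # exact-k designs
    if need < 0 or need > spec.K - L:
        return 0.0
    return float(count_dist[need])


# ---------------------------------------------------------------------------
# table construction


def _interesting_rows(L: int) -> np.ndarray:
    """All 2**L indicator rows, first listed intervention fastest-varying."""
    rows = np.arange(2**L)[:, None]
    bits = np.arange(L)[None, :]
    return ((rows >> bits) & 1).astype(np.uint8)


def build_allocation_table(
    spec: DesignSpec,
    interesting: InterestingSet | None = None,
    effects=None,
) -> AllocationTable:
    """Compute the exact allocation table for a design.

    ``interesting`` defaults to automatic detection from unbalanced
    allocation probabilities and (if given) the effect specification.
    Combinations whose completion is infeasible get probability zero; the
    rest are normalized so the final probabilities sum to one.  For the
    controlled distributive design the normalized rows are scaled by
    (1 - c) and an explicit control row with probability c is appended.
    """
    if spec.kind is DesignKind.SEPARATE:
        raise ValueError("separate-trials design: use separate_trials_tables()")
    if spec.kind is DesignKind.PARALLEL:
        return _parallel_table(spec)

    if interesting is None:
        interesting = InterestingSet.detect(spec, effects)
    interesting.validate_against(spec)

    L = interesting.L
    probs = spec.probs
    p_int = probs[[i - 1 for i in interesting.indices]]
    X = _interesting_rows(L)
    l = X.sum(axis=1).astype(int)
    p_prime = np.prod(X * p_int + (1 - X) * (1 - p_int), axis=1)

    if spec.kind is DesignKind.FULL_FACTORIAL:
        p_dprime = np.ones(X.shape[0])
    else:
        count_dist = uninteresting_count_distribution(spec, interesting)
        p_dprime = np.array(
            [completion_prob(int(li), spec, interesting, count_dist) for li in l]
        )
    p_tprime = p_prime * p_dprime
    total = p_tprime.sum()
    if total <= 0.0:
        raise DegenerateDesignError(
            "all combinatorial arms are infeasible for this (K, k, L)"
        )
    p_final = p_tprime / total
    is_control = np.zeros(X.shape[0], dtype=bool)

    if spec.kind is DesignKind.CONTROLLED_DISTRIBUTIVE and spec.control_fraction > 0:
        c = spec.control_fraction
        p_final = p_final * (1 - c)
        X = np.vstack([X, np.zeros((1, L), dtype=np.uint8)])
        l = np.append(l, 0)
        p_prime = np.append(p_prime, np.nan)
        p_dprime = np.append(p_dprime, np.nan)
        p_tprime = np.append(p_tprime, np.nan)
        p_final = np.append(p_final, c)
        is_control = np.append(is_control, True)

    return AllocationTable(
        spec=spec,
        interesting=interesting,
        X=X,
        l=np.asarray(l, dtype=int),
        p_prime=p_prime,
        p_dprime=p_dprime,
        p_tprime=p_tprime,
        p_final=p_final,
        is_control=is_control,
    )


def _parallel_table(spec: DesignSpec) -> AllocationTable:
    """Control arm plus one arm per intervention, all equally sized (1:1
    between each intervention and the shared control)."""
    K = spec.K
    X = np.vstack([np.zeros((1, K), dtype=np.uint8), np.eye(K, dtype=np.uint8)])
    n = K + 1
    p_final = np.full(n, 1.0 / n)
    return AllocationTable(
        spec=spec,
        interesting=InterestingSet(tuple(range(1, K + 1))),
        X=X,
        l=X.sum(axis=1).astype(int),
        p_prime=np.ones(n),
        p_dprime=np.ones(n),
        p_tprime=np.ones(n),
        p_final=p_final,
        is_control=np.concatenate([[True], np.zeros(K, dtype=bool)]),
    )


def separate_trials_tables(spec: DesignSpec) -> list[AllocationTable]:
    """K independent two-arm (intervention vs control) trials, one table each."""
    out = []
    for i in range(1, spec.K + 1):
        sub = DesignSpec(kind=DesignKind.PARALLEL, K=2, alloc_probs=None)
        out.append(_parallel_table(sub))
    return out


# ---------------------------------------------------------------------------
# marginals


def allocation_weight_given_row(table: AllocationTable, intervention: int) -> np.ndarray:
    """Per-row probability that ``intervention`` (1-based) is allocated.

    For an interesting intervention this is its indicator column; for an
    uninteresting one it is the chance of being picked by the completion
    draw given the row's number of interesting allocations (requires
    balanced uninteresting interventions, which makes them exchangeable).
    Control rows always get 0.
    """
    spec = table.spec
    if not 1 <= intervention <= spec.K:
        raise ValueError("intervention index out of range")
    if intervention in table.interesting.indices:
        pos = table.interesting.indices.index(intervention)
        w = table.X[:, pos].astype(float)
        w[table.is_control] = 0.0
        return w

    if spec.kind is DesignKind.FULL_FACTORIAL:
        return np.full(table.n_rows, spec.probs[intervention - 1])

    probs = spec.probs
    others = [i for i in range(spec.K) if (i + 1) not in table.interesting.indices]
    if any(probs[i] != 0.5 for i in others):
        raise NotImplementedError(
            "per-identity marginals for unbalanced uninteresting interventions"
        )
    U = spec.K - table.L
    w = np.zeros(table.n_rows)
    if spec.kind is DesignKind.CAPPED_FACTORIAL:
        dist = uninteresting_count_distribution(spec, table.interesting)
        for r in range(table.n_rows):
            cap = spec.k - int(table.l[r])
            if cap < 0:
                continue
            d = dist[: cap + 1]
            tot = d.sum()
            if tot > 0:
                w[r] = float((d * np.arange(d.size)).sum()) / (tot * U)
    else:  # exact-k designs
        need = spec.k - table.l.astype(float)
        w = np.clip(need, 0, U) / U
    w[table.is_control] = 0.0
    return w


def marginal_allocation_prob(table: AllocationTable, intervention: int) -> float:
    """P(intervention allocated) under the design; k/K for a balanced
    distributive design, 0.5 for a balanced full factorial, scaled by
    (1 - c) under a controlled distributive design."""
    w = allocation_weight_given_row(table, intervention)
    return float(np.sum(table.p_final * w))
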