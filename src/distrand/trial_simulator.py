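"""Virtual-trial simulation.

A trial draw proceeds in three steps: (1) patients are assigned to
combinatorial arms by a multinomial over the exact allocation table,
(2) the design matrix is completed with the uninteresting interventions
(exactly k - l of them, drawn uniformly, for the distributive design;
independent coins for the full factorial), and (3) binary outcomes are
drawn at each arm's success probability.

Two representations are provided.  :class:`TrialData` is the per-patient
N x K design matrix with an outcome vector — the natural input to a
regression analysis.  :class:`ArmExpansion` enumerates every detailed arm
(interesting combination x uninteresting completion) with its probability
and success rate, allowing a whole trial to be drawn as multinomial counts
plus binomial success counts; this is distributionally identical to the
per-patient path and much faster inside power loops.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design_core import (
    AllocationTable,
    DesignKind,
    DesignSpec,
    InterestingSet,
    build_allocation_table,
)
from .outcome_model import EffectSpec, annotate_table


@dataclass
class TrialData:
    """One simulated trial: N x K binary design matrix plus outcomes."""

    design_matrix: np.ndarray
    outcomes: np.ndarray
    spec: DesignSpec
    interesting: InterestingSet
    effects: EffectSpec | None = None
    seed: int | None = None

    @property
    def N(self) -> int:
        return self.design_matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.design_matrix,
            columns=[f"X_{i}" for i in range(1, self.spec.K + 1)],
        )
        df["Y"] = self.outcomes
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ArmExpansion:
    """Fully expanded arms over all K interventions."""

    design: np.ndarray        # (n_arms, K) uint8
    probs: np.ndarray         # sums to 1
    success: np.ndarray | None
    spec: DesignSpec

    @property
    def n_arms(self) -> int:
        return self.design.shape[0]


def _rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _uninteresting_positions(spec: DesignSpec, interesting: InterestingSet) -> list[int]:
    return [i for i in range(spec.K) if (i + 1) not in interesting.indices]


def _require_balanced_uninteresting(spec: DesignSpec, interesting: InterestingSet):
    probs = spec.probs
    others = _uninteresting_positions(spec, interesting)
    if any(probs[i] != 0.5 for i in others):
        raise NotImplementedError(
            "per-patient completion draws require balanced (p=0.5) "
            "uninteresting interventions"
        )
    return others


# ---------------------------------------------------------------------------
# per-patient path


def draw_arm_assignments(table: AllocationTable, N: int, rng):
    """Multinomial patient counts over table rows plus per-patient row labels.

    Returns ``(counts, labels)`` where ``labels`` is a length-N vector of
    table-row indices in randomized patient order.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = _rng(rng)
    counts = rng.multinomial(N, table.p_final)
    labels = np.repeat(np.arange(table.n_rows), counts)
    return counts, rng.permutation(labels)


def complete_design_matrix(
    labels: np.ndarray,
    table: AllocationTable,
    rng,
) -> np.ndarray:
    """Expand per-patient row labels to a full N x K design matrix.

    Distributive / controlled distributive: a uniform random subset of
    k - l uninteresting interventions per patient; full factorial:
    independent Bernoulli(p_i) per uninteresting intervention; parallel:
    nothing to complete.  Control-arm patients get all zeros.  The capped
    factorial has no completion algorithm (its simulations would need a
    two-stage count-then-identity draw) and raises NotImplementedError.
    """
    spec = table.spec
    if spec.kind is DesignKind.CAPPED_FACTORIAL:
        raise NotImplementedError(
            "design-matrix completion is not defined for the capped factorial"
        )
    rng = _rng(rng)
    N = labels.shape[0]
    X = np.zeros((N, spec.K), dtype=np.uint8)
    int_pos = [i - 1 for i in table.interesting.indices]
    X[:, int_pos] = table.X[labels]
    X[table.is_control[labels]] = 0

    if spec.kind is DesignKind.PARALLEL:
        return X

    others = _uninteresting_positions(spec, table.interesting)
    if not others:
        return X
    if spec.kind is DesignKind.FULL_FACTORIAL:
        p = spec.probs[others]
        X[:, others] = (rng.random((N, len(others))) < p).astype(np.uint8)
        return X

    # exact-k completion: uniform subset of size k - l, grouped by l
    _require_balanced_uninteresting(spec, table.interesting)
    others = np.asarray(others)
    need = spec.k - table.l[labels]
    need[table.is_control[labels]] = 0
    for c in np.unique(need):
        if c <= 0:
            continue
        rows = np.nonzero(need == c)[0]
        # rank a uniform matrix: the c smallest per row form a uniform subset
        u = rng.random((rows.size, others.size))
        picked = np.argpartition(u, c - 1, axis=1)[:, :c]
        X[rows[:, None], others[picked]] = 1
    return X


def draw_outcomes(success_probs: np.ndarray, rng) -> np.ndarray:
    """Independent Bernoulli outcomes at each patient's success probability."""
    rng = _rng(rng)
    success_probs = np.asarray(success_probs, dtype=float)
    return (rng.random(success_probs.shape) < success_probs).astype(np.uint8)


def simulate_trial(
    spec: DesignSpec,
    interesting: InterestingSet | None,
    effects: EffectSpec,
    N: int,
    rng,
    table: AllocationTable | None = None,
) -> TrialData:
    """Draw one complete virtual trial (assignments, completion, outcomes)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = _rng(rng)
    if table is None:
        table = build_allocation_table(spec, interesting, effects)
        table = annotate_table(table, effects)
    elif table.success_prob is None:
        table = annotate_table(table, effects)
    counts, labels = draw_arm_assignments(table, N, rng)
    X = complete_design_matrix(labels, table, rng)
    y = draw_outcomes(table.success_prob[labels], rng)
    if spec.kind in (DesignKind.DISTRIBUTIVE, DesignKind.CONTROLLED_DISTRIBUTIVE):
        sums = X.sum(axis=1)
        ctrl = table.is_control[labels]
        assert np.all(sums[~ctrl] == spec.k) and np.all(sums[ctrl] == 0)
    return TrialData(
        design_matrix=X,
        outcomes=y,
        spec=spec,
        interesting=table.interesting,
        effects=effects,
    )


# ---------------------------------------------------------------------------
# aggregated (arm-level) path


def expand_arms(table: AllocationTable, max_arms: int = 500_000) -> ArmExpansion:
    """Enumerate every detailed arm over all K interventions.

    Each interesting-combination row is split across its equiprobable
    uninteresting completions (balanced case).  Raises NotImplementedError
    for unbalanced uninteresting interventions and ValueError when the
    expansion would exceed ``max_arms``.
    """
    spec = table.spec
    if spec.kind is DesignKind.CAPPED_FACTORIAL:
        raise NotImplementedError("no completion algorithm for the capped factorial")
    K = spec.K
    int_pos = [i - 1 for i in table.interesting.indices]

    if spec.kind is DesignKind.PARALLEL:
        return ArmExpansion(
            design=table.X.copy(),
            probs=table.p_final.copy(),
            success=None if table.success_prob is None else table.success_prob.copy(),
            spec=spec,
        )

    others = _uninteresting_positions(spec, table.interesting)
    rows_design: list[np.ndarray] = []
    rows_p: list[float] = []
    rows_s: list[float] = []
    has_s = table.success_prob is not None

    if spec.kind is DesignKind.FULL_FACTORIAL:
        n_sub = 2 ** len(others)
        if table.n_rows * n_sub > max_arms:
            raise ValueError("full factorial expansion too large; use the per-patient path")
        p_oth = spec.probs[others]
        subsets = list(itertools.product((0, 1), repeat=len(others)))
        for r in range(table.n_rows):
            base = np.zeros(K, dtype=np.uint8)
            base[int_pos] = table.X[r]
            for sub in subsets:
                arm = base.copy()
                arm[others] = sub
                w = float(np.prod([p if b else 1 - p for b, p in zip(sub, p_oth)]))
                rows_design.append(arm)
                rows_p.append(table.p_final[r] * w)
                if has_s:
                    rows_s.append(table.success_prob[r])
    else:
        _require_balanced_uninteresting(spec, table.interesting)
        for r in range(table.n_rows):
            base = np.zeros(K, dtype=np.uint8)
            if not table.is_control[r]:
                base[int_pos] = table.X[r]
            if table.is_control[r] or not others:
                rows_design.append(base)
                rows_p.append(float(table.p_final[r]))
                if has_s:
                    rows_s.append(table.success_prob[r])
                continue
            need = spec.k - int(table.l[r])
            if need < 0 or need > len(others) or table.p_final[r] == 0.0:
                continue
            from math import comb

            n_comb = comb(len(others), need)
            if len(rows_design) + n_comb > max_arms:
                raise ValueError("arm expansion too large; use the per-patient path")
            share = float(table.p_final[r]) / n_comb
            for sub in itertools.combinations(others, need):
                arm = base.copy()
                arm[list(sub)] = 1
                rows_design.append(arm)
                rows_p.append(share)
                if has_s:
                    rows_s.append(table.success_prob[r])

    probs = np.asarray(rows_p)
    return ArmExpansion(
        design=np.asarray(rows_design, dtype=np.uint8),
        probs=probs / probs.sum(),
        success=np.asarray(rows_s) if has_s else None,
        spec=spec,
    )


def simulate_arm_counts(expansion: ArmExpansion, N: int, rng):
    """Draw one trial at the arm level: ``(patient counts, success counts)``."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if expansion.success is None:
        raise ValueError("expansion has no success probabilities")
    rng = _rng(rng)
    counts = rng.multinomial(N, expansion.probs)
    successes = rng.binomial(counts, expansion.success)
    return counts, successes
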