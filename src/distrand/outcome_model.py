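"""Clinical-success probabilities for intervention combinations.

Effects are declared as an explicit, prioritized rule list: a baseline
success probability for patients receiving no effective intervention, plus
rules mapping specific combinations to success probabilities.  Larger
combinations take precedence (a rule for {1, 2} overrides the rule for {1}
in any arm containing both), mirroring how interaction assumptions are
written down when planning a trial.  Only "interesting" interventions may
carry effects; the rest are null by definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .design_core import AllocationTable, allocation_weight_given_row
from .errors import AmbiguousEffectError, UndefinedContrastError


@dataclass(frozen=True)
class EffectSpec:
    """Baseline success probability plus ordered combination rules.

    ``rules`` is a sequence of ``(combination, success_prob)`` pairs, where a
    combination is a set of 1-based intervention labels.  Rule resolution
    picks the largest matching combination; among equally large matches the
    earliest-listed wins, but conflicting values among equal-size matches
    raise :class:`AmbiguousEffectError` (ambiguity is a specification error,
    not a silent choice).
    """

    baseline: float = 0.5
    rules: tuple[tuple[frozenset, float], ...] = ()

    def __post_init__(self) -> None:
        b = float(self.baseline)
        if not 0.0 < b < 1.0:
            raise ValueError("baseline must lie in (0, 1)")
        object.__setattr__(self, "baseline", b)
        norm = []
        seen = set()
        for combo, p in self.rules:
            combo = frozenset(int(i) for i in combo)
            if not combo:
                raise ValueError("effect rule combinations must be non-empty")
            if any(i < 1 for i in combo):
                raise ValueError("intervention labels are 1-based")
            if combo in seen:
                raise ValueError(f"duplicate rule for combination {sorted(combo)}")
            seen.add(combo)
            p = float(p)
            if not 0.0 < p < 1.0:
                raise ValueError("success probabilities must lie in (0, 1)")
            norm.append((combo, p))
        object.__setattr__(self, "rules", tuple(norm))

    def interventions(self) -> tuple[int, ...]:
        """All intervention labels named by any rule."""
        out: set[int] = set()
        for combo, _ in self.rules:
            out |= combo
        return tuple(sorted(out))

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline,
            "rules": [{"combo": sorted(c), "p": p} for c, p in self.rules],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EffectSpec":
        rules = tuple(
            (frozenset(r["combo"]), r["p"]) for r in d.get("rules", [])
        )
        return cls(baseline=d.get("baseline", 0.5), rules=rules)


def resolve_success_prob(allocated, effects: EffectSpec) -> float:
    """Success probability of an arm given the set of allocated interesting
    interventions, by the priority rule (largest matching combination wins;
    baseline when nothing matches)."""
    allocated = frozenset(int(i) for i in allocated)
    matches = [(combo, p) for combo, p in effects.rules if combo <= allocated]
    if not matches:
        return effects.baseline
    top_size = max(len(c) for c, _ in matches)
    top = [(c, p) for c, p in matches if len(c) == top_size]
    values = {p for _, p in top}
    if len(values) > 1:
        raise AmbiguousEffectError(
            f"arm {sorted(allocated)}: same-size rules "
            f"{[sorted(c) for c, _ in top]} give conflicting values {sorted(values)}"
        )
    return top[0][1]


def logit_additive_combo(p1: float, p2: float) -> float:
    """Combine two standalone success probabilities additively on the logit
    scale relative to a 50% baseline: expit(logit(p1) + logit(p2)).

    0.5 is the identity (a null effect); the operation is commutative.
    """
    for p in (p1, p2):
        if not 0.0 < p < 1.0:
            raise ValueError("probabilities must lie strictly in (0, 1)")
    return float(expit(logit(p1) + logit(p2)))


def annotate_table(table: AllocationTable, effects: EffectSpec) -> AllocationTable:
    """Attach a success probability to every table row.

    Rules may only reference interventions in the table's interesting set
    (uninteresting interventions have no effect by definition).  The
    explicit control row gets the baseline.
    """
    named = set(effects.interventions())
    avail = set(table.interesting.indices)
    if not named <= avail:
        raise ValueError(
            f"effect rules reference interventions {sorted(named - avail)} "
            "outside the interesting set"
        )
    success = np.empty(table.n_rows)
    for r, allocated in enumerate(table.row_sets()):
        if table.is_control[r]:
            success[r] = effects.baseline
        else:
            success[r] = resolve_success_prob(allocated, effects)
    return table.with_success(success)


def overall_success_rate(table: AllocationTable) -> float:
    """Law-of-total-probability success rate: sum of p(X_I) * success."""
    if table.success_prob is None:
        raise ValueError("table has no success probabilities attached")
    return float(np.sum(table.p_final * table.success_prob))


def marginal_success_rates(
    table: AllocationTable, intervention: int | None = None
):
    """Success rate among receivers and non-receivers of an intervention.

    These are the p_I and p_C of the closed-form two-proportion sample-size
    formula under a pooled analysis.  With ``intervention=None`` a dict over
    all K interventions is returned.  Raises
    :class:`UndefinedContrastError` when an intervention is never or always
    allocated.
    """
    if table.success_prob is None:
        raise ValueError("annotate the table with effects first")
    if intervention is None:
        return {
            i: marginal_success_rates(table, i)
            for i in range(1, table.spec.K + 1)
        }
    w = allocation_weight_given_row(table, intervention)
    p = table.p_final
    s = table.success_prob
    m_in = float(np.sum(p * w))
    m_out = float(np.sum(p * (1 - w)))
    if m_in <= 0.0 or m_out <= 0.0:
        raise UndefinedContrastError(
            f"intervention {intervention} is never or always allocated"
        )
    p_i = float(np.sum(p * w * s)) / m_in
    p_c = float(np.sum(p * (1 - w) * s)) / m_out
    return p_i, p_c
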