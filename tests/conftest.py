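"""Shared fixtures and independent brute-force oracles.

The oracle enumerates every admissible arm over all K interventions with
weight prod_i [X_i p_i + (1 - X_i)(1 - p_i)], then marginalizes onto the
interesting combinations — deliberately ignorant of the reduced p'/p''
factorization it is used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from distrand import DesignKind, DesignSpec, InterestingSet


def brute_force_interesting_probs(
    spec: DesignSpec, interesting: InterestingSet
) -> np.ndarray:
    """Exact interesting-combination probabilities by full enumeration.

    Returns a vector aligned with the allocation-table row order (first
    listed interesting intervention = fastest-varying bit); for the
    controlled distributive design the explicit control arm is appended
    last.
    """
    K, probs = spec.K, spec.probs
    kind = spec.kind
    if kind in (DesignKind.DISTRIBUTIVE, DesignKind.CONTROLLED_DISTRIBUTIVE):
        arms = itertools.combinations(range(K), spec.k)
        arms = [frozenset(a) for a in arms]
    elif kind is DesignKind.CAPPED_FACTORIAL:
        arms = [
            frozenset(a)
            for size in range(spec.k + 1)
            for a in itertools.combinations(range(K), size)
        ]
    elif kind is DesignKind.FULL_FACTORIAL:
        arms = [
            frozenset(a)
            for size in range(K + 1)
            for a in itertools.combinations(range(K), size)
        ]
    else:
        raise ValueError(kind)

    L = interesting.L
    pos = [i - 1 for i in interesting.indices]
    out = np.zeros(2**L)
    for arm in arms:
        w = 1.0
        for i in range(K):
            w *= probs[i] if i in arm else 1 - probs[i]
        key = sum((1 << j) for j, p in enumerate(pos) if p in arm)
        out[key] += w
    out /= out.sum()
    if kind is DesignKind.CONTROLLED_DISTRIBUTIVE and spec.control_fraction > 0:
        out = np.append(out * (1 - spec.control_fraction), spec.control_fraction)
    return out


def brute_force_marginal(spec: DesignSpec, intervention: int) -> float:
    """P(intervention allocated) by full enumeration."""
    K, probs = spec.K, spec.probs
    if spec.kind in (DesignKind.DISTRIBUTIVE, DesignKind.CONTROLLED_DISTRIBUTIVE):
        arms = [frozenset(a) for a in itertools.combinations(range(K), spec.k)]
    elif spec.kind is DesignKind.CAPPED_FACTORIAL:
        arms = [
            frozenset(a)
            for size in range(spec.k + 1)
            for a in itertools.combinations(range(K), size)
        ]
    else:
        raise ValueError(spec.kind)
    tot = hit = 0.0
    for arm in arms:
        w = 1.0
        for i in range(K):
            w *= probs[i] if i in arm else 1 - probs[i]
        tot += w
        if intervention - 1 in arm:
            hit += w
    m = hit / tot
    if spec.kind is DesignKind.CONTROLLED_DISTRIBUTIVE:
        m *= 1 - spec.control_fraction
    return m


@pytest.fixture
def rng():
    return np.random.default_rng(20240311)
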