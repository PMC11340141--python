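"""Trial analysis: pooled proportion tests and logistic Wald tests.

Each candidate intervention is tested through either

* a pooled difference of proportions — all receivers versus all
  non-receivers, accepting a small bias from co-interventions — or
* the Wald test of its main-effect coefficient in a multivariate logistic
  regression logit P(Y=1) = a + b_1 X_1 + ... + b_K X_K, optionally
  adjusted with two-way interaction terms.

Interaction-adjustment strategies (``interaction_strategy``):

``none``
    main effects only.
``prespecified``
    listed product terms always retained; conclusions are drawn on main
    effects only.
``gated``
    the pre-specified term(s) are kept only if significant at
    ``gate_threshold`` (raw, unadjusted gate), otherwise the model is
    refit without them.
``backward_tested``
    per tested intervention, start from all two-way terms involving it and
    iteratively drop the worst-p term above ``elimination_threshold``
    (one term per refit, worst first).
``backward_all``
    as above but starting from all two-way terms among all interventions;
    a single final model serves every main-effect test.

Multiplicity is controlled by Bonferroni on the alpha threshold (divided
by the number of main-effect tests, K by default; never by the number of
interaction terms).  A model that fails to converge yields p = 1 for its
tests, and a term with an absurd standard error (> 100 on the logit
scale, quasi-separation) yields p = 1 for that term: conservative
non-discovery rather than a spurious rejection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design_core import DesignSpec
from .errors import RankDeficientModelError, UndefinedContrastError
from .trial_simulator import ArmExpansion, TrialData

#: logit-scale standard error beyond which a Wald test is treated as
#: quasi-separated and returns p = 1.
SE_ABSURD = 100.0

Term = int | tuple[int, int]


@dataclass(frozen=True)
class AnalysisSpec:
    """How a trial is analyzed."""

    test: str = "logistic"                    # "logistic" | "pooled_prop_diff"
    sidedness: str = "two_sided"              # "two_sided" | "one_sided"
    alpha: float = 0.05
    n_tests: int | None = None                # Bonferroni divisor; defaults to K
    interaction_strategy: str = "none"
    interaction_pairs: tuple[tuple[int, int], ...] = ()
    gate_threshold: float = 0.05
    elimination_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.test not in ("logistic", "pooled_prop_diff"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.sidedness not in ("two_sided", "one_sided"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.gate_threshold < 1.0:
            raise ValueError("gate_threshold must lie in (0, 1)")
        # elimination_threshold = 1 means "retain all" (no elimination step)
        if not 0.0 < self.elimination_threshold <= 1.0:
            raise ValueError("elimination_threshold must lie in (0, 1]")
        if self.interaction_strategy not in (
            "none",
            "prespecified",
            "gated",
            "backward_tested",
            "backward_all",
        ):
            raise ValueError(
                f"unknown interaction strategy {self.interaction_strategy!r}"
            )
        pairs = tuple(
            (min(int(a), int(b)), max(int(a), int(b)))
            for a, b in self.interaction_pairs
        )
        if any(a == b for a, b in pairs):
            raise ValueError("interaction pairs must involve two distinct interventions")
        object.__setattr__(self, "interaction_pairs", pairs)

    def adjusted_alpha(self, K: int) -> float:
        return bonferroni_alpha(self.alpha, self.n_tests if self.n_tests else K)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisSpec":
        d = dict(d)
        if "interaction_pairs" in d:
            d["interaction_pairs"] = tuple(tuple(p) for p in d["interaction_pairs"])
        return cls(**d)


@dataclass
class TestResult:
    """Per-intervention test outcomes plus model diagnostics."""

    table: pd.DataFrame      # intervention, estimate, statistic, p, significant, ...
    alpha_adjusted: float
    spec: AnalysisSpec

    def significant_set(self) -> set[int]:
        return set(self.table.loc[self.table["significant"], "intervention"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted threshold: alpha divided by the number of tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# aggregated trial representation


@dataclass
class AggregatedTrial:
    """Binomial aggregation of a trial over unique covariate rows."""

    arms: np.ndarray          # (n_rows, K) uint8
    counts: np.ndarray
    successes: np.ndarray

    @property
    def K(self) -> int:
        return self.arms.shape[1]

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_trial(cls, trial: TrialData) -> "AggregatedTrial":
        X = np.ascontiguousarray(trial.design_matrix)
        arms, inverse = np.unique(X, axis=0, return_inverse=True)
        counts = np.bincount(inverse, minlength=arms.shape[0])
        succ = np.bincount(
            inverse, weights=trial.outcomes, minlength=arms.shape[0]
        ).astype(int)
        return cls(arms=arms.astype(np.uint8), counts=counts, successes=succ)

    @classmethod
    def from_counts(cls, expansion: ArmExpansion, counts, successes) -> "AggregatedTrial":
        keep = counts > 0
        return cls(
            arms=expansion.design[keep],
            counts=np.asarray(counts)[keep],
            successes=np.asarray(successes)[keep],
        )


def _as_aggregated(trial) -> AggregatedTrial:
    if isinstance(trial, AggregatedTrial):
        return trial
    return AggregatedTrial.from_trial(trial)


# ---------------------------------------------------------------------------
# core logistic machinery


def _exog(agg: AggregatedTrial, terms: Sequence[Term]) -> np.ndarray:
    cols = [np.ones(agg.arms.shape[0])]
    for t in terms:
        if isinstance(t, tuple):
            a, b = t
            cols.append((agg.arms[:, a - 1] * agg.arms[:, b - 1]).astype(float))
        else:
            cols.append(agg.arms[:, t - 1].astype(float))
    return np.column_stack(cols)


def _glm_fit(exog: np.ndarray, successes: np.ndarray, counts: np.ndarray):
    """IRLS binomial fit; returns the results object or None on failure."""
    endog = np.column_stack([successes, counts - successes])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(maxiter=100)
    except Exception:
        return None
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        return None
    return res


def _independent_cols(exog: np.ndarray) -> np.ndarray:
    """Earliest-first maximal set of linearly independent columns.

    Exact-k designs are intrinsically aliased (the K allocation columns sum
    to the constant k, and the two-way products to C(k, 2)), so later
    dependent columns are dropped deterministically — the same resolution
    R's glm applies when it reports NA coefficients.  Unpivoted QR leaves a
    (near-)zero diagonal entry exactly at columns dependent on earlier ones.
    """
    _, R = np.linalg.qr(exog)
    diag = np.abs(np.diag(R))
    tol = max(exog.shape) * np.finfo(float).eps * max(diag.max(), 1.0)
    keep = diag > tol
    if exog.shape[1] > R.shape[0]:  # more columns than rows: rest dependent
        keep = np.concatenate([keep, np.zeros(exog.shape[1] - R.shape[0], bool)])
    keep[0] = True  # the intercept is always retained
    return keep


def fit_logistic(trial, terms: Sequence[Term]) -> pd.DataFrame:
    """Maximum-likelihood logistic fit with Wald statistics per term.

    ``terms`` lists main effects (1-based intervention labels) and product
    terms (pairs).  Returns a DataFrame with columns term, estimate, se,
    z, p (two-sided) and a ``converged`` attribute in ``df.attrs``.
    Rank-deficient designs raise :class:`RankDeficientModelError`;
    non-convergence and quasi-separation are flagged, never silent.
    """
    terms = list(terms)
    if len(set(terms)) != len(terms):
        raise RankDeficientModelError("duplicate model terms requested")
    agg = _as_aggregated(trial)
    if agg.N <= len(terms) + 1:
        raise ValueError("more model terms than observations")
    fit = _fit_terms(agg, terms)
    names = ["intercept"] + [str(t) for t in terms]
    df = pd.DataFrame(
        {
            "term": names,
            "estimate": fit.estimate,
            "se": fit.se,
            "z": fit.z,
            "p": fit.p_two,
            "aliased": ~fit.estimable,
        }
    )
    df.attrs["converged"] = fit.converged
    return df


@dataclass
class _ModelFit:
    """Internal: one fitted model, indexed by term.  Aliased (structurally
    non-estimable) terms carry NaN estimates and p = 1."""

    terms: list[Term]
    estimate: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p_two: np.ndarray
    estimable: np.ndarray
    converged: bool

    def entry(self, term: Term):
        i = self.terms.index(term) + 1  # offset for intercept
        return self.estimate[i], self.se[i], self.z[i], self.p_two[i]


def _fit_terms(agg: AggregatedTrial, terms: list[Term]) -> _ModelFit:
    exog = _exog(agg, terms)
    keep = _independent_cols(exog)
    res = _glm_fit(exog[:, keep], agg.successes, agg.counts)
    n = len(terms) + 1
    est = np.full(n, np.nan)
    se = np.full(n, np.nan)
    z = np.full(n, np.nan)
    p = np.ones(n)
    if res is None:
        return _ModelFit(terms, est, se, z, p, keep, False)
    z_k = res.params / res.bse
    p_k = 2 * stats.norm.sf(np.abs(z_k))
    p_k = np.where(res.bse > SE_ABSURD, 1.0, p_k)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        p_k = np.ones_like(p_k)
    est[keep], se[keep], z[keep], p[keep] = res.params, res.bse, z_k, p_k
    return _ModelFit(terms, est, se, z, p, keep, converged)


def _interaction_pvals(fit: _ModelFit) -> list[tuple[Term, float]]:
    return [
        (t, fit.p_two[i + 1])
        for i, t in enumerate(fit.terms)
        if isinstance(t, tuple)
    ]


def _strategy_model(
    agg: AggregatedTrial, aspec: AnalysisSpec, target: int | None = None
) -> _ModelFit:
    """Fit the model implied by the interaction strategy.

    ``target`` is required for ``backward_tested`` (interactions involving
    the analyzed intervention only).
    """
    K = agg.K
    mains: list[Term] = list(range(1, K + 1))
    strat = aspec.interaction_strategy

    if strat == "none":
        return _fit_terms(agg, mains)

    if strat == "prespecified":
        return _fit_terms(agg, mains + list(aspec.interaction_pairs))

    if strat == "gated":
        fit = _fit_terms(agg, mains + list(aspec.interaction_pairs))
        keep = [
            t for t, p in _interaction_pvals(fit) if p < aspec.gate_threshold
        ]
        if len(keep) == len(aspec.interaction_pairs):
            return fit
        return _fit_terms(agg, mains + keep)

    if strat == "backward_tested":
        if target is None:
            raise ValueError("backward_tested requires a target intervention")
        pairs: list[Term] = [
            (min(target, j), max(target, j)) for j in range(1, K + 1) if j != target
        ]
    elif strat == "backward_all":
        pairs = [(i, j) for i in range(1, K + 1) for j in range(i + 1, K + 1)]
    else:  # pragma: no cover
        raise ValueError(strat)

    fit = _fit_terms(agg, mains + pairs)
    while True:
        inter = _interaction_pvals(fit)
        if not inter:
            break
        worst_term, worst_p = max(inter, key=lambda tp: tp[1])
        if worst_p <= aspec.elimination_threshold:
            break
        remaining = [t for t in fit.terms if t != worst_term]
        fit = _fit_terms(agg, remaining)
    return fit


def _directional_p(z: float, p_two: float, sidedness: str) -> float:
    if sidedness == "two_sided":
        return p_two
    if not np.isfinite(z):
        return 1.0
    if p_two >= 1.0:  # non-convergence policy already applied
        return 1.0
    return float(stats.norm.sf(z))  # benefit only (positive effect)


# ---------------------------------------------------------------------------
# pooled proportion test


def pooled_prop_test(trial, intervention: int, sidedness: str = "two_sided"):
    """Two-sample pooled-variance z-test of receivers vs non-receivers.

    Returns ``(estimate, z, p)`` where estimate is the difference of
    proportions (receivers minus non-receivers).  The one-sided variant
    tests for benefit only.  Degenerate variance (pooled rate 0 or 1)
    yields z = 0, p = 1 by convention.
    """
    agg = _as_aggregated(trial)
    mask = agg.arms[:, intervention - 1] == 1
    n1 = int(agg.counts[mask].sum())
    n0 = int(agg.counts[~mask].sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedContrastError(
            f"intervention {intervention}: a pooled group is empty"
        )
    s1 = int(agg.successes[mask].sum())
    s0 = int(agg.successes[~mask].sum())
    p1, p0 = s1 / n1, s0 / n0
    pbar = (s1 + s0) / (n1 + n0)
    var = pbar * (1 - pbar) * (1 / n1 + 1 / n0)
    diff = p1 - p0
    if var <= 0.0:
        return diff, 0.0, 1.0
    z = diff / np.sqrt(var)
    if sidedness == "two_sided":
        p = 2 * stats.norm.sf(abs(z))
    else:
        p = stats.norm.sf(z)
    return diff, float(z), float(p)


# ---------------------------------------------------------------------------
# top-level analysis


def analyze(trial, aspec: AnalysisSpec) -> TestResult:
    """Test every candidate intervention per the analysis specification."""
    agg = _as_aggregated(trial)
    K = agg.K
    alpha_adj = aspec.adjusted_alpha(K)
    rows = []

    if aspec.test == "pooled_prop_diff":
        for i in range(1, K + 1):
            est, z, p = pooled_prop_test(agg, i, aspec.sidedness)
            rows.append((i, est, z, p, "", True))
    elif aspec.interaction_strategy == "backward_tested":
        for i in range(1, K + 1):
            fit = _strategy_model(agg, aspec, target=i)
            est, se, z, p2 = fit.entry(i)
            p = _directional_p(z, p2, aspec.sidedness)
            retained = ";".join(str(t) for t in fit.terms if isinstance(t, tuple))
            rows.append((i, est, z, p, retained, fit.converged))
    else:
        fit = _strategy_model(agg, aspec)
        retained = ";".join(str(t) for t in fit.terms if isinstance(t, tuple))
        for i in range(1, K + 1):
            est, se, z, p2 = fit.entry(i)
            p = _directional_p(z, p2, aspec.sidedness)
            rows.append((i, est, z, p, retained, fit.converged))

    df = pd.DataFrame(
        rows,
        columns=["intervention", "estimate", "statistic", "p", "terms_retained", "converged"],
    )
    df["adjusted_alpha"] = alpha_adj
    df["significant"] = df["p"] < alpha_adj
    df["strategy"] = (
        aspec.test if aspec.test == "pooled_prop_diff" else aspec.interaction_strategy
    )
    return TestResult(table=df, alpha_adjusted=alpha_adj, spec=aspec)


def target_pvalue(trial, aspec: AnalysisSpec, target: int) -> float:
    """P-value for one pre-specified intervention only (fast path for
    power loops)."""
    agg = _as_aggregated(trial)
    if aspec.test == "pooled_prop_diff":
        _, _, p = pooled_prop_test(agg, target, aspec.sidedness)
        return p
    tgt = target if aspec.interaction_strategy == "backward_tested" else None
    fit = _strategy_model(agg, aspec, target=tgt)
    _, _, z, p2 = fit.entry(target)
    return _directional_p(z, p2, aspec.sidedness)


def fwer_decision(result: TestResult, truly_null) -> bool:
    """True iff any truly-null intervention was flagged significant."""
    return bool(result.significant_set() & set(truly_null))
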