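"""Sample size, power and family-wise error rate machinery.

Closed form
-----------
For a single effective intervention analyzed by a pooled difference of
proportions, the standard unbalanced two-proportion Gaussian formula gives
the number of receivers

    n_I = ( z_a sqrt((r+1) pbar (1-pbar)) +
            z_b sqrt(r p_I (1-p_I) + p_C (1-p_C)) )^2 / ( r (p_I - p_C)^2 )

with r the non-receiver:receiver ratio implied by the design, pbar the
pooled rate (p_I + r p_C) / (r + 1), and N = n_I + r n_I.  A variant with
both variances under one radical in the z_b term is available behind
``as_printed=True`` for auditing against older write-ups; the default
reproduces textbook values (n_I = 124 at p 0.7 vs 0.5, r = 1, two-sided
alpha 5%, 90% power).

Simulation
----------
Power is the frequency, over simulated trials, of a p-value below the
Bonferroni-adjusted threshold for one pre-specified intervention.  FWER is
the frequency of at least one false rejection among truly-null
interventions, with a Jeffreys Beta(x+1/2, n-x+1/2) interval.

Adaptive sample-size search
---------------------------
The probability of discovery is modeled as a modified probit in the
square root of the trial size,

    p_d = Phi( z_{1-beta} + b (X - X0) ),   X = sqrt(N),

so that X0**2 is the trial size achieving the target power exactly.  The
search seeds the fit with two pseudo-observations (a failure at N = 1, a
success at N = 1e6) and 48 log-spaced simulated trials between 50 and
10,000 (re-drawn if all land on the same side), then keeps simulating in
batches of max(50, 10% of the history) spread uniformly over
X0_hat +/- min(SE(X0_hat), 10), refitting after each batch, until at
least ``min_sims`` trials have been run.  The robust variant (default)
constrains b > 0 and refits the final estimate without the pseudo-anchors
and the initial batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .analysis import AnalysisSpec, analyze, fwer_decision, target_pvalue
from .analysis import AggregatedTrial
from .design_core import (
    AllocationTable,
    DesignSpec,
    InterestingSet,
    build_allocation_table,
    marginal_allocation_prob,
)
from .errors import (
    NonIdentifiableFitError,
    SearchFailureError,
    UndefinedContrastError,
)
from .outcome_model import EffectSpec, annotate_table, marginal_success_rates
from .trial_simulator import (
    ArmExpansion,
    expand_arms,
    simulate_arm_counts,
    simulate_trial,
)

# ---------------------------------------------------------------------------
# Monte-Carlo error helpers


def mc_se(p: float, n_sims: int) -> float:
    """Standard error of a simulated proportion: sqrt(p (1-p) / n)."""
    return math.sqrt(p * (1.0 - p) / n_sims)


def two_stage_se(p: float, n_first: int, n_second: int) -> float:
    """SE of a power check at a simulated sample size: the Monte-Carlo
    variances of the search stage and the re-check stage add."""
    return math.sqrt(p * (1 - p) / n_first + p * (1 - p) / n_second)


def jeffreys_interval(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Jeffreys Beta(x + 1/2, n - x + 1/2) binomial interval."""
    a = (1 - level) / 2
    lo = stats.beta.ppf(a, x + 0.5, n - x + 0.5) if x > 0 else 0.0
    hi = stats.beta.ppf(1 - a, x + 0.5, n - x + 0.5) if x < n else 1.0
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# closed form


@dataclass(frozen=True)
class ClosedFormInput:
    """Inputs to the two-proportion sample-size formula."""

    p_I: float
    p_C: float
    r: float
    alpha: float = 0.05
    beta: float = 0.10
    sidedness: str = "two_sided"

    def __post_init__(self) -> None:
        if self.p_I == self.p_C:
            raise ValueError("zero effect: p_I must differ from p_C")
        if self.r <= 0:
            raise ValueError("r must be positive")

    @property
    def z_alpha(self) -> float:
        q = 1 - self.alpha / 2 if self.sidedness == "two_sided" else 1 - self.alpha
        return float(stats.norm.ppf(q))

    @property
    def z_beta(self) -> float:
        return float(stats.norm.ppf(1 - self.beta))


def closed_form_sample_size(
    inp: ClosedFormInput, as_printed: bool = False
) -> tuple[int, int]:
    """Return ``(n_I, N)``: receivers (ceiling) and total N = n_I + r n_I
    (non-receivers also ceiled; conservative whole patients)."""
    pI, pC, r = inp.p_I, inp.p_C, inp.r
    qI, qC = 1 - pI, 1 - pC
    pbar = (pI + r * pC) / (r + 1)
    if as_printed:
        t2 = math.sqrt(r * pI * qI * pC * qC)
    else:
        t2 = math.sqrt(r * pI * qI + pC * qC)
    num = (inp.z_alpha * math.sqrt((r + 1) * pbar * (1 - pbar)) + inp.z_beta * t2) ** 2
    n_I = num / (r * (pI - pC) ** 2)
    n_I_int = math.ceil(n_I - 1e-9)
    N = n_I_int + math.ceil(r * n_I_int - 1e-9)
    return n_I_int, N


def closed_form_power(N: float, inp: ClosedFormInput) -> float:
    """Power of the pooled two-proportion test at total size N (Gaussian
    approximation, inverse of the sample-size formula)."""
    pI, pC, r = inp.p_I, inp.p_C, inp.r
    n_I = N / (1 + r)
    pbar = (pI + r * pC) / (r + 1)
    num = math.sqrt(n_I * r) * abs(pI - pC) - inp.z_alpha * math.sqrt(
        (r + 1) * pbar * (1 - pbar)
    )
    den = math.sqrt(r * pI * (1 - pI) + pC * (1 - pC))
    return float(stats.norm.cdf(num / den))


def closed_form_from_table(
    table: AllocationTable,
    target: int,
    alpha: float,
    beta: float = 0.10,
    sidedness: str = "two_sided",
) -> ClosedFormInput:
    """Build the closed-form inputs implied by a design: r from the
    marginal allocation probability, p_I / p_C from the success-annotated
    table under pooling."""
    m = marginal_allocation_prob(table, target)
    if not 0.0 < m < 1.0:
        raise ValueError("target intervention must sometimes (not always) be allocated")
    p_i, p_c = marginal_success_rates(table, target)
    return ClosedFormInput(
        p_I=p_i, p_C=p_c, r=(1 - m) / m, alpha=alpha, beta=beta, sidedness=sidedness
    )


# ---------------------------------------------------------------------------
# simulation-based power / FWER


def _prepare(spec, interesting, effects):
    table = annotate_table(build_allocation_table(spec, interesting, effects), effects)
    try:
        expansion = expand_arms(table)
    except (NotImplementedError, ValueError):
        expansion = None
    return table, expansion


def _one_aggregated(table, expansion, effects, N, rng) -> AggregatedTrial:
    if expansion is not None:
        counts, succ = simulate_arm_counts(expansion, N, rng)
        return AggregatedTrial.from_counts(expansion, counts, succ)
    trial = simulate_trial(table.spec, table.interesting, effects, N, rng, table=table)
    return AggregatedTrial.from_trial(trial)


def _safe_target_pvalue(agg, analysis, target) -> float:
    """Undefined contrasts (a pooled group empty at tiny N) count as
    non-discovery."""
    try:
        return target_pvalue(agg, analysis, target)
    except UndefinedContrastError:
        return 1.0


def power_by_simulation(
    spec: DesignSpec,
    interesting: InterestingSet | None,
    effects: EffectSpec,
    analysis: AnalysisSpec,
    N: int,
    n_sims: int,
    target_intervention: int,
    rng,
) -> tuple[float, float]:
    """Estimated power for one pre-specified intervention, with its
    Monte-Carlo standard error."""
    if N < 1 or n_sims < 1:
        raise ValueError("N and n_sims must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    table, expansion = _prepare(spec, interesting, effects)
    alpha_adj = analysis.adjusted_alpha(spec.K)
    hits = 0
    for _ in range(n_sims):
        agg = _one_aggregated(table, expansion, effects, N, rng)
        if _safe_target_pvalue(agg, analysis, target_intervention) < alpha_adj:
            hits += 1
    p_hat = hits / n_sims
    return p_hat, mc_se(max(p_hat, 1.0 / n_sims), n_sims)


def fwer_by_simulation(
    spec: DesignSpec,
    interesting: InterestingSet | None,
    effects: EffectSpec,
    analysis: AnalysisSpec,
    N: int,
    n_sims: int,
    rng,
    truly_null=None,
) -> dict:
    """Family-wise error rate: proportion of trials with at least one
    false rejection of a truly-null intervention; Jeffreys interval."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    table, expansion = _prepare(spec, interesting, effects)
    if truly_null is None:
        effective = set(effects.interventions())
        truly_null = [i for i in range(1, spec.K + 1) if i not in effective]
    hits = 0
    for _ in range(n_sims):
        agg = _one_aggregated(table, expansion, effects, N, rng)
        result = analyze(agg, analysis)
        if fwer_decision(result, truly_null):
            hits += 1
    fwer = hits / n_sims
    lo, hi = jeffreys_interval(hits, n_sims)
    return {"fwer": fwer, "ci_low": lo, "ci_high": hi, "n_sims": n_sims}


def make_discovery_fn(
    spec: DesignSpec,
    interesting: InterestingSet | None,
    effects: EffectSpec,
    analysis: AnalysisSpec,
    target_intervention: int,
    rng,
):
    """Closure simulating one trial of size N and reporting discovery of
    the target intervention (used by the adaptive search)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    table, expansion = _prepare(spec, interesting, effects)
    alpha_adj = analysis.adjusted_alpha(spec.K)

    def discover(N: int) -> bool:
        agg = _one_aggregated(table, expansion, effects, int(N), rng)
        return _safe_target_pvalue(agg, analysis, target_intervention) < alpha_adj

    return discover


# ---------------------------------------------------------------------------
# probit power-curve fit


@dataclass
class ProbitFit:
    X0: float
    b: float
    se_X0: float
    converged: bool


def _probit_nll(params, X, d, z_target, log_b: bool):
    X0, braw = params
    b = math.exp(braw) if log_b else braw
    eta = z_target + b * (X - X0)
    return -(
        np.sum(stats.norm.logcdf(eta[d])) + np.sum(stats.norm.logcdf(-eta[~d]))
    )


def fit_probit_powercurve(
    X, d, z_target: float, constrain_b: bool = False
) -> ProbitFit:
    """ML fit of p_d = Phi(z_target + b (X - X0)).

    Fit as a probit GLM with offset z_target (eta = z_target + c0 + c1 X,
    so b = c1 and X0 = -c0 / c1); SE(X0) by the delta method from the
    observed information, equivalent to the Hessian of the (X0, b)
    parameterization by ML invariance.  ``constrain_b`` enforces b > 0
    (via an optimization over log b) when the GLM solution has b <= 0.
    Histories with all-identical outcomes are non-identifiable.
    """
    X = np.asarray(X, dtype=float)
    d = np.asarray(d, dtype=bool)
    if d.all() or (~d).all():
        raise NonIdentifiableFitError(
            "need at least one discovery and one non-discovery"
        )
    exog = np.column_stack([np.ones_like(X), X])
    offset = np.full_like(X, z_target)
    res = None
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(
                d.astype(float),
                exog,
                family=sm.families.Binomial(link=sm.families.links.Probit()),
                offset=offset,
            ).fit(maxiter=100)
        if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
            res = None
    except Exception:
        res = None

    if res is not None and res.params[1] > 0:
        c0, c1 = res.params
        V = res.cov_params()
        X0 = -c0 / c1
        grad = np.array([-1.0 / c1, c0 / c1**2])
        var = float(grad @ V @ grad)
        se = math.sqrt(var) if var > 0 else math.inf
        return ProbitFit(
            X0=float(X0), b=float(c1), se_X0=se,
            converged=bool(getattr(res, "converged", True)),
        )
    if res is not None and not constrain_b:
        c0, c1 = res.params
        V = res.cov_params()
        X0 = -c0 / c1 if c1 != 0 else math.inf
        grad = np.array([-1.0 / c1, c0 / c1**2]) if c1 != 0 else np.array([0.0, 0.0])
        var = float(grad @ V @ grad)
        return ProbitFit(
            X0=float(X0), b=float(c1),
            se_X0=math.sqrt(var) if var > 0 else math.inf,
            converged=False,
        )

    # constrained (b > 0) direct ML over (X0, log b)
    x0_init = float(np.median(X))
    start = np.array([x0_init, math.log(0.05)])
    opt = optimize.minimize(
        _probit_nll, start, args=(X, d, z_target, True), method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-10},
    )
    X0_hat, logb_hat = opt.x
    b_hat = math.exp(logb_hat)
    # numeric Hessian in the (X0, b) parameterization
    def nll_xb(p):
        return _probit_nll(p, X, d, z_target, False)

    h = np.array([max(1e-4, 1e-4 * abs(X0_hat)), max(1e-6, 1e-4 * b_hat)])
    H = np.zeros((2, 2))
    p0 = np.array([X0_hat, b_hat])
    f0 = nll_xb(p0)
    for i in range(2):
        for j in range(2):
            pi, pj = np.zeros(2), np.zeros(2)
            pi[i] = h[i]
            pj[j] = h[j]
            H[i, j] = (
                nll_xb(p0 + pi + pj) - nll_xb(p0 + pi - pj)
                - nll_xb(p0 - pi + pj) + nll_xb(p0 - pi - pj)
            ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = math.sqrt(cov[0, 0]) if cov[0, 0] > 0 else math.inf
    except np.linalg.LinAlgError:
        se = math.inf
    return ProbitFit(X0=float(X0_hat), b=float(b_hat), se_X0=se, converged=opt.success)


# ---------------------------------------------------------------------------
# adaptive sample-size search


@dataclass
class SampleSizeResult:
    N_required: int
    X0: float
    b: float
    se_X0: float
    n_sims: int
    n_batches: int
    converged: bool
    history_N: np.ndarray = field(repr=False, default=None)
    history_d: np.ndarray = field(repr=False, default=None)
    log: list = field(repr=False, default_factory=list)


def adaptive_search_from_fn(
    discovery_fn,
    beta: float = 0.10,
    min_sims: int = 5000,
    robust: bool = True,
    init_range: tuple[int, int] = (50, 10_000),
    n_init: int = 48,
    max_reruns: int = 20,
    anchors: tuple[int, int] = (1, 1_000_000),
) -> SampleSizeResult:
    """Adaptive probit-based sample-size search over a discovery oracle.

    ``discovery_fn(N) -> bool`` runs one trial of size N and reports
    whether the target intervention was declared significant.
    """
    z_target = float(stats.norm.ppf(1 - beta))
    anchor_X = np.sqrt(np.array(anchors, dtype=float))
    anchor_d = np.array([False, True])

    for attempt in range(max_reruns):
        init_N = np.unique(
            np.round(np.geomspace(init_range[0], init_range[1], n_init)).astype(int)
        )
        init_d = np.array([discovery_fn(int(n)) for n in init_N])
        if init_d.any() and not init_d.all():
            break
    else:
        raise SearchFailureError(
            f"initial batch all-{'significant' if init_d.all() else 'non-significant'} "
            f"after {max_reruns} re-runs; widen init_range"
        )

    hist_N = list(init_N)
    hist_d = list(init_d)
    n_init_actual = len(hist_N)
    log = []
    fit = None
    n_batches = 0
    while True:
        X_all = np.concatenate([anchor_X, np.sqrt(hist_N)])
        d_all = np.concatenate([anchor_d, hist_d])
        fit = fit_probit_powercurve(X_all, d_all, z_target, constrain_b=robust)
        log.append(
            {"batch": n_batches, "total": len(hist_N), "X0": fit.X0,
             "b": fit.b, "se_X0": fit.se_X0}
        )
        if len(hist_N) >= min_sims:
            break
        n_batches += 1
        batch = max(50, math.ceil(0.1 * len(hist_N)))
        w = min(fit.se_X0, 10.0)
        if not math.isfinite(w) or w <= 0:
            w = 10.0
        lo = max(1.0, fit.X0 - w)
        hi = max(lo + 1e-6, fit.X0 + w)
        Xs = np.linspace(lo, hi, batch)
        Ns = np.maximum(1, np.round(Xs**2)).astype(int)
        for n in Ns:
            hist_N.append(int(n))
            hist_d.append(discovery_fn(int(n)))

    hist_N = np.asarray(hist_N)
    hist_d = np.asarray(hist_d, dtype=bool)
    final = fit
    if robust:
        # forget the pseudo-anchors and the initial batch
        tail_N = hist_N[n_init_actual:]
        tail_d = hist_d[n_init_actual:]
        if tail_d.size and tail_d.any() and not tail_d.all():
            final = fit_probit_powercurve(
                np.sqrt(tail_N), tail_d, z_target, constrain_b=True
            )
    N_req = max(1, math.ceil(final.X0**2 - 1e-9))
    return SampleSizeResult(
        N_required=N_req,
        X0=final.X0,
        b=final.b,
        se_X0=final.se_X0,
        n_sims=len(hist_N),
        n_batches=n_batches,
        converged=final.converged,
        history_N=hist_N,
        history_d=hist_d,
        log=log,
    )


def adaptive_sample_size_search(
    spec: DesignSpec,
    interesting: InterestingSet | None,
    effects: EffectSpec,
    analysis: AnalysisSpec,
    rng,
    target_intervention: int | None = None,
    beta: float = 0.10,
    min_sims: int = 5000,
    robust: bool = True,
    init_range: tuple[int, int] = (50, 10_000),
) -> SampleSizeResult:
    """Required trial size for the target power, by simulation.

    ``target_intervention`` defaults to the first intervention named by an
    effect rule.
    """
    if target_intervention is None:
        named = effects.interventions()
        if not named:
            raise ValueError("no effective intervention to target")
        target_intervention = named[0]
    fn = make_discovery_fn(
        spec, interesting, effects, analysis, target_intervention, rng
    )
    return adaptive_search_from_fn(
        fn, beta=beta, min_sims=min_sims, robust=robust, init_range=init_range
    )
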