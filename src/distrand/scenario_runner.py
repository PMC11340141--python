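"""Declarative scenario presets and sweep execution.

Presets encode the study's canonical simulation scenarios at three scales
(``smoke`` = 200 simulations with coarse grids, ``desk`` = 1000,
``full`` = 5000 with full grids):

* group ``"1"`` — one effective intervention (50% -> 70%), pooled
  difference-of-proportions analysis, closed-form sample sizes across
  designs (distributive, capped/full factorial, pooled and unpooled
  parallel, separate trials) as K grows;
* ``"2A"``/``"2B"`` — logistic main-effects analysis, sample size by the
  adaptive search, sweeping k at fixed K and K at fixed k;
* ``"2C"``–``"2F"`` — realized power when a second intervention is
  unexpectedly effective (logit-additive 84.48276%, synergistic 99%,
  non-additive 70%, or weaker 60% non-additive) while the trial was sized
  for a single 70% effect;
* ``"4A"``–``"4D"`` — the same interaction structures foreseen at the
  sizing stage (sample size under correct assumptions);
* ``"5A"``–``"5D"`` — mitigation strategies: intervention-free control
  arms (0–80% of patients) crossed with analysis strategies (pooled,
  main-effects, pre-specified / gated interaction term, backward
  elimination) for {k, K} = {4, 10} and {2, 20}.

Every job row yields one line of schema-stable CSV output: the estimand
(sample size, power or FWER) with its Monte-Carlo uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import AnalysisSpec
from .design_core import (
    DesignKind,
    DesignSpec,
    InterestingSet,
    build_allocation_table,
)
from .outcome_model import EffectSpec, annotate_table, logit_additive_combo
from .power_engine import (
    ClosedFormInput,
    adaptive_sample_size_search,
    closed_form_from_table,
    closed_form_sample_size,
    fwer_by_simulation,
    mc_se,
    power_by_simulation,
)

SCALES = {"smoke": 200, "desk": 1000, "full": 5000}

#: combined success of two standalone-70% interventions under logit additivity
ADDITIVE_COMBO = logit_additive_combo(0.7, 0.7)   # 0.8448276...


@dataclass(frozen=True)
class ScenarioJob:
    """One design x effect x analysis point of a scenario sweep."""

    label: str
    design: DesignSpec
    analysis: AnalysisSpec
    true_effects: EffectSpec
    assumed_effects: EffectSpec
    estimand: str                      # sample_size | power | fwer
    target: int = 1
    N: int | None = None               # fixed N for power/fwer jobs
    pooling: str = "pooled"            # pooled | unpooled | separate (closed form)
    meta: tuple = ()


@dataclass(frozen=True)
class ScenarioConfig:
    scenario_id: str
    jobs: tuple[ScenarioJob, ...]
    n_sims: int
    search_min_sims: int
    foresight: bool
    description: str = ""


def _one_effective(p: float = 0.7) -> EffectSpec:
    return EffectSpec(baseline=0.5, rules=((frozenset({1}), p),))


def _two_effective(p1: float, p2: float, combo: float) -> EffectSpec:
    return EffectSpec(
        baseline=0.5,
        rules=(
            (frozenset({1, 2}), combo),
            (frozenset({1}), p1),
            (frozenset({2}), p2),
        ),
    )


def _closed_form_N(job: ScenarioJob, effects: EffectSpec) -> tuple[int, dict]:
    """Closed-form total N for pooled / unpooled / separate analyses."""
    spec = job.design
    alpha_adj = job.analysis.adjusted_alpha(spec.K)
    if job.pooling in ("unpooled", "separate"):
        # two equally sized arms per comparison at the adjusted threshold
        inp = ClosedFormInput(
            p_I=0.7, p_C=effects.baseline, r=1.0,
            alpha=alpha_adj, beta=0.10, sidedness=job.analysis.sidedness,
        )
        n_I, _ = closed_form_sample_size(inp)
        if job.pooling == "unpooled":
            N = (spec.K + 1) * n_I        # shared control of equal size
        else:
            N = 2 * spec.K * n_I          # K separate two-arm trials summed
        return N, {"n_I": n_I, "r": 1.0}
    table = annotate_table(build_allocation_table(spec, effects=effects), effects)
    inp = closed_form_from_table(
        table, job.target, alpha=alpha_adj, sidedness=job.analysis.sidedness
    )
    n_I, N = closed_form_sample_size(inp)
    return N, {"n_I": n_I, "r": inp.r}


def run_scenario(
    config: ScenarioConfig, seed: int, out_dir=None
) -> pd.DataFrame:
    """Execute every job of a scenario; returns (and optionally writes) a
    tidy result table with one row per job."""
    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(config.jobs))
    for job, child in zip(config.jobs, children):
        rng = np.random.default_rng(child)
        spec = job.design
        row = {
            "scenario": config.scenario_id,
            "label": job.label,
            "design": spec.kind.value,
            "K": spec.K,
            "k": spec.k,
            "control_fraction": spec.control_fraction,
            "analysis": job.analysis.test
            if job.analysis.test == "pooled_prop_diff"
            else f"logistic/{job.analysis.interaction_strategy}",
            "estimand": job.estimand,
        }
        if job.estimand == "sample_size":
            if job.analysis.test == "pooled_prop_diff":
                N, extra = _closed_form_N(job, job.assumed_effects)
                row.update(value=N, se=0.0, n_sims=0, **extra)
            else:
                res = adaptive_sample_size_search(
                    spec, None, job.assumed_effects, job.analysis, rng,
                    target_intervention=job.target,
                    min_sims=config.search_min_sims,
                )
                row.update(
                    value=res.N_required,
                    se=2 * res.X0 * res.se_X0,   # delta method on N = X0^2
                    n_sims=res.n_sims,
                )
        elif job.estimand == "power":
            N = job.N
            if N is None:
                if job.analysis.test == "pooled_prop_diff":
                    N, _ = _closed_form_N(job, job.assumed_effects)
                else:
                    N = adaptive_sample_size_search(
                        spec, None, job.assumed_effects, job.analysis, rng,
                        target_intervention=job.target,
                        min_sims=config.search_min_sims,
                    ).N_required
            p_hat, se = power_by_simulation(
                spec, None, job.true_effects, job.analysis,
                N, config.n_sims, job.target, rng,
            )
            row.update(value=p_hat, se=se, n_sims=config.n_sims, N=N)
        elif job.estimand == "fwer":
            N = job.N
            if N is None:
                raise ValueError("fwer jobs need a fixed N")
            out = fwer_by_simulation(
                spec, None, job.true_effects, job.analysis, N, config.n_sims, rng
            )
            row.update(
                value=out["fwer"],
                se=mc_se(max(out["fwer"], 1 / config.n_sims), config.n_sims),
                ci_low=out["ci_low"], ci_high=out["ci_high"],
                n_sims=config.n_sims, N=N,
            )
        else:
            raise ValueError(f"unknown estimand {job.estimand!r}")
        rows.append(row)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"scenario_{config.scenario_id}.csv", index=False)
    return df


# ---------------------------------------------------------------------------
# presets


def _grids(scale: str):
    if scale == "smoke":
        return {"K_sweep": [6, 10], "k_fixed": [2], "K_fixed": [10],
                "control": [0.0, 0.4], "kK": [(4, 10)]}
    if scale == "desk":
        return {"K_sweep": [4, 8, 12, 16, 20], "k_fixed": [2, 4],
                "K_fixed": [10, 20], "control": [0.0, 0.2, 0.4, 0.8],
                "kK": [(4, 10), (2, 20)]}
    return {"K_sweep": list(range(4, 21)), "k_fixed": [2, 4, 6, 8],
            "K_fixed": [5, 10, 15, 20], "control": [0.0, 0.2, 0.4, 0.6, 0.8],
            "kK": [(4, 10), (2, 20)]}


_SECOND_EFFECTS = {
    "C": ("additive", _two_effective(0.7, 0.7, ADDITIVE_COMBO)),
    "D": ("synergy", _two_effective(0.7, 0.7, 0.99)),
    "E": ("non_additive", _two_effective(0.7, 0.7, 0.7)),
    "F": ("weak_non_additive", _two_effective(0.7, 0.6, 0.7)),
}


def builtin_presets(scale: str = "smoke") -> dict[str, ScenarioConfig]:
    """All built-in scenario presets at the requested scale."""
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; choose from {sorted(SCALES)}")
    n_sims = SCALES[scale]
    g = _grids(scale)
    one = _one_effective()
    pooled = AnalysisSpec(test="pooled_prop_diff")
    logistic = AnalysisSpec(test="logistic")
    presets: dict[str, ScenarioConfig] = {}

    # group 1: closed-form sample sizes across designs, pooled analysis
    jobs = []
    for K in g["K_sweep"]:
        k = 2
        jobs += [
            ScenarioJob("distributive", DesignSpec("distributive", K, k),
                        pooled, one, one, "sample_size"),
            ScenarioJob("capped_factorial", DesignSpec("capped_factorial", K, k),
                        pooled, one, one, "sample_size"),
            ScenarioJob("full_factorial", DesignSpec("full_factorial", K),
                        pooled, one, one, "sample_size"),
            ScenarioJob("parallel_pooled", DesignSpec("parallel", K),
                        pooled, one, one, "sample_size"),
            ScenarioJob("parallel_unpooled", DesignSpec("parallel", K),
                        pooled, one, one, "sample_size", pooling="unpooled"),
            ScenarioJob("separate", DesignSpec("separate", K),
                        pooled, one, one, "sample_size", pooling="separate"),
        ]
    presets["1"] = ScenarioConfig(
        "1", tuple(jobs), n_sims, n_sims, True,
        "closed-form sizes, one effective intervention, pooled analysis",
    )

    # 2A: sweep k at fixed K; 2B: sweep K at fixed k (logistic, search)
    jobs = []
    for K in g["K_fixed"]:
        ks = [2, K // 2] if scale == "smoke" else list(range(2, min(K, 9)))
        for k in sorted(set(ks)):
            jobs.append(
                ScenarioJob(f"K{K}_k{k}", DesignSpec("distributive", K, k),
                            logistic, one, one, "sample_size")
            )
    presets["2A"] = ScenarioConfig(
        "2A", tuple(jobs), n_sims, n_sims, True,
        "sample size vs allocations per patient",
    )
    jobs = []
    for k in g["k_fixed"]:
        for K in g["K_sweep"]:
            if K >= k + 2:
                jobs.append(
                    ScenarioJob(f"k{k}_K{K}", DesignSpec("distributive", K, k),
                                logistic, one, one, "sample_size")
                )
    presets["2B"] = ScenarioConfig(
        "2B", tuple(jobs), n_sims, n_sims, True,
        "sample size vs number of candidates",
    )

    # 2C-2F: power under a wrongly assumed single effective intervention
    for suffix, (name, truth) in _SECOND_EFFECTS.items():
        jobs = []
        for k in g["k_fixed"]:
            for K in g["K_sweep"]:
                if K >= k + 2:
                    jobs.append(
                        ScenarioJob(f"k{k}_K{K}", DesignSpec("distributive", K, k),
                                    logistic, truth, one, "power")
                    )
        presets[f"2{suffix}"] = ScenarioConfig(
            f"2{suffix}", tuple(jobs), n_sims, n_sims, False,
            f"power with an unexpected second effective intervention ({name})",
        )

    # 4A-4D: same interactions but foreseen at the sizing stage
    for suffix, (name, truth) in _SECOND_EFFECTS.items():
        jobs = []
        for k in g["k_fixed"]:
            for K in g["K_sweep"]:
                if K >= k + 2:
                    jobs.append(
                        ScenarioJob(f"k{k}_K{K}", DesignSpec("distributive", K, k),
                                    logistic, truth, truth, "sample_size")
                    )
        idx = "ABCD"["CDEF".index(suffix)]
        presets[f"4{idx}"] = ScenarioConfig(
            f"4{idx}", tuple(jobs), n_sims, n_sims, True,
            f"sample size with a foreseen second effective intervention ({name})",
        )

    # 5A-5D: control arms x analysis strategies
    strategies = [
        ("confound", AnalysisSpec(test="pooled_prop_diff")),
        ("no_interaction", AnalysisSpec()),
        ("prespecified", AnalysisSpec(interaction_strategy="prespecified",
                                      interaction_pairs=((1, 2),))),
        ("gated_05", AnalysisSpec(interaction_strategy="gated",
                                  interaction_pairs=((1, 2),), gate_threshold=0.05)),
        ("backward_05", AnalysisSpec(interaction_strategy="backward_tested",
                                     elimination_threshold=0.05)),
        ("backward_25", AnalysisSpec(interaction_strategy="backward_tested",
                                     elimination_threshold=0.25)),
    ]
    if scale == "smoke":
        strategies = strategies[:3]
    combos = {"A": ((4, 10), ADDITIVE_COMBO), "B": ((4, 10), 0.7),
              "C": ((2, 20), ADDITIVE_COMBO), "D": ((2, 20), 0.7)}
    for suffix, ((k, K), combo) in combos.items():
        truth = _two_effective(0.7, 0.7, combo)
        jobs = []
        for c in g["control"]:
            kind = "controlled_distributive" if c > 0 else "distributive"
            design = DesignSpec(kind, K, k, control_fraction=c)
            for sname, aspec in strategies:
                jobs.append(
                    ScenarioJob(f"c{c:g}_{sname}", design, aspec,
                                truth, truth, "sample_size")
                )
        presets[f"5{suffix}"] = ScenarioConfig(
            f"5{suffix}", tuple(jobs), n_sims, n_sims, True,
            f"control arms and interaction strategies, k={k}, K={K}",
        )
    return presets
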