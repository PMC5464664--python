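"""Simulation experiments on known-truth synthetic studies.

Each routine generates data with :mod:`wqsses.synthetic`, runs the estimator,
and measures how well the truth is recovered: optimiser-vs-grid agreement,
weight recovery and specificity, confidence-interval coverage for the index
odds ratio, and AIC-based model-comparison behaviour (estimated vs. equal
weights; block-group vs. tract spatial scale).  The same routines back both
the test suite and ``scripts/acceptance.py``.

Problem sizes are scaled-down simulation designs (documented in the methods
note); replicate seeds are spawned from one entry seed so every experiment is
fully reproducible.
"""

from __future__ import annotations

import json

import numpy as np

from . import assembly, scoring
from .report import ModelPortfolio, PortfolioModel, run_portfolio
from .specs import ComponentDef, IndexSpec
from .synthetic import BG_VARIABLES, default_specs, simulate_study
from .wqs import WQSOptions, fit_constrained, run_wqs, _glm_logistic

# Degenerate prevalences for reduced-size runs: only gender varies, so the
# covariate design stays full rank at small n.
REDUCED_PREVALENCES = {
    "age_band": {"70-74": 1.0},
    "race": {"white": 1.0},
    "ethnicity": {"non_hispanic": 1.0},
    "tobacco": {"never": 1.0},
}


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def small_spec(n_components: int = 4) -> IndexSpec:
    """A block-group-only index over the first few generated variables."""
    comps = [ComponentDef(v, v, "block_group") for v in BG_VARIABLES[:n_components]]
    return IndexSpec(f"bg_small{n_components}", comps)


def oracle_gap(seed: int, n: int = 300) -> dict:
    """Constrained optimiser vs. profile-likelihood grid search, c = 2.

    Fits the two-component constrained model, then profiles the log-likelihood
    over w1 on a 101-point grid (refitting the betas by ordinary logistic
    regression at each grid point).  Returns the one-sided gap
    max(0, grid max - fit loglik); the optimiser may legitimately exceed the
    grid, whose points straddle the true optimum.
    """
    study = simulate_study(
        seed=seed, n_individuals=n, n_tracts=30, bgs_per_tract=3,
        spec=small_spec(2), true_weights=np.array([0.7, 0.3]), true_beta1=0.6,
        covariate_prevalences=REDUCED_PREVALENCES,
    )
    comp = assembly.join_components(study.individuals, study.areas, study.spec)
    rules = scoring.fit_index_rules(comp, study.spec)
    q = scoring.score_index(comp, study.spec, rules).to_numpy()
    z = assembly.encode_covariates(study.individuals)
    z = z.loc[:, z.std() > 0].to_numpy()
    y = study.individuals["outcome"].to_numpy(dtype=float)

    est = fit_constrained(q, z, y)
    grid_ll = []
    ones = np.ones(n)
    for w1 in np.linspace(0.0, 1.0, 101):
        idx = w1 * q[:, 0] + (1.0 - w1) * q[:, 1]
        X = np.column_stack([ones, idx, z])
        grid_ll.append(float(_glm_logistic(X, y).llf))
    gap = max(0.0, max(grid_ll) - est.loglik)
    return {"gap": gap, "fit_loglik": est.loglik, "grid_max": max(grid_ll),
            "w_hat": est.w.tolist(), "n": n}


def weight_recovery(
    seed: int, n: int = 5000, B: int = 50, n_replicates: int = 10
) -> dict:
    """Recovery of a known 10-component weight vector (half true zeros).

    Truth: weights (0.3, 0.25, 0.2, 0.15, 0.1, 0, 0, 0, 0, 0), beta1 = 0.4.
    ``n`` is the training sample the bootstraps draw from (the model's n); the
    study generates 2n individuals and splits 50%, using the generator's
    default 200 x 5 geography.  Returns per-component mean absolute error
    across replicates and the mean estimated weight of the true-zero
    components (specificity).
    """
    truth_w = np.array([0.3, 0.25, 0.2, 0.15, 0.1, 0, 0, 0, 0, 0])
    spec = default_specs()["bg1"]
    W = []
    for s in _child_seeds(seed, n_replicates):
        s_sim, s_split, s_boot = _child_seeds(s, 3)
        study = simulate_study(
            seed=s_sim, n_individuals=2 * n,
            spec=spec, true_weights=truth_w, true_beta1=0.4,
        )
        fit = run_wqs(
            study.individuals, study.areas, spec,
            WQSOptions(B=B, split_seed=s_split, bootstrap_seed=s_boot),
        )
        W.append(fit.weights.w)
    W = np.stack(W)
    per_component_mae = np.mean(np.abs(W - truth_w), axis=0)
    zero_mask = truth_w == 0
    return {
        "per_component_mae": per_component_mae.tolist(),
        "mean_abs_error": float(per_component_mae.mean()),
        "true_zero_mean_weight": float(W[:, zero_mask].mean()),
        "mean_weights": W.mean(axis=0).tolist(),
        "true_weights": truth_w.tolist(),
        "n": n,
        "B": B,
        "n_replicates": n_replicates,
    }


def _coverage_once(rep_seed: int, n: int, B: int, beta1: float) -> tuple[bool, float]:
    s_sim, s_split, s_boot = _child_seeds(rep_seed, 3)
    study = simulate_study(
        seed=s_sim, n_individuals=n, n_tracts=60, bgs_per_tract=4,
        spec=small_spec(4), true_weights=np.array([0.4, 0.3, 0.2, 0.1]),
        true_beta1=beta1, covariate_prevalences=REDUCED_PREVALENCES,
    )
    fit = run_wqs(
        study.individuals, study.areas, study.spec,
        WQSOptions(B=B, split_seed=s_split, bootstrap_seed=s_boot),
    )
    target_or = float(np.exp(beta1))
    return bool(fit.ci_low <= target_or <= fit.ci_high), fit.beta1


def ci_coverage(
    seed: int, beta1: float = 0.4, n_replicates: int = 200, n: int = 800, B: int = 10
) -> dict:
    """Wald CI coverage for the validation odds ratio under a known truth.

    With beta1 = 0 this is the null-calibration check: the CI should cover
    OR = 1 at close to the nominal 95% rate.
    """
    hits, betas = [], []
    for s in _child_seeds(seed, n_replicates):
        covered, b1 = _coverage_once(s, n, B, beta1)
        hits.append(covered)
        betas.append(b1)
    return {
        "coverage": float(np.mean(hits)),
        "true_beta1": beta1,
        "mean_beta1_hat": float(np.mean(betas)),
        "sd_beta1_hat": float(np.std(betas, ddof=1)),
        "n_replicates": n_replicates,
        "n": n,
        "B": B,
    }


def equal_vs_estimated(
    seed: int, n_replicates: int = 20, n: int = 6000, B: int = 25
) -> dict:
    """Validation AIC: estimated weights vs. fixed equal weights.

    Truth weights are strongly unequal, so estimating the weights should fit
    better than assuming equal importance in most replicates.
    """
    spec = default_specs()["bg1"]
    wins = 0
    for s in _child_seeds(seed, n_replicates):
        s_sim, s_split, s_boot = _child_seeds(s, 3)
        study = simulate_study(
            seed=s_sim, n_individuals=n, n_tracts=150, bgs_per_tract=4,
            spec=spec, true_beta1=0.4, covariate_prevalences=REDUCED_PREVALENCES,
        )
        base = WQSOptions(B=B, split_seed=s_split, bootstrap_seed=s_boot)
        portfolio = ModelPortfolio(
            [
                PortfolioModel("estimated", spec, base),
                PortfolioModel("equal", spec,
                               WQSOptions(B=B, bootstrap_seed=s_boot, equal_weights=True)),
            ]
        )
        table = run_portfolio(study.individuals, study.areas, portfolio,
                              split_seed=s_split)
        aics = table.models.set_index("model")["aic"]
        wins += int(aics["estimated"] < aics["equal"])
    return {"wins": wins, "n_replicates": n_replicates, "n": n, "B": B}


def scale_recovery(
    seed: int, n_replicates: int = 20, n: int = 4000, B: int = 20
) -> dict:
    """Block-group vs. tract-aggregated index when the truth is block-group scale.

    Outcomes are generated from block-group components; the tract variant uses
    the same variables aggregated (averaged) to tracts, losing within-tract
    variation, so the block-group spec should win on AIC in most replicates.
    """
    specs = default_specs()
    bg_spec, ct_spec = specs["bg1"], specs["ct2"]
    wins = 0
    for s in _child_seeds(seed, n_replicates):
        s_sim, s_split, s_boot = _child_seeds(s, 3)
        study = simulate_study(
            seed=s_sim, n_individuals=n, n_tracts=120, bgs_per_tract=4,
            spec=bg_spec, true_beta1=0.4, covariate_prevalences=REDUCED_PREVALENCES,
        )
        base = WQSOptions(B=B, bootstrap_seed=s_boot)
        portfolio = ModelPortfolio(
            [PortfolioModel("block_group", bg_spec, base),
             PortfolioModel("tract", ct_spec, base)]
        )
        table = run_portfolio(study.individuals, study.areas, portfolio,
                              split_seed=s_split)
        aics = table.models.set_index("model")["aic"]
        wins += int(aics["block_group"] < aics["tract"])
    return {"wins": wins, "n_replicates": n_replicates, "n": n, "B": B}


def determinism_check(seed: int, n: int = 600, B: int = 5) -> dict:
    """Two end-to-end runs with identical seeds must serialise identically."""
    outputs = []
    for _ in range(2):
        study = simulate_study(
            seed=seed, n_individuals=n, n_tracts=40, bgs_per_tract=3,
            spec=small_spec(4), true_weights=np.array([0.4, 0.3, 0.2, 0.1]),
            covariate_prevalences=REDUCED_PREVALENCES,
        )
        fit = run_wqs(study.individuals, study.areas, study.spec,
                      WQSOptions(B=B, split_seed=seed, bootstrap_seed=seed + 1))
        outputs.append(json.dumps(fit.to_dict(), sort_keys=True))
    return {"identical": outputs[0] == outputs[1], "n": n}
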