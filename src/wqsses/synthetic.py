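"""Known-truth synthetic study generator.

Emulates the structure of an EHR-plus-census colonoscopy-screening study:
nested census geography (block groups within tracts), positively
inter-correlated area-level SES variables observed at two spatial scales,
individual-level categorical covariates, and a Bernoulli adherence outcome
generated from a logistic model whose linear predictor contains a true
weighted-quantile SES index.  The true weights, effect sizes and seed are
recorded in a :class:`TruthManifest` so recovery can be tested downstream.

Latent structure
----------------
Each tract t carries a standard-normal SES factor f_t.  The latent value of
variable v in block group j of tract t is

    x_tjv = a * f_t + b * u_tj + c * e_tjv,   a^2 + b^2 + c^2 = 1,

with u_tj a block-group factor shared across variables and e_tjv idiosyncratic
noise.  Then corr(same variable, two block groups of one tract) = a^2 and
corr(two variables, same block group) = a^2 + b^2, so the two correlation
knobs map directly onto (a, b, c).  Latents are pushed through monotone maps
chosen by variable name (log-normal for income/rent amounts, bounded affine
for percentages), which leaves quantile scores untouched.  The tract table
holds within-tract means of every block-group variable (the tract-scale
version of each variable) plus tract-only variables; the income-inequality
Gini is computed from simulated log-normal household incomes whose dispersion
falls with the tract factor, so raw Gini correlates negatively with SES.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import assembly, scoring
from .specs import ComponentDef, IndexSpec

BG_VARIABLES = [
    "median_household_income",
    "per_capita_income",
    "pct_no_public_assistance",
    "pct_families_not_in_poverty",
    "pct_bachelors_degree",
    "pct_owner_occupied",
    "pct_not_vacant",
    "median_gross_rent",
    "pct_household_mortgage",
    "pct_white",
]

TRACT_ONLY_VARIABLES = ["gini_income"]

# Default covariate prevalences (fixture values; chosen to resemble a
# primary-care screening population, with small "null"/unknown fractions).
DEFAULT_PREVALENCES: dict[str, dict[str, float]] = {
    "age_band": {"50-54": 0.25, "55-59": 0.22, "60-64": 0.21, "65-69": 0.17, "70-74": 0.15},
    "gender": {"female": 0.55, "male": 0.45},
    "race": {"white": 0.80, "black": 0.06, "asian": 0.05, "american_indian": 0.01,
             "native_hawaiian": 0.005, "null": 0.075},
    "ethnicity": {"non_hispanic": 0.90, "hispanic": 0.04, "null": 0.06},
    "tobacco": {"never": 0.45, "quit": 0.30, "passive": 0.02, "yes": 0.15, "null": 0.08},
}

# Default true covariate effects (log odds per indicator column), on the scale
# of adjusted odds ratios typically reported for colonoscopy adherence: younger
# band below reference, mid bands above, current tobacco use strongly negative,
# unknown ("null") levels negative.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "age_50_54": np.log(0.65),
    "age_55_59": np.log(1.34),
    "age_60_64": np.log(1.23),
    "age_65_69": np.log(1.38),
    "male": np.log(0.98),
    "race_black": np.log(0.76),
    "race_asian": np.log(0.63),
    "race_american_indian": np.log(0.85),
    "race_native_hawaiian": np.log(0.58),
    "race_null": np.log(0.70),
    "ethnicity_hispanic": np.log(0.64),
    "ethnicity_null": np.log(0.73),
    "tobacco_quit": np.log(1.03),
    "tobacco_passive": np.log(0.87),
    "tobacco_yes": np.log(0.56),
    "tobacco_null": np.log(0.06),
}

# True weights used by default for a 10-component block-group index: half the
# components carry signal, half are true zeros generated correlated with the
# rest -- the hard case for specificity.
DEFAULT_TRUE_WEIGHTS_10 = np.array([0.3, 0.25, 0.2, 0.15, 0.1, 0.0, 0.0, 0.0, 0.0, 0.0])


@dataclass
class TruthManifest:
    """Ground truth behind a synthetic study, for recovery tests."""

    component_names: list[str]
    true_weights: np.ndarray
    true_beta1: float
    true_beta0: float
    true_covariate_effects: dict[str, float]
    seed: int
    scoring: str = "quantile"

    def __post_init__(self) -> None:
        self.true_weights = np.asarray(self.true_weights, dtype=float)
        if len(self.true_weights) != len(self.component_names):
            raise ValueError("true_weights length must match component_names")
        if np.any(self.true_weights < 0) or np.any(self.true_weights > 1):
            raise ValueError("true weights must lie in [0, 1]")
        if abs(self.true_weights.sum() - 1.0) > 1e-8:
            raise ValueError("true weights must sum to 1")

    def to_dict(self) -> dict:
        return {
            "component_names": list(self.component_names),
            "true_weights": [float(w) for w in self.true_weights],
            "true_beta1": float(self.true_beta1),
            "true_beta0": float(self.true_beta0),
            "true_covariate_effects": {k: float(v) for k, v in self.true_covariate_effects.items()},
            "seed": int(self.seed),
            "scoring": self.scoring,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthManifest":
        return cls(**d)


def gini_coefficient(values: np.ndarray) -> float:
    """Population Gini index: sum_ij |x_i - x_j| / (2 n^2 mean(x)).

    0 for perfect equality, 1 for perfect inequality (all mass on one unit).
    Computed via the sorted-values identity, equivalent to the O(n^2)
    mean-absolute-difference definition.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValueError("values must be finite and non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("values must not all be zero")
    xs = np.sort(x)
    n = xs.size
    ranks = np.arange(1, n + 1)
    return float(2.0 * np.sum(ranks * xs) / (n * total) - (n + 1) / n)


def _raw_transform(name: str, latent: np.ndarray) -> np.ndarray:
    """Monotone map from a standard-normal latent to a realistic raw scale."""
    if "income" in name:
        return np.exp(10.6 + 0.40 * latent)  # log-normal dollars
    if "rent" in name:
        return np.exp(6.8 + 0.30 * latent)
    if name.startswith("pct_"):
        return np.clip(0.65 + 0.12 * latent, 0.01, 0.99)
    return latent


def generate_areas(
    n_tracts: int,
    bgs_per_tract: int,
    var_names_bg: list[str] | None = None,
    var_names_tract: list[str] | None = None,
    within_tract_corr: float = 0.35,
    between_var_corr: float = 0.55,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate block-group and tract area tables from the latent-factor model.

    Returns ``(block_group_table, tract_table)``, both indexed by ``area_id``.
    The block-group table has one numeric column per block-group variable plus
    ``parent_id``; the tract table has the within-tract means of those same
    variables plus any tract-only variables.
    """
    if n_tracts < 2 or bgs_per_tract < 1:
        raise ValueError("need n_tracts >= 2 and bgs_per_tract >= 1")
    for name, r in (("within_tract_corr", within_tract_corr),
                    ("between_var_corr", between_var_corr)):
        if not 0.0 <= r < 1.0:
            raise ValueError(f"{name} must be in [0, 1), got {r}")
    if between_var_corr < within_tract_corr:
        raise ValueError(
            "between_var_corr must be >= within_tract_corr in the latent-factor model"
        )
    var_names_bg = list(BG_VARIABLES if var_names_bg is None else var_names_bg)
    var_names_tract = list(TRACT_ONLY_VARIABLES if var_names_tract is None else var_names_tract)

    a = np.sqrt(within_tract_corr)
    b = np.sqrt(between_var_corr - within_tract_corr)
    c = np.sqrt(1.0 - between_var_corr)

    rng = np.random.default_rng(seed)
    nv = len(var_names_bg)
    f = rng.standard_normal(n_tracts)  # tract SES factor
    u = rng.standard_normal((n_tracts, bgs_per_tract))  # block-group factor
    e = rng.standard_normal((n_tracts, bgs_per_tract, nv))
    latent = a * f[:, None, None] + b * u[:, :, None] + c * e

    tract_ids = [f"t{t:05d}" for t in range(n_tracts)]
    bg_ids = [f"bg{t:05d}_{j:02d}" for t in range(n_tracts) for j in range(bgs_per_tract)]

    bg = pd.DataFrame(index=pd.Index(bg_ids, name="area_id"))
    for v, name in enumerate(var_names_bg):
        bg[name] = _raw_transform(name, latent[:, :, v].reshape(-1))
    bg["parent_id"] = np.repeat(tract_ids, bgs_per_tract)

    tract = pd.DataFrame(index=pd.Index(tract_ids, name="area_id"))
    for name in var_names_bg:
        tract[name] = bg.groupby("parent_id")[name].mean().reindex(tract_ids).to_numpy()
    for name in var_names_tract:
        if "gini" in name:
            sigmas = np.clip(0.55 - 0.18 * f, 0.15, 1.2)
            tract[name] = [
                gini_coefficient(rng.lognormal(mean=10.6, sigma=s, size=80)) for s in sigmas
            ]
        else:
            noise = rng.standard_normal(n_tracts)
            tract[name] = _raw_transform(
                name, np.sqrt(between_var_corr) * f + np.sqrt(1 - between_var_corr) * noise
            )
    return bg, tract


def generate_individuals(
    n: int,
    bg_table: pd.DataFrame,
    covariate_prevalences: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample individuals: a block group (uniform), its parent tract, covariates.

    ``covariate_prevalences`` maps covariate -> {level: probability}; levels
    must belong to the covariate's enum and probabilities sum to 1.  Returns a
    table without an outcome column.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    prev = dict(DEFAULT_PREVALENCES)
    if covariate_prevalences:
        prev.update(covariate_prevalences)
    for cov, probs in prev.items():
        if cov not in assembly.COVARIATE_LEVELS:
            raise ValueError(f"unknown covariate {cov!r}")
        bad = sorted(set(probs) - set(assembly.COVARIATE_LEVELS[cov]))
        if bad:
            raise ValueError(f"unknown {cov} level(s) in prevalences: {bad}")
        if abs(sum(probs.values()) - 1.0) > 1e-8:
            raise ValueError(f"{cov} prevalences must sum to 1")

    rng = np.random.default_rng(seed)
    bg_ids = bg_table.index.to_numpy()
    chosen = rng.choice(bg_ids, size=n)
    parents = bg_table["parent_id"].reindex(chosen).to_numpy()
    out = pd.DataFrame(
        {
            "individual_id": np.arange(n),
            "block_group_id": chosen,
            "tract_id": parents,
        }
    )
    for cov, probs in prev.items():
        levels = list(probs)
        p = np.array([probs[l] for l in levels], dtype=float)
        out[cov] = rng.choice(levels, size=n, p=p / p.sum())
    return out


def calibrate_intercept(partial_lp: np.ndarray, target_prevalence: float) -> float:
    """Solve for the intercept making mean(expit(b0 + lp)) equal the target."""
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must be in (0, 1)")
    lp = np.asarray(partial_lp, dtype=float)

    def f(b0: float) -> float:
        return float(np.mean(expit(b0 + lp)) - target_prevalence)

    return float(brentq(f, -30.0, 30.0, xtol=1e-10))


def generate_outcomes(
    individuals: pd.DataFrame, scored: pd.DataFrame | np.ndarray, truth: TruthManifest
) -> pd.DataFrame:
    """Draw Bernoulli outcomes from logit(p) = b0 + b1 * (q @ w) + z' phi.

    ``scored`` must align row-for-row with ``individuals``; its columns (when a
    DataFrame) must match the truth's component order.
    """
    q = scored[truth.component_names].to_numpy(dtype=float) if isinstance(
        scored, pd.DataFrame
    ) else np.asarray(scored, dtype=float)
    if q.shape[0] != len(individuals):
        raise ValueError(
            f"scored rows ({q.shape[0]}) do not align with individuals ({len(individuals)})"
        )
    if q.shape[1] != len(truth.component_names):
        raise ValueError("scored columns do not match the truth's components")
    z = assembly.encode_covariates(individuals)
    eff = np.array([truth.true_covariate_effects.get(c, 0.0) for c in z.columns])
    lp = truth.true_beta0 + truth.true_beta1 * (q @ truth.true_weights) + z.to_numpy() @ eff
    rng = np.random.default_rng(truth.seed)
    out = individuals.copy()
    out["outcome"] = (rng.random(len(out)) < expit(lp)).astype(int)
    return out


def default_specs() -> dict[str, IndexSpec]:
    """Canonical index specifications over the generated variables.

    - ``bg1``: the 10 block-group variables;
    - ``bg2``: bg1 plus the tract-level income Gini (reversed), a multi-scale
      11-component index;
    - ``ct2``: the bg1 variables measured at the tract scale instead.
    """
    bg_comps = [ComponentDef(v, v, "block_group") for v in BG_VARIABLES]
    ct_comps = [ComponentDef(v, v, "tract") for v in BG_VARIABLES]
    gini = ComponentDef("gini_income", "gini_income", "tract", "one_minus")
    return {
        "bg1": IndexSpec("bg1", bg_comps),
        "bg2": IndexSpec("bg2", bg_comps + [gini]),
        "ct2": IndexSpec("ct2", ct_comps),
    }


@dataclass
class SimulatedStudy:
    """A complete synthetic study: individuals, area tables, spec, ground truth."""

    individuals: pd.DataFrame
    areas: dict[str, pd.DataFrame]
    spec: IndexSpec
    truth: TruthManifest


def simulate_study(
    seed: int = 0,
    n_individuals: int = 10_000,
    n_tracts: int = 200,
    bgs_per_tract: int = 5,
    spec: IndexSpec | None = None,
    true_weights: np.ndarray | None = None,
    true_beta1: float = 0.4,
    target_prevalence: float = 0.526,
    covariate_effects: dict[str, float] | None = None,
    covariate_prevalences: dict[str, dict[str, float]] | None = None,
    within_tract_corr: float = 0.35,
    between_var_corr: float = 0.55,
    generation_scoring: str = "quantile",
) -> SimulatedStudy:
    """Generate a full study with a known-truth weighted-quantile index effect.

    Outcomes are generated from quartile scores of the spec's components
    (population-wide breaks), so the default estimation model is correctly
    specified; ``generation_scoring="zscore"`` provides a misspecification
    toggle.  The intercept is calibrated so the outcome prevalence matches
    ``target_prevalence``.
    """
    ss = np.random.SeedSequence(seed)
    s_area, s_ind, s_out = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))

    if spec is None:
        spec = default_specs()["bg1"]
    if true_weights is None:
        c = spec.n_components
        if c == len(DEFAULT_TRUE_WEIGHTS_10):
            true_weights = DEFAULT_TRUE_WEIGHTS_10
        elif c > len(DEFAULT_TRUE_WEIGHTS_10):
            true_weights = np.concatenate(
                [DEFAULT_TRUE_WEIGHTS_10, np.zeros(c - len(DEFAULT_TRUE_WEIGHTS_10))]
            )
        else:
            w = DEFAULT_TRUE_WEIGHTS_10[:c]
            true_weights = w / w.sum()
    if covariate_effects is None:
        covariate_effects = dict(DEFAULT_COVARIATE_EFFECTS)

    bg, tract = generate_areas(
        n_tracts, bgs_per_tract,
        within_tract_corr=within_tract_corr, between_var_corr=between_var_corr,
        seed=s_area,
    )
    areas = {"block_group": bg, "tract": tract}
    individuals = generate_individuals(
        n_individuals, bg, covariate_prevalences=covariate_prevalences, seed=s_ind
    )
    components = assembly.join_components(individuals, areas, spec)
    rules = scoring.fit_index_rules(components, spec, mode=generation_scoring)
    q = scoring.score_index(components, spec, rules)

    z = assembly.encode_covariates(individuals)
    eff = np.array([covariate_effects.get(col, 0.0) for col in z.columns])
    partial_lp = true_beta1 * (q.to_numpy() @ np.asarray(true_weights, float)) + z.to_numpy() @ eff
    beta0 = calibrate_intercept(partial_lp, target_prevalence)

    truth = TruthManifest(
        component_names=spec.component_names,
        true_weights=np.asarray(true_weights, dtype=float),
        true_beta1=float(true_beta1),
        true_beta0=beta0,
        true_covariate_effects=covariate_effects,
        seed=s_out,
        scoring=generation_scoring,
    )
    individuals = generate_outcomes(individuals, q, truth)
    return SimulatedStudy(individuals=individuals, areas=areas, spec=spec, truth=truth)


def write_dataset(outdir: str | Path, study: SimulatedStudy) -> None:
    """Write CSV tables plus a JSON sidecar with the truth manifest and spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.individuals.to_csv(outdir / "individuals.csv", index=False)
    study.areas["block_group"].to_csv(outdir / "areas_block_group.csv")
    study.areas["tract"].to_csv(outdir / "areas_tract.csv")
    sidecar = {"truth": study.truth.to_dict(), "spec": study.spec.to_dict()}
    (outdir / "truth.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_dataset(indir: str | Path) -> SimulatedStudy:
    """Read a dataset written by :func:`write_dataset`."""
    indir = Path(indir)
    # "null" is a legitimate covariate level, not a missing value
    individuals = pd.read_csv(indir / "individuals.csv", keep_default_na=False,
                              na_values=[""])
    bg = pd.read_csv(indir / "areas_block_group.csv", index_col="area_id")
    tract = pd.read_csv(indir / "areas_tract.csv", index_col="area_id")
    sidecar = json.loads((indir / "truth.json").read_text())
    return SimulatedStudy(
        individuals=individuals,
        areas={"block_group": bg, "tract": tract},
        spec=IndexSpec.from_dict(sidecar["spec"]),
        truth=TruthManifest.from_dict(sidecar["truth"]),
    )
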