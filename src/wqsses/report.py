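"""Fitting and comparing a portfolio of index specifications.

Several candidate index definitions (different spatial scales, variable sets,
quantile vs. z-score scoring, estimated vs. equal weights) are fitted on the
*same* train/validation split and ranked by validation AIC.  Comparing AICs is
only meaningful on a common validation set, so the portfolio runner forces a
shared split seed and the tabulator refuses to mix fits from different splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .specs import IndexSpec
from .wqs import WQSFit, WQSOptions, aic, run_wqs  # noqa: F401  (aic re-exported here)


@dataclass
class PortfolioModel:
    """One named entry of a model portfolio: a spec plus its fitting options."""

    name: str
    spec: IndexSpec
    options: WQSOptions = field(default_factory=WQSOptions)


@dataclass
class ModelPortfolio:
    """A named collection of candidate index models."""

    models: list[PortfolioModel]

    def __post_init__(self) -> None:
        names = [m.name for m in self.models]
        if len(set(names)) != len(names):
            raise ValueError("portfolio model names must be unique")


@dataclass
class ComparisonTable:
    """Ranked comparison of fitted models plus weight and odds-ratio tables."""

    models: pd.DataFrame  # name, aic, delta_aic, mode, weight_mode, odds_ratio, ci
    weights: pd.DataFrame  # long format: model, component, weight
    odds_ratios: pd.DataFrame  # long format: model, term, odds_ratio, ci, pvalue
    provenance: dict
    failures: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "models": self.models.to_dict(orient="records"),
            "weights": self.weights.to_dict(orient="records"),
            "odds_ratios": self.odds_ratios.to_dict(orient="records"),
            "provenance": self.provenance,
            "failures": self.failures,
        }


def tabulate_fits(fits: dict[str, WQSFit], failures: dict[str, str] | None = None) -> ComparisonTable:
    """Build a ComparisonTable from named fits sharing one split.

    Raises if the fits disagree on split seed, fraction or total sample size
    (their AICs would not be comparable).
    """
    if not fits:
        raise ValueError("no fits to tabulate")
    keys = ("split_seed", "fraction", "n_total")
    stamps = {name: tuple(f.provenance.get(k) for k in keys) for name, f in fits.items()}
    if len(set(stamps.values())) > 1:
        raise ValueError(f"fits come from different splits; refusing to compare AICs: {stamps}")

    rows, wrows, orows = [], [], []
    for name, f in fits.items():
        rows.append(
            {
                "model": name,
                "aic": f.aic,
                "mode": f.mode,
                "weight_mode": f.weight_mode,
                "odds_ratio": f.odds_ratio,
                "ci_low": f.ci_low,
                "ci_high": f.ci_high,
                "pvalue": f.pvalue,
                "converged": f.converged,
            }
        )
        for comp, w in zip(f.weights.components, f.weights.w):
            wrows.append({"model": name, "component": comp, "weight": float(w)})
        keep = f.coef_table[f.coef_table["term"] != "intercept"]
        for _, r in keep.iterrows():
            orows.append(
                {
                    "model": name,
                    "term": r["term"],
                    "odds_ratio": float(r["odds_ratio"]),
                    "ci_low": float(r["ci_low"]),
                    "ci_high": float(r["ci_high"]),
                    "pvalue": float(r["pvalue"]),
                }
            )
    models = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    models["delta_aic"] = models["aic"] - models["aic"].min()
    first = next(iter(fits.values()))
    provenance = {k: first.provenance.get(k) for k in keys}
    return ComparisonTable(
        models=models,
        weights=pd.DataFrame(wrows),
        odds_ratios=pd.DataFrame(orows),
        provenance=provenance,
        failures=failures or {},
    )


def run_portfolio(
    individuals: pd.DataFrame,
    area_tables: dict[str, pd.DataFrame],
    portfolio: ModelPortfolio,
    split_seed: int = 0,
    fraction: float = 0.5,
) -> ComparisonTable:
    """Fit every portfolio model on a shared split and rank by validation AIC.

    A model that fails is recorded under ``failures`` and does not abort the
    rest of the portfolio.
    """
    fits: dict[str, WQSFit] = {}
    failures: dict[str, str] = {}
    for m in portfolio.models:
        opts = replace(m.options, split_seed=split_seed, fraction=fraction)
        try:
            fits[m.name] = run_wqs(individuals, area_tables, m.spec, opts)
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            failures[m.name] = f"{type(exc).__name__}: {exc}"
    if not fits:
        raise RuntimeError(f"every portfolio model failed: {failures}")
    return tabulate_fits(fits, failures)


def render_tables(table: ComparisonTable, outdir: str | Path, format: str = "csv") -> list[Path]:
    """Write the comparison to disk.

    ``csv`` writes models.csv, a wide weight table (rows = models, columns =
    components) and a wide odds-ratio table (rows = terms, columns = models);
    ``json`` writes a single comparison.json; ``both`` writes all of them.
    """
    if format not in ("csv", "json", "both"):
        raise ValueError(f"unknown format {format!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if format in ("csv", "both"):
        p = outdir / "models.csv"
        table.models.to_csv(p, index=False)
        written.append(p)
        wide_w = table.weights.pivot(index="model", columns="component", values="weight")
        p = outdir / "weights.csv"
        wide_w.to_csv(p)
        written.append(p)
        wide_or = table.odds_ratios.pivot(index="term", columns="model", values="odds_ratio")
        p = outdir / "odds_ratios.csv"
        wide_or.to_csv(p)
        written.append(p)
    if format in ("json", "both"):
        p = outdir / "comparison.json"
        p.write_text(json.dumps(table.to_dict(), indent=2, sort_keys=True))
        written.append(p)
    return written
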