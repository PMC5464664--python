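"""Component scoring: direction alignment, quartile scores, z-score comparator.

Raw component values are transformed before entering the weighted index.  In
quantile mode each component is cut at empirical quantile breaks derived from
the *training* split only and coded as integers 0..Q-1, so a unit increase in
the index corresponds to one quantile step.  The z-score mode standardises with
training mean and standard deviation and reproduces the conventional
Townsend/Carstairs-style z-score index when combined with equal weights.

Tie rule: a value exactly equal to a breakpoint is assigned the upper bin.
Validation rows never influence the fitted breaks (no leakage into the
held-out effect estimate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .specs import Direction, IndexSpec


class ConstantComponentError(ValueError):
    """Raised when a z-score rule is requested for a constant component (sd = 0)."""


def align_direction(values: np.ndarray, direction: Direction | str) -> np.ndarray:
    """Orient raw values: identity, or 1 - x for inverse-coded [0, 1] variables."""
    direction = Direction(direction)
    values = np.asarray(values, dtype=float)
    if direction is Direction.AS_IS:
        return values
    if np.any((values < 0) | (values > 1)):
        raise ValueError("one_minus direction requires values in [0, 1]")
    return 1.0 - values


@dataclass
class ScoringRule:
    """Per-component scoring parameters derived from training data."""

    mode: str  # "quantile" | "zscore"
    n_quantiles: int = 4
    breaks: np.ndarray | None = None  # quantile mode: Q-1 non-decreasing cut points
    mean: float | None = None  # zscore mode
    sd: float | None = None

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_quantiles": self.n_quantiles,
            "breaks": None if self.breaks is None else [float(b) for b in self.breaks],
            "mean": self.mean,
            "sd": self.sd,
        }


def fit_scoring_rule(
    training_values: np.ndarray, mode: str = "quantile", n_quantiles: int = 4
) -> ScoringRule:
    """Derive a scoring rule from one component's training values.

    Quantile mode stores the 1/Q ... (Q-1)/Q empirical quantiles; z-score mode
    stores the training mean and (ddof=1) standard deviation.
    """
    x = np.asarray(training_values, dtype=float)
    if x.ndim != 1 or x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("training values must be a finite, non-empty 1-D array")
    if mode == "quantile":
        if n_quantiles < 2:
            raise ValueError("n_quantiles must be >= 2")
        if np.unique(x).size < n_quantiles:
            raise ValueError(
                f"need at least {n_quantiles} distinct training values for "
                f"{n_quantiles}-quantile scoring"
            )
        probs = np.arange(1, n_quantiles) / n_quantiles
        return ScoringRule(mode="quantile", n_quantiles=n_quantiles,
                           breaks=np.quantile(x, probs))
    if mode == "zscore":
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        if sd == 0.0:
            raise ConstantComponentError("constant component: sd = 0 in zscore mode")
        return ScoringRule(mode="zscore", mean=float(np.mean(x)), sd=sd)
    raise ValueError(f"unknown scoring mode {mode!r}")


def score(values: np.ndarray, rule: ScoringRule) -> np.ndarray:
    """Apply a fitted rule: integer bins 0..Q-1 (quantile) or (x-mean)/sd (zscore)."""
    x = np.asarray(values, dtype=float)
    if rule.mode == "quantile":
        if rule.breaks is None:
            raise ValueError("quantile rule has no fitted breaks")
        # side="right": a value equal to a break goes to the upper bin
        return np.searchsorted(rule.breaks, x, side="right").astype(float)
    if rule.mode == "zscore":
        if rule.mean is None or rule.sd is None or rule.sd <= 0:
            raise ValueError("zscore rule not fitted")
        return (x - rule.mean) / rule.sd
    raise ValueError(f"unknown scoring mode {rule.mode!r}")


def fit_index_rules(
    components: pd.DataFrame,
    spec: IndexSpec,
    mode: str = "quantile",
    n_quantiles: int = 4,
    training_mask: np.ndarray | None = None,
) -> dict[str, ScoringRule]:
    """Fit one rule per component of *spec*, applying direction alignment first.

    Breaks/moments are computed on ``training_mask`` rows only when a mask is
    given, otherwise on all rows.
    """
    rules: dict[str, ScoringRule] = {}
    for comp in spec.components:
        values = components[comp.name].to_numpy(dtype=float)
        if training_mask is not None:
            values = values[np.asarray(training_mask, dtype=bool)]
        aligned = align_direction(values, comp.direction)
        rules[comp.name] = fit_scoring_rule(aligned, mode=mode, n_quantiles=n_quantiles)
    return rules


def score_index(
    components: pd.DataFrame, spec: IndexSpec, rules: dict[str, ScoringRule]
) -> pd.DataFrame:
    """Score every component of *spec* with its fitted rule (column order = spec order)."""
    out = {}
    for comp in spec.components:
        if comp.name not in rules:
            raise KeyError(f"no fitted scoring rule for component {comp.name!r}")
        aligned = align_direction(components[comp.name].to_numpy(dtype=float), comp.direction)
        out[comp.name] = score(aligned, rules[comp.name])
    return pd.DataFrame(out, index=components.index)
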