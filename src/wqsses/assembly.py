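"""Joining individuals to area-level components, covariate encoding, data splitting.

Individuals carry a block-group ID and its parent tract ID; components are
looked up at whichever scale their definition declares, so an index can mix
scales. Categorical covariates are expanded to indicator columns against fixed
reference levels, and the train/validation partition is a seeded random split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .specs import IndexSpec, Scale

# Categorical covariate levels; the first-listed reference level is omitted
# from the indicator encoding.
COVARIATE_LEVELS: dict[str, list[str]] = {
    "age_band": ["50-54", "55-59", "60-64", "65-69", "70-74"],
    "gender": ["female", "male"],
    "race": ["white", "black", "asian", "american_indian", "native_hawaiian", "null"],
    "ethnicity": ["non_hispanic", "hispanic", "null"],
    "tobacco": ["never", "quit", "passive", "yes", "null"],
}

REFERENCE_LEVELS: dict[str, str] = {
    "age_band": "70-74",
    "gender": "female",
    "race": "white",
    "ethnicity": "non_hispanic",
    "tobacco": "never",
}


def _column_name(covariate: str, level: str) -> str:
    if covariate == "age_band":
        return "age_" + level.replace("-", "_")
    if covariate == "gender":
        return level
    return f"{covariate}_{level}"


def covariate_columns() -> list[str]:
    """Names of all indicator columns, in covariate-then-level order."""
    cols = []
    for cov, levels in COVARIATE_LEVELS.items():
        for level in levels:
            if level != REFERENCE_LEVELS[cov]:
                cols.append(_column_name(cov, level))
    return cols


@dataclass
class SplitPlan:
    """Seeded boolean partition of individuals into training and validation."""

    training: np.ndarray  # bool, one flag per individual
    fraction: float
    seed: int

    @property
    def n(self) -> int:
        return self.training.size

    @property
    def training_idx(self) -> np.ndarray:
        return np.flatnonzero(self.training)

    @property
    def validation_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.training)


def make_split(n: int, fraction: float = 0.5, seed: int = 0) -> SplitPlan:
    """Randomly assign exactly round(n * fraction) individuals to training."""
    if n < 4:
        raise ValueError(f"need at least 4 individuals to split, got {n}")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n_train = int(round(n * fraction))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    training = np.zeros(n, dtype=bool)
    training[perm[:n_train]] = True
    return SplitPlan(training=training, fraction=fraction, seed=seed)


def join_components(
    individuals: pd.DataFrame,
    area_tables: dict[str, pd.DataFrame],
    spec: IndexSpec,
) -> pd.DataFrame:
    """Assemble the raw component matrix (one column per component, spec order).

    Row i, column j holds the value of component j's variable in individual
    i's area at that component's scale.  Direction alignment is *not* applied
    here; it belongs to scoring.

    Parameters
    ----------
    individuals : table with ``block_group_id`` and ``tract_id`` columns.
    area_tables : mapping ``{"block_group": ..., "tract": ...}`` of tables
        indexed by area ID.
    """
    id_col = {Scale.BLOCK_GROUP: "block_group_id", Scale.TRACT: "tract_id"}
    out = {}
    for comp in spec.components:
        table = area_tables.get(comp.scale.value)
        if table is None:
            raise ValueError(f"no area table for scale {comp.scale.value!r}")
        if comp.variable not in table.columns:
            raise ValueError(
                f"variable {comp.variable!r} not present at scale "
                f"{comp.scale.value!r} (component {comp.name!r})"
            )
        ids = individuals[id_col[comp.scale]]
        missing = pd.unique(ids[~ids.isin(table.index)])
        if missing.size:
            shown = ", ".join(map(repr, missing[:5]))
            raise ValueError(
                f"{missing.size} area IDs missing from the {comp.scale.value} "
                f"table for component {comp.name!r}: {shown}"
            )
        out[comp.name] = table[comp.variable].reindex(ids).to_numpy(dtype=float)
    return pd.DataFrame(out, index=individuals.index)


def encode_covariates(individuals: pd.DataFrame) -> pd.DataFrame:
    """Indicator-encode the categorical covariates, omitting reference levels.

    Returns an n x p 0/1 matrix with one column per non-reference level;
    an individual at all reference levels yields an all-zero row.
    """
    n = len(individuals)
    out = pd.DataFrame(index=individuals.index)
    for cov, levels in COVARIATE_LEVELS.items():
        values = individuals[cov].astype(str)
        unseen = sorted(set(values.unique()) - set(levels))
        if unseen:
            raise ValueError(f"unknown {cov} level(s): {unseen}")
        for level in levels:
            if level == REFERENCE_LEVELS[cov]:
                continue
            out[_column_name(cov, level)] = (values == level).to_numpy(dtype=float)
    assert out.shape == (n, len(covariate_columns()))
    return out
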