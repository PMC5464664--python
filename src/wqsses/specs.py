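"""Index specifications: named sets of components bound to a variable, a spatial scale
and a direction.

An SES (socioeconomic status) index is a weighted sum of scored component
variables.  Each component names an area-level variable, the spatial scale it is
measured at (census block group or tract), and whether its raw values enter
as-is or reversed (``1 - x``, for variables such as the Gini inequality index
whose natural direction opposes the rest of the index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import yaml


class Scale(str, Enum):
    """Spatial scale of an area-level variable (block groups nest within tracts)."""

    BLOCK_GROUP = "block_group"
    TRACT = "tract"


class Direction(str, Enum):
    """Orientation applied to raw values before scoring.

    ``ONE_MINUS`` maps x to 1 - x and is only valid for variables bounded in
    [0, 1]; it aligns inverse-coded variables (e.g. an inequality measure) with
    the hypothesised positive direction of the index.
    """

    AS_IS = "as_is"
    ONE_MINUS = "one_minus"


@dataclass(frozen=True)
class ComponentDef:
    """One index component: a variable at a spatial scale with a direction."""

    name: str
    variable: str
    scale: Scale
    direction: Direction = Direction.AS_IS

    def __post_init__(self) -> None:
        object.__setattr__(self, "scale", Scale(self.scale))
        object.__setattr__(self, "direction", Direction(self.direction))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "variable": self.variable,
            "scale": self.scale.value,
            "direction": self.direction.value,
        }


@dataclass
class IndexSpec:
    """An ordered list of components defining one candidate SES index.

    Components may mix spatial scales (a multi-scale index). Component names
    must be unique and at least one component is required.
    """

    name: str
    components: list[ComponentDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.components = [
            c if isinstance(c, ComponentDef) else ComponentDef(**c)
            for c in self.components
        ]
        if not self.components:
            raise ValueError(f"index spec {self.name!r} has no components")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate component names in {self.name!r}: {dupes}")

    @property
    def component_names(self) -> list[str]:
        return [c.name for c in self.components]

    @property
    def n_components(self) -> int:
        return len(self.components)

    def to_dict(self) -> dict:
        return {"name": self.name, "components": [c.to_dict() for c in self.components]}

    @classmethod
    def from_dict(cls, d: dict) -> "IndexSpec":
        return cls(name=d["name"], components=[ComponentDef(**c) for c in d["components"]])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "IndexSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
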