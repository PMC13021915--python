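"""Cell table: one row per segmented cell.

The table is a pandas DataFrame wrapped with its marker panel and a
transform-state tag.  Mandatory columns are ``cell_id``, ``sample_id``,
``roi_id``, ``group``, ``x``, ``y`` (centroid, μm, per-ROI frame, origin
top-left, y down) plus one intensity column per panel marker.  Nuclear
readouts live in ``nuc_<marker>`` columns; classification and geometry
results are added in place as ``region``, ``signed_distance`` and
``level1``..``level4``.

``transform_state`` tracks the intensity scale and only moves forward:
raw → winsorized → arcsinh.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import StateError, ValidationError
from .panel import MarkerPanel

GROUPS = ("Control", "ONJ", "Tonsil")
REGION_NAMES = ("epithelium", "stroma", "vessel")

#: Ordered transform states; transitions may only move right.
TRANSFORM_STATES = ("raw", "winsorized", "arcsinh")

META_COLUMNS = ("cell_id", "sample_id", "roi_id", "group", "x", "y")

NUCLEAR_PREFIX = "nuc_"


def nuclear_column(marker: str) -> str:
    return NUCLEAR_PREFIX + marker


@dataclass
class CellTable:
    """Per-cell measurements plus panel and transform bookkeeping."""

    data: pd.DataFrame
    panel: MarkerPanel
    transform_state: str = "raw"

    def __post_init__(self) -> None:
        if self.transform_state not in TRANSFORM_STATES:
            raise ValidationError(f"unknown transform_state {self.transform_state!r}")
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"cell table missing mandatory columns: {missing}")
        missing_markers = [m for m in self.panel.names if m not in self.data.columns]
        if missing_markers:
            raise ValidationError(f"cell table missing marker columns: {missing_markers}")
        bad_groups = set(self.data["group"].unique()) - set(GROUPS)
        if bad_groups:
            raise ValidationError(
                f"unknown group labels {sorted(bad_groups)}; expected one of {GROUPS}"
            )
        xy = self.data[["x", "y"]].to_numpy(float)
        if not np.all(np.isfinite(xy)):
            bad = self.data.loc[~np.isfinite(xy).all(axis=1), "cell_id"].tolist()
            raise ValidationError(f"non-finite coordinates for cells {bad[:5]}")
        if self.transform_state == "raw":
            inten = self.data[self.panel.names].to_numpy(float)
            if np.any(inten < 0):
                rows = np.unique(np.nonzero(inten < 0)[0])
                bad = self.data.iloc[rows]["cell_id"].tolist()
                raise ValidationError(f"negative raw intensities for cells {bad[:5]}")

    # -- convenience ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def markers(self) -> list[str]:
        return self.panel.names

    def intensities(self, markers: list[str] | None = None) -> pd.DataFrame:
        """Whole-cell intensity block (view on the underlying frame)."""
        return self.data[markers if markers is not None else self.panel.names]

    def intensity_for(self, marker: str, compartment: str | None = None) -> pd.Series:
        """Intensity for one marker, honouring its panel compartment.

        Falls back to the whole-cell column when a nuclear channel is
        requested but absent.
        """
        comp = compartment or self.panel[marker].compartment
        if comp == "nuclear":
            col = nuclear_column(marker)
            if col in self.data.columns:
                return self.data[col]
        return self.data[marker]

    def nuclear_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith(NUCLEAR_PREFIX)]

    def with_state(self, state: str) -> "CellTable":
        """Return a tag-updated shallow copy, enforcing forward transitions."""
        if TRANSFORM_STATES.index(state) < TRANSFORM_STATES.index(self.transform_state):
            raise StateError(
                f"cannot move transform_state backwards: {self.transform_state} -> {state}"
            )
        return replace(self, transform_state=state)

    def copy(self) -> "CellTable":
        return CellTable(self.data.copy(), self.panel, self.transform_state)
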