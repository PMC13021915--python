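"""Region label raster.

Tissue sections are partitioned into three anatomical regions —
epithelium, stroma and vessel — stored as an integer raster with a
physical pixel size in μm.  Label 0 is background (no tissue / no
annotation); every nonzero label must appear in the legend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .celltable import REGION_NAMES
from .errors import ValidationError

DEFAULT_LEGEND = {1: "epithelium", 2: "stroma", 3: "vessel"}


@dataclass
class RegionMap:
    labels: np.ndarray                  # 2-D integer raster, row = y, col = x
    pixel_size: float                   # μm per pixel, square pixels
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError(f"region raster must be 2-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("region raster must have an integer dtype")
        if not self.pixel_size > 0:
            raise ValidationError("pixel_size must be > 0")
        bad_names = set(self.legend.values()) - set(REGION_NAMES)
        if bad_names:
            raise ValidationError(
                f"legend names {sorted(bad_names)} not in {REGION_NAMES}"
            )
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.legend)
        if unknown:
            raise ValidationError(f"raster labels {sorted(unknown)} missing from legend")

    # -- geometry ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def height_um(self) -> float:
        return self.labels.shape[0] * self.pixel_size

    @property
    def width_um(self) -> float:
        return self.labels.shape[1] * self.pixel_size

    def code_for(self, region: str) -> int:
        for code, name in self.legend.items():
            if name == region:
                return code
        raise ValidationError(f"region {region!r} not in legend {self.legend}")

    def region_mask(self, region: str) -> np.ndarray:
        return self.labels == self.code_for(region)

    def area_um2(self, region: str) -> float:
        return float(self.region_mask(region).sum()) * self.pixel_size**2

    def region_at(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Region name under each point; 'none' on background.

        Points are mapped to the pixel containing them (floor of the
        coordinate divided by pixel size).  Out-of-bounds points raise.
        """
        col = np.floor(np.asarray(x_um, float) / self.pixel_size).astype(int)
        row = np.floor(np.asarray(y_um, float) / self.pixel_size).astype(int)
        h, w = self.labels.shape
        oob = (col < 0) | (col >= w) | (row < 0) | (row >= h)
        if np.any(oob):
            raise ValidationError(
                f"{int(oob.sum())} point(s) outside the raster bounds"
            )
        codes = self.labels[row, col]
        names = np.full(codes.shape, "none", dtype=object)
        for code, name in self.legend.items():
            names[codes == code] = name
        return names
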