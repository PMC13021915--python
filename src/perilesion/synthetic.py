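"""Synthetic tissue cohort generator.

Emulates the data structure of an IMC study of peri-lesional oral mucosa:
a cohort of 8 Control and 6 ONJ individuals, 2–5 ROIs each, a 38-marker
panel, and three annotated tissue regions (an epithelial band, stroma,
and vessel disks inside the stroma).  Cells are points placed per type
and region by a homogeneous Poisson process (CSR), a Thomas cluster
process (planted attraction) or a hard-core inhibition process (planted
avoidance).  Marker intensities are drawn from a two-population
lognormal model: a marker is "positive" in a cell with some probability
(1 for a type's signature markers, a baseline rate for functional
markers) and its intensity is then drawn from the positive or the
negative/background lognormal accordingly.

Group differences are *planted* and recorded in a
:class:`SyntheticTruth`: shifted type proportions (default Treg 2% in
Control vs 6% in ONJ), a spatial-mode switch (Treg CSR → Thomas in ONJ),
raised functional positivity (Ki67, pNFkB), and a higher overall cell
density in ONJ.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .celltable import CellTable
from .errors import ConfigurationError, ParameterError
from .panel import MarkerPanel
from .regionmap import RegionMap

IMMUNE_SUBTYPES = (
    "B", "CD4 T", "CD8 T", "BnT", "macrophage", "M2", "NK", "Treg",
    "exhausted T", "DC",
)
STRUCTURAL_TYPES = ("epithelial", "endothelial", "fibroblast", "functional", "unclassified")
ALL_TYPES = STRUCTURAL_TYPES + IMMUNE_SUBTYPES


def level1_of(cell_type: str) -> str:
    return "immune" if cell_type in IMMUNE_SUBTYPES else cell_type


# ---------------------------------------------------------------------
# spatial modes
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class SpatialMode:
    """How points of one type are arranged within their region.

    kind 'csr' — homogeneous Poisson; 'thomas' — Poisson parents with
    ``mu`` Gaussian-dispersed (sd ``sigma`` μm) offspring each, parent
    intensity ``kappa`` per μm² (derived from the type's intensity when
    None); 'inhibition' — hard-core thinning with minimum spacing
    ``r_min`` μm.
    """

    kind: str = "csr"
    kappa: float | None = None
    mu: float | None = None
    sigma: float | None = None
    r_min: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("csr", "thomas", "inhibition"):
            raise ParameterError(f"unknown spatial mode {self.kind!r}")
        if self.kind == "thomas":
            if not (self.mu and self.mu > 0 and self.sigma and self.sigma > 0):
                raise ParameterError("thomas mode needs mu > 0 and sigma > 0")
            if self.kappa is not None and not self.kappa > 0:
                raise ParameterError("thomas kappa must be > 0")
        if self.kind == "inhibition" and not (self.r_min and self.r_min > 0):
            raise ParameterError("inhibition mode needs r_min > 0")

    @classmethod
    def csr(cls) -> "SpatialMode":
        return cls("csr")

    @classmethod
    def thomas(cls, mu: float = 20.0, sigma: float = 15.0, kappa: float | None = None) -> "SpatialMode":
        return cls("thomas", kappa=kappa, mu=mu, sigma=sigma)

    @classmethod
    def inhibition(cls, r_min: float = 20.0) -> "SpatialMode":
        return cls("inhibition", r_min=r_min)


# ---------------------------------------------------------------------
# region raster
# ---------------------------------------------------------------------

def generate_region_map(
    width_um: float = 1000.0,
    height_um: float = 1000.0,
    pixel_size: float = 1.0,
    band_depth_um: float = 250.0,
    n_vessels: int = 3,
    vessel_radius_um: float | list[float] = 40.0,
    vessel_in_epithelium: bool = False,
    seed: int | np.random.Generator = 0,
) -> RegionMap:
    """Synthesise a region raster: epithelial band, stroma, vessel disks.

    The epithelium is a connected band along the top edge with a gently
    undulating lower boundary (emulating the interdigitated
    epithelium–stroma junction); vessels are non-overlapping disks placed
    uniformly inside the stroma, optionally plus one small disk inside
    the epithelium.
    """
    if width_um < 200 or height_um < 200:
        raise ParameterError("window must be at least 200×200 μm")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h = int(round(height_um / pixel_size))
    w = int(round(width_um / pixel_size))
    radii = (
        [float(vessel_radius_um)] * n_vessels
        if np.isscalar(vessel_radius_um)
        else [float(r) for r in vessel_radius_um]
    )
    if len(radii) != n_vessels:
        raise ParameterError("need one vessel radius per vessel")
    stroma_depth = height_um - band_depth_um
    if radii and n_vessels > 0 and 2 * max(radii) >= stroma_depth:
        raise ParameterError(
            f"vessel diameter {2 * max(radii):.0f} μm exceeds stroma depth {stroma_depth:.0f} μm"
        )

    labels = np.full((h, w), 2, dtype=np.uint8)  # stroma everywhere ...
    cols = np.arange(w) * pixel_size
    amp = 0.1 * band_depth_um
    wavelength = max(width_um / 4.0, 1.0)
    phase = rng.uniform(0, 2 * np.pi)
    boundary = band_depth_um + amp * np.sin(2 * np.pi * cols / wavelength + phase)
    rows_um = (np.arange(h) + 0.5) * pixel_size
    labels[rows_um[:, None] < boundary[None, :]] = 1  # ... epithelial band on top

    # vessels: rejection-sampled non-overlapping disks inside the stroma
    yy = rows_um[:, None]
    xx = (np.arange(w)[None, :] + 0.5) * pixel_size
    centers: list[tuple[float, float, float]] = []
    for r in radii:
        placed = False
        for _ in range(2000):
            margin = r + 2 * pixel_size
            cx = rng.uniform(margin, width_um - margin)
            cy = rng.uniform(boundary.max() + margin, height_um - margin)
            if all(
                np.hypot(cx - ox, cy - oy) > r + orr + 2 * pixel_size
                for ox, oy, orr in centers
            ):
                centers.append((cx, cy, r))
                placed = True
                break
        if not placed:
            raise ParameterError("could not place vessels without overlap; reduce count/radius")
    if vessel_in_epithelium and band_depth_um > 60:
        r = min(20.0, band_depth_um / 4)
        centers.append((rng.uniform(r + 2, width_um - r - 2), band_depth_um / 2, r))
    for cx, cy, r in centers:
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        labels[disk] = 3
    return RegionMap(labels, pixel_size)


# ---------------------------------------------------------------------
# point placement
# ---------------------------------------------------------------------

def _uniform_in_region(mask: np.ndarray, pixel_size: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """n points uniform over the region: random region pixel + jitter."""
    flat = np.flatnonzero(mask)
    idx = flat[rng.integers(0, flat.size, size=n)]
    row, col = np.unravel_index(idx, mask.shape)
    x = (col + rng.uniform(0, 1, n)) * pixel_size
    y = (row + rng.uniform(0, 1, n)) * pixel_size
    return np.column_stack([x, y])


def _points_in_mask(pts: np.ndarray, mask: np.ndarray, pixel_size: float) -> np.ndarray:
    h, w = mask.shape
    col = np.floor(pts[:, 0] / pixel_size).astype(int)
    row = np.floor(pts[:, 1] / pixel_size).astype(int)
    ok = (col >= 0) & (col < w) & (row >= 0) & (row < h)
    ok[ok] = mask[row[ok], col[ok]]
    return ok


def place_points(
    region_map: RegionMap,
    region: str,
    intensity: float,
    mode: SpatialMode,
    rng: np.random.Generator,
) -> np.ndarray:
    """Place points of one type in one region at the given intensity
    (cells/μm²), arranged per the spatial mode.  Returns an (n, 2) array
    of (x, y) in μm."""
    if intensity < 0:
        raise ParameterError("intensity must be >= 0")
    if intensity == 0:
        return np.empty((0, 2))
    mask = region_map.region_mask(region)
    area = float(mask.sum()) * region_map.pixel_size**2
    if area == 0:
        raise ParameterError(f"region {region!r} has zero area but positive intensity")
    ps = region_map.pixel_size

    if mode.kind == "csr":
        n = rng.poisson(intensity * area)
        return _uniform_in_region(mask, ps, int(n), rng)

    if mode.kind == "thomas":
        kappa = mode.kappa if mode.kappa is not None else intensity / mode.mu
        n_parents = rng.poisson(kappa * area)
        if n_parents == 0:
            return np.empty((0, 2))
        parents = _uniform_in_region(mask, ps, int(n_parents), rng)
        counts = rng.poisson(mode.mu, size=n_parents)
        total = int(counts.sum())
        if total == 0:
            return np.empty((0, 2))
        centers = np.repeat(parents, counts, axis=0)
        pts = centers + rng.normal(0, mode.sigma, size=(total, 2))
        return pts[_points_in_mask(pts, mask, ps)]

    # hard-core inhibition: dart throwing toward a Poisson target count
    n_target = int(rng.poisson(intensity * area))
    accepted: list[np.ndarray] = []
    attempts = 0
    max_attempts = 50 * max(n_target, 1)
    while len(accepted) < n_target and attempts < max_attempts:
        cand = _uniform_in_region(mask, ps, 1, rng)[0]
        attempts += 1
        if all(np.hypot(*(cand - a)) >= mode.r_min for a in accepted):
            accepted.append(cand)
    return np.asarray(accepted).reshape(-1, 2)


def place_cells(
    region_map: RegionMap,
    intensities: dict[str, dict[str, float]],
    modes: dict[str, SpatialMode] | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Place all cell types: ``intensities[type][region]`` in cells/μm².

    Returns a DataFrame with x, y (μm), true_type, and region (the region
    the point was placed in — every point lies inside its region's
    pixels by construction).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    modes = modes or {}
    frames = []
    for cell_type in sorted(intensities):
        per_region = intensities[cell_type]
        mode = modes.get(cell_type, SpatialMode.csr())
        for region in sorted(per_region):
            pts = place_points(region_map, region, per_region[region], mode, rng)
            if len(pts):
                frames.append(
                    pd.DataFrame(
                        {"x": pts[:, 0], "y": pts[:, 1], "true_type": cell_type, "region": region}
                    )
                )
    if not frames:
        return pd.DataFrame(columns=["x", "y", "true_type", "region"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------
# intensity model
# ---------------------------------------------------------------------

def _default_signatures() -> dict[str, tuple[tuple[float, frozenset], ...]]:
    """Marker signatures per placement type; (weight, marker set) variants."""
    s = lambda *m: frozenset(m)  # noqa: E731
    return {
        "epithelial": ((1.0, s("Ecad", "EGFR", "PanCK")),),
        "endothelial": (
            (0.5, s("CD31", "CD140b", "CD146", "CD34")),   # blood
            (0.5, s("Podoplanin", "LYVE1")),               # lymphatic
        ),
        "fibroblast": (
            (0.7, s("CD90", "Collagen1", "Vimentin", "FSP1")),
            (0.3, s("CD90", "Collagen1", "Vimentin", "FSP1", "aSMA")),  # myofibroblast
        ),
        "functional": ((1.0, s()),),
        "unclassified": ((1.0, s()),),
        "B": ((1.0, s("CD20", "HLADR")),),
        "CD4 T": ((1.0, s("CD4")),),
        "CD8 T": ((1.0, s("CD8a")),),
        "BnT": ((1.0, s("CD20", "CD4")),),
        "macrophage": ((1.0, s("CD68", "CD11c", "HLADR")),),
        "M2": ((1.0, s("CD68", "CD163", "Arginase1", "CD11c")),),
        "NK": ((1.0, s("CD56")),),
        "Treg": ((1.0, s("CD4", "FoxP3")),),
        "exhausted T": ((1.0, s("CD8a", "PD1")),),
        "DC": ((1.0, s("CD11c", "HLADR")),),
    }


DEFAULT_FUNCTIONAL_BASELINE = {
    "Ki67": 0.15, "pERK": 0.12, "BNIP3": 0.10, "Caveolin": 0.10,
    "pNFkB": 0.10, "IntegrinB1": 0.12, "pSTAT3": 0.10, "PD1": 0.02,
    "YAP1": 0.10,
}

#: chance an immune cell picks up the region's lineage marker
DEFAULT_INFILTRATION = {
    "epithelium": ("Ecad", 0.5),
    "vessel": ("CD31", 0.3),
    "stroma": ("CD90", 0.1),
}

LEVEL4_STATES = {
    "proliferation": ("Ki67", "pERK"),
    "apoptosis": ("BNIP3",),
    "autophagy": ("Caveolin",),
    "pro-inflammatory": ("pNFkB",),
    "migration": ("IntegrinB1",),
    "transcriptional": ("pSTAT3",),
}


@dataclass
class IntensityModel:
    """Two-population lognormal intensity model.

    A positive draw has log-mean ``pos_meanlog`` and log-sd
    ``pos_sdlog``; negatives come from the background population.  The
    defining (signature) markers of a type are positive with probability
    ``signature_positive``; functional markers are positive at per-marker
    baseline rates.  ``noise_free()`` collapses both populations to
    constants for exact-recovery tests.
    """

    pos_meanlog: float = float(np.log(10.0))
    pos_sdlog: float = 0.4
    neg_meanlog: float = float(np.log(0.3))
    neg_sdlog: float = 0.4
    signature_positive: float = 1.0
    signatures: dict = field(default_factory=_default_signatures)
    functional_baseline: dict = field(default_factory=lambda: dict(DEFAULT_FUNCTIONAL_BASELINE))
    infiltration: dict = field(default_factory=lambda: dict(DEFAULT_INFILTRATION))

    def __post_init__(self) -> None:
        if self.pos_meanlog <= self.neg_meanlog:
            raise ConfigurationError("positive log-mean must exceed negative log-mean")

    @classmethod
    def noise_free(cls) -> "IntensityModel":
        """Constant intensities and unambiguous signatures.

        PD1 doubles as the exhausted-T defining marker, so its baseline
        positivity is zeroed here — otherwise a chance PD1-positive T
        cell is a *correct* exhausted-T call that disagrees with the
        planted label.
        """
        baseline = dict(DEFAULT_FUNCTIONAL_BASELINE)
        baseline["PD1"] = 0.0
        return cls(pos_sdlog=0.0, neg_sdlog=0.0, functional_baseline=baseline)

    def lognormal(self, positive: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        m = np.where(positive, self.pos_meanlog, self.neg_meanlog)
        s = np.where(positive, self.pos_sdlog, self.neg_sdlog)
        return np.exp(rng.normal(m, s))


def draw_intensities(
    cells: pd.DataFrame,
    model: IntensityModel,
    panel: MarkerPanel,
    seed: int | np.random.Generator = 0,
) -> tuple[CellTable, pd.DataFrame]:
    """Draw a raw marker-intensity table for placed cells.

    ``cells`` needs columns sample_id, roi_id, group, x, y, region,
    true_type.  Returns the raw :class:`CellTable` (with cell ids and a
    populated nuclear YAP1 channel) and the ground-truth label frame
    (true_level1..true_level4 plus the true positivity of every drawn
    marker).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells = cells.reset_index(drop=True)
    n = len(cells)
    for t in cells["true_type"].unique():
        if t not in model.signatures:
            raise ConfigurationError(f"type {t!r} has no signature in the intensity model")

    # resolve one signature variant per cell
    sig_sets = np.empty(n, dtype=object)
    for t, idx in cells.groupby("true_type", observed=True).groups.items():
        variants = model.signatures[t]
        weights = np.array([v[0] for v in variants], float)
        weights = weights / weights.sum()
        choice = rng.choice(len(variants), size=len(idx), p=weights)
        for k, i in zip(choice, idx):
            sig_sets[i] = variants[k][1]

    is_immune = cells["true_type"].isin(IMMUNE_SUBTYPES).to_numpy()
    is_filler = (cells["true_type"] == "unclassified").to_numpy()
    is_functional_type = (cells["true_type"] == "functional").to_numpy()

    # infiltration co-expression for immune cells, by region
    extra = [set() for _ in range(n)]
    regions = cells["region"].to_numpy()
    for region, (marker, prob) in model.infiltration.items():
        sel = is_immune & (regions == region)
        hits = sel & (rng.uniform(size=n) < prob)
        for i in np.flatnonzero(hits):
            extra[i].add(marker)

    gating_markers = panel.lineage + panel.functional
    positive = np.zeros((n, len(panel)), dtype=bool)
    col_of = {m: j for j, m in enumerate(panel.names)}
    for j, m in enumerate(panel.names):
        role = panel[m].role
        if role == "dna":
            positive[:, j] = True
            continue
        if role == "segmentation":
            continue
        in_sig = np.fromiter(
            (m in sig_sets[i] or m in extra[i] for i in range(n)), bool, count=n
        )
        p = np.zeros(n)
        p[in_sig] = model.signature_positive
        if role == "functional":
            base = model.functional_baseline.get(m, 0.0)
            p[~in_sig & ~is_filler] = np.maximum(p[~in_sig & ~is_filler], base)
        positive[:, j] = rng.uniform(size=n) < p

    # "functional" basic type must carry at least one functional flag
    func_cols = [col_of[m] for m in panel.functional]
    none_on = ~positive[:, func_cols].any(axis=1)
    fix = np.flatnonzero(is_functional_type & none_on)
    if fix.size:
        pick = rng.integers(0, len(func_cols), size=fix.size)
        positive[fix, np.asarray(func_cols)[pick]] = True

    data = cells[["sample_id", "roi_id", "group", "x", "y", "region"]].reset_index(drop=True).copy()
    data.insert(0, "cell_id", [
        f"{s}_{r}_{i}" for i, (s, r) in enumerate(zip(data["sample_id"], data["roi_id"]))
    ])
    for j, m in enumerate(panel.names):
        data[m] = model.lognormal(positive[:, j], rng)
    # nuclear channel for nuclear-compartment markers: the signal lives
    # there; the whole-cell column shows background only
    for m in panel.nuclear:
        j = col_of[m]
        data[f"nuc_{m}"] = data[m].to_numpy()
        data[m] = model.lognormal(np.zeros(n, bool), rng)

    truth = pd.DataFrame({"cell_id": data["cell_id"]})
    truth["true_type"] = cells["true_type"].to_numpy()
    truth["true_level1"] = [level1_of(t) for t in truth["true_type"]]
    truth["true_level2"] = [
        t if t in IMMUNE_SUBTYPES else None for t in truth["true_type"]
    ]
    lvl3 = []
    for i, t in enumerate(truth["true_type"]):
        if t not in IMMUNE_SUBTYPES:
            lvl3.append(None)
        elif "Ecad" in extra[i]:
            lvl3.append("immune-in-epithelial")
        elif "CD31" in extra[i]:
            lvl3.append("immune-in-endothelial")
        elif "CD90" in extra[i]:
            lvl3.append("immune-in-fibroblast")
        else:
            lvl3.append("immune")
    truth["true_level3"] = lvl3
    flags = []
    for i in range(n):
        fl = sorted(
            state
            for state, markers in LEVEL4_STATES.items()
            if any(positive[i, col_of[m]] for m in markers if m in col_of)
        )
        flags.append("+".join(fl) if fl else "non-functional")
    truth["true_level4"] = flags
    for m in gating_markers:
        truth[f"pos_{m}"] = positive[:, col_of[m]]

    table = CellTable(data, panel, transform_state="raw")
    return table, truth


# ---------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------

#: per-region type composition (fractions of the region's cell density;
#: normalised at use).  Chosen once to emulate oral mucosa: epithelium
#: dominated by epithelial cells, stroma by fibroblasts with a broad
#: immune infiltrate, vessels by endothelium.  DC is kept rare so the
#: min-count invalid path of the spatial scorer is exercised.
DEFAULT_COMPOSITION: dict[str, dict[str, float]] = {
    "epithelium": {
        "epithelial": 0.76, "fibroblast": 0.02, "endothelial": 0.015,
        "functional": 0.04, "unclassified": 0.04,
        "macrophage": 0.02, "M2": 0.015, "CD4 T": 0.02, "CD8 T": 0.015,
        "B": 0.01, "BnT": 0.01, "NK": 0.018, "Treg": 0.02,
        "exhausted T": 0.015, "DC": 0.002,
    },
    "stroma": {
        "fibroblast": 0.46, "endothelial": 0.08, "epithelial": 0.01,
        "functional": 0.065, "unclassified": 0.04,
        "macrophage": 0.07, "M2": 0.04, "CD4 T": 0.06, "CD8 T": 0.05,
        "B": 0.02, "BnT": 0.018, "NK": 0.035, "Treg": 0.02,
        "exhausted T": 0.025, "DC": 0.005,
    },
    "vessel": {
        "endothelial": 0.57, "fibroblast": 0.06, "epithelial": 0.0,
        "functional": 0.05, "unclassified": 0.04,
        "macrophage": 0.08, "M2": 0.035, "CD4 T": 0.05, "CD8 T": 0.04,
        "B": 0.01, "BnT": 0.01, "NK": 0.025, "Treg": 0.02,
        "exhausted T": 0.015, "DC": 0.002,
    },
}


@dataclass(frozen=True)
class CohortDesign:
    """Cohort shape and tissue geometry.

    Defaults follow the study design this generator emulates: 8 Control
    and 6 ONJ individuals, 2-5 ROIs each, 1000x1000 um windows at
    1 um/pixel.  Tests and the acceptance script pass smaller windows
    and densities to keep runtimes short.
    """

    n_control: int = 8
    n_onj: int = 6
    rois_min: int = 2
    rois_max: int = 5
    width_um: float = 1000.0
    height_um: float = 1000.0
    pixel_size: float = 1.0
    band_depth_um: float = 250.0
    n_vessels: int = 3
    vessel_radius_um: float = 40.0
    total_density: float = 1.2e-3       # cells/um^2 (Control)
    noise_free: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.rois_min <= self.rois_max):
            raise ParameterError("need 1 <= rois_min <= rois_max")


@dataclass(frozen=True)
class PlantedEffects:
    """Planted Control-vs-ONJ differences.

    ``type_proportions``: type -> (Control fraction, ONJ fraction) of all
    cells, applied uniformly across regions with the remaining
    composition rescaled.  ``spatial_modes``: type -> (Control mode, ONJ
    mode).  ``functional_positivity``: marker -> (Control, ONJ) baseline
    positive fraction.  ``density_factor`` scales the overall density
    per group.
    """

    type_proportions: tuple = (("Treg", (0.02, 0.06)),)
    spatial_modes: tuple = (("Treg", (SpatialMode.csr(), SpatialMode.thomas(mu=20.0, sigma=15.0))),)
    functional_positivity: tuple = (("Ki67", (0.15, 0.30)), ("pNFkB", (0.10, 0.25)))
    density_factor: tuple[float, float] = (1.0, 1.25)

    @classmethod
    def null(cls) -> "PlantedEffects":
        """No group differences: both groups drawn from Control parameters."""
        return cls(
            type_proportions=(("Treg", (0.02, 0.02)),),
            spatial_modes=(),
            functional_positivity=(),
            density_factor=(1.0, 1.0),
        )

    def validate(self) -> None:
        for t, _ in self.type_proportions:
            if t not in ALL_TYPES:
                raise ConfigurationError(f"planted proportion for undeclared type {t!r}")
        for t, _ in self.spatial_modes:
            if t not in ALL_TYPES:
                raise ConfigurationError(f"planted spatial mode for undeclared type {t!r}")


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for recovery testing."""

    seed: int
    sample_groups: dict[str, str]
    labels: pd.DataFrame            # per-cell true labels and positivity
    params: dict                    # planted proportions, modes, effects

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "truth_params.json").write_text(
            json.dumps({"seed": self.seed, "sample_groups": self.sample_groups,
                        "params": self.params}, indent=2, default=str)
        )
        self.labels.to_csv(out / "truth_labels.csv", index=False)


def _group_composition(
    region_comp: dict[str, float],
    planted: dict[str, float],
) -> dict[str, float]:
    """Set planted type fractions exactly; rescale the rest to fill up."""
    comp = dict(region_comp)
    free = {t: f for t, f in comp.items() if t not in planted}
    free_total = sum(free.values())
    planted_total = sum(planted.values())
    if planted_total >= 1.0:
        raise ConfigurationError("planted proportions sum to >= 1")
    scale = (1.0 - planted_total) / free_total
    out = {t: f * scale for t, f in free.items()}
    out.update(planted)
    return out


def generate_cohort(
    design: CohortDesign | None = None,
    effects: PlantedEffects | None = None,
    seed: int = 0,
    panel: MarkerPanel | None = None,
    draw_markers: bool = True,
) -> tuple[CellTable | pd.DataFrame, dict, SyntheticTruth]:
    """Generate a full synthetic cohort.

    Returns ``(cells, region_maps, truth)`` where ``region_maps`` maps
    (sample_id, roi_id) to its :class:`RegionMap`.  With
    ``draw_markers=False`` the cell frame carries only coordinates,
    regions and true labels (no intensity table) -- enough for spatial
    power studies at a fraction of the cost.
    """
    design = design or CohortDesign()
    effects = effects or PlantedEffects()
    effects.validate()
    panel = panel or MarkerPanel.default()
    root = np.random.SeedSequence(seed)
    ss_structure, ss_intensity = root.spawn(2)
    rng = np.random.default_rng(ss_structure)

    model_by_group: dict[str, IntensityModel] = {}
    for gi, group in enumerate(("Control", "ONJ")):
        model = IntensityModel.noise_free() if design.noise_free else IntensityModel()
        for marker, vals in effects.functional_positivity:
            model.functional_baseline[marker] = vals[gi]
        model_by_group[group] = model

    samples = [(f"C{i+1}", "Control") for i in range(design.n_control)]
    samples += [(f"P{i+1}", "ONJ") for i in range(design.n_onj)]
    planted_props = dict(effects.type_proportions)
    planted_modes = dict(effects.spatial_modes)

    frames = []
    truth_frames = []
    region_maps: dict[tuple[str, str], RegionMap] = {}
    sample_groups = {}
    for sample_id, group in samples:
        gi = 0 if group == "Control" else 1
        sample_groups[sample_id] = group
        density = design.total_density * effects.density_factor[gi]
        n_rois = int(rng.integers(design.rois_min, design.rois_max + 1))
        for k in range(n_rois):
            roi_id = f"roi{k+1}"
            rmap = generate_region_map(
                design.width_um, design.height_um, design.pixel_size,
                design.band_depth_um, design.n_vessels, design.vessel_radius_um,
                seed=rng,
            )
            region_maps[(sample_id, roi_id)] = rmap
            intensities: dict[str, dict[str, float]] = {}
            for region, comp in DEFAULT_COMPOSITION.items():
                if not rmap.region_mask(region).any():
                    continue  # e.g. vessel-free raster
                comp_g = _group_composition(
                    comp, {t: v[gi] for t, v in planted_props.items()}
                )
                for t, frac in comp_g.items():
                    intensities.setdefault(t, {})[region] = frac * density
            modes = {t: v[gi] for t, v in planted_modes.items()}
            placed = place_cells(rmap, intensities, modes, seed=rng)
            placed["sample_id"] = sample_id
            placed["roi_id"] = roi_id
            placed["group"] = group
            frames.append(placed)

    all_cells = pd.concat(frames, ignore_index=True)
    params = {
        "design": asdict(design),
        "type_proportions": {t: list(v) for t, v in planted_props.items()},
        "spatial_modes": {t: [asdict(v[0]), asdict(v[1])] for t, v in planted_modes.items()},
        "functional_positivity": {m: list(v) for m, v in effects.functional_positivity},
        "density_factor": list(effects.density_factor),
        "unclassified_fraction": {
            r: _group_composition(c, {t: v[0] for t, v in planted_props.items()})["unclassified"]
            for r, c in DEFAULT_COMPOSITION.items()
        },
    }

    if not draw_markers:
        all_cells["cell_id"] = [f"cell{i}" for i in range(len(all_cells))]
        truth = SyntheticTruth(
            seed=seed,
            sample_groups=sample_groups,
            labels=pd.DataFrame({
                "cell_id": all_cells["cell_id"],
                "true_type": all_cells["true_type"],
                "true_level1": [level1_of(t) for t in all_cells["true_type"]],
            }),
            params=params,
        )
        return all_cells, region_maps, truth

    rng_draw = np.random.default_rng(ss_intensity)
    tables = []
    for group in ("Control", "ONJ"):
        sub = all_cells[all_cells["group"] == group]
        if sub.empty:
            continue
        table, truth_df = draw_intensities(sub, model_by_group[group], panel, seed=rng_draw)
        tables.append(table.data)
        truth_frames.append(truth_df)
    data = pd.concat(tables, ignore_index=True)
    cells = CellTable(data, panel, transform_state="raw")
    truth = SyntheticTruth(
        seed=seed,
        sample_groups=sample_groups,
        labels=pd.concat(truth_frames, ignore_index=True),
        params=params,
    )
    return cells, region_maps, truth
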