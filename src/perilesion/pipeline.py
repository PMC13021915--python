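"""End-to-end orchestration: simulate → preprocess → regions → classify →
spatial → diffstats (→ embed → report).

Every random draw flows from the single config seed via spawned
substreams, so identical config + seed gives byte-identical result CSVs.
The run manifest records the config hash, seed, per-stage timings and
in/out counts, making filter effects auditable.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffstats, gating, regions, spatial
from .celltable import CellTable
from .errors import ParameterError, PerilesionError
from .io import write_results
from .panel import MarkerPanel
from .preprocess import TransformParams, preprocess_table
from .synthetic import CohortDesign, PlantedEffects, generate_cohort

log = logging.getLogger(__name__)

FUNCTIONAL_MARKERS_TESTED = (
    "PD1", "YAP1", "BNIP3", "pNFkB", "Caveolin", "Ki67", "pERK",
    "IntegrinB1", "pSTAT3",
)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    seed: int = 0
    design: CohortDesign = field(default_factory=CohortDesign)
    effects: PlantedEffects = field(default_factory=PlantedEffects)
    transform: TransformParams = field(default_factory=TransformParams)
    per_roi_quantiles: bool = False
    gating_rules: str | None = None        # TOML path; None = packaged default
    radii: tuple[float, ...] = (50.0, 100.0)
    min_count: int = 10
    alpha: float = 0.05
    embed: bool = False
    embed_n_neighbors: int = 30
    embed_min_dist: float = 0.3
    embed_max_cells: int = 5000

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ParameterError("radii must be positive")
        if not (0 < self.alpha < 1):
            raise ParameterError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        """Load a run config from TOML.

        The optional [effects] table supports ``null = true`` or the
        simple planted-effect fields, e.g.::

            [effects]
            type_proportions = { Treg = [0.02, 0.06] }
            functional_positivity = { Ki67 = [0.15, 0.30] }
            density_factor = [1.0, 1.25]
            thomas_types = ["Treg"]       # CSR in Control, Thomas in ONJ
        """
        from .synthetic import SpatialMode

        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        kwargs: dict = {}
        if "design" in doc:
            kwargs["design"] = CohortDesign(**doc.pop("design"))
        if "transform" in doc:
            kwargs["transform"] = TransformParams(**doc.pop("transform"))
        if "effects" in doc:
            eff = doc.pop("effects")
            if eff.get("null"):
                kwargs["effects"] = PlantedEffects.null()
            else:
                kwargs["effects"] = PlantedEffects(
                    type_proportions=tuple(
                        (t, tuple(v)) for t, v in eff.get("type_proportions", {}).items()
                    ),
                    functional_positivity=tuple(
                        (m, tuple(v)) for m, v in eff.get("functional_positivity", {}).items()
                    ),
                    density_factor=tuple(eff.get("density_factor", (1.0, 1.25))),
                    spatial_modes=tuple(
                        (t, (SpatialMode.csr(), SpatialMode.thomas()))
                        for t in eff.get("thomas_types", ["Treg"])
                    ),
                )
        if "radii" in doc:
            doc["radii"] = tuple(doc["radii"])
        kwargs.update(doc)
        return cls(**kwargs)


def embed_cells(
    table: CellTable,
    n_neighbors: int = 30,
    min_dist: float = 0.3,
    seed: int = 0,
    max_cells: int | None = None,
) -> pd.DataFrame:
    """2-D UMAP embedding of arcsinh marker expression.

    Parameters follow the analysis this package re-implements
    (n_neighbors=30, min_dist=0.3).  Optionally subsamples to
    ``max_cells`` (deterministic given seed) to bound runtime.
    """
    if table.transform_state != "arcsinh":
        raise ParameterError("embedding expects arcsinh-transformed intensities")
    df = table.data
    if max_cells is not None and len(df) > max_cells:
        rng = np.random.default_rng(seed)
        df = df.iloc[np.sort(rng.choice(len(df), size=max_cells, replace=False))]
    if len(df) < n_neighbors:
        raise ParameterError(
            f"{len(df)} cells < n_neighbors={n_neighbors}; reduce n_neighbors"
        )
    import umap  # deferred: heavy import

    X = df[table.panel.lineage + table.panel.functional].to_numpy(float)
    emb = umap.UMAP(
        n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed, n_jobs=1
    ).fit_transform(X)
    out = df[["cell_id", "sample_id", "group"]].copy()
    for col in ("level1", "level2", "level4_dominant"):
        if col in df.columns:
            out[col] = df[col]
    out["umap1"] = emb[:, 0]
    out["umap2"] = emb[:, 1]
    return out.reset_index(drop=True)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis on a simulated cohort; return a result bundle.

    Bundle keys: cells (labelled CellTable), truth, region_maps,
    positivity, interactions_roi / interactions_sample / contrasts,
    composition and differential tables, optional embedding, manifest.
    """
    stages: dict[str, dict] = {}
    bundle: dict = {}

    def _stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise PerilesionError(f"stage {name!r} failed: {exc}") from exc
                stages[name] = {"seconds": round(time.perf_counter() - self_inner.t0, 3)}

        return _Timer()

    with _stage("simulate"):
        cells, region_maps, truth = generate_cohort(
            config.design, config.effects, seed=config.seed
        )
        stages_in = len(cells)
        bundle["truth"] = truth
        bundle["region_maps"] = region_maps
    stages["simulate"]["cells"] = stages_in

    with _stage("preprocess"):
        cells = preprocess_table(cells, config.transform, per_roi=config.per_roi_quantiles)

    with _stage("regions"):
        parts = []
        for (sample_id, roi_id), rmap in region_maps.items():
            sel = (cells.data["sample_id"] == sample_id) & (cells.data["roi_id"] == roi_id)
            sub = CellTable(cells.data[sel].copy(), cells.panel, cells.transform_state)
            parts.append(regions.annotate(sub, rmap, distance_to="epithelium").data)
        cells = CellTable(
            pd.concat(parts, ignore_index=True), cells.panel, cells.transform_state
        )

    with _stage("classify"):
        panel = cells.panel
        cfg = (
            gating.load_gating_config(config.gating_rules, panel)
            if config.gating_rules
            else gating.default_gating_config(panel)
        )
        thresholds = gating.estimate_thresholds(cells, random_state=config.seed)
        cells, positivity = gating.classify_table(cells, cfg, thresholds)
        bundle["positivity"] = positivity
        bundle["thresholds"] = thresholds
    stages["classify"]["unclassified_pct"] = round(
        100.0 * float((cells.data["level1"] == "unclassified").mean()), 2
    )

    window = (config.design.width_um, config.design.height_um)
    with _stage("spatial"):
        roi_scores = spatial.roi_interaction_scores(
            cells, level="level1", radii=config.radii,
            default_window=window, min_count=config.min_count,
        )
        roi_scores_l2 = spatial.roi_interaction_scores(
            cells, level="level2", radii=config.radii,
            default_window=window, min_count=config.min_count,
        )
        roi_all = pd.concat([roi_scores, roi_scores_l2], ignore_index=True)
        sample_u = spatial.aggregate_to_sample(roi_all)
        contrasts = spatial.contrast_groups(sample_u, alpha=config.alpha)
        bundle["interactions_roi"] = roi_all
        bundle["interactions_sample"] = sample_u
        bundle["contrasts"] = contrasts

    with _stage("diffstats"):
        comp1_all = diffstats.per_sample_proportions(cells, "level1", "all")
        comp1_reg = diffstats.per_sample_proportions(cells, "level1", "by-region")
        comp2 = diffstats.per_sample_proportions(cells, "level2", "all")
        comp3 = diffstats.per_sample_proportions(cells, "level3", "all")
        comp4 = diffstats.per_sample_proportions(cells, "level4_dominant", "all")
        frac_frames = []
        for marker in FUNCTIONAL_MARKERS_TESTED:
            if marker not in bundle["positivity"].columns:
                continue
            for region in ("epithelium", "stroma", "vessel"):
                frac_frames.append(
                    diffstats.positive_fraction(cells, bundle["positivity"], marker, stratum=region)
                )
        fractions = pd.concat(frac_frames, ignore_index=True) if frac_frames else pd.DataFrame()
        bundle["compositions"] = {
            "level1_all": comp1_all, "level1_by_region": comp1_reg,
            "level2": comp2, "level3": comp3, "level4": comp4,
            "functional_fractions": fractions,
        }
        bundle["differential"] = {
            name: diffstats.differential_table(df)
            for name, df in bundle["compositions"].items()
            if not df.empty
        }

    if config.embed:
        with _stage("embed"):
            bundle["embedding"] = embed_cells(
                cells,
                n_neighbors=config.embed_n_neighbors,
                min_dist=config.embed_min_dist,
                seed=config.seed,
                max_cells=config.embed_max_cells,
            )
        stages["embed"]["params"] = {
            "n_neighbors": config.embed_n_neighbors,
            "min_dist": config.embed_min_dist,
        }

    bundle["cells"] = cells
    bundle["stages"] = stages

    if out_dir is not None:
        out_dir = Path(out_dir)
        tables = {
            "labeled_cells": cells.data,
            "interactions_roi": bundle["interactions_roi"],
            "interactions_sample": bundle["interactions_sample"],
            "interaction_contrasts": bundle["contrasts"],
        }
        for name, df in bundle["compositions"].items():
            if not df.empty:
                tables[f"composition_{name}"] = df
        for name, df in bundle["differential"].items():
            tables[f"diff_{name}"] = df
        if "embedding" in bundle:
            tables["embedding"] = bundle["embedding"]
        bundle["manifest"] = write_results(
            tables, out_dir, config=config.to_dict(), seed=config.seed,
            extra={"stages": stages},
        )
        bundle["truth"].save(out_dir)
    return bundle
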