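import numpy as np
import pandas as pd
import pytest

from perilesion.celltable import CellTable
from perilesion.panel import MarkerPanel
from perilesion.preprocess import preprocess_table
from perilesion.synthetic import CohortDesign, generate_cohort


@pytest.fixture(scope="session")
def panel() -> MarkerPanel:
    return MarkerPanel.default()


@pytest.fixture(scope="session")
def small_design() -> CohortDesign:
    """Scaled-down cohort: same structure, ~10k cells instead of ~50k."""
    return CohortDesign(
        width_um=400.0,
        height_um=400.0,
        band_depth_um=120.0,
        n_vessels=2,
        vessel_radius_um=25.0,
        total_density=1.5e-3,
        rois_min=2,
        rois_max=3,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    """(raw cells, region maps, truth) for a default-effects cohort."""
    return generate_cohort(small_design, seed=7)


@pytest.fixture(scope="session")
def small_cohort_arcsinh(small_cohort):
    cells, region_maps, truth = small_cohort
    return preprocess_table(cells), region_maps, truth


def make_tiny_table(panel: MarkerPanel, n: int = 5, seed: int = 0) -> CellTable:
    """Minimal valid raw cell table for I/O and contract tests."""
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "sample_id": ["s1"] * n,
            "roi_id": ["roi1"] * n,
            "group": ["Control"] * n,
            "x": rng.uniform(0, 100, n),
            "y": rng.uniform(0, 100, n),
        }
    )
    for m in panel.names:
        data[m] = rng.lognormal(0.0, 0.5, n)
    data["nuc_YAP1"] = rng.lognormal(0.0, 0.5, n)
    return CellTable(data, panel, transform_state="raw")
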