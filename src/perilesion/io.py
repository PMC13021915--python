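"""Readers and writers.

Cell tables travel as plain CSV (comma separator, '.' decimal, UTF-8);
floats are written with Python's shortest round-tripping repr so a
write/read cycle is lossless.  Region masks are single-channel integer
TIFFs.  Result bundles are a directory of CSVs plus a JSON run manifest
carrying the config hash, seed and library versions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile

from .celltable import META_COLUMNS, CellTable
from .errors import FormatError, ValidationError
from .panel import MarkerPanel
from .regionmap import DEFAULT_LEGEND, RegionMap


def read_cell_table(path: str | Path, panel: MarkerPanel) -> CellTable:
    """Read a per-cell CSV into a raw :class:`CellTable`.

    The header must contain the mandatory metadata columns and one column
    per panel marker; extra columns (nuclear channels, prior labels) are
    carried through untouched.
    """
    df = pd.read_csv(
        path,
        dtype={"cell_id": str, "sample_id": str, "roi_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in (*META_COLUMNS, *panel.names) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return CellTable(df, panel, transform_state="raw")


def write_cell_table(table: CellTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # shortest round-tripping float repr, so write∘read is lossless
    table.data.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_region_map(
    path: str | Path,
    pixel_size: float,
    legend: Mapping[int, str] | None = None,
) -> RegionMap:
    """Read a single-channel integer TIFF as a :class:`RegionMap`.

    With no explicit legend the default coding {1: epithelium, 2: stroma,
    3: vessel, 0: background} applies.
    """
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected a single-channel raster, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: expected an integer raster, got dtype {arr.dtype}")
    return RegionMap(arr, pixel_size, dict(legend) if legend else dict(DEFAULT_LEGEND))


def write_region_map(region_map: RegionMap, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    labels = region_map.labels
    dtype = np.uint8 if labels.max(initial=0) < 256 and labels.min(initial=0) >= 0 else np.int32
    tifffile.imwrite(path, labels.astype(dtype))


def _config_hash(config: Any) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _versions() -> dict[str, str]:
    import scipy
    import sklearn
    import statsmodels

    from . import __version__

    return {
        "perilesion": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Any = None,
    seed: int | None = None,
    extra: Mapping[str, Any] | None = None,
) -> dict:
    """Write one CSV per result table plus a JSON run manifest.

    Returns the manifest (also written to ``run_manifest.json``).  The
    manifest records a sha256 per output file, so byte-identical reruns
    can be verified from the manifests alone.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"result directory {out} is not writable: {exc}") from exc

    files: dict[str, dict] = {}
    for name, df in tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        files[path.name] = {
            "rows": int(len(df)),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }
    manifest = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "versions": _versions(),
        "files": files,
    }
    if extra:
        manifest.update(extra)
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
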