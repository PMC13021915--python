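"""Hierarchical supervised cell classification from marker positivity.

Four levels, mirroring the region-aware phenotyping workflow this package
implements:

* Level 1 — five basic types (immune, endothelial, epithelial,
  fibroblast, functional) with an "unclassified" fallback;
* Level 2 — immune subtypes (Treg, exhausted T, BnT, M2, macrophage, B,
  CD4 T, CD8 T, NK, DC), only for level-1 immune cells;
* Level 3 — infiltration phenotype: an immune cell co-expressing a
  compartment lineage marker is flagged ``immune-in-<compartment>``
  (precedence epithelial > endothelial > fibroblast);
* Level 4 — non-exclusive functional state flags (proliferation,
  apoptosis, autophagy, pro-inflammatory, migration, transcriptional),
  with "non-functional" when no flag is set.

Positivity is a strict ``intensity > threshold`` comparison on the
arcsinh scale, per marker, using the nuclear channel where the panel
says so (YAP1).  Thresholds come either from a two-component Gaussian
mixture per marker (boundary at the equal-posterior crossing between the
component means) or from fixed user overrides.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .celltable import CellTable
from .errors import ConfigurationError, ValidationError
from .panel import MarkerPanel

log = logging.getLogger(__name__)

LEVEL1_TYPES = ("immune", "endothelial", "epithelial", "fibroblast", "functional")
UNCLASSIFIED = "unclassified"

#: fixed order used to collapse level-4 flag sets to one state for plots
DOMINANT_ORDER = (
    "proliferation",
    "apoptosis",
    "autophagy",
    "pro-inflammatory",
    "migration",
    "transcriptional",
)
NON_FUNCTIONAL = "non-functional"
LEVEL4_SEP = "+"


@dataclass(frozen=True)
class GatingRule:
    level: int
    label: str
    priority: int
    require_all: tuple[str, ...] = ()
    require_any: tuple[str, ...] = ()
    require_none: tuple[str, ...] = ()
    parent: str | None = None


@dataclass
class GatingConfig:
    """Parsed rule file: rules plus level-3/4 marker maps and options."""

    rules: list[GatingRule]
    level3_markers: dict[str, list[str]]
    level4_markers: dict[str, list[str]]
    options: dict = field(default_factory=dict)

    def rules_for(self, level: int) -> list[GatingRule]:
        out = sorted(
            (r for r in self.rules if r.level == level),
            key=lambda r: -r.priority,
        )
        prios = [r.priority for r in out]
        if len(set(prios)) != len(prios):
            raise ConfigurationError(f"duplicate priorities within level {level}")
        return out

    def validate(self, panel: MarkerPanel) -> None:
        for r in self.rules:
            for m in (*r.require_all, *r.require_any, *r.require_none):
                if m not in panel:
                    raise ConfigurationError(
                        f"rule {r.label!r} references unknown marker {m!r}"
                    )
            if r.level == 2 and r.parent != "immune":
                raise ConfigurationError(
                    f"level-2 rule {r.label!r} must have parent 'immune', got {r.parent!r}"
                )
        mapped = {m for ms in self.level4_markers.values() for m in ms}
        for m in panel.functional:
            if m not in mapped:
                log.warning("functional marker %s has no level-4 state mapping", m)


def _expand(tokens: list[str], panel: MarkerPanel) -> tuple[str, ...]:
    out: list[str] = []
    for t in tokens:
        if t == "@lineage":
            out.extend(panel.lineage)
        elif t == "@functional":
            out.extend(panel.functional)
        else:
            out.append(t)
    return tuple(out)


def load_gating_config(path: str | Path, panel: MarkerPanel) -> GatingConfig:
    """Read a TOML gating file and expand @role tokens against the panel."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    rules = []
    for raw in doc.get("rule", []):
        rules.append(
            GatingRule(
                level=int(raw["level"]),
                label=str(raw["label"]),
                priority=int(raw["priority"]),
                require_all=_expand(list(raw.get("all", [])), panel),
                require_any=_expand(list(raw.get("any", [])), panel),
                require_none=_expand(list(raw.get("none", [])), panel),
                parent=raw.get("parent"),
            )
        )
    cfg = GatingConfig(
        rules=rules,
        level3_markers={k: list(v) for k, v in doc.get("level3", {}).items()},
        level4_markers={k: list(v) for k, v in doc.get("level4", {}).items()},
        options=dict(doc.get("options", {})),
    )
    cfg.validate(panel)
    return cfg


def default_gating_config(panel: MarkerPanel | None = None) -> GatingConfig:
    panel = panel or MarkerPanel.default()
    with resources.as_file(
        resources.files("perilesion.data") / "gating_default.toml"
    ) as p:
        return load_gating_config(p, panel)


# ---------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------

@dataclass
class PositivityThresholds:
    """Per-marker positivity cut on the arcsinh scale."""

    values: dict[str, float]
    method: dict[str, str] = field(default_factory=dict)   # gmm2 | fixed | fallback
    flagged: set[str] = field(default_factory=set)

    def __getitem__(self, marker: str) -> float:
        return self.values[marker]


def _gmm2_threshold(values: np.ndarray, random_state: int = 0) -> tuple[float, bool]:
    """Two-component GMM cut: equal-posterior crossing between the means.

    Returns (threshold, fell_back).  Degenerate fits (component weight
    < 0.02 or means closer than 0.1) fall back to the midpoint of the
    10th and 90th percentiles.
    """
    gm = GaussianMixture(n_components=2, random_state=random_state, n_init=2)
    gm.fit(values.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    m1, m2 = means[order]
    s1, s2 = sds[order]
    w1, w2 = weights[order]
    if min(w1, w2) < 0.02 or (m2 - m1) < 0.1:
        lo, hi = np.percentile(values, [10, 90])
        return float((lo + hi) / 2.0), True

    def logratio(x: float) -> float:
        return (np.log(w1) + norm.logpdf(x, m1, s1)) - (
            np.log(w2) + norm.logpdf(x, m2, s2)
        )

    try:
        if logratio(m1) > 0 and logratio(m2) < 0:
            thr = brentq(logratio, m1, m2)
        else:  # weights so lopsided that no crossing sits between the means
            thr = (m1 + m2) / 2.0
    except ValueError:  # pragma: no cover - brentq bracketing guard
        thr = (m1 + m2) / 2.0
    return float(thr), False


def estimate_thresholds(
    table: CellTable,
    method: str = "gmm2",
    overrides: dict[str, float] | None = None,
    markers: list[str] | None = None,
    random_state: int = 0,
    min_cells: int = 200,
    max_cells: int = 20000,
) -> PositivityThresholds:
    """Estimate positivity thresholds per gating marker.

    ``method='gmm2'`` fits a two-component Gaussian mixture per marker on
    arcsinh intensities; ``method='fixed'`` requires an override for every
    marker.  Overrides always win and are recorded as 'fixed'.  Nuclear
    markers are estimated on their nuclear channel.
    """
    if table.transform_state != "arcsinh":
        raise ValidationError("thresholds are estimated on arcsinh-transformed data")
    overrides = overrides or {}
    if markers is None:
        markers = table.panel.lineage + table.panel.functional
    values: dict[str, float] = {}
    methods: dict[str, str] = {}
    flagged: set[str] = set()
    rng = np.random.default_rng(random_state)
    for m in markers:
        if m in overrides:
            values[m] = float(overrides[m])
            methods[m] = "fixed"
            continue
        if method == "fixed":
            raise ConfigurationError(f"method 'fixed' but no override for marker {m!r}")
        v = table.intensity_for(m).to_numpy(float)
        if v.size < min_cells:
            raise ValidationError(
                f"marker {m!r}: {v.size} cells < {min_cells} required for gmm2"
            )
        if v.size > max_cells:
            v = rng.choice(v, size=max_cells, replace=False)
        thr, fell_back = _gmm2_threshold(v, random_state=random_state)
        values[m] = thr
        methods[m] = "fallback" if fell_back else "gmm2"
        if fell_back:
            flagged.add(m)
            log.warning(
                "marker %s: degenerate mixture, fell back to P10/P90 midpoint", m
            )
    return PositivityThresholds(values, methods, flagged)


def call_positivity(table: CellTable, thresholds: PositivityThresholds) -> pd.DataFrame:
    """Boolean cell × marker positivity matrix (strict '>' at threshold)."""
    if table.transform_state != "arcsinh":
        raise ValidationError("positivity is called on arcsinh-transformed data")
    out = {}
    for m, thr in thresholds.values.items():
        comp = table.panel[m].compartment
        if comp == "nuclear" and f"nuc_{m}" not in table.data.columns:
            log.warning(
                "marker %s wants the nuclear channel but none is present; "
                "using whole-cell signal",
                m,
            )
        out[m] = table.intensity_for(m).to_numpy(float) > thr
    return pd.DataFrame(out, index=table.data.index)


# ---------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------

def _rule_mask(pos: pd.DataFrame, rule: GatingRule) -> np.ndarray:
    mask = np.ones(len(pos), dtype=bool)
    if rule.require_all:
        mask &= pos[list(rule.require_all)].to_numpy().all(axis=1)
    if rule.require_any:
        mask &= pos[list(rule.require_any)].to_numpy().any(axis=1)
    if rule.require_none:
        mask &= ~pos[list(rule.require_none)].to_numpy().any(axis=1)
    return mask


def classify_level1(pos: pd.DataFrame, config: GatingConfig) -> np.ndarray:
    """Assign each cell its highest-priority matching level-1 label."""
    rules = config.rules_for(1)
    if not rules:
        raise ConfigurationError("no level-1 rules defined")
    labels = np.full(len(pos), UNCLASSIFIED, dtype=object)
    unset = np.ones(len(pos), dtype=bool)
    for rule in rules:  # descending priority
        m = _rule_mask(pos, rule) & unset
        labels[m] = rule.label
        unset &= ~m
    return labels


def classify_level2(
    pos: pd.DataFrame, level1: np.ndarray, config: GatingConfig
) -> np.ndarray:
    """Subtype level-1 immune cells; non-immune cells get no label (None)."""
    rules = config.rules_for(2)
    labels = np.full(len(pos), None, dtype=object)
    immune = np.asarray(level1) == "immune"
    unset = immune.copy()
    for rule in rules:
        m = _rule_mask(pos, rule) & unset
        labels[m] = rule.label
        unset &= ~m
    labels[unset] = "immune-other"
    return labels


def classify_level3(
    pos: pd.DataFrame, level1: np.ndarray, config: GatingConfig
) -> np.ndarray:
    """Infiltration phenotype: immune cells co-expressing compartment markers.

    Precedence when several compartments co-express: epithelial >
    endothelial > fibroblast.  Immune cells without co-expression are
    labelled plain 'immune'; non-immune cells get no label.
    """
    labels = np.full(len(pos), None, dtype=object)
    immune = np.asarray(level1) == "immune"
    labels[immune] = "immune"
    # ascending precedence: the last write (epithelial) wins ties
    for comp in ("fibroblast", "endothelial", "epithelial"):
        markers = [m for m in config.level3_markers.get(comp, []) if m in pos.columns]
        if not markers:
            continue
        co = pos[markers].to_numpy().any(axis=1)
        labels[immune & co] = f"immune-in-{comp}"
    return labels


def classify_level4(pos: pd.DataFrame, config: GatingConfig) -> list[frozenset[str]]:
    """Non-exclusive functional state flags per cell."""
    flags_per_state = {}
    for state, markers in config.level4_markers.items():
        markers = [m for m in markers if m in pos.columns]
        if not markers:
            log.warning("level-4 state %s has no measured markers", state)
            continue
        flags_per_state[state] = pos[markers].to_numpy().any(axis=1)
    out = []
    states = list(flags_per_state)
    matrix = np.column_stack([flags_per_state[s] for s in states]) if states else np.zeros((len(pos), 0), bool)
    for row in matrix:
        out.append(frozenset(s for s, f in zip(states, row) if f))
    return out


def level4_to_string(flags: frozenset[str]) -> str:
    if not flags:
        return NON_FUNCTIONAL
    return LEVEL4_SEP.join(sorted(flags))


def dominant_state(flags: frozenset[str]) -> str:
    """Collapse a flag set to one state for visualisation (fixed order)."""
    for s in DOMINANT_ORDER:
        if s in flags:
            return s
    return NON_FUNCTIONAL


def classify_table(
    table: CellTable,
    config: GatingConfig | None = None,
    thresholds: PositivityThresholds | None = None,
    positivity: pd.DataFrame | None = None,
) -> tuple[CellTable, pd.DataFrame]:
    """Run all four levels and write label columns onto a copy of the table.

    Returns (labelled table, positivity matrix).  ``level4`` holds the
    '+'-joined flag string, ``level4_dominant`` the collapsed state.
    """
    config = config or default_gating_config(table.panel)
    if positivity is None:
        if thresholds is None:
            thresholds = estimate_thresholds(table)
        positivity = call_positivity(table, thresholds)
    out = table.copy()
    l1 = classify_level1(positivity, config)
    out.data["level1"] = l1
    out.data["level2"] = classify_level2(positivity, l1, config)
    out.data["level3"] = classify_level3(positivity, l1, config)
    flags = classify_level4(positivity, config)
    out.data["level4"] = [level4_to_string(f) for f in flags]
    out.data["level4_dominant"] = [dominant_state(f) for f in flags]
    return out, positivity
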