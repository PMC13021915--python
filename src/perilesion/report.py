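"""Figure rendering for a pipeline result bundle.

One image per figure family, echoing the shapes of the analysis this
package re-implements: per-group composition box plots (median + IQR
box), region × cell-type heatmaps, the half-circle interaction plot
(left half Control, right half ONJ, circle size ∝ |difference|, bold
outline where the adjusted p falls below alpha), and an embedding
scatter when present.  A markdown index ties them together.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Wedge

log = logging.getLogger(__name__)

GROUP_COLORS = {"Control": "#4878cf", "ONJ": "#d65f5f", "Tonsil": "#6acc65"}


def composition_boxplot(compositions: pd.DataFrame, path: Path, level_name: str = "level1") -> None:
    labels = sorted(compositions["label"].unique())
    groups = [g for g in ("Control", "ONJ") if g in set(compositions["group"])]
    fig, ax = plt.subplots(figsize=(max(6, 0.9 * len(labels)), 4))
    width = 0.35
    for gi, group in enumerate(groups):
        data = [
            compositions.loc[
                (compositions["label"] == lab) & (compositions["group"] == group),
                "proportion",
            ].to_numpy()
            for lab in labels
        ]
        pos = np.arange(len(labels)) + (gi - (len(groups) - 1) / 2) * width
        bp = ax.boxplot(
            data, positions=pos, widths=width * 0.9, patch_artist=True,
            showfliers=False, medianprops={"color": "black"},
        )
        for box in bp["boxes"]:
            box.set_facecolor(GROUP_COLORS.get(group, "grey"))
            box.set_alpha(0.7)
    ax.set_xticks(np.arange(len(labels)))
    ax.set_xticklabels(labels, rotation=45, ha="right")
    ax.set_ylabel("per-sample proportion")
    ax.set_title(f"Cell composition by group ({level_name})")
    handles = [plt.Rectangle((0, 0), 1, 1, fc=GROUP_COLORS[g], alpha=0.7) for g in groups]
    ax.legend(handles, groups, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def region_heatmap(composition: pd.DataFrame, path: Path) -> None:
    pivot = composition.pivot_table(
        index="region", columns=composition.columns[1], values="count", fill_value=0
    )
    fig, ax = plt.subplots(figsize=(max(5, 0.8 * pivot.shape[1]), 3))
    frac = pivot.to_numpy(float)
    frac = frac / frac.sum(axis=1, keepdims=True)
    im = ax.imshow(frac, cmap="viridis", aspect="auto")
    ax.set_xticks(range(pivot.shape[1]))
    ax.set_xticklabels(pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(pivot.shape[0]))
    ax.set_yticklabels(pivot.index)
    fig.colorbar(im, ax=ax, label="row fraction")
    ax.set_title("Cell types across regions")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def interaction_halfcircles(
    contrasts: pd.DataFrame, path: Path, radius: float = 50.0, alpha: float = 0.05
) -> None:
    """Half-circle matrix: left half Control mean u, right half ONJ.

    Circle size scales with |ONJ − Control|; a bold black outline marks
    pairs whose BH-adjusted p is below alpha.
    """
    sub = contrasts[contrasts["radius"] == radius].copy()
    if sub.empty:
        log.warning("no contrasts at radius %s; skipping interaction plot", radius)
        return
    types = sorted(set(sub["type_a"]) | set(sub["type_b"]))
    pos = {t: i for i, t in enumerate(types)}
    umax = np.nanmax(np.abs(sub[["mean_u_Control", "mean_u_ONJ"]].to_numpy())) or 1.0
    dmax = np.nanmax(np.abs(sub["diff"].to_numpy())) or 1.0
    cmap = plt.get_cmap("coolwarm")
    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(types), 1 + 0.6 * len(types)))
    for _, row in sub.iterrows():
        i, j = pos[row["type_a"]], pos[row["type_b"]]
        size = 0.12 + 0.33 * min(abs(row["diff"]) / dmax, 1.0) if np.isfinite(row["diff"]) else 0.12
        lw = 2.2 if (np.isfinite(row.get("p_adj", np.nan)) and row["p_adj"] < alpha) else 0.5
        for (x, y) in ({(i, j), (j, i)}):
            c_ctrl = cmap(0.5 + 0.5 * np.clip(row["mean_u_Control"] / umax, -1, 1))
            c_onj = cmap(0.5 + 0.5 * np.clip(row["mean_u_ONJ"] / umax, -1, 1))
            ax.add_patch(Wedge((x, y), size, 90, 270, fc=c_ctrl, ec="black", lw=lw))
            ax.add_patch(Wedge((x, y), size, 270, 90, fc=c_onj, ec="black", lw=lw))
    ax.set_xlim(-0.6, len(types) - 0.4)
    ax.set_ylim(-0.6, len(types) - 0.4)
    ax.set_xticks(range(len(types)))
    ax.set_xticklabels(types, rotation=45, ha="right")
    ax.set_yticks(range(len(types)))
    ax.set_yticklabels(types)
    ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.set_title(
        f"Spatial interaction at r = {radius:g} μm\n"
        "left half Control / right half ONJ; bold outline: adj. p < "
        f"{alpha:g}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def embedding_scatter(embedding: pd.DataFrame, path: Path, color_by: str = "level1") -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    for lab, sub in embedding.groupby(color_by, observed=True):
        ax.scatter(sub["umap1"], sub["umap2"], s=3, label=str(lab), alpha=0.6)
    ax.legend(markerscale=3, frameon=False, fontsize=7)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.set_title(f"Embedding coloured by {color_by}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(bundle: dict, out_dir: str | Path, alpha: float = 0.05) -> list[Path]:
    """Write all applicable figures plus a markdown index; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    comps = bundle.get("compositions", {})
    if not comps and "contrasts" not in bundle:
        log.warning("render_report: empty result bundle, nothing to draw")
    if "level1_all" in comps and not comps["level1_all"].empty:
        p = out / "composition_level1.png"
        composition_boxplot(comps["level1_all"], p, "level1")
        written.append(p)
    if "level2" in comps and not comps["level2"].empty:
        p = out / "composition_level2.png"
        composition_boxplot(comps["level2"], p, "level2")
        written.append(p)
    cells = bundle.get("cells")
    if cells is not None and "region" in cells.data.columns and "level1" in cells.data.columns:
        from .regions import region_composition

        p = out / "region_heatmap.png"
        region_heatmap(region_composition(cells), p)
        written.append(p)
    contrasts = bundle.get("contrasts")
    if contrasts is not None and not contrasts.empty:
        for r in sorted(contrasts["radius"].unique()):
            p = out / f"interactions_r{int(r)}.png"
            interaction_halfcircles(contrasts, p, radius=r, alpha=alpha)
            if p.exists():
                written.append(p)
    if "embedding" in bundle:
        p = out / "embedding.png"
        embedding_scatter(bundle["embedding"], p)
        written.append(p)
    index = out / "report.md"
    lines = ["# Run report", ""]
    lines += [f"![{p.stem}]({p.name})" for p in written]
    index.write_text("\n\n".join(lines) + "\n")
    written.append(index)
    return written
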