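"""Report artifacts: heatmap tables, heatmap figures, comparison matrices.

CSV tables are the canonical artifacts; the PNG heatmap is an optional,
headless-safe rendering of the same numbers.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import pandas as pd

from .consistency import SDNMIcTable
from .stats import ComparisonMatrix

__all__ = [
    "heatmap_frame",
    "write_heatmap_csv",
    "render_heatmap",
    "write_comparison",
]


def heatmap_frame(table: SDNMIcTable) -> pd.DataFrame:
    """One row per method, one column per evaluated ROI, plus a Mean column."""
    frame = table.values.copy()
    frame["Mean"] = table.method_summary["mean"]
    return frame


def write_heatmap_csv(table: SDNMIcTable, path: os.PathLike) -> Path:
    path = Path(path)
    heatmap_frame(table).to_csv(path, index_label="method", float_format="%.6f")
    return path


def render_heatmap(table: SDNMIcTable, path: os.PathLike) -> Path:
    """Render the SD NMI_c table as an annotated heatmap PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = heatmap_frame(table)
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.75 * len(frame.columns), 1.0 + 0.5 * len(frame))
    )
    im = ax.imshow(frame.to_numpy(), cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(frame.columns)), frame.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(frame)), frame.index)
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            ax.text(
                j, i, f"{frame.iat[i, j]:.2f}",
                ha="center", va="center", color="w", fontsize=7,
            )
    ax.set_title(f"SD NMI_c — {table.cohort_label}")
    fig.colorbar(im, ax=ax, label="SD NMI_c")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def write_comparison(
    matrix: ComparisonMatrix, csv_path: os.PathLike, json_path: os.PathLike | None = None
) -> Path:
    """Serialize a comparison matrix (long CSV + JSON summary).

    When the Friedman gate did not pass, the CSV holds a skip record and the
    JSON carries the omnibus result with ``computed: false``.
    """
    csv_path = Path(csv_path)
    payload = {
        "methods": matrix.methods,
        "friedman_statistic": matrix.friedman_statistic,
        "friedman_p": matrix.friedman_p,
        "alpha": matrix.alpha,
        "m": matrix.m,
        "computed": matrix.computed,
    }
    if matrix.computed:
        matrix.to_long().to_csv(csv_path, index=False, float_format="%.6g")
        payload["corrected_p"] = {
            f"{a}|{b}": float(matrix.corrected_p.loc[a, b])
            for i, a in enumerate(matrix.methods)
            for b in matrix.methods[i + 1 :]
        }
    else:
        pd.DataFrame(
            [{
                "skipped": True,
                "reason": "Friedman test not significant",
                "friedman_p": matrix.friedman_p,
                "alpha": matrix.alpha,
            }]
        ).to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(payload, indent=2))
    return csv_path
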