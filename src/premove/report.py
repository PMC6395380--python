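"""Summaries of search results: top-3 means, paired tests, area tables.

Per-subject cells are the mean of the three highest cross-validated
accuracies over all component pairs for a window condition, with the
shuffle-control mean in parentheses; footers give mean +/- SD across
subjects. Paired t-tests compare single-window against two-window
accuracies at the subject level.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .classify import SearchResult

WINDOW_CONDITIONS: tuple[str, ...] = ("F", "M", "B", "FB", "MB")

#: Single-window vs. two-window pairings tested at the subject level.
PAIRINGS: tuple[tuple[str, str], ...] = (("F", "FB"), ("B", "FB"), ("M", "MB"), ("B", "MB"))


def top3_summary(result: SearchResult) -> float:
    """Mean of the three highest record accuracies (all of them, with a
    warning, if fewer than three exist)."""
    if not result.records:
        raise ValueError("empty search result")
    top = result.top_accuracies(3)
    if len(top) < 3:
        warnings.warn(
            f"only {len(top)} record(s); averaging all of them", stacklevel=2
        )
    return float(np.mean(top))


def paired_comparison(
    acc_single: list[float] | np.ndarray, acc_fused: list[float] | np.ndarray
) -> tuple[float, float]:
    """Two-sided paired t-test on per-subject accuracies."""
    a = np.asarray(acc_single, float)
    b = np.asarray(acc_fused, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("paired t-test needs at least 2 subjects")
    d = b - a
    if np.all(d == 0.0):
        return 0.0, 1.0
    t, p = scipy.stats.ttest_rel(b, a)
    return float(t), float(p)


def holm_correct(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; the default presentation
    reports raw p-values)."""
    return list(multipletests(p_values, method="holm")[1])


@dataclass
class SummaryTable:
    """Rows per subject, columns per window condition, cells
    (accuracy, shuffle-control accuracy)."""

    rows: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    task: str = "LR"
    condition: str = "visual"

    def set_cell(
        self, subject: str, window: str, accuracy: float, shuffle: float
    ) -> None:
        if window not in WINDOW_CONDITIONS:
            raise ValueError(f"window must be one of {WINDOW_CONDITIONS}")
        self.rows.setdefault(subject, {})[window] = (accuracy, shuffle)

    def footer(self) -> dict[str, tuple[float, float]]:
        """Mean +/- SD (sample SD) across subjects per window condition."""
        out = {}
        for w in WINDOW_CONDITIONS:
            vals = [cells[w][0] for cells in self.rows.values() if w in cells]
            if vals:
                sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
                out[w] = (float(np.mean(vals)), sd)
        return out


def area_summary(
    results: dict[tuple[str, str], list[SearchResult]]
) -> dict[tuple[str, str], float | None]:
    """Mean best accuracy per (area, window position).

    ``results`` maps (area, position) to the per-subject-and-task searches
    restricted accordingly; each search contributes its highest accuracy.
    Unpopulated cells are None (missing), never zero.
    """
    if not any(results.values()):
        raise ValueError("no populated area in results")
    out: dict[tuple[str, str], float | None] = {}
    for key, searches in results.items():
        maxima = [s.best().accuracy for s in searches if s.records]
        out[key] = float(np.mean(maxima)) if maxima else None
    return out


def _fmt_cell(cell: tuple[float, float]) -> str:
    return f"{cell[0]:.2f} ({cell[1]:.2f})"


def _parse_cell(text: str) -> tuple[float, float]:
    acc, rest = text.split("(")
    return float(acc.strip()), float(rest.rstrip(") "))


def render_tables(table: SummaryTable, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Write a SummaryTable as CSV and JSON; returns the written paths.

    CSV cells use the ``"85.90 (52.38)"`` accuracy-(shuffle) format with a
    ``mean +/- SD`` footer; JSON keeps the raw numbers so the table
    round-trips losslessly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.json"

    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject", *WINDOW_CONDITIONS])
        for subj in sorted(table.rows):
            cells = table.rows[subj]
            w.writerow(
                [subj]
                + [_fmt_cell(cells[c]) if c in cells else "" for c in WINDOW_CONDITIONS]
            )
        foot = table.footer()
        w.writerow(
            ["Mean"]
            + [
                f"{foot[c][0]:.2f} +/- {foot[c][1]:.2f}" if c in foot else ""
                for c in WINDOW_CONDITIONS
            ]
        )

    payload = {
        "task": table.task,
        "condition": table.condition,
        "rows": {
            subj: {w: list(cell) for w, cell in cells.items()}
            for subj, cells in table.rows.items()
        },
    }
    json_path.write_text(json.dumps(payload, indent=2))
    return {"csv": csv_path, "json": json_path}


def load_table(json_path: str | Path) -> SummaryTable:
    """Inverse of :func:`render_tables` (from the JSON artifact)."""
    payload = json.loads(Path(json_path).read_text())
    table = SummaryTable(task=payload["task"], condition=payload["condition"])
    for subj, cells in payload["rows"].items():
        for w, (acc, shuf) in cells.items():
            table.set_cell(subj, w, acc, shuf)
    return table


def parse_csv_cell(text: str) -> tuple[float, float]:
    """Parse an ``"85.90 (52.38)"`` cell back to numbers."""
    return _parse_cell(text)


def scalp_map_gallery(decomp, out_dir: str | Path, cmap: str = "RdBu_r") -> list[Path]:
    """Render one topography image per component (interpolated over the
    projected electrode positions, electrodes overlaid); returns the paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.interpolate import griddata

    from .montage import positions_array

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pos = positions_array(decomp.channel_labels)
    gx, gy = np.meshgrid(np.linspace(-1.2, 1.2, 80), np.linspace(-1.2, 1.2, 80))
    paths = []
    for k in range(decomp.n_components):
        w = decomp.scalp_maps[:, k]
        gz = griddata(pos, w, (gx, gy), method="cubic")
        gz[gx**2 + gy**2 > 1.3**2] = np.nan
        fig, ax = plt.subplots(figsize=(3, 3))
        lim = np.nanmax(np.abs(w))
        ax.contourf(gx, gy, gz, levels=16, cmap=cmap, vmin=-lim, vmax=lim)
        ax.scatter(pos[:, 0], pos[:, 1], s=6, c="k")
        ax.add_patch(plt.Circle((0, 0), 1.15, fill=False, lw=1))
        flag = decomp.artifact_flags[k] if decomp.artifact_flags else "none"
        area = decomp.area[k] if decomp.area else ""
        ax.set_title(f"IC{k} {area} {'' if flag == 'none' else flag}".strip(), fontsize=8)
        ax.set_aspect("equal")
        ax.axis("off")
        path = out_dir / f"component_{k:02d}.png"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
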