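"""Heat-map arrangement and database-style record export.

Fold-change results for one strain and measure are arranged into the
presentation scheme of the screen: eight panels keyed by the categoric levels
(oxygen, carbon, nitrogen), each a 3x3 matrix of pH (rows, ascending code)
by temperature (columns, ascending code) holding (fc, significant).  Per
strain a JSON record collects the three heat maps plus the three contribution
tables with control-normalized deltas; global CSV matrices (strains x
variants, one per measure) give the collective view.  Exports are
deterministic: fixed orderings and fixed float formatting make re-export
byte-identical for identical inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ReportError

__all__ = ["HeatmapGrid", "arrange_heatmap", "export_records", "plot_heatmap"]

NUMERIC_LEVELS = (-1.0, 0.0, 1.0)


@dataclass
class HeatmapGrid:
    """One strain x measure heat map: 8 categoric panels of 3x3 (pH x temp) cells."""

    strain: str
    measure: str
    panels: dict[tuple[float, float, float], np.ndarray]  # (oxygen, carbon, nitrogen) -> 3x3 of (fc, sig)
    variant_ids: dict[tuple[float, float, float], np.ndarray]

    def lookup(self, oxygen: float, carbon: float, nitrogen: float,
               ph: float, temperature: float) -> tuple[float, bool]:
        """Cell lookup by the full coded condition; roundtrips to the record."""
        panel = self.panels[(oxygen, carbon, nitrogen)]
        i = NUMERIC_LEVELS.index(ph)
        j = NUMERIC_LEVELS.index(temperature)
        fc, sig = panel[i, j]
        return float(fc), bool(sig)

    @property
    def n_cells(self) -> int:
        return sum(p.shape[0] * p.shape[1] for p in self.panels.values())


def arrange_heatmap(fc_records: pd.DataFrame, design: pd.DataFrame) -> HeatmapGrid:
    """Arrange one strain's FC records for one measure into the panel grid.

    Expects exactly one record per design variant; raises naming the missing
    or duplicated coded combinations otherwise.
    """
    strains = fc_records["strain_id"].unique()
    measures = fc_records["measure"].unique()
    if len(strains) != 1 or len(measures) != 1:
        raise ReportError("arrange_heatmap expects records for exactly one strain and measure")
    sub = fc_records.merge(design, on="variant_id", validate="1:1")

    dup = sub["variant_id"].duplicated()
    if dup.any():
        raise ReportError(f"duplicate variants: {sorted(sub.loc[dup, 'variant_id'])}")

    panels: dict[tuple[float, float, float], np.ndarray] = {}
    vids: dict[tuple[float, float, float], np.ndarray] = {}
    import itertools
    missing = []
    for combo in itertools.product((-1.0, 1.0), repeat=3):
        grid = np.empty((3, 3), dtype=object)
        vid = np.zeros((3, 3), dtype=int)
        panel = sub[(sub["coded_oxygen"] == combo[0])
                    & (sub["coded_carbon"] == combo[1])
                    & (sub["coded_nitrogen"] == combo[2])]
        for i, ph in enumerate(NUMERIC_LEVELS):
            for j, temp in enumerate(NUMERIC_LEVELS):
                cell = panel[(panel["coded_pH"] == ph) & (panel["coded_temperature"] == temp)]
                if len(cell) == 0:
                    missing.append(combo + (ph, temp))
                    continue
                if len(cell) > 1:
                    raise ReportError(f"duplicate cell at {combo + (ph, temp)}")
                grid[i, j] = (float(cell["fc"].iloc[0]), bool(cell["significant"].iloc[0]))
                vid[i, j] = int(cell["variant_id"].iloc[0])
        panels[combo] = grid
        vids[combo] = vid
    if missing:
        raise ReportError(f"missing cells for coded combinations: {missing}")
    return HeatmapGrid(strain=str(strains[0]), measure=str(measures[0]),
                       panels=panels, variant_ids=vids)


def _grid_json(grid: HeatmapGrid) -> dict:
    return {
        ",".join(f"{int(k)}" for k in key): [
            [[round(float(fc), 10), bool(sig)] for fc, sig in row] for row in panel
        ]
        for key, panel in sorted(grid.panels.items())
    }


def export_records(
    fc_records: pd.DataFrame,
    design: pd.DataFrame,
    out_dir: str | Path,
    contributions: dict[str, dict[str, pd.DataFrame]] | None = None,
) -> list[Path]:
    """Write per-strain JSON records and global strains x variants CSV matrices.

    ``contributions`` optionally maps strain -> measure -> contribution table
    (with delta columns) to embed in the records.  Every strain must carry all
    three measures.  Output ordering and float formatting are fixed, so
    identical inputs re-export byte-identically.  Returns the written paths;
    empty input writes nothing.
    """
    out_dir = Path(out_dir)
    if fc_records.empty:
        return []
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    measures = ("growth", "total_rprot", "normalized_rprot")
    for strain in sorted(fc_records["strain_id"].unique()):
        strain_fc = fc_records[fc_records["strain_id"] == strain]
        record: dict = {"strain": str(strain), "heatmaps": {}, "contributions": {}}
        for measure in measures:
            sub = strain_fc[strain_fc["measure"] == measure]
            if sub.empty:
                raise ReportError(f"strain {strain!r} is missing measure {measure!r}")
            record["heatmaps"][measure] = _grid_json(arrange_heatmap(sub, design))
            if contributions and measure in contributions.get(str(strain), {}):
                table = contributions[str(strain)][measure]
                record["contributions"][measure] = {
                    f: {k: (round(float(v), 10) if isinstance(v, (int, float, np.floating)) else v)
                        for k, v in row.items()}
                    for f, row in table.to_dict("index").items()
                }
        path = out_dir / f"strain_{strain}.json"
        path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
        written.append(path)

    for measure in measures:
        sub = fc_records[fc_records["measure"] == measure]
        matrix = sub.pivot(index="strain_id", columns="variant_id", values="fc")
        matrix = matrix.sort_index().sort_index(axis=1)
        path = out_dir / f"global_{measure}.csv"
        matrix.to_csv(path, float_format="%.10g")
        written.append(path)
    return written


def plot_heatmap(grid: HeatmapGrid, path: str | Path | None = None):
    """Render one heat-map grid with a diverging scale centered at FC = 1;
    significant cells are outlined.  Returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = sorted(grid.panels)
    fig, axes = plt.subplots(2, 4, figsize=(14, 6), constrained_layout=True)
    fcs = [fc for p in grid.panels.values() for row in p for fc, _ in row]
    span = max(abs(np.log2(max(min(fcs), 1e-6))), abs(np.log2(max(fcs))), 0.1)
    for ax, key in zip(axes.ravel(), keys):
        panel = grid.panels[key]
        vals = np.array([[fc for fc, _ in row] for row in panel], dtype=float)
        im = ax.imshow(np.log2(vals), cmap="RdBu_r", vmin=-span, vmax=span, origin="lower")
        for i in range(3):
            for j in range(3):
                if panel[i, j][1]:
                    ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False, lw=1.5))
        ax.set_title(f"O2={key[0]:+.0f} C={key[1]:+.0f} N={key[2]:+.0f}", fontsize=8)
        ax.set_xticks(range(3), ["-1", "0", "+1"])
        ax.set_yticks(range(3), ["-1", "0", "+1"])
        ax.set_xlabel("temperature (coded)")
        ax.set_ylabel("pH (coded)")
    fig.colorbar(im, ax=axes, label="log2 FC", shrink=0.8)
    fig.suptitle(f"{grid.strain} — {grid.measure}")
    if path is not None:
        fig.savefig(path, dpi=100)
    return fig
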