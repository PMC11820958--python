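"""Deliverables: per-cell CSV, per-timepoint fate CSV, and per-cell crops.

All CSV output is deterministic (fixed column order, fixed row order, fixed
3-decimal float formatting) so identical runs produce byte-identical files.
Timepoints in tables are 1-based.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from somatrack.io import ImageStack4D
from somatrack.tracking import CellComponent, FateTable

logger = logging.getLogger(__name__)

_CELL_COLUMNS = [
    "cell_id", "timepoint", "x_vox", "y_vox", "z_vox",
    "x_um", "y_um", "z_um", "n_voxels", "first_timepoint", "last_timepoint",
    "is_new", "is_lost",
]


def cell_table(components: list[CellComponent], voxel_size, T: int) -> pd.DataFrame:
    """One row per (cell, detected timepoint): centroid, size, fate flags."""
    rows = []
    for c in sorted(components, key=lambda c: c.cell_id):
        is_new = c.first_t > 0
        is_lost = c.last_t < T - 1
        for t in c.present_at:
            cx, cy, cz = c.centroid_by_timepoint[t]
            rows.append(
                {
                    "cell_id": c.cell_id,
                    "timepoint": t + 1,
                    "x_vox": cx,
                    "y_vox": cy,
                    "z_vox": cz,
                    "x_um": cx * voxel_size[0],
                    "y_um": cy * voxel_size[1],
                    "z_um": cz * voxel_size[2],
                    "n_voxels": len(c.voxels_by_timepoint[t]),
                    "first_timepoint": c.first_t + 1,
                    "last_timepoint": c.last_t + 1,
                    "is_new": is_new,
                    "is_lost": is_lost,
                }
            )
    return pd.DataFrame(rows, columns=_CELL_COLUMNS)


def write_cell_table(
    components: list[CellComponent],
    voxel_size,
    path: str | Path,
    T: int,
) -> Path:
    """Write the per-cell spreadsheet (coordinates, unique id, size)."""
    df = cell_table(components, voxel_size, T)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.3f", lineterminator="\n")
    return path


def write_fate_table(fate_table: FateTable, path: str | Path) -> Path:
    """Write per-timepoint totals, new/lost counts and % of baseline."""
    df = fate_table.to_dataframe()
    baseline = int(fate_table.n_total[0])
    if baseline > 0:
        df["pct_of_baseline"] = [
            f"{100.0 * n / baseline:.2f}" for n in fate_table.n_total
        ]
    else:
        logger.warning("baseline n_total(1) is zero; percentage column left empty")
        df["pct_of_baseline"] = ""
    path = Path(path)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def export_crops(
    stack: ImageStack4D,
    components: list[CellComponent],
    crop_halfwidth: tuple[int, int, int] = (20, 20, 5),
    outdir: str | Path = ".",
) -> list[Path]:
    """Write one cropped TIFF per (cell, timepoint) for visual review.

    Each crop is centered on the cell's centroid at the nearest timepoint
    with a detection (so absence before first / after last detection can be
    inspected), and clipped at the volume borders.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hx, hy, hz = (int(h) for h in crop_halfwidth)
    I, J, K, T = stack.shape
    paths = []
    for c in sorted(components, key=lambda c: c.cell_id):
        present = np.asarray(c.present_at)
        for t in range(T):
            nearest = int(present[np.argmin(np.abs(present - t))])
            cx, cy, cz = (int(round(v)) for v in c.centroid_by_timepoint[nearest])
            x0, x1 = max(0, cx - hx), min(I, cx + hx + 1)
            y0, y1 = max(0, cy - hy), min(J, cy + hy + 1)
            z0, z1 = max(0, cz - hz), min(K, cz + hz + 1)
            if (x1 - x0, y1 - y0, z1 - z0) != (2 * hx + 1, 2 * hy + 1, 2 * hz + 1):
                logger.info("crop for cell %d at t=%d clipped at volume border", c.cell_id, t + 1)
            crop = stack.data[x0:x1, y0:y1, z0:z1, t]
            path = outdir / f"cell{c.cell_id:04d}_t{t + 1:02d}.tif"
            tifffile.imwrite(
                path, np.transpose(crop, (2, 1, 0)),
                photometric="minisblack", metadata={"axes": "ZYX"},
            )
            paths.append(path)
    return paths
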