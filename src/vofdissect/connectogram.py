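"""Connectogram table export for circular-plot table viewers.

The export is a tab-separated square table: one color row, one label row,
then the symmetric count matrix, each parcel carrying its RGB color from
the label table.  The format is defined by its own round-trip contract:
:func:`parse_connectogram` reproduces the matrix and colors exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix

__all__ = ["export_connectogram", "parse_connectogram"]

_HEADER = "#vofdissect-connectogram\tv1"


def export_connectogram(
    m: ConnectivityMatrix, table: pd.DataFrame, path: str | Path
) -> Path:
    """Write the matrix with per-parcel RGB colors; drops all-zero parcels.

    Raises if the matrix is empty (no streamline counted)."""
    if m.total() == 0:
        raise ValueError("refusing to export an empty connectivity matrix")
    keep = [p for p in m.parcels if m.counts.loc[p].sum() > 0 or m.counts.loc[p, p] > 0]
    counts = m.counts.loc[keep, keep]
    sub = table[table["hemisphere"] == m.hemisphere].set_index("name")
    colors = {}
    for p in keep:
        if p not in sub.index:
            raise ValueError(f"parcel {p!r} missing from label table")
        row = sub.loc[p]
        colors[p] = f"{int(row['r'])},{int(row['g'])},{int(row['b'])}"
    lines = [_HEADER, f"hemisphere\t{m.hemisphere}"]
    lines.append("\t".join(["colors"] + [colors[p] for p in keep]))
    lines.append("\t".join(["labels"] + keep))
    for p in keep:
        lines.append("\t".join([p] + [str(int(v)) for v in counts.loc[p]]))
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def parse_connectogram(path: str | Path) -> tuple[ConnectivityMatrix, dict[str, tuple[int, int, int]]]:
    """Inverse of :func:`export_connectogram`."""
    lines = Path(path).read_text().rstrip("\n").split("\n")
    if not lines or lines[0] != _HEADER:
        raise ValueError(f"{path}: not a connectogram table (bad header)")
    hemisphere = lines[1].split("\t")[1]
    color_cells = lines[2].split("\t")[1:]
    labels = lines[3].split("\t")[1:]
    colors = {
        lab: tuple(int(c) for c in cell.split(","))
        for lab, cell in zip(labels, color_cells)
    }
    rows = []
    for line in lines[4:]:
        cells = line.split("\t")
        rows.append([int(v) for v in cells[1:]])
    counts = pd.DataFrame(np.array(rows, dtype=np.int64), index=labels, columns=labels)
    return ConnectivityMatrix(counts=counts, hemisphere=hemisphere), colors
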