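"""Plain-text readers/writers for the pipeline's exchange formats.

Formats (all columns exact):

* tracks CSV:   cell_id,parent_id,phenotype,frame,time_s,x_um,y_um,attached
* series CSV:   time_s,n_bulk,n_surface,n_total
* fluor CSV:    cell_id,population,egfp_au,lectin_au,latent_au
* lineage JSON: {"nodes": [{"id","parent","t_birth_s","t_division_s","fate"}],
                 "config": {...}}
* height map CSV: plain n x m numeric grid
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import StructuralError
from .hetero import FluorTable
from .lineage import LineageForest, LineageNode
from .simulate import CellTrack
from .biofilm import HeightMap
from .tracks import AttachmentSeries

PathLike = Union[str, Path]

TRACK_COLUMNS = ["cell_id", "parent_id", "phenotype", "frame", "time_s", "x_um", "y_um", "attached"]
SERIES_COLUMNS = ["time_s", "n_bulk", "n_surface", "n_total"]
FLUOR_COLUMNS = ["cell_id", "population", "egfp_au", "lectin_au", "latent_au"]


def tracks_to_frame(tracks: Sequence[CellTrack]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        n = len(t)
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": t.cell_id,
                    "parent_id": t.parent_id if t.parent_id is not None else "",
                    "phenotype": t.phenotype,
                    "frame": np.arange(n),
                    "time_s": t.times,
                    "x_um": t.xy[:, 0],
                    "y_um": t.xy[:, 1],
                    "attached": t.attached.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[TRACK_COLUMNS]


def write_tracks_csv(tracks: Sequence[CellTrack], path: PathLike) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False, float_format="%.4f")


def read_tracks_csv(path: PathLike) -> List[CellTrack]:
    df = pd.read_csv(path, dtype={"cell_id": str, "parent_id": str}, keep_default_na=False)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise StructuralError(f"tracks CSV missing columns: {sorted(missing)}")
    out = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        parent = grp["parent_id"].iloc[0] or None
        out.append(
            CellTrack(
                cell_id=str(cid),
                phenotype=int(grp["phenotype"].iloc[0]),
                times=grp["time_s"].to_numpy(float),
                xy=grp[["x_um", "y_um"]].to_numpy(float),
                attached=grp["attached"].to_numpy(int).astype(bool),
                parent_id=parent,
            )
        )
    return out


def write_series_csv(series: AttachmentSeries, path: PathLike) -> None:
    pd.DataFrame(
        {
            "time_s": series.times,
            "n_bulk": series.n_bulk,
            "n_surface": series.n_surface,
            "n_total": series.n_total,
        }
    ).to_csv(path, index=False)


def read_series_csv(path: PathLike) -> AttachmentSeries:
    df = pd.read_csv(path)
    missing = set(SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise StructuralError(f"series CSV missing columns: {sorted(missing)}")
    n_total = df["n_total"].to_numpy()
    if len(np.unique(n_total)) != 1:
        raise StructuralError("n_total must be constant")
    return AttachmentSeries(
        times=df["time_s"].to_numpy(float),
        n_bulk=df["n_bulk"].to_numpy(),
        n_surface=df["n_surface"].to_numpy(),
        n_total=int(n_total[0]),
    )


def write_fluor_csv(table: FluorTable, path: PathLike) -> None:
    cols = [c for c in FLUOR_COLUMNS if c in table.data.columns]
    cols += [c for c in table.data.columns if c not in cols]
    table.data[cols].to_csv(path, index=False, float_format="%.4f")


def read_fluor_csv(path: PathLike) -> FluorTable:
    df = pd.read_csv(path, dtype={"cell_id": str, "population": str})
    return FluorTable(df)


def write_forest_json(forest: LineageForest, path: PathLike,
                      config: Optional[Dict] = None) -> None:
    payload = {
        "nodes": [
            {
                "id": n.id,
                "parent": n.parent,
                "t_birth_s": n.t_birth,
                "t_division_s": n.t_division,
                "fate": n.fate,
            }
            for n in forest.nodes.values()
        ],
        "config": config or {},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_forest_json(path: PathLike) -> LineageForest:
    payload = json.loads(Path(path).read_text())
    nodes = {
        rec["id"]: LineageNode(
            id=rec["id"],
            parent=rec["parent"],
            t_birth=float(rec["t_birth_s"]),
            t_division=None if rec["t_division_s"] is None else float(rec["t_division_s"]),
            fate=rec["fate"],
        )
        for rec in payload["nodes"]
    }
    return LineageForest(nodes)


def write_heightmap_csv(hmap: HeightMap, path: PathLike) -> None:
    np.savetxt(path, hmap.grid, delimiter=",", fmt="%.6g")


def read_heightmap_csv(path: PathLike, pixel_size: float = 1.0) -> HeightMap:
    grid = np.loadtxt(path, delimiter=",", ndmin=2)
    return HeightMap(grid, pixel_size=pixel_size)


def write_json(obj: Dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
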