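"""On-disk formats: multi-page TIFF fields of view, sidecars and tables.

Layout of a sample directory (format ``pnpcyto.fov/1``)::

    sample/
      manifest.json            # lists the FOV subdirectories
      truth.tsv                # optional simulator ground truth
      fov_000/
        darkfield.tif          # Z pages of RGB, float32
        fluor.tif              # 4 pages of RGB (one per excitation band)
        meta.json              # pixel pitch, z positions, channel order, seed

Cell masks travel inside the cell-level TSV as run-length-encoded strings
so the output stays single-file.
"""

from __future__ import annotations

import json
import os
from typing import List, Optional

import numpy as np
import pandas as pd
import tifffile

from .datatypes import FieldOfView
from .errors import InputError

FOV_FORMAT = "pnpcyto.fov/1"


def write_fov(fov: FieldOfView, path: str) -> None:
    """Write one field of view as two multi-page TIFFs plus a JSON sidecar."""
    os.makedirs(path, exist_ok=True)
    if fov.darkfield is not None:
        tifffile.imwrite(
            os.path.join(path, "darkfield.tif"),
            np.asarray(fov.darkfield, dtype=np.float32),
            photometric="rgb",
        )
    if fov.fluorescence is not None:
        tifffile.imwrite(
            os.path.join(path, "fluor.tif"),
            np.asarray(fov.fluorescence, dtype=np.float32),
            photometric="rgb",
        )
    sidecar = {
        "format": FOV_FORMAT,
        "pixel_pitch_um": fov.pixel_pitch_um,
        "z_positions_um": None
        if fov.z_positions_um is None
        else [float(z) for z in fov.z_positions_um],
        "channel_order": list(fov.channel_order),
        "meta": {k: v for k, v in fov.meta.items() if _jsonable(v)},
    }
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_fov(path: str) -> FieldOfView:
    """Read a field of view written by :func:`write_fov`."""
    meta_path = os.path.join(path, "meta.json")
    if not os.path.exists(meta_path):
        raise InputError(f"{path}: missing meta.json sidecar")
    with open(meta_path) as fh:
        sidecar = json.load(fh)
    if sidecar.get("format") != FOV_FORMAT:
        raise InputError(f"{path}: unknown FOV format {sidecar.get('format')!r}")
    darkfield = fluor = None
    df_path = os.path.join(path, "darkfield.tif")
    fl_path = os.path.join(path, "fluor.tif")
    if os.path.exists(df_path):
        darkfield = tifffile.imread(df_path)
    if os.path.exists(fl_path):
        fluor = tifffile.imread(fl_path)
    z = sidecar.get("z_positions_um")
    return FieldOfView(
        fluorescence=fluor,
        darkfield=darkfield,
        pixel_pitch_um=float(sidecar["pixel_pitch_um"]),
        z_positions_um=None if z is None else np.asarray(z, dtype=float),
        channel_order=tuple(sidecar.get("channel_order", ("R", "G", "B"))),
        meta=sidecar.get("meta", {}),
    )


def write_sample(sample, mixing, path: str, include_darkfield: bool = True) -> None:
    """Render and write every FOV of a simulated sample plus its ground truth."""
    os.makedirs(path, exist_ok=True)
    names = []
    for i in range(len(sample.cells_by_fov)):
        name = f"fov_{i:03d}"
        fov = sample.render_fov(i, mixing, include_darkfield=include_darkfield)
        write_fov(fov, os.path.join(path, name))
        names.append(name)
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump({"format": FOV_FORMAT, "sample_id": sample.sample_id,
                   "fovs": names}, fh, indent=1)
    sample.truth.to_csv(os.path.join(path, "truth.tsv"), sep="\t", index=False)


def list_fovs(sample_dir: str) -> List[str]:
    """FOV subdirectories of a sample, from the manifest or by globbing."""
    manifest = os.path.join(sample_dir, "manifest.json")
    if os.path.exists(manifest):
        with open(manifest) as fh:
            return [os.path.join(sample_dir, f) for f in json.load(fh)["fovs"]]
    subdirs = sorted(
        d for d in os.listdir(sample_dir)
        if os.path.isdir(os.path.join(sample_dir, d))
        and os.path.exists(os.path.join(sample_dir, d, "meta.json"))
    )
    if not subdirs:
        raise InputError(f"{sample_dir}: no fields of view found")
    return [os.path.join(sample_dir, d) for d in subdirs]


def rle_encode(mask: np.ndarray) -> str:
    """Run-length encode a boolean mask as 'HxW:start,len,start,len,...'."""
    mask = np.asarray(mask, dtype=bool)
    flat = mask.ravel()
    edges = np.flatnonzero(np.diff(flat.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [flat.size]])
    runs = [
        f"{s},{e - s}" for s, e in zip(starts, ends) if flat[s]
    ]
    return f"{mask.shape[0]}x{mask.shape[1]}:" + ",".join(runs)


def rle_decode(text: str) -> np.ndarray:
    """Inverse of :func:`rle_encode`."""
    header, _, body = text.partition(":")
    h, w = (int(v) for v in header.split("x"))
    mask = np.zeros(h * w, dtype=bool)
    if body:
        vals = [int(v) for v in body.split(",")]
        for start, length in zip(vals[::2], vals[1::2]):
            mask[start : start + length] = True
    return mask.reshape(h, w)


def write_cells_table(records, path: str) -> pd.DataFrame:
    """Serialize CellRecords to a TSV; returns the DataFrame written."""
    df = records_to_frame(records)
    df.to_csv(path, sep="\t", index=False)
    return df


def records_to_frame(records) -> pd.DataFrame:
    from .config import MARKERS

    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "fov_id": r.fov_id,
            "cell_id": r.cell_id,
            "x_ds": r.center_ds[0],
            "y_ds": r.center_ds[1],
            "radius_ds": r.radius_ds,
            "area_um2": r.area_um2,
            "lineage": r.lineage,
            "pnp_count": r.pnp_count,
            "n_detections": len(r.detections),
        }
        for m in MARKERS:
            call = r.calls.get(m)
            if call is not None:
                row[f"{m}_pos"] = call.positive
                row[f"{m}_in"] = call.mean_inside
                row[f"{m}_out"] = call.mean_outside
                row[f"{m}_out_sd"] = call.sd_outside
        row["mask_rle"] = "" if r.mask_ds is None else rle_encode(r.mask_ds)
        rows.append(row)
    return pd.DataFrame(rows)


def read_cells_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
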