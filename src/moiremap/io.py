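"""File formats: TSV mosaics with JSON provenance, HDF5 map containers."""

from __future__ import annotations

import json
import math
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .mosaics import Rect, RGCMosaic
from .wiring_model import CorticalGrid, TuningMap

__all__ = ["save_mosaic", "load_mosaic", "save_map", "load_map",
           "save_pinwheels_tsv"]


def save_mosaic(mosaic: RGCMosaic, path) -> None:
    """Write a mosaic as TSV (x_um, y_um, polarity) plus ``.json`` sidecar."""
    path = Path(path)
    df = pd.DataFrame({
        "x_um": mosaic.positions[:, 0],
        "y_um": mosaic.positions[:, 1],
        "polarity": mosaic.polarity,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.8f")
    sidecar = {
        "extent_um": [mosaic.extent.xmin, mosaic.extent.xmax,
                      mosaic.extent.ymin, mosaic.extent.ymax],
        "provenance": _jsonable(mosaic.provenance),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )


def load_mosaic(path) -> RGCMosaic:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        extent = Rect(*sidecar["extent_um"])
        prov = sidecar.get("provenance", {})
    else:
        x, y = df["x_um"].to_numpy(), df["y_um"].to_numpy()
        extent = Rect(x.min(), x.max(), y.min(), y.max())
        prov = {}
    return RGCMosaic(
        np.stack([df["x_um"].to_numpy(), df["y_um"].to_numpy()], axis=1),
        df["polarity"].to_numpy(dtype=object),
        extent,
        prov,
    )


def save_map(tmap: TuningMap, path) -> None:
    """HDF5 map container: datasets theta/osi/kpref/valid_mask + attrs."""
    from . import __version__

    with h5py.File(path, "w") as f:
        f.create_dataset("theta", data=tmap.theta)
        f.create_dataset("osi", data=tmap.osi)
        f.create_dataset("kpref", data=tmap.kpref)
        f.create_dataset("valid_mask", data=tmap.valid_mask.astype(bool))
        f.attrs["pixel_size_mm"] = tmap.grid.pixel_size_mm
        f.attrs["stage"] = tmap.stage
        f.attrs["software_version"] = __version__
        f.attrs["meta_json"] = json.dumps(_jsonable(tmap.meta))


def load_map(path) -> TuningMap:
    with h5py.File(path, "r") as f:
        theta = f["theta"][()]
        osi = f["osi"][()]
        kpref = f["kpref"][()]
        valid = f["valid_mask"][()].astype(bool)
        px = float(f.attrs["pixel_size_mm"])
        stage = str(f.attrs["stage"])
        meta = json.loads(f.attrs.get("meta_json", "{}"))
    ny, nx = theta.shape
    grid = CorticalGrid(nx=nx, ny=ny, pixel_size_mm=px)
    return TuningMap(theta=theta, osi=osi, kpref=kpref, grid=grid,
                     stage=stage, valid_mask=valid, meta=meta)


def save_pinwheels_tsv(pws, path) -> None:
    """Write pinwheel positions/charges/confidence as TSV (map units)."""
    pd.DataFrame({
        "x_mm": pws.positions[:, 0],
        "y_mm": pws.positions[:, 1],
        "charge": pws.charges,
        "low_confidence": pws.low_confidence.astype(int),
    }).to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.random.SeedSequence):
        return {"seed_sequence_entropy": obj.entropy,
                "spawn_key": list(obj.spawn_key)}
    if obj is None or isinstance(obj, (str, int, bool)):
        return obj
    if isinstance(obj, float):
        return obj if math.isfinite(obj) else str(obj)
    return str(obj)
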