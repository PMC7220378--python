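"""File formats: HDF5 / long-CSV session blocks, label images, EM tables.

Long-format CSV is the canonical inspectable interchange; HDF5 is the
compact form for full session blocks.  ``write_traces`` followed by
``read_traces`` is the identity on values and metadata.

HDF5 layout::

    /recordings/<j>/soma        (frames x ROIs) float64
    /recordings/<j>/neuropil    (frames x ROIs) float64
    /recordings/<j>/encoder     (frames x 2)  [time_s, position_cm]
    /recordings/<j>  attrs: index, condition, wavelength, frame_rate, roi_labels
    /masks/<condition>          uint16 label image
    root attrs: pixel_size_um, frame_rate
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .blocks import Recording, SessionBlock


class TraceLayoutError(ValueError):
    """Malformed trace file layout."""


def write_traces(block: SessionBlock, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["pixel_size_um"] = block.pixel_size_um
        f.attrs["frame_rate"] = block.frame_rate
        grp = f.create_group("recordings")
        for rec in block:
            g = grp.create_group(str(rec.index))
            g.create_dataset("soma", data=rec.soma.to_numpy())
            g.create_dataset("neuropil", data=rec.neuropil.to_numpy())
            g.create_dataset("encoder", data=rec.encoder[["time_s", "position_cm"]].to_numpy())
            g.attrs["index"] = rec.index
            g.attrs["condition"] = rec.condition
            g.attrs["wavelength"] = rec.wavelength
            g.attrs["frame_rate"] = rec.frame_rate
            g.attrs["roi_labels"] = rec.soma.columns.to_numpy(dtype=np.int64)
        masks = f.create_group("masks")
        for cond, img in block.masks.items():
            masks.create_dataset(cond, data=np.asarray(img, dtype=np.uint16))
    return path


def read_traces(path: str | Path) -> SessionBlock:
    path = Path(path)
    recordings = []
    with h5py.File(path, "r") as f:
        if "recordings" not in f:
            raise TraceLayoutError(f"{path}: missing /recordings group")
        for name in sorted(f["recordings"], key=int):
            g = f["recordings"][name]
            for ds in ("soma", "neuropil", "encoder"):
                if ds not in g:
                    raise TraceLayoutError(f"{path}: /recordings/{name} missing {ds!r}")
            labels = g.attrs["roi_labels"]
            enc = pd.DataFrame(g["encoder"][()], columns=["time_s", "position_cm"])
            recordings.append(
                Recording(
                    index=int(g.attrs["index"]),
                    condition=str(g.attrs["condition"]),
                    soma=pd.DataFrame(g["soma"][()], columns=labels),
                    neuropil=pd.DataFrame(g["neuropil"][()], columns=labels),
                    encoder=enc,
                    frame_rate=float(g.attrs["frame_rate"]),
                    wavelength=int(g.attrs["wavelength"]),
                )
            )
        masks = {cond: f["masks"][cond][()] for cond in f.get("masks", [])}
        block = SessionBlock(
            recordings=recordings,
            masks=masks,
            pixel_size_um=float(f.attrs["pixel_size_um"]),
            frame_rate=float(f.attrs["frame_rate"]),
        )
    return block


def write_traces_csv(block: SessionBlock, directory: str | Path) -> Path:
    """Long-format CSV export: traces.csv, encoder.csv, masks as TIFF."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = []
    enc_frames = []
    for rec in block:
        long = (
            rec.soma.reset_index(names="frame")
            .melt(id_vars="frame", var_name="roi", value_name="soma")
            .merge(
                rec.neuropil.reset_index(names="frame").melt(
                    id_vars="frame", var_name="roi", value_name="neuropil"
                ),
                on=["frame", "roi"],
            )
        )
        long.insert(0, "recording", rec.index)
        long.insert(1, "condition", rec.condition)
        long.insert(2, "wavelength", rec.wavelength)
        frames.append(long)
        enc = rec.encoder.copy()
        enc.insert(0, "recording", rec.index)
        enc_frames.append(enc)
    pd.concat(frames).to_csv(directory / "traces.csv", index=False)
    pd.concat(enc_frames).to_csv(directory / "encoder.csv", index=False)
    for cond, img in block.masks.items():
        tifffile.imwrite(directory / f"mask_{cond}.tif", np.asarray(img, dtype=np.uint16))
    meta = {
        "pixel_size_um": block.pixel_size_um,
        "frame_rate": block.frame_rate,
        "frame_rates": {str(r.index): r.frame_rate for r in block},
    }
    (directory / "block_meta.json").write_text(json.dumps(meta, indent=1))
    return directory


def read_traces_csv(directory: str | Path) -> SessionBlock:
    directory = Path(directory)
    traces = pd.read_csv(directory / "traces.csv", float_precision="round_trip")
    required = {"recording", "condition", "wavelength", "frame", "roi", "soma", "neuropil"}
    missing = required - set(traces.columns)
    if missing:
        raise TraceLayoutError(f"traces.csv missing columns {sorted(missing)}")
    encoder = pd.read_csv(directory / "encoder.csv", float_precision="round_trip")
    meta = json.loads((directory / "block_meta.json").read_text())
    recordings = []
    for j, sub in traces.groupby("recording"):
        roi_order = sub["roi"].unique()  # preserve stored column order
        soma = sub.pivot(index="frame", columns="roi", values="soma").sort_index()[roi_order]
        neuropil = sub.pivot(index="frame", columns="roi", values="neuropil").sort_index()[roi_order]
        soma.columns = soma.columns.astype(np.int64)
        neuropil.columns = neuropil.columns.astype(np.int64)
        soma.index = pd.RangeIndex(len(soma))
        neuropil.index = pd.RangeIndex(len(neuropil))
        enc = encoder[encoder["recording"] == j][["time_s", "position_cm"]].reset_index(drop=True)
        recordings.append(
            Recording(
                index=int(j),
                condition=str(sub["condition"].iloc[0]),
                soma=soma,
                neuropil=neuropil,
                encoder=enc,
                frame_rate=float(meta["frame_rates"][str(int(j))]),
                wavelength=int(sub["wavelength"].iloc[0]),
            )
        )
    recordings.sort(key=lambda r: r.index)
    masks = {}
    for tif in sorted(directory.glob("mask_*.tif")):
        masks[tif.stem.removeprefix("mask_")] = tifffile.imread(tif)
    return SessionBlock(
        recordings=recordings,
        masks=masks,
        pixel_size_um=float(meta["pixel_size_um"]),
        frame_rate=float(meta["frame_rate"]),
    )


def write_label_image(img: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(img, dtype=np.uint16))
    return path


def read_label_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_em_sample(particles: np.ndarray, polygon_vertices: np.ndarray, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(np.asarray(particles, float).reshape(-1, 2), columns=["x_nm", "y_nm"]).to_csv(
        directory / "particles.csv", index=False
    )
    pd.DataFrame(np.asarray(polygon_vertices, float), columns=["vertex_x_nm", "vertex_y_nm"]).to_csv(
        directory / "psd_polygon.csv", index=False
    )
    return directory


def read_em_sample(particles_csv: str | Path, polygon_csv: str | Path):
    from .em import PSDSample

    particles = pd.read_csv(particles_csv, float_precision="round_trip")
    poly = pd.read_csv(polygon_csv, float_precision="round_trip")
    for df, cols, name in (
        (particles, ["x_nm", "y_nm"], "particle CSV"),
        (poly, ["vertex_x_nm", "vertex_y_nm"], "polygon CSV"),
    ):
        missing = set(cols) - set(df.columns)
        if missing:
            raise TraceLayoutError(f"{name} missing columns {sorted(missing)}")
    return PSDSample(
        psd_polygon=poly[["vertex_x_nm", "vertex_y_nm"]].to_numpy(),
        particles=particles[["x_nm", "y_nm"]].to_numpy(),
    )


def read_stim_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"cell", "condition", "frequency_hz", "duration_s", "compartment", "peak_dff"}
    missing = required - set(table.columns)
    if missing:
        raise TraceLayoutError(f"stimulation CSV missing columns {sorted(missing)}")
    return table
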