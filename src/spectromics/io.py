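"""File I/O: ENVI cubes, HDF5 parameter maps and cohorts, TIFF masks.

ENVI support is a minimal header+binary reader/writer (band-sequential
float32 with a wavelength list), enough to exchange cubes with standard
hyperspectral tooling.  Parameter maps and whole cohorts go to HDF5 with
one named dataset per channel; label masks go to single-channel 8-bit
TIFF with codes {0 background, 1 healthy, 2 tumor}.
"""
from __future__ import annotations

import os

import h5py
import numpy as np
import tifffile

from .grids import WavelengthGrid
from .inversion import ParameterMaps
from .params import PARAM_NAMES
from .preprocessing import HyperCube, TissueMask

__all__ = [
    "write_envi", "read_envi",
    "save_parameter_maps", "load_parameter_maps",
    "save_mask", "load_mask",
    "save_cohort", "load_cohort",
]


def write_envi(cube: HyperCube, path: str) -> None:
    """Write a cube as ENVI header (.hdr) + band-sequential float32 body."""
    base, ext = os.path.splitext(path)
    if ext == ".hdr":
        path = base
    rows, cols, bands = cube.data.shape
    wav = ", ".join(f"{w:g}" for w in cube.grid.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"wavelength units = nm\n"
        f"wavelength = {{ {wav} }}\n"
    )
    with open(path + ".hdr", "w") as fh:
        fh.write(header)
    # BSQ: band, then line, then sample
    np.ascontiguousarray(
        np.moveaxis(cube.data, 2, 0).astype("<f4")).tofile(path + ".img")


def _parse_envi_header(text: str) -> dict:
    fields = {}
    key = None
    buf = ""
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if key is None:
            if "=" not in line:
                continue
            key, val = (s.strip() for s in line.split("=", 1))
            key = key.lower()
            if val.startswith("{") and "}" not in val:
                buf = val
                continue
            fields[key] = val.strip("{} ")
            key = None
        else:
            buf += " " + line
            if "}" in line:
                fields[key] = buf.strip("{} ")
                key = None
                buf = ""
    return fields


def read_envi(path: str) -> HyperCube:
    """Read a band-sequential float32 ENVI cube written by write_envi."""
    base, ext = os.path.splitext(path)
    if ext in (".hdr", ".img"):
        path = base
    with open(path + ".hdr") as fh:
        fields = _parse_envi_header(fh.read())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    if int(fields.get("data type", 4)) != 4:
        raise ValueError("only float32 ENVI cubes are supported")
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only band-sequential ENVI cubes are supported")
    data = np.fromfile(path + ".img", dtype="<f4", count=rows * cols * bands)
    data = np.moveaxis(data.reshape(bands, rows, cols), 0, 2).astype(float)
    wav = np.array([float(w) for w in fields["wavelength"].split(",")])
    return HyperCube(data, WavelengthGrid(wav), stage="raw")


def save_parameter_maps(maps: ParameterMaps, path: str) -> None:
    """One HDF5 group with a named dataset per fitted parameter, plus the
    residual map and the valid/converged masks."""
    with h5py.File(path, "w") as f:
        g = f.create_group("parameter_maps")
        for name in PARAM_NAMES:
            g.create_dataset(name, data=maps.map(name))
        g.create_dataset("residual", data=maps.residual)
        g.create_dataset("valid", data=maps.valid.astype(np.uint8))
        g.create_dataset("converged", data=maps.converged.astype(np.uint8))


def load_parameter_maps(path: str) -> ParameterMaps:
    with h5py.File(path, "r") as f:
        g = f["parameter_maps"]
        params = {name: g[name][()] for name in PARAM_NAMES}
        return ParameterMaps(params=params, residual=g["residual"][()],
                             valid=g["valid"][()].astype(bool),
                             converged=g["converged"][()].astype(bool))


def save_cohort(cohort, directory: str) -> None:
    """One HDF5 per image (raw cube, references, truth maps + labels)
    plus a manifest CSV (mouse, day, file, split)."""
    os.makedirs(directory, exist_ok=True)
    rows = []
    for k, im in enumerate(cohort.images):
        fname = f"image_{k:03d}.h5"
        with h5py.File(os.path.join(directory, fname), "w") as f:
            f.attrs["mouse"] = im.mouse
            f.attrs["day"] = im.day
            f.attrs["split"] = im.split
            f.create_dataset("raw", data=im.raw.data)
            f.create_dataset("wavelengths", data=im.raw.grid.wavelengths)
            f.create_dataset("dark", data=im.dark)
            f.create_dataset("white", data=im.white)
            f.create_dataset("truth_labels", data=im.truth_mask.labels)
            g = f.create_group("truth_maps")
            for name in PARAM_NAMES:
                g.create_dataset(name, data=im.truth_maps.map(name))
        rows.append(dict(mouse=im.mouse, day=im.day, file=fname,
                         split=im.split))
    import pandas as pd
    pd.DataFrame(rows).to_csv(os.path.join(directory, "manifest.csv"),
                              index=False)


def load_cohort(directory: str, design=None, trajectory=None, seed=0):
    """Rebuild a Cohort from a directory written by save_cohort."""
    import pandas as pd

    from .cohort import Cohort, CohortDesign, CohortImage, TumorTrajectory
    manifest = pd.read_csv(os.path.join(directory, "manifest.csv"))
    images = []
    for _, row in manifest.iterrows():
        with h5py.File(os.path.join(directory, row["file"]), "r") as f:
            grid = WavelengthGrid(f["wavelengths"][()])
            labels = f["truth_labels"][()].astype(np.uint8)
            params = {n: f["truth_maps"][n][()] for n in PARAM_NAMES}
            valid = labels > 0
            maps = ParameterMaps(params=params,
                                 residual=np.zeros(labels.shape),
                                 valid=valid,
                                 converged=np.ones(labels.shape, bool))
            images.append(CohortImage(
                mouse=int(f.attrs["mouse"]), day=float(f.attrs["day"]),
                split=str(f.attrs["split"]),
                raw=HyperCube(f["raw"][()], grid, stage="raw"),
                dark=f["dark"][()], white=f["white"][()],
                truth_maps=maps,
                truth_mask=TissueMask(tissue=valid, labels=labels)))
    return Cohort(design=design or CohortDesign(),
                  trajectory=trajectory or TumorTrajectory(),
                  seed=seed, images=images)


def save_mask(mask: TissueMask, path: str) -> None:
    """8-bit single-channel TIFF, codes {0 background, 1 healthy, 2 tumor}."""
    tifffile.imwrite(path, mask.labels.astype(np.uint8))


def load_mask(path: str) -> TissueMask:
    labels = tifffile.imread(path).astype(np.uint8)
    return TissueMask(tissue=labels > 0, labels=labels)
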