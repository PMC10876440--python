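"""File formats: TIFF movies, CSV traces and tables, JSON truth, YAML config.

Movies travel as ImageJ-compatible multi-page TIFF with TYX axes; calibration
(pixel size, frame interval) is written to the ImageJ metadata and can be
overridden on read.  Mechanics traces are 2-column CSV (time_s, value) whose
header column name declares the trace kind.  All CSV output is
comma-separated, '.'-decimal, UTF-8, with a mandatory header row.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .kymo import Kymograph, MovieStack
from .mechanics import MechTrace, StimulusResponse
from .synthetic import GroundTruth

__all__ = [
    "read_movie",
    "write_movie",
    "read_trace",
    "write_trace",
    "read_responses",
    "write_responses",
    "write_kymograph",
    "read_truth",
    "write_truth",
    "load_config_file",
]


def write_movie(stack: MovieStack, path: str | Path) -> None:
    data = stack.data
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)  # ImageJ TIFF has no float64
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / stack.pixel_size_um, 1.0 / stack.pixel_size_um),
        metadata={
            "axes": "TYX",
            "unit": "um",
            "finterval": stack.frame_interval_s,
        },
    )


def read_movie(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> MovieStack:
    """Read a TYX (or squeezable TZYX) TIFF movie.

    Explicit calibration arguments take precedence over file metadata; if a
    value is in neither place, an error is raised.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = tif.imagej_metadata or {}
            if frame_interval_s is None:
                frame_interval_s = meta.get("finterval")
            if pixel_size_um is None:
                tags = tif.pages[0].tags
                if "XResolution" in tags:
                    num, den = tags["XResolution"].value
                    if num:
                        pixel_size_um = den / num
    except tifffile.TiffFileError as exc:
        raise ValueError(f"{path} is not a readable TIFF file: {exc}") from exc
    if data.ndim == 4 and data.shape[1] == 1:
        data = data[:, 0]
    if data.ndim != 3:
        raise ValueError(f"expected TYX data, got shape {data.shape}")
    if frame_interval_s is None or pixel_size_um is None:
        raise ValueError(
            "missing calibration: provide pixel_size_um / frame_interval_s "
            "or write them into the TIFF metadata"
        )
    return MovieStack(data, float(frame_interval_s), float(pixel_size_um))


def write_kymograph(kymo: Kymograph, path: str | Path) -> None:
    tifffile.imwrite(path, kymo.matrix.astype(np.float32))


def write_trace(trace: MechTrace, path: str | Path) -> None:
    t = np.arange(trace.values.size) / trace.sample_rate_hz
    pd.DataFrame({"time_s": t, trace.kind: trace.values}).to_csv(path, index=False)


def read_trace(path: str | Path, temperature_K: float = 298.0) -> MechTrace:
    df = pd.read_csv(path)
    if "time_s" not in df.columns or len(df.columns) != 2:
        raise ValueError("trace CSV must have columns (time_s, <kind>)")
    kind = [c for c in df.columns if c != "time_s"][0]
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    return MechTrace(df[kind].to_numpy(), fs, kind, temperature_K)


def write_responses(resp: StimulusResponse, path: str | Path) -> None:
    df = pd.DataFrame(
        {"spv_m_s": resp.spv_m_s, "displacement_m": resp.displacement_m}
    )
    df.attrs["f_eigen_hz"] = resp.f_eigen_hz
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# f_eigen_hz={resp.f_eigen_hz}\n")
        df.to_csv(fh, index=False)


def read_responses(path: str | Path, f_eigen_hz: float | None = None) -> StimulusResponse:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#") and "f_eigen_hz=" in first:
            f_eigen_hz = float(first.split("f_eigen_hz=")[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if f_eigen_hz is None:
        raise ValueError("f_eigen_hz missing from header and not provided")
    return StimulusResponse(
        df["spv_m_s"].to_numpy(), df["displacement_m"].to_numpy(), f_eigen_hz
    )


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json(), encoding="utf-8")


def read_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text(encoding="utf-8"))


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        d = json.loads(text)
    else:
        d = yaml.safe_load(text)
    if not isinstance(d, dict):
        raise ValueError("config file must contain a mapping")
    return d
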