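"""File formats: HDF5 frame sets, CSV trial tables and calibration grids,
TIFF movies with JSON sidecars, label-image ROI masks, CSV estimates."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .behavior import TuningCurve
from .imaging import Movie, Roi
from .stimulus import CalibrationMap, FrameSet
from .synthetic import SyntheticMovie, Trial, WbaRecording

__all__ = [
    "save_frameset", "load_frameset",
    "save_calibration", "load_calibration",
    "wba_to_csv", "wba_from_csv",
    "save_movie", "load_movie",
    "save_rois",
    "load_image",
]


def save_frameset(fs: FrameSet, path):
    """Write a FrameSet to HDF5 (datasets uv/green/azimuth/elevation)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("uv", data=fs.uv, compression="gzip")
        f.create_dataset("green", data=fs.green, compression="gzip")
        f.create_dataset("azimuth", data=fs.azimuth)
        f.create_dataset("elevation", data=fs.elevation)
        f.attrs["frame_rate"] = fs.frame_rate
        f.attrs["channel_labels"] = list(fs.channel_labels)
        meta = {k: v for k, v in fs.meta.items() if not isinstance(v, np.ndarray)}
        f.attrs["meta"] = json.dumps(meta)
        if "half_angles" in fs.meta:
            f.create_dataset("half_angles", data=np.asarray(fs.meta["half_angles"]))


def load_frameset(path) -> FrameSet:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs.get("meta", "{}"))
        if "half_angles" in f:
            meta["half_angles"] = f["half_angles"][:]
        return FrameSet(
            f["uv"][:], f["green"][:], float(f.attrs["frame_rate"]),
            f["azimuth"][:], f["elevation"][:],
            tuple(f.attrs["channel_labels"]), meta,
        )


def save_calibration(calib: CalibrationMap, path):
    """CSV of (azimuth, elevation, uv_irradiance, green_mask) sites."""
    az, el = np.meshgrid(calib.site_azimuth, calib.site_elevation, indexing="ij")
    pd.DataFrame({
        "azimuth": az.ravel(), "elevation": el.ravel(),
        "uv_irradiance": calib.uv_irradiance.ravel(),
        "green_mask": calib.green_mask.ravel(),
        "scale": calib.scale,
    }).to_csv(path, index=False)


def load_calibration(path) -> CalibrationMap:
    df = pd.read_csv(path)
    az = np.unique(df["azimuth"])
    el = np.unique(df["elevation"])
    shape = (az.size, el.size)
    return CalibrationMap(
        az, el,
        df["uv_irradiance"].to_numpy().reshape(shape),
        df["green_mask"].to_numpy().reshape(shape),
        float(df["scale"].iloc[0]),
    )


def wba_to_csv(rec: WbaRecording, path):
    """Long-format CSV (fly, trial, protocol, uv_level, rotation, t, dwba)."""
    df = rec.to_frame()
    df["compact"] = rec.compact
    df.to_csv(path, index=False)


def wba_from_csv(path) -> WbaRecording:
    df = pd.read_csv(path)
    trials = []
    sample_rate = 500.0
    for (_, _), g in df.groupby(["fly", "trial"], sort=True):
        g = g.sort_values("t")
        t = g["t"].to_numpy()
        if t.size > 1:
            sample_rate = 1.0 / float(np.median(np.diff(t)))
        trials.append(Trial(
            g["dwba"].to_numpy(), str(g["protocol"].iloc[0]),
            int(g["uv_level"].iloc[0]), str(g["rotation"].iloc[0]),
            int(g["fly"].iloc[0]),
        ))
    compact = bool(df["compact"].iloc[0]) if "compact" in df else False
    fly = trials[0].fly_id if trials else 0
    return WbaRecording(trials, round(sample_rate, 6), fly, compact)


def save_movie(obj, tiff_path, json_path=None):
    """Multi-page TIFF + JSON sidecar for a Movie or SyntheticMovie."""
    movie = obj.movie if isinstance(obj, SyntheticMovie) else obj
    tifffile.imwrite(tiff_path, movie.frames.astype(np.float32))
    sidecar = {
        "frame_rate": movie.frame_rate,
        "stim_onset": movie.stim_onset,
        "expansion_end": movie.expansion_end,
        "hold_end": movie.hold_end,
        "trials": movie.trials.to_dict(orient="records"),
    }
    if isinstance(obj, SyntheticMovie):
        sidecar["ground_truth"] = {
            "rois": obj.rois, "seed": obj.seed, "params": obj.params,
            "jitter": obj.jitter.tolist(),
        }
    if json_path is None:
        json_path = str(Path(tiff_path).with_suffix(".json"))
    Path(json_path).write_text(json.dumps(sidecar))
    return json_path


def load_movie(tiff_path, json_path=None):
    """Load a movie; returns a SyntheticMovie when ground truth is present."""
    if json_path is None:
        json_path = str(Path(tiff_path).with_suffix(".json"))
    sidecar = json.loads(Path(json_path).read_text())
    frames = tifffile.imread(tiff_path)
    movie = Movie(frames, sidecar["frame_rate"], pd.DataFrame(sidecar["trials"]),
                  sidecar["stim_onset"], sidecar["expansion_end"], sidecar["hold_end"])
    gt = sidecar.get("ground_truth")
    if gt is None:
        return movie
    return SyntheticMovie(movie, gt["rois"], np.asarray(gt["jitter"], dtype=int),
                          gt["seed"], gt["params"])


def save_rois(rois, label_tiff_path, peaks_csv_path):
    """Label-image TIFF (0 = background, i = ROI i) plus a peaks CSV."""
    rois = list(rois)
    if not rois:
        raise ValueError("no ROIs to save")
    labels = np.zeros(rois[0].mask.shape, dtype=np.uint16)
    rows = []
    for i, roi in enumerate(rois, start=1):
        labels[roi.mask] = i
        rows.append({"roi": i, "peak_row": roi.peak[0], "peak_col": roi.peak[1],
                     "n_pixels": roi.size, "polarity": roi.polarity or ""})
    tifffile.imwrite(label_tiff_path, labels)
    pd.DataFrame(rows).to_csv(peaks_csv_path, index=False)


def load_image(path) -> np.ndarray:
    """RGB image as float array in [0, 1]."""
    img = np.asarray(Image.open(path).convert("RGB"), dtype=float)
    return img / 255.0
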