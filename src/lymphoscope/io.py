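"""Readers, writers, dual-channel compositing, and configuration.

Stacks travel as multi-page TIFF (one page per frame) with calibration
in a sidecar JSON (``<stem>.json``) rather than proprietary TIFF tags.
ROIs and polylines are small JSON documents; metrics, events and
velocities are RFC-4180 CSV with "." decimals and "NA" for undefined
ratios.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .dynamics import CircleROI, PolygonROI
from .profiles import Polyline, VesselMetrics
from .stack import ImageStack
from .synthetic import GroundTruth

__all__ = [
    "read_stack",
    "write_stack",
    "read_polyline",
    "write_polyline",
    "read_roi",
    "overlay_channels",
    "write_composite_png",
    "write_metrics",
    "read_metrics",
    "write_events",
    "write_velocity",
    "load_config",
]

log = logging.getLogger("lymphoscope")

_DEFAULT_PIXEL_PITCH = 0.1  # mm/px
_DEFAULT_FRAME_INTERVAL = 0.1  # s


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path, ground_truth: GroundTruth | None = None) -> Path:
    """Write a stack as multi-page TIFF plus a calibration sidecar JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = np.moveaxis(stack.data, 2, 0)  # (frame, row, col)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "pixel_pitch_mm": stack.pixel_pitch,
        "frame_interval_s": stack.frame_interval,
        "band": stack.band,
        "meta": {k: v for k, v in stack.meta.items() if _jsonable(v)},
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = ground_truth.to_dict()
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_stack(path) -> ImageStack:
    """Read a multi-page TIFF stack, with its sidecar JSON when present.

    Missing calibration falls back to the package defaults
    (0.1 mm/px, 0.1 s/frame) with a logged warning.  The ground truth,
    when recorded by the simulator, is attached under
    ``stack.meta["ground_truth"]``.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None, :, :]
    if pages.ndim != 3:
        raise OSError(f"{path}: expected a 2-D/3-D TIFF, got {pages.ndim}-D")
    data = np.moveaxis(pages, 0, 2)
    sidecar = _sidecar_path(path)
    pitch, interval, band, meta = _DEFAULT_PIXEL_PITCH, _DEFAULT_FRAME_INTERVAL, "unknown", {}
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
        pitch = d.get("pixel_pitch_mm", pitch)
        interval = d.get("frame_interval_s", interval)
        band = d.get("band", band)
        meta = d.get("meta", {})
        if "ground_truth" in d:
            meta["ground_truth"] = GroundTruth.from_dict(d["ground_truth"])
    else:
        log.warning("%s: no calibration sidecar; using defaults %.3g mm/px, %.3g s/frame",
                    path, pitch, interval)
    return ImageStack(data=data, pixel_pitch=pitch, frame_interval=interval, band=band, meta=meta)


def write_polyline(line: Polyline, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({
        "vertices_px": line.vertices.tolist(),
        "calibration_mm_per_px": line.calibration,
    }, indent=1))
    return path


def read_polyline(path) -> Polyline:
    d = json.loads(Path(path).read_text())
    return Polyline(vertices=np.asarray(d["vertices_px"]), calibration=d["calibration_mm_per_px"])


def read_roi(path):
    """Read one ROI or a list of ROIs from JSON.

    Each entry: ``{"type": "circle", "cx":…, "cy":…, "radius":…, "id":…}``
    or ``{"type": "polygon", "vertices_px": [[x, y]…], "id":…}``.
    """
    d = json.loads(Path(path).read_text())
    entries = d if isinstance(d, list) else [d]
    rois = []
    for e in entries:
        kind = e.get("type", "circle")
        if kind == "circle":
            rois.append(CircleROI(cx=e["cx"], cy=e["cy"], radius=e["radius"], roi_id=str(e.get("id", ""))))
        elif kind == "polygon":
            rois.append(PolygonROI(vertices=np.asarray(e["vertices_px"]), roi_id=str(e.get("id", ""))))
        else:
            raise ValueError(f"unknown ROI type {kind!r}")
    return rois if isinstance(d, list) else rois[0]


def overlay_channels(nir: np.ndarray, swir: np.ndarray) -> dict:
    """Composite co-registered NIR and SWIR frames into one RGB image.

    After independent max-normalization the NIR channel drives red and
    blue (rendering NIR-only signal purple) and the SWIR channel drives
    green; pixels bright in both bands render white.  Inputs must be
    pre-aligned and equal-shaped.
    """
    nir = np.asarray(nir, dtype=float)
    swir = np.asarray(swir, dtype=float)
    if nir.shape != swir.shape or nir.ndim != 2:
        raise ValueError("nir and swir frames must be 2-D and equal-shaped")
    bounds = {}
    chans = {}
    for name, img in (("NIR", nir), ("SWIR", swir)):
        peak = img.max()
        bounds[name] = (float(img.min()), float(peak))
        chans[name] = img / peak if peak > 0 else np.zeros_like(img)
    rgb = np.stack([chans["NIR"], chans["SWIR"], chans["NIR"]], axis=-1)
    return {
        "rgb": np.clip(rgb, 0.0, 1.0),
        "provenance": {"red": "NIR", "green": "SWIR", "blue": "NIR"},
        "normalization_bounds": bounds,
    }


def write_composite_png(composite: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (composite["rgb"] * 255).astype(np.uint8))
    return path


_METRIC_COLUMNS = [
    "label", "band", "distinguishability", "n_vessels", "line_length_cm",
    "resolution_mean_mm", "resolution_sd_mm",
]


def write_metrics(metrics: list, path, summary: bool = True) -> Path:
    """Write VesselMetrics rows to CSV (stable column order, NA for
    undefined values); with ``summary`` a mean/sd row is appended when
    more than one row is present."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "label": m.label,
            "band": m.band,
            "distinguishability": m.distinguishability,
            "n_vessels": m.n_vessels,
            "line_length_cm": m.line_length_cm,
            "resolution_mean_mm": m.resolution_mean,
            "resolution_sd_mm": m.resolution_sd,
        }
        for m in metrics
    ]
    df = pd.DataFrame(rows, columns=_METRIC_COLUMNS)
    if summary and len(rows) > 1:
        d = df["distinguishability"].astype(float)
        r = df["resolution_mean_mm"].astype(float)
        df = pd.concat(
            [df, pd.DataFrame([{
                "label": "average",
                "band": "",
                "distinguishability": d.mean(),
                "n_vessels": int(df["n_vessels"].sum()),
                "line_length_cm": float(df["line_length_cm"].astype(float).sum()),
                "resolution_mean_mm": r.mean(),
                "resolution_sd_mm": r.std(ddof=1) if len(r) > 1 else 0.0,
            }])],
            ignore_index=True,
        )
    df.to_csv(path, index=False, na_rep="NA")
    return path


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA"])


def metrics_from_row(row: pd.Series) -> VesselMetrics:
    """Rebuild a VesselMetrics from one CSV row (round-trip helper)."""
    return VesselMetrics(
        distinguishability=float(row["distinguishability"]),
        n_vessels=int(row["n_vessels"]),
        line_length_cm=float(row["line_length_cm"]),
        resolution_mean=float(row["resolution_mean_mm"]) if pd.notna(row["resolution_mean_mm"]) else math.nan,
        resolution_sd=float(row["resolution_sd_mm"]) if pd.notna(row["resolution_sd_mm"]) else math.nan,
        label=str(row["label"]),
        band=str(row["band"]),
    )


def write_events(events: list, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "roi_id": e.roi_id,
                "frame": e.frame_index,
                "time_s": e.time,
                "value": e.peak_value,
                "prominence": e.prominence,
                "near_boundary": e.near_boundary,
            }
            for e in events
        ],
        columns=["roi_id", "frame", "time_s", "value", "prominence", "near_boundary"],
    ).to_csv(path, index=False, na_rep="NA")
    return path


def read_events(path) -> list:
    from .dynamics import BolusEvent

    df = pd.read_csv(path, na_values=["NA"])
    return [
        BolusEvent(
            time=float(r["time_s"]),
            frame_index=int(r["frame"]),
            roi_id=str(r["roi_id"]),
            peak_value=float(r["value"]),
            prominence=float(r["prominence"]),
            near_boundary=bool(r["near_boundary"]),
        )
        for _, r in df.iterrows()
    ]


def write_velocity(estimate, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "t1_s": p[0].time,
            "t2_s": p[1].time,
            "transit_s": p[1].time - p[0].time,
            "velocity_mm_s": p[2],
        }
        for p in estimate.matched_pairs
    ]
    rows.append(
        {
            "t1_s": math.nan,
            "t2_s": math.nan,
            "transit_s": estimate.transit_time,
            "velocity_mm_s": estimate.velocity,
        }
    )
    pd.DataFrame(rows, columns=["t1_s", "t2_s", "transit_s", "velocity_mm_s"]).to_csv(
        path, index=False, na_rep="NA"
    )
    return path


def load_config(path) -> dict:
    """Load a YAML/JSON configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)
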