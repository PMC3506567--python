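"""File formats: TIFF images with sidecar metadata, delimited tables, YAML configs.

Images are single-channel TIFF — unsigned integers for counts, float32 for
rates — with a small YAML sidecar (``<name>.meta.yaml``) carrying view,
pixel size, dwell time and acquisition time.  Tables (depth series, ROI
pixel lists, time-activity curves, dose results) are tab-separated text
with headers.  Camera calibrations and run configuration are YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import CalibrationResult
from .kinetics import TimeActivitySeries
from .phantom import CountImage, RateImage
from .quantify import RoiMask

__all__ = [
    "write_image",
    "read_image",
    "write_depth_series",
    "read_depth_series",
    "write_roi",
    "read_roi",
    "write_calibration",
    "read_calibration",
    "write_timeactivity",
    "read_timeactivity",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_image(image: CountImage | RateImage, path: str | Path) -> None:
    path = Path(path)
    if isinstance(image, CountImage):
        data = image.pixels.astype(np.uint32)
    else:
        data = image.pixels.astype(np.float32)
    tifffile.imwrite(path, data)
    meta = {
        "kind": "counts" if isinstance(image, CountImage) else "rates",
        "view": image.view,
        "pixel_size_cm": float(image.pixel_size),
        "dwell_time_s": float(image.dwell_time),
        "acquisition_time_h": float(image.acquisition_time_h),
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_image(path: str | Path) -> CountImage | RateImage:
    path = Path(path)
    data = tifffile.imread(path)
    meta = yaml.safe_load(_sidecar(path).read_text())
    cls = CountImage if meta["kind"] == "counts" else RateImage
    return cls(
        pixels=np.asarray(data),
        view=meta["view"],
        pixel_size=meta["pixel_size_cm"],
        dwell_time=meta["dwell_time_s"],
        acquisition_time_h=meta.get("acquisition_time_h", 0.0),
    )


def write_depth_series(series: pd.DataFrame, path: str | Path) -> None:
    series.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_depth_series(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"depth_cm", "counts", "duration_s"}
    if not required <= set(df.columns):
        raise ValueError(f"depth series needs columns {sorted(required)}")
    return df


def write_roi(roi: RoiMask, path: str | Path) -> None:
    df = pd.DataFrame(sorted(roi.pixels), columns=["row", "col"])
    header = f"# label={roi.label} kind={roi.kind}\n"
    Path(path).write_text(header + df.to_csv(sep="\t", index=False))


def read_roi(path: str | Path) -> RoiMask:
    text = Path(path).read_text().splitlines()
    label, kind = "", "kidney"
    if text and text[0].startswith("#"):
        for token in text[0][1:].split():
            key, _, val = token.partition("=")
            if key == "label":
                label = val
            elif key == "kind":
                kind = val
        text = text[1:]
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(text)), sep="\t")
    return RoiMask.from_pixels(df[["row", "col"]].itertuples(index=False), label=label, kind=kind)


def write_calibration(calib: CalibrationResult, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "sensitivity_k_cps_per_mbq": float(calib.sensitivity_k),
                "mu_per_cm": float(calib.mu),
                "fit_r_squared": float(calib.fit_r_squared),
                "n_points": int(calib.n_points),
            },
            sort_keys=False,
        )
    )


def read_calibration(path: str | Path) -> CalibrationResult:
    d = yaml.safe_load(Path(path).read_text())
    return CalibrationResult(
        sensitivity_k=d["sensitivity_k_cps_per_mbq"],
        mu=d["mu_per_cm"],
        fit_r_squared=d.get("fit_r_squared", float("nan")),
        n_points=d.get("n_points", 0),
    )


def write_timeactivity(series: TimeActivitySeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_h": series.times_h, "activity_mbq": series.activities_mbq}
    )
    df["decay_corrected"] = series.decay_corrected
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_timeactivity(path: str | Path) -> TimeActivitySeries:
    df = pd.read_csv(path, sep="\t")
    return TimeActivitySeries(
        times_h=tuple(df["time_h"].astype(float)),
        activities_mbq=tuple(df["activity_mbq"].astype(float)),
        decay_corrected=bool(df["decay_corrected"].iloc[0]) if "decay_corrected" in df else False,
    )
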