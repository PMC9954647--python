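"""Reading and writing the pipeline's on-disk formats.

Images: 16-bit grayscale TIFF (PNG fallback), masks as 8-bit TIFF.
Traces: headerless float32 binary with a JSON sidecar (fs_hz, duration_s,
electrode/well ids) or two-column CSV (time_s, voltage_uv).
qPCR plates: tidy CSV (well, gene, sample_id, stage, task, amount_ng, ct);
non-detect Ct is an empty field.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .mea import VoltageTrace
from .morphometry import BrightfieldImage

# image filenames carry the metadata: <batch>_<well>_d<day>.tif
IMAGE_NAME_RE = re.compile(r"(?P<batch>.+)_(?P<well>[A-H]\d{1,2})_d(?P<day>\d+)\.(tiff?|png)$")


def image_path(directory: Path, batch_id: str, well_id: str, day: int) -> Path:
    return Path(directory) / f"{batch_id}_{well_id}_d{day}.tif"


def write_brightfield(path: Path, image: BrightfieldImage) -> None:
    path = Path(path)
    px = image.pixels
    if px.dtype != np.uint16:
        px = np.clip(px, 0, 65535).astype(np.uint16)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, px)
    else:
        tifffile.imwrite(path, px)


def write_mask(path: Path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_brightfield(path: Path, scale_um_per_px: float = 1.0) -> BrightfieldImage:
    """Load an image and parse batch/well/day metadata from its filename."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        px = iio.imread(path)
    else:
        px = tifffile.imread(path)
    m = IMAGE_NAME_RE.match(path.name)
    batch, well, day = (m["batch"], m["well"], int(m["day"])) if m else ("", "", 0)
    return BrightfieldImage(
        pixels=px, scale_um_per_px=scale_um_per_px,
        well_id=well, timepoint_days=day, batch_id=batch,
    )


def write_trace(path: Path, trace: VoltageTrace) -> None:
    """Write float32 binary samples plus a JSON metadata sidecar."""
    path = Path(path)
    trace.samples.astype(np.float32).tofile(path)
    sidecar = {
        "fs_hz": trace.fs_hz,
        "duration_s": trace.duration_s,
        "electrode_id": trace.electrode_id,
        "well_id": trace.well_id,
        "timepoint_days": trace.timepoint_days,
        "included": trace.included,
        "dtype": "float32",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_trace(path: Path) -> VoltageTrace:
    """Read a binary trace via its JSON sidecar, or a (time_s, voltage_uv) CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        dt = np.diff(df["time_s"].to_numpy())
        return VoltageTrace(
            samples=df["voltage_uv"].to_numpy(float), fs_hz=1.0 / float(np.median(dt))
        )
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    samples = np.fromfile(path, dtype=meta.get("dtype", "float32"))
    return VoltageTrace(
        samples=samples.astype(float),
        fs_hz=float(meta["fs_hz"]),
        electrode_id=meta.get("electrode_id", ""),
        well_id=meta.get("well_id", ""),
        timepoint_days=int(meta.get("timepoint_days", 0)),
        included=bool(meta.get("included", True)),
    )


def write_trace_csv(path: Path, trace: VoltageTrace) -> None:
    t = np.arange(trace.samples.size) / trace.fs_hz
    pd.DataFrame({"time_s": t, "voltage_uv": trace.samples}).to_csv(path, index=False)


def write_plate(path: Path, plate: pd.DataFrame) -> None:
    plate.to_csv(Path(path), index=False, float_format="%.6g")


def read_plate(path: Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")   # empty field -> NaN non-detect
    df["stage"] = df["stage"].fillna("")
    return df
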