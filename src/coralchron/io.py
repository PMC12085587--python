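"""File formats: CSV tables with ISO-8601 dates, multi-page 16-bit TIFF
volumes with plain-text sidecar metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def write_env_csv(env: pd.DataFrame, path) -> None:
    out = env.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_env_csv(path) -> pd.DataFrame:
    env = pd.read_csv(path)
    env["date"] = pd.to_datetime(env["date"])
    return env


def write_growth_csv(growth: pd.DataFrame, path) -> None:
    growth.to_csv(path, index=False)


def read_growth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_core_tiff(image: np.ndarray, path, voxel_pitch_um: float,
                    metadata: dict | None = None) -> None:
    """Multi-page TIFF (one page per cross-section slice) plus a ``.meta.json``
    sidecar holding the voxel pitch and provenance."""
    path = Path(path)
    tifffile.imwrite(path, image.astype(np.uint16))
    meta = {"voxel_pitch_um": voxel_pitch_um, "shape": list(image.shape)}
    meta.update(metadata or {})
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2))


def read_core_tiff(path) -> tuple:
    """Returns ``(volume, metadata)``; metadata comes from the sidecar."""
    path = Path(path)
    image = tifffile.imread(path)
    if image.ndim == 2:
        image = image[None, ...]
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return image, meta


def write_standard_csv(insert_density, insert_grey, path) -> None:
    pd.DataFrame({"insert_density_g_cm3": insert_density,
                  "insert_grey": insert_grey}).to_csv(path, index=False)


def read_standard_csv(path):
    from .densitometry import CalibrationStandard
    df = pd.read_csv(path)
    return CalibrationStandard(tuple(df["insert_density_g_cm3"]),
                               tuple(df["insert_grey"]))
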