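"""File IO for the pipeline's external formats.

Outlines and site tables travel as CSV, ratio stacks as one multi-page TIFF
per channel plus a JSON sidecar carrying frame times (hours) and pixel size
(µm), model configuration as YAML mirroring ``GrainModelConfig`` field names,
and power-law fits as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .ratiometric import RatioStack
from .scaling import PowerLawFit
from .transport import GrainModelConfig
from .upscaling import SiteRecord

__all__ = [
    "save_outlines_csv", "load_outlines_csv",
    "save_ratio_stack", "load_ratio_stack",
    "save_site_table_csv", "load_site_table_csv",
    "load_calibration_table_csv",
    "save_config_yaml", "load_config_yaml",
    "save_powerlaw_json", "load_powerlaw_json",
]


def save_outlines_csv(path: str | Path, outlines: list[np.ndarray]) -> None:
    """Write grain outlines as CSV with columns x_um, y_um, grain_id."""
    frames = [
        pd.DataFrame({"x_um": o[:, 0], "y_um": o[:, 1], "grain_id": i})
        for i, o in enumerate(outlines)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_outlines_csv(path: str | Path) -> list[np.ndarray]:
    df = pd.read_csv(path)
    return [
        g[["x_um", "y_um"]].to_numpy(dtype=float)
        for _, g in df.groupby("grain_id", sort=True)
    ]


def save_ratio_stack(stack: RatioStack, directory: str | Path,
                     prefix: str = "stack") -> None:
    """Write a stack as <prefix>_red.tif, <prefix>_green.tif + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / f"{prefix}_red.tif",
                     stack.red.astype(np.float32))
    tifffile.imwrite(directory / f"{prefix}_green.tif",
                     stack.green.astype(np.float32))
    sidecar = {"times_h": stack.times_h.tolist(),
               "pixel_size_um": stack.pixel_size_um}
    (directory / f"{prefix}.json").write_text(json.dumps(sidecar, indent=2))


def load_ratio_stack(directory: str | Path, prefix: str = "stack") -> RatioStack:
    directory = Path(directory)
    meta = json.loads((directory / f"{prefix}.json").read_text())
    return RatioStack(
        times_h=np.asarray(meta["times_h"], dtype=float),
        red=tifffile.imread(directory / f"{prefix}_red.tif").astype(float),
        green=tifffile.imread(directory / f"{prefix}_green.tif").astype(float),
        pixel_size_um=float(meta["pixel_size_um"]),
    )


_SITE_COLUMNS = [f.name for f in dataclasses.fields(SiteRecord)]


def save_site_table_csv(path: str | Path, sites: list[SiteRecord]) -> None:
    """Site table CSV; columns are the SiteRecord field names (units in names)."""
    pd.DataFrame([dataclasses.asdict(s) for s in sites])[_SITE_COLUMNS].to_csv(
        path, index=False
    )


def load_site_table_csv(path: str | Path) -> list[SiteRecord]:
    df = pd.read_csv(path)
    return [SiteRecord(**row) for row in df[_SITE_COLUMNS].to_dict("records")]


def load_calibration_table_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a calibration table with columns o2_umol_L, ratio."""
    df = pd.read_csv(path)
    return df["o2_umol_L"].to_numpy(float), df["ratio"].to_numpy(float)


def save_config_yaml(path: str | Path, config: GrainModelConfig) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)))


def load_config_yaml(path: str | Path) -> GrainModelConfig:
    return GrainModelConfig(**yaml.safe_load(Path(path).read_text()))


def save_powerlaw_json(path: str | Path, fit: PowerLawFit) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(fit), indent=2))


def load_powerlaw_json(path: str | Path) -> PowerLawFit:
    return PowerLawFit(**json.loads(Path(path).read_text()))
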