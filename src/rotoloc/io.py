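"""Frame and localization-table I/O, and the batch pipeline driver.

Frames travel as single- or multi-page grayscale TIFF; localizations as a
flat CSV (nm units) with a versioned header comment.  Each pipeline run
writes the resolved configuration and a JSON run report next to its
outputs so results can be reproduced from the output directory alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .admm import ADMMParams
from .bench import localize_frame, subtract_background
from .config import ConfigurationError, OpticalConfig
from .forward import Frame
from .optics import PSFStack
from .refine import Localization

logger = logging.getLogger(__name__)

TABLE_SCHEMA_VERSION = 1
TABLE_COLUMNS = ["frame", "x_nm", "y_nm", "z_nm", "photons", "residual", "accepted"]
# ThunderSTORM-style header aliases accepted on import
_COLUMN_ALIASES = {
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "z [nm]": "z_nm",
    "intensity [photon]": "photons",
    "intensity": "photons",
    "uncertainty": "residual",
}


class DataFormatError(ValueError):
    """Raised for unreadable or malformed data files."""


def read_frame_stack(
    path: str | Path,
    pixel_size_nm: float,
    offset: float = 0.0,
) -> list[Frame]:
    """Read a single- or multi-page TIFF into a list of frames.

    ``offset`` (camera dark level, counts) is subtracted from every pixel.
    RGB/multi-sample pages are rejected.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            frames = []
            for i, page in enumerate(tf.pages):
                data = page.asarray()
                if data.ndim != 2:
                    raise DataFormatError(
                        f"{path}: page {i} is not single-channel 2D "
                        f"(shape {data.shape})"
                    )
                frames.append(
                    Frame(
                        pixels=np.asarray(data, dtype=np.float64) - offset,
                        pixel_size_nm=pixel_size_nm,
                        provenance={"source": str(path), "page": i},
                    )
                )
    except DataFormatError:
        raise
    except Exception as exc:
        raise DataFormatError(f"cannot read TIFF {path}: {exc}") from exc
    return frames


def write_frame_stack(frames: list[Frame], path: str | Path, dtype=np.float32) -> None:
    """Write frames as a multi-page TIFF (float32, or uint16 after clipping)."""
    arr = np.stack([f.pixels for f in frames]).astype(dtype)
    if np.issubdtype(dtype, np.integer):
        arr = np.clip(arr, 0, np.iinfo(dtype).max)
    tifffile.imwrite(path, arr, photometric="minisblack")


def write_localizations(locs_per_frame: dict[int, list[Localization]], path) -> None:
    """Write the localization table with its schema-version header."""
    rows = []
    for frame_idx, locs in sorted(locs_per_frame.items()):
        for l in locs:
            rows.append(
                {
                    "frame": frame_idx,
                    "x_nm": l.x_nm,
                    "y_nm": l.y_nm,
                    "z_nm": l.z_nm,
                    "photons": l.photons,
                    "residual": l.residual_norm,
                    "accepted": "" if l.accepted is None else int(l.accepted),
                }
            )
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# rotoloc localization table v{TABLE_SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_localizations(path) -> pd.DataFrame:
    """Read a localization CSV; ThunderSTORM-style headers are renamed."""
    df = pd.read_csv(path, comment="#")
    df = df.rename(columns=_COLUMN_ALIASES)
    missing = {"x_nm", "y_nm"} - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    optical: OpticalConfig = field(default_factory=OpticalConfig)
    admm: dict = field(default_factory=dict)
    refine: dict = field(default_factory=dict)
    mask: dict = field(default_factory=lambda: {"name": "double_helix"})
    seed: int = 0
    model_path: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["optical"] = self.optical.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "optical" in d:
            d["optical"] = OpticalConfig.from_dict(d["optical"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a YAML mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def run_pipeline(
    config: RunConfig,
    frames: list[Frame],
    stack: PSFStack,
    out_dir: str | Path,
    model=None,
) -> tuple[pd.DataFrame, dict]:
    """Deconvolve, refine and (optionally) threshold a batch of frames.

    Each frame is an independent recovery problem.  Writes the localization
    table, the resolved config and a JSON run report into ``out_dir``;
    per-frame failures are logged and skipped.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = ADMMParams(**{"log_every": 0, **config.admm})
    locs_per_frame: dict[int, list[Localization]] = {}
    counts = {"frames": len(frames), "failed": 0, "localizations": 0, "accepted": 0}
    warnings_log: list[str] = []
    for i, frame in enumerate(frames):
        try:
            work = subtract_background(frame)
            locs = localize_frame(work, stack, params, **config.refine)
            if model is not None:
                from .mlfilter import apply_threshold

                locs = apply_threshold(locs, model)
            locs_per_frame[i] = locs
            counts["localizations"] += len(locs)
            counts["accepted"] += sum(1 for l in locs if l.accepted)
        except (ValueError, ConfigurationError) as exc:
            counts["failed"] += 1
            warnings_log.append(f"frame {i}: {exc}")
            logger.warning("frame %d failed: %s", i, exc)
    table_path = out_dir / "localizations.csv"
    write_localizations(locs_per_frame, table_path)
    config.to_yaml(out_dir / "run_config.yaml")
    report = {
        "counts": counts,
        "warnings": warnings_log,
        "seed": config.seed,
        "ml_enabled": model is not None,
        "table": str(table_path),
        "schema_version": TABLE_SCHEMA_VERSION,
    }
    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    df = read_localizations(table_path)
    return df, report
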