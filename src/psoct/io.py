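"""Persistence: TIFF volumes with JSON sidecars, manifests, run configs.

A B-scan pair is stored as a two-page 32-bit float TIFF (page 0 = Av,
page 1 = Ah) next to a JSON sidecar holding the acquisition parameters and,
for synthetic data, the ground-truth BRC.  Manifests and per-sample results
are plain CSV; run configurations are YAML.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ShapeMismatchError
from .optics import AcquisitionParams, BScanPair
from .pipeline import PipelineSettings
from .reconstruction import IntensityImage, PhaseImage
from .tissue import CONFIG_LABELS, GRADE_LABELS

MANIFEST_COLUMNS = [
    "sample_id",
    "grade_label",
    "config_label",
    "volume_path",
    "center_ascan",
    "seed",
]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_bscan(path, pair: BScanPair, truth_brc: Optional[float] = None) -> Path:
    """Write one B-scan pair as a two-page float32 TIFF + JSON sidecar."""
    path = Path(path)
    stack = np.stack([pair.Av, pair.Ah]).astype(np.float32)
    tifffile.imwrite(path, stack)
    meta = {"params": dataclasses.asdict(pair.params)}
    if truth_brc is None and pair.truth is not None:
        truth_brc = pair.truth.truth_brc
    if truth_brc is not None:
        meta["truth_brc"] = float(truth_brc)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_bscan(path) -> BScanPair:
    """Read a B-scan pair written by :func:`write_bscan`; validates shape agreement."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ShapeMismatchError(
            f"{path}: expected a two-page (Av, Ah) TIFF, got shape {stack.shape}"
        )
    meta = json.loads(_sidecar_path(path).read_text())
    params = AcquisitionParams(**meta["params"])
    return BScanPair(
        Av=stack[0].astype(np.float64), Ah=stack[1].astype(np.float64), params=params
    )


def write_volume(directory, volume: Sequence[BScanPair], stem: str = "bscan") -> list[Path]:
    """Write a sample's B-scan volume as numbered TIFF pairs in a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [
        write_bscan(directory / f"{stem}_{i:02d}.tif", pair)
        for i, pair in enumerate(volume)
    ]


def read_volume(paths: Sequence) -> list[BScanPair]:
    """Read a volume from explicit TIFF paths, validating co-registration."""
    volume = [read_bscan(p) for p in paths]
    shapes = {pair.shape for pair in volume}
    if len(shapes) > 1:
        raise ShapeMismatchError(f"B-scans in volume disagree in shape: {shapes}")
    return volume


def write_image_tiff(path, image: IntensityImage | PhaseImage) -> Path:
    """Write a reconstructed intensity or phase image as single-page float TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image.values, dtype=np.float32))
    return path


def write_manifest(path, rows: pd.DataFrame) -> Path:
    """Write a study manifest (one row per sample volume) as CSV."""
    missing = [c for c in MANIFEST_COLUMNS if c not in rows.columns]
    if missing:
        raise ShapeMismatchError(f"manifest missing columns: {missing}")
    if rows["sample_id"].duplicated().any():
        raise ShapeMismatchError("manifest sample ids must be unique")
    bad_grades = set(rows["grade_label"]) - set(GRADE_LABELS)
    bad_configs = set(rows["config_label"]) - set(CONFIG_LABELS)
    if bad_grades or bad_configs:
        raise ShapeMismatchError(
            f"unknown labels in manifest: grades {bad_grades}, configs {bad_configs}"
        )
    path = Path(path)
    rows[MANIFEST_COLUMNS].to_csv(path, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ShapeMismatchError(f"manifest missing columns: {missing}")
    return df


@dataclass
class RunConfig:
    """Everything needed to reproduce a full study replication."""

    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    pipeline: PipelineSettings = field(default_factory=PipelineSettings)
    preset_file: Optional[str] = None  # None: packaged study defaults
    output_dir: str = "psoct_study"
    seed: int = 0
    log_level: str = "INFO"
    write_volumes: bool = False  # persist every simulated TIFF (large)
    write_boxplot: bool = False

    def to_yaml(self, path) -> Path:
        payload = {
            "acquisition": dataclasses.asdict(self.acquisition),
            "pipeline": dataclasses.asdict(self.pipeline),
            "preset_file": self.preset_file,
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "log_level": self.log_level,
            "write_volumes": self.write_volumes,
            "write_boxplot": self.write_boxplot,
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            acquisition=AcquisitionParams(**raw.get("acquisition", {})),
            pipeline=PipelineSettings(**raw.get("pipeline", {})),
            preset_file=raw.get("preset_file"),
            output_dir=raw.get("output_dir", "psoct_study"),
            seed=int(raw.get("seed", 0)),
            log_level=raw.get("log_level", "INFO"),
            write_volumes=bool(raw.get("write_volumes", False)),
            write_boxplot=bool(raw.get("write_boxplot", False)),
        )
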