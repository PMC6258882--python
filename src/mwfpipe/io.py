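"""File I/O and configuration for the pipeline.

NIfTI volumes are read and written with nibabel, preserving the input
affine on every derived map.  Echo timing always comes from configuration
(TE = i * echo_spacing), never from NIfTI headers, which are unreliable
for echo spacing.  Tabular outputs are UTF-8 comma-separated files with a
header row; NaN cells are written empty.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_decay_volume",
    "read_mask",
    "write_map",
    "write_table",
    "StudyManifest",
    "PipelineConfig",
]


def read_decay_volume(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4-D multi-echo NIfTI volume.

    Returns ``(data, affine)`` with the echo axis last.  Raises with the
    path in the message for unreadable or non-4-D files.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D decay volume, got {data.ndim}-D")
    return data, img.affine


def read_mask(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3-D NIfTI mask or probability map as ``(data, affine)``."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=float)
    while data.ndim > 3 and data.shape[-1] == 1:  # drop degenerate volume axes
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got {data.ndim}-D")
    return data, img.affine


def write_map(
    data: np.ndarray, affine: np.ndarray, path: str | os.PathLike
) -> None:
    """Write a 3-D or 4-D map as NIfTI, atomically (write + rename)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    fd, tmp = tempfile.mkstemp(
        suffix="".join(path.suffixes), dir=path.parent or "."
    )
    os.close(fd)
    try:
        nib.save(img, tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """CSV with header row, '.' decimals, NaN as empty cells; atomic."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(suffix=".csv", dir=path.parent or ".")
    os.close(fd)
    try:
        df.to_csv(tmp, index=False, na_rep="")
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


@dataclass
class ManifestRow:
    participant: str
    site: str
    decay_path: Path
    mask_paths: tuple[Path, ...]
    truth_path: Path | None = None


@dataclass
class StudyManifest:
    """Table of (participant, site) -> input files for a two-site study."""

    rows: list[ManifestRow]

    def __post_init__(self) -> None:
        seen = set()
        for row in self.rows:
            key = (row.participant, row.site)
            if key in seen:
                raise ValueError(f"duplicate (participant, site) pair {key}")
            seen.add(key)

    @classmethod
    def from_csv(cls, path: str | os.PathLike, check_files: bool = True):
        df = pd.read_csv(path, dtype=str)
        required = {"participant", "site", "decay_path", "mask_paths"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
        base = Path(path).parent
        rows = []
        for _, rec in df.iterrows():
            masks = tuple(
                base / m.strip() for m in str(rec["mask_paths"]).split(";") if m.strip()
            )
            truth = rec.get("truth_path")
            truth_p = base / truth if isinstance(truth, str) and truth else None
            rows.append(
                ManifestRow(
                    participant=str(rec["participant"]),
                    site=str(rec["site"]),
                    decay_path=base / str(rec["decay_path"]),
                    mask_paths=masks,
                    truth_path=truth_p,
                )
            )
        manifest = cls(rows)
        if check_files:
            for row in manifest.rows:
                for p in (row.decay_path, *row.mask_paths):
                    if not Path(p).exists():
                        raise FileNotFoundError(f"manifest references missing file {p}")
        return manifest

    def to_csv(self, path: str | os.PathLike) -> None:
        base = Path(path).parent
        recs = []
        for row in self.rows:
            recs.append(
                {
                    "participant": row.participant,
                    "site": row.site,
                    "decay_path": os.path.relpath(row.decay_path, base),
                    "mask_paths": ";".join(
                        os.path.relpath(m, base) for m in row.mask_paths
                    ),
                    "truth_path": (
                        os.path.relpath(row.truth_path, base) if row.truth_path else ""
                    ),
                }
            )
        write_table(pd.DataFrame(recs), path)


@dataclass
class PipelineConfig:
    """All pipeline parameters, with defaults matching the reference study.

    Unknown keys in a YAML config are rejected on load.
    """

    # echo train
    echo_spacing: float = 0.010
    n_echoes: int = 32
    repetition_time: float = 1.0
    # spectrum fit
    t2_min: float = 0.015
    t2_max: float = 2.0
    n_t2: int = 40
    n_angles: int = 8
    angle_min: float = 50.0
    angle_max: float = 180.0
    myelin_window: tuple[float, float] = (0.015, 0.040)
    reg_ratio_lo: float = 1.02
    reg_ratio_hi: float = 1.025
    t1: float = 1.0
    # roi stage
    wm_threshold: float = 0.9
    erode_iterations: int = 1
    # stats stage
    tost_bound: float = 0.005
    alpha: float = 0.05
    # simulation
    sim_shape: tuple[int, int, int] = (10, 10, 2)
    sim_n_participants: int = 10
    sim_snr_site1: float = 200.0
    sim_snr_site2: float = 150.0
    sim_b1_mean: float = 165.0
    sim_b1_amplitude: float = 10.0
    sim_between_participant_sd: float = 0.01
    sim_base_mwf: float = 0.10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        for key in ("myelin_window", "sim_shape"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        data = {}
        for f in fields(self):
            val = getattr(self, f.name)
            data[f.name] = list(val) if isinstance(val, tuple) else val
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    # adapters to the domain configs -------------------------------------
    def train(self):
        from .epg import EchoTrainSpec

        return EchoTrainSpec(self.echo_spacing, self.n_echoes, self.repetition_time)

    def grid(self):
        from .spectrum import make_t2_grid

        return make_t2_grid(self.t2_min, self.t2_max, self.n_t2)

    def fit_config(self):
        import numpy as np

        from .spectrum import FitConfig

        return FitConfig(
            candidate_angles=np.linspace(self.angle_min, self.angle_max, self.n_angles),
            reg_ratio_lo=self.reg_ratio_lo,
            reg_ratio_hi=self.reg_ratio_hi,
            myelin_window=tuple(self.myelin_window),
            t1=self.t1,
        )
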