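"""Readers and writers for the pipeline's on-disk formats.

ROI series travel as TSV (scan index + one column per region) with a
JSON sidecar holding the TR; volumes and masks as NIfTI-1; session
logs as JSON-lines (one FeedbackEvent per line); configuration as YAML
with strict schema validation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .data import CANONICAL_REGIONS, ROITimeSeries
from .pipeline import CleanerConfig, FeedbackEvent, WindowSpec

__all__ = [
    "SessionConfig",
    "read_roi_timeseries",
    "write_roi_timeseries",
    "read_roi_from_volumes",
    "write_volumes",
    "write_session_log",
    "read_session_log",
    "load_config",
    "save_config",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_roi_timeseries(series: ROITimeSeries, path: str | Path) -> Path:
    """TSV with scan index + per-region columns; TR in a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(series.values, columns=list(series.region_labels))
    df.insert(0, "scan", np.arange(series.n_scans))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    _sidecar_path(path).write_text(json.dumps(
        {"TR": series.TR, "region_labels": list(series.region_labels)},
        indent=2))
    return path


def read_roi_timeseries(path: str | Path, TR: float | None = None
                        ) -> ROITimeSeries:
    """Read a TSV ROI series (+ sidecar TR); canonicalize region order.

    If all four canonical region labels are present, columns are
    reordered to (VC_L, VC_R, SPL_L, SPL_R).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "scan" in df.columns:
        df = df.drop(columns=["scan"])
    sidecar = _sidecar_path(path)
    if TR is None:
        if not sidecar.exists():
            raise ValueError(
                f"TR not given and sidecar {sidecar.name} is missing"
            )
        TR = float(json.loads(sidecar.read_text())["TR"])
    labels = list(df.columns)
    if set(CANONICAL_REGIONS) <= set(labels):
        df = df[list(CANONICAL_REGIONS)]
        labels = list(CANONICAL_REGIONS)
    elif set(labels) & set(CANONICAL_REGIONS) and \
            not set(CANONICAL_REGIONS) <= set(labels):
        missing = sorted(set(CANONICAL_REGIONS) - set(labels))
        raise ValueError(f"region column(s) missing: {', '.join(missing)}")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-numeric or missing cells in {path.name}")
    return ROITimeSeries(values=values, TR=TR, region_labels=tuple(labels))


def write_volumes(vol: np.ndarray, masks: dict[str, np.ndarray],
                  TR: float, out_dir: str | Path,
                  prefix: str = "synthetic") -> dict[str, Path]:
    """Write a 4-D volume and binary ROI masks as NIfTI-1 files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    paths: dict[str, Path] = {}
    img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine)
    img.header.set_zooms((1.0, 1.0, 1.0, TR))
    p = out_dir / f"{prefix}_bold.nii"
    nib.save(img, p)
    paths["bold"] = p
    for label, mask in masks.items():
        mimg = nib.Nifti1Image(mask.astype(np.uint8), affine)
        mp = out_dir / f"{prefix}_mask-{label}.nii"
        nib.save(mimg, mp)
        paths[label] = mp
    return paths


def read_roi_from_volumes(bold_path: str | Path,
                          mask_paths: dict[str, str | Path],
                          TR: float | None = None) -> ROITimeSeries:
    """Mask-mean extraction of ROI time courses from a 4-D NIfTI."""
    img = nib.load(str(bold_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if TR is None:
        TR = float(img.header.get_zooms()[3])
        if TR <= 0:
            raise ValueError("TR absent from NIfTI header; pass it explicitly")
    labels = [r for r in CANONICAL_REGIONS if r in mask_paths] or \
        list(mask_paths)
    cols = []
    for label in labels:
        mask = np.asanyarray(nib.load(str(mask_paths[label])).dataobj) > 0
        if not mask.any():
            raise ValueError(f"mask {label} is empty")
        cols.append(data[mask].mean(axis=0))
    return ROITimeSeries(values=np.column_stack(cols), TR=TR,
                         region_labels=tuple(labels))


def write_session_log(events: list[FeedbackEvent], path: str | Path,
                      header: dict | None = None) -> Path:
    """JSON-lines log, one event per line, optional header line first."""
    path = Path(path)
    with path.open("w") as fh:
        if header is not None:
            fh.write(json.dumps({"_header": header}) + "\n")
        for ev in events:
            fh.write(json.dumps(ev.to_dict()) + "\n")
    return path


def read_session_log(path: str | Path
                     ) -> tuple[list[FeedbackEvent], dict | None]:
    path = Path(path)
    events = []
    header = None
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            if "_header" in d:
                header = d["_header"]
            else:
                events.append(FeedbackEvent.from_dict(d))
    return events, header


# ---------------------------------------------------------------------------
# session configuration
# ---------------------------------------------------------------------------

_CONFIG_DEFAULTS = {
    "max_iter": 44,
    "tol": 0.05,
    "window_length": 90,
    "window_step": 20,
    "drift_half_life": 10.0,
    "spike_sd": 3.0,
    "ema_weight": 0.6,
    "dt": None,
    "seed": 0,
    "input_path": None,
    "output_path": None,
}


@dataclass
class SessionConfig:
    """Validated run configuration with documented defaults.

    Defaults mirror the operating point of the neurofeedback pipeline:
    iteration cap 44 per model, 90-scan windows shifted by 20 scans.
    """

    max_iter: int = 44
    tol: float = 0.05
    window_length: int = 90
    window_step: int = 20
    drift_half_life: float = 10.0
    spike_sd: float = 3.0
    ema_weight: float = 0.6
    dt: float | None = None
    seed: int = 0
    input_path: str | None = None
    output_path: str | None = None

    def __post_init__(self) -> None:
        if self.max_iter < 0:
            raise ValueError("max_iter must be non-negative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.window_length < 30:
            raise ValueError("window_length must be at least 30 scans")
        if self.window_step < 1:
            raise ValueError("window_step must be at least 1")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")

    def window_spec(self) -> WindowSpec:
        return WindowSpec(length_scans=self.window_length,
                          step_scans=self.window_step)

    def cleaner_config(self) -> CleanerConfig:
        return CleanerConfig(drift_half_life=self.drift_half_life,
                             spike_sd=self.spike_sd,
                             ema_weight=self.ema_weight)

    def content_hash(self) -> str:
        """Provenance hash of the configuration values."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> SessionConfig:
    """Load a YAML/JSON config; unknown keys are rejected."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path.name} must be a mapping")
    unknown = set(data) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(
            f"unknown config key(s): {', '.join(sorted(unknown))}"
        )
    merged = {**_CONFIG_DEFAULTS, **data}
    try:
        return SessionConfig(**merged)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config {path.name}: {exc}") from exc


def save_config(cfg: SessionConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
    return path
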