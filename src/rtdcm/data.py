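"""Shared data containers: ROI time series and experiment designs.

Region order is canonical throughout the package: ``("VC_L", "VC_R",
"SPL_L", "SPL_R")`` — left/right early visual cortex and left/right
superior parietal lobule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

CANONICAL_REGIONS = ("VC_L", "VC_R", "SPL_L", "SPL_R")

#: block labels used by designs
BASELINE, REST, DISPLAY = "baseline", "rest", "display"
COND_AL, COND_AR = "aL", "aR"


@dataclass(frozen=True)
class Block:
    """One contiguous design block (onset and duration in seconds)."""

    onset: float
    duration: float
    label: str
    trial: int = -1  # -1 for blocks outside any trial


@dataclass(frozen=True)
class TrialInfo:
    """Location of one neurofeedback trial inside a run.

    ``start_scan``/``stop_scan`` delimit the regulation window (the 5
    baseline + 4 regulation blocks), excluding rest and display scans.
    """

    index: int
    condition: str  # "aL" | "aR"
    start_scan: int
    stop_scan: int  # exclusive


@dataclass
class ExperimentDesign:
    """Input time courses and block structure of one run.

    ``u`` holds the external input channels sampled once per scan and is
    treated as piecewise constant (zero-order hold) between scans.
    """

    TR: float
    n_scans: int
    u: np.ndarray  # (n_scans, n_inputs)
    input_labels: tuple[str, ...]
    blocks: tuple[Block, ...] = ()
    trials: tuple[TrialInfo, ...] = ()

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if self.u.ndim != 2 or self.u.shape[0] != self.n_scans:
            raise ValueError(
                f"u must have shape (n_scans, n_inputs); got {self.u.shape} "
                f"for n_scans={self.n_scans}"
            )
        if self.u.shape[1] != len(self.input_labels):
            raise ValueError("input_labels length must match u columns")

    @property
    def n_inputs(self) -> int:
        return self.u.shape[1]

    def window(self, start_scan: int, stop_scan: int) -> "ExperimentDesign":
        """Sub-design covering scans ``[start_scan, stop_scan)``."""
        if not (0 <= start_scan < stop_scan <= self.n_scans):
            raise ValueError(
                f"window [{start_scan}, {stop_scan}) outside run of "
                f"{self.n_scans} scans"
            )
        t0, t1 = start_scan * self.TR, stop_scan * self.TR
        blocks = tuple(
            replace(b, onset=b.onset - t0)
            for b in self.blocks
            if b.onset < t1 and b.onset + b.duration > t0
        )
        return ExperimentDesign(
            TR=self.TR,
            n_scans=stop_scan - start_scan,
            u=self.u[start_scan:stop_scan].copy(),
            input_labels=self.input_labels,
            blocks=blocks,
            trials=(),
        )

    def collapse_inputs(self, label: str = "attention") -> "ExperimentDesign":
        """Merge all input channels into one generic channel.

        The fitted candidate models carry a single attention input; the
        generative design distinguishes aL and aR channels.  Collapsing
        sums the channels (blocks never overlap, so the sum stays 0/1).
        """
        return ExperimentDesign(
            TR=self.TR,
            n_scans=self.n_scans,
            u=self.u.sum(axis=1, keepdims=True),
            input_labels=(label,),
            blocks=self.blocks,
            trials=self.trials,
        )

    def scan_condition_labels(self) -> np.ndarray:
        """Per-scan label array ('aL'/'aR'/'baseline'/...) from blocks."""
        labels = np.array([BASELINE] * self.n_scans, dtype=object)
        for b in self.blocks:
            i0 = int(round(b.onset / self.TR))
            i1 = int(round((b.onset + b.duration) / self.TR))
            labels[i0 : min(i1, self.n_scans)] = b.label
        return labels


@dataclass
class ROITimeSeries:
    """Scans x regions signal matrix with its repetition time.

    Values may be raw scanner units, percent signal change, or cleaned
    (drift/spike-filtered) signal — the container does not care, the
    consumer does.
    """

    values: np.ndarray  # (n_scans, n_regions)
    TR: float
    region_labels: tuple[str, ...]
    scan_onset_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (scans x regions) array")
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if len(self.region_labels) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.region_labels)} region labels for "
                f"{self.values.shape[1]} columns"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at scan {bad[0]}, region "
                f"{self.region_labels[bad[1]]}"
            )
        if self.scan_onset_times is None:
            self.scan_onset_times = np.arange(self.n_scans) * self.TR
        else:
            self.scan_onset_times = np.asarray(self.scan_onset_times, dtype=float)

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def window(self, start_scan: int, stop_scan: int) -> "ROITimeSeries":
        if not (0 <= start_scan < stop_scan <= self.n_scans):
            raise ValueError(
                f"window [{start_scan}, {stop_scan}) outside series of "
                f"{self.n_scans} scans"
            )
        return ROITimeSeries(
            values=self.values[start_scan:stop_scan].copy(),
            TR=self.TR,
            region_labels=self.region_labels,
            scan_onset_times=self.scan_onset_times[start_scan:stop_scan].copy(),
        )
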