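"""Ground-truth experiment generator.

Builds block designs (localizer and neurofeedback layouts), simulates
ROI BOLD from a known connectivity ground truth (aL blocks drive the
right-hemisphere network, aR blocks the left), and adds the nuisance
structure the real-time cleaner has to cope with: autocorrelated noise,
slow drift and occasional spikes.  Optionally renders the session into a
small 4-D volume with binary ROI masks to exercise the mask-extraction
path.

Every stochastic operation takes an explicit seed; there is no hidden
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data import (BASELINE, COND_AL, COND_AR, DISPLAY, REST, Block,
                   ExperimentDesign, ROITimeSeries, TrialInfo)
from .forward import ConnectivityParams, HemodynamicParams, simulate_timeseries
from .models import attention_pair, build_params, validate

__all__ = [
    "NoiseSpec",
    "TruthSpec",
    "make_design",
    "ground_truth_params",
    "simulate_session",
    "simulate_volumes",
]

#: trial geometry (seconds) — 5 baseline blocks interleaved with 4
#: regulation blocks, feedback computed during the rest block and shown
#: during the display block.
BLOCK_S = 10.0
N_BASELINE = 5
N_REGULATION = 4
REST_S = 60.0
DISPLAY_S = 5.0
TRIAL_S = N_BASELINE * BLOCK_S + N_REGULATION * BLOCK_S  # 90 s
TRIAL_PERIOD_S = TRIAL_S + REST_S + DISPLAY_S  # 155 s


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise model, amplitudes in percent of baseline signal.

    ``white_sd`` is the innovation SD of an AR(1) process with
    coefficient ``ar1``; ``drift`` is a linear trend per scan; spikes
    are Bernoulli per scan with amplitude ``spike_amp`` (in units of
    white_sd, random sign).
    """

    white_sd: float = 0.5
    ar1: float = 0.3
    drift: float = 0.01
    spike_p: float = 0.005
    spike_amp: float = 8.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar1 < 1.0):
            raise ValueError("ar1 must lie in [0, 1)")
        if not (0.0 <= self.spike_p <= 1.0):
            raise ValueError("spike_p must be a probability")
        if self.white_sd < 0:
            raise ValueError("white_sd must be non-negative")


@dataclass(frozen=True)
class TruthSpec:
    """Generative effect sizes (Hz) for the attention network.

    Defaults keep the modulated network strictly stable (largest
    effective eigenvalue -0.2 Hz during attention, self-decay -0.5) and
    produce regulation-window BOLD fluctuations of ~0.5-1 percent —
    about SNR 1-2 against the default 0.5 percent noise, in line with
    the percent-signal-change magnitudes attention paradigms show.
    """

    a: float = 0.15         # intrinsic VC<->SPL coupling
    b: float = 0.15         # modulatory increase under attention
    c: float = 0.04         # direct attention input weight
    self_decay: float = -0.5


def make_design(
    layout: str,
    n_trials: int = 8,
    conditions: tuple[str, ...] = (COND_AL,),
    TR: float = 1.0,
    block_s: float = BLOCK_S,
) -> ExperimentDesign:
    """Build a block design.

    ``layout='localizer'``: 11 baseline blocks interleaved with 10 task
    blocks (210 scans at TR = 1 s); task blocks cycle through
    ``conditions``.  ``layout='neurofeedback'``: ``n_trials`` trials of
    5 baseline + 4 regulation blocks (90 scans) followed by 60 s rest
    and 5 s feedback display; aL/aR conditions alternate.

    Input channels are ("aL", "aR"), each 1 during its condition's
    regulation/task blocks.
    """
    if layout == "localizer":
        blocks: list[Block] = []
        t = 0.0
        k = 0
        for _ in range(10):
            blocks.append(Block(t, block_s, BASELINE))
            t += block_s
            blocks.append(Block(t, block_s, conditions[k % len(conditions)]))
            t += block_s
            k += 1
        blocks.append(Block(t, block_s, BASELINE))
        t += block_s
        n_scans = int(round(t / TR))
        trials: tuple[TrialInfo, ...] = ()
    elif layout == "neurofeedback":
        blocks = []
        trial_list = []
        t = 0.0
        for trial in range(n_trials):
            cond = (COND_AL, COND_AR)[trial % 2]
            start_scan = int(round(t / TR))
            for b in range(N_BASELINE + N_REGULATION):
                label = BASELINE if b % 2 == 0 else cond
                blocks.append(Block(t, block_s, label, trial=trial))
                t += block_s
            trial_list.append(TrialInfo(
                index=trial, condition=cond,
                start_scan=start_scan, stop_scan=int(round(t / TR)),
            ))
            blocks.append(Block(t, REST_S, REST, trial=trial))
            t += REST_S
            blocks.append(Block(t, DISPLAY_S, DISPLAY, trial=trial))
            t += DISPLAY_S
        n_scans = int(round(t / TR))
        trials = tuple(trial_list)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    u = np.zeros((n_scans, 2))
    chan = {COND_AL: 0, COND_AR: 1}
    for b in blocks:
        if b.label in chan:
            i0 = int(round(b.onset / TR))
            i1 = int(round((b.onset + b.duration) / TR))
            u[i0:i1, chan[b.label]] = 1.0
    return ExperimentDesign(
        TR=TR, n_scans=n_scans, u=u, input_labels=(COND_AL, COND_AR),
        blocks=tuple(blocks), trials=trials,
    )


def ground_truth_params(truth: TruthSpec = TruthSpec()) -> ConnectivityParams:
    """Union generative model with separate aL and aR input channels.

    The aL channel drives/modulates the right hemisphere (the M_aL
    architecture), the aR channel the left, on a shared intrinsic
    structure — so a single forward simulation covers a whole mixed
    session.
    """
    m_al, m_ar = attention_pair()
    p_r = build_params(validate(m_al), a=truth.a, b=truth.b, c=truth.c,
                       self_decay=truth.self_decay)
    p_l = build_params(validate(m_ar), a=truth.a, b=truth.b, c=truth.c,
                       self_decay=truth.self_decay)
    return ConnectivityParams(
        A=p_r.A,
        B=np.concatenate([p_r.B, p_l.B], axis=0),
        C=np.concatenate([p_r.C, p_l.C], axis=1),
        region_labels=p_r.region_labels,
        input_labels=(COND_AL, COND_AR),
    )


def simulate_session(
    design: ExperimentDesign,
    noise: NoiseSpec = NoiseSpec(),
    seed: int | None = None,
    truth: TruthSpec = TruthSpec(),
    baseline_level: float = 100.0,
    hemo: HemodynamicParams | None = None,
    dt: float | None = None,
) -> tuple[ROITimeSeries, dict]:
    """Forward-simulate a session and add drift, spikes and AR(1) noise.

    Output values are in raw signal units with baseline mean
    ``baseline_level`` (default 100, so 1 unit = 1 percent signal
    change).  Returns the series plus the exact generative record.
    """
    if hemo is None:
        hemo = HemodynamicParams()
    params = ground_truth_params(truth)
    clean = simulate_timeseries(params, hemo, design, dt=dt)

    rng = np.random.default_rng(seed if seed is not None else noise.seed)
    n, r = clean.values.shape
    unit = baseline_level / 100.0  # 1 percent in raw units
    w = rng.standard_normal((n, r)) * noise.white_sd * unit
    e = np.zeros((n, r))
    for t in range(n):
        e[t] = (noise.ar1 * e[t - 1] if t else 0.0) + w[t]
    drift = noise.drift * unit * np.arange(n)[:, None]
    spikes = np.zeros((n, r))
    hit = rng.random((n, r)) < noise.spike_p
    signs = rng.choice([-1.0, 1.0], size=(n, r))
    spikes[hit] = (signs * noise.spike_amp * noise.white_sd * unit)[hit]

    values = baseline_level + unit * clean.values + e + drift + spikes
    series = ROITimeSeries(values=values, TR=design.TR,
                           region_labels=clean.region_labels)
    record = {
        "truth": asdict(truth),
        "noise": asdict(noise),
        "seed": seed,
        "baseline_level": baseline_level,
        "params": params,
        "clean_percent": clean.values,
        "n_spikes": int(hit.sum()),
        "conditions": [t.condition for t in design.trials],
    }
    return series, record


_DEFAULT_ROI_VOXELS = {"VC_L": 16, "VC_R": 16, "SPL_L": 24, "SPL_R": 24}


def simulate_volumes(
    series: ROITimeSeries,
    grid: tuple[int, int, int] = (16, 16, 4),
    roi_voxels: dict[str, int] | None = None,
    voxel_noise_sd: float = 0.5,
    seed: int | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Render ROI time courses into a small 4-D voxel grid.

    Each ROI is a contiguous cluster in its own grid quadrant (left
    regions at low x, SPL at high y); every ROI voxel carries its
    region's time course plus independent Gaussian noise, background
    voxels carry noise only.  Default cluster sizes follow typical
    functionally-defined ROI extents (~24 voxels SPL, ~16 voxels VC).

    Returns the 4-D array (x, y, z, t) and one binary mask per region.
    """
    if roi_voxels is None:
        roi_voxels = dict(_DEFAULT_ROI_VOXELS)
    nx, ny, nz = grid
    quad = {
        "VC_L": (slice(0, nx // 2), slice(0, ny // 2)),
        "VC_R": (slice(nx // 2, nx), slice(0, ny // 2)),
        "SPL_L": (slice(0, nx // 2), slice(ny // 2, ny)),
        "SPL_R": (slice(nx // 2, nx), slice(ny // 2, ny)),
    }
    masks: dict[str, np.ndarray] = {}
    occupied = np.zeros(grid, dtype=bool)
    for label in series.region_labels:
        if label not in quad:
            raise ValueError(f"no quadrant defined for region {label!r}")
        k = roi_voxels[label]
        mask = np.zeros(grid, dtype=bool)
        xs, ys = quad[label]
        cells = np.argwhere(np.ones((xs.stop - xs.start, ys.stop - ys.start, nz)))
        if k > len(cells):
            raise ValueError(f"ROI {label} of {k} voxels exceeds its quadrant")
        for x, y, z in cells[:k]:
            mask[xs.start + x, ys.start + y, z] = True
        if np.any(mask & occupied):
            raise ValueError(f"ROI {label} overlaps a previously placed ROI")
        occupied |= mask
        masks[label] = mask

    rng = np.random.default_rng(seed)
    vol = rng.standard_normal(grid + (series.n_scans,)) * voxel_noise_sd
    for r, label in enumerate(series.region_labels):
        vol[masks[label]] += series.values[:, r][None, :]
    return vol, masks
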