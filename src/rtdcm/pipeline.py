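"""Streaming neurofeedback engine.

Scans arrive one at a time, pass through a strictly causal cleaner
(drift removal, spike clipping, high-frequency smoothing), and are
windowed into trials.  At the end of each trial both candidate models
are inverted on the 90-scan trial window; the signed log Bayes factor
F(M_aL) - F(M_aR) is the feedback value, converted to a display word,
a rounded display value, a success flag and a 1-CHF reward increment.
The same machinery drives the sliding-window optimization sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import COND_AL, COND_AR, ExperimentDesign, ROITimeSeries
from .forward import HemodynamicParams
from .inversion import (DEFAULT_MAX_ITER, DEFAULT_TOL, InversionError,
                        InversionResult, Priors, default_priors, invert)
from .models import DcmSkeleton, ModelSpec, attention_pair, validate
from .stats import sign_test

__all__ = [
    "WindowSpec",
    "CleanerConfig",
    "OnlineCleaner",
    "FeedbackEvent",
    "SlidingWindowReport",
    "clean_sample",
    "clean_series",
    "extract_trial_window",
    "compute_feedback",
    "run_session",
    "window_sweep",
]

SWEEP_LENGTHS = (30, 50, 70, 90, 110, 130, 150, 170, 190, 210)


@dataclass(frozen=True)
class WindowSpec:
    """Trial window geometry: one trial = 5 baseline + 4 regulation
    blocks of 10 s at TR = 1 s, i.e. 90 scans."""

    length_scans: int = 90
    step_scans: int = 20

    def __post_init__(self) -> None:
        if self.length_scans < 30:
            raise ValueError("window length must be at least 30 scans")
        if self.step_scans < 1:
            raise ValueError("window step must be at least 1 scan")


@dataclass(frozen=True)
class CleanerConfig:
    """Constants of the causal cleaner (all configurable).

    ``drift_half_life``: scans over which the exponentially weighted
    running mean forgets half its mass; ``spike_sd``: robust-SD clip
    threshold (1.4826 x running MAD); ``ema_weight``: weight on the
    current sample in the 2-tap smoothing stage; ``spike_warmup``:
    samples before clipping activates.
    """

    drift_half_life: float = 10.0
    spike_sd: float = 3.0
    ema_weight: float = 0.6
    spike_warmup: int = 10


class OnlineCleaner:
    """Strictly causal per-region signal cleaner.

    Stage 1 removes drift by subtracting an exponentially weighted
    running mean; stage 2 replaces samples further than ``spike_sd``
    robust SDs from the running median by that median; stage 3 smooths
    with a 2-tap exponential moving average.  Output at scan t depends
    only on scans <= t, so streaming and offline application agree
    bit-identically.
    """

    def __init__(self, n_regions: int, config: CleanerConfig = CleanerConfig()):
        self.config = config
        self.n_regions = n_regions
        self._decay = 0.5 ** (1.0 / config.drift_half_life)
        self._num = np.zeros(n_regions)
        self._den = np.zeros(n_regions)
        self._history: list[list[float]] = [[] for _ in range(n_regions)]
        self._prev = np.zeros(n_regions)
        self._t = 0

    def update(self, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        if raw.shape != (self.n_regions,):
            raise ValueError(
                f"expected {self.n_regions} region values, got shape {raw.shape}"
            )
        if not np.all(np.isfinite(raw)):
            bad = int(np.flatnonzero(~np.isfinite(raw))[0])
            raise ValueError(
                f"non-finite sample at scan {self._t}, region index {bad}"
            )
        cfg = self.config
        # 1) drift removal: weighted running mean with exact warm-up weights
        self._num = self._decay * self._num + raw
        self._den = self._decay * self._den + 1.0
        x = raw - self._num / self._den
        # 2) spike clipping against running median / MAD; the history keeps
        # the raw drift-removed values (the robust stats tolerate spikes,
        # whereas feeding clipped values back would shrink the MAD until
        # ordinary signal gets clipped too)
        out = np.empty(self.n_regions)
        for r in range(self.n_regions):
            xi = x[r]
            hist = self._history[r]
            hist.append(xi)
            if len(hist) > cfg.spike_warmup:
                arr = np.asarray(hist[:-1])
                med = float(np.median(arr))
                mad = float(np.median(np.abs(arr - med)))
                robust_sd = 1.4826 * mad
                if robust_sd > 0 and abs(xi - med) > cfg.spike_sd * robust_sd:
                    xi = med
            out[r] = xi
        # 3) 2-tap exponential moving average
        if self._t == 0:
            smoothed = out
        else:
            smoothed = cfg.ema_weight * out + (1 - cfg.ema_weight) * self._prev
        self._prev = smoothed
        self._t += 1
        return smoothed


def clean_sample(raw: np.ndarray, state: OnlineCleaner
                 ) -> tuple[np.ndarray, OnlineCleaner]:
    """Clean one scan's ROI values; returns (cleaned, updated state)."""
    return state.update(raw), state


def clean_series(series: ROITimeSeries,
                 config: CleanerConfig = CleanerConfig()) -> ROITimeSeries:
    """Run the causal cleaner over a whole series scan by scan."""
    cleaner = OnlineCleaner(series.n_regions, config)
    out = np.empty_like(series.values)
    for t in range(series.n_scans):
        out[t] = cleaner.update(series.values[t])
    return ROITimeSeries(values=out, TR=series.TR,
                         region_labels=series.region_labels,
                         scan_onset_times=series.scan_onset_times.copy())


@dataclass
class FeedbackEvent:
    """Outcome of one neurofeedback trial."""

    trial_index: int
    condition: str                 # "aL" | "aR"
    logBF: float                   # F(M_aL) - F(M_aR), nats
    display_word: str              # "UP" for aL trials, "DOWN" for aR
    display_value: int             # rounded logBF (half away from zero)
    success: bool
    reward_total: float            # CHF, cumulative
    pooled_logBF: float            # logBF for aL, -logBF for aR
    n_iterations: dict[str, int]
    converged: dict[str, bool]
    valid: bool = True

    def to_dict(self) -> dict:
        return {
            "trial_index": self.trial_index,
            "condition": self.condition,
            "logBF": None if not np.isfinite(self.logBF) else float(self.logBF),
            "display_word": self.display_word,
            "display_value": self.display_value,
            "success": self.success,
            "reward_total": self.reward_total,
            "pooled_logBF": None if not np.isfinite(self.pooled_logBF)
            else float(self.pooled_logBF),
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "valid": self.valid,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeedbackEvent":
        d = dict(d)
        for key in ("logBF", "pooled_logBF"):
            if d.get(key) is None:
                d[key] = float("nan")
        return cls(**d)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def extract_trial_window(
    series: ROITimeSeries,
    trial_index: int,
    design: ExperimentDesign,
    spec: WindowSpec = WindowSpec(),
) -> tuple[ROITimeSeries, str, ExperimentDesign]:
    """The (cleaned) trial window, its condition, and its sub-design.

    Only the regulation window (5 baseline + 4 regulation blocks)
    enters; rest and display scans are excluded.
    """
    trials = {t.index: t for t in design.trials}
    if trial_index not in trials:
        raise ValueError(f"design defines no trial {trial_index}")
    tr = trials[trial_index]
    stop = tr.start_scan + spec.length_scans
    if stop > series.n_scans:
        raise ValueError(
            f"trial {trial_index} window [{tr.start_scan}, {stop}) extends "
            f"past the {series.n_scans} acquired scans"
        )
    window = series.window(tr.start_scan, stop)
    wdesign = design.window(tr.start_scan, stop).collapse_inputs()
    return window, tr.condition, wdesign


def compute_feedback(
    window: ROITimeSeries | np.ndarray,
    window_design: ExperimentDesign,
    pair: tuple[DcmSkeleton, DcmSkeleton] | None = None,
    condition: str = COND_AL,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    hemo: HemodynamicParams | None = None,
    dt: float | None = None,
    priors: tuple[Priors, Priors] | None = None,
    reward_so_far: float = 0.0,
    return_results: bool = False,
):
    """Invert (M_aL, M_aR) on one trial window and emit a FeedbackEvent.

    logBF = F(M_aL) - F(M_aR); the trial is successful when the sign
    matches the condition (positive for aL, negative for aR; an exact
    tie counts as failure).  A failed inversion of either model yields
    an invalid event and no reward.
    """
    if condition not in (COND_AL, COND_AR):
        raise ValueError(f"unknown condition {condition!r}")
    if pair is None:
        m_al, m_ar = attention_pair()
        pair = (validate(m_al), validate(m_ar))
    if priors is None:
        priors = (default_priors(pair[0]), default_priors(pair[1]))
    word = "UP" if condition == COND_AL else "DOWN"
    results: dict[str, InversionResult] = {}
    try:
        for skel, pri in zip(pair, priors):
            results[skel.spec.name] = invert(
                window, window_design, skel, priors=pri, hemo=hemo, dt=dt,
                max_iter=max_iter, tol=tol,
            )
    except InversionError:
        event = FeedbackEvent(
            trial_index=-1, condition=condition, logBF=float("nan"),
            display_word=word, display_value=0, success=False,
            reward_total=reward_so_far, pooled_logBF=float("nan"),
            n_iterations={k: r.n_iterations for k, r in results.items()},
            converged={k: r.converged for k, r in results.items()},
            valid=False,
        )
        return (event, results) if return_results else event

    name_l, name_r = pair[0].spec.name, pair[1].spec.name
    logbf = results[name_l].F - results[name_r].F
    success = (condition == COND_AL and logbf > 0) or \
              (condition == COND_AR and logbf < 0)
    event = FeedbackEvent(
        trial_index=-1,
        condition=condition,
        logBF=float(logbf),
        display_word=word,
        display_value=_round_half_away(logbf),
        success=bool(success),
        reward_total=reward_so_far + (1.0 if success else 0.0),
        pooled_logBF=float(logbf if condition == COND_AL else -logbf),
        n_iterations={k: r.n_iterations for k, r in results.items()},
        converged={k: r.converged for k, r in results.items()},
        valid=True,
    )
    return (event, results) if return_results else event


def run_session(
    series: ROITimeSeries,
    design: ExperimentDesign,
    pair: tuple[DcmSkeleton, DcmSkeleton] | None = None,
    cleaner_config: CleanerConfig = CleanerConfig(),
    window_spec: WindowSpec = WindowSpec(),
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    hemo: HemodynamicParams | None = None,
    dt: float | None = None,
) -> list[FeedbackEvent]:
    """Process a session's scans in order and emit one event per trial.

    Scans stream through the causal cleaner; each trial's 90-scan
    window is cut from the cleaned stream and both models are inverted
    under the per-model iteration cap.  An exhausted budget still emits
    the event (converged=False); rewards accumulate across the session.
    """
    if not design.trials:
        raise ValueError("design has no trials; use the neurofeedback layout")
    cleaned = clean_series(series, cleaner_config)
    events: list[FeedbackEvent] = []
    reward = 0.0
    for tr in design.trials:
        window, condition, wdesign = extract_trial_window(
            cleaned, tr.index, design, window_spec)
        event = compute_feedback(
            window, wdesign, pair=pair, condition=condition,
            max_iter=max_iter, tol=tol, hemo=hemo, dt=dt,
            reward_so_far=reward,
        )
        event.trial_index = tr.index
        reward = event.reward_total
        events.append(event)
    return events


@dataclass
class SlidingWindowRow:
    length: int
    n_windows: int
    n_correct: int
    sign_k: int
    sign_n: int
    z: float
    p: float
    iter_mean: float
    iter_sd: float


@dataclass
class SlidingWindowReport:
    """Per-window-length dominance counts from the optimization sweep."""

    rows: list[SlidingWindowRow]

    def row(self, length: int) -> SlidingWindowRow:
        for r in self.rows:
            if r.length == length:
                return r
        raise KeyError(f"no sweep row for window length {length}")


def expected_n_windows(run_length: int, window: int, step: int) -> int:
    """Number of window placements: floor((L - W)/step) + 1."""
    if window > run_length:
        raise ValueError("window longer than the run")
    return (run_length - window) // step + 1


def window_sweep(
    series: ROITimeSeries,
    design: ExperimentDesign,
    pair: tuple[DcmSkeleton, DcmSkeleton] | None = None,
    lengths=SWEEP_LENGTHS,
    step: int = 20,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    hemo: HemodynamicParams | None = None,
    dt: float | None = None,
) -> SlidingWindowReport:
    """Slide windows of several lengths across a run and invert the pair.

    Each window is labeled by the majority condition among its aL/aR
    scans; dominance is correct when the logBF sign matches that label.
    Signed (pooled) log Bayes factors per window enter a one-tailed
    sign test per length.
    """
    if pair is None:
        m_al, m_ar = attention_pair()
        pair = (validate(m_al), validate(m_ar))
    labels = design.scan_condition_labels()
    if series.n_scans < max(lengths):
        raise ValueError(
            f"series of {series.n_scans} scans is shorter than the largest "
            f"window ({max(lengths)})"
        )
    rows = []
    for W in lengths:
        n_windows = expected_n_windows(series.n_scans, W, step)
        pooled = []
        n_correct = 0
        iters = []
        for w in range(n_windows):
            start = w * step
            stop = start + W
            wl = labels[start:stop]
            n_al = int(np.sum(wl == COND_AL))
            n_ar = int(np.sum(wl == COND_AR))
            if n_al == 0 and n_ar == 0:
                continue
            condition = COND_AL if n_al >= n_ar else COND_AR
            event = compute_feedback(
                series.window(start, stop),
                design.window(start, stop).collapse_inputs(),
                pair=pair, condition=condition, max_iter=max_iter, tol=tol,
                hemo=hemo, dt=dt,
            )
            if not event.valid:
                continue
            pooled.append(event.pooled_logBF)
            n_correct += int(event.success)
            for v in event.n_iterations.values():
                iters.append(v)
        pooled_arr = np.asarray(pooled)
        nz = pooled_arr[pooled_arr != 0]
        if nz.size:
            st = sign_test(nz)
            sign_k, sign_n, z, p = st.k, st.n, st.z, st.p
        else:
            sign_k = sign_n = 0
            z = p = float("nan")
        rows.append(SlidingWindowRow(
            length=W, n_windows=n_windows, n_correct=n_correct,
            sign_k=sign_k, sign_n=sign_n, z=z, p=p,
            iter_mean=float(np.mean(iters)) if iters else float("nan"),
            iter_sd=float(np.std(iters)) if iters else float("nan"),
        ))
    return SlidingWindowReport(rows=rows)
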