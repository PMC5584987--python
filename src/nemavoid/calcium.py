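"""GCaMP trace pipeline: dF/F0, buffer-control subtraction, stimulus AUC.

The imaging protocol exposes a trapped worm to buffer for 15 s, stimulus
for 60 s (15-75 s), then buffer again, sampling fluorescence every 0.5 s.
The pipeline normalizes each trace to percent change relative to the
intensity at the 15 s pre-stimulus timepoint, subtracts the averaged
buffer-control time series, integrates the normalized trace over the
stimulus window (trapezoid rule, units %*s), and compares genotypes by a
two-sample t-test on the per-worm AUC values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import behavior

__all__ = [
    "FluorescenceTrace",
    "NormalizedTrace",
    "AucResult",
    "delta_f_over_f",
    "subtract_buffer_control",
    "auc_stimulus",
    "group_trace_summary",
    "compare_auc",
    "read_traces_csv",
]

_DT = 0.5  # acquisition interval, s


@dataclass(frozen=True)
class FluorescenceTrace:
    """Registered, background-subtracted intensity series for one worm."""

    worm_id: str
    genotype: str
    condition: str  # "stimulus" | "buffer_control"
    times: np.ndarray
    intensities: np.ndarray
    stimulus_window: tuple[float, float] = (15.0, 75.0)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", f)
        if t.shape != f.shape:
            raise ValueError(
                f"trace {self.worm_id!r}: times and intensities lengths differ"
            )
        if len(t) < 2:
            raise ValueError(f"trace {self.worm_id!r}: too few samples")
        steps = np.diff(t)
        if np.any(np.abs(steps - _DT) > 1e-9):
            bad = int(np.argmax(np.abs(steps - _DT) > 1e-9))
            raise ValueError(
                f"trace {self.worm_id!r}: non-uniform sampling at "
                f"t={t[bad]:.2f}->{t[bad + 1]:.2f} s (expected {_DT} s steps; "
                "gapped traces are rejected, not interpolated)"
            )
        lo, hi = self.stimulus_window
        if t[0] > lo or t[-1] < hi:
            raise ValueError(
                f"trace {self.worm_id!r}: stimulus window [{lo}, {hi}] s "
                f"not covered by time range [{t[0]}, {t[-1]}] s"
            )


@dataclass(frozen=True)
class NormalizedTrace:
    """Percent-change (dF/F0) series; ``normalized`` marks control subtraction."""

    worm_id: str
    genotype: str
    times: np.ndarray
    dff_percent: np.ndarray
    normalized: bool = False
    stimulus_window: tuple[float, float] = (15.0, 75.0)


@dataclass(frozen=True)
class AucResult:
    """Area under the normalized trace over the stimulus window, %*s."""

    worm_id: str
    genotype: str
    auc: float
    stimulus: str = "stimulus"


def _baseline_value(trace: FluorescenceTrace, mode: str,
                    window: tuple[float, float]) -> float:
    t = trace.times
    onset = trace.stimulus_window[0]
    if mode == "frame":
        idx = np.flatnonzero(np.abs(t - onset) < 1e-9)
        if idx.size == 0:
            raise ValueError(
                f"trace {trace.worm_id!r}: no sample at the {onset} s baseline timepoint"
            )
        return float(trace.intensities[idx[0]])
    if mode == "window":
        lo, hi = window
        mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
        if not mask.any():
            raise ValueError(
                f"trace {trace.worm_id!r}: baseline window [{lo}, {hi}] s has no samples"
            )
        return float(trace.intensities[mask].mean())
    raise ValueError(f"unknown baseline mode {mode!r}")


def delta_f_over_f(
    trace: FluorescenceTrace,
    baseline_mode: str = "frame",
    baseline_window: tuple[float, float] = (10.0, 15.0),
) -> NormalizedTrace:
    """Percent change relative to the pre-stimulus baseline.

    dF/F(t) = 100 * (F(t) - F0) / F0 with F0 the single frame at the
    stimulus-onset timepoint (default), or the mean over a short window
    ending at onset (``baseline_mode="window"``) when a single-frame
    baseline is too noise-sensitive.
    """
    f0 = _baseline_value(trace, baseline_mode, baseline_window)
    if f0 <= 0:
        raise ValueError(
            f"trace {trace.worm_id!r}: non-positive baseline F0 = {f0}"
        )
    dff = 100.0 * (trace.intensities - f0) / f0
    return NormalizedTrace(
        worm_id=trace.worm_id,
        genotype=trace.genotype,
        times=trace.times,
        dff_percent=dff,
        normalized=False,
        stimulus_window=trace.stimulus_window,
    )


def _check_common_grid(traces: Sequence[NormalizedTrace]) -> np.ndarray:
    ref = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != ref.shape or np.any(np.abs(tr.times - ref) > 1e-9):
            if tr.times.shape != ref.shape:
                raise ValueError(
                    f"trace {tr.worm_id!r}: time grid length differs from "
                    f"{traces[0].worm_id!r}"
                )
            bad = int(np.argmax(np.abs(tr.times - ref) > 1e-9))
            raise ValueError(
                f"trace {tr.worm_id!r}: time grid mismatch at t={ref[bad]} s"
            )
    return ref


def subtract_buffer_control(
    treatment: Sequence[NormalizedTrace],
    buffer_controls: Sequence[NormalizedTrace],
) -> list[NormalizedTrace]:
    """Subtract the pointwise mean buffer-control trace from each trace.

    All traces (treatment and control) must share an identical time grid.
    Applied to the buffer-control group itself, the group mean of the
    output is the zero series.
    """
    if not treatment or not buffer_controls:
        raise ValueError("treatment and buffer-control groups must be non-empty")
    grid = _check_common_grid(list(treatment) + list(buffer_controls))
    control_mean = np.mean([tr.dff_percent for tr in buffer_controls], axis=0)
    return [
        NormalizedTrace(
            worm_id=tr.worm_id,
            genotype=tr.genotype,
            times=grid,
            dff_percent=tr.dff_percent - control_mean,
            normalized=True,
            stimulus_window=tr.stimulus_window,
        )
        for tr in treatment
    ]


def auc_stimulus(trace: NormalizedTrace, stimulus: str = "stimulus") -> AucResult:
    """Trapezoidal area under dF/F over the stimulus window, in %*s.

    Negative areas are kept: a suppressed response integrates below zero.
    """
    lo, hi = trace.stimulus_window
    t = trace.times
    if t[0] > lo + 1e-9 or t[-1] < hi - 1e-9:
        raise ValueError(
            f"trace {trace.worm_id!r}: stimulus window [{lo}, {hi}] s not covered"
        )
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    area = float(np.trapezoid(trace.dff_percent[mask], t[mask]))
    return AucResult(worm_id=trace.worm_id, genotype=trace.genotype,
                     auc=area, stimulus=stimulus)


def group_trace_summary(
    traces: Sequence[NormalizedTrace],
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise group mean and SEM (sd/sqrt(n)) across worms."""
    if len(traces) < 2:
        raise ValueError("SEM undefined for fewer than 2 traces")
    _check_common_grid(traces)
    stack = np.vstack([tr.dff_percent for tr in traces])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    return mean, sem


def compare_auc(
    wildtype: Sequence[AucResult],
    mutant: Sequence[AucResult],
    labels: tuple[str, str] = ("wild-type", "mutant"),
) -> behavior.StatResult:
    """Two-sample t-test on per-worm AUCs (each stimulus analyzed separately)."""
    return behavior.two_sample_t_test(
        [r.auc for r in wildtype], [r.auc for r in mutant], labels=labels
    )


def read_traces_csv(path) -> list[FluorescenceTrace]:
    """Read long-form traces: worm_id,genotype,condition,t_s,intensity."""
    df = pd.read_csv(path)
    traces = []
    for worm_id, sub in df.groupby("worm_id", sort=False):
        sub = sub.sort_values("t_s")
        traces.append(
            FluorescenceTrace(
                worm_id=str(worm_id),
                genotype=str(sub["genotype"].iloc[0]),
                condition=str(sub["condition"].iloc[0]),
                times=sub["t_s"].to_numpy(dtype=float),
                intensities=sub["intensity"].to_numpy(dtype=float),
            )
        )
    return traces
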