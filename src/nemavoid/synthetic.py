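"""Synthetic data generators emulating the study's measurement structure.

Each generator draws from an explicitly seeded :class:`numpy.random.Generator`
so every modality is reproducible and independent of global RNG state.
The defaults mirror the study conditions: Gamma-distributed backing
latencies (short into repellents, long into buffer), Bernoulli head
responses (buffer ~0.2, repellent ~0.8), multinomial chemotaxis plate
counts, stimulus-locked GCaMP transients on a 15 s buffer / 60 s stimulus
/ buffer protocol sampled every 0.5 s, and centroided LC-MS scans with
Gaussian elution profiles and ppm-scale m/z jitter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior import BackingTimeRecord, ChemotaxisPlate, HeadResponseRecord
from .calcium import FluorescenceTrace
from .eic import CentroidRun

__all__ = [
    "BehaviorGroup",
    "BehaviorSimConfig",
    "TraceSimConfig",
    "MsPeak",
    "MsSimConfig",
    "gen_backing_times",
    "gen_head_responses",
    "gen_chemotaxis_plates",
    "gen_gcamp_traces",
    "gen_ms_run",
    "backing_records_to_frame",
    "head_records_to_frame",
    "plates_to_frame",
    "traces_to_frame",
    "write_ms_run_jsonl",
]


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorGroup:
    """One assay group: genotype x treatment with its latency model.

    ``dispersion`` is the coefficient of variation (sd/mean) of the
    Gamma backing-time distribution; 0 gives the noise-free limit where
    every animal backs for exactly the group mean.
    """

    genotype: str
    treatment: str
    mean_s: float
    dispersion: float
    n: int


@dataclass(frozen=True)
class BehaviorSimConfig:
    """Group structure for behavioral simulations.

    ``response_probs`` maps treatment label to the Bernoulli probability
    of a head (amphid) response; buffer defaults near 0.2 and repellents
    near 0.8, the proportions the assays are powered for.
    """

    groups: Sequence[BehaviorGroup]
    response_probs: Mapping[str, float] = field(default_factory=dict)
    day_count: int = 1
    observation_cap_s: float = 20.0
    day_effect_sd: float = 0.0  # multiplicative log-normal day factor; 0 = off
    seed: int = 0

    def __post_init__(self) -> None:
        if self.day_count < 1:
            raise ValueError("day_count must be >= 1")
        for g in self.groups:
            if g.mean_s <= 0:
                raise ValueError(
                    f"group ({g.genotype}, {g.treatment}): mean backing time "
                    f"must be > 0, got {g.mean_s}"
                )
            if g.n < 1:
                raise ValueError(
                    f"group ({g.genotype}, {g.treatment}): n must be >= 1, got {g.n}"
                )
            if g.dispersion < 0:
                raise ValueError(
                    f"group ({g.genotype}, {g.treatment}): dispersion must be >= 0"
                )
        for treatment, p in self.response_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(
                    f"response probability for {treatment!r} outside [0,1]: {p}"
                )


@dataclass(frozen=True)
class TraceSimConfig:
    """GCaMP trace simulation on the buffer/stimulus/buffer protocol.

    The transient is a difference of exponentials starting at stimulus
    onset, scaled so its peak equals ``amplitude * baseline``.  Sampling
    is fixed at 0.5 s, matching the imaging frame rate.
    """

    n_worms: int = 15
    duration_s: float = 90.0
    stimulus_onset_s: float = 15.0
    stimulus_offset_s: float = 75.0
    baseline: float = 100.0
    amplitude: float = 0.5  # peak dF/F as a fraction of baseline
    tau_rise_s: float = 2.0
    tau_decay_s: float = 10.0
    noise_sd: float = 0.0
    bleach_slope: float = 0.0  # intensity units lost per second
    seed: int = 0

    sampling_interval_s: float = 0.5  # fixed by the acquisition protocol

    def __post_init__(self) -> None:
        if self.duration_s <= self.stimulus_offset_s:
            raise ValueError(
                "duration must exceed the stimulus offset "
                f"({self.stimulus_offset_s} s); got {self.duration_s} s"
            )
        if self.baseline <= 0:
            raise ValueError("baseline intensity must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0 < self.tau_rise_s < self.tau_decay_s:
            raise ValueError("need 0 < tau_rise < tau_decay")
        if self.sampling_interval_s != 0.5:
            raise ValueError("sampling interval is fixed at 0.5 s")


@dataclass(frozen=True)
class MsPeak:
    """One chromatographic peak: target m/z with a Gaussian elution profile."""

    mz: float
    rt_center_s: float
    rt_sigma_s: float
    apex_intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"m/z must be > 0, got {self.mz}")
        if self.rt_sigma_s <= 0:
            raise ValueError("rt sigma must be > 0")
        if self.apex_intensity < 0:
            raise ValueError("apex intensity must be >= 0")


@dataclass(frozen=True)
class MsSimConfig:
    """Centroided LC-MS run simulation (QToF-style peak lists per scan)."""

    peaks: Sequence[MsPeak]
    scan_interval_s: float = 1.0
    rt_start_s: float = 0.0
    rt_end_s: float = 300.0
    mz_jitter_ppm: float = 0.0
    noise_floor: float = 0.0
    noise_centroids_per_scan: int = 5
    noise_mz_range: tuple[float, float] = (100.0, 1000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_interval_s <= 0:
            raise ValueError("scan interval must be > 0")
        if self.mz_jitter_ppm < 0:
            raise ValueError("m/z jitter sd must be >= 0")
        if self.noise_floor < 0:
            raise ValueError("noise floor must be >= 0")


# ---------------------------------------------------------------------------
# Behavioral generators
# ---------------------------------------------------------------------------

def _day_labels(day_count: int) -> list[str]:
    return [f"day{i + 1}" for i in range(day_count)]


def gen_backing_times(config: BehaviorSimConfig) -> list[BackingTimeRecord]:
    """Draw per-animal backing times for every configured group.

    Times come from a Gamma distribution with the group's mean and
    coefficient of variation, censored at the observation cap (an animal
    that never stops is recorded at the cap with ``censored=True``).
    Day labels cycle through ``day_count``; an optional multiplicative
    log-normal day effect exercises within-day normalization.
    """
    rng = np.random.default_rng(config.seed)
    days = _day_labels(config.day_count)
    day_factor = {d: 1.0 for d in days}
    if config.day_effect_sd > 0:
        for d in days:
            day_factor[d] = float(
                rng.lognormal(mean=0.0, sigma=config.day_effect_sd)
            )

    cap = config.observation_cap_s
    records: list[BackingTimeRecord] = []
    for g in config.groups:
        assigned_days = [days[i % len(days)] for i in range(g.n)]
        if g.dispersion == 0:
            draws = np.full(g.n, g.mean_s)
        else:
            shape = 1.0 / g.dispersion**2
            scale = g.mean_s * g.dispersion**2
            draws = rng.gamma(shape, scale, size=g.n)
        for i, (t, day) in enumerate(zip(draws, assigned_days)):
            t = float(t) * day_factor[day]
            censored = t >= cap
            records.append(
                BackingTimeRecord(
                    animal_id=f"{g.genotype}-{g.treatment}-{i + 1}",
                    genotype=g.genotype,
                    treatment=g.treatment,
                    day=day,
                    backing_time=min(t, cap) if censored else max(t, 1e-9),
                    censored=censored,
                )
            )
    return records


def gen_head_responses(config: BehaviorSimConfig) -> list[HeadResponseRecord]:
    """Bernoulli halt/no-halt draws per animal, per configured group."""
    rng = np.random.default_rng(config.seed)
    days = _day_labels(config.day_count)
    records: list[HeadResponseRecord] = []
    for g in config.groups:
        if g.treatment not in config.response_probs:
            raise ValueError(
                f"no response probability configured for treatment {g.treatment!r}"
            )
        p = config.response_probs[g.treatment]
        draws = rng.random(g.n) < p
        for i, hit in enumerate(draws):
            records.append(
                HeadResponseRecord(
                    animal_id=f"{g.genotype}-{g.treatment}-{i + 1}",
                    genotype=g.genotype,
                    treatment=g.treatment,
                    day=days[i % len(days)],
                    responded=bool(hit),
                )
            )
    return records


def gen_chemotaxis_plates(
    n_plates: int,
    p_experimental: float,
    p_control: float,
    worms_per_plate: int,
    seed: int = 0,
) -> list[ChemotaxisPlate]:
    """Multinomial allocation of worms to experimental / control / elsewhere."""
    if not (0 <= p_experimental <= 1 and 0 <= p_control <= 1):
        raise ValueError("spot probabilities must lie in [0,1]")
    if p_experimental + p_control > 1 + 1e-12:
        raise ValueError(
            f"p_experimental + p_control > 1 ({p_experimental} + {p_control})"
        )
    rng = np.random.default_rng(seed)
    p_rest = max(0.0, 1.0 - p_experimental - p_control)
    counts = rng.multinomial(
        worms_per_plate, [p_experimental, p_control, p_rest], size=n_plates
    )
    return [
        ChemotaxisPlate(
            plate_id=f"plate{i + 1}",
            n_experimental=int(c[0]),
            n_control=int(c[1]),
            n_total=worms_per_plate,
        )
        for i, c in enumerate(counts)
    ]


# ---------------------------------------------------------------------------
# Calcium-trace generator
# ---------------------------------------------------------------------------

def _transient_kernel(t_since_onset: np.ndarray, tau_rise: float,
                      tau_decay: float) -> np.ndarray:
    """Difference of exponentials normalized to a unit peak."""
    t = np.maximum(t_since_onset, 0.0)
    raw = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    t_peak = math.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    peak = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    out = raw / peak
    out[t_since_onset < 0] = 0.0
    return out


def gen_gcamp_traces(
    config: TraceSimConfig,
    responsive: bool,
    genotype: str = "wild-type",
    condition: str = "stimulus",
) -> list[FluorescenceTrace]:
    """Simulate per-worm fluorescence traces on the 0.5 s grid.

    Each trace is baseline, minus optional linear bleach drift, plus (for
    responsive worms) a stimulus-locked difference-of-exponentials
    transient starting at onset, plus i.i.d. Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.sampling_interval_s
    n_samples = int(round(config.duration_s / dt)) + 1
    times = np.arange(n_samples) * dt

    signal = np.full(n_samples, config.baseline, dtype=float)
    signal -= config.bleach_slope * times
    if responsive and config.amplitude != 0:
        kernel = _transient_kernel(
            times - config.stimulus_onset_s, config.tau_rise_s, config.tau_decay_s
        )
        signal = signal + config.amplitude * config.baseline * kernel

    traces = []
    for w in range(config.n_worms):
        noise = rng.normal(0.0, config.noise_sd, n_samples) if config.noise_sd else 0.0
        traces.append(
            FluorescenceTrace(
                worm_id=f"{genotype}-{condition}-w{w + 1}",
                genotype=genotype,
                condition=condition,
                times=times.copy(),
                intensities=signal + noise,
                stimulus_window=(config.stimulus_onset_s, config.stimulus_offset_s),
            )
        )
    return traces


# ---------------------------------------------------------------------------
# LC-MS run generator
# ---------------------------------------------------------------------------

def gen_ms_run(config: MsSimConfig) -> CentroidRun:
    """Simulate a centroided run: Gaussian elution peaks plus a noise floor.

    Each scan carries one centroid per configured peak (m/z jittered by
    the configured ppm sd, intensity from the Gaussian elution profile;
    zero-intensity centroids are dropped) plus ``noise_centroids_per_scan``
    uniform-m/z centroids with intensities uniform on (0, noise_floor].
    """
    rng = np.random.default_rng(config.seed)
    rts = np.arange(config.rt_start_s, config.rt_end_s + 1e-9, config.scan_interval_s)
    lo, hi = config.noise_mz_range
    scans: list[tuple[float, np.ndarray]] = []
    for rt in rts:
        mzs: list[float] = []
        intens: list[float] = []
        for pk in config.peaks:
            inten = pk.apex_intensity * math.exp(
                -((rt - pk.rt_center_s) ** 2) / (2 * pk.rt_sigma_s**2)
            )
            if inten <= 0:
                continue
            mz = pk.mz
            if config.mz_jitter_ppm > 0:
                mz += rng.normal(0.0, pk.mz * config.mz_jitter_ppm * 1e-6)
            mzs.append(mz)
            intens.append(inten)
        if config.noise_floor > 0 and config.noise_centroids_per_scan > 0:
            k = config.noise_centroids_per_scan
            mzs.extend(rng.uniform(lo, hi, k).tolist())
            intens.extend((rng.random(k) * config.noise_floor).tolist())
        order = np.argsort(mzs) if mzs else []
        centroids = (
            np.column_stack([np.asarray(mzs)[order], np.asarray(intens)[order]])
            if len(mzs)
            else np.empty((0, 2))
        )
        scans.append((float(rt), centroids))
    return CentroidRun(scans=scans)


# ---------------------------------------------------------------------------
# Tabular / file writers
# ---------------------------------------------------------------------------

def backing_records_to_frame(records: Sequence[BackingTimeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "genotype": [r.genotype for r in records],
            "treatment": [r.treatment for r in records],
            "day": [r.day for r in records],
            "backing_time_s": [r.backing_time for r in records],
            "censored": [r.censored for r in records],
        }
    )


def head_records_to_frame(records: Sequence[HeadResponseRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "genotype": [r.genotype for r in records],
            "treatment": [r.treatment for r in records],
            "day": [r.day for r in records],
            "responded": [r.responded for r in records],
        }
    )


def plates_to_frame(plates: Sequence[ChemotaxisPlate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plate_id": [p.plate_id for p in plates],
            "n_experimental": [p.n_experimental for p in plates],
            "n_control": [p.n_control for p in plates],
            "n_total": [p.n_total for p in plates],
        }
    )


def traces_to_frame(traces: Sequence[FluorescenceTrace]) -> pd.DataFrame:
    """Long-form table: worm_id, genotype, condition, t_s, intensity."""
    frames = [
        pd.DataFrame(
            {
                "worm_id": tr.worm_id,
                "genotype": tr.genotype,
                "condition": tr.condition,
                "t_s": tr.times,
                "intensity": tr.intensities,
            }
        )
        for tr in traces
    ]
    return pd.concat(frames, ignore_index=True)


def write_ms_run_jsonl(run: CentroidRun, path: str | Path) -> None:
    """Write a centroid run as JSON lines: {"rt_s": ..., "centroids": [[mz, i], ...]}."""
    with open(path, "w", encoding="utf-8") as fh:
        for rt, centroids in run.scans:
            fh.write(
                json.dumps(
                    {"rt_s": rt, "centroids": np.asarray(centroids).tolist()}
                )
                + "\n"
            )
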