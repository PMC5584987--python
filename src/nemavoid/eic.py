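"""Exact-mass targets and extracted-ion chromatograms from centroided runs.

Secreted fatty acids are detected after fixed-charge pyridinium-ester
derivatization by positive-mode ESI-QToF.  Quantification proceeds by
computing the monoisotopic m/z of each target ion, extracting an EIC by
summing centroid intensities within a +/-100 ppm m/z window per scan,
integrating the peak over an explicit retention-time window (trapezoid
rule, optional linear baseline), and reporting sample/control area ratios
against a detection floor.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "ElementalFormula",
    "CentroidRun",
    "Eic",
    "PeakArea",
    "parse_formula",
    "monoisotopic_mz",
    "extract_eic",
    "integrate_peak",
    "relative_abundance",
    "read_centroid_jsonl",
    "eic_to_frame",
]

# Monoisotopic atomic masses, u (CODATA/IUPAC 2021 values).
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

ELECTRON_MASS = 0.000548579909  # u

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element counts plus net charge (e.g. +1 for a fixed-charge cation)."""

    counts: Mapping[str, int]
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.counts or sum(self.counts.values()) == 0:
            raise ValueError("formula must contain at least one atom")
        for el, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for element {el}")
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(
                    f"unknown element symbol {el!r} "
                    f"(known: {sorted(MONOISOTOPIC_MASS)})"
                )


def parse_formula(text: str, charge: int = 0) -> ElementalFormula:
    """Parse a Hill-style formula string like ``"C18H30NO2"``."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        pos = m.end()
        el = m.group(1)
        counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return ElementalFormula(counts=counts, charge=charge)


def monoisotopic_mz(formula: ElementalFormula) -> float:
    """Monoisotopic m/z of an ion, or the neutral mass when charge is 0.

    For a charged species the electron deficit/excess is accounted for:
    m/z = (sum(count * atomic mass) - charge * m_e) / |charge|.
    """
    mass = sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.counts.items())
    if formula.charge == 0:
        return mass
    return (mass - formula.charge * ELECTRON_MASS) / abs(formula.charge)


@dataclass(frozen=True)
class CentroidRun:
    """Ordered scans of (retention time s, centroid array of (m/z, intensity))."""

    scans: Sequence[tuple[float, np.ndarray]]

    def __post_init__(self) -> None:
        rts = [rt for rt, _ in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be strictly increasing")
        for rt, cen in self.scans:
            cen = np.asarray(cen)
            if cen.size and (cen.ndim != 2 or cen.shape[1] != 2):
                raise ValueError(f"scan at rt={rt}: centroids must be (n, 2)")
            if cen.size and np.any(cen[:, 0] <= 0):
                raise ValueError(f"scan at rt={rt}: m/z values must be > 0")

    @property
    def rt_s(self) -> np.ndarray:
        return np.array([rt for rt, _ in self.scans])


@dataclass(frozen=True)
class Eic:
    """Per-scan summed intensity within a ppm window around a target m/z."""

    target_mz: float
    ppm_tol: float
    rt_s: np.ndarray
    intensity: np.ndarray


@dataclass(frozen=True)
class PeakArea:
    """Integrated EIC peak over an explicit retention-time window."""

    area: float
    rt_window: tuple[float, float]
    apex_rt: float
    baseline_mode: str = "none"


def extract_eic(run: CentroidRun, target_mz: float, ppm_tol: float = 100.0) -> Eic:
    """Sum centroid intensities within target_mz * ppm_tol * 1e-6 per scan.

    The window is closed on both sides: centroids exactly at the boundary
    are included.  Scans with no in-window centroid contribute zero, so
    the EIC always spans the full run.
    """
    if target_mz <= 0:
        raise ValueError("target m/z must be > 0")
    if ppm_tol <= 0:
        raise ValueError("ppm tolerance must be > 0")
    if len(run.scans) == 0:
        raise ValueError("empty centroid run")
    half_width = target_mz * ppm_tol * 1e-6
    intensity = np.zeros(len(run.scans))
    for i, (_, cen) in enumerate(run.scans):
        cen = np.asarray(cen)
        if cen.size == 0:
            continue
        mask = np.abs(cen[:, 0] - target_mz) <= half_width
        intensity[i] = cen[mask, 1].sum()
    return Eic(target_mz=target_mz, ppm_tol=ppm_tol, rt_s=run.rt_s,
               intensity=intensity)


def integrate_peak(
    eic: Eic,
    rt_window: tuple[float, float],
    baseline_mode: str = "none",
) -> PeakArea:
    """Trapezoidal peak area over ``rt_window``, in intensity*s.

    ``baseline_mode="linear"`` subtracts the chord between the window
    endpoints' intensities before integrating, flooring the corrected
    signal at 0 (a flat EIC then integrates to exactly zero).
    """
    lo, hi = rt_window
    if lo >= hi:
        raise ValueError(f"rt window start must precede end: {rt_window}")
    if lo < eic.rt_s[0] - 1e-9 or hi > eic.rt_s[-1] + 1e-9:
        raise ValueError(
            f"rt window {rt_window} outside EIC range "
            f"[{eic.rt_s[0]}, {eic.rt_s[-1]}] s"
        )
    if baseline_mode not in ("none", "linear"):
        raise ValueError(f"unknown baseline mode {baseline_mode!r}")
    mask = (eic.rt_s >= lo - 1e-9) & (eic.rt_s <= hi + 1e-9)
    t = eic.rt_s[mask]
    y = eic.intensity[mask].astype(float)
    if baseline_mode == "linear":
        chord = np.interp(t, [t[0], t[-1]], [y[0], y[-1]])
        y = np.maximum(y - chord, 0.0)
    area = float(np.trapezoid(y, t))
    apex_rt = float(t[int(np.argmax(y))])
    return PeakArea(area=area, rt_window=(lo, hi), apex_rt=apex_rt,
                    baseline_mode=baseline_mode)


def relative_abundance(
    sample_area: PeakArea,
    control_area: PeakArea,
    detection_floor: float = 0.0,
) -> tuple[float, bool]:
    """Sample/control area ratio plus a detected-above-background flag.

    When the control area does not exceed the detection floor the ratio is
    infinite (the analyte is absent from the control); the flag reports
    whether the sample itself rises above the floor.
    """
    if sample_area.area < 0 or control_area.area < 0:
        raise ValueError("peak areas must be >= 0")
    detected = sample_area.area > detection_floor
    if control_area.area > detection_floor:
        return sample_area.area / control_area.area, detected
    return math.inf, detected


def read_centroid_jsonl(path: str | Path) -> CentroidRun:
    """Read a JSON-lines centroid run: {"rt_s": ..., "centroids": [[mz, i], ...]}."""
    scans: list[tuple[float, np.ndarray]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            cen = np.asarray(obj["centroids"], dtype=float)
            if cen.size == 0:
                cen = np.empty((0, 2))
            scans.append((float(obj["rt_s"]), cen))
    return CentroidRun(scans=scans)


def eic_to_frame(eic: Eic) -> pd.DataFrame:
    return pd.DataFrame({"rt_s": eic.rt_s, "intensity": eic.intensity})
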