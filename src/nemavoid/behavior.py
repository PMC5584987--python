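"""Avoidance-assay scoring and inference.

Scores the three behavioral readouts of the repellent-avoidance study —
phasmid (tail) backing times, amphid (head) halt/no-halt responses, and
chemotaxis plate counts — and runs the study's statistical toolkit:
two-proportion z-tests, one-way ANOVA with Tukey HSD, pooled two-sample
t-tests, Hochberg step-up multiplicity adjustment, Cohen's d, and
power-based sample-size calculations.

Conventions
-----------
* Backing times are in seconds; shorter backing means stronger avoidance.
* Response indices are percentages normalized to same-day controls
  (SDS positive control and/or buffer negative control); the SDS
  self-index is exactly 100 %.
* Significance codes follow the ``***``/``**``/``*``/``ns`` convention at
  0.001 / 0.01 / 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BackingTimeRecord",
    "HeadResponseRecord",
    "ChemotaxisPlate",
    "ResponseIndexResult",
    "StatResult",
    "PowerSpec",
    "response_index_wildtype",
    "response_index_normalized",
    "head_response_proportion",
    "chemotaxis_index",
    "two_sample_z_test",
    "one_way_anova_tukey",
    "two_sample_t_test",
    "hochberg_adjust",
    "cohens_d",
    "sample_size_t",
    "sample_size_two_prop",
    "power_t_test",
    "significance_code",
    "run_figure_analysis",
    "read_backing_csv",
    "read_head_csv",
    "read_plates_csv",
]


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackingTimeRecord:
    """One phasmid dry-drop trial: time (s) the animal backs into the drop."""

    animal_id: str
    genotype: str
    treatment: str
    day: str
    backing_time: float
    censored: bool = False

    def __post_init__(self) -> None:
        if self.backing_time <= 0:
            raise ValueError(
                f"backing_time must be > 0 s, got {self.backing_time!r} "
                f"for animal {self.animal_id!r}"
            )


@dataclass(frozen=True)
class HeadResponseRecord:
    """One amphid dry-drop trial: did the worm halt at the drop?"""

    animal_id: str
    genotype: str
    treatment: str
    day: str
    responded: bool


@dataclass(frozen=True)
class ChemotaxisPlate:
    """Worm counts at the experimental spot, control spot, and in total."""

    plate_id: str
    n_experimental: int
    n_control: int
    n_total: int

    def __post_init__(self) -> None:
        if min(self.n_experimental, self.n_control, self.n_total) < 0:
            raise ValueError(f"plate {self.plate_id!r}: counts must be >= 0")
        if self.n_experimental + self.n_control > self.n_total:
            raise ValueError(
                f"plate {self.plate_id!r}: spot counts exceed total "
                f"({self.n_experimental}+{self.n_control} > {self.n_total})"
            )


@dataclass(frozen=True)
class ResponseIndexResult:
    """A relative response index (%) with the group means behind it."""

    index_percent: float
    mean_treatment_s: float
    mean_reference_s: float
    mean_buffer_s: float | None
    n_treatment: int
    n_reference: int
    n_buffer: int
    normalization_mode: str  # "wildtype_sds" | "mutant_buffer_sds"
    per_day: dict[str, float] | None = None


@dataclass(frozen=True)
class StatResult:
    """Generic inference output for one comparison."""

    statistic: float
    statistic_name: str  # "z" | "t" | "F" | "q"
    p_raw: float
    comparison: tuple[str, str]
    p_adjusted: float | None = None
    effect_size_d: float | None = None
    df: float | None = None
    n_per_group: tuple[int, ...] = ()

    @property
    def p(self) -> float:
        """Adjusted p when present, else the raw p."""
        return self.p_raw if self.p_adjusted is None else self.p_adjusted


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for a sample-size calculation.

    Exactly one of ``cohens_d`` (standardized mean difference) or
    ``proportions`` (p1, p2 for the arcsine effect size h) must be given.
    """

    alpha: float = 0.05
    power: float = 0.8
    cohens_d: float | None = None
    proportions: tuple[float, float] | None = None
    sides: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise ValueError(f"power must be in (0,1), got {self.power}")
        if (self.cohens_d is None) == (self.proportions is None):
            raise ValueError("specify exactly one of cohens_d or proportions")
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")


# ---------------------------------------------------------------------------
# Index scoring
# ---------------------------------------------------------------------------

def _mean_time(records: Sequence[BackingTimeRecord], what: str) -> float:
    if len(records) == 0:
        raise ValueError(f"empty group: {what}")
    return float(np.mean([r.backing_time for r in records]))


def _by_day(records: Sequence[BackingTimeRecord]) -> dict[str, list[BackingTimeRecord]]:
    out: dict[str, list[BackingTimeRecord]] = {}
    for r in records:
        out.setdefault(r.day, []).append(r)
    return out


def response_index_wildtype(
    treatment: Sequence[BackingTimeRecord],
    sds_reference: Sequence[BackingTimeRecord],
    per_day: bool = False,
) -> ResponseIndexResult:
    """Relative response index of a treatment against the SDS positive control.

    index = 100 * mean(T_treatment) / mean(T_SDS), so the SDS control
    scores 100 % by construction.  With ``per_day=True`` the ratio is
    computed within each assay day against the same-day SDS control and
    the per-day indices are averaged with equal weights.
    """
    mean_treat = _mean_time(treatment, "treatment")
    mean_sds = _mean_time(sds_reference, "sds_reference")
    if mean_sds == 0:
        raise ValueError("degenerate SDS control: zero mean backing time")

    per_day_map: dict[str, float] | None = None
    if per_day:
        treat_days = _by_day(treatment)
        sds_days = _by_day(sds_reference)
        missing = sorted(set(treat_days) - set(sds_days))
        if missing:
            raise ValueError(f"no same-day SDS control for day(s): {missing}")
        per_day_map = {
            day: 100.0 * _mean_time(recs, f"treatment day {day}")
            / _mean_time(sds_days[day], f"SDS day {day}")
            for day, recs in sorted(treat_days.items())
        }
        index = float(np.mean(list(per_day_map.values())))
    else:
        index = 100.0 * mean_treat / mean_sds

    return ResponseIndexResult(
        index_percent=index,
        mean_treatment_s=mean_treat,
        mean_reference_s=mean_sds,
        mean_buffer_s=None,
        n_treatment=len(treatment),
        n_reference=len(sds_reference),
        n_buffer=0,
        normalization_mode="wildtype_sds",
        per_day=per_day_map,
    )


def response_index_normalized(
    mut_treatment: Sequence[BackingTimeRecord],
    mut_buffer: Sequence[BackingTimeRecord],
    wt_sds: Sequence[BackingTimeRecord],
    wt_buffer: Sequence[BackingTimeRecord],
) -> ResponseIndexResult:
    """Buffer-and-SDS normalized response index for a mutant group.

    index = 100 * [mean(T_exp,mut)/mean(T_buf,mut)]
                / [mean(T_SDS,wt)/mean(T_buf,wt)]

    The mutant treatment/buffer ratio is normalized by the same-day
    wild-type SDS/buffer ratio; applied to the wild type on SDS itself
    this reduces to the plain SDS-normalized index.
    """
    m_exp = _mean_time(mut_treatment, "mut_treatment")
    m_buf = _mean_time(mut_buffer, "mut_buffer")
    w_sds = _mean_time(wt_sds, "wt_sds")
    w_buf = _mean_time(wt_buffer, "wt_buffer")
    if 0 in (m_buf, w_sds, w_buf):
        raise ValueError("zero mean in a normalization denominator group")

    index = 100.0 * (m_exp / m_buf) / (w_sds / w_buf)
    return ResponseIndexResult(
        index_percent=index,
        mean_treatment_s=m_exp,
        mean_reference_s=w_sds,
        mean_buffer_s=m_buf,
        n_treatment=len(mut_treatment),
        n_reference=len(wt_sds),
        n_buffer=len(mut_buffer),
        normalization_mode="mutant_buffer_sds",
    )


def head_response_proportion(
    records: Sequence[HeadResponseRecord],
) -> tuple[float, int]:
    """Fraction of trials in which the worm halted at the dry drop."""
    if len(records) == 0:
        raise ValueError("empty head-response group")
    n = len(records)
    return sum(r.responded for r in records) / n, n


def chemotaxis_index(plate: ChemotaxisPlate) -> float:
    """(n_experimental - n_control) / n_total, in [-1, 1]."""
    if plate.n_total == 0:
        raise ValueError(f"plate {plate.plate_id!r}: zero total worms")
    return (plate.n_experimental - plate.n_control) / plate.n_total


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------

def two_sample_z_test(
    p1: float, n1: int, p2: float, n2: int, sides: int = 2,
    labels: tuple[str, str] = ("group1", "group2"),
) -> StatResult:
    """Two-independent-sample z-test for proportions (pooled variance).

    z = (p1 - p2) / sqrt(pbar (1-pbar) (1/n1 + 1/n2)) with the pooled
    proportion pbar.  A one-sided test takes the alternative in the
    direction of the observed difference.
    """
    for p, n, side in ((p1, n1, "1"), (p2, n2, "2")):
        if not 0 <= p <= 1:
            raise ValueError(f"p{side} outside [0,1]: {p}")
        if n < 1:
            raise ValueError(f"n{side} must be >= 1: {n}")
    pbar = (p1 * n1 + p2 * n2) / (n1 + n2)
    if pbar in (0.0, 1.0):
        raise ValueError("degenerate pooled proportion (all failures or all successes)")
    expected = [p1 * n1, (1 - p1) * n1, p2 * n2, (1 - p2) * n2]
    if min(expected) < 5:
        warnings.warn(
            "normal approximation is questionable: an expected cell count "
            f"is below 5 (min {min(expected):.1f})",
            stacklevel=2,
        )
    se = math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    if sides == 2:
        p = 2 * stats.norm.sf(abs(z))
    else:
        p = stats.norm.sf(abs(z))
    return StatResult(
        statistic=z, statistic_name="z", p_raw=float(p),
        comparison=labels, n_per_group=(n1, n2),
    )


def two_sample_t_test(
    x: Sequence[float], y: Sequence[float], sides: int = 2,
    labels: tuple[str, str] = ("group1", "group2"),
) -> StatResult:
    """Classical pooled-variance two-sample t-test with Cohen's d attached.

    Degenerate zero-variance inputs: equal means give t = 0, p = 1;
    unequal means give an infinite t and p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / df
    diff = float(np.mean(x) - np.mean(y))
    if sp2 == 0:
        if diff == 0:
            t, p, d = 0.0, 1.0, 0.0
        else:
            t = math.inf if diff > 0 else -math.inf
            p, d = 0.0, math.copysign(math.inf, diff)
    else:
        t = diff / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(abs(t), df) if sides == 2 else float(stats.t.sf(abs(t), df))
        d = diff / math.sqrt(sp2)
    return StatResult(
        statistic=float(t), statistic_name="t", p_raw=float(p),
        comparison=labels, effect_size_d=float(d), df=float(df),
        n_per_group=(n1, n2),
    )


def one_way_anova_tukey(
    groups: Mapping[str, Sequence[float]],
) -> list[StatResult]:
    """One-way ANOVA F-test plus all pairwise Tukey HSD comparisons.

    Returns the overall F result first (comparison ``("overall", "F")``),
    followed by one q-statistic result per pair with the family-wise
    adjusted p from the studentized-range distribution.
    """
    if len(groups) < 3:
        raise ValueError("need >= 3 groups for ANOVA + Tukey")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    for lab, a in zip(labels, arrays):
        if len(a) < 2:
            raise ValueError(f"group {lab!r} has < 2 observations")

    f_stat, f_p = stats.f_oneway(*arrays)
    n_total = sum(len(a) for a in arrays)
    k = len(arrays)
    df_within = n_total - k
    mse = sum((len(a) - 1) * np.var(a, ddof=1) for a in arrays) / df_within

    results = [
        StatResult(
            statistic=float(f_stat), statistic_name="F", p_raw=float(f_p),
            comparison=("overall", "F"), df=float(df_within),
            n_per_group=tuple(len(a) for a in arrays),
        )
    ]
    hsd = stats.tukey_hsd(*arrays)
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(np.mean(arrays[i]) - np.mean(arrays[j]))
            if mse > 0:
                se = math.sqrt(mse / 2 * (1 / len(arrays[i]) + 1 / len(arrays[j])))
                q = abs(diff) / se
            else:
                q = 0.0 if diff == 0 else math.inf
            results.append(
                StatResult(
                    statistic=q, statistic_name="q",
                    p_raw=float(hsd.pvalue[i, j]),
                    p_adjusted=float(hsd.pvalue[i, j]),  # Tukey p is family-wise
                    comparison=(labels[i], labels[j]),
                    df=float(df_within),
                    n_per_group=(len(arrays[i]), len(arrays[j])),
                )
            )
    return results


def hochberg_adjust(p_values: Sequence[float]) -> list[float]:
    """Hochberg step-up adjusted p-values, in the input order.

    With p sorted ascending, adj(m) = p(m) and
    adj(i) = min(adj(i+1), (m - i + 1) * p(i)), capped at 1.  Adjusted
    values never fall below the raw ones.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):  # rank 0-based from largest p down
        running = min(running, (m - rank) * p[order[rank]])
        adj_sorted[rank] = running
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return [float(v) for v in adj]


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d: (mean(x) - mean(y)) / pooled sd; sign preserved."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled standard deviation")
    return float((np.mean(x) - np.mean(y)) / math.sqrt(sp2))


# ---------------------------------------------------------------------------
# Power and sample size
# ---------------------------------------------------------------------------

def power_t_test(n_per_group: int, d: float, alpha: float = 0.05,
                 sides: int = 2) -> float:
    """Power of a two-sample t-test at effect size d with n per group.

    Uses the noncentral t distribution: df = 2n - 2, noncentrality
    nc = d * sqrt(n/2), power = P(|T'| > t_crit).
    """
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    nc = d * math.sqrt(n_per_group / 2)
    if sides == 2:
        crit = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))
    crit = stats.t.ppf(1 - alpha, df)
    return float(stats.nct.sf(crit, df, nc))


def sample_size_t(spec: PowerSpec) -> int:
    """Smallest per-group n whose noncentral-t power reaches the target.

    Solved by scanning n upward, mirroring how practitioners' power
    calculators report per-group sample sizes rounded up.
    """
    if spec.cohens_d is None:
        raise ValueError("PowerSpec must carry cohens_d for sample_size_t")
    d = spec.cohens_d
    if d <= 0:
        raise ValueError("cohens_d must be > 0")
    for n in range(2, 1_000_000):
        if power_t_test(n, d, spec.alpha, spec.sides) >= spec.power:
            return n
    raise ValueError("target power unreachable at any feasible n")


def sample_size_two_prop(spec: PowerSpec) -> tuple[float, int]:
    """Arcsine effect size h and per-group n for a two-proportion test.

    h = |2 arcsin(sqrt(p2)) - 2 arcsin(sqrt(p1))|;
    n = round(2 (z_{1-alpha/2} + z_{power})^2 / h^2) under the
    normal-approximation two-sample formula applied to h.
    """
    if spec.proportions is None:
        raise ValueError("PowerSpec must carry proportions for sample_size_two_prop")
    p1, p2 = spec.proportions
    for p, name in ((p1, "p1"), (p2, "p2")):
        if not 0 < p < 1:
            raise ValueError(f"{name} must lie in (0,1), got {p}")
    if p1 == p2:
        raise ValueError("p1 == p2: no effect to power for")
    h = abs(2 * math.asin(math.sqrt(p2)) - 2 * math.asin(math.sqrt(p1)))
    z_alpha = stats.norm.ppf(1 - spec.alpha / spec.sides)
    z_power = stats.norm.ppf(spec.power)
    n = round(2 * (z_alpha + z_power) ** 2 / h**2)
    return h, int(n)


# ---------------------------------------------------------------------------
# Figure-style analysis driver
# ---------------------------------------------------------------------------

def significance_code(p: float) -> str:
    """Map a p-value to the figure-legend code: ***, **, *, or ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def run_figure_analysis(
    dataset: Mapping[str, object],
    plan: Mapping[str, object],
) -> pd.DataFrame:
    """Run a figure panel's comparison families and tabulate the results.

    ``dataset`` maps group label to its data: a sequence of backing times
    (tail assays) or a sequence of :class:`HeadResponseRecord` (head
    assays).  ``plan["families"]`` is a list of dicts, each with:

    * ``name`` — family label,
    * ``test`` — ``"z"`` (head proportions), ``"t_hochberg"`` (tail,
      pairwise t with Hochberg), or ``"anova_tukey"``,
    * ``comparisons`` — pairs of group labels (for z / t_hochberg), or
    * ``groups`` — group labels (for anova_tukey).

    Each family with more than one comparison is multiplicity-adjusted,
    and significance codes are always derived from the adjusted p.
    """
    families = plan.get("families")
    if not families:
        raise ValueError("analysis plan has no families")

    rows: list[dict[str, object]] = []
    for fam in families:
        name = fam["name"]
        test = fam["test"]
        needed: list[str] = []
        if test in ("z", "t_hochberg"):
            for a, b in fam["comparisons"]:
                needed += [a, b]
        elif test == "anova_tukey":
            needed = list(fam["groups"])
        else:
            raise ValueError(f"family {name!r}: unknown test {test!r}")
        absent = sorted({g for g in needed if g not in dataset})
        if absent:
            raise ValueError(f"family {name!r} references absent groups: {absent}")

        results: list[StatResult] = []
        if test == "z":
            for a, b in fam["comparisons"]:
                pa, na = head_response_proportion(dataset[a])
                pb, nb = head_response_proportion(dataset[b])
                results.append(two_sample_z_test(pa, na, pb, nb, labels=(a, b)))
        elif test == "t_hochberg":
            for a, b in fam["comparisons"]:
                results.append(
                    two_sample_t_test(dataset[a], dataset[b], labels=(a, b))
                )
        else:  # anova_tukey
            results = one_way_anova_tukey({g: dataset[g] for g in fam["groups"]})

        if test in ("z", "t_hochberg"):
            adjusted = hochberg_adjust([r.p_raw for r in results])
            results = [
                StatResult(
                    statistic=r.statistic, statistic_name=r.statistic_name,
                    p_raw=r.p_raw,
                    p_adjusted=adj if len(results) > 1 else None,
                    comparison=r.comparison, effect_size_d=r.effect_size_d,
                    df=r.df, n_per_group=r.n_per_group,
                )
                for r, adj in zip(results, adjusted)
            ]

        for r in results:
            rows.append(
                {
                    "family": name,
                    "test": test,
                    "group_a": r.comparison[0],
                    "group_b": r.comparison[1],
                    "statistic_name": r.statistic_name,
                    "statistic": r.statistic,
                    "df": r.df,
                    "p_raw": r.p_raw,
                    "p_adjusted": r.p_adjusted,
                    "effect_size_d": r.effect_size_d,
                    "n_per_group": "/".join(str(n) for n in r.n_per_group),
                    "code": significance_code(r.p),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV ingestion
# ---------------------------------------------------------------------------

def read_backing_csv(path) -> list[BackingTimeRecord]:
    """Read phasmid trials from CSV: animal_id,genotype,treatment,day,backing_time_s,censored."""
    df = pd.read_csv(path)
    return [
        BackingTimeRecord(
            animal_id=str(r.animal_id), genotype=str(r.genotype),
            treatment=str(r.treatment), day=str(r.day),
            backing_time=float(r.backing_time_s), censored=bool(r.censored),
        )
        for r in df.itertuples(index=False)
    ]


def read_head_csv(path) -> list[HeadResponseRecord]:
    """Read amphid trials from CSV: animal_id,genotype,treatment,day,responded."""
    df = pd.read_csv(path)
    return [
        HeadResponseRecord(
            animal_id=str(r.animal_id), genotype=str(r.genotype),
            treatment=str(r.treatment), day=str(r.day),
            responded=bool(r.responded),
        )
        for r in df.itertuples(index=False)
    ]


def read_plates_csv(path) -> list[ChemotaxisPlate]:
    """Read chemotaxis plates from CSV: plate_id,n_experimental,n_control,n_total."""
    df = pd.read_csv(path)
    return [
        ChemotaxisPlate(
            plate_id=str(r.plate_id), n_experimental=int(r.n_experimental),
            n_control=int(r.n_control), n_total=int(r.n_total),
        )
        for r in df.itertuples(index=False)
    ]
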