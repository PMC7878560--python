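"""Behavioral and physiological summary metrics with two-group tests.

Covers the novel-object-recognition investigation ratio, Morris
water-maze probe-trial summaries, urine albumin:creatinine proteinuria,
litter-averaged pup weights, and pooled-variance independent-samples
t-tests reported as ``t(df) = ..., p = ...``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UnscorableTrialError",
    "InvalidAssayError",
    "ExplorationRecord",
    "ProbeTrialRecord",
    "UrineAssayRecord",
    "GroupComparison",
    "investigation_ratio",
    "nor_summary",
    "proteinuria_ratio",
    "pup_weight_summary",
    "two_sample_t",
    "probe_trial_summary",
    "mwm_learning_curve",
    "simulate_nor_cohort",
]

logger = logging.getLogger(__name__)


class UnscorableTrialError(ValueError):
    """Trial with zero total exploration cannot yield a ratio."""


class InvalidAssayError(ValueError):
    """Assay readings outside their valid domain."""


@dataclass(frozen=True)
class ExplorationRecord:
    """One novel-object-recognition test-phase trial."""

    animal_id: str
    timepoint: str  # e.g. "3mo" | "8mo" | "12mo"
    t_novel: float
    t_familiar: float

    def __post_init__(self) -> None:
        if self.t_novel < 0 or self.t_familiar < 0:
            raise ValueError("exploration times must be >= 0")


@dataclass(frozen=True)
class ProbeTrialRecord:
    """Water-maze probe trial (60 s free swim, platform removed)."""

    animal_id: str
    time_in_target_quadrant: float
    distance_in_target_quadrant: float
    platform_crossings: int
    trial_duration: float = 60.0

    def __post_init__(self) -> None:
        if not 0 <= self.time_in_target_quadrant <= self.trial_duration:
            raise ValueError("quadrant time must lie within the trial duration")
        if self.distance_in_target_quadrant < 0:
            raise ValueError("distance must be >= 0")
        if self.platform_crossings < 0 or int(self.platform_crossings) != self.platform_crossings:
            raise ValueError("crossings must be a non-negative integer")


@dataclass(frozen=True)
class UrineAssayRecord:
    """Duplicate albumin/creatinine ELISA readings for one sample."""

    animal_id: str
    timepoint: str
    albumin: tuple[float, ...]
    creatinine: tuple[float, ...]
    dilution_factor: float = 10.0


@dataclass(frozen=True)
class GroupComparison:
    """Two-group summary: means +/- SEM and an independent-samples t-test."""

    label: str
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    t: float
    df: float
    p: float
    equal_var: bool = True

    def __str__(self) -> str:  # the paper-style reporting form
        return (
            f"{self.label}: {self.mean_a:.3g} ± {self.sem_a:.2g} (n={self.n_a}) vs "
            f"{self.mean_b:.3g} ± {self.sem_b:.2g} (n={self.n_b}); "
            f"t({self.df:g}) = {self.t:.2f}, p = {self.p:.3g}"
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label, "mean_a": self.mean_a, "sem_a": self.sem_a,
            "n_a": self.n_a, "mean_b": self.mean_b, "sem_b": self.sem_b,
            "n_b": self.n_b, "t": self.t, "df": self.df, "p": self.p,
        }


def investigation_ratio(rec_or_novel, t_familiar: float | None = None) -> float:
    """Novel-object preference: t_novel / (t_novel + t_familiar).

    0.5 is indifference; higher values indicate recognition memory.
    Accepts an :class:`ExplorationRecord` or the two times directly.
    """
    if isinstance(rec_or_novel, ExplorationRecord):
        t_novel, t_fam = rec_or_novel.t_novel, rec_or_novel.t_familiar
    else:
        if t_familiar is None:
            raise TypeError("pass an ExplorationRecord or (t_novel, t_familiar)")
        t_novel, t_fam = float(rec_or_novel), float(t_familiar)
    if t_novel < 0 or t_fam < 0:
        raise ValueError("exploration times must be >= 0")
    total = t_novel + t_fam
    if total <= 0:
        raise UnscorableTrialError("zero total exploration time")
    return t_novel / total


def nor_summary(records: pd.DataFrame | list[ExplorationRecord]) -> pd.DataFrame:
    """Per-animal investigation ratios; unscorable trials are dropped.

    Expects columns ``animal_id, timepoint, t_novel, t_familiar`` (or a
    list of records).
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([r.__dict__ for r in records])
    out = records.copy()
    total = out["t_novel"] + out["t_familiar"]
    unscorable = total <= 0
    if unscorable.any():
        logger.warning("nor_summary: dropping %d unscorable trials", int(unscorable.sum()))
        out = out[~unscorable]
        total = total[~unscorable]
    out["investigation_ratio"] = out["t_novel"] / total
    return out


def proteinuria_ratio(rec: UrineAssayRecord) -> float:
    """Albumin:creatinine ratio from duplicate diluted readings.

    Duplicates are averaged; the common dilution factor cancels in the
    ratio (it is applied to both numerator and denominator).
    """
    if len(rec.albumin) == 0 or len(rec.creatinine) == 0:
        raise InvalidAssayError("duplicate readings missing")
    alb = float(np.mean(rec.albumin)) * rec.dilution_factor
    crea = float(np.mean(rec.creatinine)) * rec.dilution_factor
    if crea <= 0:
        raise InvalidAssayError("creatinine must be > 0")
    if alb < 0:
        raise InvalidAssayError("albumin must be >= 0")
    logger.debug("proteinuria_ratio: dilution factor %g cancels", rec.dilution_factor)
    return alb / crea


def pup_weight_summary(weights: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Litter-averaged pup weights; the mother is the statistical unit.

    ``weights`` has columns ``mother_id, genotype, weight`` with one row
    per pup.  Returns (per-mother table, per-genotype group table with
    mean, SEM and n of litter means).  Empty litters are excluded.
    """
    valid = weights.dropna(subset=["weight"])
    dropped = set(weights["mother_id"]) - set(valid["mother_id"])
    if dropped:
        logger.warning("pup_weight_summary: excluding empty litters %s", sorted(dropped))
    per_mother = (
        valid.groupby(["mother_id", "genotype"], as_index=False)["weight"]
        .mean()
        .rename(columns={"weight": "litter_mean"})
    )
    group = (
        per_mother.groupby("genotype")["litter_mean"]
        .agg(mean="mean", sem=lambda x: stats.sem(x, ddof=1), n="count")
        .reset_index()
    )
    return per_mother, group


def two_sample_t(
    group_a: np.ndarray,
    group_b: np.ndarray,
    label: str = "",
    equal_var: bool = True,
) -> GroupComparison:
    """Independent-samples t-test (pooled variance by default; Welch optional)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else float(res.df)
    return GroupComparison(
        label=label,
        mean_a=float(a.mean()), sem_a=float(stats.sem(a)), n_a=a.size,
        mean_b=float(b.mean()), sem_b=float(stats.sem(b)), n_b=b.size,
        t=float(res.statistic), df=float(df), p=float(res.pvalue),
        equal_var=equal_var,
    )


_PROBE_METRICS = (
    "time_in_target_quadrant",
    "distance_in_target_quadrant",
    "platform_crossings",
)


def probe_trial_summary(
    records: pd.DataFrame, group_col: str = "group"
) -> list[GroupComparison]:
    """Group comparisons of the three probe-trial spatial-memory metrics."""
    groups = sorted(records[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    out = []
    for metric in _PROBE_METRICS:
        if metric not in records.columns:
            continue
        a = records.loc[records[group_col] == groups[0], metric].to_numpy()
        b = records.loc[records[group_col] == groups[1], metric].to_numpy()
        out.append(two_sample_t(a, b, label=f"{metric} ({groups[0]} vs {groups[1]})"))
    return out


def mwm_learning_curve(
    latencies: pd.DataFrame, group_col: str = "group"
) -> list[GroupComparison]:
    """Per-day escape-latency comparisons during water-maze training.

    ``latencies`` has columns ``animal_id, group, day, latency``; one
    pooled t-test per training day (no repeated-measures model).
    """
    groups = sorted(latencies[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    out = []
    for day, sub in latencies.groupby("day"):
        a = sub.loc[sub[group_col] == groups[0], "latency"].to_numpy()
        b = sub.loc[sub[group_col] == groups[1], "latency"].to_numpy()
        out.append(two_sample_t(a, b, label=f"day {day} escape latency"))
    return out


def simulate_nor_cohort(
    n: int,
    mean_ratio: float,
    sd_ratio: float,
    *,
    timepoint: str = "12mo",
    prefix: str = "m",
    mean_total_time: float = 30.0,
    rng: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Synthetic novel-object cohort with Beta-distributed true ratios.

    Per-animal investigation ratios are drawn from the Beta distribution
    with mean ``mean_ratio`` and standard deviation ``sd_ratio`` (for a
    group whose reported dispersion is a SEM, ``sd = sem * sqrt(n)``);
    total exploration time is Gamma-distributed around
    ``mean_total_time`` seconds and split into novel/familiar times.
    """
    if not 0 < mean_ratio < 1:
        raise ValueError("mean_ratio must lie in (0, 1)")
    max_var = mean_ratio * (1 - mean_ratio)
    if not 0 < sd_ratio ** 2 < max_var:
        raise ValueError(f"sd_ratio^2 must lie in (0, {max_var:.4g})")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    conc = max_var / sd_ratio ** 2 - 1.0  # alpha + beta
    alpha = mean_ratio * conc
    beta = (1.0 - mean_ratio) * conc
    ratios = rng.beta(alpha, beta, size=n)
    totals = rng.gamma(shape=16.0, scale=mean_total_time / 16.0, size=n)
    return pd.DataFrame(
        {
            "animal_id": [f"{prefix}{i:02d}" for i in range(n)],
            "timepoint": timepoint,
            "t_novel": ratios * totals,
            "t_familiar": (1.0 - ratios) * totals,
        }
    )
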