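"""Bud-break timing heterogeneity statistics.

Dormant buds within a genetically identical cohort do not break bud on the
same day; the spread of days-to-bud-break is the biological signal (bet
hedging). Per condition/genotype group this module computes percent bud
break, the mean day, the sample variance (n−1 denominator, suited to small
cohorts of 10–15 plants), the coefficient of variation CV = sd/mean
(dimensionless; multiplicative-rescaling invariant), and histogram summaries.

Variance and CV are always emitted side by side with explicit column names,
since the two are easily conflated in prose.

CSV input: ``plant_id, label, day_of_budbreak`` with a blank day for plants
that never broke bud. CSV output: ``label, n_total, n_broken, percent, mean,
variance, cv``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class TimingSample:
    """Days-to-bud-break for one genotype+condition group."""

    label: str
    days: list                  # one entry per plant that broke bud
    n_total: int                # plants assayed

    def __post_init__(self):
        self.days = [float(d) for d in self.days]
        if any(d <= 0 for d in self.days):
            raise ValueError("days to bud break must be positive")
        if len(self.days) > self.n_total:
            raise ValueError("more bud-break events than plants assayed")

    @property
    def n_broken(self) -> int:
        return len(self.days)


def heterogeneity(sample: TimingSample) -> tuple:
    """(mean, sample variance, CV) of days-to-bud-break.

    Sample variance uses the n−1 denominator; CV = sd / mean is reported as
    a ratio (multiply by 100 for percent).
    """
    if sample.n_broken < 2:
        raise ValueError("insufficient events: need >= 2 bud-break days")
    days = np.asarray(sample.days, dtype=float)
    mean = float(days.mean())
    var = float(days.var(ddof=1))
    cv = float(np.sqrt(var) / mean)
    return mean, var, cv


def percent_budbreak(sample: TimingSample) -> float:
    """Percentage of assayed plants that broke bud."""
    if sample.n_total < 1:
        raise ValueError("n_total must be >= 1")
    return 100.0 * sample.n_broken / sample.n_total


def timing_histogram(sample: TimingSample, bin_width: float = 1.0) -> pd.DataFrame:
    """Left-closed right-open bins from floor(min) to ceil(max).

    Counts always sum to ``n_broken``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not sample.days:
        raise ValueError("no bud-break events to bin")
    days = np.asarray(sample.days, dtype=float)
    lo = float(np.floor(days.min()))
    idx = np.floor((days - lo) / bin_width).astype(int)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    edges = lo + bin_width * np.arange(n_bins + 1)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count": counts,
    })


def read_timing_csv(path: str | Path) -> list:
    """Read ``plant_id, label, day_of_budbreak`` rows into TimingSamples.

    A blank ``day_of_budbreak`` means the plant never broke bud: it counts
    toward ``n_total`` but contributes no event day.
    """
    df = pd.read_csv(path, dtype={"plant_id": str, "label": str})
    required = {"plant_id", "label", "day_of_budbreak"}
    if not required.issubset(df.columns):
        raise ValueError(f"timing CSV must have columns {sorted(required)}")
    samples = []
    for label, grp in df.groupby("label", sort=True):
        days = grp["day_of_budbreak"].dropna().astype(float).tolist()
        samples.append(TimingSample(label=str(label), days=days,
                                    n_total=len(grp)))
    return samples


def summarize(samples: list) -> pd.DataFrame:
    """Per-group summary table: percent bud break, mean, variance, CV."""
    rows = []
    for s in samples:
        if s.n_broken >= 2:
            mean, var, cv = heterogeneity(s)
        else:
            mean = float(np.mean(s.days)) if s.days else np.nan
            var = np.nan
            cv = np.nan
        rows.append({
            "label": s.label,
            "n_total": s.n_total,
            "n_broken": s.n_broken,
            "percent": percent_budbreak(s),
            "mean": mean,
            "variance": var,
            "cv": cv,
        })
    return pd.DataFrame(rows, columns=["label", "n_total", "n_broken",
                                       "percent", "mean", "variance", "cv"])
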