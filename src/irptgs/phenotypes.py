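"""Silencing-phenotype statistics for the two-reporter system.

T2 families are scored into four anthocyanin classes (red = no silencing,
red-yellow = weak, yellow-green = trace pigment, green = complete silencing);
family efficacy is (green + 0.5 * yellow-green) / total.  GUS silencing in
the matched T1 plants is 1 - activity / wild-type mean activity.  Cross-
construct differences in sRNA output are compared with a chi-square test of
homogeneity on cumulative per-fragment counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ANTHOCYANIN_CLASSES = ("red", "red_yellow", "yellow_green", "green")


@dataclass(frozen=True)
class T2FamilyCounts:
    family: str
    construct: str
    red: int
    red_yellow: int
    yellow_green: int
    green: int

    @property
    def n_total(self) -> int:
        return self.red + self.red_yellow + self.yellow_green + self.green


@dataclass
class StatResult:
    statistic: float
    p: float
    n: int
    df: int | None = None


def silencing_efficacy(counts: T2FamilyCounts) -> float:
    """Family efficacy: completely green plants plus half the trace-pigment
    (yellow-green) plants, divided by the total scored."""
    if counts.n_total == 0:
        raise ValueError("family with zero plants")
    return (counts.green + 0.5 * counts.yellow_green) / counts.n_total


def gus_silencing(activities: Sequence[float], wildtype_mean: float) -> float:
    """GUS silencing of a T1 plant from replicate activities: 1 - act/WT."""
    if wildtype_mean <= 0:
        raise ValueError("wild-type mean activity must be positive")
    return 1.0 - float(np.mean(activities)) / wildtype_mean


def reporter_correlation(
    gus: Sequence[float], efficacy: Sequence[float]
) -> StatResult:
    """Pearson correlation between T1 GUS silencing and matched T2 efficacy."""
    gus = np.asarray(gus, dtype=float)
    eff = np.asarray(efficacy, dtype=float)
    if len(gus) != len(eff):
        raise ValueError("unequal numbers of matched pairs")
    if len(gus) < 3:
        raise ValueError("need at least 3 matched pairs")
    if np.ptp(gus) == 0 or np.ptp(eff) == 0:
        raise ValueError("zero-variance reporter values")
    r, p = stats.pearsonr(gus, eff)
    return StatResult(statistic=float(r), p=float(p), n=len(gus))


def construct_chisq(table: pd.DataFrame | np.ndarray) -> StatResult:
    """Chi-square test of homogeneity on cumulative sRNA counts.

    Rows are constructs, columns trigger fragments (or vice versa); the
    statistic compares whether fragments yield sRNA in the same proportions
    across constructs.  Zero-expected cells are an error: pool categories.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a 2-D contingency table with >= 2 rows and columns")
    chi2, p, df, expected = stats.chi2_contingency(arr, correction=False)
    if (expected <= 0).any():
        raise ValueError("zero expected cell counts; pool sparse categories first")
    return StatResult(statistic=float(chi2), p=float(p), n=int(arr.sum()), df=int(df))


def efficacy_table(families: Sequence[T2FamilyCounts]) -> pd.DataFrame:
    rows = [
        {
            "family": f.family,
            "construct": f.construct,
            "n_total": f.n_total,
            "efficacy": silencing_efficacy(f),
        }
        for f in families
    ]
    return pd.DataFrame(rows)
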