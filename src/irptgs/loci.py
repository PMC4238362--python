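"""sRNA locus definition and differential-abundance calling.

A locus is a maximal run of >= ``min_run`` consecutive nucleotides covered by
at least ``min_cov`` per-million sequences *in every library analyzed*.
A difference between silenced and control libraries is significant only when
it exceeds the fold threshold in the same direction in BOTH silenced-vs-
control comparisons (the two strongly silenced libraries vs the wild-type
control).  Calls above twofold carry a ``strong`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageProfile, SizeClassProfile, fold_change


@dataclass(frozen=True)
class Locus:
    chrom: str
    start: int  # 0-based half-open
    end: int
    size_class: str

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("empty locus interval")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DifferentialCall:
    locus: Locus
    abundance: dict[str, float]  # per-library per-million sums over the interval
    fold: dict[str, float]  # per silenced library, vs control (max/min ratio)
    direction: str  # "over" | "under" | "none"
    significant: bool
    strong: bool  # > twofold in both comparisons
    infinite_fold: bool = False


def call_loci(
    coverages: Mapping[str, Mapping[str, CoverageProfile]],
    size_cls: str,
    *,
    min_run: int = 10,
    min_cov: float = 10.0,
) -> list[Locus]:
    """Call loci from per-library, per-chromosome coverage.

    ``coverages[library][chrom]`` is a :class:`CoverageProfile`.  A position
    qualifies iff its per-million coverage in ``size_cls`` is >= ``min_cov``
    in every library; maximal qualifying runs of length >= ``min_run``
    become loci.
    """
    if min_run <= 0 or min_cov <= 0:
        raise ValueError("thresholds must be positive")
    libs = list(coverages)
    if not libs:
        return []
    chrom_sets = [set(coverages[lib]) for lib in libs]
    if any(s != chrom_sets[0] for s in chrom_sets):
        raise ValueError("libraries cover different reference sets")
    loci: list[Locus] = []
    for chrom in sorted(chrom_sets[0]):
        mask = None
        for lib in libs:
            pm = coverages[lib][chrom].per_million(size_cls)
            ok = pm >= min_cov
            mask = ok if mask is None else (mask & ok)
        # maximal runs of qualifying positions
        padded = np.concatenate(([False], mask, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= min_run:
                loci.append(Locus(chrom=chrom, start=int(s), end=int(e), size_class=size_cls))
    return loci


def differential_loci(
    loci: Sequence[Locus],
    coverages: Mapping[str, Mapping[str, CoverageProfile]],
    control: str,
    silenced: Sequence[str],
    *,
    fold_threshold: float = 1.5,
    strong_threshold: float = 2.0,
) -> list[DifferentialCall]:
    """Score loci for differential abundance between silenced and control.

    Locus abundance is the per-million coverage summed over the interval.
    ``significant`` requires fold > ``fold_threshold`` in the SAME direction
    against the control in every silenced library.
    """
    if len(silenced) < 2:
        raise ValueError("need at least two silenced libraries for the both-comparison rule")
    calls = []
    for locus in loci:
        abundance = {}
        for lib in (control, *silenced):
            pm = coverages[lib][locus.chrom].per_million(locus.size_class)
            abundance[lib] = float(pm[locus.start : locus.end].sum())
        a0 = abundance[control]
        folds: dict[str, float] = {}
        dirs: list[str] = []
        infinite = False
        for lib in silenced:
            a = abundance[lib]
            if a0 == 0:
                infinite = True
                folds[lib] = float("inf")
                dirs.append("over" if a > 0 else "none")
                continue
            fc = fold_change(a0, a)
            folds[lib] = fc.fold
            dirs.append({"increase": "over", "decrease": "under", "none": "none", "undefined": "under"}[fc.direction])
        exceed = [folds[lib] > fold_threshold for lib in silenced]
        same_dir = len(set(dirs)) == 1 and dirs[0] != "none"
        significant = all(exceed) and same_dir
        strong = significant and all(folds[lib] > strong_threshold for lib in silenced)
        direction = dirs[0] if same_dir else "none"
        calls.append(
            DifferentialCall(
                locus=locus,
                abundance=abundance,
                fold=folds,
                direction=direction,
                significant=significant,
                strong=strong,
                infinite_fold=infinite,
            )
        )
    return calls


@dataclass
class ChromDistribution:
    bin_size: int
    counts: dict[str, np.ndarray]  # per-chromosome binned locus counts
    pericentromeric_fraction: float
    window_fraction: float  # genome-length fraction covered by the windows
    n_loci: int


def chrom_distribution(
    calls: Sequence[DifferentialCall] | Sequence[Locus],
    chromosomes: Sequence[tuple[str, int, int]],
    *,
    bin_size: int = 10_000,
    centromere_window: float = 0.10,
) -> ChromDistribution:
    """Bin loci along chromosomes and measure pericentromeric concentration.

    ``chromosomes`` is ``(name, length, centromere_position)`` triples; the
    pericentromeric window is the centromere +/- ``centromere_window`` of the
    chromosome length.
    """
    loci = [c.locus if isinstance(c, DifferentialCall) else c for c in calls]
    counts: dict[str, np.ndarray] = {}
    windows: dict[str, tuple[float, float]] = {}
    total_len = 0
    window_len = 0.0
    for name, length, cen in chromosomes:
        counts[name] = np.zeros(int(np.ceil(length / bin_size)), dtype=int)
        half = centromere_window * length
        lo, hi = max(0.0, cen - half), min(float(length), cen + half)
        windows[name] = (lo, hi)
        total_len += length
        window_len += hi - lo
    in_window = 0
    for locus in loci:
        if locus.chrom not in counts:
            raise KeyError(f"locus on unknown chromosome {locus.chrom!r}")
        mid = (locus.start + locus.end) / 2
        counts[locus.chrom][int(mid // bin_size)] += 1
        lo, hi = windows[locus.chrom]
        if lo <= mid < hi:
            in_window += 1
    frac = in_window / len(loci) if loci else float("nan")
    return ChromDistribution(
        bin_size=bin_size,
        counts=counts,
        pericentromeric_fraction=frac,
        window_fraction=window_len / total_len,
        n_loci=len(loci),
    )


def size_shift_summary(
    profiles: Mapping[str, SizeClassProfile],
    control: str,
    *,
    classes: Sequence[str] = ("20-21", "23-24"),
) -> pd.DataFrame:
    """Directioned fold changes in size-class tspm, control vs each library.

    Expects :class:`SizeClassProfile` objects computed with the hairpin
    construct supplied, so transgene-derived reads are already excluded and
    the folds reflect endogenous sRNA only.
    """
    if control not in profiles:
        raise KeyError(f"control library {control!r} missing")
    rows = []
    for lib, prof in profiles.items():
        if lib == control:
            continue
        for cls in classes:
            a = profiles[control].per_class[cls]
            b = prof.per_class[cls]
            fc = fold_change(a, b)
            rows.append(
                {
                    "library": lib,
                    "size_class": cls,
                    "control_tspm": a,
                    "tspm": b,
                    "fold": fc.rounded,
                    "direction": fc.direction,
                }
            )
    return pd.DataFrame(rows)


def calls_to_frame(calls: Sequence[DifferentialCall]) -> pd.DataFrame:
    """BED-like table (0-based start, half-open end) of differential calls."""
    rows = []
    for c in calls:
        row = {
            "chrom": c.locus.chrom,
            "start": c.locus.start,
            "end": c.locus.end,
            "size_class": c.locus.size_class,
            "direction": c.direction,
            "significant": c.significant,
            "strong": c.strong,
        }
        for lib, a in c.abundance.items():
            row[f"abundance_{lib}"] = a
        for lib, f in c.fold.items():
            row[f"fold_{lib}"] = f
        rows.append(row)
    return pd.DataFrame(rows)
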