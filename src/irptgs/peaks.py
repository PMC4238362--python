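"""Peak detection on sRNA coverage profiles, peak spacing (periodicity),
abundance-vs-loop-distance correlation, and 3' transitivity quantification.

Hairpin-derived sRNAs accumulate in discrete peaks along the trigger
sequence; their abundance falls with distance from the hairpin loop, and
secondary (transitive) sRNAs appear only 3' of the target region on the
full-length mRNA.  These routines formalize those observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .coverage import CoverageProfile


@dataclass
class Peak:
    reference_id: str
    start: int  # 0-based half-open interval
    end: int
    apex: int
    abundance: float  # summed per-million over the interval
    apex_height: float
    label: int  # ordinal in coordinate order, 1-based (paper-style numerals)

    def __post_init__(self) -> None:
        assert self.start <= self.apex < self.end
        assert self.abundance > 0


def _as_pm_array(profile, size_cls=None) -> tuple[np.ndarray, str]:
    if isinstance(profile, CoverageProfile):
        return profile.per_million(size_cls), profile.reference_id
    return np.asarray(profile, dtype=float), "reference"


def detect_peaks(
    profile,
    *,
    smoothing_window: int = 10,
    min_height: float = 0.0,
    min_separation: int = 30,
    size_cls: str | None = None,
) -> list[Peak]:
    """Local-maximum peaks of a (boxcar-smoothed) per-million profile.

    Candidate apexes are local maxima of the smoothed profile above
    ``min_height``; they are accepted greedily by decreasing height subject
    to a minimum apex separation.  Peak intervals extend outward to the
    half-height crossings, and peaks are labelled in coordinate order.
    """
    pm, ref_id = _as_pm_array(profile, size_cls)
    if smoothing_window < 1:
        raise ValueError("smoothing_window must be >= 1")
    n = len(pm)
    if n == 0 or pm.max() <= 0:
        return []
    kernel = np.ones(smoothing_window) / smoothing_window
    smooth = np.convolve(pm, kernel, mode="same")
    # local maxima (plateau-safe: first index of a maximal plateau)
    candidates = []
    for i in range(n):
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[i + 1] if i < n - 1 else -np.inf
        if smooth[i] > left and smooth[i] >= right and smooth[i] > min_height:
            candidates.append(i)
    candidates.sort(key=lambda i: -smooth[i])
    apexes: list[int] = []
    for i in candidates:
        if all(abs(i - j) >= min_separation for j in apexes):
            apexes.append(i)
    peaks = []
    for apex in sorted(apexes):
        half = smooth[apex] / 2.0
        start = apex
        while start > 0 and smooth[start - 1] >= half and smooth[start - 1] <= smooth[start]:
            start -= 1
        end = apex
        while end < n - 1 and smooth[end + 1] >= half and smooth[end + 1] <= smooth[end]:
            end += 1
        end += 1
        abundance = float(pm[start:end].sum())
        if abundance <= 0:
            continue
        peaks.append(
            Peak(
                reference_id=ref_id,
                start=start,
                end=end,
                apex=apex,
                abundance=abundance,
                apex_height=float(smooth[apex]),
                label=0,
            )
        )
    for k, p in enumerate(peaks, start=1):
        p.label = k
    return peaks


@dataclass
class PeriodicityEstimate:
    mean_spacing: float
    spacing_sd: float  # NaN when only two peaks (a single spacing)
    n_peaks: int


def peak_periodicity(peaks: list[Peak]) -> PeriodicityEstimate:
    """Mean and SD of consecutive apex-to-apex distances."""
    if len(peaks) < 2:
        raise ValueError("periodicity requires at least 2 peaks")
    apexes = np.sort([p.apex for p in peaks])
    spacings = np.diff(apexes)
    sd = float(np.std(spacings, ddof=1)) if len(spacings) > 1 else float("nan")
    return PeriodicityEstimate(
        mean_spacing=float(spacings.mean()), spacing_sd=sd, n_peaks=len(peaks)
    )


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    defined: bool = True


def _pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("correlation requires at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), len(x), defined=False)
    r, p = stats.pearsonr(x, y)  # two-tailed p via the t-transform, n-2 df
    return CorrelationResult(float(r), float(p), len(x))


def loop_distance_correlation(
    peak_tables: dict[str, list[tuple[float, float]]]
) -> CorrelationResult:
    """Pearson correlation of peak abundance with loop distance.

    ``peak_tables`` maps construct name to ``(loop_distance, abundance)``
    pairs.  Abundances are standardized to the mean within each construct
    before pooling, so constructs with different overall sRNA yields
    contribute comparably.
    """
    dists: list[float] = []
    stdized: list[float] = []
    for pairs in peak_tables.values():
        if not pairs:
            continue
        d = np.array([p[0] for p in pairs], dtype=float)
        a = np.array([p[1] for p in pairs], dtype=float)
        mean = a.mean()
        if mean == 0:
            continue
        dists.extend(d)
        stdized.extend(a / mean)
    return _pearson(np.array(dists), np.array(stdized))


@dataclass
class TransitivityReport:
    """Regionalized sRNA abundance over a full-length target mRNA.

    ``abundance`` and ``per_nt_mean`` are per-million sums / per-nucleotide
    means for the upstream (5'), trigger and downstream (3') regions.  The
    3' transitivity index is downstream/(upstream+downstream), a bounded
    [0, 1] ratio; trigger-region signal whose per-nt mean exceeds the
    attribution threshold is attributed to hairpin processing rather than
    mRNA-derived transitive sRNA.
    """

    abundance: dict[str, float]
    per_nt_mean: dict[str, float]
    transitivity_index_3prime: float  # NaN when upstream+downstream == 0
    attribution_threshold: float
    trigger_attributed_to_hairpin: bool


def transitivity_report(
    profile: CoverageProfile,
    trigger: tuple[int, int],
    *,
    attribution_threshold: float = 300.0,
    size_cls: str | None = None,
) -> TransitivityReport:
    """Partition mRNA coverage into 5'/trigger/3' regions and index 3' bias."""
    t0, t1 = trigger
    if not (0 <= t0 < t1 <= profile.length):
        raise ValueError("trigger interval outside mRNA")
    pm = profile.per_million(size_cls)
    regions = {
        "upstream": pm[:t0],
        "trigger": pm[t0:t1],
        "downstream": pm[t1:],
    }
    abundance = {k: float(v.sum()) for k, v in regions.items()}
    per_nt = {k: (float(v.mean()) if len(v) else 0.0) for k, v in regions.items()}
    denom = abundance["upstream"] + abundance["downstream"]
    index = abundance["downstream"] / denom if denom > 0 else float("nan")
    return TransitivityReport(
        abundance=abundance,
        per_nt_mean=per_nt,
        transitivity_index_3prime=index,
        attribution_threshold=attribution_threshold,
        trigger_attributed_to_hairpin=per_nt["trigger"] > attribution_threshold,
    )


def profile_similarity(
    profile_a,
    profile_b,
    region: tuple[int, int] | None = None,
    *,
    size_cls: str | None = None,
) -> CorrelationResult:
    """Pearson correlation of two per-nucleotide per-million profiles."""
    a, _ = _as_pm_array(profile_a, size_cls)
    b, _ = _as_pm_array(profile_b, size_cls)
    if region is not None:
        s, e = region
        a, b = a[s:e], b[s:e]
    if len(a) != len(b):
        raise ValueError("profiles must cover equal-length regions")
    return _pearson(a, b)
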