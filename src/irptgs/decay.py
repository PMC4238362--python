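"""Capped vs uncapped transcript comparison from paired RNA-Seq libraries.

A 5'-phosphate-dependent exonuclease (5'PDE) degrades uncapped RNA, so a
treated library (ESeq-like) is depleted of uncapped species relative to its
untreated partner (RSeq-like).  After rescaling the treated library to a set
of capped normalizer transcripts, a transcript whose abundance falls is
5'PDE-sensitive (uncapped); one whose abundance holds or rises relative to
the depleted background carries a protective cap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def rpkm_table(
    counts: Mapping[str, int],
    lengths: Mapping[str, int],
    total: int,
    *,
    library_id: str = "library",
) -> pd.DataFrame:
    """Reads-per-kilobase-per-million abundance table.

    abundance = count * 1e9 / (length_nt * total_reads)
    """
    if total <= 0:
        raise ValueError("total must be positive")
    rows = []
    for ref, count in counts.items():
        length = lengths[ref]
        if length <= 0:
            raise ValueError(f"reference {ref!r} has non-positive length")
        rows.append(
            {
                "reference": ref,
                "count": count,
                "length": length,
                "abundance": count * 1e9 / (length * total),
                "library": library_id,
            }
        )
    return pd.DataFrame(rows)


def normalize_to_reference_set(
    treated: pd.DataFrame,
    untreated: pd.DataFrame,
    normalizer_ids: Sequence[str],
) -> tuple[float, pd.DataFrame]:
    """Rescale the treated table so the normalizer set matches the untreated.

    The scaling factor is the median untreated/treated abundance ratio over
    the normalizer transcripts (median for outlier robustness); the treated
    abundances are multiplied by it.  Idempotent: re-applying to the rescaled
    table yields factor 1.
    """
    t = treated.set_index("reference")["abundance"]
    u = untreated.set_index("reference")["abundance"]
    common = [r for r in normalizer_ids if r in t.index and r in u.index and t[r] > 0]
    if not common:
        raise ValueError("no usable normalizer references shared by both tables")
    factor = float(np.median([u[r] / t[r] for r in common]))
    rescaled = treated.copy()
    rescaled["abundance"] = rescaled["abundance"] * factor
    return factor, rescaled


@dataclass
class CapCall:
    reference: str
    percent_change: float  # treated vs untreated, after normalization
    call: str  # "capped" | "pde_sensitive" | "unchanged" | "undefined"


def cap_calls(
    treated: pd.DataFrame,
    untreated: pd.DataFrame,
    *,
    increase_threshold: float = 10.0,
    decrease_threshold: float = 10.0,
) -> list[CapCall]:
    """Classify transcripts by abundance change in the treated library.

    percent change = 100 * (treated - untreated) / untreated;
    >= ``increase_threshold`` => capped, <= -``decrease_threshold`` =>
    pde_sensitive, else unchanged.  Inputs should be normalized first.
    """
    t = treated.set_index("reference")["abundance"]
    u = untreated.set_index("reference")["abundance"]
    calls = []
    for ref in untreated["reference"]:
        if u[ref] == 0:
            calls.append(CapCall(ref, float("nan"), "undefined"))
            continue
        pct = 100.0 * (t.get(ref, 0.0) - u[ref]) / u[ref]
        if pct >= increase_threshold:
            call = "capped"
        elif pct <= -decrease_threshold:
            call = "pde_sensitive"
        else:
            call = "unchanged"
        calls.append(CapCall(ref, float(pct), call))
    return calls


@dataclass
class RegionComparison:
    per_nt_mean: dict[str, dict[str, float]]  # library -> region -> mean coverage
    five_prime_depleted: bool
    three_prime_pde_sensitive: bool
    rho: float
    delta: float


def region_coverage_compare(
    coverages: Mapping[str, np.ndarray],
    trigger: tuple[int, int],
    *,
    control_untreated: str = "control_untreated",
    silenced_untreated: str = "silenced_untreated",
    silenced_treated: str = "silenced_treated",
    rho: float = 0.5,
    delta: float = 0.25,
) -> RegionComparison:
    """Region-wise RNA-Seq coverage comparison over the target mRNA.

    ``coverages`` maps library keys to per-nucleotide read coverage.  The
    5' region is flagged depleted when the silenced untreated library's
    upstream per-nt mean falls below ``rho`` x the control's; the 3' region
    is flagged 5'PDE-sensitive when its mean drops by >= ``delta`` in the
    treated vs untreated silenced libraries.
    """
    t0, t1 = trigger
    regions = {}
    for lib, cov in coverages.items():
        cov = np.asarray(cov, dtype=float)
        if not (0 <= t0 < t1 <= len(cov)):
            raise ValueError("trigger interval outside mRNA coverage")
        regions[lib] = {
            "upstream": float(cov[:t0].mean()) if t0 > 0 else 0.0,
            "trigger": float(cov[t0:t1].mean()),
            "downstream": float(cov[t1:].mean()) if t1 < len(cov) else 0.0,
        }
    up_ctrl = regions[control_untreated]["upstream"]
    up_sil = regions[silenced_untreated]["upstream"]
    five_prime = up_ctrl > 0 and up_sil < rho * up_ctrl
    down_u = regions[silenced_untreated]["downstream"]
    down_t = regions[silenced_treated]["downstream"]
    three_prime = down_u > 0 and (down_u - down_t) / down_u >= delta
    return RegionComparison(
        per_nt_mean=regions,
        five_prime_depleted=five_prime,
        three_prime_pde_sensitive=three_prime,
        rho=rho,
        delta=delta,
    )
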