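"""Small-RNA read handling: adapter trimming, collapsing, exact mapping, and
size-class-resolved per-nucleotide coverage.

Mapping is exact substring matching on both strands (no mismatches by
default), which at 18-30 nt is what near-exact local alignment reduces to and
keeps every downstream quantity deterministic.  Coverage is reported raw and
per million library reads; size-class abundances use tspm (thousand sequences
per million reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hairpin import HairpinConstruct, revcomp
from . import io as _io

#: default size-class bins; lengths outside fall in "other"
SIZE_CLASSES = ("20-21", "22", "23-24", "other")
MIN_READ_LENGTH = 18
MAX_READ_LENGTH = 30


def size_class(length: int) -> str:
    if length in (20, 21):
        return "20-21"
    if length == 22:
        return "22"
    if length in (23, 24):
        return "23-24"
    return "other"


@dataclass
class SrnaLibrary:
    """Collapsed small-RNA reads: distinct sequence -> count."""

    id: str
    reads: dict[str, int]
    total_reads: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        retained = sum(self.reads.values())
        if self.total_reads < retained:
            raise ValueError("total_reads smaller than sum of retained counts")

    @classmethod
    def from_reads(cls, id: str, reads: Mapping[str, int], **metadata) -> "SrnaLibrary":
        reads = dict(reads)
        return cls(id=id, reads=reads, total_reads=sum(reads.values()), metadata=metadata)

    @classmethod
    def from_collapsed_fasta(cls, path, id: str | None = None) -> "SrnaLibrary":
        reads = _io.read_collapsed_fasta(path)
        return cls.from_reads(id or str(path), reads)

    def to_collapsed_fasta(self, path) -> None:
        _io.write_collapsed_fasta(path, self.reads)


def trim_and_collapse(
    reads: Iterable[str] | str,
    adapter: str,
    *,
    library_id: str = "library",
    min_length: int = MIN_READ_LENGTH,
    min_overlap: int = 5,
) -> SrnaLibrary:
    """Trim a 3' adapter, drop undetected/short reads, collapse duplicates.

    The adapter is located as the leftmost position where the read's tail
    matches a prefix of the adapter with at least ``min_overlap`` aligned
    bases (or the whole tail, if shorter).  Reads with no detectable adapter,
    or shorter than ``min_length`` after trimming, are removed; the library
    total used for per-million normalization counts the retained reads.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    adapter = adapter.upper()
    collapsed: dict[str, int] = {}
    if isinstance(reads, (str,)):
        reads = _io.read_raw_reads(reads)
    for read in reads:
        read = read.upper()
        insert = None
        for i in range(len(read)):
            tail = read[i:]
            ov = min(len(tail), len(adapter))
            if ov >= min(min_overlap, len(adapter)) and tail[:ov] == adapter[:ov]:
                insert = read[:i]
                break
        if insert is None or len(insert) < min_length:
            continue
        collapsed[insert] = collapsed.get(insert, 0) + 1
    return SrnaLibrary.from_reads(library_id, collapsed, adapter=adapter)


class ReferenceIndex:
    """Exact-match site lookup over one or more reference sequences.

    Builds, lazily per read length, a k-mer -> positions table per reference.
    Equivalent to a full substring scan but O(1) per query, which matters for
    genome-wide mapping of collapsed libraries.
    """

    def __init__(self, references: Mapping[str, str]):
        self.references = {name: seq.upper() for name, seq in references.items()}
        self._tables: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _table(self, k: int) -> dict[str, list[tuple[str, int]]]:
        tab = self._tables.get(k)
        if tab is None:
            tab = {}
            for name, seq in self.references.items():
                for i in range(len(seq) - k + 1):
                    tab.setdefault(seq[i : i + k], []).append((name, i))
            self._tables[k] = tab
        return tab

    def sites(self, read: str) -> list[tuple[str, int, str]]:
        """All exact-match sites of a read: (reference, start, strand).

        A reverse-strand match is reported at the forward-strand interval it
        covers, per the convention that coverage lives in reference
        coordinates regardless of matching strand.
        """
        tab = self._table(len(read))
        out = [(name, pos, "+") for name, pos in tab.get(read, ())]
        rc = revcomp(read)
        if rc != read:
            out += [(name, pos, "-") for name, pos in tab.get(rc, ())]
        return out

    def matches(self, read: str) -> bool:
        tab = self._table(len(read))
        return read in tab or revcomp(read) in tab


@dataclass
class CoverageProfile:
    """Per-nucleotide, size-class-resolved coverage over one reference."""

    reference_id: str
    length: int
    total_reads: int
    raw: dict[str, np.ndarray]
    mapped_reads: dict[str, float]

    def per_million(self, size_cls: str | None = None) -> np.ndarray:
        """Per-million coverage for one size class, or summed over all."""
        if size_cls is not None:
            arr = self.raw[size_cls]
        else:
            arr = sum(self.raw.values())
        return arr * 1e6 / self.total_reads

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (1-based positions) for TSV export."""
        rows = []
        for cls in SIZE_CLASSES:
            raw = self.raw[cls]
            pm = raw * 1e6 / self.total_reads
            rows.append(
                pd.DataFrame(
                    {
                        "reference": self.reference_id,
                        "position": np.arange(1, self.length + 1),
                        "size_class": cls,
                        "raw": raw,
                        "per_million": pm,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def map_reads_multi(
    library: SrnaLibrary,
    references: Mapping[str, str],
    *,
    policy: str = "all",
    lengths: Sequence[int] | None = None,
    index: ReferenceIndex | None = None,
) -> dict[str, CoverageProfile]:
    """Map a collapsed library onto several references at once.

    Each read contributes its count to every nucleotide it covers at every
    exact-match site on either strand.  ``policy='all'`` places the full
    count at every site; ``policy='fractional'`` divides the count by the
    number of sites across all supplied references.
    """
    if policy not in ("all", "fractional"):
        raise ValueError(f"unknown multi-hit policy {policy!r}")
    if index is None:
        index = ReferenceIndex(references)
    arrays = {
        name: {cls: np.zeros(len(seq)) for cls in SIZE_CLASSES}
        for name, seq in references.items()
    }
    mapped = {name: {cls: 0.0 for cls in SIZE_CLASSES} for name in references}
    for read, count in library.reads.items():
        if lengths is not None and len(read) not in lengths:
            continue
        sites = index.sites(read)
        if not sites:
            continue
        cls = size_class(len(read))
        weight = count / len(sites) if policy == "fractional" else float(count)
        per_read = count / len(sites) if policy == "fractional" else float(count)
        for name, start, _strand in sites:
            arrays[name][cls][start : start + len(read)] += weight
            mapped[name][cls] += per_read
    return {
        name: CoverageProfile(
            reference_id=name,
            length=len(seq),
            total_reads=library.total_reads,
            raw=arrays[name],
            mapped_reads=mapped[name],
        )
        for name, seq in references.items()
    }


def map_reads(
    library: SrnaLibrary,
    reference: str,
    *,
    reference_id: str = "reference",
    policy: str = "all",
    lengths: Sequence[int] | None = None,
    index: ReferenceIndex | None = None,
) -> CoverageProfile:
    """Map a collapsed library onto a single reference sequence."""
    return map_reads_multi(
        library, {reference_id: reference}, policy=policy, lengths=lengths, index=index
    )[reference_id]


@dataclass
class SizeClassProfile:
    """tspm abundance per size class and per individual read length."""

    library_id: str
    per_length: dict[int, float]
    per_class: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"length": list(self.per_length), "tspm": list(self.per_length.values())}
        ).assign(library=self.library_id)


def size_class_profile(
    library: SrnaLibrary,
    references: Mapping[str, str],
    *,
    construct: HairpinConstruct | None = None,
    index: ReferenceIndex | None = None,
) -> SizeClassProfile:
    """Size-class abundances (tspm) of reads matching a reference set.

    When a hairpin ``construct`` is supplied, reads matching its precursor
    are treated as transgene-derived and excluded, leaving the endogenous
    complement — the convention used when profiling genome-matching sRNA in
    transgenic libraries.
    """
    if index is None:
        index = ReferenceIndex(references)
    precursor_index = (
        ReferenceIndex({"precursor": construct.precursor_sequence}) if construct else None
    )
    per_length = {L: 0.0 for L in range(MIN_READ_LENGTH, MAX_READ_LENGTH + 1)}
    for read, count in library.reads.items():
        L = len(read)
        if L not in per_length:
            continue
        if precursor_index is not None and precursor_index.matches(read):
            continue
        if not index.matches(read):
            continue
        per_length[L] += count
    # tspm: thousand sequences per million library reads
    scale = 1e6 / library.total_reads / 1e3
    per_length = {L: c * scale for L, c in per_length.items()}
    per_class = {cls: 0.0 for cls in SIZE_CLASSES}
    for L, tspm in per_length.items():
        per_class[size_class(L)] += tspm
    return SizeClassProfile(library_id=library.id, per_length=per_length, per_class=per_class)


@dataclass(frozen=True)
class FoldChange:
    """Directioned fold change between two abundances (ratio max/min)."""

    fold: float
    direction: str  # "increase" | "decrease" | "none" | "undefined"

    @property
    def rounded(self) -> float:
        # round half away from zero to 1 decimal, matching printed folds
        import math

        return math.floor(self.fold * 10 + 0.5) / 10


def fold_change(a: float, b: float) -> FoldChange:
    """Fold change from abundance ``a`` (reference) to ``b``.

    Returns the max/min ratio with the direction of change of ``b`` relative
    to ``a``; a zero denominator yields an undefined-fold flag.
    """
    if a == 0 or b == 0:
        return FoldChange(float("inf"), "undefined")
    if a == b:
        return FoldChange(1.0, "none")
    if b > a:
        return FoldChange(b / a, "increase")
    return FoldChange(a / b, "decrease")
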