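"""Relative codon frequency (RCF, codon rarity) scoring and ORF association.

For the j-th synonymous codon of amino acid i with usage frequency X_ij and
synonymous-codon mean X_avg,i, the rarity score is

    RCF_ij = -(X_ij - X_avg,i) / X_avg,i

i.e. the negated relative deviation of a codon's usage from its synonymous
mean, so that rarer codons score higher.  Scores sum to zero within each
amino acid and are invariant to rescaling one amino acid's usages.  Rarity
profiles along a CDS are 20-codon sliding-window means; ORFs are ATG-to-stop
spans in the three forward frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable as _BioCodonTable

from .coverage import CoverageProfile
from .peaks import CorrelationResult, _pearson

STOP = "*"


@dataclass
class CodonUsageTable:
    """Per-codon usage frequencies grouped by amino acid."""

    frequency: dict[str, float]  # codon -> X_ij (any consistent scale)
    amino_acid: dict[str, str]  # codon -> one-letter amino acid (stop = '*')

    def __post_init__(self) -> None:
        missing = set(self.frequency) - set(self.amino_acid)
        if missing:
            raise ValueError(f"codons without amino-acid assignment: {sorted(missing)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodonUsageTable":
        df = pd.read_csv(path, sep="\t")
        need = {"codon", "amino_acid", "frequency"}
        if not need <= set(df.columns):
            raise ValueError(f"codon table needs columns {sorted(need)}")
        return cls(
            frequency=dict(zip(df["codon"].str.upper(), df["frequency"].astype(float))),
            amino_acid=dict(zip(df["codon"].str.upper(), df["amino_acid"])),
        )

    @classmethod
    def builtin(cls) -> "CodonUsageTable":
        """The bundled synthetic test table (not organism-derived)."""
        path = resources.files("irptgs") / "data" / "codon_usage_synthetic.tsv"
        return cls.from_tsv(str(path))

    def synonymous_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for codon, aa in self.amino_acid.items():
            if aa == STOP or codon not in self.frequency:
                continue
            groups.setdefault(aa, []).append(codon)
        return groups


def rcf(table: CodonUsageTable, *, negate: bool = True) -> dict[str, float]:
    """Per-codon rarity scores; ``negate=False`` recovers the raw deviation."""
    out: dict[str, float] = {}
    sign = -1.0 if negate else 1.0
    for aa, codons in table.synonymous_groups().items():
        xs = np.array([table.frequency[c] for c in codons], dtype=float)
        avg = xs.mean()
        if avg == 0:
            raise ValueError(f"amino acid {aa!r}: zero mean usage, RCF undefined")
        for c, x in zip(codons, xs):
            out[c] = sign * (x - avg) / avg
    return out


@dataclass
class RcfProfile:
    per_codon: np.ndarray  # NaN where the codon is unknown/ambiguous
    windowed: np.ndarray  # length n_codons - window + 1
    window: int
    negated: bool = True


def rarity_profile(
    cds: str, rcf_values: dict[str, float], *, window: int = 20
) -> RcfProfile:
    """Per-codon rarity and its sliding-window (by one codon) mean.

    Codons containing ambiguity codes are masked; each window mean is taken
    over its unmasked positions.  A CDS with internal stops is accepted (the
    stop codon is masked) since trigger fragments need not be clean ORFs.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    n = len(cds) // 3
    if window < 1 or window > n:
        raise ValueError("window must be in [1, n_codons]")
    per = np.full(n, np.nan)
    for i in range(n):
        codon = cds[3 * i : 3 * i + 3]
        if codon in rcf_values:
            per[i] = rcf_values[codon]
    # masked boxcar mean
    valid = ~np.isnan(per)
    filled = np.where(valid, per, 0.0)
    kernel = np.ones(window)
    sums = np.convolve(filled, kernel, mode="valid")
    counts = np.convolve(valid.astype(float), kernel, mode="valid")
    with np.errstate(invalid="ignore"):
        windowed = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return RcfProfile(per_codon=per, windowed=windowed, window=window)


@dataclass(frozen=True)
class OrfAnnotation:
    frame: int  # 1..3 (forward frames)
    start: int  # 0-based half-open nt interval on the mRNA
    end: int
    rank: str = "other"  # "primary" | "secondary" | "other"

    @property
    def n_codons(self) -> int:
        return (self.end - self.start) // 3


def find_orfs(mrna: str, *, min_length: int = 50) -> list[OrfAnnotation]:
    """ATG-to-stop spans in the 3 forward frames, ranked primary/secondary.

    The primary ORF is the longest overall; the secondary is the longest ORF
    in another frame that extends past the primary's 3' end (falling back to
    the longest remaining).  ``min_length`` is in codons, stop included when
    present; an ORF without an in-frame stop runs to the end of the sequence.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    mrna = mrna.upper()
    stops = {"TAA", "TAG", "TGA"}
    orfs: list[OrfAnnotation] = []
    for offset in range(3):
        i = offset
        claimed_until = -1
        while i + 3 <= len(mrna):
            if mrna[i : i + 3] == "ATG" and i > claimed_until:
                j = i
                end = None
                while j + 3 <= len(mrna):
                    if mrna[j : j + 3] in stops:
                        end = j + 3
                        break
                    j += 3
                if end is None:
                    end = i + 3 * ((len(mrna) - i) // 3)
                if (end - i) // 3 >= min_length:
                    orfs.append(OrfAnnotation(frame=offset + 1, start=i, end=end))
                claimed_until = end - 1  # nested starts within an ORF are not re-reported
            i += 3
    if not orfs:
        return []
    orfs.sort(key=lambda o: (-(o.end - o.start), o.start))
    primary = orfs[0]
    ranked = [OrfAnnotation(primary.frame, primary.start, primary.end, "primary")]
    rest = orfs[1:]
    secondary = None
    extending = [o for o in rest if o.frame != primary.frame and o.end > primary.end]
    if extending:
        secondary = max(extending, key=lambda o: o.end - o.start)
    elif rest:
        secondary = rest[0]
    for o in rest:
        rank = "secondary" if o is secondary else "other"
        ranked.append(OrfAnnotation(o.frame, o.start, o.end, rank))
    ranked.sort(key=lambda o: o.start)
    return ranked


def codon_srna_correlation(
    rarity: np.ndarray, coverage: CoverageProfile, *, size_cls: str | None = None
) -> CorrelationResult:
    """Pearson correlation of per-codon rarity with per-codon sRNA abundance.

    The sRNA abundance of a codon is the mean per-million coverage of its
    three nucleotides; the two-tailed p uses the t-transform with n-2 df.
    """
    rarity = np.asarray(rarity, dtype=float)
    n = len(rarity)
    pm = coverage.per_million(size_cls)
    if len(pm) < 3 * n:
        raise ValueError("coverage shorter than 3 x n_codons")
    per_codon_cov = pm[: 3 * n].reshape(n, 3).mean(axis=1)
    ok = ~np.isnan(rarity)
    return _pearson(rarity[ok], per_codon_cov[ok])


@dataclass
class OrfAssociation:
    fraction_in_orfs: float
    density_inside: float  # per-million per nt
    density_outside: float
    density_ratio: float


def orf_association_fraction(
    coverage: CoverageProfile,
    orfs: list[OrfAnnotation],
    *,
    ranks: tuple[str, ...] = ("primary", "secondary"),
    size_cls: str | None = None,
) -> OrfAssociation:
    """Fraction of total sRNA abundance inside primary/secondary ORF spans."""
    pm = coverage.per_million(size_cls)
    total = float(pm.sum())
    if total == 0:
        return OrfAssociation(float("nan"), float("nan"), float("nan"), float("nan"))
    mask = np.zeros(len(pm), dtype=bool)
    for orf in orfs:
        if orf.rank in ranks:
            mask[orf.start : orf.end] = True
    inside = float(pm[mask].sum())
    n_in = int(mask.sum())
    n_out = len(pm) - n_in
    d_in = inside / n_in if n_in else 0.0
    d_out = (total - inside) / n_out if n_out else 0.0
    ratio = d_in / d_out if d_out > 0 else float("inf") if d_in > 0 else float("nan")
    return OrfAssociation(
        fraction_in_orfs=inside / total,
        density_inside=d_in,
        density_outside=d_out,
        density_ratio=ratio,
    )


def standard_amino_acid_map() -> dict[str, str]:
    """Codon -> amino acid for the standard genetic code (stops as '*')."""
    tab = _BioCodonTable.unambiguous_dna_by_id[1]
    mapping = dict(tab.forward_table)
    for stop in tab.stop_codons:
        mapping[stop] = STOP
    return mapping
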