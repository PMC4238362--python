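"""Synthetic data generators for the whole pipeline.

Every generator is a pure function of (parameters, seed) and every emitted
read is an exact substring (either strand) of its declared source sequence.
Defaults emulate the study conditions the analyses assume: hairpin-derived
sRNA at 5.7-9.6% of the library, dominated by 20-21-mers; peaked positional
coverage with 79-nt spacing whose abundance decays with distance from the
loop; 3'-restricted transitive sRNA on the target mRNA; pericentromeric
23-24-nt locus clusters on a toy genome; paired exonuclease-treated /
untreated RNA-Seq libraries; and correlated two-reporter silencing
phenotypes.  Library sizes are scaled down from the study's millions of
reads to keep simulations desk-sized; see docs/methods.md.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import SrnaLibrary
from .hairpin import HairpinConstruct, TriggerFragment, revcomp
from .phenotypes import T2FamilyCounts

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: read-length choices per feature role (uniform within each role's class)
ROLE_LENGTHS = {
    "hc_cluster": (23, 24),
    "mirna": (20, 21),
    "tasirna": (21,),
    "gene": (20, 21, 22),
}
_CLASS_LENGTHS = {"20-21": (20, 21), "22": (22,), "23-24": (23, 24)}


def random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


# ---------------------------------------------------------------------------
# toy genome
# ---------------------------------------------------------------------------


@dataclass
class GenomeModel:
    """A toy multi-chromosome genome with planted sRNA-producing features."""

    chromosomes: list[tuple[str, str, int]]  # (name, sequence, centromere)
    features: pd.DataFrame  # feature_id, chrom, start, end, role, weight

    def sequences(self) -> dict[str, str]:
        return {name: seq for name, seq, _ in self.chromosomes}

    def chrom_table(self) -> list[tuple[str, int, int]]:
        return [(name, len(seq), cen) for name, seq, cen in self.chromosomes]

    def pericentromeric_fraction_of_features(
        self, role: str, window: float = 0.10
    ) -> float:
        cen = {name: (c, len(seq)) for name, seq, c in self.chromosomes}
        sub = self.features[self.features["role"] == role]
        if sub.empty:
            return float("nan")
        hits = 0
        for _, row in sub.iterrows():
            c, length = cen[row["chrom"]]
            mid = (row["start"] + row["end"]) / 2
            if abs(mid - c) <= window * length:
                hits += 1
        return hits / len(sub)


def gen_toy_genome(
    n_chrom: int = 2,
    chrom_length: int = 120_000,
    n_features: Mapping[str, int] | None = None,
    seed: int = 0,
    *,
    concentration: float = 4.0,
    centromere_window: float = 0.10,
) -> GenomeModel:
    """Generate a toy genome with feature roles planted at known positions.

    hc_cluster features (23-24-nt sRNA sources) are pericentromeric with
    probability concentration/(concentration+1); all other roles are placed
    uniformly.  Deterministic given the seed.
    """
    if n_features is None:
        n_features = {"hc_cluster": 400, "mirna": 120, "tasirna": 24, "gene": 120}
    role_lengths = {"hc_cluster": (60, 140), "mirna": (21, 22), "tasirna": (60, 90), "gene": (150, 250)}
    rng = np.random.default_rng(seed)
    chroms = []
    for i in range(n_chrom):
        seq = random_dna(rng, chrom_length)
        cen = int(rng.integers(int(0.4 * chrom_length), int(0.6 * chrom_length)))
        chroms.append((f"chr{i + 1}", seq, cen))
    p_center = concentration / (concentration + 1.0) if math.isfinite(concentration) else 1.0
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name, _, _ in chroms}
    rows = []
    fid = 0
    total_demand = sum(
        n * (role_lengths[r][1]) for r, n in n_features.items()
    )
    if total_demand > 0.5 * n_chrom * chrom_length:
        raise ValueError("feature demand exceeds half the genome; enlarge chromosomes")
    for role in sorted(n_features):
        lo, hi = role_lengths[role]
        for _ in range(n_features[role]):
            length = int(rng.integers(lo, hi + 1))
            for _attempt in range(500):
                ci = int(rng.integers(n_chrom))
                name, _, cen = chroms[ci]
                if role == "hc_cluster" and rng.random() < p_center:
                    half = centromere_window * chrom_length
                    start = int(rng.integers(max(0, cen - half), min(chrom_length - length, cen + half)))
                else:
                    start = int(rng.integers(0, chrom_length - length))
                end = start + length
                if all(end <= s or start >= e for s, e in occupied[name]):
                    occupied[name].append((start, end))
                    rows.append(
                        {
                            "feature_id": f"{role}_{fid:04d}",
                            "chrom": name,
                            "start": start,
                            "end": end,
                            "role": role,
                            "weight": float(rng.lognormal(0.0, 0.4)),
                        }
                    )
                    fid += 1
                    break
            else:
                raise ValueError("could not place feature without overlap")
    return GenomeModel(chromosomes=chroms, features=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# sRNA libraries
# ---------------------------------------------------------------------------


@dataclass
class LibraryRecipe:
    """Parameters of one synthetic sRNA library.

    Defaults are anchored to the study conditions: ~7.6% hairpin-derived
    reads (the reported 5.7-9.6% range's midpoint), a 20-21-mer-dominated
    transgene size mixture, peaks every 79 nt whose weight decays
    exponentially with loop distance.
    """

    total_reads: int = 200_000
    transgene_fraction: float = 0.076
    transgene_size_mix: dict[str, float] = field(
        default_factory=lambda: {"20-21": 0.85, "22": 0.11, "23-24": 0.04}
    )
    peak_spacing: int = 79
    peak_offset: int = 20
    peak_layout: list[tuple[float, float]] | None = None  # (loop_distance, weight)
    loop_decay_length: float | None = 300.0  # nt; None disables decay
    peak_jitter_sd: float = 8.0
    endogenous_mix: dict[str, float] = field(
        default_factory=lambda: {"hc_cluster": 0.50, "mirna": 0.28, "tasirna": 0.06, "gene": 0.16}
    )
    transitive_3prime_weight: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        for name, mix in (("transgene_size_mix", self.transgene_size_mix),
                          ("endogenous_mix", self.endogenous_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1")
        if not 0 <= self.transgene_fraction <= 1:
            raise ValueError("transgene_fraction must be in [0, 1]")

    def loop_decay(self, distance: float) -> float:
        if self.loop_decay_length is None:
            return 1.0
        return math.exp(-distance / self.loop_decay_length)


def transgene_peak_table(
    recipe: LibraryRecipe, construct: HairpinConstruct
) -> pd.DataFrame:
    """The planted peak layout on a construct: ground truth for recovery tests.

    Columns: loop_distance, arm1_pos (apex, precursor coordinates), weight
    (decay-modulated, normalized).
    """
    arm = construct.arm_length
    if recipe.peak_layout is not None:
        layout = list(recipe.peak_layout)
    else:
        layout = []
        d = float(recipe.peak_offset)
        while d <= arm - 1 - recipe.peak_offset:
            layout.append((d, 1.0))
            d += recipe.peak_spacing
    rows = []
    for dist, w in layout:
        if not 0 <= dist < arm:
            raise ValueError(f"peak loop distance {dist} outside arm")
        rows.append(
            {
                "loop_distance": dist,
                "arm1_pos": arm - 1 - int(dist),
                "weight": w * recipe.loop_decay(dist),
            }
        )
    df = pd.DataFrame(rows)
    df["weight"] /= df["weight"].sum()
    return df


def _sample_class_lengths(rng, mix: Mapping[str, float], n: int) -> np.ndarray:
    classes = list(mix)
    idx = rng.choice(len(classes), size=n, p=[mix[c] for c in classes])
    lengths = np.empty(n, dtype=int)
    for i, cls in enumerate(classes):
        sel = idx == i
        opts = _CLASS_LENGTHS[cls]
        lengths[sel] = rng.choice(opts, size=int(sel.sum()))
    return lengths


def gen_srna_library(
    recipe: LibraryRecipe,
    genome: GenomeModel | None = None,
    construct: HairpinConstruct | None = None,
    *,
    target_mrna: str | None = None,
    trigger_interval: tuple[int, int] | None = None,
    feature_multipliers: Mapping[str, float] | None = None,
    library_id: str = "library",
    seed: int | None = None,
) -> SrnaLibrary:
    """Generate one collapsed sRNA library.

    Reads are drawn from three sources: the hairpin precursor (peaked
    positions, loop-decay-weighted), transitive 3' regions of the target
    mRNA, and endogenous genome features.  ``feature_multipliers`` scales
    the expected read count of selected features (used to plant differential
    loci); affected features then draw Poisson rather than fixed-total
    counts, so planted folds are realized on the per-million scale.
    """
    rng = np.random.default_rng(recipe.seed if seed is None else seed)
    if recipe.transgene_fraction > 0 and construct is None:
        raise ValueError("transgene_fraction > 0 requires a construct")
    f_t = recipe.transgene_fraction
    f_tr = recipe.transitive_3prime_weight
    f_e = 1.0 - f_t - f_tr
    if f_e < -1e-9:
        raise ValueError("transgene + transitive fractions exceed 1")
    if f_tr > 0 and (target_mrna is None or trigger_interval is None):
        raise ValueError("transitive reads require target_mrna and trigger_interval")
    if f_e > 1e-9 and genome is None:
        raise ValueError("endogenous reads require a genome")
    n_t, n_tr, n_e = rng.multinomial(recipe.total_reads, [f_t, f_tr, max(f_e, 0.0)])
    reads: Counter[str] = Counter()

    if n_t > 0:
        peaks = transgene_peak_table(recipe, construct)
        arm = construct.arm_length
        pre = construct.precursor_sequence
        which = rng.choice(len(peaks), size=n_t, p=peaks["weight"].to_numpy())
        lengths = _sample_class_lengths(rng, recipe.transgene_size_mix, n_t)
        apexes = peaks["arm1_pos"].to_numpy()[which]
        starts = np.rint(
            apexes - lengths / 2 + rng.normal(0.0, recipe.peak_jitter_sd, size=n_t)
        ).astype(int)
        starts = np.clip(starts, 0, arm - lengths)
        strands = rng.integers(0, 2, size=n_t)
        for s, L, rev in zip(starts, lengths, strands):
            seq = pre[s : s + L]
            reads[revcomp(seq) if rev else seq] += 1

    if n_tr > 0:
        t0, t1 = trigger_interval
        down_len = len(target_mrna) - t1
        if down_len < 25:
            raise ValueError("no downstream region to draw transitive reads from")
        lengths = rng.choice((20, 21), size=n_tr)
        starts = t1 + rng.integers(0, down_len - lengths.max(), size=n_tr)
        strands = rng.integers(0, 2, size=n_tr)
        for s, L, rev in zip(starts, lengths, strands):
            seq = target_mrna[s : s + L]
            reads[revcomp(seq) if rev else seq] += 1

    if n_e > 0:
        feats = genome.features
        roles = feats["role"].to_numpy()
        weights = feats["weight"].to_numpy().astype(float)
        expected = np.zeros(len(feats))
        for role, mix in recipe.endogenous_mix.items():
            sel = roles == role
            if sel.any():
                expected[sel] = n_e * mix * weights[sel] / weights[sel].sum()
        if feature_multipliers:
            mult = feats["feature_id"].map(feature_multipliers).fillna(1.0).to_numpy()
            expected = expected * mult
            counts = rng.poisson(expected)
        else:
            p = expected / expected.sum()
            counts = rng.multinomial(n_e, p)
        seqs = genome.sequences()
        chrom_arr = feats["chrom"].to_numpy()
        f_start = feats["start"].to_numpy()
        f_end = feats["end"].to_numpy()
        for i in np.flatnonzero(counts):
            c = int(counts[i])
            chrom_seq = seqs[chrom_arr[i]]
            opts = ROLE_LENGTHS[roles[i]]
            lengths = rng.choice(opts, size=c)
            lo = f_start[i]
            hi = np.maximum(lo + 1, f_end[i] - lengths)
            starts = rng.integers(lo, hi)
            starts = np.clip(starts, 0, len(chrom_seq) - lengths)
            strands = rng.integers(0, 2, size=c)
            for s, L, rev in zip(starts, lengths, strands):
                seq = chrom_seq[s : s + L]
                reads[revcomp(seq) if rev else seq] += 1

    return SrnaLibrary.from_reads(library_id, dict(reads))


def gen_target_mrna(
    fragment: TriggerFragment,
    upstream_length: int = 400,
    downstream_length: int = 500,
    seed: int = 0,
) -> tuple[str, tuple[int, int]]:
    """A synthetic full-length target mRNA embedding the trigger fragment.

    Returns the mRNA sequence and the trigger interval on it.
    """
    rng = np.random.default_rng(seed)
    up = random_dna(rng, upstream_length)
    down = random_dna(rng, downstream_length)
    mrna = up + fragment.sequence + down
    return mrna, (upstream_length, upstream_length + fragment.length)


def plant_differential_loci(
    genome: GenomeModel,
    base_recipe: LibraryRecipe,
    n_up: int = 50,
    n_down: int = 50,
    fold: float = 2.0,
    size_class: str = "23-24",
    seed: int = 0,
    *,
    min_coverage_floor: float = 10.0,
) -> tuple[dict[str, SrnaLibrary], pd.DataFrame]:
    """Three libraries (control + two silenced) with planted differential loci.

    Planted features of the role producing ``size_class`` reads are over- or
    under-represented by ``fold`` in both silenced libraries.  Returns the
    libraries and a truth table (feature, interval, direction, fold).
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    role = {"23-24": "hc_cluster", "20-21": "mirna"}.get(size_class)
    if role is None:
        raise ValueError(f"no planted role produces size class {size_class!r}")
    rng = np.random.default_rng(seed)
    pool = genome.features[genome.features["role"] == role]
    if len(pool) < n_up + n_down:
        raise ValueError("not enough features of the target role to plant loci")
    chosen = pool.sample(n=n_up + n_down, random_state=int(rng.integers(2**31)))
    up_ids = list(chosen["feature_id"].iloc[:n_up])
    down_ids = list(chosen["feature_id"].iloc[n_up:])
    multipliers = {fid: fold for fid in up_ids}
    multipliers.update({fid: 1.0 / fold for fid in down_ids})

    # detectability: expected per-nt per-million coverage in the weakest library
    mix = base_recipe.endogenous_mix[role]
    wsum = pool["weight"].sum()
    mean_len = float((chosen["end"] - chosen["start"]).mean())
    endo_frac = 1.0 - base_recipe.transgene_fraction - base_recipe.transitive_3prime_weight
    truth_rows = []
    for fid, direction in [(f, "over") for f in up_ids] + [(f, "under") for f in down_ids]:
        row = pool[pool["feature_id"] == fid].iloc[0]
        w = row["weight"] / wsum
        exp_reads = base_recipe.total_reads * endo_frac * mix * w
        worst = exp_reads / fold if direction == "under" else exp_reads
        read_len = float(np.mean(ROLE_LENGTHS[role]))
        per_nt_pm = worst * read_len / max(row["end"] - row["start"], 1) * 1e6 / base_recipe.total_reads
        if per_nt_pm < min_coverage_floor:
            import warnings

            warnings.warn(
                f"planted locus {fid} expected below the detectability floor "
                f"({per_nt_pm:.1f} < {min_coverage_floor} per million per nt)",
                stacklevel=2,
            )
        truth_rows.append(
            {
                "feature_id": fid,
                "chrom": row["chrom"],
                "start": int(row["start"]),
                "end": int(row["end"]),
                "size_class": size_class,
                "direction": direction,
                "fold": fold,
            }
        )
    libs = {}
    for lib_id, mult in (("lib0", None), ("lib5", multipliers), ("lib6", multipliers)):
        libs[lib_id] = gen_srna_library(
            base_recipe,
            genome,
            feature_multipliers=mult,
            library_id=lib_id,
            seed=int(rng.integers(2**31)),
        )
    return libs, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# RNA-Seq pairs (exonuclease-treated vs untreated)
# ---------------------------------------------------------------------------


@dataclass
class DecayRecipe:
    """Parameters of the paired treated/untreated RNA-Seq simulation."""

    capped_fraction: float = 1.0  # of target-mRNA molecules
    pde_depletion_efficiency: float = 0.9
    cleavage_position: int = 0  # on the target mRNA; 3' fragments are uncapped
    total_reads: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("capped_fraction", "pde_depletion_efficiency"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def default_reference_panel(target_expression: float = 0.05) -> pd.DataFrame:
    """A fixed reference panel: 13 capped normalizers, an rRNA-like species,
    and five uncapped decay-fragment decoys, plus the target mRNA slot.

    Expression values are relative weights; capped_fraction 1.0 marks fully
    capped transcripts.  The rRNA-like species' capped fraction is set so
    5'PDE treatment removes roughly half of it at the default efficiency.
    """
    rows = []
    norm_expr = [0.050, 0.042, 0.060, 0.035, 0.055, 0.030, 0.047, 0.065, 0.038, 0.052, 0.044, 0.058, 0.040]
    for i, e in enumerate(norm_expr, start=1):
        rows.append({"reference": f"norm{i:02d}", "length": 1500, "expression": e,
                     "capped_fraction": 1.0, "is_normalizer": True})
    rows.append({"reference": "rRNA_like", "length": 120, "expression": 0.22,
                 "capped_fraction": 0.35, "is_normalizer": False})
    for i in range(1, 6):
        rows.append({"reference": f"uncapped_decoy{i}", "length": 1000, "expression": 0.02,
                     "capped_fraction": 0.2, "is_normalizer": False})
    rows.append({"reference": "target_mrna", "length": None, "expression": target_expression,
                 "capped_fraction": None, "is_normalizer": False})
    return pd.DataFrame(rows)


def gen_rnaseq_pair(
    target_mrna: str,
    references: pd.DataFrame,
    decay: DecayRecipe,
) -> dict:
    """Paired RSeq-like (untreated) and ESeq-like (5'PDE-treated) libraries.

    Molecules flagged uncapped (by reference capped_fraction, or by being 3'
    cleavage fragments of the target) are removed from the treated library
    with probability ``pde_depletion_efficiency``; capped molecules are
    untouched.  Both libraries are sampled to the same depth, so depletion
    shifts relative composition exactly as re-sequencing a depleted pool
    would.  Returns counts tables, per-nt target coverage per library, and a
    truth table of per-reference depletion.
    """
    rng = np.random.default_rng(decay.seed)
    refs = references.copy()
    L = len(target_mrna)
    refs.loc[refs["reference"] == "target_mrna", "length"] = L
    refs.loc[refs["reference"] == "target_mrna", "capped_fraction"] = decay.capped_fraction
    refs["length"] = refs["length"].astype(int)
    expr = refs["expression"].to_numpy(float)
    cap = refs["capped_fraction"].to_numpy(float)
    pde = decay.pde_depletion_efficiency
    keep = cap + (1.0 - cap) * (1.0 - pde)

    p_u = expr / expr.sum()
    counts_u = rng.multinomial(decay.total_reads, p_u)
    p_t = expr * keep
    p_t = p_t / p_t.sum()
    counts_t = rng.multinomial(decay.total_reads, p_t)

    names = refs["reference"].tolist()
    untreated = pd.DataFrame({"reference": names, "count": counts_u, "length": refs["length"]})
    treated = pd.DataFrame({"reference": names, "count": counts_t, "length": refs["length"]})

    # per-nt molecule coverage of the target: capped molecules are full
    # length, cleaved (uncapped) molecules contribute only the 3' fragment
    tgt = names.index("target_mrna")
    cov = {}
    for label, n in (("untreated", counts_u[tgt]), ("treated", counts_t[tgt])):
        if label == "untreated":
            p_capped = decay.capped_fraction
        else:
            denom = keep[tgt]
            p_capped = decay.capped_fraction / denom if denom > 0 else 1.0
        n_capped = rng.binomial(n, min(p_capped, 1.0))
        arr = np.zeros(L)
        arr[:] += n_capped
        arr[decay.cleavage_position :] += n - n_capped
        cov[label] = arr
    depletion = (1.0 - cap) * pde
    truth = pd.DataFrame(
        {
            "reference": names,
            "capped_fraction": cap,
            "expected_depletion": depletion,
            "pde_sensitive_true": depletion >= 0.15,
        }
    )
    return {
        "untreated": untreated,
        "treated": treated,
        "target_coverage": cov,
        "truth": truth,
        "normalizers": refs.loc[refs["is_normalizer"], "reference"].tolist(),
    }


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeTable:
    families: list[T2FamilyCounts]
    gus: pd.DataFrame  # family, construct, rep1..rep3 (activity), latent columns
    wildtype_mean: float

    def matched_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(gus_silencing, efficacy) arrays over matched families."""
        from .phenotypes import gus_silencing, silencing_efficacy

        eff = np.array([silencing_efficacy(f) for f in self.families])
        reps = self.gus[["rep1", "rep2", "rep3"]].to_numpy()
        gus = np.array([gus_silencing(r, self.wildtype_mean) for r in reps])
        return gus, eff


def gen_phenotypes(
    n_t1_per_construct: int = 60,
    n_t2_per_family: int = 48,
    target_correlation: float = 0.83,
    construct_effects: Mapping[str, float] | None = None,
    seed: int = 0,
    *,
    constructs: Sequence[str] = ("c1", "c2", "c3", "c4"),
    gus_noise_sd: float = 0.05,
    wildtype_mean: float = 1000.0,
) -> PhenotypeTable:
    """Correlated two-reporter phenotypes for T1 plants and their T2 families.

    A latent silencing strength is shared between the anthocyanin assay
    (four-class counts over ``n_t2_per_family`` plants) and the triplicate
    GUS activity of the matched T1 plant.  The latent bivariate-normal
    correlation is calibrated (Gaussian-copula relation plus measurement-
    noise attenuation) so the empirical Pearson r between family efficacy
    and GUS silencing targets ``target_correlation``.
    """
    if n_t2_per_family < 48:
        raise ValueError("n_t2_per_family must be >= 48 (study floor)")
    if not 0 <= target_correlation <= 1:
        raise ValueError("target_correlation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    # attenuation from class-count and assay noise around the latent signal
    var_u = 1.0 / 12.0
    v_eff = (1.0 / 12.0) / n_t2_per_family
    v_gus = gus_noise_sd**2 / 3.0
    atten = 1.0 / math.sqrt((1 + v_eff / var_u) * (1 + v_gus / var_u))
    r_uniform = min(target_correlation / atten, 1.0)
    rho = 2.0 * math.sin(math.pi * r_uniform / 6.0)  # Gaussian-copula inverse
    rho = min(rho, 0.9999)
    from scipy.stats import norm

    families = []
    gus_rows = []
    effects = dict(construct_effects or {})
    k = 0
    for construct in constructs:
        shift = effects.get(construct, 0.0)
        for _ in range(n_t1_per_construct):
            x = rng.normal()
            y = rho * x + math.sqrt(1 - rho**2) * rng.normal()
            s = float(norm.cdf(x + shift))
            t = float(norm.cdf(y + shift))
            # class probabilities chosen so E[efficacy | s] = s exactly
            p = [(1 - s) ** 2 / 2, (1 - s) ** 2 / 2, 2 * s * (1 - s), s**2]
            counts = rng.multinomial(n_t2_per_family, p)
            fam = f"{construct}_f{k:03d}"
            families.append(
                T2FamilyCounts(
                    family=fam,
                    construct=construct,
                    red=int(counts[0]),
                    red_yellow=int(counts[1]),
                    yellow_green=int(counts[2]),
                    green=int(counts[3]),
                )
            )
            reps = wildtype_mean * (1 - t) + rng.normal(0, gus_noise_sd * wildtype_mean, size=3)
            reps = np.maximum(reps, 0.0)
            gus_rows.append(
                {
                    "family": fam,
                    "construct": construct,
                    "rep1": reps[0],
                    "rep2": reps[1],
                    "rep3": reps[2],
                }
            )
            k += 1
    return PhenotypeTable(
        families=families, gus=pd.DataFrame(gus_rows), wildtype_mean=wildtype_mean
    )


def gen_fragment_count_table(
    constructs: Sequence[str] = ("c1", "c2", "c3", "c4"),
    fragments: Sequence[str] = ("chs", "gus"),
    effects: Mapping[str, Sequence[float]] | None = None,
    total_per_construct: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Cumulative sRNA counts per trigger fragment per construct.

    Under the null (no effects) every construct draws from the same fragment
    proportions; ``effects`` maps a construct to per-fragment multipliers.
    """
    rng = np.random.default_rng(seed)
    base = np.array([0.55, 0.45] if len(fragments) == 2 else [1.0 / len(fragments)] * len(fragments))
    rows = {}
    for c in constructs:
        p = base.copy()
        if effects and c in effects:
            p = p * np.asarray(effects[c], dtype=float)
        p = p / p.sum()
        rows[c] = rng.multinomial(total_per_construct, p)
    return pd.DataFrame(rows, index=list(fragments)).T
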