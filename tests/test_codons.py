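"""RCF rarity scoring, windowed profiles, ORF finding and sRNA association."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irptgs.codons import (
    CodonUsageTable,
    codon_srna_correlation,
    find_orfs,
    orf_association_fraction,
    rarity_profile,
    rcf,
    standard_amino_acid_map,
)
from irptgs.coverage import CoverageProfile


def _prof(pm):
    raw = {c: np.zeros(len(pm)) for c in ("20-21", "22", "23-24", "other")}
    raw["20-21"] = np.asarray(pm, dtype=float)
    return CoverageProfile("mrna", len(pm), 10**6, raw, {c: 0.0 for c in raw})


class TestRcf:
    def test_two_codon_hand_case(self):
        table = CodonUsageTable(
            frequency={"GAA": 0.75, "GAG": 0.25}, amino_acid={"GAA": "E", "GAG": "E"}
        )
        values = rcf(table)
        assert values["GAA"] == pytest.approx(-0.5)
        assert values["GAG"] == pytest.approx(+0.5)

    def test_uniform_usage_gives_zero(self):
        table = CodonUsageTable(
            frequency={"CAA": 0.5, "CAG": 0.5}, amino_acid={"CAA": "Q", "CAG": "Q"}
        )
        assert all(v == 0.0 for v in rcf(table).values())

    def test_single_codon_amino_acids_zero(self, codon_table):
        values = rcf(codon_table)
        assert values["ATG"] == 0.0  # Met
        assert values["TGG"] == 0.0  # Trp

    def test_zero_sum_per_amino_acid(self, codon_table):
        values = rcf(codon_table)
        for aa, codons in codon_table.synonymous_groups().items():
            assert sum(values[c] for c in codons) == pytest.approx(0.0, abs=1e-9)

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=20)
    def test_scale_invariance(self, c):
        table = CodonUsageTable.builtin()
        base = rcf(table)
        scaled_freq = dict(table.frequency)
        group = table.synonymous_groups()["L"]
        for codon in group:
            scaled_freq[codon] *= c
        scaled = rcf(CodonUsageTable(scaled_freq, table.amino_acid))
        for codon in group:
            assert scaled[codon] == pytest.approx(base[codon])

    def test_unnegated_form_recoverable(self, codon_table):
        neg = rcf(codon_table, negate=True)
        pos = rcf(codon_table, negate=False)
        for codon in neg:
            assert neg[codon] == pytest.approx(-pos[codon])


class TestRarityProfile:
    def test_single_window_is_mean_of_rcfs(self, codon_table):
        values = rcf(codon_table)
        cds = "".join(["GCT", "GCC"] * 10)  # 20 codons
        prof = rarity_profile(cds, values, window=20)
        assert len(prof.windowed) == 1
        assert prof.windowed[0] == pytest.approx(np.nanmean(prof.per_codon))

    def test_constant_rcf_gives_constant_profile(self):
        values = {"AAA": 0.3}
        prof = rarity_profile("AAA" * 40, values, window=20)
        np.testing.assert_allclose(prof.windowed, 0.3)

    def test_matches_rolling_mean_oracle(self, codon_table):
        rng = np.random.default_rng(0)
        codons = list(codon_table.frequency)
        cds = "".join(rng.choice(codons, size=100))
        values = rcf(codon_table)
        prof = rarity_profile(cds, values, window=20)
        per = [values.get(cds[3 * i : 3 * i + 3], np.nan) for i in range(100)]
        for i in range(len(prof.windowed)):
            window = [v for v in per[i : i + 20] if not np.isnan(v)]
            assert prof.windowed[i] == pytest.approx(np.mean(window))

    def test_ambiguous_codon_masked(self, codon_table):
        values = rcf(codon_table)
        cds = "GCT" * 19 + "GNN" + "GCT" * 5
        prof = rarity_profile(cds, values, window=20)
        assert np.isnan(prof.per_codon[19])
        assert not np.isnan(prof.windowed).any()

    def test_frame_violation_rejected(self, codon_table):
        with pytest.raises(ValueError):
            rarity_profile("ACGTA", rcf(codon_table))


def oracle_find_orfs(mrna, min_length):
    """Independent stop-segment scan: first ATG per stop-to-stop segment."""
    stops = {"TAA", "TAG", "TGA"}
    found = []
    for offset in range(3):
        codons = [mrna[i : i + 3] for i in range(offset, len(mrna) - 2, 3)]
        seg_start = 0
        k = 0
        while k <= len(codons):
            if k == len(codons) or codons[k] in stops:
                segment = codons[seg_start:k]
                for j, c in enumerate(segment):
                    if c == "ATG":
                        start = offset + 3 * (seg_start + j)
                        end = offset + 3 * (k + 1) if k < len(codons) else offset + 3 * k
                        if (end - start) // 3 >= min_length:
                            found.append((offset + 1, start, end))
                        break
                seg_start = k + 1
            k += 1
    return sorted(found)


class TestFindOrfs:
    def test_minimal_orf(self):
        orfs = find_orfs("ATGAAATAA", min_length=1)
        assert len(orfs) == 1
        assert (orfs[0].frame, orfs[0].start, orfs[0].end) == (1, 0, 9)
        assert orfs[0].n_codons == 3

    def test_no_atg_no_orfs(self):
        assert find_orfs("CCCCCCCCCCCC", min_length=1) == []

    def test_interval_divisible_by_three(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        for orf in find_orfs(seq, min_length=5):
            assert (orf.end - orf.start) % 3 == 0
            assert seq[orf.start : orf.start + 3] == "ATG"

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        ours = sorted((o.frame, o.start, o.end) for o in find_orfs(seq, min_length=3))
        assert ours == oracle_find_orfs(seq, 3)

    def test_secondary_orf_extending_past_primary(self):
        # find (via the independent oracle) a random sequence whose longest
        # ORF is out-extended by a shorter ORF in another frame, then check
        # the primary/secondary ranking on it
        rng = np.random.default_rng(12)
        fixture = None
        while fixture is None:
            seq = "".join(rng.choice(list("ACGT"), size=500))
            spans = oracle_find_orfs(seq, 10)
            if len(spans) < 2:
                continue
            frame_p, start_p, end_p = max(spans, key=lambda s: s[2] - s[1])
            extending = [s for s in spans if s[0] != frame_p and s[2] > end_p]
            if extending:
                fixture = (seq, (frame_p, start_p, end_p), max(extending, key=lambda s: s[2] - s[1]))
        seq, p_span, s_span = fixture
        orfs = find_orfs(seq, min_length=10)
        primary = next(o for o in orfs if o.rank == "primary")
        secondary = next(o for o in orfs if o.rank == "secondary")
        assert (primary.frame, primary.start, primary.end) == p_span
        assert (secondary.frame, secondary.start, secondary.end) == s_span
        assert secondary.end > primary.end and secondary.frame != primary.frame


class TestCodonSrnaAssociation:
    def test_coverage_proportional_to_rarity_r_one(self):
        rng = np.random.default_rng(2)
        rarity = rng.normal(0, 0.3, size=100)
        pm = np.repeat(rarity, 3) * 10 + 50
        res = codon_srna_correlation(rarity, _prof(pm))
        assert res.r == pytest.approx(1.0)

    def test_simulated_positive_coupling_significant(self):
        rng = np.random.default_rng(3)
        rarity = rng.normal(0, 0.3, size=150)
        pm = np.repeat(rarity, 3) * 20 + 100 + rng.normal(0, 5, size=450)
        res = codon_srna_correlation(rarity, _prof(pm))
        assert res.r > 0
        assert res.p <= 0.01

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(4)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            rarity = rng.normal(0, 0.3, size=80)
            pm = rng.exponential(50, size=240)
            if codon_srna_correlation(rarity, _prof(pm)).p <= 0.05:
                rejections += 1
        assert rejections / n_sim == pytest.approx(0.05, abs=0.04)

    def test_zero_variance_flagged(self):
        res = codon_srna_correlation(np.zeros(50), _prof(np.ones(150)))
        assert not res.defined


class TestOrfAssociation:
    def test_no_orfs_gives_zero(self):
        from irptgs.codons import OrfAnnotation

        res = orf_association_fraction(_prof(np.ones(300)), [])
        assert res.fraction_in_orfs == 0.0

    def test_orf_spanning_whole_sequence_gives_one(self):
        from irptgs.codons import OrfAnnotation

        orf = OrfAnnotation(1, 0, 300, "primary")
        res = orf_association_fraction(_prof(np.ones(300)), [orf])
        assert res.fraction_in_orfs == 1.0

    def test_density_ratio_arithmetic(self):
        from irptgs.codons import OrfAnnotation

        # ORF covers 25% of the sequence and holds half the abundance
        pm = np.ones(400)
        pm[:100] = 3.0  # 300 inside, 300 outside
        orf = OrfAnnotation(1, 0, 100, "primary")
        res = orf_association_fraction(_prof(pm), [orf])
        assert res.fraction_in_orfs == pytest.approx(0.5)
        assert res.density_ratio == pytest.approx(3.0)
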