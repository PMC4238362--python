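"""Generator contracts: determinism, realized mixtures, exact-substring reads."""

import numpy as np
import pytest

import irptgs as G
from irptgs import simulate as S
from irptgs.coverage import ReferenceIndex, size_class


class TestToyGenome:
    def test_deterministic_given_seed(self):
        a = S.gen_toy_genome(seed=5)
        b = S.gen_toy_genome(seed=5)
        assert a.features.equals(b.features)
        assert [c[1] for c in a.chromosomes] == [c[1] for c in b.chromosomes]

    def test_infinite_concentration_puts_all_clusters_in_window(self):
        g = S.gen_toy_genome(
            seed=1, concentration=float("inf"),
            n_features={"hc_cluster": 30, "mirna": 5, "tasirna": 2, "gene": 5},
        )
        assert g.pericentromeric_fraction_of_features("hc_cluster") == 1.0

    def test_default_concentration_exceeds_window_fraction(self, toy_genome):
        frac = toy_genome.pericentromeric_fraction_of_features("hc_cluster")
        assert frac > 0.2  # window is 20% of each chromosome

    def test_features_within_bounds_and_disjoint(self, toy_genome):
        lengths = {name: len(seq) for name, seq, _ in toy_genome.chromosomes}
        for chrom, sub in toy_genome.features.groupby("chrom"):
            assert (sub["start"] >= 0).all()
            assert (sub["end"] <= lengths[chrom]).all()
            ivals = sorted(zip(sub["start"], sub["end"]))
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                assert e1 <= s2

    def test_excess_demand_rejected(self):
        with pytest.raises(ValueError):
            S.gen_toy_genome(chrom_length=2_000, n_features={"gene": 100, "hc_cluster": 0, "mirna": 0, "tasirna": 0})


class TestSrnaLibrary:
    def test_deterministic_given_seed(self, construct):
        recipe = S.LibraryRecipe(total_reads=20_000, transgene_fraction=1.0, seed=3)
        a = S.gen_srna_library(recipe, construct=construct)
        b = S.gen_srna_library(recipe, construct=construct)
        assert a.reads == b.reads

    def test_transgene_fraction_within_reported_range(self, construct, toy_genome):
        recipe = S.LibraryRecipe(total_reads=150_000, seed=4)
        lib = S.gen_srna_library(recipe, toy_genome, construct)
        idx = ReferenceIndex({"pre": construct.precursor_sequence})
        transgene = sum(c for r, c in lib.reads.items() if idx.matches(r))
        frac = transgene / lib.total_reads
        assert 0.057 <= frac <= 0.096

    def test_zero_transgene_fraction_no_precursor_reads(self, construct, toy_genome):
        recipe = S.LibraryRecipe(total_reads=30_000, transgene_fraction=0.0, seed=5)
        lib = S.gen_srna_library(recipe, toy_genome)
        idx = ReferenceIndex({"pre": construct.precursor_sequence})
        assert sum(c for r, c in lib.reads.items() if idx.matches(r)) == 0

    def test_every_read_is_exact_substring_of_a_source(self, construct, toy_genome):
        recipe = S.LibraryRecipe(total_reads=20_000, seed=6)
        lib = S.gen_srna_library(recipe, toy_genome, construct)
        sources = dict(toy_genome.sequences())
        sources["pre"] = construct.precursor_sequence
        idx = ReferenceIndex(sources)
        assert all(idx.matches(r) for r in lib.reads)

    def test_size_mix_matches_recipe_within_sampling_error(self, construct):
        recipe = S.LibraryRecipe(total_reads=100_000, transgene_fraction=1.0, seed=7)
        lib = S.gen_srna_library(recipe, construct=construct)
        by_class = {}
        for r, c in lib.reads.items():
            by_class[size_class(len(r))] = by_class.get(size_class(len(r)), 0) + c
        total = sum(by_class.values())
        for cls, expect in recipe.transgene_size_mix.items():
            assert by_class.get(cls, 0) / total == pytest.approx(expect, abs=0.01)

    def test_loop_decay_orders_peak_abundance(self, construct):
        recipe = S.LibraryRecipe(total_reads=80_000, transgene_fraction=1.0,
                                 loop_decay_length=250.0, seed=8)
        truth = S.transgene_peak_table(recipe, construct)
        lib = S.gen_srna_library(recipe, construct=construct)
        prof = G.map_reads(lib, construct.precursor_sequence)
        pm = prof.per_million()
        realized = []
        for _, row in truth.iterrows():
            apex = int(row["arm1_pos"])
            realized.append(pm[max(apex - 20, 0) : apex + 20].sum())
        # analytic expected weights decrease with loop distance; realized
        # counts must follow the same ranking (allowing adjacent-rank noise)
        order = np.argsort(truth["loop_distance"].to_numpy())
        realized = np.array(realized)[order]
        rho = np.corrcoef(np.arange(len(realized)), realized)[0, 1]
        assert rho < -0.9

    def test_fraction_requires_construct(self, toy_genome):
        recipe = S.LibraryRecipe(total_reads=1000, transgene_fraction=0.5, seed=9)
        with pytest.raises(ValueError):
            S.gen_srna_library(recipe, toy_genome, None)

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            S.LibraryRecipe(transgene_size_mix={"20-21": 0.5, "22": 0.2, "23-24": 0.2})


class TestPlantDifferentialLoci:
    def test_truth_table_deterministic(self, toy_genome):
        base = S.LibraryRecipe(total_reads=30_000, transgene_fraction=0.0, seed=0)
        _, t1 = S.plant_differential_loci(toy_genome, base, n_up=5, n_down=5, seed=2)
        _, t2 = S.plant_differential_loci(toy_genome, base, n_up=5, n_down=5, seed=2)
        assert t1.equals(t2)

    def test_no_planting_gives_exchangeable_libraries(self, toy_genome):
        base = S.LibraryRecipe(total_reads=60_000, transgene_fraction=0.0, seed=0)
        libs, truth = S.plant_differential_loci(toy_genome, base, n_up=0, n_down=0, seed=3)
        assert truth.empty
        totals = [lib.total_reads for lib in libs.values()]
        assert max(totals) - min(totals) < 0.05 * np.mean(totals)

    def test_median_realized_fold_near_planted(self, toy_genome):
        base = S.LibraryRecipe(total_reads=200_000, transgene_fraction=0.0, seed=0)
        libs, truth = S.plant_differential_loci(toy_genome, base, fold=2.0, seed=4)
        refs = toy_genome.sequences()
        covs = {lid: G.map_reads_multi(l, refs, lengths=(23, 24)) for lid, l in libs.items()}
        folds = []
        for _, row in truth.iterrows():
            pm0 = covs["lib0"][row["chrom"]].per_million("23-24")[row["start"] : row["end"]].sum()
            pm5 = covs["lib5"][row["chrom"]].per_million("23-24")[row["start"] : row["end"]].sum()
            if pm0 > 0 and pm5 > 0:
                ratio = pm5 / pm0
                folds.append(ratio if row["direction"] == "over" else 1 / ratio)
        assert 1.8 <= float(np.median(folds)) <= 2.2


class TestRnaseqPair:
    def test_no_depletion_gives_identically_distributed_pair(self):
        panel = S.default_reference_panel()
        pair = S.gen_rnaseq_pair(
            "ACGT" * 300, panel, S.DecayRecipe(capped_fraction=0.3, pde_depletion_efficiency=0.0, seed=5)
        )
        u = pair["untreated"].set_index("reference")["count"]
        t = pair["treated"].set_index("reference")["count"]
        # multinomial draws from identical composition: compare proportions
        for ref in u.index:
            pu, pt = u[ref] / u.sum(), t[ref] / t.sum()
            assert pt == pytest.approx(pu, abs=4 * np.sqrt(pu * (1 - pu) / u.sum()) + 1e-4)

    def test_all_capped_ratio_one_within_sampling_error(self):
        panel = S.default_reference_panel()
        panel = panel.assign(capped_fraction=panel["capped_fraction"].where(panel["capped_fraction"].isna(), 1.0))
        pair = S.gen_rnaseq_pair("ACGT" * 300, panel, S.DecayRecipe(capped_fraction=1.0, seed=6))
        u = pair["untreated"].set_index("reference")["count"]
        t = pair["treated"].set_index("reference")["count"]
        for ref in u.index:
            if u[ref] > 100:
                assert t[ref] / u[ref] == pytest.approx(1.0, abs=0.15)

    def test_rrna_like_depletion_near_default(self):
        panel = S.default_reference_panel()
        pair = S.gen_rnaseq_pair("ACGT" * 300, panel, S.DecayRecipe(capped_fraction=1.0, seed=7))
        truth = pair["truth"].set_index("reference")
        # (1 - capped) * pde = 0.65 * 0.9 — the species the treatment removes
        assert truth.loc["rRNA_like", "expected_depletion"] == pytest.approx(0.585)
        assert bool(truth.loc["rRNA_like", "pde_sensitive_true"])


class TestPhenotypeGenerator:
    def test_deterministic(self):
        a = S.gen_phenotypes(seed=8)
        b = S.gen_phenotypes(seed=8)
        assert a.gus.equals(b.gus)
        assert a.families == b.families

    def test_floor_on_family_size(self):
        with pytest.raises(ValueError):
            S.gen_phenotypes(n_t2_per_family=20)

    def test_construct_effect_shifts_efficacy(self):
        pheno = S.gen_phenotypes(seed=9, construct_effects={"c1": 1.5})
        from irptgs.phenotypes import silencing_efficacy

        eff = {}
        for f in pheno.families:
            eff.setdefault(f.construct, []).append(silencing_efficacy(f))
        assert np.mean(eff["c1"]) > np.mean(eff["c2"]) + 0.15
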