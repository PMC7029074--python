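import numpy as np
import pytest

from hybridzone.simulate import (
    CLASSES,
    HaplotypePool,
    ParentalPopulation,
    generate_parental_populations,
    sample_individuals,
    simulate_hybrid_classes,
)


def _allele_sets(pop):
    return [set(f) for f in pop.allele_freqs]


class TestParentalPopulations:
    def test_full_divergence_all_loci_diagnostic(self):
        p, w = generate_parental_populations(divergence=1.0, seed=1)
        for sp, sw in zip(_allele_sets(p), _allele_sets(w)):
            assert not sp & sw

    def test_zero_divergence_all_loci_shared(self):
        p, w = generate_parental_populations(divergence=0.0, seed=1)
        for sp, sw in zip(_allele_sets(p), _allele_sets(w)):
            assert sp == sw

    def test_partial_divergence_ceil_rule(self):
        p, w = generate_parental_populations(n_loci=12, divergence=0.5, seed=1)
        n_diag = sum(
            not (sp & sw) for sp, sw in zip(_allele_sets(p), _allele_sets(w))
        )
        assert n_diag == 6

    def test_same_seed_identical(self):
        a = generate_parental_populations(seed=9)
        b = generate_parental_populations(seed=9)
        assert a[0].allele_freqs == b[0].allele_freqs
        assert a[1].mt_haplotypes.seqs == b[1].mt_haplotypes.seqs

    def test_frequencies_sum_to_one(self):
        p, _ = generate_parental_populations(seed=2)
        for f in p.allele_freqs:
            assert sum(f.values()) == pytest.approx(1.0, abs=1e-9)
        assert p.mt_haplotypes.freqs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_allele_rejected(self):
        with pytest.raises(ValueError):
            generate_parental_populations(alleles_per_locus=1)


def _fixed_pop(freq, tag="P"):
    pool = HaplotypePool(["h1"], ["ACGT"], np.array([1.0]))
    return ParentalPopulation(
        species_tag=tag,
        loci=["MS01"],
        allele_freqs=[freq],
        mt_haplotypes=pool,
        nuclear_seq_alleles=pool,
        rflp_pattern=(100,),
    )


class TestHardyWeinbergSampling:
    def test_fixed_locus_all_homozygous(self):
        ds = sample_individuals(_fixed_pop({"150": 1.0}), 20, seed=1)
        assert all(
            tuple(ds.genotypes.calls[i, 0]) == ("150", "150") for i in range(20)
        )

    def test_heterozygosity_within_three_se(self):
        # biallelic p = 0.5: E[het] = 0.5, SE = sqrt(0.25/n)
        n = 2000
        ds = sample_individuals(_fixed_pop({"150": 0.5, "152": 0.5}), n, seed=2)
        het = np.mean(
            [ds.genotypes.calls[i, 0, 0] != ds.genotypes.calls[i, 0, 1] for i in range(n)]
        )
        assert abs(het - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_same_seed_same_matrix(self):
        p, _ = generate_parental_populations(seed=3)
        a = sample_individuals(p, 10, seed=4)
        b = sample_individuals(p, 10, seed=4)
        assert a.genotypes == b.genotypes


class TestHybridClasses:
    def test_class_counts_exact(self, small_classes):
        counts = small_classes.labels["class"].value_counts()
        assert all(counts[c] == 100 for c in CLASSES)

    def test_f1_heterozygous_everywhere_on_diagnostic_panel(
        self, diagnostic_pops, small_classes
    ):
        pop_p, _ = diagnostic_pops
        p_alleles = [set(f) for f in pop_p.allele_freqs]
        gm = small_classes.genotypes
        idx = {i: k for k, i in enumerate(gm.individual_ids)}
        for iid in small_classes.ids_of("F1"):
            for l in range(gm.n_loci):
                a, b = gm.calls[idx[iid], l]
                assert (a in p_alleles[l]) != (b in p_alleles[l])

    def test_f2_segregation_quarter_half_quarter(self, diagnostic_pops):
        pop_p, pop_w = diagnostic_pops
        n = 1000
        ds = simulate_hybrid_classes(
            pop_p, pop_w, {"F2": n}, seed=21
        )
        p_alleles = set(pop_p.allele_freqs[0])
        gm = ds.genotypes
        kinds = {"PP": 0, "PW": 0, "WW": 0}
        for i in range(n):
            a, b = gm.calls[i, 0]
            np_cnt = (a in p_alleles) + (b in p_alleles)
            kinds[["WW", "PW", "PP"][np_cnt]] += 1
        for kind, p in (("PP", 0.25), ("PW", 0.5), ("WW", 0.25)):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(kinds[kind] / n - p) < 4 * se

    def test_backcross_never_homozygous_for_other_species(
        self, diagnostic_pops, small_classes
    ):
        pop_p, pop_w = diagnostic_pops
        w_alleles = [set(f) for f in pop_w.allele_freqs]
        gm = small_classes.genotypes
        idx = {i: k for k, i in enumerate(gm.individual_ids)}
        for iid in small_classes.ids_of("Bkc_Pit"):
            for l in range(gm.n_loci):
                a, b = gm.calls[idx[iid], l]
                assert not (a in w_alleles[l] and b in w_alleles[l])

    def test_f1_allele_frequency_conservation(self, diagnostic_pops):
        # E[freq in F1] = mean of parental frequencies; checked at n = 5000
        pop_p, pop_w = diagnostic_pops
        n = 5000
        ds = simulate_hybrid_classes(pop_p, pop_w, {"F1": n}, seed=22)
        locus = 0
        expected = {
            a: 0.5 * pop_p.allele_freqs[locus].get(a, 0.0)
            + 0.5 * pop_w.allele_freqs[locus].get(a, 0.0)
            for a in set(pop_p.allele_freqs[locus]) | set(pop_w.allele_freqs[locus])
        }
        obs = {}
        for i in range(n):
            for a in ds.genotypes.calls[i, locus]:
                obs[a] = obs.get(a, 0) + 1
        for a, e in expected.items():
            se = np.sqrt(e * (1 - e) / (2 * n))
            assert abs(obs.get(a, 0) / (2 * n) - e) < 4 * se + 1e-12

    @pytest.mark.parametrize("direction,species", [("P-mother", "P"), ("W-mother", "W")])
    def test_mtdna_follows_cross_direction(self, diagnostic_pops, direction, species):
        pop_p, pop_w = diagnostic_pops
        ds = simulate_hybrid_classes(
            pop_p, pop_w, {"F1": 20, "F2": 20, "Bkc_Pit": 20, "Bkc_Wil": 20},
            direction=direction, seed=23,
        )
        assert set(ds.mt["species"]) == {species}
        pool = (pop_p if species == "P" else pop_w).mt_haplotypes
        assert set(ds.mt["sequence"]) <= set(pool.seqs)

    def test_pure_classes_keep_own_mtdna(self, small_classes):
        mt = small_classes.mt.set_index("id")["species"]
        for iid in small_classes.ids_of("P_pit"):
            assert mt[iid] == "P"
        for iid in small_classes.ids_of("P_wil"):
            assert mt[iid] == "W"

    def test_missing_rate_injection(self, diagnostic_pops):
        pop_p, pop_w = diagnostic_pops
        ds = simulate_hybrid_classes(
            pop_p, pop_w, {"P_pit": 500}, seed=24, missing_rate=0.1
        )
        frac = ds.genotypes.is_missing().mean()
        assert 0.05 < frac < 0.15

    def test_unknown_direction_rejected(self, diagnostic_pops):
        with pytest.raises(ValueError, match="direction"):
            simulate_hybrid_classes(*diagnostic_pops, 5, direction="sideways")
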