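"""Generator contracts: determinism, placement rules, mating-system
invariants, and read-simulation arithmetic."""

import numpy as np
import pytest

from tepop import io as tio
from tepop.synthetic import (
    FAMILIES, SpeciesProfile, build_reference, simulate_population,
    simulate_read_pairs, simulate_reads, simulate_sites,
)


class TestBuildReference:
    def test_parameter_echo(self):
        bundle = build_reference(
            n_chromosomes=1, chrom_length=100_000, n_genes=20,
            n_te_family_members=2, pericentromere_fraction=0.2, seed=1,
        )
        assert len(bundle.te_library) == 8
        assert len(bundle.genes["chr1"]) == 20
        (start, end), = bundle.pericentromeres["chr1"]
        assert end - start == 20_000
        assert len(bundle.masked_genome["chr1"]) == 100_000
        assert set(fam for fam, _ in bundle.te_library.values()) == set(FAMILIES)

    def test_te_sequences_long_and_distinct(self):
        bundle = build_reference(chrom_length=50_000, n_genes=5, seed=7)
        seqs = [s for _, s in bundle.te_library.values()]
        assert all(len(s) >= 400 for s in seqs)
        assert len(set(seqs)) == len(seqs)

    def test_genes_outside_pericentromere(self):
        bundle = build_reference(chrom_length=100_000, n_genes=30, seed=3)
        (ps, pe), = bundle.pericentromeres["chr1"]
        for a, b in bundle.genes["chr1"]:
            assert b <= ps or a >= pe

    def test_same_seed_byte_identical_files(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        build_reference(chrom_length=30_000, n_genes=5, seed=9).write(d1)
        build_reference(chrom_length=30_000, n_genes=5, seed=9).write(d2)
        for name in ("genome.fa", "genome.masked.fa", "te_library.fa",
                     "genes.gff3", "pericentromeres.bed"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_roundtrip_via_files(self, tmp_path):
        bundle = build_reference(chrom_length=30_000, n_genes=5, seed=9)
        bundle.write(tmp_path)
        back = type(bundle).load(tmp_path)
        assert back.chromosomes == bundle.chromosomes
        assert back.te_library == bundle.te_library
        assert back.genes == bundle.genes
        assert back.pericentromeres == bundle.pericentromeres

    def test_zero_genes_is_valid(self):
        bundle = build_reference(chrom_length=20_000, n_genes=0, seed=1)
        assert bundle.genes["chr1"] == []

    def test_rejects_impossible_parameters(self):
        with pytest.raises(ValueError):
            build_reference(chrom_length=5_000)
        with pytest.raises(ValueError):
            build_reference(chrom_length=20_000, pericentromere_fraction=0.7)
        with pytest.raises(ValueError):
            # arms cannot hold this many non-overlapping genes
            build_reference(chrom_length=12_000, n_genes=50,
                            gene_length_range=(500, 800), seed=1)

    def test_masked_spans_are_reference_te_copies(self):
        bundle = build_reference(chrom_length=100_000, n_genes=5, seed=2)
        spans = bundle.masked_spans()["chr1"]
        assert spans, "expected planted reference TE copies"
        lib = {seq for _, seq in bundle.te_library.values()}
        for a, b in spans:
            assert bundle.chromosomes["chr1"][a:b] in lib


class TestSimulateSites:
    def test_spacing_and_margins(self, small_bundle, small_sites):
        positions = sorted(s.pos for s in small_sites)
        assert all(b - a >= 500 for a, b in zip(positions, positions[1:]))
        L = len(small_bundle.chromosomes["chr1"])
        assert all(500 <= p <= L - 500 for p in positions)

    def test_rejects_unsatisfiable_spacing(self, small_bundle):
        with pytest.raises(ValueError):
            simulate_sites(small_bundle, 500, seed=1)


class TestSimulatePopulation:
    def test_frequency_one_fixes_site(self, small_bundle, small_sites):
        profile = SpeciesProfile("s", "selfing", 6,
                                 site_frequency_model=lambda rng, n: np.ones(n))
        pop = simulate_population(small_bundle, profile, sites=small_sites, seed=5)
        for ind in pop.individuals:
            assert all(ind.genotypes.get(s) == 2 for s in small_sites)

    def test_selfers_never_heterozygous(self, selfing_population):
        for ind in selfing_population.individuals:
            assert set(ind.genotypes.values()) <= {2}

    def test_outcrosser_heterozygote_fraction_hardy_weinberg(self, small_bundle, small_sites):
        # at f = 0.5 the heterozygote probability is exactly 1/2
        profile = SpeciesProfile("o", "outcrossing", 400,
                                 site_frequency_model=lambda rng, n: np.full(n, 0.5))
        pop = simulate_population(small_bundle, profile, sites=small_sites[:1], seed=6)
        site = pop.sites[0]
        n_het = sum(ind.genotypes.get(site) == 1 for ind in pop.individuals)
        # binomial(400, 0.5): 4 sigma band around 200
        assert abs(n_het - 200) < 4 * np.sqrt(400 * 0.25)

    def test_population_frequency_converges(self, small_bundle, small_sites):
        profile = SpeciesProfile("s", "selfing", 600,
                                 site_frequency_model=lambda rng, n: np.full(n, 0.3))
        pop = simulate_population(small_bundle, profile, sites=small_sites, seed=8)
        carrier_frac = np.mean([
            np.mean([s in ind.genotypes for ind in pop.individuals])
            for s in pop.sites
        ])
        assert abs(carrier_frac - 0.3) < 0.03

    def test_truth_table_columns(self, selfing_population):
        df = selfing_population.truth_frame()
        assert list(df.columns) == ["sample_id", "chrom", "pos0", "family", "copy_count"]
        assert set(df["copy_count"]) <= {1, 2}


class TestSimulateReads:
    def test_pair_count_near_expectation(self, small_bundle, selfing_population):
        ind = selfing_population.individuals[0]
        pairs = simulate_read_pairs(small_bundle, ind, 20.0, seed=10)
        expected = 20.0 * 100_000 / (2 * 108)  # ~9259
        assert abs(len(pairs) - expected) < 5 * np.sqrt(expected)

    def test_error_free_reads_are_reference_substrings(self, small_bundle):
        from tepop.synthetic import IndividualTruth

        empty = IndividualTruth("none", {})
        pairs = simulate_read_pairs(small_bundle, empty, 2.0, seed=11)
        genome = small_bundle.chromosomes["chr1"]
        for _, r1, r2 in pairs[:200]:
            assert r1 in genome
            assert tio.revcomp(r2) in genome

    def test_rejects_tight_insert(self, small_bundle, selfing_population):
        ind = selfing_population.individuals[0]
        with pytest.raises(ValueError):
            simulate_read_pairs(small_bundle, ind, 10.0, read_length=108,
                                insert_mean=200.0, seed=1)

    def test_junction_pairs_at_expected_rate(self):
        # homozygous carrier: pairs with one mate fully inside the TE and the
        # other fully genomic arise from ~2 sides x 2 haplotypes x (i - 2r)
        # start positions at rate coverage/(4 r) per position (Lander-Waterman)
        from tepop.synthetic import IndividualTruth

        bundle = build_reference(chrom_length=100_000, n_genes=0,
                                 n_reference_te_copies=0, seed=21)
        site = simulate_sites(bundle, 1, seed=22)[0]
        ind = IndividualTruth("hom", {site: 2})
        cov, r, i = 30.0, 108, 430.0
        pairs = simulate_read_pairs(bundle, ind, cov, insert_mean=i,
                                    insert_sd=25.0, seed=12)
        te_seq = bundle.te_sequence(site.te_name)
        genome = bundle.chromosomes["chr1"]

        def where(read):
            for s in (read, tio.revcomp(read)):
                if s in te_seq:
                    return "te"
                if s in genome:
                    return "genome"
            return "junction"

        n_junction = sum(
            {where(r1), where(r2)} == {"te", "genome"} for _, r1, r2 in pairs
        )
        lam = 4 * (i - 2 * r) * cov / (4 * r)
        assert abs(n_junction - lam) < 5 * np.sqrt(lam) + 5

    def test_same_seed_byte_identical_fastq(self, small_bundle, selfing_population, tmp_path):
        ind = selfing_population.individuals[0]
        p1 = simulate_reads(small_bundle, ind, 2.0, tmp_path / "a", seed=13)
        p2 = simulate_reads(small_bundle, ind, 2.0, tmp_path / "b", seed=13)
        assert open(p1[0], "rb").read() == open(p2[0], "rb").read()
        assert open(p1[1], "rb").read() == open(p2[1], "rb").read()
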