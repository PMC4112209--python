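"""Copy-number stratification, population frequencies (with a haplotype
enumeration oracle), spectra, and distance-to-gene binning."""

import numpy as np
import pytest

from tepop.genotyping import InsertionSite
from tepop.popgen import (
    ARMS, CENTROMERIC, GENOME_WIDE, bin_by_distance, copy_number_per_individual,
    distance_to_nearest_gene, frequency_spectrum, population_frequency,
    species_site_frequencies,
)


def _site(pos, calls, family="LTR", chrom="chr1", sid=""):
    return InsertionSite(sid or f"s{pos}", chrom, pos, family, calls, [pos])


PERI = {"chr1": [(40_000, 60_000)]}


class TestCopyNumber:
    def test_presence_based_count(self):
        sites = [_site(100 * i, {"A": "homozygous"}) for i in range(3)]
        sites += [_site(10_000 + 100 * i, {"A": "heterozygous"}) for i in range(2)]
        df = copy_number_per_individual(sites, ["A"])
        assert df.loc["A", "total"] == 5

    def test_dosage_counts_homozygotes_twice(self):
        sites = [_site(100, {"A": "homozygous"}), _site(900, {"A": "heterozygous"})]
        df = copy_number_per_individual(sites, ["A"], dosage=True)
        assert df.loc["A", "total"] == 3

    def test_compartment_partition(self):
        sites = [_site(1_000, {"A": "homozygous"}),      # arm
                 _site(50_000, {"A": "homozygous"}),     # pericentromere
                 _site(95_000, {"A": "heterozygous"})]   # arm
        gw = copy_number_per_individual(sites, ["A"], GENOME_WIDE)
        arms = copy_number_per_individual(sites, ["A"], ARMS, PERI)
        cen = copy_number_per_individual(sites, ["A"], CENTROMERIC, PERI)
        assert arms.loc["A", "total"] + cen.loc["A", "total"] == gw.loc["A", "total"]
        assert cen.loc["A", "total"] == 1

    def test_per_family_breakdown(self):
        sites = [_site(100, {"A": "homozygous"}, "LTR"),
                 _site(900, {"A": "homozygous"}, "DNA")]
        df = copy_number_per_individual(sites, ["A"])
        assert df.loc["A", "LTR"] == 1 and df.loc["A", "DNA"] == 1

    def test_stratified_counts_need_intervals(self):
        with pytest.raises(ValueError):
            copy_number_per_individual([_site(1, {"A": "homozygous"})], ["A"], ARMS)


class TestPopulationFrequency:
    def test_selfing_carrier_fraction(self):
        site = _site(100, {f"s{i}": "homozygous" for i in range(4)})
        samples = [f"s{i}" for i in range(8)]
        assert population_frequency(site, samples, "selfing") == pytest.approx(0.5)

    def test_outcrossing_haplotype_counting(self):
        # 2 hom + 1 het + 1 absent of 4 individuals; enumerate haplotypes:
        # hom contributes both, het one, absent none -> 5 of 8
        site = _site(100, {"i1": "homozygous", "i2": "homozygous", "i3": "heterozygous"})
        samples = ["i1", "i2", "i3", "i4"]
        carriers = {"i1": 2, "i2": 2, "i3": 1, "i4": 0}
        oracle = sum(carriers.values()) / (2 * len(samples))
        assert population_frequency(site, samples, "outcrossing") == pytest.approx(oracle)
        assert oracle == pytest.approx(0.625)

    def test_fixed_in_sample(self):
        samples = [f"s{i}" for i in range(8)]
        site = _site(100, {s: "homozygous" for s in samples})
        assert population_frequency(site, samples, "selfing") == 1.0

    def test_selfing_treats_het_calls_as_carriers(self):
        site = _site(100, {"s0": "heterozygous"})
        assert population_frequency(site, ["s0", "s1"], "selfing") == pytest.approx(0.5)

    def test_empty_sample_list_fatal(self):
        with pytest.raises(ValueError):
            population_frequency(_site(100, {}), [], "selfing")

    def test_subsampling_is_seeded(self):
        sites = [_site(100 * k, {f"s{i}": "homozygous" for i in range(k)})
                 for k in range(1, 9)]
        samples = [f"s{i}" for i in range(10)]
        a = species_site_frequencies(sites, samples, "selfing", subsample=4, seed=7)
        b = species_site_frequencies(sites, samples, "selfing", subsample=4, seed=7)
        assert a.equals(b)


class TestFrequencySpectrum:
    def test_degenerate_all_fixed(self):
        spec = frequency_spectrum([1.0] * 10, n_boot=50, seed=1)
        assert spec.proportions[-1] == 1.0
        assert spec.ci_low[-1] == spec.ci_high[-1] == 1.0
        assert spec.n_sites == 10

    def test_exclude_fixed_empties_spectrum(self):
        spec = frequency_spectrum([1.0] * 10, include_fixed=False, seed=1)
        assert spec.n_sites == 0 and not spec.defined

    def test_proportions_sum_to_one(self, rng):
        freqs = rng.random(200) * 0.999 + 0.001
        spec = frequency_spectrum(freqs, n_boot=50, seed=2)
        assert spec.proportions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(spec.ci_low <= spec.proportions + 1e-12)
        assert np.all(spec.proportions <= spec.ci_high + 1e-12)

    def test_adding_a_site_increments_its_bin(self):
        base = [0.05, 0.55, 0.95]
        spec0 = frequency_spectrum(base, n_boot=10, seed=3)
        spec1 = frequency_spectrum(base + [0.55], n_boot=10, seed=3)
        counts0 = spec0.proportions * spec0.n_sites
        counts1 = spec1.proportions * spec1.n_sites
        assert counts1[5] == counts0[5] + 1

    def test_rejects_zero_or_out_of_range(self):
        with pytest.raises(ValueError):
            frequency_spectrum([0.0, 0.5])
        with pytest.raises(ValueError):
            frequency_spectrum([0.5, 1.2])


class TestDistanceToGene:
    GENES = {"chr1": [(1_300, 2_000), (3_000, 3_500)]}

    @pytest.mark.parametrize("pos,expected", [
        (1_200, 100),     # 100 bp upstream of a gene start
        (1_500, 0),       # inside a gene
        (2_249, 250),     # equidistant between gene end (1999) and next start
        (2_750, 250),
        (0, 1_300),
    ])
    def test_distances(self, pos, expected):
        site = _site(pos, {"A": "homozygous"})
        assert distance_to_nearest_gene(site, [], gene_map=self.GENES) == expected

    def test_no_genes_is_undefined(self):
        site = _site(100, {"A": "homozygous"}, chrom="chr2")
        assert distance_to_nearest_gene(site, [], gene_map={"chr2": []}) is None


class TestBinByDistance:
    GENES = {"chr1": [(10_000, 12_000)]}

    def test_binning_and_moments(self):
        # one individual with sites at distances 50, 60, 150 -> bins [2, 1]
        sites = [_site(10_000 - 50, {"A": "homozygous"}),
                 _site(10_000 - 60, {"A": "homozygous"}),
                 _site(12_000 - 1 + 150, {"A": "homozygous"})]
        table = bin_by_distance(sites, self.GENES, ["A"], bin_width=100,
                                max_distance=500).frame()
        assert table.loc[0, "mean"] == 2
        assert table.loc[1, "mean"] == 1

    def test_boundary_distances(self):
        # distance 0 -> bin 0; distance exactly 100 -> bin 1 (half-open bins)
        sites = [_site(10_500, {"A": "homozygous"}),            # inside gene, d=0
                 _site(10_000 - 100, {"A": "homozygous"})]      # d=100
        table = bin_by_distance(sites, self.GENES, ["A"], bin_width=100,
                                max_distance=300).frame()
        assert table.loc[0, "mean"] == 1 and table.loc[1, "mean"] == 1

    def test_mean_and_se_across_individuals(self):
        sites = [_site(9_950, {"A": "homozygous", "B": "homozygous"}),
                 _site(9_920, {"A": "homozygous"})]
        table = bin_by_distance(sites, self.GENES, ["A", "B"], bin_width=100,
                                max_distance=200).frame()
        assert table.loc[0, "mean"] == pytest.approx(1.5)
        assert table.loc[0, "se"] == pytest.approx(np.std([2, 1], ddof=1) / np.sqrt(2))
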