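"""Aligner conventions, pair classification rules, and clustering of
supporting evidence into insertion observations."""

import numpy as np
import pytest

from tepop import io as tio
from tepop.evidence import (
    MateAlignment, PairAlignment, PairEvidence, align_reads, classify_pairs,
    detect_insertions, estimate_frequency, load_sam_pairs, write_sam,
    ExactReadAligner,
)
from tepop.synthetic import ReferenceBundle

TE_FAMS = {"TE_A": "LTR", "TE_B": "DNA"}


def _bundle_with_duplication(seed=5):
    """Small hand-built bundle: chr with a duplicated 300-bp block and one
    masked TE copy, so multi-mapping and TE-mapping rules can be probed."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    rand = lambda n: "".join(bases[i] for i in rng.integers(0, 4, n))
    block = rand(300)
    te_seq = rand(450)
    chrom = rand(2000) + block + rand(1500) + block + rand(1000) + te_seq + rand(800)
    te_start = 2000 + 300 + 1500 + 300 + 1000
    masked = chrom[:te_start] + "N" * 450 + chrom[te_start + 450:]
    return ReferenceBundle(
        chromosomes={"chrA": chrom}, genes={"chrA": []}, pericentromeres={"chrA": []},
        te_library={"TE_A": ("LTR", te_seq), "TE_B": ("DNA", rand(420))},
        masked_genome={"chrA": masked},
    ), block, te_seq, te_start


class TestExactAligner:
    def test_unique_read_coordinates(self, small_bundle, aligner):
        read = small_bundle.chromosomes["chr1"][5000:5108]
        aln = aligner.map_read(read)
        assert aln.mapped and aln.unique
        assert (aln.rname, aln.pos, aln.strand) == ("chr1", 5000, "+")

    def test_reverse_strand_read(self, small_bundle, aligner):
        read = tio.revcomp(small_bundle.chromosomes["chr1"][7000:7108])
        aln = aligner.map_read(read)
        assert aln.mapped and aln.unique and aln.strand == "-" and aln.pos == 7000

    def test_duplicated_read_flagged_multimapped(self):
        bundle, block, _, _ = _bundle_with_duplication()
        aln = ExactReadAligner(bundle, seed_length=32).map_read(block[:108])
        assert aln.mapped and not aln.unique

    def test_te_read_maps_to_library_not_genome(self):
        bundle, _, te_seq, _ = _bundle_with_duplication()
        aln = ExactReadAligner(bundle, seed_length=32).map_read(te_seq[100:208])
        assert aln.unique and aln.rname == "TE_A"

    def test_unseen_read_unmapped(self, aligner):
        assert not aligner.map_read("A" * 108).mapped

    def test_sam_pos_is_one_based(self, small_bundle, aligner, tmp_path):
        read = small_bundle.chromosomes["chr1"][5000:5108]
        fq = tio.write_fastq_pair(tmp_path / "x", [("r1", read, tio.revcomp(read))])
        sam = align_reads(fq[0], fq[1], small_bundle, tmp_path / "x.sam", aligner=aligner)
        pos_field = [l.split("\t") for l in open(sam) if l.startswith("r1")][0][3]
        assert pos_field == "5001"

    def test_sam_roundtrip_preserves_alignments(self, small_bundle, aligner, tmp_path):
        genome = small_bundle.chromosomes["chr1"]
        pairs = [
            (f"p{i}", genome[s:s + 108], tio.revcomp(genome[s + 322:s + 430]))
            for i, s in enumerate(range(3000, 4000, 100))
        ]
        alns = list(aligner.align_pairs(pairs))
        write_sam(alns, small_bundle, tmp_path / "rt.sam")
        back = {p.name: p for p in load_sam_pairs(tmp_path / "rt.sam")}
        assert len(back) == len(alns)
        for a in alns:
            b = back[a.name]
            for m_in, m_out in ((a.mate1, b.mate1), (a.mate2, b.mate2)):
                assert (m_in.mapped, m_in.unique) == (m_out.mapped, m_out.unique)
                if m_in.mapped:
                    assert (m_in.rname, m_in.pos, m_in.strand) == \
                        (m_out.rname, m_out.pos, m_out.strand)

    def test_sam_without_sq_header_is_fatal(self, tmp_path):
        bad = tmp_path / "bad.sam"
        bad.write_text("@HD\tVN:1.6\nr1\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")
        with pytest.raises(ValueError, match="@SQ"):
            list(load_sam_pairs(bad))

    def test_unequal_mate_counts_fatal(self, tmp_path):
        (tmp_path / "a_1.fastq").write_text("@r1/1\nACGT\n+\nIIII\n@r2/1\nACGT\n+\nIIII\n")
        (tmp_path / "a_2.fastq").write_text("@r1/2\nACGT\n+\nIIII\n")
        with pytest.raises(ValueError, match="unequal"):
            list(tio.iter_fastq_pairs(tmp_path / "a_1.fastq", tmp_path / "a_2.fastq"))


def _pair(name, m1, m2):
    return PairAlignment(name, m1, m2)


def _mate(rname, pos, strand="+", unique=True, length=108):
    return MateAlignment(mapped=True, unique=unique, rname=rname, pos=pos,
                         strand=strand, length=length)


class TestClassifyPairs:
    def test_genomic_plus_te_is_supporting_forward(self):
        ev, = classify_pairs(
            [_pair("r", _mate("chr1", 10_000, "+"), _mate("TE_A", 50))], TE_FAMS)
        assert ev.kind == "supporting"
        assert ev.side == "forward"
        assert ev.genomic_pos == 10_108  # proximal end of the forward mate
        assert (ev.te_id, ev.te_family) == ("TE_A", "LTR")

    def test_reverse_genomic_mate_gives_reverse_side(self):
        ev, = classify_pairs(
            [_pair("r", _mate("TE_B", 10), _mate("chr1", 20_000, "-"))], TE_FAMS)
        assert (ev.side, ev.genomic_pos, ev.te_family) == ("reverse", 20_000, "DNA")

    def test_concordant_pair_is_spanning(self):
        ev, = classify_pairs(
            [_pair("r", _mate("chr1", 10_000, "+"), _mate("chr1", 10_322, "-"))],
            TE_FAMS, insert_mean=430, insert_sd=25)
        assert ev.kind == "spanning"
        assert (ev.span_start, ev.span_end) == (10_108, 10_322)

    def test_discordant_insert_dropped(self):
        out = classify_pairs(
            [_pair("r", _mate("chr1", 10_000, "+"), _mate("chr1", 14_000, "-"))],
            TE_FAMS, insert_mean=430, insert_sd=25)
        assert out == []

    def test_multimapped_genomic_mate_dropped(self):
        out = classify_pairs(
            [_pair("r", _mate("chr1", 10_000, "+", unique=False), _mate("TE_A", 5))],
            TE_FAMS)
        assert out == []

    def test_both_te_dropped(self):
        out = classify_pairs(
            [_pair("r", _mate("TE_A", 5), _mate("TE_B", 9))], TE_FAMS)
        assert out == []

    def test_outward_facing_pair_dropped(self):
        out = classify_pairs(
            [_pair("r", _mate("chr1", 10_000, "-"), _mate("chr1", 10_322, "+"))],
            TE_FAMS, insert_mean=430, insert_sd=25)
        assert out == []


def _support(read_id, pos, side, family="LTR"):
    return PairEvidence(read_id, "chr1", pos, side, "TE_A", family, "supporting")


def _span(read_id, start, end):
    return PairEvidence(read_id, "chr1", start, None, None, None, "spanning",
                        span_start=start, span_end=end)


class TestDetectInsertions:
    def test_two_sided_cluster_midpoint(self):
        ev = [_support(f"f{i}", p, "forward") for i, p in enumerate([9940, 9960, 9980])]
        ev += [_support(f"r{i}", p, "reverse") for i, p in enumerate([10020, 10040, 10060])]
        obs, = detect_insertions(ev, cluster_window=505, min_support=2)
        assert obs.pos_estimate == (9980 + 10020) // 2 == 10_000
        assert (obs.n_support_fwd, obs.n_support_rev, obs.n_spanning) == (3, 3, 0)
        assert obs.freq_estimate == 1.0
        assert obs.both_sided

    def test_below_min_support_not_emitted(self):
        assert detect_insertions([_support("f1", 9980, "forward")],
                                 min_support=2) == []

    def test_single_sided_frequency_is_support_ratio(self):
        ev = [_support(f"f{i}", 10_000 - 10 * i, "forward") for i in range(4)]
        ev += [_span(f"s{i}", 9_500, 10_400) for i in range(4)]
        obs, = detect_insertions(ev, cluster_window=505, min_support=2)
        assert obs.pos_estimate == 10_000
        assert obs.n_spanning == 4
        assert obs.freq_estimate == pytest.approx(0.5)

    def test_spanning_requires_strict_containment(self):
        ev = [_support(f"f{i}", 10_000, "forward") for i in range(2)]
        ev += [_span("edge", 10_000, 10_400),   # starts exactly at the estimate
               _span("inside", 9_900, 10_100),
               _span("outside", 10_100, 10_500)]
        obs, = detect_insertions(ev, cluster_window=505, min_support=2)
        assert obs.n_spanning == 1

    def test_families_never_merge(self):
        ev = [_support("a1", 10_000, "forward", "LTR"),
              _support("a2", 10_010, "forward", "LTR"),
              _support("b1", 10_000, "forward", "DNA"),
              _support("b2", 10_010, "forward", "DNA")]
        obs = detect_insertions(ev, min_support=2)
        assert sorted(o.family for o in obs) == ["DNA", "LTR"]

    def test_excluded_regions_suppress_evidence(self):
        ev = [_support(f"f{i}", 10_000, "forward") for i in range(3)]
        assert detect_insertions(ev, exclude_regions={"chr1": [(9_000, 11_000)]}) == []
        assert len(detect_insertions(ev, exclude_regions={"chr1": [(20_000, 21_000)]})) == 1

    def test_order_invariance(self, rng):
        ev = []
        for k in range(40):
            pos = int(rng.integers(0, 50_000))
            if rng.random() < 0.7:
                ev.append(_support(f"e{k}", pos, ("forward", "reverse")[int(rng.integers(2))],
                                   ("LTR", "DNA")[int(rng.integers(2))]))
            else:
                ev.append(_span(f"e{k}", pos, pos + int(rng.integers(100, 400))))
        ref = detect_insertions(ev, min_support=1)
        for _ in range(5):
            perm = [ev[i] for i in rng.permutation(len(ev))]
            assert detect_insertions(perm, min_support=1) == ref

    def test_single_side_clustering_matches_transitive_closure(self, rng):
        # greedy left-to-right chaining must equal the brute-force closure of
        # the pairwise |a-b| <= window relation on sorted positions
        for _ in range(50):
            n = int(rng.integers(1, 60))
            window = int(rng.integers(10, 400))
            positions = sorted(int(p) for p in rng.integers(0, 3_000, n))
            ev = [_support(f"e{i}", p, "forward") for i, p in enumerate(positions)]
            obs = detect_insertions(ev, cluster_window=window, min_support=1)
            # oracle: union-find over all pairs
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    if abs(positions[i] - positions[j]) <= window:
                        parent[find(i)] = find(j)
            comps = {}
            for i in range(n):
                comps.setdefault(find(i), []).append(positions[i])
            expected = sorted((max(v), len(v)) for v in comps.values())
            got = sorted((o.pos_estimate, o.n_support) for o in obs)
            assert got == expected


class TestEstimateFrequency:
    @pytest.mark.parametrize("support,spanning,expected",
                             [(6, 4, 0.6), (5, 0, 1.0), (1, 9, 0.1)])
    def test_ratio(self, support, spanning, expected):
        assert estimate_frequency(support, spanning) == pytest.approx(expected)

    def test_zero_denominator_is_error(self):
        with pytest.raises(ValueError):
            estimate_frequency(0, 0)


class TestEndToEndSample:
    def test_homozygous_sites_recovered_with_frequency_one(
            self, small_bundle, selfing_population, aligner):
        from tepop.evidence import detect_sample
        from tepop.synthetic import simulate_read_pairs

        ind = selfing_population.individuals[0]
        pairs = simulate_read_pairs(small_bundle, ind, 20.0, seed=42)
        obs = detect_sample(pairs, small_bundle, ind.sample_id, aligner=aligner)
        truth = {(s.chrom, s.pos) for s in ind.genotypes}
        matched = 0
        for chrom, pos in truth:
            hits = [o for o in obs if o.chrom == chrom and abs(o.pos_estimate - pos) <= 200]
            if hits:
                matched += 1
                assert all(h.freq_estimate > 0.8 for h in hits)
        assert matched >= 0.9 * len(truth)
        for o in obs:
            assert any(o.chrom == c and abs(o.pos_estimate - p) <= 500 for c, p in truth)
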