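"""Seeded end-to-end experiments measuring pipeline performance on synthetic
truth: site recovery, genotype-call accuracy, hybrid/pooled/reference-swap
controls, statistical calibration and bootstrap coverage.

Every experiment takes a single integer seed and derives named substreams
from it, so results are reproducible and independent of execution order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evidence import ExactReadAligner, detect_sample
from .genotyping import (
    ABSENT, HETEROZYGOUS, HOMOZYGOUS, InsertionSite, merge_across_samples,
    sharing_counts,
)
from .popgen import frequency_spectrum
from .stats import kruskal_wallis, poisson_glm_counts, rank_sum, wilcoxon_signed_rank
from .synthetic import (
    IndividualTruth, Population, ReferenceBundle, SpeciesProfile, TrueSite,
    build_reference, default_profiles, simulate_population, simulate_read_pairs,
    simulate_sites,
)
from .validation import (
    SampleReads, hybrid_check, make_diverged_bundle, pooled_vs_individual,
    reference_swap,
)


def subseed(seed: int, name: str) -> int:
    """Deterministic named substream seed, kept below 2**31."""
    return (int(seed) * 1_000_003 + zlib.crc32(name.encode())) % (2**31)


# ---------------------------------------------------------------------------
# Main detection experiment


@dataclass
class DetectionResult:
    """Outcome of the full synthetic three-species detection experiment."""

    metrics: dict[str, float]
    bundle: ReferenceBundle
    sites_true: list[TrueSite]
    populations: list[Population]
    called_sites: list[InsertionSite]
    species_of: dict[str, str]
    copy_numbers: dict[str, int] = field(default_factory=dict)


def _match_called(called: Sequence[InsertionSite], site: TrueSite,
                  window: int) -> InsertionSite | None:
    best, best_d = None, None
    for c in called:
        if c.chrom != site.chrom or c.family != site.family:
            continue
        d = abs(c.pos_consensus - site.pos)
        if d <= window and (best_d is None or d < best_d):
            best, best_d = c, d
    return best


def detection_experiment(
    seed: int,
    chrom_length: int = 500_000,
    n_sites: int = 50,
    n_individuals: int = 8,
    coverage: float = 20.0,
    n_genes: int = 60,
    error_rate: float = 0.0,
    insert_mean: float = 430.0,
    insert_sd: float = 25.0,
    min_support: int = 2,
    identity_window: int = 200,
    position_tolerance: int = 200,
    false_site_margin: int = 500,
) -> DetectionResult:
    """Simulate three species over a shared site pool, run detection and
    genotyping, and score against the truth table.

    Recovery is scored over true sites carried by at least one sequenced
    individual (a pool site left uncarried by the finite sample emits no
    reads and is unrecoverable in principle). A called site counts as false
    when no true site of any family lies within ``false_site_margin`` bp.
    """
    bundle = build_reference(
        chrom_length=chrom_length, n_genes=n_genes, seed=subseed(seed, "ref"),
    )
    sites = simulate_sites(bundle, n_sites, seed=subseed(seed, "sites"))
    profiles = default_profiles({p: n_individuals for p in
                                 ("grandiflora", "orientalis", "rubella")})
    populations = [
        simulate_population(bundle, prof, sites=sites, seed=subseed(seed, f"pop:{prof.name}"))
        for prof in profiles
    ]

    aligner = ExactReadAligner(bundle)
    all_obs = []
    species_of: dict[str, str] = {}
    for pop in populations:
        for ind in pop.individuals:
            species_of[ind.sample_id] = pop.profile.name
            pairs = simulate_read_pairs(
                bundle, ind, coverage, insert_mean=insert_mean, insert_sd=insert_sd,
                error_rate=error_rate, seed=subseed(seed, f"reads:{ind.sample_id}"),
            )
            all_obs.extend(detect_sample(
                pairs, bundle, ind.sample_id, insert_mean=insert_mean,
                insert_sd=insert_sd, min_support=min_support, aligner=aligner,
            ))

    called = merge_across_samples(all_obs, identity_window=identity_window)

    carried = sorted({s for pop in populations for ind in pop.individuals
                      for s in ind.genotypes})
    recovered = [s for s in carried if _match_called(called, s, position_tolerance)]

    true_positions = {(s.chrom, s.pos) for s in sites}
    false_sites = [
        c for c in called
        if not any(ch == c.chrom and abs(p - c.pos_consensus) <= false_site_margin
                   for ch, p in true_positions)
    ]

    # genotype accuracy against the truth table
    hom_total = hom_correct = het_total = het_correct = 0
    matched: dict[TrueSite, InsertionSite | None] = {
        s: _match_called(called, s, position_tolerance) for s in carried
    }
    for pop in populations:
        selfing = pop.profile.mating_system == "selfing"
        for ind in pop.individuals:
            for site, copies in ind.genotypes.items():
                call_site = matched.get(site)
                call = call_site.call_for(ind.sample_id) if call_site else ABSENT
                if selfing or copies == 2:
                    hom_total += 1
                    hom_correct += call == HOMOZYGOUS
                elif copies == 1:
                    het_total += 1
                    het_correct += call == HETEROZYGOUS

    shares = sharing_counts(called, species_of)
    unique = sum(n for subset, n in shares.items() if len(subset) == 1)

    metrics = {
        "n_true_sites": float(len(sites)),
        "n_carried_sites": float(len(carried)),
        "n_called_sites": float(len(called)),
        "site_recovery_pct": 100.0 * len(recovered) / max(len(carried), 1),
        "false_sites": float(len(false_sites)),
        "homozygous_call_accuracy_pct": 100.0 * hom_correct / max(hom_total, 1),
        "heterozygous_call_accuracy_pct": 100.0 * het_correct / max(het_total, 1),
        "species_unique_site_pct": 100.0 * unique / max(len(called), 1),
    }
    result = DetectionResult(metrics, bundle, sites, populations, called, species_of)
    # per-sample genome-wide copy numbers (presence-based)
    for sample in species_of:
        result.copy_numbers[sample] = sum(
            c.call_for(sample) != ABSENT for c in called
        )
    return result


def species_copy_statistics(result: DetectionResult) -> dict[str, float]:
    """Kruskal-Wallis on per-individual copy numbers across the three species."""
    groups: dict[str, list[int]] = {}
    for sample, species in result.species_of.items():
        groups.setdefault(species, []).append(result.copy_numbers[sample])
    kw = kruskal_wallis([groups[s] for s in sorted(groups)])
    means = {s: float(np.mean(v)) for s, v in groups.items()}
    return {"kw_H": kw.statistic, "kw_p": kw.p_value, **{f"mean_{s}": m for s, m in means.items()}}


# ---------------------------------------------------------------------------
# Hybrid check replicates


def _simulate_selfed_parents(bundle: ReferenceBundle, seed: int,
                             n_shared: int = 8, n_private: int = 8,
                             coverage: float = 30.0) -> tuple[SampleReads, SampleReads]:
    sites = simulate_sites(bundle, n_shared + 2 * n_private, seed=subseed(seed, "sites"))
    shared = sites[:n_shared]
    p1_only = sites[n_shared:n_shared + n_private]
    p2_only = sites[n_shared + n_private:]
    t1 = IndividualTruth("parent1", {s: 2 for s in shared + p1_only})
    t2 = IndividualTruth("parent2", {s: 2 for s in shared + p2_only})
    r1 = simulate_read_pairs(bundle, t1, coverage, seed=subseed(seed, "reads1"))
    r2 = simulate_read_pairs(bundle, t2, coverage, seed=subseed(seed, "reads2"))
    return SampleReads(t1, r1), SampleReads(t2, r2)


def hybrid_experiment(seed: int, n_replicates: int = 10,
                      chrom_length: int = 120_000, coverage: float = 30.0) -> dict[str, float]:
    """Replicated hybrid self-check on small genomes with known truth."""
    holds = 0
    frac_high_parents: list[float] = []
    frac_high_hybrid: list[float] = []
    het_rates: list[float] = []
    for r in range(n_replicates):
        rep_seed = subseed(seed, f"hybrid:{r}")
        bundle = build_reference(chrom_length=chrom_length, n_genes=10,
                                 seed=subseed(rep_seed, "ref"))
        p1, p2 = _simulate_selfed_parents(bundle, rep_seed, coverage=coverage)
        report = hybrid_check(p1, p2, bundle)
        holds += report.pattern_holds
        frac_high_parents.append((report.frac_high["parent1"] + report.frac_high["parent2"]) / 2)
        frac_high_hybrid.append(report.frac_high["hybrid"])
        het_rates.append(report.het_rate_discordant)
    return {
        "pattern_holds_pct": 100.0 * holds / n_replicates,
        "parent_high_freq_pct": 100.0 * float(np.mean(frac_high_parents)),
        "hybrid_high_freq_pct": 100.0 * float(np.mean(frac_high_hybrid)),
        "hybrid_het_rate_discordant_pct": 100.0 * float(np.nanmean(het_rates)),
        "n_replicates": float(n_replicates),
    }


# ---------------------------------------------------------------------------
# Merging oracle


def brute_force_merge_partition(items: Sequence[tuple[str, str, int]],
                                window: int) -> set[frozenset[int]]:
    """Reference partition: connected components of the pairwise
    same-chromosome, same-family, |Δpos| ≤ window relation."""
    n = len(items)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, fi, pi = items[i]
            cj, fj, pj = items[j]
            if ci == cj and fi == fj and abs(pi - pj) <= window:
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def merge_oracle_experiment(seed: int, n_instances: int = 1000,
                            max_observations: int = 200, window: int = 200) -> dict[str, float]:
    """Greedy chaining vs brute-force transitive closure on random instances."""
    from .evidence import InsertionObservation

    rng = np.random.default_rng(subseed(seed, "merge-oracle"))
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(1, max_observations + 1))
        chroms = rng.integers(1, 3, n)
        fams = rng.integers(0, 2, n)
        positions = rng.integers(0, 4000, n)
        obs = [
            InsertionObservation(
                sample_id=f"s{int(rng.integers(4))}", chrom=f"chr{c}",
                pos_estimate=int(p), family=("LTR", "DNA")[f],
                n_support_fwd=2, n_support_rev=2, n_spanning=0, freq_estimate=1.0,
            )
            for c, f, p in zip(chroms, fams, positions)
        ]
        sites = merge_across_samples(obs, identity_window=window)
        expected = brute_force_merge_partition(
            [(o.chrom, o.family, o.pos_estimate) for o in obs], window
        )
        agree += _partitions_equal(obs, sites, expected)
    return {"merge_oracle_agreement_pct": 100.0 * agree / n_instances,
            "n_instances": float(n_instances)}


def _partitions_equal(obs, sites, expected: set[frozenset[int]]) -> bool:
    # reconstruct the chain partition by assigning each observation index to
    # the unique site whose member-position multiset it belongs to
    from collections import Counter

    buckets: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for i, o in enumerate(obs):
        buckets.setdefault((o.chrom, o.family), []).append((o.pos_estimate, i))
    site_members = {
        id(s): Counter(s.member_positions) for s in sites
    }
    assignment: dict[int, set[int]] = {}
    for site in sites:
        assignment[id(site)] = set()
    for (chrom, fam), members in buckets.items():
        cands = [s for s in sites if s.chrom == chrom and s.family == fam]
        for pos, i in sorted(members):
            home = None
            for s in cands:
                c = site_members[id(s)]
                if c.get(pos, 0) > 0:
                    home = s
                    c[pos] -= 1
                    break
            if home is None:
                return False
            assignment[id(home)].add(i)
    got = [g for g in assignment.values() if g]
    return {frozenset(g) for g in got} == expected


# ---------------------------------------------------------------------------
# Statistical calibration and power


def type1_error_experiment(seed: int, n_replicates: int = 2000,
                           alpha: float = 0.05) -> dict[str, float]:
    """Empirical type-I error of each test under its null."""
    rng = np.random.default_rng(subseed(seed, "type1"))
    rej = {"kruskal_wallis": 0, "wilcoxon": 0, "rank_sum": 0, "poisson_glm": 0}
    for _ in range(n_replicates):
        g = [rng.normal(size=15) for _ in range(3)]
        rej["kruskal_wallis"] += kruskal_wallis(g).p_value < alpha
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        rej["wilcoxon"] += wilcoxon_signed_rank(a, b).p_value < alpha
        rej["rank_sum"] += rank_sum(rng.normal(size=20), rng.normal(size=20)).p_value < alpha
        counts = rng.poisson(5.0, size=40)
        labels = ["a"] * 20 + ["b"] * 20
        rej["poisson_glm"] += poisson_glm_counts(counts, labels)[0].p_value < alpha
    return {f"type1_{k}": v / n_replicates for k, v in rej.items()} | {
        "n_replicates": float(n_replicates)
    }


def ordering_power_experiment(seed: int, n_replicates: int = 500,
                              means: tuple[float, float, float] = (10.0, 15.0, 20.0),
                              group_sizes: tuple[int, int, int] = (10, 8, 24),
                              alpha: float = 0.01) -> dict[str, float]:
    """Power to detect and order three species with low/mid/high copy numbers.

    Group sizes follow the three-species study design (10, 8 and 24
    individuals).
    """
    rng = np.random.default_rng(subseed(seed, "power"))
    ok = 0
    for _ in range(n_replicates):
        groups = [rng.poisson(m, size=n) for m, n in zip(means, group_sizes)]
        kw = kruskal_wallis(groups)
        sample_means = [g.mean() for g in groups]
        ok += (kw.p_value < alpha) and (sample_means == sorted(sample_means))
    return {"ordering_recovery_pct": 100.0 * ok / n_replicates,
            "n_replicates": float(n_replicates)}


def spectrum_coverage_experiment(seed: int, n_replicates: int = 150,
                                 n_sites: int = 400, n_boot: int = 200,
                                 ci: float = 0.95) -> dict[str, float]:
    """Coverage of site-bootstrap CIs against a known multinomial spectrum."""
    rng = np.random.default_rng(subseed(seed, "spectrum"))
    edges = np.linspace(0, 1, 11)
    true_p = np.array([0.22, 0.14, 0.10, 0.08, 0.07, 0.06, 0.06, 0.07, 0.08, 0.12])
    true_p = true_p / true_p.sum()
    covered = total = 0
    for r in range(n_replicates):
        counts = rng.multinomial(n_sites, true_p)
        freqs = np.concatenate([
            edges[i] + (edges[i + 1] - edges[i]) * (1 - rng.random(c))  # (low, high]
            for i, c in enumerate(counts)
        ])
        spec = frequency_spectrum(freqs, bin_edges=edges, n_boot=n_boot, ci=ci,
                                  seed=subseed(seed, f"boot:{r}"))
        covered += int(np.sum((spec.ci_low <= true_p) & (true_p <= spec.ci_high)))
        total += len(true_p)
    return {"spectrum_ci_coverage_pct": 100.0 * covered / total,
            "n_replicates": float(n_replicates)}


# ---------------------------------------------------------------------------
# Reference swap


def _distinct_abundance_profiles(n_individuals: int) -> list[SpeciesProfile]:
    """Three designed species whose simulated abundances are clearly ordered
    low < mid < high (via site occupancy), so "ordering preserved" is a
    well-posed question."""
    return [
        SpeciesProfile("low", "selfing", n_individuals,
                       site_frequency_model=("beta", 1.5, 1.5), site_occupancy=0.30),
        SpeciesProfile("mid", "selfing", n_individuals,
                       site_frequency_model=("beta", 1.5, 1.5), site_occupancy=0.60),
        SpeciesProfile("high", "outcrossing", n_individuals,
                       site_frequency_model=("beta", 1.5, 1.5), site_occupancy=0.95),
    ]


def swap_experiment(seed: int, chrom_length: int = 150_000, n_sites: int = 30,
                    n_individuals: int = 4, coverage: float = 20.0,
                    divergence: float = 0.01) -> dict[str, float]:
    """Species abundance ordering under a diverged alternative reference.

    The baseline to preserve is the simulated design ordering low < mid <
    high; the experiment checks that it survives remapping against a genome
    carrying ~1% random substitutions.
    """
    bundle = build_reference(chrom_length=chrom_length, n_genes=15,
                             seed=subseed(seed, "ref"))
    sites = simulate_sites(bundle, n_sites, seed=subseed(seed, "sites"))
    reads: dict[str, list] = {}
    for prof in _distinct_abundance_profiles(n_individuals):
        pop = simulate_population(bundle, prof, sites=sites,
                                  seed=subseed(seed, f"pop:{prof.name}"))
        reads[prof.name] = [
            simulate_read_pairs(bundle, ind, coverage,
                                seed=subseed(seed, f"reads:{ind.sample_id}"))
            for ind in pop.individuals
        ]
    simulated_ranking = ["low", "mid", "high"]

    aligner = ExactReadAligner(bundle)
    base_means = {}
    for species, sets in reads.items():
        counts = [len(detect_sample(p, bundle, f"{species}_{i}", aligner=aligner))
                  for i, p in enumerate(sets)]
        base_means[species] = float(np.mean(counts))
    baseline_ranking = sorted(base_means, key=lambda s: base_means[s])

    alt = make_diverged_bundle(bundle, divergence=divergence, seed=subseed(seed, "div"))
    report = reference_swap(reads, alt, simulated_ranking)
    out = {
        "swap_ordering_preserved": float(report.ordering_preserved),
        "swap_baseline_matches_design": float(baseline_ranking == simulated_ranking),
    }
    for s in sorted(base_means):
        out[f"swap_count_reduction_pct_{s}"] = (
            100.0 * (1 - report.mean_counts[s] / base_means[s]) if base_means[s] else 0.0
        )
    return out


# ---------------------------------------------------------------------------
# Pooled vs individual


def pooled_experiment(seed: int, chrom_length: int = 150_000, n_sites: int = 30,
                      n_individuals: int = 4, coverage: float = 20.0) -> dict[str, float]:
    """Pooled vs per-individual agreement on species with clearly distinct
    mean copy numbers (low / mid / high site occupancy)."""
    bundle = build_reference(chrom_length=chrom_length, n_genes=15,
                             seed=subseed(seed, "ref"))
    sites = simulate_sites(bundle, n_sites, seed=subseed(seed, "sites"))
    reads = {}
    for prof in _distinct_abundance_profiles(n_individuals):
        pop = simulate_population(bundle, prof, sites=sites,
                                  seed=subseed(seed, f"pop:{prof.name}"))
        reads[prof.name] = [
            simulate_read_pairs(bundle, ind, coverage,
                                seed=subseed(seed, f"reads:{ind.sample_id}"))
            for ind in pop.individuals
        ]
    report = pooled_vs_individual(reads, bundle)
    return {
        "pooled_ranking_agrees": float(report.ranking_agrees),
        "pooled_kw_p": report.kruskal_p,
    }
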