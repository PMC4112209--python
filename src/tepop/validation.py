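"""End-to-end self-checks of the detection pipeline.

Three control experiments, run on synthetic data with known truth:

* **Hybrid check** — detection on two fully homozygous (selfed) samples and
  on the merge of their reads. If frequency-threshold genotyping works, the
  pure samples concentrate at inferred frequency 1 while the merge shifts
  sites homozygous in exactly one parent toward 0.5 (heterozygous calls).
* **Pooled vs individual** — species abundance conclusions should not depend
  on whether individuals are analysed separately or as one pooled sample.
* **Reference swap** — rerunning detection against a diverged alternative
  reference and/or a restricted TE database; the between-species abundance
  ordering should be preserved even though absolute counts drop
  (reference-bias control).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import io as tio
from .evidence import ExactReadAligner, InsertionObservation, detect_sample
from .genotyping import HETEROZYGOUS, call_genotype
from .stats import kruskal_wallis
from .synthetic import IndividualTruth, ReferenceBundle, TrueSite

ReadPairs = list[tuple[str, str, str]]


# ---------------------------------------------------------------------------
# Read merging


def merge_read_sets(read_sets: Sequence[ReadPairs]) -> ReadPairs:
    """Concatenate read sets; names are tagged per input (when merging more
    than one set) so pairing stays unambiguous even if ids collide."""
    if len(read_sets) == 1:
        return list(read_sets[0])
    merged: ReadPairs = []
    for i, pairs in enumerate(read_sets):
        merged.extend((f"m{i}|{name}", r1, r2) for name, r1, r2 in pairs)
    return merged


def merge_samples(fastq_sets: Sequence[tuple[str, str]],
                  out_prefix: str | os.PathLike) -> tuple[str, str]:
    """Merge paired FASTQ files into one pair (the "pooled sample")."""
    def _pairs():
        lengths: set[int] = set()
        tag_inputs = len(fastq_sets) > 1
        for i, (fq1, fq2) in enumerate(fastq_sets):
            for name, r1, r2 in tio.iter_fastq_pairs(fq1, fq2):
                lengths.add(len(r1))
                if len(lengths) > 1:
                    raise ValueError("incompatible read lengths across inputs")
                yield (f"m{i}|{name}" if tag_inputs else name), r1, r2

    return tio.write_fastq_pair(out_prefix, _pairs())


# ---------------------------------------------------------------------------
# Hybrid check


@dataclass
class SampleReads:
    """Reads plus ground truth for one simulated sample."""

    truth: IndividualTruth
    pairs: ReadPairs


@dataclass
class HybridReport:
    frac_high: dict[str, float]      # per run: fraction of insertions at freq >= 0.8
    frac_intermediate: dict[str, float]  # per run: fraction in [0.2, 0.8]
    het_rate_discordant: float       # hybrid het-call rate at one-parent-only sites
    n_discordant: int
    pattern_holds: bool
    warning: str = ""


def _freq_fractions(observations: Sequence[InsertionObservation],
                    low: float = 0.2, high: float = 0.8) -> tuple[float, float]:
    kept = [o for o in observations if o.freq_estimate >= low]
    if not kept:
        return float("nan"), float("nan")
    n_high = sum(o.freq_estimate >= high for o in kept)
    n_mid = sum(low <= o.freq_estimate < high for o in kept)
    return n_high / len(kept), n_mid / len(kept)


def hybrid_check(
    parent1: SampleReads,
    parent2: SampleReads,
    ref: ReferenceBundle,
    insert_mean: float = 430.0,
    insert_sd: float = 25.0,
    min_support: int = 2,
    identity_window: int = 200,
    aligner: ExactReadAligner | None = None,
) -> HybridReport:
    """Run detection on two homozygous parents and their read merge."""
    shared = set(parent1.truth.genotypes) & set(parent2.truth.genotypes)
    warning = ""
    if set(parent1.truth.genotypes) == set(parent2.truth.genotypes):
        warning = "parents carry identical insertion sets; hybrid check is uninformative"

    aligner = aligner or ExactReadAligner(ref)
    runs = {
        "parent1": parent1.pairs,
        "parent2": parent2.pairs,
        "hybrid": merge_read_sets([parent1.pairs, parent2.pairs]),
    }
    obs: dict[str, list[InsertionObservation]] = {}
    for name, pairs in runs.items():
        obs[name] = detect_sample(
            pairs, ref, name, insert_mean=insert_mean, insert_sd=insert_sd,
            min_support=min_support, aligner=aligner,
        )

    frac_high, frac_mid = {}, {}
    for name in runs:
        frac_high[name], frac_mid[name] = _freq_fractions(obs[name])

    discordant = (set(parent1.truth.genotypes) ^ set(parent2.truth.genotypes))
    n_het = 0
    n_called = 0
    for site in discordant:
        match = _nearest_observation(obs["hybrid"], site, identity_window)
        if match is None:
            continue
        n_called += 1
        if call_genotype(match.freq_estimate) == HETEROZYGOUS:
            n_het += 1
    het_rate = n_het / n_called if n_called else float("nan")

    pattern = bool(
        discordant
        and n_called > 0
        and frac_high["hybrid"] < frac_high["parent1"]
        and frac_high["hybrid"] < frac_high["parent2"]
        and het_rate >= 0.5
    )
    return HybridReport(frac_high, frac_mid, het_rate, len(discordant), pattern, warning)


def _nearest_observation(observations: Sequence[InsertionObservation],
                         site: TrueSite, window: int) -> InsertionObservation | None:
    best, best_d = None, None
    for o in observations:
        if o.chrom != site.chrom or o.family != site.family:
            continue
        d = abs(o.pos_estimate - site.pos)
        if d <= window and (best_d is None or d < best_d):
            best, best_d = o, d
    return best


# ---------------------------------------------------------------------------
# Pooled vs individual


@dataclass
class PooledReport:
    individual_means: dict[str, float]
    pooled_copy_estimates: dict[str, float]  # sum of pooled insertion frequencies
    ranking_individual: list[str]
    ranking_pooled: list[str]
    ranking_agrees: bool
    kruskal_p: float


def pooled_vs_individual(
    species_reads: Mapping[str, Sequence[ReadPairs]],
    ref: ReferenceBundle,
    insert_mean: float = 430.0,
    insert_sd: float = 25.0,
    min_support: int = 2,
    aligner: ExactReadAligner | None = None,
) -> PooledReport:
    """Compare species copy-number conclusions per-individual vs pooled.

    In pooled mode the per-species copy-number estimate is the sum of the
    pooled insertion-frequency estimates (the expected number of insertions
    per individual), the pooled analogue of the per-individual mean count.
    """
    if len(species_reads) < 2:
        raise ValueError("need at least two species")
    aligner = aligner or ExactReadAligner(ref)

    per_ind_counts: dict[str, list[int]] = {}
    pooled_estimates: dict[str, float] = {}
    for species in sorted(species_reads):
        counts = []
        for i, pairs in enumerate(species_reads[species]):
            observations = detect_sample(
                pairs, ref, f"{species}_{i}", insert_mean=insert_mean,
                insert_sd=insert_sd, min_support=min_support, aligner=aligner,
            )
            counts.append(sum(o.freq_estimate >= 0.2 for o in observations))
        per_ind_counts[species] = counts
        pooled_obs = detect_sample(
            merge_read_sets(list(species_reads[species])), ref, f"{species}_pooled",
            insert_mean=insert_mean, insert_sd=insert_sd, min_support=min_support,
            aligner=aligner,
        )
        pooled_estimates[species] = float(sum(o.freq_estimate for o in pooled_obs))

    means = {s: float(np.mean(c)) for s, c in per_ind_counts.items()}
    rank_ind = sorted(means, key=lambda s: means[s])
    rank_pool = sorted(pooled_estimates, key=lambda s: pooled_estimates[s])
    kw = kruskal_wallis([per_ind_counts[s] for s in sorted(per_ind_counts)])
    return PooledReport(
        means, pooled_estimates, rank_ind, rank_pool,
        ranking_agrees=rank_ind == rank_pool, kruskal_p=kw.p_value,
    )


# ---------------------------------------------------------------------------
# Reference swap


def make_diverged_bundle(ref: ReferenceBundle, divergence: float = 0.01,
                         seed: int = 0) -> ReferenceBundle:
    """A copy of the bundle whose genome carries random substitutions.

    Emulates mapping against a related species' assembly; masked positions
    stay masked, annotation and TE library are carried over unchanged.
    """
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    new_chroms: dict[str, str] = {}
    new_masked: dict[str, str] = {}
    for chrom in sorted(ref.chromosomes):
        arr = np.frombuffer(ref.chromosomes[chrom].encode(), dtype=np.uint8).copy()
        hit = rng.random(len(arr)) < divergence
        idx = np.flatnonzero(hit)
        if len(idx):
            arr[idx] = bases[(np.searchsorted(bases, arr[idx])
                              + rng.integers(1, 4, len(idx))) % 4]
        new_chroms[chrom] = arr.tobytes().decode()
        masked = np.frombuffer(ref.masked_genome[chrom].encode(), dtype=np.uint8).copy()
        keep = masked != ord("N")
        masked[keep] = arr[keep]
        new_masked[chrom] = masked.tobytes().decode()
    return ReferenceBundle(
        new_chroms, {c: list(v) for c, v in ref.genes.items()},
        {c: list(v) for c, v in ref.pericentromeres.items()},
        dict(ref.te_library), new_masked,
    )


def subset_te_library(ref: ReferenceBundle, families: Iterable[str]) -> ReferenceBundle:
    """Restrict the TE database to the given families (alternative TE db)."""
    wanted = set(families)
    lib = {n: fs for n, fs in ref.te_library.items() if fs[0] in wanted}
    if not lib:
        raise ValueError("TE library subset is empty")
    return ReferenceBundle(
        dict(ref.chromosomes), {c: list(v) for c, v in ref.genes.items()},
        {c: list(v) for c, v in ref.pericentromeres.items()}, lib,
        dict(ref.masked_genome),
    )


@dataclass
class SwapReport:
    mean_counts: dict[str, float]
    ranking: list[str]
    baseline_ranking: list[str]
    ordering_preserved: bool


def reference_swap(
    species_reads: Mapping[str, Sequence[ReadPairs]],
    alt_ref: ReferenceBundle,
    baseline_ranking: Sequence[str],
    te_families: Iterable[str] | None = None,
    insert_mean: float = 430.0,
    insert_sd: float = 25.0,
    min_support: int = 2,
) -> SwapReport:
    """Re-detect against an alternative reference/TE database.

    Reports per-species mean detected insertion counts and whether the
    abundance ordering matches ``baseline_ranking`` (lowest first).
    """
    bundle = subset_te_library(alt_ref, te_families) if te_families else alt_ref
    aligner = ExactReadAligner(bundle)
    means: dict[str, float] = {}
    for species in sorted(species_reads):
        counts = [
            len(detect_sample(
                pairs, bundle, f"{species}_{i}", insert_mean=insert_mean,
                insert_sd=insert_sd, min_support=min_support, aligner=aligner,
            ))
            for i, pairs in enumerate(species_reads[species])
        ]
        means[species] = float(np.mean(counts))
    ranking = sorted(means, key=lambda s: means[s])
    return SwapReport(means, ranking, list(baseline_ranking),
                      ordering_preserved=ranking == list(baseline_ranking))
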