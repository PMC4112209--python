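"""Descriptive population genetics of TE insertion sites.

Per-individual copy numbers (genome wide and stratified into gene-rich
chromosome arms vs TE-dense pericentromeres), distance-to-nearest-gene
profiles in 100-bp bins, and population site-frequency spectra with
percentile-bootstrap confidence intervals.

Population frequency follows the mating system: for selfers every carrier is
taken as homozygous, so the frequency is carriers / individuals; for
outcrossers each haplotype is an independent sample, so the frequency is
(2·hom + het) / (2·individuals). Frequency calculations can be restricted to
a seeded random subsample of individuals (8 per selfing species and half of
that, 4, for the outcrosser, in the default design) to equalize sample sizes
across species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotyping import ABSENT, HETEROZYGOUS, HOMOZYGOUS, InsertionSite

GENOME_WIDE = "genome_wide"
ARMS = "arms"
CENTROMERIC = "centromeric"

Interval = tuple[int, int]


def compartment_of(chrom: str, pos: int,
                   pericentromeres: Mapping[str, Sequence[Interval]]) -> str:
    for a, b in pericentromeres.get(chrom, []):
        if a <= pos < b:
            return CENTROMERIC
    return ARMS


def _in_compartment(site: InsertionSite, grouping: str,
                    pericentromeres: Mapping[str, Sequence[Interval]] | None) -> bool:
    if grouping == GENOME_WIDE:
        return True
    if pericentromeres is None:
        raise ValueError("compartment intervals required for stratified counts")
    return compartment_of(site.chrom, site.pos_consensus, pericentromeres) == grouping


def copy_number_per_individual(
    sites: Iterable[InsertionSite],
    samples: Sequence[str],
    grouping: str = GENOME_WIDE,
    pericentromeres: Mapping[str, Sequence[Interval]] | None = None,
    dosage: bool = False,
) -> pd.DataFrame:
    """Per-sample insertion counts, total and per family.

    Presence-based by default (a heterozygous and a homozygous call each
    count one site); ``dosage=True`` counts homozygotes twice.
    """
    sites = [s for s in sites if _in_compartment(s, grouping, pericentromeres)]
    families = sorted({s.family for s in sites})
    data = {s: {"total": 0, **{f: 0 for f in families}} for s in samples}
    for site in sites:
        for sample_id, call in site.calls.items():
            if call == ABSENT or sample_id not in data:
                continue
            w = 2 if (dosage and call == HOMOZYGOUS) else 1
            data[sample_id]["total"] += w
            data[sample_id][site.family] += w
    df = pd.DataFrame.from_dict(data, orient="index").reindex(samples)
    df.index.name = "sample_id"
    return df


def population_frequency(
    site: InsertionSite, species_samples: Sequence[str], mating_system: str
) -> float:
    """Population frequency of one site within one species sample."""
    if not species_samples:
        raise ValueError("empty sample list")
    calls = [site.call_for(s) for s in species_samples]
    if mating_system == "selfing":
        # carriers treated as homozygous regardless of the nominal call
        return sum(c != ABSENT for c in calls) / len(calls)
    if mating_system == "outcrossing":
        alleles = sum(2 if c == HOMOZYGOUS else 1 if c == HETEROZYGOUS else 0 for c in calls)
        return alleles / (2 * len(calls))
    raise ValueError(f"unknown mating system {mating_system!r}")


def subsample_individuals(samples: Sequence[str], k: int | None,
                          rng: np.random.Generator) -> list[str]:
    if k is None or k >= len(samples):
        return list(samples)
    idx = rng.choice(len(samples), size=k, replace=False)
    return [samples[i] for i in sorted(idx)]


def species_site_frequencies(
    sites: Iterable[InsertionSite],
    species_samples: Sequence[str],
    mating_system: str,
    subsample: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Frequencies of all sites segregating in a (sub)sampled species.

    Sites absent from every sampled individual are omitted (frequency 0 means
    the species does not carry the insertion in this sample).
    """
    rng = np.random.default_rng(seed)
    chosen = subsample_individuals(list(species_samples), subsample, rng)
    rows = []
    for site in sites:
        f = population_frequency(site, chosen, mating_system)
        if f > 0:
            rows.append((site.site_id, site.chrom, site.pos_consensus, site.family, f))
    return pd.DataFrame(rows, columns=["site_id", "chrom", "pos0", "family", "freq"])


# ---------------------------------------------------------------------------
# Frequency spectra


@dataclass
class FrequencySpectrum:
    """Binned population frequencies with bootstrap confidence bounds."""

    bin_edges: np.ndarray  # len B+1, spanning (0, 1]
    proportions: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_sites: int
    species: str = ""
    compartment: str = GENOME_WIDE

    @property
    def defined(self) -> bool:
        return self.n_sites > 0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": self.species, "compartment": self.compartment,
            "bin_low": self.bin_edges[:-1], "bin_high": self.bin_edges[1:],
            "proportion": self.proportions, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "n_sites": self.n_sites,
        })


def _bin_counts(freqs: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Counts per right-closed bin (e[i], e[i+1]]; frequency 1 lands in the top bin."""
    idx = np.searchsorted(edges, freqs, side="left") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    return np.bincount(idx, minlength=len(edges) - 1).astype(float)


def frequency_spectrum(
    frequencies: Sequence[float],
    bin_edges: Sequence[float] | None = None,
    n_boot: int = 200,
    ci: float = 0.95,
    seed: int = 0,
    include_fixed: bool = True,
    species: str = "",
    compartment: str = GENOME_WIDE,
) -> FrequencySpectrum:
    """Site-frequency spectrum with percentile-bootstrap CIs.

    Sites are resampled with replacement ``n_boot`` times; per-bin CI bounds
    are the (1±ci)/2 percentiles of the bootstrap proportions.
    ``include_fixed=False`` drops frequency-1 sites before binning.
    """
    edges = np.asarray(bin_edges if bin_edges is not None else np.linspace(0, 1, 11), float)
    freqs = np.asarray(frequencies, dtype=float)
    if np.any((freqs <= 0) | (freqs > 1)):
        raise ValueError("frequencies must lie in (0, 1]")
    if not include_fixed:
        freqs = freqs[freqs < 1.0]
    n = len(freqs)
    B = len(edges) - 1
    if n == 0:
        nan = np.full(B, np.nan)
        return FrequencySpectrum(edges, nan, nan, nan, 0, species, compartment)

    counts = _bin_counts(freqs, edges)
    proportions = counts / n

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, B))
    for b in range(n_boot):
        resampled = freqs[rng.integers(0, n, size=n)]
        boot[b] = _bin_counts(resampled, edges) / n
    alpha = (1 - ci) / 2
    ci_low = np.quantile(boot, alpha, axis=0)
    ci_high = np.quantile(boot, 1 - alpha, axis=0)
    # the point estimate is always inside the reported band
    ci_low = np.minimum(ci_low, proportions)
    ci_high = np.maximum(ci_high, proportions)
    return FrequencySpectrum(edges, proportions, ci_low, ci_high, n, species, compartment)


# ---------------------------------------------------------------------------
# Distance to genes


def distance_to_nearest_gene(
    site: InsertionSite | int, genes: Sequence[Interval], chrom: str | None = None,
    gene_map: Mapping[str, Sequence[Interval]] | None = None,
) -> int | None:
    """Gap (bp) from a site's position to the nearer edge of the closest gene.

    0 inside a gene; ``None`` when the chromosome has no annotated genes.
    Accepts either an InsertionSite plus ``gene_map`` or a bare position plus
    the gene intervals of its chromosome.
    """
    if isinstance(site, InsertionSite):
        pos = site.pos_consensus
        genes = (gene_map or {}).get(site.chrom, genes)
    else:
        pos = int(site)
    if not genes:
        return None
    best = None
    for start, end in genes:
        if start <= pos < end:
            return 0
        d = start - pos if pos < start else pos - (end - 1)
        best = d if best is None else min(best, d)
    return best


@dataclass
class DistanceBinTable:
    """Mean per-individual insertion counts in distance-to-gene bins."""

    bin_width: int
    table: pd.DataFrame  # columns: bin_index, bin_low, mean, se

    def frame(self) -> pd.DataFrame:
        return self.table


def bin_by_distance(
    sites: Sequence[InsertionSite],
    genes: Mapping[str, Sequence[Interval]],
    samples: Sequence[str],
    bin_width: int = 100,
    max_distance: int = 2000,
) -> DistanceBinTable:
    """Per-individual insertion counts binned by distance to the nearest gene.

    Bins are [k·w, (k+1)·w); the mean and standard error are taken across the
    given individuals. Sites on gene-less chromosomes are skipped.
    """
    n_bins = max_distance // bin_width
    per_ind = np.zeros((len(samples), n_bins))
    index = {s: i for i, s in enumerate(samples)}
    for site in sites:
        d = distance_to_nearest_gene(site, [], gene_map=genes)
        if d is None or d >= max_distance:
            continue
        b = d // bin_width
        for sample_id, call in site.calls.items():
            if call != ABSENT and sample_id in index:
                per_ind[index[sample_id], b] += 1
    mean = per_ind.mean(axis=0)
    se = (per_ind.std(axis=0, ddof=1) / np.sqrt(len(samples))
          if len(samples) > 1 else np.zeros(n_bins))
    table = pd.DataFrame({
        "bin_index": np.arange(n_bins),
        "bin_low": np.arange(n_bins) * bin_width,
        "mean": mean,
        "se": se,
    })
    return DistanceBinTable(bin_width, table)
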