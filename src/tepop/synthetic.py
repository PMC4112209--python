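"""Synthetic genome, population and read simulator.

Generates a fully specified toy system mirroring the study design this
package targets: a repeat-masked reference genome plus a TE library with four
family labels (LTR, non-LTR, DNA, Helitron), three populations of differing
mating system (two selfers, one outcrosser) segregating TE insertions with
species-specific abundance and site-frequency structure, and 108-bp
forward-reverse paired-end reads at tens-fold coverage.

Every operation is deterministic for a fixed seed. Coordinates are 0-based
half-open internally; files are written with each format's native convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import io as tio

FAMILIES = ("LTR", "non-LTR", "DNA", "Helitron")

#: Genome-wide family mix used when drawing site families: LTR elements
#: dominate, DNA elements second, Helitrons and non-LTRs minor — the typical
#: crucifer TE landscape.
DEFAULT_FAMILY_WEIGHTS = {"LTR": 0.59, "DNA": 0.19, "Helitron": 0.11, "non-LTR": 0.11}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

Interval = tuple[int, int]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


@dataclass(frozen=True, order=True)
class TrueSite:
    """A ground-truth TE insertion locus (TE inserted before base ``pos``)."""

    chrom: str
    pos: int
    family: str
    te_name: str = ""


@dataclass
class ReferenceBundle:
    """Reference genome + annotation + TE library, as one unit.

    ``masked_genome`` equals ``chromosomes`` with TE-derived spans replaced by
    ``N`` — the repeat-masked sequence reads are actually mapped against.
    """

    chromosomes: dict[str, str]
    genes: dict[str, list[Interval]]
    pericentromeres: dict[str, list[Interval]]
    te_library: dict[str, tuple[str, str]]  # name -> (family, sequence)
    masked_genome: dict[str, str]

    def __post_init__(self) -> None:
        for name, (family, _) in self.te_library.items():
            if family not in FAMILIES:
                raise ValueError(f"unknown TE family {family!r} for {name!r}")
        for chrom, seq in self.chromosomes.items():
            if len(self.masked_genome[chrom]) != len(seq):
                raise ValueError(f"masked/raw length mismatch on {chrom}")
            for start, end in self.genes.get(chrom, []) + self.pericentromeres.get(chrom, []):
                if not (0 <= start < end <= len(seq)):
                    raise ValueError(f"interval ({start},{end}) outside {chrom}")

    @property
    def te_names(self) -> set[str]:
        return set(self.te_library)

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def family_of(self, te_name: str) -> str:
        return self.te_library[te_name][0]

    def te_sequence(self, te_name: str) -> str:
        return self.te_library[te_name][1]

    def masked_spans(self) -> dict[str, list[Interval]]:
        """Runs of N in the masked genome (the reference TE copies)."""
        out: dict[str, list[Interval]] = {}
        for chrom, seq in self.masked_genome.items():
            spans, start = [], None
            for i, base in enumerate(seq):
                if base == "N" and start is None:
                    start = i
                elif base != "N" and start is not None:
                    spans.append((start, i))
                    start = None
            if start is not None:
                spans.append((start, len(seq)))
            out[chrom] = spans
        return out

    def write(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        tio.write_fasta(os.path.join(outdir, "genome.fa"), self.chromosomes)
        tio.write_fasta(os.path.join(outdir, "genome.masked.fa"), self.masked_genome)
        # family labels ride in the FASTA description (">name family=LTR")
        with open(os.path.join(outdir, "te_library.fa"), "w") as fh:
            for name, (fam, seq) in self.te_library.items():
                fh.write(f">{name} family={fam}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        tio.write_gff3_genes(os.path.join(outdir, "genes.gff3"), self.genes)
        tio.write_bed(os.path.join(outdir, "pericentromeres.bed"), self.pericentromeres)

    @classmethod
    def load(cls, refdir: str | os.PathLike) -> "ReferenceBundle":
        refdir = str(refdir)
        chroms = tio.read_fasta(os.path.join(refdir, "genome.fa"))
        masked = tio.read_fasta(os.path.join(refdir, "genome.masked.fa"))
        library: dict[str, tuple[str, str]] = {}
        with open(os.path.join(refdir, "te_library.fa")) as fh:
            name, fam, parts = None, None, []
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if name is not None:
                        library[name] = (fam, "".join(parts))
                    tokens = line[1:].split()
                    name = tokens[0]
                    fam = dict(t.split("=", 1) for t in tokens[1:] if "=" in t).get("family", "")
                    parts = []
                else:
                    parts.append(line)
            if name is not None:
                library[name] = (fam, "".join(parts))
        genes = tio.read_gff3_genes(os.path.join(refdir, "genes.gff3"))
        genes = {c: genes.get(c, []) for c in chroms}
        peri = tio.read_bed(os.path.join(refdir, "pericentromeres.bed"))
        peri = {c: peri.get(c, []) for c in chroms}
        return cls(chroms, genes, peri, library, masked)


def build_reference(
    n_chromosomes: int = 1,
    chrom_length: int = 500_000,
    n_genes: int = 60,
    n_te_family_members: int = 2,
    pericentromere_fraction: float = 0.2,
    seed: int = 0,
    te_length_range: tuple[int, int] = (400, 1500),
    gene_length_range: tuple[int, int] = (500, 2000),
    n_reference_te_copies: int = 2,
) -> ReferenceBundle:
    """Build a toy reference bundle.

    Each chromosome carries a centred pericentromere spanning
    ``pericentromere_fraction`` of its length; genes are placed without
    overlap on the arms only; ``n_reference_te_copies`` verbatim TE copies per
    chromosome are planted inside the pericentromere and masked to N in the
    masked genome. ``n_genes`` is the per-chromosome gene count.
    """
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10000")
    if not 0 <= pericentromere_fraction <= 0.5:
        raise ValueError("pericentromere_fraction must be in [0, 0.5]")
    rng = np.random.default_rng(seed)

    # TE library: mutually non-identical random sequences, >= 400 bp each
    library: dict[str, tuple[str, str]] = {}
    lo, hi = te_length_range
    if lo < 400:
        raise ValueError("TE sequences must be at least 400 bp")
    seen: set[str] = set()
    for fam in FAMILIES:
        for i in range(n_te_family_members):
            while True:
                seq = _random_dna(rng, int(rng.integers(lo, hi + 1)))
                if seq not in seen:
                    seen.add(seq)
                    break
            safe = fam.replace("-", "")
            library[f"{safe}_{i + 1}"] = (fam, seq)

    chroms: dict[str, str] = {}
    masked: dict[str, str] = {}
    genes: dict[str, list[Interval]] = {}
    peri: dict[str, list[Interval]] = {}
    te_names = sorted(library)

    for c in range(n_chromosomes):
        chrom = f"chr{c + 1}"
        seq = np.frombuffer(_random_dna(rng, chrom_length).encode(), dtype=np.uint8).copy()
        p_len = int(round(pericentromere_fraction * chrom_length))
        p_start = (chrom_length - p_len) // 2
        peri[chrom] = [(p_start, p_start + p_len)] if p_len > 0 else []

        # reference TE copies inside the pericentromere, masked afterwards
        copy_spans: list[Interval] = []
        n_copies = n_reference_te_copies if p_len > 0 else 0
        for k in range(n_copies):
            te = te_names[int(rng.integers(len(te_names)))]
            te_seq = library[te][1]
            if len(te_seq) + 200 > p_len:
                continue
            for _ in range(200):
                s = int(rng.integers(p_start + 100, p_start + p_len - len(te_seq) - 100))
                span = (s, s + len(te_seq))
                if all(span[1] + 200 <= a or b + 200 <= span[0] for a, b in copy_spans):
                    copy_spans.append(span)
                    seq[span[0]:span[1]] = np.frombuffer(te_seq.encode(), dtype=np.uint8)
                    break
        mask = seq.copy()
        for s, e in copy_spans:
            mask[s:e] = ord("N")

        # genes on the arms, non-overlapping
        placed: list[Interval] = []
        glo, ghi = gene_length_range
        attempts = 0
        while len(placed) < n_genes:
            attempts += 1
            if attempts > 200 * max(n_genes, 1):
                raise ValueError(
                    f"cannot place {n_genes} genes of {glo}-{ghi} bp on the arms of {chrom}"
                )
            glen = int(rng.integers(glo, ghi + 1))
            start = int(rng.integers(0, chrom_length - glen))
            iv = (start, start + glen)
            if p_len > 0 and not (iv[1] <= p_start or iv[0] >= p_start + p_len):
                continue
            if any(not (iv[1] <= a or b <= iv[0]) for a, b in placed):
                continue
            placed.append(iv)
        genes[chrom] = sorted(placed)
        chroms[chrom] = seq.tobytes().decode()
        masked[chrom] = mask.tobytes().decode()

    return ReferenceBundle(chroms, genes, peri, library, masked)


# ---------------------------------------------------------------------------
# Populations


FrequencyModel = Callable[[np.random.Generator, int], np.ndarray]


@dataclass
class SpeciesProfile:
    """Study-design description of one species population.

    ``site_frequency_model`` draws true population frequencies for the sites
    the species segregates; ``site_occupancy`` is the probability that a site
    from a shared pool segregates in this species at all (0 elsewhere) —
    together they set both abundance and frequency architecture.
    """

    name: str
    mating_system: str
    n_individuals: int
    site_frequency_model: FrequencyModel | tuple = ("beta", 0.5, 1.0)
    site_occupancy: float = 1.0
    mean_copy_target: float | None = None
    pericentromere_enrichment: float = 3.0

    def __post_init__(self) -> None:
        if self.mating_system not in ("selfing", "outcrossing"):
            raise ValueError(f"unknown mating system {self.mating_system!r}")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")

    def draw_frequencies(self, rng: np.random.Generator, n: int) -> np.ndarray:
        model = self.site_frequency_model
        if callable(model):
            freqs = np.asarray(model(rng, n), dtype=float)
        elif isinstance(model, (tuple, list)) and model[0] == "beta":
            freqs = rng.beta(model[1], model[2], size=n)
        else:
            raise ValueError(f"unsupported site_frequency_model: {model!r}")
        if np.any((freqs < 0) | (freqs > 1)):
            raise ValueError("site frequencies must lie in [0, 1]")
        return freqs


def default_profiles(n_individuals: dict[str, int] | None = None) -> list[SpeciesProfile]:
    """The three-species study design: one outcrosser with many rare
    insertions, one young selfer with an excess of rare insertions and the
    highest abundance, one older selfer with few but common/fixed insertions.
    """
    n = {"grandiflora": 8, "orientalis": 10, "rubella": 24}
    if n_individuals:
        n.update(n_individuals)
    return [
        SpeciesProfile("grandiflora", "outcrossing", n["grandiflora"],
                       site_frequency_model=("beta", 0.6, 1.8), site_occupancy=0.80),
        SpeciesProfile("orientalis", "selfing", n["orientalis"],
                       site_frequency_model=("beta", 1.8, 0.6), site_occupancy=0.30),
        SpeciesProfile("rubella", "selfing", n["rubella"],
                       site_frequency_model=("beta", 0.5, 1.0), site_occupancy=0.95),
    ]


@dataclass
class IndividualTruth:
    """Ground-truth genotypes of one simulated individual.

    ``genotypes`` maps carried sites to copy count (1 = heterozygous, 2 =
    homozygous); absent sites are simply missing. Selfing individuals are
    fully homozygous and never carry copy count 1.
    """

    sample_id: str
    genotypes: dict[TrueSite, int]
    species: str = ""

    def carried(self) -> list[TrueSite]:
        return sorted(self.genotypes)


def simulate_sites(
    ref: ReferenceBundle,
    n_sites: int,
    seed: int = 0,
    pericentromere_enrichment: float = 3.0,
    min_spacing: int = 500,
    end_margin: int = 500,
    mask_margin: int = 1000,
    family_weights: dict[str, float] | None = None,
) -> list[TrueSite]:
    """Draw a pool of true insertion loci, enriched inside pericentromeres.

    Sites keep ``min_spacing`` bp from each other, ``end_margin`` from
    chromosome ends and ``mask_margin`` from masked reference-TE spans.
    """
    rng = np.random.default_rng(seed)
    weights = dict(family_weights or DEFAULT_FAMILY_WEIGHTS)
    fams = sorted(weights)
    p_fam = np.array([weights[f] for f in fams], dtype=float)
    p_fam /= p_fam.sum()
    members: dict[str, list[str]] = {f: [] for f in FAMILIES}
    for name, (fam, _) in sorted(ref.te_library.items()):
        members[fam].append(name)

    chrom_names = sorted(ref.chromosomes)
    lens = np.array([len(ref.chromosomes[c]) for c in chrom_names], dtype=float)
    masked = ref.masked_spans()

    taken: dict[str, list[int]] = {c: [] for c in chrom_names}
    sites: list[TrueSite] = []
    attempts = 0
    while len(sites) < n_sites:
        attempts += 1
        if attempts > 500 * max(n_sites, 1):
            raise ValueError(
                f"cannot place {n_sites} sites with spacing {min_spacing} bp"
            )
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=lens / lens.sum()))]
        L = len(ref.chromosomes[chrom])
        pos = int(rng.integers(end_margin, L - end_margin))
        in_peri = any(a <= pos < b for a, b in ref.pericentromeres.get(chrom, []))
        # enrichment via thinning of arm draws
        if not in_peri and rng.random() > 1.0 / pericentromere_enrichment:
            continue
        if any(abs(pos - p) < min_spacing for p in taken[chrom]):
            continue
        if any(a - mask_margin <= pos < b + mask_margin for a, b in masked.get(chrom, [])):
            continue
        fam = fams[int(rng.choice(len(fams), p=p_fam))]
        if not members[fam]:
            continue
        te_name = members[fam][int(rng.integers(len(members[fam])))]
        taken[chrom].append(pos)
        sites.append(TrueSite(chrom, pos, fam, te_name))
    return sorted(sites)


@dataclass
class Population:
    """A simulated population: site pool, true frequencies, and individuals."""

    profile: SpeciesProfile
    sites: list[TrueSite]
    frequencies: np.ndarray  # per site; 0 where the species does not segregate it
    individuals: list[IndividualTruth]

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            (ind.sample_id, s.chrom, s.pos, s.family, copies)
            for ind in self.individuals
            for s, copies in sorted(ind.genotypes.items())
        ]
        return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos0", "family", "copy_count"])

    def write_truth(self, path: str | os.PathLike) -> None:
        tio.write_tsv(self.truth_frame(), path)


def simulate_population(
    ref: ReferenceBundle,
    profile: SpeciesProfile,
    n_true_sites: int | None = None,
    seed: int = 0,
    sites: Sequence[TrueSite] | None = None,
) -> Population:
    """Simulate true genotypes for one species.

    Selfers carry a site (as a homozygote, copy count 2) with probability
    equal to its true frequency; outcrossers draw two haplotypes
    independently (Hardy-Weinberg). Pass ``sites`` to share one locus pool
    across species; otherwise ``n_true_sites`` loci are drawn fresh.
    """
    rng = np.random.default_rng(seed)
    if sites is None:
        if n_true_sites is None:
            raise ValueError("provide either sites or n_true_sites")
        sites = simulate_sites(
            ref, n_true_sites, seed=int(rng.integers(2**31)),
            pericentromere_enrichment=profile.pericentromere_enrichment,
        )
    sites = sorted(sites)
    n = len(sites)

    occupied = rng.random(n) < profile.site_occupancy
    freqs = np.zeros(n)
    freqs[occupied] = profile.draw_frequencies(rng, int(occupied.sum()))

    if profile.mean_copy_target is not None:
        if profile.mating_system == "selfing":
            expected = freqs.sum()
        else:
            expected = (1.0 - (1.0 - freqs) ** 2).sum()
        if expected > profile.mean_copy_target:
            keep = rng.random(n) < profile.mean_copy_target / expected
            freqs = np.where(keep, freqs, 0.0)

    individuals = []
    for i in range(profile.n_individuals):
        sample_id = f"{profile.name}_{i + 1:02d}"
        genotypes: dict[TrueSite, int] = {}
        if profile.mating_system == "selfing":
            carried = rng.random(n) < freqs
            for j in np.flatnonzero(carried):
                genotypes[sites[j]] = 2
        else:
            copies = (rng.random(n) < freqs).astype(int) + (rng.random(n) < freqs).astype(int)
            for j in np.flatnonzero(copies):
                genotypes[sites[j]] = int(copies[j])
        individuals.append(IndividualTruth(sample_id, genotypes, species=profile.name))

    return Population(profile, list(sites), freqs, individuals)


# ---------------------------------------------------------------------------
# Reads


def _haplotype(ref: ReferenceBundle, chrom: str, carried: list[TrueSite]) -> str:
    parts, prev = [], 0
    seq = ref.chromosomes[chrom]
    for site in sorted(carried):
        parts.append(seq[prev:site.pos])
        parts.append(ref.te_sequence(site.te_name))
        prev = site.pos
    parts.append(seq[prev:])
    return "".join(parts)


def simulate_read_pairs(
    ref: ReferenceBundle,
    truth: IndividualTruth,
    coverage: float,
    read_length: int = 108,
    insert_mean: float = 430.0,
    insert_sd: float = 25.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Draw paired-end reads from the individual's diploid genome.

    TE sequences are spliced in at carried sites (heterozygous copies go to a
    randomly chosen haplotype). Pair count is Poisson around
    ``coverage * genome_length / (2 * read_length)``; mates are
    forward-reverse inward with Gaussian insert size.
    """
    if insert_mean <= 2 * read_length:
        raise ValueError("insert_mean must exceed 2 * read_length")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)

    # assemble the two haplotypes per chromosome
    units: list[str] = []
    for chrom in sorted(ref.chromosomes):
        at_chrom = sorted(s for s in truth.genotypes if s.chrom == chrom)
        hap_sites: tuple[list[TrueSite], list[TrueSite]] = ([], [])
        for site in at_chrom:
            copies = truth.genotypes[site]
            if copies == 2:
                hap_sites[0].append(site)
                hap_sites[1].append(site)
            elif copies == 1:
                hap_sites[int(rng.integers(2))].append(site)
        units.append(_haplotype(ref, chrom, hap_sites[0]))
        units.append(_haplotype(ref, chrom, hap_sites[1]))

    n_pairs = int(rng.poisson(coverage * ref.genome_length / (2 * read_length)))
    lengths = np.array([len(u) for u in units], dtype=float)
    counts = rng.multinomial(n_pairs, lengths / lengths.sum())

    pairs: list[tuple[str, str, str]] = []
    k = 0
    min_insert = 2 * read_length
    for unit, count in zip(units, counts):
        if count == 0:
            continue
        L = len(unit)
        inserts = np.maximum(
            np.rint(rng.normal(insert_mean, insert_sd, size=count)).astype(int), min_insert
        )
        inserts = np.minimum(inserts, L)
        starts = (rng.random(count) * (L - inserts + 1)).astype(int)
        for s, ins in zip(starts, inserts):
            r1 = unit[s:s + read_length]
            r2 = tio.revcomp(unit[s + ins - read_length:s + ins])
            if error_rate > 0:
                r1 = _mutate_read(rng, r1, error_rate)
                r2 = _mutate_read(rng, r2, error_rate)
            k += 1
            pairs.append((f"{truth.sample_id}.p{k}", r1, r2))
    return pairs


def _mutate_read(rng: np.random.Generator, read: str, rate: float) -> str:
    n_err = rng.binomial(len(read), rate)
    if n_err == 0:
        return read
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(read), size=n_err, replace=False)
    arr[pos] = _BASES[(np.searchsorted(_BASES, arr[pos]) + rng.integers(1, 4, n_err)) % 4]
    return arr.tobytes().decode()


def simulate_reads(
    ref: ReferenceBundle,
    truth: IndividualTruth,
    coverage: float,
    out_prefix: str | os.PathLike,
    read_length: int = 108,
    insert_mean: float = 430.0,
    insert_sd: float = 25.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[str, str]:
    """Simulate reads and write them as a ``_1``/``_2`` FASTQ pair."""
    pairs = simulate_read_pairs(
        ref, truth, coverage, read_length=read_length, insert_mean=insert_mean,
        insert_sd=insert_sd, error_rate=error_rate, seed=seed,
    )
    return tio.write_fastq_pair(out_prefix, pairs)
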