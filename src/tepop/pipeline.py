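"""Configuration and stage orchestration for one reproducible run.

A run is driven by a single :class:`RunConfig` (YAML-loadable) and one root
seed; every stage derives a named substream, so rerunning with the same
config and seed reproduces all TSV outputs byte for byte. Stages:

``simulate`` → reference bundle, truth tables, sample sheet, FASTQ reads;
``detect``   → per-sample SAM + insertion observations;
``genotype`` → merged site × sample genotype matrix (+ BED of sites);
``popgen``   → copy-number, spectrum and distance-to-gene tables;
``compare``  → the statistical comparisons on those tables;
``validate`` → hybrid / pooled / reference-swap control experiments.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
import shutil
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .evidence import (
    ExactReadAligner, InsertionObservation, align_reads, classify_pairs,
    detect_insertions, observations_frame, padded_mask_regions,
)
from .experiments import subseed
from .genotyping import ABSENT, matrix_frame, merge_across_samples, sites_from_matrix
from .popgen import (
    ARMS, CENTROMERIC, GENOME_WIDE, bin_by_distance, copy_number_per_individual,
    frequency_spectrum, species_site_frequencies,
)
from .stats import kruskal_wallis, poisson_glm_counts, rank_sum, wilcoxon_signed_rank
from .synthetic import (
    ReferenceBundle, build_reference, default_profiles, simulate_population,
    simulate_reads, simulate_sites,
)
from .validation import SampleReads, hybrid_check, make_diverged_bundle, reference_swap

log = logging.getLogger("tepop")

STAGES = ("simulate", "detect", "genotype", "popgen", "compare", "validate")


class PipelineError(RuntimeError):
    pass


@dataclass
class Parameters:
    """All numeric knobs of the pipeline, with the study-design defaults."""

    read_length: int = 108
    coverage: float = 20.0
    insert_mean: float = 430.0
    insert_sd: float = 25.0
    error_rate: float = 0.0
    min_support: int = 2
    min_mapq: int = 20
    identity_window: int = 200
    freq_low: float = 0.2
    freq_high: float = 0.8
    n_boot: int = 200
    ci: float = 0.95
    bin_width: int = 100
    max_gene_distance: int = 2000
    subsample_selfing: int = 8
    subsample_outcrossing: int = 4

    @property
    def cluster_window(self) -> float:
        return self.insert_mean + 3 * self.insert_sd

    def validate(self) -> None:
        if not (0 <= self.freq_low < self.freq_high <= 1):
            raise PipelineError("frequency thresholds must satisfy 0 <= low < high <= 1")
        for name in ("identity_window", "bin_width", "read_length"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be positive")
        if self.insert_mean <= 2 * self.read_length:
            raise PipelineError("insert_mean must exceed 2 * read_length")


@dataclass
class SimulationDesign:
    n_chromosomes: int = 1
    chrom_length: int = 200_000
    n_genes: int = 25
    n_te_family_members: int = 2
    pericentromere_fraction: float = 0.2
    n_sites: int = 30
    n_individuals: dict = field(default_factory=lambda: {
        "grandiflora": 4, "orientalis": 4, "rubella": 4,
    })


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "tepop_out"
    keep_sam: bool = True
    params: Parameters = field(default_factory=Parameters)
    simulation: SimulationDesign = field(default_factory=SimulationDesign)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("seed", "outdir", "keep_sam"):
            if key in raw:
                setattr(cfg, key, raw[key])
        for section, obj in (("params", cfg.params), ("simulation", cfg.simulation)):
            for k, v in (raw.get(section) or {}).items():
                if not hasattr(obj, k):
                    raise PipelineError(f"unknown config key {section}.{k}")
                setattr(obj, k, v)
        cfg.params.validate()
        return cfg

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "outdir": self.outdir, "keep_sam": self.keep_sam,
            "params": dataclasses.asdict(self.params),
            "simulation": dataclasses.asdict(self.simulation),
        }

    def config_hash(self) -> str:
        # the hash covers the scientific configuration, not the output path
        payload = self.to_dict()
        payload.pop("outdir")
        canon = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha1(canon.encode()).hexdigest()[:10]

    def header(self) -> str:
        return f"tepop run config={self.config_hash()} seed={self.seed}"


# ---------------------------------------------------------------------------
# Stage implementations


def _path(cfg: RunConfig, *parts: str) -> str:
    return os.path.join(cfg.outdir, *parts)


def _require(cfg: RunConfig, relpath: str, produced_by: str) -> str:
    p = _path(cfg, relpath)
    if not os.path.exists(p):
        raise PipelineError(
            f"missing input {p!r}; run the {produced_by!r} stage first"
        )
    return p


def stage_simulate(cfg: RunConfig) -> None:
    design, params = cfg.simulation, cfg.params
    bundle = build_reference(
        n_chromosomes=design.n_chromosomes, chrom_length=design.chrom_length,
        n_genes=design.n_genes, n_te_family_members=design.n_te_family_members,
        pericentromere_fraction=design.pericentromere_fraction,
        seed=subseed(cfg.seed, "reference"),
    )
    refdir = _path(cfg, "reference")
    bundle.write(refdir)
    sites = simulate_sites(bundle, design.n_sites, seed=subseed(cfg.seed, "sites"))

    os.makedirs(_path(cfg, "truth"), exist_ok=True)
    os.makedirs(_path(cfg, "reads"), exist_ok=True)
    sheet_rows = []
    for profile in default_profiles(design.n_individuals):
        pop = simulate_population(
            bundle, profile, sites=sites, seed=subseed(cfg.seed, f"pop:{profile.name}"),
        )
        pop.write_truth(_path(cfg, "truth", f"{profile.name}.truth.tsv"))
        for ind in pop.individuals:
            sheet_rows.append((ind.sample_id, profile.name, profile.mating_system))
            simulate_reads(
                bundle, ind, params.coverage,
                out_prefix=_path(cfg, "reads", ind.sample_id),
                read_length=params.read_length, insert_mean=params.insert_mean,
                insert_sd=params.insert_sd, error_rate=params.error_rate,
                seed=subseed(cfg.seed, f"reads:{ind.sample_id}"),
            )
    sheet = pd.DataFrame(sheet_rows, columns=["sample_id", "species", "mating_system"])
    tio.write_tsv(sheet, _path(cfg, "samples.tsv"), header_comment=cfg.header())
    log.info("simulate: %d samples, %d true sites", len(sheet), len(sites))


def _load_sheet(cfg: RunConfig) -> pd.DataFrame:
    return tio.read_tsv(_require(cfg, "samples.tsv", "simulate"))


def stage_detect(cfg: RunConfig) -> None:
    params = cfg.params
    bundle = ReferenceBundle.load(_require(cfg, "reference", "simulate"))
    sheet = _load_sheet(cfg)
    aligner = ExactReadAligner(bundle)
    te_families = {name: fam for name, (fam, _) in bundle.te_library.items()}
    exclude = padded_mask_regions(bundle, params.cluster_window)
    os.makedirs(_path(cfg, "observations"), exist_ok=True)
    os.makedirs(_path(cfg, "sam"), exist_ok=True)
    for sample in sheet["sample_id"]:
        fq1 = _require(cfg, os.path.join("reads", f"{sample}_1.fastq"), "simulate")
        fq2 = _require(cfg, os.path.join("reads", f"{sample}_2.fastq"), "simulate")
        sam_path = _path(cfg, "sam", f"{sample}.sam")
        align_reads(fq1, fq2, bundle, sam_path, aligner=aligner)
        evidence = classify_pairs(
            sam_path, te_families, insert_mean=params.insert_mean,
            insert_sd=params.insert_sd, min_mapq=params.min_mapq,
        )
        observations = detect_insertions(
            evidence, cluster_window=params.cluster_window,
            min_support=params.min_support, exclude_regions=exclude,
            sample_id=sample,
        )
        tio.write_tsv(observations_frame(observations),
                      _path(cfg, "observations", f"{sample}.obs.tsv"),
                      header_comment=cfg.header())
        log.info("detect %s: %d evidence pairs, %d observations",
                 sample, len(evidence), len(observations))
        if not cfg.keep_sam:
            os.remove(sam_path)
    if not cfg.keep_sam:
        shutil.rmtree(_path(cfg, "sam"), ignore_errors=True)


def _load_observations(cfg: RunConfig) -> list[InsertionObservation]:
    obs_dir = _require(cfg, "observations", "detect")
    out: list[InsertionObservation] = []
    for fname in sorted(os.listdir(obs_dir)):
        if not fname.endswith(".obs.tsv"):
            continue
        df = tio.read_tsv(os.path.join(obs_dir, fname))
        for row in df.itertuples(index=False):
            out.append(InsertionObservation(
                sample_id=row.sample_id, chrom=row.chrom, pos_estimate=int(row.pos0),
                family=row.family, n_support_fwd=int(row.n_support_fwd),
                n_support_rev=int(row.n_support_rev), n_spanning=int(row.n_spanning),
                freq_estimate=float(row.freq), both_sided=bool(row.both_sided),
            ))
    return out


def stage_genotype(cfg: RunConfig) -> None:
    params = cfg.params
    sheet = _load_sheet(cfg)
    observations = _load_observations(cfg)
    sites = merge_across_samples(
        observations, identity_window=params.identity_window,
        low=params.freq_low, high=params.freq_high,
    )
    matrix = matrix_frame(sites, list(sheet["sample_id"]))
    tio.write_tsv(matrix, _path(cfg, "matrix.tsv"), header_comment=cfg.header())
    intervals = {}
    names = {}
    for s in sites:
        intervals.setdefault(s.chrom, []).append((s.pos_consensus, s.pos_consensus + 1))
        names.setdefault(s.chrom, []).append(s.site_id)
    tio.write_bed(_path(cfg, "sites.bed"), intervals, names)
    log.info("genotype: %d observations -> %d sites", len(observations), len(sites))


def stage_popgen(cfg: RunConfig) -> None:
    params = cfg.params
    sheet = _load_sheet(cfg)
    matrix = tio.read_tsv(_require(cfg, "matrix.tsv", "genotype"))
    sites = sites_from_matrix(matrix)
    bundle = ReferenceBundle.load(_require(cfg, "reference", "simulate"))
    outdir = _path(cfg, "popgen")
    os.makedirs(outdir, exist_ok=True)

    samples = list(sheet["sample_id"])
    species_of = dict(zip(sheet["sample_id"], sheet["species"]))
    mating_of = dict(zip(sheet["species"], sheet["mating_system"]))

    frames = []
    for grouping in (GENOME_WIDE, ARMS, CENTROMERIC):
        df = copy_number_per_individual(
            sites, samples, grouping=grouping, pericentromeres=bundle.pericentromeres,
        ).reset_index()
        df.insert(1, "compartment", grouping)
        df.insert(2, "species", df["sample_id"].map(species_of))
        frames.append(df)
    tio.write_tsv(pd.concat(frames, ignore_index=True),
                  os.path.join(outdir, "copy_numbers.tsv"), header_comment=cfg.header())

    spec_frames = []
    freq_frames = []
    for species in sorted(set(species_of.values())):
        sp_samples = [s for s in samples if species_of[s] == species]
        mating = mating_of[species]
        k = (params.subsample_selfing if mating == "selfing"
             else params.subsample_outcrossing)
        freqs = species_site_frequencies(
            sites, sp_samples, mating, subsample=k,
            seed=subseed(cfg.seed, f"subsample:{species}"),
        )
        freqs.insert(0, "species", species)
        freq_frames.append(freqs)
        for compartment in (GENOME_WIDE, ARMS, CENTROMERIC):
            if compartment == GENOME_WIDE:
                sel = freqs
            else:
                keep = [
                    i for i, sid in enumerate(freqs["site_id"])
                    if _site_compartment(sites, sid, bundle) == compartment
                ]
                sel = freqs.iloc[keep]
            spectrum = frequency_spectrum(
                sel["freq"].to_numpy(), n_boot=params.n_boot, ci=params.ci,
                seed=subseed(cfg.seed, f"boot:{species}:{compartment}"),
                species=species, compartment=compartment,
            )
            spec_frames.append(spectrum.frame())
    tio.write_tsv(pd.concat(freq_frames, ignore_index=True),
                  os.path.join(outdir, "frequencies.tsv"), header_comment=cfg.header())
    tio.write_tsv(pd.concat(spec_frames, ignore_index=True),
                  os.path.join(outdir, "spectra.tsv"), header_comment=cfg.header())

    dist_frames = []
    for species in sorted(set(species_of.values())):
        sp_samples = [s for s in samples if species_of[s] == species]
        table = bin_by_distance(
            sites, bundle.genes, sp_samples, bin_width=params.bin_width,
            max_distance=params.max_gene_distance,
        ).frame()
        table.insert(0, "species", species)
        dist_frames.append(table)
    tio.write_tsv(pd.concat(dist_frames, ignore_index=True),
                  os.path.join(outdir, "distance_bins.tsv"), header_comment=cfg.header())
    log.info("popgen: tables written to %s", outdir)


def _site_compartment(sites, site_id: str, bundle: ReferenceBundle) -> str:
    from .popgen import compartment_of

    for s in sites:
        if s.site_id == site_id:
            return compartment_of(s.chrom, s.pos_consensus, bundle.pericentromeres)
    raise KeyError(site_id)


def stage_compare(cfg: RunConfig) -> None:
    sheet = _load_sheet(cfg)
    copy_path = _require(cfg, os.path.join("popgen", "copy_numbers.tsv"), "popgen")
    copies = tio.read_tsv(copy_path)
    gw = copies[copies["compartment"] == GENOME_WIDE]
    species = sorted(gw["species"].unique())
    rows = []

    groups = [gw.loc[gw["species"] == s, "total"].to_numpy() for s in species]
    kw = kruskal_wallis(groups)
    rows.append(("kruskal_wallis", "per-individual genome-wide copy number",
                 kw.statistic_name, kw.statistic, kw.df, kw.p_value))

    for i, a in enumerate(species):
        for b in species[i + 1:]:
            rs = rank_sum(gw.loc[gw["species"] == a, "total"],
                          gw.loc[gw["species"] == b, "total"])
            rows.append((f"rank_sum:{a}-vs-{b}", "per-individual copy number",
                         rs.statistic_name, rs.statistic, rs.df, rs.p_value))

    # paired per-site comparison across species over shared 1-kb windows
    matrix = tio.read_tsv(_require(cfg, "matrix.tsv", "genotype"))
    sites = sites_from_matrix(matrix)
    species_of = dict(zip(sheet["sample_id"], sheet["species"]))
    window_means: dict[str, dict[tuple[str, int], float]] = {s: {} for s in species}
    all_windows: set[tuple[str, int]] = set()
    for s in sites:
        w = (s.chrom, s.pos_consensus // 1000)
        all_windows.add(w)
        carriers = s.carriers()
        for sp in species:
            sp_samples = [x for x in species_of if species_of[x] == sp]
            frac = sum(c in carriers for c in sp_samples) / max(len(sp_samples), 1)
            window_means[sp][w] = window_means[sp].get(w, 0.0) + frac
    ordered = sorted(all_windows)
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            xa = [window_means[a].get(w, 0.0) for w in ordered]
            xb = [window_means[b].get(w, 0.0) for w in ordered]
            wt = wilcoxon_signed_rank(xa, xb)
            rows.append((f"wilcoxon:{a}-vs-{b}", "mean copy indicator per 1-kb window",
                         wt.statistic_name, wt.statistic, wt.df, wt.p_value))

    # Poisson GLM on near-gene insertion counts per individual
    bundle = ReferenceBundle.load(_require(cfg, "reference", "simulate"))
    from .popgen import distance_to_nearest_gene

    near = [s for s in sites
            if (d := distance_to_nearest_gene(s, [], gene_map=bundle.genes)) is not None
            and d <= 200]
    counts, labels = [], []
    for sample in sheet["sample_id"]:
        counts.append(sum(s.call_for(sample) != ABSENT for s in near))
        labels.append(species_of[sample])
    if len(set(labels)) >= 2:
        for res in poisson_glm_counts(counts, labels):
            rows.append((
                f"poisson_glm:{res.extra.get('group')}-vs-{res.extra.get('baseline')}",
                "near-gene (<=200 bp) insertions per individual",
                res.statistic_name, res.statistic, res.df, res.p_value,
            ))

    df = pd.DataFrame(rows, columns=["test", "unit", "statistic_name",
                                     "statistic", "df", "p_value"])
    os.makedirs(_path(cfg, "compare"), exist_ok=True)
    tio.write_tsv(df, _path(cfg, "compare", "tests.tsv"), header_comment=cfg.header())
    log.info("compare: %d tests written", len(df))


def stage_validate(cfg: RunConfig) -> None:
    params = cfg.params
    bundle = ReferenceBundle.load(_require(cfg, "reference", "simulate"))
    sheet = _load_sheet(cfg)
    selfing = sheet[sheet["mating_system"] == "selfing"]
    rows = []

    # hybrid check on the first two selfed individuals with reads on disk
    if len(selfing) >= 2:
        parents = []
        for sample, species in zip(selfing["sample_id"][:2], selfing["species"][:2]):
            truth_df = tio.read_tsv(_path(cfg, "truth", f"{species}.truth.tsv"))
            truth_df = truth_df[truth_df["sample_id"] == sample]
            from .synthetic import IndividualTruth, TrueSite

            genotypes = {
                TrueSite(r.chrom, int(r.pos0), r.family): int(r.copy_count)
                for r in truth_df.itertuples(index=False)
            }
            pairs = list(tio.iter_fastq_pairs(
                _require(cfg, os.path.join("reads", f"{sample}_1.fastq"), "simulate"),
                _require(cfg, os.path.join("reads", f"{sample}_2.fastq"), "simulate"),
            ))
            parents.append(SampleReads(IndividualTruth(sample, genotypes), pairs))
        report = hybrid_check(parents[0], parents[1], bundle,
                              insert_mean=params.insert_mean, insert_sd=params.insert_sd,
                              min_support=params.min_support)
        for run in ("parent1", "parent2", "hybrid"):
            rows.append(("hybrid_check", f"frac_freq_ge_0.8:{run}", report.frac_high[run]))
        rows.append(("hybrid_check", "het_rate_discordant", report.het_rate_discordant))
        rows.append(("hybrid_check", "pattern_holds", float(report.pattern_holds)))

    # reference swap with a 1%-diverged genome, two individuals per species
    species_reads = {}
    for species in sorted(sheet["species"].unique()):
        ids = sheet.loc[sheet["species"] == species, "sample_id"][:2]
        species_reads[species] = [
            list(tio.iter_fastq_pairs(
                _path(cfg, "reads", f"{s}_1.fastq"), _path(cfg, "reads", f"{s}_2.fastq"),
            ))
            for s in ids
        ]
    from .evidence import detect_sample

    aligner = ExactReadAligner(bundle)
    base = {
        sp: float(np.mean([
            len(detect_sample(p, bundle, f"{sp}_{i}", insert_mean=params.insert_mean,
                              insert_sd=params.insert_sd, min_support=params.min_support,
                              aligner=aligner))
            for i, p in enumerate(sets)
        ]))
        for sp, sets in species_reads.items()
    }
    ranking = sorted(base, key=lambda s: base[s])
    alt = make_diverged_bundle(bundle, divergence=0.01, seed=subseed(cfg.seed, "swap"))
    swap = reference_swap(species_reads, alt, ranking,
                          insert_mean=params.insert_mean, insert_sd=params.insert_sd,
                          min_support=params.min_support)
    rows.append(("reference_swap", "ordering_preserved", float(swap.ordering_preserved)))
    for sp in sorted(swap.mean_counts):
        rows.append(("reference_swap", f"mean_count:{sp}", swap.mean_counts[sp]))

    df = pd.DataFrame(rows, columns=["experiment", "quantity", "value"])
    os.makedirs(_path(cfg, "validate"), exist_ok=True)
    tio.write_tsv(df, _path(cfg, "validate", "report.tsv"), header_comment=cfg.header())
    log.info("validate: report written")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "detect": stage_detect,
    "genotype": stage_genotype,
    "popgen": stage_popgen,
    "compare": stage_compare,
    "validate": stage_validate,
}


def run_pipeline(config: RunConfig, stages: list[str] | tuple[str, ...] = STAGES) -> str:
    """Run the requested stages in dependency order; returns the output dir."""
    config.params.validate()
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s): {', '.join(unknown)}")
    ordered = [s for s in STAGES if s in stages]
    os.makedirs(config.outdir, exist_ok=True)
    outputs = {
        "simulate": ["reference", "truth", "reads", "samples.tsv"],
        "detect": ["observations", "sam"],
        "genotype": ["matrix.tsv", "sites.bed"],
        "popgen": ["popgen"],
        "compare": ["compare"],
        "validate": ["validate"],
    }
    for stage in ordered:
        log.info("=== stage %s ===", stage)
        try:
            _STAGE_FUNCS[stage](config)
        except Exception:
            # do not leave partial outputs behind
            for rel in outputs[stage]:
                p = _path(config, rel)
                if os.path.isdir(p):
                    shutil.rmtree(p, ignore_errors=True)
                elif os.path.exists(p):
                    os.remove(p)
            raise
    return config.outdir
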