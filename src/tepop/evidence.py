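"""Paired-end evidence for TE insertions.

An insertion absent from the reference leaves a signature in paired-end data:
one mate maps uniquely to the (repeat-masked) genome, its mate maps to a TE
library sequence. Pairs that instead map concordantly across a candidate
position argue against an insertion on that haplotype. This module turns
alignments into per-sample insertion observations with a position estimate
(cluster midpoint of the forward- and reverse-side junction evidence) and a
within-individual frequency estimate.

Alignment of synthetic fixtures is done by a built-in exact matcher: a read
is reported mapped only where it occurs verbatim (either strand), and only if
that location is unique. Real data can supply SAM from any aligner; records
with MAPQ < 20 or secondary/supplementary flags are treated as non-unique.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam

from . import io as tio
from .synthetic import ReferenceBundle

SIDE_FORWARD = "forward"
SIDE_REVERSE = "reverse"


@dataclass(frozen=True)
class PairEvidence:
    """One read pair's classification at a locus.

    ``genomic_pos`` is the proximal end of the uniquely mapped genomic mate
    (the end facing the inferred junction): its rightmost aligned coordinate
    (exclusive) on the forward strand, its leftmost on the reverse strand.
    For spanning pairs ``span_start``/``span_end`` hold the inner span
    (between the two mates' aligned footprints).
    """

    read_id: str
    chrom: str
    genomic_pos: int
    side: str | None
    te_id: str | None
    te_family: str | None
    kind: str  # "supporting" | "spanning"
    span_start: int | None = None
    span_end: int | None = None


@dataclass
class InsertionObservation:
    """One sample's detected insertion at a locus."""

    sample_id: str
    chrom: str
    pos_estimate: int
    family: str
    n_support_fwd: int
    n_support_rev: int
    n_spanning: int
    freq_estimate: float
    both_sided: bool = False

    @property
    def n_support(self) -> int:
        return self.n_support_fwd + self.n_support_rev


def estimate_frequency(n_support: int, n_spanning: int) -> float:
    """Within-individual insertion frequency: support / (support + spanning)."""
    if n_support + n_spanning <= 0:
        raise ValueError("need at least one supporting or spanning pair")
    return n_support / (n_support + n_spanning)


# ---------------------------------------------------------------------------
# Built-in exact matcher


@dataclass
class MateAlignment:
    mapped: bool
    unique: bool = False
    rname: str | None = None
    pos: int = 0  # 0-based leftmost
    strand: str = "+"
    length: int = 0

    @property
    def end(self) -> int:
        return self.pos + self.length


@dataclass
class PairAlignment:
    name: str
    mate1: MateAlignment
    mate2: MateAlignment


class ExactReadAligner:
    """Seed-and-verify exact matcher over masked genome + TE library.

    Indexes every ``seed_length``-mer of the combined reference (forward
    strand); a query is looked up by its leading seed on both strands and
    verified over its full length. Mapping requires exactly one full-length
    match; multi-locus reads are flagged non-unique (MAPQ 0).
    """

    def __init__(self, ref: ReferenceBundle, seed_length: int = 32):
        self.ref = ref
        self.seed_length = seed_length
        self.names: list[str] = sorted(ref.masked_genome) + sorted(ref.te_library)
        self.seqs: list[str] = [ref.masked_genome[c] for c in sorted(ref.masked_genome)]
        self.seqs += [ref.te_sequence(t) for t in sorted(ref.te_library)]
        for name, seq in zip(self.names, self.seqs):
            if len(seq) < seed_length:
                raise ValueError(f"reference sequence {name!r} shorter than the seed")
        index: dict[str, object] = {}
        for ref_i, seq in enumerate(self.seqs):
            k = seed_length
            for i in range(len(seq) - k + 1):
                km = seq[i:i + k]
                if "N" in km:
                    continue
                hit = (ref_i, i)
                prev = index.get(km)
                if prev is None:
                    index[km] = hit
                elif isinstance(prev, list):
                    prev.append(hit)
                else:
                    index[km] = [prev, hit]
        self._index = index

    def _hits(self, query: str, max_hits: int = 2) -> list[tuple[int, int, str]]:
        out: list[tuple[int, int, str]] = []
        k = self.seed_length
        for strand, seq in (("+", query), ("-", tio.revcomp(query))):
            cand = self._index.get(seq[:k])
            if cand is None:
                continue
            cand_list = cand if isinstance(cand, list) else [cand]
            for ref_i, pos in cand_list:
                if self.seqs[ref_i][pos:pos + len(seq)] == seq:
                    out.append((ref_i, pos, strand))
                    if len(out) >= max_hits:
                        return out
        return out

    def map_read(self, query: str) -> MateAlignment:
        hits = self._hits(query)
        if not hits:
            return MateAlignment(mapped=False)
        ref_i, pos, strand = hits[0]
        return MateAlignment(
            mapped=True, unique=len(hits) == 1, rname=self.names[ref_i],
            pos=pos, strand=strand, length=len(query),
        )

    def align_pairs(self, pairs: Iterable[tuple[str, str, str]]) -> Iterator[PairAlignment]:
        for name, r1, r2 in pairs:
            yield PairAlignment(name, self.map_read(r1), self.map_read(r2))


def write_sam(alignments: Iterable[PairAlignment], ref: ReferenceBundle,
              path: str | os.PathLike) -> None:
    """Serialize pair alignments as SAM (SEQ/QUAL omitted as ``*``)."""
    ref_lengths = {c: len(s) for c, s in ref.masked_genome.items()}
    ref_lengths.update({t: len(ref.te_sequence(t)) for t in ref.te_library})
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:queryname\n")
        for name in sorted(ref.masked_genome) + sorted(ref.te_library):
            fh.write(f"@SQ\tSN:{name}\tLN:{ref_lengths[name]}\n")
        fh.write("@PG\tID:tepop\tPN:tepop\n")
        for pair in alignments:
            for mate, other, mate_flag in ((pair.mate1, pair.mate2, 0x40),
                                           (pair.mate2, pair.mate1, 0x80)):
                flag = 0x1 | mate_flag
                if not mate.mapped:
                    flag |= 0x4
                if not other.mapped:
                    flag |= 0x8
                if mate.mapped and mate.strand == "-":
                    flag |= 0x10
                if other.mapped and other.strand == "-":
                    flag |= 0x20
                if mate.unique and other.unique:
                    flag |= 0x2
                rname = mate.rname if mate.mapped else "*"
                pos = mate.pos + 1 if mate.mapped else 0
                mapq = 60 if mate.unique else 0
                cigar = f"{mate.length}M" if mate.mapped else "*"
                rnext, pnext = "*", 0
                if other.mapped:
                    rnext = "=" if other.rname == rname else (other.rname or "*")
                    pnext = other.pos + 1
                fh.write(
                    f"{pair.name}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar}"
                    f"\t{rnext}\t{pnext}\t0\t*\t*\n"
                )


def load_sam_pairs(path: str | os.PathLike, min_mapq: int = 20) -> Iterator[PairAlignment]:
    """Read mate pairs back from SAM; MAPQ < ``min_mapq`` means non-unique."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        if not sam.header.get("SQ"):
            raise ValueError(f"{path}: SAM has no @SQ header lines")
        mates: dict[str, dict[int, MateAlignment]] = {}
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            which = 1 if rec.is_read1 else 2
            if rec.is_unmapped:
                aln = MateAlignment(mapped=False)
            else:
                aln = MateAlignment(
                    mapped=True,
                    unique=rec.mapping_quality >= min_mapq,
                    rname=rec.reference_name,
                    pos=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    length=rec.reference_end - rec.reference_start,
                )
            entry = mates.setdefault(rec.query_name, {})
            entry[which] = aln
            if len(entry) == 2:
                del mates[rec.query_name]
                yield PairAlignment(rec.query_name, entry[1], entry[2])


def align_reads(fastq1: str | os.PathLike, fastq2: str | os.PathLike,
                ref: ReferenceBundle, out_sam: str | os.PathLike,
                aligner: ExactReadAligner | None = None) -> str:
    """Map a FASTQ pair with the built-in exact matcher and write SAM."""
    aligner = aligner or ExactReadAligner(ref)
    pairs = tio.iter_fastq_pairs(fastq1, fastq2)
    write_sam(aligner.align_pairs(pairs), ref, out_sam)
    return str(out_sam)


# ---------------------------------------------------------------------------
# Classification


def classify_pairs(
    alignments: str | os.PathLike | Iterable[PairAlignment],
    te_families: Mapping[str, str],
    insert_mean: float = 430.0,
    insert_sd: float = 25.0,
    min_mapq: int = 20,
) -> list[PairEvidence]:
    """Classify mate pairs into TE-supporting and spanning evidence.

    Supporting: one mate uniquely mapped to the genome, the other mapped to a
    TE library sequence (``te_families`` maps TE name to family label).
    Spanning: both mates uniquely genomic, forward-reverse inward on one
    chromosome with outer insert within ``insert_mean ± 3·insert_sd``.
    Everything else (both-TE, multi-mapped genomic mate, discordant) drops.
    """
    if isinstance(alignments, (str, os.PathLike)):
        alignments = load_sam_pairs(alignments, min_mapq=min_mapq)
    lo = insert_mean - 3 * insert_sd
    hi = insert_mean + 3 * insert_sd
    out: list[PairEvidence] = []
    for pair in alignments:
        m1, m2 = pair.mate1, pair.mate2
        te1 = m1.mapped and m1.rname in te_families
        te2 = m2.mapped and m2.rname in te_families
        gen1 = m1.mapped and m1.unique and not te1
        gen2 = m2.mapped and m2.unique and not te2
        if te1 and te2:
            continue
        if (gen1 and te2) or (gen2 and te1):
            genomic, te = (m1, m2) if gen1 else (m2, m1)
            if genomic.strand == "+":
                side, gpos = SIDE_FORWARD, genomic.end
            else:
                side, gpos = SIDE_REVERSE, genomic.pos
            out.append(PairEvidence(
                read_id=pair.name, chrom=genomic.rname, genomic_pos=gpos,
                side=side, te_id=te.rname, te_family=te_families[te.rname],
                kind="supporting",
            ))
        elif gen1 and gen2 and m1.rname == m2.rname and m1.strand != m2.strand:
            left, right = (m1, m2) if m1.pos <= m2.pos else (m2, m1)
            if left.strand != "+":
                continue  # outward-facing pair
            insert = right.end - left.pos
            if lo <= insert <= hi:
                out.append(PairEvidence(
                    read_id=pair.name, chrom=m1.rname, genomic_pos=left.end,
                    side=None, te_id=None, te_family=None, kind="spanning",
                    span_start=left.end, span_end=right.pos,
                ))
    return out


# ---------------------------------------------------------------------------
# Detection


@dataclass
class _Cluster:
    side: str
    positions: list[int]
    reads: list[str]

    @property
    def innermost(self) -> int:
        # forward evidence sits upstream of the junction: innermost = max end;
        # reverse evidence downstream: innermost = min start
        return max(self.positions) if self.side == SIDE_FORWARD else min(self.positions)

    @property
    def size(self) -> int:
        return len(self.positions)


def _chain(positions: Sequence[tuple[int, str]], side: str, window: float) -> list[_Cluster]:
    clusters: list[_Cluster] = []
    for pos, read in positions:
        if clusters and pos - clusters[-1].positions[-1] <= window:
            clusters[-1].positions.append(pos)
            clusters[-1].reads.append(read)
        else:
            clusters.append(_Cluster(side, [pos], [read]))
    return clusters


def detect_insertions(
    evidence: Iterable[PairEvidence],
    cluster_window: float = 505.0,
    min_support: int = 2,
    exclude_regions: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    sample_id: str = "",
) -> list[InsertionObservation]:
    """Cluster supporting evidence from one sample into insertion observations.

    Same-family, same-side evidence is chained greedily after a position sort
    (a pair joins the open cluster if within ``cluster_window`` of the last
    member — equivalent to transitive closure on sorted positions). A forward
    and a reverse cluster of one family whose innermost positions lie within
    ``cluster_window`` merge into one observation at their midpoint;
    single-sided clusters reaching ``min_support`` are emitted at their
    innermost position. Spanning pairs count toward an observation when their
    inner span strictly contains the position estimate. The frequency
    estimate is the mean of the per-side support ratios.

    ``exclude_regions`` (e.g. masked reference-TE spans padded by the cluster
    window) removes supporting evidence before clustering.
    """
    supporting: list[PairEvidence] = []
    spans: dict[str, list[tuple[int, int]]] = {}
    for ev in evidence:
        if ev.kind == "spanning":
            spans.setdefault(ev.chrom, []).append((ev.span_start, ev.span_end))
        else:
            if exclude_regions is not None and any(
                a <= ev.genomic_pos < b for a, b in exclude_regions.get(ev.chrom, [])
            ):
                continue
            supporting.append(ev)

    span_arrays = {
        chrom: (np.sort(np.array([s for s, _ in v])), np.sort(np.array([e for _, e in v])))
        for chrom, v in spans.items()
    }

    def n_spanning_at(chrom: str, pos: int) -> int:
        if chrom not in span_arrays:
            return 0
        starts, ends = span_arrays[chrom]
        # strict containment: start < pos < end
        return int(np.searchsorted(starts, pos, side="left")
                   - np.searchsorted(ends, pos, side="right"))

    groups: dict[tuple[str, str, str], list[tuple[int, str]]] = {}
    for ev in supporting:
        groups.setdefault((ev.chrom, ev.te_family, ev.side), []).append(
            (ev.genomic_pos, ev.read_id)
        )

    clusters: dict[tuple[str, str], dict[str, list[_Cluster]]] = {}
    for (chrom, family, side), items in groups.items():
        items.sort()
        clusters.setdefault((chrom, family), {})[side] = _chain(items, side, cluster_window)

    observations: list[InsertionObservation] = []
    for (chrom, family) in sorted(clusters):
        by_side = clusters[(chrom, family)]
        fwd = by_side.get(SIDE_FORWARD, [])
        rev = by_side.get(SIDE_REVERSE, [])
        # pair forward and reverse clusters, nearest gap first
        candidates = sorted(
            (r.innermost - f.innermost, fi, ri)
            for fi, f in enumerate(fwd)
            for ri, r in enumerate(rev)
            if 0 <= r.innermost - f.innermost <= cluster_window
        )
        used_f: set[int] = set()
        used_r: set[int] = set()
        matched: list[tuple[_Cluster, _Cluster]] = []
        for _, fi, ri in candidates:
            if fi in used_f or ri in used_r:
                continue
            used_f.add(fi)
            used_r.add(ri)
            matched.append((fwd[fi], rev[ri]))

        for f, r in matched:
            if f.size + r.size < min_support:
                continue
            pos = (f.innermost + r.innermost) // 2
            nspan = n_spanning_at(chrom, pos)
            freq = (estimate_frequency(f.size, nspan) + estimate_frequency(r.size, nspan)) / 2
            observations.append(InsertionObservation(
                sample_id, chrom, pos, family, f.size, r.size, nspan, freq, both_sided=True,
            ))
        for side_clusters, is_fwd in ((fwd, True), (rev, False)):
            used = used_f if is_fwd else used_r
            for i, c in enumerate(side_clusters):
                if i in used or c.size < min_support:
                    continue
                pos = c.innermost
                nspan = n_spanning_at(chrom, pos)
                freq = estimate_frequency(c.size, nspan)
                nf, nr = (c.size, 0) if is_fwd else (0, c.size)
                observations.append(InsertionObservation(
                    sample_id, chrom, pos, family, nf, nr, nspan, freq, both_sided=False,
                ))

    observations.sort(key=lambda o: (o.chrom, o.pos_estimate, o.family))
    return observations


# ---------------------------------------------------------------------------
# Convenience: one sample end to end (in memory)


def padded_mask_regions(ref: ReferenceBundle, pad: float) -> dict[str, list[tuple[int, int]]]:
    return {
        chrom: [(max(0, a - int(pad)), b + int(pad)) for a, b in spans]
        for chrom, spans in ref.masked_spans().items()
    }


def detect_sample(
    read_pairs: Iterable[tuple[str, str, str]],
    ref: ReferenceBundle,
    sample_id: str,
    insert_mean: float = 430.0,
    insert_sd: float = 25.0,
    min_support: int = 2,
    cluster_window: float | None = None,
    aligner: ExactReadAligner | None = None,
) -> list[InsertionObservation]:
    """Align in-memory read pairs and detect insertions for one sample."""
    aligner = aligner or ExactReadAligner(ref)
    window = cluster_window if cluster_window is not None else insert_mean + 3 * insert_sd
    te_families = {name: fam for name, (fam, _) in ref.te_library.items()}
    evidence = classify_pairs(
        aligner.align_pairs(read_pairs), te_families,
        insert_mean=insert_mean, insert_sd=insert_sd,
    )
    return detect_insertions(
        evidence, cluster_window=window, min_support=min_support,
        exclude_regions=padded_mask_regions(ref, window), sample_id=sample_id,
    )


def observations_frame(observations: Iterable[InsertionObservation]):
    import pandas as pd

    rows = [
        (o.sample_id, o.chrom, o.pos_estimate, o.family, o.n_support_fwd,
         o.n_support_rev, o.n_spanning, o.freq_estimate, int(o.both_sided))
        for o in observations
    ]
    return pd.DataFrame(rows, columns=[
        "sample_id", "chrom", "pos0", "family", "n_support_fwd", "n_support_rev",
        "n_spanning", "freq", "both_sided",
    ])
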