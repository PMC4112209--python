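"""Reading and writing the flat-file formats the pipeline touches.

FASTA goes through Biopython; GFF3/BED intervals are written here and read
back with standard conventions (GFF3 1-based closed, BED 0-based half-open).
All tabular output is TSV with an optional ``#``-prefixed provenance header so
reruns can be compared byte for byte.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

Interval = tuple[int, int]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 / BED interval files


def write_gff3_genes(
    path: str | os.PathLike, genes: Mapping[str, Iterable[Interval]], source: str = "tepop"
) -> None:
    """Write gene intervals (0-based half-open in memory) as GFF3 gene features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(genes):
            for i, (start, end) in enumerate(sorted(genes[chrom])):
                gid = f"{chrom}.g{i + 1}"
                fh.write(
                    f"{chrom}\t{source}\tgene\t{start + 1}\t{end}\t.\t+\t.\tID={gid}\n"
                )


def read_gff3_genes(path: str | os.PathLike) -> dict[str, list[Interval]]:
    """Read gene features back to 0-based half-open intervals per chromosome."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique")
    genes: dict[str, list[Interval]] = {}
    for feature in db.features_of_type("gene"):
        genes.setdefault(feature.seqid, []).append((feature.start - 1, feature.end))
    for chrom in genes:
        genes[chrom].sort()
    return genes


def write_bed(path: str | os.PathLike, intervals: Mapping[str, Iterable[Interval]],
              names: Mapping[str, Iterable[str]] | None = None) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            ivs = sorted(intervals[chrom])
            labels = list(names[chrom]) if names else [""] * len(ivs)
            for (start, end), label in zip(ivs, labels):
                extra = f"\t{label}" if label else ""
                fh.write(f"{chrom}\t{start}\t{end}{extra}\n")


def read_bed(path: str | os.PathLike) -> dict[str, list[Interval]]:
    out: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    for chrom in out:
        out[chrom].sort()
    return out


# ---------------------------------------------------------------------------
# FASTQ


def iter_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, str]]:
    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def iter_fastq_pairs(path1: str | os.PathLike, path2: str | os.PathLike
                     ) -> Iterator[tuple[str, str, str]]:
    """Yield (name, mate1_seq, mate2_seq); raises on unequal mate counts."""
    it1, it2 = iter_fastq(path1), iter_fastq(path2)
    sentinel = object()
    while True:
        a = next(it1, sentinel)
        b = next(it2, sentinel)
        if a is sentinel and b is sentinel:
            return
        if a is sentinel or b is sentinel:
            raise ValueError(f"unequal mate counts in {path1} / {path2}")
        name1 = a[0].split()[0].removesuffix("/1")
        name2 = b[0].split()[0].removesuffix("/2")
        if name1 != name2:
            raise ValueError(f"mate name mismatch: {name1!r} vs {name2!r}")
        yield name1, a[1], b[1]


def write_fastq_pair(prefix: str | os.PathLike,
                     pairs: Iterable[tuple[str, str, str]],
                     quality_char: str = "I") -> tuple[str, str]:
    """Write paired reads to ``<prefix>_1.fastq`` / ``<prefix>_2.fastq``."""
    p1, p2 = f"{prefix}_1.fastq", f"{prefix}_2.fastq"
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for name, s1, s2 in pairs:
            f1.write(f"@{name}/1\n{s1}\n+\n{quality_char * len(s1)}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{quality_char * len(s2)}\n")
    return p1, p2


# ---------------------------------------------------------------------------
# TSV


def write_tsv(df: pd.DataFrame, path: str | os.PathLike,
              header_comment: str | None = None, index: bool = False) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n", float_format="%.6g")


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
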