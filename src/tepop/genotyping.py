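"""Genotype calling and cross-sample merging of insertion observations.

Within-individual frequency estimates are thresholded into three genotype
states (frequency > 0.8 homozygous, < 0.2 treated as error/absent,
intermediate heterozygous; the boundaries themselves fall in the
heterozygous band). Observations from all samples are then merged into
insertion sites: same-chromosome, same-family observations chained whenever
consecutive positions lie within the identity window (200 bp by default),
giving a site × sample genotype matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .evidence import InsertionObservation

ABSENT = "absent"
HETEROZYGOUS = "heterozygous"
HOMOZYGOUS = "homozygous"

_DOSAGE = {ABSENT: 0, HETEROZYGOUS: 1, HOMOZYGOUS: 2}


def call_genotype(freq_estimate: float, low: float = 0.2, high: float = 0.8) -> str:
    """Threshold a within-individual frequency estimate into a genotype call."""
    if not 0.0 <= freq_estimate <= 1.0:
        raise ValueError(f"frequency {freq_estimate} outside [0, 1]")
    if freq_estimate > high:
        return HOMOZYGOUS
    if freq_estimate < low:
        return ABSENT
    return HETEROZYGOUS


@dataclass
class InsertionSite:
    """A merged cross-sample insertion site (one row of the genotype matrix)."""

    site_id: str
    chrom: str
    pos_consensus: int
    family: str
    calls: dict[str, str]  # sample_id -> genotype call (absent samples omitted or "absent")
    member_positions: list[int] = field(default_factory=list)

    def call_for(self, sample_id: str) -> str:
        return self.calls.get(sample_id, ABSENT)

    def carriers(self) -> list[str]:
        return sorted(s for s, c in self.calls.items() if c != ABSENT)


def _chain_groups(positions: Sequence[int], window: int) -> list[list[int]]:
    """Indices grouped by transitive chaining of the sorted positions."""
    order = np.argsort(np.asarray(positions), kind="stable")
    groups: list[list[int]] = []
    prev = None
    for idx in order:
        pos = positions[idx]
        if prev is not None and pos - prev <= window:
            groups[-1].append(int(idx))
        else:
            groups.append([int(idx)])
        prev = pos
    return groups


def _anchor_groups(observations: Sequence[InsertionObservation], window: int) -> list[list[int]]:
    """Anchor-based alternative: seed on the best-supported observation, absorb
    everything within the window of the anchor, repeat on the remainder."""
    remaining = sorted(
        range(len(observations)),
        key=lambda i: (-observations[i].n_support, observations[i].pos_estimate),
    )
    taken = [False] * len(observations)
    groups: list[list[int]] = []
    for i in remaining:
        if taken[i]:
            continue
        anchor = observations[i].pos_estimate
        members = [
            j for j in range(len(observations))
            if not taken[j] and abs(observations[j].pos_estimate - anchor) <= window
        ]
        for j in members:
            taken[j] = True
        groups.append(sorted(members))
    return groups


def merge_across_samples(
    observations: Iterable[InsertionObservation],
    identity_window: int = 200,
    low: float = 0.2,
    high: float = 0.8,
    require_same_family: bool = True,
    method: str = "chain",
) -> list[InsertionSite]:
    """Merge per-sample observations into insertion sites.

    Observations whose frequency falls below ``low`` are treated as errors and
    dropped before merging (they never seed a site; the sample stays absent at
    sites formed by others). ``method`` is ``"chain"`` (transitive chaining,
    default) or ``"anchor"``. The consensus position is the floor of the mean
    of member positions. Output is sorted and independent of input order.
    """
    kept = [o for o in observations if call_genotype(o.freq_estimate, low, high) != ABSENT]
    kept.sort(key=lambda o: (o.chrom, o.pos_estimate, o.family, o.sample_id, -o.n_support))

    partitions: dict[tuple[str, str], list[InsertionObservation]] = {}
    for o in kept:
        key = (o.chrom, o.family if require_same_family else "")
        partitions.setdefault(key, []).append(o)

    sites: list[InsertionSite] = []
    for (chrom, _), obs in sorted(partitions.items()):
        if method == "chain":
            groups = _chain_groups([o.pos_estimate for o in obs], identity_window)
        elif method == "anchor":
            groups = _anchor_groups(obs, identity_window)
        else:
            raise ValueError(f"unknown merge method {method!r}")
        for idxs in groups:
            members = [obs[i] for i in idxs]
            positions = [m.pos_estimate for m in members]
            consensus = int(np.floor(np.mean(positions)))
            calls: dict[str, str] = {}
            best: dict[str, InsertionObservation] = {}
            for m in members:
                cur = best.get(m.sample_id)
                if cur is None or m.n_support > cur.n_support:
                    best[m.sample_id] = m
            for sample_id, m in best.items():
                calls[sample_id] = call_genotype(m.freq_estimate, low, high)
            family = members[0].family if require_same_family else \
                max({m.family for m in members}, key=[m.family for m in members].count)
            sites.append(InsertionSite(
                site_id="", chrom=chrom, pos_consensus=consensus, family=family,
                calls=calls, member_positions=sorted(positions),
            ))

    sites.sort(key=lambda s: (s.chrom, s.pos_consensus, s.family))
    for i, site in enumerate(sites):
        site.site_id = f"site{i + 1:05d}"
    return sites


def classify_sharing(
    sites: Iterable[InsertionSite], species_of: Mapping[str, str]
) -> dict[str, frozenset[str]]:
    """Which species carry each site (≥ 1 non-absent call among its samples)."""
    out: dict[str, frozenset[str]] = {}
    for site in sites:
        species = set()
        for sample_id, call in site.calls.items():
            if sample_id not in species_of:
                raise KeyError(f"sample {sample_id!r} has no species assignment")
            if call != ABSENT:
                species.add(species_of[sample_id])
        out[site.site_id] = frozenset(species)
    return out


def sharing_counts(
    sites: Iterable[InsertionSite], species_of: Mapping[str, str]
) -> dict[frozenset[str], int]:
    """Counts per species subset (the Venn-diagram cells)."""
    counts: dict[frozenset[str], int] = {}
    for subset in classify_sharing(sites, species_of).values():
        counts[subset] = counts.get(subset, 0) + 1
    return counts


def matrix_frame(sites: Iterable[InsertionSite], samples: Sequence[str]) -> pd.DataFrame:
    """Site × sample matrix with 0 = absent, 1 = heterozygous, 2 = homozygous."""
    rows = []
    for site in sites:
        row = {"site_id": site.site_id, "chrom": site.chrom,
               "pos0": site.pos_consensus, "family": site.family}
        for s in samples:
            row[s] = _DOSAGE[site.call_for(s)]
        rows.append(row)
    return pd.DataFrame(rows, columns=["site_id", "chrom", "pos0", "family", *samples])


def sites_from_matrix(df: pd.DataFrame) -> list[InsertionSite]:
    """Rebuild InsertionSite objects from a genotype-matrix frame."""
    meta = {"site_id", "chrom", "pos0", "family"}
    samples = [c for c in df.columns if c not in meta]
    rev = {0: ABSENT, 1: HETEROZYGOUS, 2: HOMOZYGOUS}
    sites = []
    for _, row in df.iterrows():
        calls = {s: rev[int(row[s])] for s in samples if int(row[s]) > 0}
        sites.append(InsertionSite(
            site_id=str(row["site_id"]), chrom=str(row["chrom"]),
            pos_consensus=int(row["pos0"]), family=str(row["family"]),
            calls=calls, member_positions=[int(row["pos0"])],
        ))
    return sites
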