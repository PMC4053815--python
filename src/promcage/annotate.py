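"""Final promoter catalogue: categories, redundancy removal, tissue calls.

The same promoter can be detected in several libraries and can serve several
miRNAs in a genomic cluster. Same-locus calls (overlapping intervals on one
strand) are merged into a single catalogue entry that accumulates the
libraries it is expressed in; sequence-level redundancy is then removed with
a cd-hit-like greedy clustering at 0.8 identity, keeping the entry with the
highest tag count as representative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from promcage.features import FeatureVector, PriorPair
from promcage.io import DataError, GeneModel, GenomicInterval, MirnaRecord
from promcage.model import PosteriorResult
from promcage.preprocess import CandidateRegion

CATEGORIES = ("intergenic", "host_gene", "intronic", "hybrid")


@dataclass(frozen=True)
class PromoterCall:
    region: CandidateRegion
    features: FeatureVector
    prior: PriorPair
    posterior: PosteriorResult
    category: str
    libraries_expressed: frozenset[str] = frozenset()
    tissue_specific: bool = False
    representative: bool = True

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise DataError(f"unknown category: {self.category}")


def assign_category(
    region: CandidateRegion,
    mirnas: Mapping[str, MirnaRecord],
    genes: Mapping[str, GeneModel],
    host_tss_flank: int = 100,
) -> str:
    """Category of a classified candidate.

    ``host_gene`` (overlaps a host-gene transcript TSS +/- flank) takes
    precedence over ``intronic`` (inside any intron of the host gene);
    candidates in intergenic space are ``intergenic`` when they serve an
    intergenic miRNA and ``hybrid`` when they sit upstream of an intragenic
    miRNA and cannot be assigned unambiguously.
    """
    assigned = [mirnas[m] for m in region.assigned_mirnas if m in mirnas]
    if not assigned:
        raise DataError("candidate with no assigned miRNA cannot be categorized")
    iv = region.cluster.interval
    hosts = [
        genes[m.host_gene_id]
        for m in assigned
        if m.host_gene_id and m.host_gene_id in genes
    ]
    for g in hosts:
        for tx in g.transcripts:
            flank = GenomicInterval(
                tx.interval.chrom,
                max(0, tx.tss - host_tss_flank),
                tx.tss + host_tss_flank + 1,
                tx.interval.strand,
            )
            if iv.overlaps(flank):
                return "host_gene"
    for g in hosts:
        if any(intron.contains(iv) for intron in g.introns()):
            return "intronic"
    if any(m.locus_class == "intergenic" for m in assigned):
        return "intergenic"
    return "hybrid"


# ---------------------------------------------------------------------------
# Redundancy removal


def _merge_same_locus(calls: Sequence[PromoterCall]) -> list[PromoterCall]:
    """Merge overlapping same-strand calls (one promoter seen in several
    libraries) into one entry accumulating libraries and tag counts."""
    by_key: dict[tuple[str, str], list[PromoterCall]] = {}
    for c in calls:
        iv = c.region.cluster.interval
        by_key.setdefault((iv.chrom, iv.strand), []).append(c)
    merged: list[PromoterCall] = []
    for group in by_key.values():
        group.sort(key=lambda c: c.region.cluster.interval.start)
        chunk: list[PromoterCall] = []
        end = -1
        for c in group:
            iv = c.region.cluster.interval
            if chunk and iv.start < end:
                chunk.append(c)
                end = max(end, iv.end)
            else:
                if chunk:
                    merged.append(_collapse(chunk))
                chunk = [c]
                end = iv.end
        if chunk:
            merged.append(_collapse(chunk))
    return merged


def _collapse(chunk: list[PromoterCall]) -> PromoterCall:
    best = max(chunk, key=lambda c: c.region.cluster.x)
    libs = frozenset().union(*(c.libraries_expressed for c in chunk))
    total_x = sum(c.region.cluster.x for c in chunk)
    cluster = replace(best.region.cluster, x=total_x)
    region = replace(best.region, cluster=cluster)
    return replace(best, region=region, libraries_expressed=libs)


def _identity(a: str, b: str) -> float:
    """Ungapped sliding identity: best fraction of matching positions when
    the shorter sequence is slid along the longer one."""
    if len(a) > len(b):
        a, b = b, a
    la, lb = len(a), len(b)
    best = 0.0
    for off in range(lb - la + 1):
        matches = sum(1 for x, y in zip(a, b[off : off + la]) if x == y)
        best = max(best, matches / la)
        if best == 1.0:
            break
    return best


def _kmer_set(seq: str, k: int = 8) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def deduplicate(
    calls: Sequence[PromoterCall],
    sequences: Mapping[int, str] | Sequence[str],
    similarity: float = 0.8,
) -> list[PromoterCall]:
    """Greedy longest-first sequence clustering; flags representatives.

    ``sequences[i]`` is the promoter sequence of ``calls[i]``. A call joins
    an existing cluster when its identity to the cluster representative is at
    least ``similarity`` (a shared-k-mer word filter skips hopeless pairs
    first). Within each cluster the call with the highest tag count is the
    representative. Calls at the same locus are merged beforehand.
    """
    if not calls:
        return []
    seqs = [sequences[i].upper() for i in range(len(calls))]
    merged = _merge_same_locus(
        [replace(c, representative=False) for c in calls]
    )
    # map each merged entry back to a sequence via its best member interval
    seq_of: list[str] = []
    for c in merged:
        iv = c.region.cluster.interval
        match = next(
            (
                seqs[i]
                for i, orig in enumerate(calls)
                if orig.region.cluster.interval.overlaps(iv)
            ),
            "",
        )
        seq_of.append(match)

    order = sorted(range(len(merged)), key=lambda i: -len(seq_of[i]))
    cluster_of = [-1] * len(merged)
    reps: list[int] = []
    kmers = [_kmer_set(s) if s else set() for s in seq_of]
    for i in order:
        placed = False
        for ci, r in enumerate(reps):
            if seq_of[i] and kmers[i] and kmers[r]:
                shared = len(kmers[i] & kmers[r])
                if shared / max(1, min(len(kmers[i]), len(kmers[r]))) < 0.05:
                    continue
                if _identity(seq_of[i], seq_of[r]) >= similarity:
                    cluster_of[i] = ci
                    placed = True
                    break
        if not placed:
            cluster_of[i] = len(reps)
            reps.append(i)

    out: list[PromoterCall] = []
    for ci in range(len(reps)):
        members = [merged[i] for i in range(len(merged)) if cluster_of[i] == ci]
        best = max(members, key=lambda c: c.region.cluster.x)
        for c in members:
            out.append(replace(c, representative=c is best))
    out.sort(
        key=lambda c: (c.region.cluster.interval.chrom, c.region.cluster.interval.start)
    )
    return out


def apply_tissue_specificity(
    calls: Sequence[PromoterCall], n_libraries: int
) -> list[PromoterCall]:
    """Flag promoters expressed in fewer than ceil(4 L / 33) libraries.

    On a 33-library panel this is the "fewer than 4 of 33" rule; the
    threshold scales proportionally for other library counts.
    """
    threshold = math.ceil(4 * n_libraries / 33)
    return [
        replace(c, tissue_specific=len(c.libraries_expressed) < threshold)
        for c in calls
    ]


# ---------------------------------------------------------------------------
# Summary


def summarize(calls: Sequence[PromoterCall], mirnas: Sequence[MirnaRecord]):
    """Per-category promoter counts and miRNA coverage (Table-1-shaped).

    For each category and overall: number of representative promoters, the
    percentage of eligible miRNAs with at least one / more than one promoter,
    and the mean number of alternative TSSs per covered miRNA. Intergenic
    percentages are relative to intergenic miRNAs; host-gene, intronic and
    hybrid to intragenic miRNAs.
    """
    import pandas as pd

    reps = [c for c in calls if c.representative]
    n_inter = sum(1 for m in mirnas if m.locus_class == "intergenic")
    n_intra = len(mirnas) - n_inter
    denominators = {
        "intergenic": n_inter,
        "host_gene": n_intra,
        "intronic": n_intra,
        "hybrid": n_intra,
        "all": len(mirnas),
    }
    rows = []
    for cat in list(CATEGORIES) + ["all"]:
        sel = reps if cat == "all" else [c for c in reps if c.category == cat]
        per_mirna: dict[str, int] = {}
        for c in sel:
            for m in c.region.assigned_mirnas:
                per_mirna[m] = per_mirna.get(m, 0) + 1
        denom = denominators[cat]
        covered = len(per_mirna)
        multi = sum(1 for v in per_mirna.values() if v > 1)
        rows.append(
            {
                "category": cat,
                "n_promoters": len(sel),
                "pct_mirnas_with_promoter": 100.0 * covered / denom if denom else 0.0,
                "pct_mirnas_multiple_promoters": 100.0 * multi / denom if denom else 0.0,
                "mean_tss_per_mirna": (
                    sum(per_mirna.values()) / covered if covered else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)
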