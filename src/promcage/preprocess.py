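"""CAGE tag normalization, clustering and candidate-region construction.

The observation unit of the mixture model is the per-library tag cluster:
tags from one library whose mapped coordinates overlap by at least 1 bp are
merged, and the quantile-normalized counts inside the cluster are summed.
Clusters are kept as promoter candidates when they lie within 50 kb upstream
of an annotated miRNA precursor on the same strand, do not coincide with the
TSS of another annotated transcript, and do not span host-gene exons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import rankdata

from promcage.io import (
    CageTag,
    DataError,
    GeneModel,
    GenomicInterval,
    MirnaRecord,
)

#: floor for background observations with no overlapping tags. The
#: inverse-Gaussian support requires x > 0; the floor sits at half the
#: smallest possible normalized single-tag count so that empty regions stay
#: on the count scale, adjacent to the noise mode, instead of forming a
#: detached spike that distorts the background component.
X_FLOOR = 0.5


@dataclass(frozen=True)
class NormalizedTag:
    interval: GenomicInterval
    library_id: str
    norm_count: float

    def __post_init__(self) -> None:
        if self.norm_count <= 0:
            raise DataError(f"non-positive normalized count: {self.norm_count}")


@dataclass(frozen=True)
class TagCluster:
    """Maximal chain of >=1 bp-overlapping tags from one library."""

    interval: GenomicInterval
    library_id: str
    members: tuple[NormalizedTag, ...]
    x: float

    @property
    def width(self) -> int:
        return len(self.interval)

    def representative_tss(self) -> int:
        """Position of the highest-count member tag (ties: most 5')."""
        best = max(
            self.members,
            key=lambda t: (t.norm_count, -t.interval.five_prime()
                           if self.interval.strand != "-" else t.interval.five_prime()),
        )
        return best.interval.five_prime()


@dataclass(frozen=True)
class CandidateRegion:
    cluster: TagCluster
    representative_tss: int
    feature_window: GenomicInterval
    assigned_mirnas: tuple[str, ...] = ()
    category_hint: str = "intergenic"
    is_background: bool = False


# ---------------------------------------------------------------------------
# Quantile normalization


def choose_reference_library(
    libraries: Mapping[str, Sequence[CageTag]],
    rng: np.random.Generator | None = None,
) -> str:
    """Default reference: the library of median total tag count.

    Passing ``rng`` instead draws the reference uniformly at random, matching
    the original procedure of picking one library at random.
    """
    ids = sorted(libraries)
    if rng is not None:
        return ids[int(rng.integers(len(ids)))]
    totals = sorted(ids, key=lambda k: (sum(t.count for t in libraries[k]), k))
    return totals[len(totals) // 2]


def quantile_normalize(
    libraries: Mapping[str, Sequence[CageTag]],
    reference_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, list[NormalizedTag]]:
    """Per-position quantile normalization against a reference library.

    Within each library the multiset of tag counts is replaced rank-wise by
    the reference library's empirical quantiles. Tied counts receive the mean
    of the tied reference quantiles; libraries of unequal size are rank-mapped
    through linear interpolation of the reference's empirical quantile
    function. The reference library itself is returned unchanged.
    """
    if not libraries:
        raise DataError("no libraries to normalize")
    for lib_id, tags in libraries.items():
        if len(tags) == 0:
            raise DataError(f"library {lib_id} is empty")
    if reference_id is None:
        reference_id = choose_reference_library(libraries, rng=rng)
    if reference_id not in libraries:
        raise DataError(f"reference library {reference_id!r} not among libraries")

    ref_sorted = np.sort([t.count for t in libraries[reference_id]])
    m = len(ref_sorted)
    # empirical quantile function knots at p = (k - 0.5)/m
    ref_p = (np.arange(1, m + 1) - 0.5) / m

    out: dict[str, list[NormalizedTag]] = {}
    for lib_id, tags in libraries.items():
        counts = np.array([t.count for t in tags], dtype=float)
        if lib_id == reference_id:
            normed = counts
        else:
            n = len(counts)
            ranks = rankdata(counts, method="average")
            p = (ranks - 0.5) / n
            normed = np.interp(p, ref_p, ref_sorted)
        out[lib_id] = [
            NormalizedTag(t.interval, t.library_id, float(v))
            for t, v in zip(tags, normed)
        ]
    return out


# ---------------------------------------------------------------------------
# Tag clustering


def cluster_tags(tags: Sequence[NormalizedTag]) -> list[TagCluster]:
    """Merge tags whose coordinates overlap by >= 1 bp into clusters.

    Input must come from a single library and a single chromosome-strand;
    abutting tags (0 bp overlap under half-open coordinates) stay separate.
    The cluster observation ``x`` is the sum of member normalized counts.
    """
    if not tags:
        return []
    keys = {(t.interval.chrom, t.interval.strand, t.library_id) for t in tags}
    if len(keys) > 1:
        raise DataError(f"cluster_tags requires one chromosome-strand-library, got {keys}")
    ordered = sorted(tags, key=lambda t: (t.interval.start, t.interval.end))
    clusters: list[TagCluster] = []
    chunk = [ordered[0]]
    end = ordered[0].interval.end
    for t in ordered[1:]:
        if t.interval.start < end:  # >= 1 bp overlap
            chunk.append(t)
            end = max(end, t.interval.end)
        else:
            clusters.append(_make_cluster(chunk))
            chunk = [t]
            end = t.interval.end
    clusters.append(_make_cluster(chunk))
    return clusters


def _make_cluster(chunk: list[NormalizedTag]) -> TagCluster:
    iv0 = chunk[0].interval
    interval = GenomicInterval(
        iv0.chrom,
        min(t.interval.start for t in chunk),
        max(t.interval.end for t in chunk),
        iv0.strand,
    )
    return TagCluster(
        interval=interval,
        library_id=chunk[0].library_id,
        members=tuple(chunk),
        x=float(sum(t.norm_count for t in chunk)),
    )


def cluster_library(tags: Sequence[NormalizedTag]) -> list[TagCluster]:
    """Cluster a whole library, grouping by chromosome and strand."""
    groups: dict[tuple[str, str], list[NormalizedTag]] = {}
    for t in tags:
        groups.setdefault((t.interval.chrom, t.interval.strand), []).append(t)
    out: list[TagCluster] = []
    for key in sorted(groups):
        out.extend(cluster_tags(groups[key]))
    return out


# ---------------------------------------------------------------------------
# Candidate extraction


def _feature_window(
    chrom: str, tss: int, strand: str, size: int, chrom_sizes: Mapping[str, int]
) -> GenomicInterval:
    half = size // 2
    start = max(0, tss - half)
    end = min(chrom_sizes[chrom], tss + size - half)
    return GenomicInterval(chrom, start, end, strand)


def _tss_distance(tss: int, precursor: GenomicInterval) -> int:
    """Strand-aware distance from a TSS to the precursor 5' end.

    Positive when the TSS is upstream of the precursor.
    """
    p5 = precursor.five_prime()
    return (p5 - tss) if precursor.strand != "-" else (tss - p5)


def extract_candidates(
    clusters: Sequence[TagCluster],
    mirnas: Sequence[MirnaRecord],
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    window: int = 50_000,
    feature_window: int = 1_000,
    host_tss_flank: int = 100,
) -> list[CandidateRegion]:
    """Keep clusters within ``window`` bp upstream of a precursor and filter.

    Filters: clusters overlapping the TSS of any annotated transcript other
    than a host-gene transcript of an assigned miRNA are dropped (they mark
    other genes' promoters); clusters containing tags that overlap annotated
    exons of an assigned host gene are dropped (they mark host-gene splice
    products). Each surviving candidate gets a category hint:

    - ``host_gene``: overlaps a host-gene transcript TSS +/- ``host_tss_flank``
    - ``intronic``: inside an intron of the host gene (any intron)
    - ``intergenic``: assigned to at least one intergenic miRNA
    - ``hybrid``: intergenic space upstream of an intragenic miRNA only
    """
    genes_by_id = {g.gene_id: g for g in genes}
    candidates: list[CandidateRegion] = []
    for cluster in clusters:
        iv = cluster.interval
        tss = cluster.representative_tss()
        assigned = [
            m
            for m in mirnas
            if m.precursor.chrom == iv.chrom
            and m.precursor.strand == iv.strand
            and 0 <= _tss_distance(tss, m.precursor) <= window
        ]
        if not assigned:
            continue
        host_ids = {m.host_gene_id for m in assigned if m.host_gene_id}

        # overlap with TSS of any non-host transcript
        if any(
            iv.overlaps(GenomicInterval(tx.interval.chrom, tx.tss, tx.tss + 1))
            for g in genes
            if g.gene_id not in host_ids
            for tx in g.transcripts
        ):
            continue
        hosts = [genes_by_id[h] for h in host_ids if h in genes_by_id]
        category = _category_hint(iv, assigned, hosts, host_tss_flank)
        # member tags spanning host-gene exons mark alternative host
        # transcripts, not miRNA TSSs; clusters at the host TSS itself are
        # exempt (the first exon necessarily starts there)
        if category != "host_gene" and any(
            t.interval.overlaps(ex)
            for t in cluster.members
            for g in hosts
            for tx in g.transcripts
            for ex in tx.exons
        ):
            continue
        candidates.append(
            CandidateRegion(
                cluster=cluster,
                representative_tss=tss,
                feature_window=_feature_window(
                    iv.chrom, tss, iv.strand, feature_window, chrom_sizes
                ),
                assigned_mirnas=tuple(m.mirna_id for m in assigned),
                category_hint=category,
            )
        )
    return candidates


def _category_hint(
    iv: GenomicInterval,
    assigned: list[MirnaRecord],
    hosts: list[GeneModel],
    host_tss_flank: int,
) -> str:
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
# Background sampling


def sample_background(
    chrom_sizes: Mapping[str, int],
    genes: Sequence[GeneModel],
    repeat_mask: Sequence[GenomicInterval],
    n: int,
    rng: np.random.Generator,
    normalized_tags: Sequence[NormalizedTag] = (),
    region_size: int = 1_000,
) -> list[CandidateRegion]:
    """Sample ``n`` fixed-label background regions from intergenic space.

    Regions of ``region_size`` bp are drawn uniformly from the portion of the
    genome covered by neither gene bodies nor the repeat mask. Each region
    carries the sum of overlapping normalized CAGE tag counts as its
    observation; regions with no tags get the floor ``X_FLOOR`` so the
    inverse-Gaussian likelihood stays finite.
    """
    if n < 1:
        raise DataError("background sample size must be >= 1")
    blocked: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for g in genes:
        if g.interval.chrom in blocked:
            blocked[g.interval.chrom].append((g.interval.start, g.interval.end))
    for r in repeat_mask:
        if r.chrom in blocked:
            blocked[r.chrom].append((r.start, r.end))

    eligible: list[GenomicInterval] = []
    for chrom, size in sorted(chrom_sizes.items()):
        merged: list[list[int]] = []
        for s, e in sorted(blocked[chrom]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        prev = 0
        for s, e in merged + [[size, size]]:
            if s - prev >= region_size:
                eligible.append(GenomicInterval(chrom, prev, s))
            prev = max(prev, e)
    weights = np.array([len(iv) - region_size + 1 for iv in eligible], dtype=float)
    if not eligible or weights.sum() <= 0:
        raise DataError("insufficient intergenic non-repeat space for background")

    tag_trees: dict[str, IntervalTree] = {}
    for t in normalized_tags:
        tag_trees.setdefault(t.interval.chrom, IntervalTree()).addi(
            t.interval.start, t.interval.end, t.norm_count
        )

    probs = weights / weights.sum()
    out: list[CandidateRegion] = []
    for _ in range(n):
        iv = eligible[int(rng.choice(len(eligible), p=probs))]
        offset = int(rng.integers(0, len(iv) - region_size + 1))
        region = GenomicInterval(iv.chrom, iv.start + offset, iv.start + offset + region_size)
        tree = tag_trees.get(region.chrom)
        x = (
            sum(hit.data for hit in tree.overlap(region.start, region.end))
            if tree is not None
            else 0.0
        )
        tss = region.start + region_size // 2
        cluster = TagCluster(
            interval=region,
            library_id="background",
            members=(NormalizedTag(region, "background", max(x, X_FLOOR)),),
            x=max(float(x), X_FLOOR),
        )
        out.append(
            CandidateRegion(
                cluster=cluster,
                representative_tss=tss,
                feature_window=region,
                assigned_mirnas=(),
                category_hint="intergenic",
                is_background=True,
            )
        )
    return out
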