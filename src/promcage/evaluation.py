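"""Indirect validation of promoter calls.

Two procedures are provided:

1. **PolII occupancy.** The 1,000 bp windows around candidate TSSs are
   overlapped with RNA-polymerase-II ChIP-seq peaks. At posterior cutoff c a
   called promoter overlapping a peak is a true positive, a call with no
   overlap a false positive, a non-call with no overlap a true negative and a
   non-call overlapping a peak a false negative; ROC and precision-recall
   curves follow by varying c.

2. **RNA-seq coverage.** The putative primary transcript of each promoter
   (TSS to 70 bp past the mature miRNA) is tested for expression: its
   per-library continuous read coverage is compared to a background coverage
   distribution from random intergenic (or intronic, for intragenic
   pri-miRNAs) regions with a two-sample Kolmogorov-Smirnov test and a
   Benjamini-Hochberg correction. A transcript is "present" with fold
   enrichment >= 2 over the background mean and adjusted P < 0.1; precision
   is the fraction present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import ks_2samp
from statsmodels.stats.multitest import multipletests

from promcage.io import DataError, GenomicInterval


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else float("nan")


@dataclass(frozen=True)
class CoverageCall:
    pri_mirna_region: GenomicInterval
    coverages: tuple[float, ...]
    fold_enrichment: float
    p_adj: float
    present: bool


def _peak_tree(peaks: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    return trees


def polii_confusion(
    regions: Sequence[GenomicInterval],
    posteriors: Sequence[float],
    peaks: Sequence[GenomicInterval],
    c: float = 0.5,
) -> ConfusionCounts:
    """Confusion counts of promoter calls (posterior > c) against PolII peaks."""
    if len(regions) != len(posteriors):
        raise DataError("regions and posteriors length mismatch")
    trees = _peak_tree(peaks)
    tp = fp = tn = fn = 0
    for region, p in zip(regions, posteriors):
        tree = trees.get(region.chrom)
        hit = bool(tree is not None and tree.overlap(region.start, region.end))
        called = p > c
        if called and hit:
            tp += 1
        elif called:
            fp += 1
        elif hit:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn, c)


def roc_pr_curves(
    regions: Sequence[GenomicInterval],
    posteriors: Sequence[float],
    peaks: Sequence[GenomicInterval],
    cutoffs: Sequence[float],
):
    """One confusion row per cutoff: (c, FPR, recall, precision)."""
    import pandas as pd

    if len(cutoffs) < 1:
        raise DataError("need at least one cutoff")
    rows = []
    for c in cutoffs:
        cc = polii_confusion(regions, posteriors, peaks, c)
        rows.append(
            {
                "cutoff": c,
                "tp": cc.tp,
                "fp": cc.fp,
                "tn": cc.tn,
                "fn": cc.fn,
                "fpr": cc.fpr,
                "recall": cc.recall,
                "precision": cc.precision,
            }
        )
    return pd.DataFrame(rows)


def pri_mirna_region(
    tss: int, mature: GenomicInterval, downstream: int = 70
) -> GenomicInterval:
    """Putative primary transcript: TSS to ``downstream`` bp past the mature
    miRNA, strand-aware."""
    if mature.strand == "-":
        start, end = mature.start - downstream, tss + 1
    else:
        start, end = tss, mature.end + downstream
    if end <= start:
        raise DataError(
            f"TSS {tss} is not upstream of the mature miRNA {mature}"
        )
    return GenomicInterval(mature.chrom, max(0, start), end, mature.strand)


def continuous_coverage(
    region: GenomicInterval,
    reads: Sequence[GenomicInterval],
    mode: str = "longest_run",
) -> float:
    """Fraction of the region continuously covered by reads.

    ``mode="longest_run"`` (default): length of the longest gap-free run of
    bases with depth >= 1, over the region length — a transcript needs
    contiguous support. ``mode="fraction"``: plain covered fraction
    (coverageBed semantics).
    """
    if len(region) == 0:
        raise DataError("empty region")
    if mode not in ("longest_run", "fraction"):
        raise ValueError(f"unknown coverage mode: {mode}")
    spans = sorted(
        (max(r.start, region.start), min(r.end, region.end))
        for r in reads
        if r.chrom == region.chrom and r.start < region.end and r.end > region.start
    )
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    if not merged:
        return 0.0
    if mode == "longest_run":
        covered = max(e - s for s, e in merged)
    else:
        covered = sum(e - s for s, e in merged)
    return covered / len(region)


def presence_calls(
    pri_regions: Sequence[GenomicInterval],
    locus_classes: Sequence[str],
    reads_by_library: Mapping[str, Sequence[GenomicInterval]],
    background_regions: Mapping[str, Sequence[GenomicInterval]],
    fold_min: float = 2.0,
    alpha: float = 0.1,
    mode: str = "longest_run",
) -> tuple[list[CoverageCall], float]:
    """Coverage-based presence calls for putative pri-miRNA transcripts.

    ``background_regions`` maps "intergenic"/"intragenic" to the sampled
    background region sets (random intergenic regions for intergenic
    pri-miRNAs, random intronic regions for intragenic ones). Returns the
    per-region calls and the overall precision TP/(TP+FP).
    """
    if len(pri_regions) != len(locus_classes):
        raise DataError("pri_regions and locus_classes length mismatch")
    for key in set(locus_classes):
        if not background_regions.get(key):
            raise DataError(f"no background regions for class {key!r}")

    pooled = [r for reads in reads_by_library.values() for r in reads]
    bg_cov = {
        key: np.array([continuous_coverage(b, pooled, mode=mode) for b in regions])
        for key, regions in background_regions.items()
    }

    covs = []
    pvals = []
    folds = []
    for region, cls in zip(pri_regions, locus_classes):
        values = np.array(
            [
                continuous_coverage(region, reads, mode=mode)
                for reads in reads_by_library.values()
            ]
        )
        bg = bg_cov[cls]
        bg_mean = bg.mean()
        fold = float(values.mean() / bg_mean) if bg_mean > 0 else (
            float("inf") if values.mean() > 0 else 1.0
        )
        stat = ks_2samp(values, bg, alternative="two-sided")
        covs.append(values)
        folds.append(fold)
        pvals.append(stat.pvalue)

    p_adj = multipletests(pvals, method="fdr_bh")[1] if pvals else np.array([])
    calls = []
    for region, values, fold, pa in zip(pri_regions, covs, folds, p_adj):
        present = fold >= fold_min and pa < alpha
        calls.append(
            CoverageCall(
                pri_mirna_region=region,
                coverages=tuple(float(v) for v in values),
                fold_enrichment=fold,
                p_adj=float(pa),
                present=bool(present),
            )
        )
    precision = (
        sum(c.present for c in calls) / len(calls) if calls else float("nan")
    )
    return calls, precision


def sample_regions_from_space(
    space: Sequence[GenomicInterval],
    n: int,
    size: int,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """Uniformly sample ``n`` fixed-size regions from a set of intervals
    (used to build the intergenic / intronic coverage backgrounds)."""
    eligible = [iv for iv in space if len(iv) >= size]
    if not eligible:
        raise DataError("no interval large enough to sample from")
    weights = np.array([len(iv) - size + 1 for iv in eligible], dtype=float)
    probs = weights / weights.sum()
    out = []
    for _ in range(n):
        iv = eligible[int(rng.choice(len(eligible), p=probs))]
        off = int(rng.integers(0, len(iv) - size + 1))
        out.append(GenomicInterval(iv.chrom, iv.start + off, iv.start + off + size, iv.strand))
    return out
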