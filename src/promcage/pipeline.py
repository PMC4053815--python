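"""End-to-end orchestration: normalize -> cluster -> filter -> features ->
prior -> EM -> posterior -> categorize -> dedup -> summarize."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator
from pyfaidx import Fasta

from promcage import annotate, evaluation, features as ft, model as mx
from promcage.io import (
    DataError,
    GenomicInterval,
    read_bed_intervals,
    read_cage_tags,
    read_conservation,
    read_gene_annotation,
    read_mirna_annotation,
    read_pssms,
    write_promoter_table,
)
from promcage.preprocess import (
    CandidateRegion,
    cluster_library,
    extract_candidates,
    quantile_normalize,
    sample_background,
)

logger = logging.getLogger("promcage")


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    cage: dict[str, str]  # library_id -> BED path
    cage_format: str = "bed6"
    gtf: str
    mirna_gff3: str
    genome_fasta: str
    conservation: str
    tata_pfm: str
    repeats: Optional[str] = None
    known_promoters: Optional[str] = None  # BED of labelled positive examples
    polii_peaks: Optional[str] = None
    rnaseq: dict[str, str] = Field(default_factory=dict)

    beta: Optional[list[float]] = None  # (b0..b4); fitted when absent
    prior_mode: str = "features"  # "features" | "flat"
    upstream_window: int = 50_000
    feature_window: int = 1_000
    host_tss_flank: int = 100
    background_n: int = 100
    coverage_background_n: int = 200
    seed: int = 0
    cutoff: float = 0.5
    reference_library: Optional[str] = None
    ridge: float = 0.5
    prior_clip: float = 0.02  # beliefs bounded to [clip, 1-clip]
    trap_lambda: float = ft.TRAP_LAMBDA
    trap_lnr0_slope: float = ft.TRAP_LNR0_SLOPE
    trap_lnr0_intercept: float = ft.TRAP_LNR0_INTERCEPT
    model: Optional[str] = None  # reuse a fitted model JSON, skipping EM
    outdir: str = "promcage_out"

    @field_validator("cage_format")
    @classmethod
    def _check_format(cls, v):
        if v not in ("bed6", "ctss"):
            raise ValueError("cage_format must be 'bed6' or 'ctss'")
        return v

    @field_validator("prior_mode")
    @classmethod
    def _check_prior(cls, v):
        if v not in ("features", "flat"):
            raise ValueError("prior_mode must be 'features' or 'flat'")
        return v

    @field_validator("cutoff")
    @classmethod
    def _check_cutoff(cls, v):
        if not 0 < v < 1:
            raise ValueError("cutoff must lie in (0, 1)")
        return v

    @field_validator("beta")
    @classmethod
    def _check_beta(cls, v):
        if v is not None and len(v) != 5:
            raise ValueError("beta must have 5 entries (b0..b4)")
        return v


@dataclass
class PipelineResult:
    calls: list  # PromoterCall records (all, with representative flags)
    candidates: list  # CandidateRegion records evaluated
    posteriors: np.ndarray  # per candidate
    priors: np.ndarray  # per candidate
    feature_vectors: list
    params: mx.MixtureParams
    beta: Optional[ft.PriorBeta]
    summary: pd.DataFrame
    counts: dict


def _best_proximity(
    tss: int, strand: str, mirnas, window: int
) -> float:
    """Best proximity of a position to any downstream precursor.

    0 when no precursor lies within the window downstream on a compatible
    strand (strand "." matches either).
    """
    best = 0.0
    for m in mirnas:
        if strand != "." and m.precursor.strand != strand:
            continue
        p5 = m.precursor.five_prime()
        d = (p5 - tss) if m.precursor.strand != "-" else (tss - p5)
        if 0 <= d <= window:
            best = max(best, (window - d) / window)
    return best


def _compute_features(
    window: GenomicInterval,
    tss: int,
    strand: str,
    fasta: Fasta,
    track,
    tata_pssm,
    mirnas,
    config: RunConfig,
) -> ft.FeatureVector:
    seq = str(fasta[window.chrom][window.start : window.end]).upper()
    ln_r0 = config.trap_lnr0_slope * tata_pssm.width + config.trap_lnr0_intercept
    return ft.FeatureVector(
        cpg=ft.cpg_score(seq),
        cons=min(1.0, max(0.0, track.mean(window))),
        tata=ft.trap_affinity(seq, tata_pssm, lam=config.trap_lambda, ln_r0=ln_r0),
        proximity=_best_proximity(tss, strand, mirnas, config.upstream_window),
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full promoter-recognition pipeline."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    counts: dict[str, int] = {}

    # -- inputs ------------------------------------------------------------
    libraries = {
        lib: read_cage_tags(path, lib, fmt=config.cage_format)
        for lib, path in sorted(config.cage.items())
    }
    counts["tags_in"] = sum(len(v) for v in libraries.values())
    genes = read_gene_annotation(config.gtf)
    mirnas = read_mirna_annotation(config.mirna_gff3, genes)
    fasta = Fasta(config.genome_fasta)
    chrom_sizes = {name: len(fasta[name]) for name in fasta.keys()}
    track = read_conservation(config.conservation)
    tata_pssm = read_pssms(config.tata_pfm)[0]
    repeats = read_bed_intervals(config.repeats) if config.repeats else []

    # -- normalize and cluster --------------------------------------------
    normalized = quantile_normalize(libraries, reference_id=config.reference_library)
    all_norm_tags = [t for tags in normalized.values() for t in tags]
    clusters = [c for lib in sorted(normalized) for c in cluster_library(normalized[lib])]
    counts["clusters"] = len(clusters)

    # -- candidates and background ----------------------------------------
    candidates = extract_candidates(
        clusters,
        mirnas,
        genes,
        chrom_sizes,
        window=config.upstream_window,
        feature_window=config.feature_window,
        host_tss_flank=config.host_tss_flank,
    )
    counts["candidates"] = len(candidates)
    background = sample_background(
        chrom_sizes,
        genes,
        repeats,
        config.background_n,
        rng,
        normalized_tags=all_norm_tags,
        region_size=config.feature_window,
    )
    counts["background"] = len(background)
    logger.info("pipeline counts: %s", counts)

    # -- features ----------------------------------------------------------
    def region_features(region: CandidateRegion) -> ft.FeatureVector:
        return _compute_features(
            region.feature_window,
            region.representative_tss,
            region.cluster.interval.strand,
            fasta,
            track,
            tata_pssm,
            mirnas,
            config,
        )

    cand_fvs = [region_features(r) for r in candidates]
    bg_fvs = [region_features(r) for r in background]

    # -- prior coefficients -------------------------------------------------
    beta: Optional[ft.PriorBeta] = None
    if config.prior_mode == "features":
        if config.beta is not None:
            beta = ft.PriorBeta(*config.beta)
        else:
            if not config.known_promoters:
                raise DataError(
                    "prior_mode='features' needs either beta or known_promoters"
                )
            examples = []
            for iv in read_bed_intervals(config.known_promoters):
                tss = (iv.start + iv.end) // 2
                fv = _compute_features(
                    iv, tss, iv.strand, fasta, track, tata_pssm, mirnas, config
                )
                examples.append((fv, "prom"))
            examples.extend((fv, "bg") for fv in bg_fvs)
            beta, _se = ft.fit_beta(examples, ridge=config.ridge)

    if beta is not None:
        # beliefs are bounded away from certainty so the tag-count evidence
        # can always override the sequence prior
        cand_prior = np.clip(
            [ft.prior_probability(fv, beta).p_prom for fv in cand_fvs],
            config.prior_clip,
            1.0 - config.prior_clip,
        )
    else:
        cand_prior = np.full(len(candidates), 0.5)

    # -- mixture -------------------------------------------------------------
    x_cand = np.array([r.cluster.x for r in candidates])
    x_bg = np.array([r.cluster.x for r in background])
    x_all = np.concatenate([x_cand, x_bg])
    fixed = np.concatenate(
        [np.zeros(len(candidates), bool), np.ones(len(background), bool)]
    )
    # counts-only mode: the standard mixture with a global EM-updated mixing
    # proportion; belief mode: fixed per-example priors
    flat = config.prior_mode == "flat"
    prior_all = (
        None if flat else np.concatenate([cand_prior, np.zeros(len(background))])
    )

    if config.model:
        est = mx.InverseGaussianBeliefMixture.from_json(config.model)
        est.cutoff = config.cutoff
    else:
        est = mx.InverseGaussianBeliefMixture(
            cutoff=config.cutoff, update_mixing=flat
        ).fit(x_all, prior=prior_all, fixed_background=fixed)
        est.to_json(
            outdir / "model.json",
            extra={
                "beta": list(beta.as_array()) if beta is not None else None,
                "seed": config.seed,
            },
        )

    posteriors = est.predict_proba(x_cand, prior=None if flat else cand_prior)
    if flat and est.mixing_ is not None:
        cand_prior = np.full(len(candidates), est.mixing_[1])
    counts["promoters_called"] = int((posteriors > config.cutoff).sum())

    # -- catalogue -----------------------------------------------------------
    mirna_map = {m.mirna_id: m for m in mirnas}
    gene_map = {g.gene_id: g for g in genes}
    lib_ids = sorted(libraries)
    calls = []
    call_seqs = []
    for region, fv, pri, post in zip(candidates, cand_fvs, cand_prior, posteriors):
        if post <= config.cutoff:
            continue
        iv = region.cluster.interval
        expressed = frozenset(
            lib
            for lib in lib_ids
            for t in normalized[lib]
            if t.interval.overlaps(iv)
        )
        calls.append(
            annotate.PromoterCall(
                region=region,
                features=fv,
                prior=ft.PriorPair(float(pri)),
                posterior=mx.PosteriorResult(float(post), "promoter"),
                category=annotate.assign_category(
                    region, mirna_map, gene_map, config.host_tss_flank
                ),
                libraries_expressed=expressed or frozenset({region.cluster.library_id}),
            )
        )
        w = region.feature_window
        call_seqs.append(str(fasta[w.chrom][w.start : w.end]).upper())

    calls = annotate.deduplicate(calls, call_seqs)
    calls = annotate.apply_tissue_specificity(calls, n_libraries=len(lib_ids))
    counts["representatives"] = sum(c.representative for c in calls)

    summary = annotate.summarize(calls, mirnas)
    write_promoter_table(calls, outdir / "catalogue.tsv")
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    (outdir / "counts.json").write_text(json.dumps(counts, indent=2))

    return PipelineResult(
        calls=calls,
        candidates=candidates,
        posteriors=posteriors,
        priors=cand_prior,
        feature_vectors=cand_fvs,
        params=est.params_,
        beta=beta,
        summary=summary,
        counts=counts,
    )


def run_eval(
    config: RunConfig,
    result: PipelineResult,
    cutoffs=None,
):
    """PolII ROC/PR table and RNA-seq presence report for a finished run."""
    if not config.polii_peaks and not config.rnaseq:
        raise DataError("evaluation needs PolII peaks and/or RNA-seq reads")
    outdir = Path(config.outdir)
    report: dict = {}

    if config.polii_peaks:
        peaks = read_bed_intervals(config.polii_peaks)
        regions = [r.feature_window for r in result.candidates]
        if cutoffs is None:
            cutoffs = [round(c, 2) for c in np.linspace(0.05, 0.95, 19)]
        roc = evaluation.roc_pr_curves(regions, result.posteriors, peaks, cutoffs)
        roc.to_csv(outdir / "polii_roc.tsv", sep="\t", index=False)
        cc = evaluation.polii_confusion(
            regions, result.posteriors, peaks, config.cutoff
        )
        report["polii"] = {
            "roc": roc,
            "confusion": cc,
            "precision": cc.precision,
            "recall": cc.recall,
        }

    if config.rnaseq:
        genes = read_gene_annotation(config.gtf)
        mirnas = {
            m.mirna_id: m for m in read_mirna_annotation(config.mirna_gff3, genes)
        }
        fasta = Fasta(config.genome_fasta)
        chrom_sizes = {name: len(fasta[name]) for name in fasta.keys()}
        reads_by_library = {
            lib: read_bed_intervals(path) for lib, path in sorted(config.rnaseq.items())
        }
        pri_regions, classes = [], []
        for c in result.calls:
            if not c.representative:
                continue
            m = mirnas.get(c.region.assigned_mirnas[0])
            if m is None or not m.matures:
                continue
            try:
                region = evaluation.pri_mirna_region(
                    c.region.representative_tss, m.matures[0]
                )
            except DataError:
                continue
            pri_regions.append(region)
            classes.append(m.locus_class)

        rng = np.random.default_rng(config.seed + 1)
        gene_ivs = sorted(
            (g.interval for g in genes), key=lambda iv: (iv.chrom, iv.start)
        )
        intergenic_space = []
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in gene_ivs:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, size in sorted(chrom_sizes.items()):
            prev = 0
            for iv in by_chrom.get(chrom, []) + [GenomicInterval(chrom, size, size + 1)]:
                if iv.start > prev:
                    intergenic_space.append(GenomicInterval(chrom, prev, iv.start))
                prev = max(prev, iv.end)
        intron_space = [i for g in genes for i in g.introns()]
        backgrounds = {}
        if "intergenic" in classes:
            backgrounds["intergenic"] = evaluation.sample_regions_from_space(
                intergenic_space, config.coverage_background_n, 2_000, rng
            )
        if "intragenic" in classes:
            backgrounds["intragenic"] = evaluation.sample_regions_from_space(
                intron_space, config.coverage_background_n, 2_000, rng
            )
        coverage_calls, precision = evaluation.presence_calls(
            pri_regions, classes, reads_by_library, backgrounds
        )
        pd.DataFrame(
            [
                {
                    "chrom": c.pri_mirna_region.chrom,
                    "start": c.pri_mirna_region.start,
                    "end": c.pri_mirna_region.end,
                    "fold_enrichment": c.fold_enrichment,
                    "p_adj": c.p_adj,
                    "present": c.present,
                }
                for c in coverage_calls
            ]
        ).to_csv(outdir / "rnaseq_presence.tsv", sep="\t", index=False)
        report["rnaseq"] = {"calls": coverage_calls, "precision": precision}

    return report
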