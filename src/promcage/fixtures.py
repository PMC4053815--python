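"""Self-contained toy dataset with planted miRNA promoters.

The generator emits every input the pipeline reads — genome FASTA, Ensembl-
style GTF, miRBase-style GFF3, per-library CAGE BED files, a conservation
bedGraph, a repeat mask, a synthetic TATA-box PFM, PolII peaks, RNA-seq read
BEDs — plus a truth table of the planted promoters, so every stage is
testable without downloads.

Default study conditions: 2 chromosomes x 1 Mb (chromosome 2 entirely on
the minus strand, to exercise strand arithmetic), 10 protein-coding genes,
20 miRNAs (10 intergenic, 10 intronic/intragenic), 4 CAGE libraries and 30
planted promoters. 24 promoters are broadly expressed with per-library
cluster tag totals ~ IG(mu, lambda=30), mu cycling through a log-spread
intensity ladder (20, 40, 80, 160) because real promoter expression spans
orders of magnitude; 6 intronic promoters are weak and library-specific
(~ IG(mu=3.5, lambda=150), active in a single library), mimicking
tissue-specific intronic promoters whose handful of tags sits above
single-tag noise but below the counts-only decision boundary, so only the
sequence-feature prior can rescue them. Background noise tags have counts
~ IG(mu=1.2, lambda=4) rounded to integers (mostly single tags, light
tail), the stochastic background transcription regime of CAGE data.

Sequence signal: intergenic and host-gene promoters get a CpG-island-like
window (GC ~ 0.7, injected CG dinucleotides); intronic promoters get a
TATAAA box 30 bp upstream of the TSS; all planted promoters get an elevated
conservation plateau. All randomness flows from one seed through named
substreams, so regenerating one file never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import invgauss

from promcage.io import DataError, GenomicInterval

_BLOCK = 100_000
_TAG_LEN = 20


def _ig_rvs(mu: float, lam: float, size, rng: np.random.Generator) -> np.ndarray:
    # scipy's invgauss is parameterized as invgauss(mu/lam, scale=lam)
    return invgauss.rvs(mu / lam, scale=lam, size=size, random_state=rng)


@dataclass(frozen=True)
class PlantedPromoter:
    promoter_id: str
    chrom: str
    tss: int
    strand: str
    category: str  # intergenic | host_gene | intronic
    mirna_id: str
    mu_tag: float
    lambda_tag: float
    active_libraries: tuple[str, ...]
    known_example: bool = False


@dataclass
class FixtureSpec:
    """Parameters of the synthetic dataset (defaults = study conditions)."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_libraries: int = 4
    # broadly expressed promoters cycle through a log-spread intensity
    # ladder (real promoter expression spans orders of magnitude)
    strong_mus: tuple[float, ...] = (20.0, 40.0, 80.0, 160.0)
    strong_lambda: float = 30.0
    weak_mu: float = 3.5
    weak_lambda: float = 150.0
    noise_mu: float = 1.2
    noise_lambda: float = 4.0
    noise_tags_per_chrom: int = 120  # per library
    promoter_gc: float = 0.7
    cpg_token_rate: float = 0.3
    conservation_high: tuple[float, float] = (0.75, 0.95)
    conservation_low: tuple[float, float] = (0.0, 0.15)
    rnaseq_libraries: int = 4

    def library_ids(self) -> list[str]:
        return [f"lib{i + 1}" for i in range(self.n_libraries)]

    def chrom_sizes(self) -> dict[str, int]:
        return {
            f"chr{i + 1}": self.chrom_length for i in range(self.n_chromosomes)
        }


# ---------------------------------------------------------------------------
# Layout


def _layout(spec: FixtureSpec):
    """Deterministic placement of genes, miRNAs and planted promoters.

    Each chromosome alternates 100 kb gene blocks and intergenic-miRNA
    blocks. Gene blocks hold a 40 kb four-exon gene with a miRNA in its
    second intron (one intronic promoter, and for some genes a host-TSS
    promoter). Intergenic blocks hold a miRNA with one (sometimes two)
    upstream promoters at varying distances.
    """
    if spec.chrom_length < 10 * _BLOCK:
        raise DataError("chromosome too short for the fixture layout")
    genes, mirnas, promoters = [], [], []
    strong_counter = [0]

    def next_strong_mu() -> float:
        mu = spec.strong_mus[strong_counter[0] % len(spec.strong_mus)]
        strong_counter[0] += 1
        return mu

    inter_distances = [500, 3_000, 8_000, 15_000, 30_000]
    weak_slots = {("chr2", i) for i in (0, 2, 4, 6, 8)} | {("chr1", 8)}
    lib_ids = spec.library_ids()

    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        strand = "+" if ci % 2 == 0 else "-"
        for bi in range(10):
            b = bi * _BLOCK
            if bi % 2 == 0:  # gene block
                gid = f"GENE_{chrom}_{bi}"
                gene_iv = GenomicInterval(chrom, b + 20_000, b + 60_000, strand)
                exon_offsets = [
                    (20_000, 20_500),
                    (32_000, 32_500),
                    (45_000, 45_500),
                    (59_500, 60_000),
                ]
                exons = [
                    GenomicInterval(chrom, b + s, b + e, strand)
                    for s, e in exon_offsets
                ]
                mid = f"mir-{chrom}-{bi}"
                prec = GenomicInterval(chrom, b + 40_000, b + 40_080, strand)
                mature = GenomicInterval(chrom, b + 40_010, b + 40_032, strand)
                genes.append((gid, gene_iv, exons))
                mirnas.append((mid, prec, mature, "intragenic", gid))

                # intronic promoter in intron 2, a few kb upstream of the miRNA
                tss = b + 36_000 if strand == "+" else b + 44_000
                weak = (chrom, bi) in weak_slots
                active = (
                    (lib_ids[(ci * 5 + bi // 2) % len(lib_ids)],)
                    if weak
                    else tuple(lib_ids)
                )
                promoters.append(
                    PlantedPromoter(
                        promoter_id=f"p_intronic_{chrom}_{bi}",
                        chrom=chrom,
                        tss=tss,
                        strand=strand,
                        category="intronic",
                        mirna_id=mid,
                        mu_tag=spec.weak_mu if weak else next_strong_mu(),
                        lambda_tag=spec.weak_lambda if weak else spec.strong_lambda,
                        active_libraries=active,
                    )
                )
                # host-gene promoter for the first three gene blocks
                if bi in (0, 2, 4):
                    host_tss = gene_iv.five_prime()
                    promoters.append(
                        PlantedPromoter(
                            promoter_id=f"p_host_{chrom}_{bi}",
                            chrom=chrom,
                            tss=host_tss,
                            strand=strand,
                            category="host_gene",
                            mirna_id=mid,
                            mu_tag=next_strong_mu(),
                            lambda_tag=spec.strong_lambda,
                            active_libraries=tuple(lib_ids),
                        )
                    )
            else:  # intergenic block
                mid = f"mir-{chrom}-{bi}"
                prec = GenomicInterval(chrom, b + 70_000, b + 70_080, strand)
                mature = GenomicInterval(chrom, b + 70_010, b + 70_032, strand)
                mirnas.append((mid, prec, mature, "intergenic", None))
                # minus-strand upstream runs toward larger coordinates, so
                # reverse the distance schedule to stay inside the chromosome
                di = (bi // 2) % len(inter_distances)
                if strand == "-":
                    di = len(inter_distances) - 1 - di
                d = inter_distances[di]
                p5 = prec.five_prime()
                tss = p5 - d if strand == "+" else p5 + d
                promoters.append(
                    PlantedPromoter(
                        promoter_id=f"p_intergenic_{chrom}_{bi}",
                        chrom=chrom,
                        tss=tss,
                        strand=strand,
                        category="intergenic",
                        mirna_id=mid,
                        mu_tag=next_strong_mu(),
                        lambda_tag=spec.strong_lambda,
                        active_libraries=tuple(lib_ids),
                    )
                )
                # alternative TSS for blocks 1 and 3
                if bi in (1, 3):
                    tss2 = p5 - (d + 10_000) if strand == "+" else p5 + d + 10_000
                    promoters.append(
                        PlantedPromoter(
                            promoter_id=f"p_intergenic_alt_{chrom}_{bi}",
                            chrom=chrom,
                            tss=tss2,
                            strand=strand,
                            category="intergenic",
                            mirna_id=mid,
                            mu_tag=next_strong_mu(),
                            lambda_tag=spec.strong_lambda,
                            active_libraries=tuple(lib_ids),
                        )
                    )

    # mark a few promoters as literature-known examples for fitting the prior
    known = [
        "p_intergenic_chr1_1",
        "p_intergenic_chr1_5",
        "p_intergenic_chr2_3",
        "p_host_chr1_0",
        "p_host_chr2_2",
        "p_intronic_chr1_0",
        "p_intronic_chr1_2",
        "p_intronic_chr2_0",  # weak, TATA-type
        "p_intronic_chr1_8",  # weak, TATA-type
        "p_intergenic_chr2_7",
    ]
    promoters = [
        PlantedPromoter(**{**p.__dict__, "known_example": p.promoter_id in known})
        for p in promoters
    ]
    return genes, mirnas, promoters


# ---------------------------------------------------------------------------
# Sequence generation


def _random_genome(spec: FixtureSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return {
        chrom: rng.choice(bases, size=size)
        for chrom, size in spec.chrom_sizes().items()
    }


def _cpg_island(length: int, gc: float, token_rate: float, rng: np.random.Generator) -> bytes:
    """GC-rich sequence with injected CG dinucleotides (obs/exp > 1)."""
    out = bytearray()
    single = np.frombuffer(b"ACGT", dtype="S1")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    while len(out) < length:
        if rng.random() < token_rate:
            out += b"CG"
        else:
            out += rng.choice(single, p=p).tobytes()
    return bytes(out[:length])


def _apply_promoter_sequence(
    genome: dict[str, np.ndarray], promoters, spec: FixtureSpec, rng: np.random.Generator
) -> None:
    for p in promoters:
        arr = genome[p.chrom]
        start = max(0, p.tss - 500)
        end = min(len(arr), p.tss + 500)
        if p.category in ("intergenic", "host_gene"):
            island = _cpg_island(end - start, spec.promoter_gc, spec.cpg_token_rate, rng)
            arr[start:end] = np.frombuffer(island, dtype="S1")
        else:  # intronic: TATA box 30 bp upstream of the TSS
            box_at = p.tss - 30 if p.strand == "+" else p.tss + 24
            box_at = int(np.clip(box_at, 0, len(arr) - 6))
            arr[box_at : box_at + 6] = np.frombuffer(b"TATAAA", dtype="S1")


# ---------------------------------------------------------------------------
# Writers


def _write_fasta(genome: dict[str, np.ndarray], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom].tobytes().decode()
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def _write_gtf(genes, path: Path) -> None:
    with open(path, "w") as fh:
        for gid, iv, exons in genes:
            attrs = f'gene_id "{gid}"; gene_biotype "protein_coding";'
            fh.write(
                f"{iv.chrom}\tfixture\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            tid = gid + "_T1"
            tattrs = f'gene_id "{gid}"; transcript_id "{tid}";'
            fh.write(
                f"{iv.chrom}\tfixture\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{tattrs}\n"
            )
            for ex in exons:
                fh.write(
                    f"{ex.chrom}\tfixture\texon\t{ex.start + 1}\t{ex.end}\t.\t{ex.strand}\t.\t{tattrs}\n"
                )


def _write_gff3(mirnas, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, (mid, prec, mature, _cls, _host) in enumerate(mirnas):
            acc = f"MI{i:07d}"
            fh.write(
                f"{prec.chrom}\t.\tmiRNA_primary_transcript\t{prec.start + 1}\t{prec.end}"
                f"\t.\t{prec.strand}\t.\tID={acc};Name={mid}\n"
            )
            fh.write(
                f"{mature.chrom}\t.\tmiRNA\t{mature.start + 1}\t{mature.end}"
                f"\t.\t{mature.strand}\t.\tID=MIMAT{i:07d};Name={mid}-5p;Derives_from={acc}\n"
            )


def _tag_lines(chrom: str, tss: int, strand: str, count: int, name: str) -> list[str]:
    """One or two overlapping tags whose 5' ends sit at the TSS."""
    if strand == "-":
        iv1 = (tss + 1 - _TAG_LEN, tss + 1)
        iv2 = (tss - 4 - _TAG_LEN, tss - 4)
    else:
        iv1 = (tss, tss + _TAG_LEN)
        iv2 = (tss + 5, tss + 5 + _TAG_LEN)
    big = count - count // 3
    rest = count - big
    lines = [f"{chrom}\t{iv1[0]}\t{iv1[1]}\t{name}\t{big}\t{strand}"]
    if rest >= 1:
        lines.append(f"{chrom}\t{iv2[0]}\t{iv2[1]}\t{name}_b\t{rest}\t{strand}")
    return lines


def _write_cage(spec: FixtureSpec, promoters, outdir: Path, rng: np.random.Generator) -> dict[str, Path]:
    paths = {}
    sizes = spec.chrom_sizes()
    for lib in spec.library_ids():
        lines = []
        for p in promoters:
            if lib not in p.active_libraries:
                continue
            total = max(1, int(round(_ig_rvs(p.mu_tag, p.lambda_tag, None, rng))))
            lines += _tag_lines(p.chrom, p.tss, p.strand, total, p.promoter_id)
        for chrom, size in sorted(sizes.items()):
            strand = "+" if (int(chrom.removeprefix("chr")) - 1) % 2 == 0 else "-"
            n = spec.noise_tags_per_chrom
            pos = rng.integers(_TAG_LEN, size - _TAG_LEN, size=n)
            counts = np.maximum(
                1, np.round(_ig_rvs(spec.noise_mu, spec.noise_lambda, n, rng))
            ).astype(int)
            for j in range(n):
                s = int(pos[j])
                lines.append(f"{chrom}\t{s}\t{s + _TAG_LEN}\tnoise_{j}\t{counts[j]}\t{strand}")
        path = outdir / f"cage_{lib}.bed"
        path.write_text("\n".join(lines) + "\n")
        paths[lib] = path
    return paths


def _write_conservation(
    spec: FixtureSpec, promoters, path: Path, rng: np.random.Generator, step: int = 200
) -> None:
    lo0, lo1 = spec.conservation_low
    hi0, hi1 = spec.conservation_high
    plateaus: dict[str, list[tuple[int, int]]] = {}
    for p in promoters:
        plateaus.setdefault(p.chrom, []).append((p.tss - 250, p.tss + 250))
    with open(path, "w") as fh:
        for chrom, size in sorted(spec.chrom_sizes().items()):
            spans = plateaus.get(chrom, [])
            for s in range(0, size, step):
                e = min(s + step, size)
                mid = (s + e) // 2
                high = any(a <= mid < b for a, b in spans)
                v = rng.uniform(hi0, hi1) if high else rng.uniform(lo0, lo1)
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.4f}\n")


def _write_repeats(spec: FixtureSpec, path: Path) -> list[GenomicInterval]:
    # a fixed repeat patch per chromosome, in intergenic space
    repeats = [
        GenomicInterval(chrom, 95_000, 99_000)
        for chrom in sorted(spec.chrom_sizes())
    ]
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\trepeat\t0\t.\n")
    return repeats


_SYNTHETIC_TBP_COUNTS = np.array(
    # synthetic TATAAA-consensus matrix (TBP-like, NOT a JASPAR export)
    [
        [2, 95, 2, 90, 85, 80],  # A
        [3, 1, 3, 4, 5, 6],  # C
        [3, 2, 3, 3, 5, 8],  # G
        [92, 2, 92, 3, 5, 6],  # T
    ],
    dtype=float,
)


def _write_tata_pfm(path: Path) -> None:
    rows = ["A", "C", "G", "T"]
    with open(path, "w") as fh:
        fh.write(">SYN0001 synthetic_TBP\n")
        for r, row in zip(rows, _SYNTHETIC_TBP_COUNTS):
            fh.write(f"{r} [ " + " ".join(f"{int(v):3d}" for v in row) + " ]\n")


def _write_polii(promoters, path: Path) -> None:
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(
                f"{p.chrom}\t{max(0, p.tss - 400)}\t{p.tss + 400}\tpeak_{p.promoter_id}\t0\t.\n"
            )


def _write_rnaseq(spec: FixtureSpec, promoters, mirnas, outdir: Path) -> dict[str, Path]:
    from promcage.evaluation import pri_mirna_region

    mature_of = {mid: mature for mid, _prec, mature, _cls, _host in mirnas}
    paths = {}
    for li in range(spec.rnaseq_libraries):
        lib = f"rna{li + 1}"
        lines = []
        for p in promoters:
            region = pri_mirna_region(p.tss, mature_of[p.mirna_id])
            for s in range(region.start, region.end, 80):
                e = min(s + 100, region.end)
                lines.append(f"{p.chrom}\t{s}\t{e}\tread\t0\t{p.strand}")
        path = outdir / f"rnaseq_{lib}.bed"
        path.write_text("\n".join(lines) + "\n")
        paths[lib] = path
    return paths


# ---------------------------------------------------------------------------
# Entry points


def make_fixture(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Write the full fixture bundle; returns paths and the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, mirnas, promoters = _layout(spec)
    for p in promoters:
        prec5 = next(
            prec.five_prime() for mid, prec, *_ in mirnas if mid == p.mirna_id
        )
        d = (prec5 - p.tss) if p.strand == "+" else (p.tss - prec5)
        if not 0 <= d <= 50_000:
            raise DataError(f"planted promoter {p.promoter_id} outside the 50 kb window")

    rng_genome = np.random.default_rng([spec.seed, 11])
    rng_cage = np.random.default_rng([spec.seed, 23])
    rng_cons = np.random.default_rng([spec.seed, 37])

    genome = _random_genome(spec, rng_genome)
    _apply_promoter_sequence(genome, promoters, spec, rng_genome)
    _write_fasta(genome, outdir / "genome.fa")
    _write_gtf(genes, outdir / "genes.gtf")
    _write_gff3(mirnas, outdir / "mirna.gff3")
    cage_paths = _write_cage(spec, promoters, outdir, rng_cage)
    _write_conservation(spec, promoters, outdir / "conservation.bedGraph", rng_cons)
    _write_repeats(spec, outdir / "repeats.bed")
    _write_tata_pfm(outdir / "tata_pfm.jaspar")
    _write_polii(promoters, outdir / "polii_peaks.bed")
    rnaseq_paths = _write_rnaseq(spec, promoters, mirnas, outdir)

    truth = pd.DataFrame(
        [
            {
                "promoter_id": p.promoter_id,
                "chrom": p.chrom,
                "tss": p.tss,
                "strand": p.strand,
                "category": p.category,
                "mirna_id": p.mirna_id,
                "mu_tag": p.mu_tag,
                "active_libraries": ",".join(p.active_libraries),
                "known_example": p.known_example,
            }
            for p in promoters
        ]
    )
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "known_promoters.bed", "w") as fh:
        for p in promoters:
            if p.known_example:
                fh.write(
                    f"{p.chrom}\t{max(0, p.tss - 500)}\t{p.tss + 500}\t{p.promoter_id}\t0\t{p.strand}\n"
                )

    return {
        "outdir": outdir,
        "genome": outdir / "genome.fa",
        "gtf": outdir / "genes.gtf",
        "gff3": outdir / "mirna.gff3",
        "cage": cage_paths,
        "conservation": outdir / "conservation.bedGraph",
        "repeats": outdir / "repeats.bed",
        "tata_pfm": outdir / "tata_pfm.jaspar",
        "polii": outdir / "polii_peaks.bed",
        "rnaseq": rnaseq_paths,
        "known_promoters": outdir / "known_promoters.bed",
        "truth": truth,
    }


def match_calls_to_truth(
    calls, truth: pd.DataFrame, tolerance: int = 300
) -> dict:
    """Compare representative promoter calls with the planted truth table.

    A call recovers a planted promoter when its representative TSS lies
    within ``tolerance`` bp of the planted TSS on the same chromosome.
    Returns recall, false-discovery rate and the raw counts.
    """
    reps = [c for c in calls if getattr(c, "representative", True)]
    recovered: set[str] = set()
    false_calls = 0
    for c in reps:
        iv = c.region.cluster.interval
        tss = c.region.representative_tss
        hits = truth[
            (truth["chrom"] == iv.chrom)
            & ((truth["tss"] - tss).abs() <= tolerance)
        ]
        if len(hits):
            recovered.update(hits["promoter_id"])
        else:
            false_calls += 1
    n_truth = len(truth)
    n_calls = len(reps)
    return {
        "recall": len(recovered) / n_truth if n_truth else float("nan"),
        "fdr": false_calls / n_calls if n_calls else 0.0,
        "n_recovered": len(recovered),
        "n_planted": n_truth,
        "n_calls": n_calls,
        "n_false": false_calls,
    }


def make_em_sample(
    n: int,
    mu1: float,
    lam1: float,
    mu0: float,
    lam0: float,
    prior_gen,
    n_labeled_bg: int,
    rng: np.random.Generator,
):
    """Simulate mixture observations with known truth.

    ``prior_gen`` is a constant prior or a callable rng -> pi_1. Returns
    (x, prior, fixed_background, true_labels) arrays, where the extra
    ``n_labeled_bg`` observations carry fixed background labels.
    """
    if min(mu1, lam1, mu0, lam0) <= 0:
        raise ValueError("all IG parameters must be positive")
    priors = np.array(
        [prior_gen(rng) if callable(prior_gen) else float(prior_gen) for _ in range(n)]
    )
    labels = (rng.random(n) < priors).astype(int)
    x = np.where(
        labels == 1,
        _ig_rvs(mu1, lam1, n, rng),
        _ig_rvs(mu0, lam0, n, rng),
    )
    x_bg = _ig_rvs(mu0, lam0, n_labeled_bg, rng)
    x_all = np.concatenate([x, x_bg])
    prior_all = np.concatenate([priors, np.zeros(n_labeled_bg)])
    fixed = np.concatenate([np.zeros(n, bool), np.ones(n_labeled_bg, bool)])
    truth = np.concatenate([labels, np.zeros(n_labeled_bg, int)])
    return x_all, prior_all, fixed, truth
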