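"""Readers and writers for the genomic file formats the pipeline touches.

All internal coordinates are 0-based half-open on the forward strand
(`GenomicInterval`), the BED convention. GTF and GFF3 are 1-based inclusive
on disk; the conversion happens here, at the file boundary, and nowhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

VALID_STRANDS = ("+", "-", ".")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise DataError("empty chromosome name")
        if self.start < 0:
            raise DataError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise DataError(f"empty interval: [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise DataError(f"bad strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def five_prime(self) -> int:
        """0-based position of the 5' end on this interval's strand."""
        return self.end - 1 if self.strand == "-" else self.start


@dataclass(frozen=True)
class CageTag:
    """One mapped CAGE tag with its raw count in one library."""

    interval: GenomicInterval
    library_id: str
    count: float

    def __post_init__(self) -> None:
        if self.count < 1:
            raise DataError(f"raw tag count < 1: {self.count}")


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    @property
    def tss(self) -> int:
        return self.interval.five_prime()


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    transcripts: tuple[Transcript, ...]
    biotype: str = "protein_coding"

    def introns(self) -> list[GenomicInterval]:
        """Intron intervals of every transcript (union, per transcript)."""
        out = []
        for tx in self.transcripts:
            exons = sorted(tx.exons, key=lambda e: e.start)
            for a, b in zip(exons, exons[1:]):
                if b.start > a.end:
                    out.append(
                        GenomicInterval(
                            tx.interval.chrom, a.end, b.start, tx.interval.strand
                        )
                    )
        return out


@dataclass(frozen=True)
class MirnaRecord:
    mirna_id: str
    precursor: GenomicInterval
    matures: tuple[GenomicInterval, ...]
    locus_class: str  # "intergenic" | "intragenic"
    host_gene_id: str | None = None
    exonic: bool = False  # intragenic subclass: precursor overlaps a host exon

    def __post_init__(self) -> None:
        if self.locus_class not in ("intergenic", "intragenic"):
            raise DataError(f"bad locus_class: {self.locus_class}")
        if self.locus_class == "intragenic" and self.host_gene_id is None:
            raise DataError(f"intragenic miRNA {self.mirna_id} without host gene")


@dataclass(frozen=True)
class Pssm:
    """Position frequency matrix: per-position base counts, rows A,C,G,T."""

    matrix_id: str
    counts: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise DataError("PFM counts must be a 4 x w array (rows A,C,G,T)")
        if (counts < 0).any():
            raise DataError("negative PFM count")
        if (counts.sum(axis=0) <= 0).any():
            raise DataError("PFM column with no positive count")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[1]


# ---------------------------------------------------------------------------
# CAGE tags


def read_cage_tags(
    path: str | Path, library_id: str, fmt: str = "bed6"
) -> list[CageTag]:
    """Read one CAGE library.

    ``fmt="bed6"``: BED6 with the score column holding the tag count at that
    position. ``fmt="ctss"``: the FANTOM CTSS dialect
    (chrom, pos, strand, count), converted to 1 bp intervals.
    """
    if fmt not in ("bed6", "ctss"):
        raise ValueError(f"unknown CAGE format: {fmt}")
    tags: list[CageTag] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed6":
                    if len(fields) < 6:
                        raise DataError("expected >= 6 tab-separated columns")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    count = float(fields[4])
                    strand = fields[5]
                else:
                    if len(fields) < 4:
                        raise DataError("expected >= 4 tab-separated columns")
                    chrom, pos, strand = fields[0], int(fields[1]), fields[2]
                    start, end = pos, pos + 1
                    count = float(fields[3])
                if count < 1:
                    raise DataError(f"tag count < 1: {count}")
                interval = GenomicInterval(chrom, start, end, strand)
            except (DataError, ValueError) as exc:
                raise DataError(f"{path}, line {lineno}: {exc}") from exc
            tags.append(CageTag(interval, library_id, count))
    return tags


# ---------------------------------------------------------------------------
# GTF gene annotation

import gffutils  # noqa: E402


def _gff_interval(feature) -> GenomicInterval:
    # gffutils keeps file coordinates (1-based inclusive)
    return GenomicInterval(
        feature.seqid, feature.start - 1, feature.end, feature.strand or "."
    )


def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Read an Ensembl-dialect GTF into :class:`GeneModel` records.

    Only gene/transcript/exon features are used; other feature types are
    ignored. An exon extending outside its transcript span is clamped with a
    warning.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for tx in db.children(g, featuretype="transcript"):
            tx_iv = _gff_interval(tx)
            exons = []
            for ex in db.children(tx, featuretype="exon"):
                ex_iv = _gff_interval(ex)
                if ex_iv.start < tx_iv.start or ex_iv.end > tx_iv.end:
                    warnings.warn(
                        f"exon outside transcript {tx.id} clamped", stacklevel=2
                    )
                    ex_iv = GenomicInterval(
                        ex_iv.chrom,
                        max(ex_iv.start, tx_iv.start),
                        min(ex_iv.end, tx_iv.end),
                        ex_iv.strand,
                    )
                exons.append(ex_iv)
            transcripts.append(Transcript(tx.id, tx_iv, tuple(exons)))
        genes.append(
            GeneModel(
                g.id,
                _gff_interval(g),
                tuple(transcripts),
                biotype=g.attributes.get("gene_biotype", ["protein_coding"])[0],
            )
        )
    if not genes:
        warnings.warn(f"{path}: no gene features found", stacklevel=2)
    return genes


# ---------------------------------------------------------------------------
# miRBase GFF3


def read_mirna_annotation(
    path: str | Path, genes: Sequence[GeneModel]
) -> list[MirnaRecord]:
    """Read a miRBase-dialect GFF3 and classify each precursor.

    A precursor is *intragenic* iff it overlaps a gene on the same strand
    (the overlapping gene becomes the host); otherwise it is *intergenic*.
    A mature miRNA whose Derives_from points to no precursor is an error.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    precursors = {f.id: f for f in db.features_of_type("miRNA_primary_transcript")}
    matures_by_parent: dict[str, list[GenomicInterval]] = {k: [] for k in precursors}
    for m in db.features_of_type("miRNA"):
        parents = m.attributes.get("Derives_from", []) or m.attributes.get(
            "Parent", []
        )
        parent = next((p for p in parents if p in precursors), None)
        if parent is None:
            raise DataError(f"mature miRNA {m.id} has no annotated precursor")
        matures_by_parent[parent].append(_gff_interval(m))

    records = []
    for pid, f in precursors.items():
        prec = _gff_interval(f)
        host = None
        exonic = False
        for g in genes:
            if g.interval.overlaps(prec) and g.interval.strand == prec.strand:
                host = g
                exonic = any(
                    ex.overlaps(prec) for tx in g.transcripts for ex in tx.exons
                )
                break
        name = f.attributes.get("Name", [pid])[0]
        records.append(
            MirnaRecord(
                mirna_id=name,
                precursor=prec,
                matures=tuple(matures_by_parent[pid]),
                locus_class="intragenic" if host else "intergenic",
                host_gene_id=host.gene_id if host else None,
                exonic=exonic,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Conservation track


class ConservationTrack:
    """Per-base conservation scores held as sorted step intervals per chrom.

    Bases absent from the track are treated as unaligned and contribute 0
    to window means.
    """

    def __init__(self, steps: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # chrom -> (starts, ends, values), starts sorted, non-overlapping
        self._steps = dict(steps)

    def mean(self, window: GenomicInterval) -> float:
        """Arithmetic mean score over the window; missing bases count 0."""
        if len(window) == 0:
            raise DataError("empty conservation window")
        entry = self._steps.get(window.chrom)
        if entry is None:
            return 0.0
        starts, ends, values = entry
        lo = np.searchsorted(ends, window.start, side="right")
        hi = np.searchsorted(starts, window.end, side="left")
        if hi <= lo:
            return 0.0
        ov = np.minimum(ends[lo:hi], window.end) - np.maximum(
            starts[lo:hi], window.start
        )
        ov = np.clip(ov, 0, None)
        return float((ov * values[lo:hi]).sum() / len(window))


def read_conservation(path: str | Path) -> ConservationTrack:
    """Read a bedGraph or fixedStep WIG conservation track."""
    rows: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        chrom = None
        pos = step = span = None
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # WIG is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                continue
            fields = line.split()
            try:
                if len(fields) == 1:  # fixedStep value line
                    if chrom is None:
                        raise DataError("value line before fixedStep header")
                    value = float(fields[0])
                    rows.setdefault(chrom, []).append((pos, pos + span, value))
                    pos += step
                else:  # bedGraph
                    c, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(
                        fields[3]
                    )
                    if e <= s:
                        raise DataError(f"empty interval [{s}, {e})")
                    rows.setdefault(c, []).append((s, e, v))
            except (DataError, ValueError) as exc:
                raise DataError(f"{path}, line {lineno}: {exc}") from exc
    steps = {}
    for c, items in rows.items():
        items.sort()
        arr = np.asarray(items, dtype=float)
        steps[c] = (arr[:, 0].astype(int), arr[:, 1].astype(int), arr[:, 2])
    return ConservationTrack(steps)


# ---------------------------------------------------------------------------
# JASPAR PFMs

_BASE_ORDER = "ACGT"


def read_pssms(path: str | Path) -> list[Pssm]:
    """Read JASPAR-format position frequency matrices via Bio.motifs."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in _BASE_ORDER], dtype=float)
        out.append(Pssm(matrix_id=m.matrix_id or m.name or "PFM", counts=counts))
    return out


# ---------------------------------------------------------------------------
# Simple BED intervals (peaks, reads, repeats)


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file as plain intervals (strand used when present)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                strand = fields[5] if len(fields) >= 6 else "."
                out.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
                )
            except (DataError, ValueError, IndexError) as exc:
                raise DataError(f"{path}, line {lineno}: {exc}") from exc
    return out


def write_bed_intervals(
    intervals: Iterable[GenomicInterval], path: str | Path, names: Sequence[str] | None = None
) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Promoter catalogue output

PROMOTER_TABLE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "mirna_id",
    "category",
    "tag_count",
    "CpG",
    "cons",
    "TATA",
    "proximity",
    "prior",
    "posterior",
    "library_ids",
    "tissue_specific",
]


def write_promoter_table(calls: Sequence, path: str | Path) -> None:
    """Write the final promoter catalogue as TSV plus a companion BED6.

    ``calls`` are :class:`promcage.annotate.PromoterCall` records. The BED6
    file gets the same basename with a ``.bed`` suffix.
    """
    rows = []
    for call in calls:
        iv = call.region.cluster.interval
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "strand": iv.strand,
                "mirna_id": ",".join(call.region.assigned_mirnas),
                "category": call.category,
                "tag_count": call.region.cluster.x,
                "CpG": call.features.cpg,
                "cons": call.features.cons,
                "TATA": call.features.tata,
                "proximity": call.features.proximity,
                "prior": call.prior.p_prom,
                "posterior": call.posterior.p_prom,
                "library_ids": ",".join(sorted(call.libraries_expressed)),
                "tissue_specific": call.tissue_specific,
            }
        )
    df = pd.DataFrame(rows, columns=PROMOTER_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    bed_path = Path(path).with_suffix(".bed")
    write_bed_intervals(
        [c.region.cluster.interval for c in calls],
        bed_path,
        names=[",".join(c.region.assigned_mirnas) or "promoter" for c in calls],
    )
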