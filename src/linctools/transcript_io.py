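"""Readers/writers for the genomic text formats the pipeline touches.

Internal coordinates are always 0-based half-open; GTF/GFF3 (1-based
inclusive) and BED (0-based half-open) conventions are applied only at the
file boundary.  Strand is one of ``'+'``, ``'-'`` or ``'.'`` (unknown);
unknown strand is preserved, never coerced, because unstranded single-exon
intergenic assemblies are common and the ORF scanner downstream handles
them explicitly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO

STRANDS = ("+", "-", ".")

__all__ = [
    "TranscriptModel",
    "GeneLocus",
    "SequenceStore",
    "read_transcripts",
    "read_genes",
    "read_fasta",
    "read_class_code_table",
    "write_bed",
    "write_gtf",
    "write_fasta",
]


@dataclass
class TranscriptModel:
    """An assembled transcript: exon chain, strand and assembly class code.

    Exons are 0-based half-open genomic intervals, sorted by start and
    pairwise non-overlapping.  ``class_code`` is the single-character
    assembly-comparison code (``'u'`` marks fully intergenic transcripts).
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    class_code: str = ""
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(
                f"{self.transcript_id}: strand must be one of {STRANDS}, got {self.strand!r}"
            )
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript must have at least one exon")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if b <= a:
                raise ValueError(f"{self.transcript_id}: empty exon [{a},{b})")
        for (_, b0), (a1, _) in zip(self.exons, self.exons[1:]):
            if a1 < b0:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)


@dataclass
class GeneLocus:
    """A reference gene span used by the proximity (flanking-region) filter."""

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    biotype: str = "coding"  # {"coding", "other"}

    def __post_init__(self) -> None:
        a, b = self.span
        if b <= a:
            raise ValueError(f"{self.gene_id}: empty span [{a},{b})")


class SequenceStore(dict):
    """Mapping transcript_id -> spliced nucleotide sequence (DNA, uppercase)."""

    def lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.items()}


def _feature_from_line(line: str, lineno: int, path: str):
    if line.count("\t") != 8:
        raise ValueError(
            f"{path}: malformed record at line {lineno}: expected 9 tab-separated fields"
        )
    try:
        return gffutils.feature.feature_from_line(line)
    except Exception as exc:  # malformed line: report its position
        raise ValueError(f"{path}: malformed record at line {lineno}: {exc}") from exc


def read_transcripts(
    gtf_path: str | Path,
    class_codes: dict[str, str] | None = None,
) -> list[TranscriptModel]:
    """Read transcript models from a GTF of exon features.

    The assembly class code is taken from the ``class_code`` attribute of
    each exon record; a separate id -> code mapping (e.g. from
    :func:`read_class_code_table`) overrides / supplements it.
    """
    gtf_path = Path(gtf_path)
    exons: dict[str, dict] = {}
    order: list[str] = []
    with open(gtf_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = _feature_from_line(line, lineno, str(gtf_path))
            if feat.featuretype != "exon":
                continue
            attrs = feat.attributes
            if "transcript_id" not in attrs:
                raise ValueError(
                    f"{gtf_path}: exon without transcript_id at line {lineno}"
                )
            tid = attrs["transcript_id"][0]
            if tid not in exons:
                order.append(tid)
                exons[tid] = {
                    "chrom": feat.seqid,
                    "strand": feat.strand if feat.strand in ("+", "-") else ".",
                    "exons": [],
                    "gene_id": attrs["gene_id"][0] if "gene_id" in attrs else "",
                    "class_code": attrs["class_code"][0] if "class_code" in attrs else "",
                }
            # GTF is 1-based inclusive -> 0-based half-open
            exons[tid]["exons"].append((feat.start - 1, feat.end))
    models = []
    for tid in order:
        rec = exons[tid]
        code = rec["class_code"]
        if class_codes and tid in class_codes:
            code = class_codes[tid]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=rec["exons"],
                class_code=code,
                gene_id=rec["gene_id"],
            )
        )
    return models


def read_class_code_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV: transcript_id, class_code."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            out[row[0]] = row[1]
    return out


def read_genes(path: str | Path, coding_only: bool = False) -> list[GeneLocus]:
    """Read gene loci from GFF3 or GTF (``gene`` features).

    Biotype comes from a ``biotype``/``gene_biotype`` attribute; values of
    ``protein_coding`` or ``coding`` map to ``coding``, anything else to
    ``other``.  A missing attribute defaults to ``coding`` since the
    annotation consumed here is the coding-gene set.
    """
    path = Path(path)
    genes: list[GeneLocus] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = _feature_from_line(line, lineno, str(path))
            if feat.featuretype != "gene":
                continue
            attrs = feat.attributes
            if "gene_id" in attrs:
                gid = attrs["gene_id"][0]
            elif "ID" in attrs:
                gid = attrs["ID"][0]
            else:
                raise ValueError(f"{path}: gene without identifier at line {lineno}")
            raw_bt = ""
            for key in ("biotype", "gene_biotype"):
                if key in attrs:
                    raw_bt = attrs[key][0]
                    break
            biotype = "coding" if raw_bt in ("", "coding", "protein_coding") else "other"
            if coding_only and biotype != "coding":
                continue
            genes.append(
                GeneLocus(
                    gene_id=gid,
                    chrom=feat.seqid,
                    strand=feat.strand if feat.strand in ("+", "-") else ".",
                    span=(feat.start - 1, feat.end),
                    biotype=biotype,
                )
            )
    return genes


def read_fasta(path: str | Path) -> SequenceStore:
    """Load a FASTA into a :class:`SequenceStore`.

    Sequences are uppercased and RNA ``U`` is stored as ``T``.  The header
    token before the first whitespace is the transcript id.
    """
    store = SequenceStore()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if rec.id in store:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        if not seq:
            raise ValueError(f"{path}: empty sequence for {rec.id!r}")
        store[rec.id] = seq
    return store


def write_fasta(store: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for tid, seq in store.items():
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(transcripts: list[TranscriptModel], path: str | Path, source: str = "linctools") -> None:
    """Write transcripts as GTF exon records (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for t in transcripts:
            for (a, b) in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                if t.class_code:
                    attrs += f' class_code "{t.class_code}";'
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{a + 1}\t{b}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def write_bed(transcripts: list[TranscriptModel], path: str | Path) -> None:
    """Write BED12, one line per transcript (blockCount = exon count)."""
    with open(path, "w") as fh:
        for t in transcripts:
            start, end = t.span
            sizes = ",".join(str(b - a) for a, b in t.exons) + ","
            starts = ",".join(str(a - start) for a, _ in t.exons) + ","
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(start),
                        str(end),
                        t.transcript_id,
                        "0",
                        t.strand if t.strand in ("+", "-") else ".",
                        str(start),
                        str(start),
                        "0",
                        str(t.exon_count),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )
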