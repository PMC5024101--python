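"""Filter cascade that reduces an assembled transcriptome to putative lincRNAs.

The cascade keeps, in order: intergenic transcripts (assembly class code
``'u'``), spliced length > 200 nt, longest ORF <= 300 nt, no protein
similarity hit (BLASTX-style e-value table), no protein-domain hit
(hmmscan-style table), coding-potential score <= 0, and genomic distance
> 500 nt from any coding gene.  Every stage is logged in a
:class:`FilterLedger` whose counts satisfy input = removed + retained and
chain across stages.  Survivors are assigned consecutive ``Ca_linc_NNNN``
identifiers in genomic coordinate order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .transcript_io import GeneLocus, TranscriptModel

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_COMP = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "OrfResult",
    "EvidenceTable",
    "FilterLedger",
    "LedgerStage",
    "LincRNARecord",
    "DiscoveryConfig",
    "find_longest_orf",
    "extract_intergenic",
    "filter_length",
    "filter_orf",
    "filter_evidence",
    "filter_cpc",
    "filter_flanking",
    "run_discovery",
    "compute_features",
]


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------

@dataclass
class OrfResult:
    """Longest open reading frame of one transcript.

    ``orf_length_nt`` includes the stop codon; 0 means no ORF was found.
    ``frame`` is +1..+3 (sense) or -1..-3 (antisense); ``orf_interval`` is
    in sense transcript coordinates (0-based half-open).
    """

    transcript_id: str
    orf_length_nt: int
    frame: int | None = None
    orf_interval: tuple[int, int] | None = None


def _scan_frames(seq: str, include_open_ended: bool):
    """Yield (length, frame_offset, start) for every maximal ORF on one strand."""
    n = len(seq)
    for off in range(3):
        start = None
        for i in range(off, n - 2, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                # an ambiguous codon never matches the start or a stop codon
                continue
            if codon == "ATG" and start is None:
                start = i
            elif codon in STOP_CODONS and start is not None:
                yield (i + 3 - start, off, start)
                start = None
        if include_open_ended and start is not None:
            length = (n - start) // 3 * 3
            if length >= 3:
                yield (length, off, start)


def find_longest_orf(
    sequence: str,
    strand_mode: str = "sense_only",
    transcript_id: str = "",
    include_open_ended: bool = False,
) -> OrfResult:
    """Find the longest ATG..stop ORF over 3 (sense) or 6 (both) frames.

    An ORF runs from an ATG to the first in-frame stop codon and its length
    counts the stop codon.  Ties are broken in favour of the sense strand,
    then the 5'-most start.  ORFs lacking an in-frame stop are ignored
    unless ``include_open_ended`` is set.
    """
    if not sequence:
        raise ValueError(f"{transcript_id or 'sequence'}: empty sequence")
    if strand_mode not in ("sense_only", "both"):
        raise ValueError(f"strand_mode must be 'sense_only' or 'both', got {strand_mode!r}")
    seq = sequence.upper().replace("U", "T")
    candidates = []  # (length, strand_rank, start, frame, interval)
    for length, off, start in _scan_frames(seq, include_open_ended):
        candidates.append((length, 0, start, off + 1, (start, start + length)))
    if strand_mode == "both":
        rc = seq.translate(_COMP)[::-1]
        n = len(seq)
        for length, off, start in _scan_frames(rc, include_open_ended):
            interval = (n - (start + length), n - start)
            candidates.append((length, 1, start, -(off + 1), interval))
    if not candidates:
        return OrfResult(transcript_id, 0)
    length, _, _, frame, interval = min(
        candidates, key=lambda c: (-c[0], c[1], c[2])
    )
    return OrfResult(transcript_id, length, frame, interval)


# ---------------------------------------------------------------------------
# Evidence tables
# ---------------------------------------------------------------------------

@dataclass
class EvidenceTable:
    """Per-transcript external evidence: homology e-values and coding score.

    Missing protein/domain entries mean "no hit"; the coding-potential
    score is mandatory for every transcript reaching that stage.
    """

    protein_evalue: dict[str, float] = field(default_factory=dict)
    domain_evalue: dict[str, float] = field(default_factory=dict)
    cpc_score: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, table in (("protein", self.protein_evalue), ("domain", self.domain_evalue)):
            for tid, ev in table.items():
                if ev < 0:
                    raise ValueError(f"negative {name} e-value for {tid}: {ev}")

    @classmethod
    def from_files(
        cls,
        protein_path: str | Path | None = None,
        domain_path: str | Path | None = None,
        cpc_path: str | Path | None = None,
    ) -> "EvidenceTable":
        """Load two-column TSVs (transcript_id, value); best value kept on duplicates."""

        def _load(path, best):
            out: dict[str, float] = {}
            if path is None:
                return out
            df = pd.read_csv(path, sep="\t", header=None, comment="#",
                             names=["transcript_id", "value"])
            for tid, val in zip(df["transcript_id"], df["value"].astype(float)):
                tid = str(tid)
                out[tid] = best(out[tid], val) if tid in out else val
            return out

        return cls(
            protein_evalue=_load(protein_path, min),
            domain_evalue=_load(domain_path, min),
            cpc_score=_load(cpc_path, max),
        )


# ---------------------------------------------------------------------------
# Ledger
# ---------------------------------------------------------------------------

@dataclass
class LedgerStage:
    stage_name: str
    input_count: int
    removed_count: int
    retained_count: int
    removed: dict[str, str] = field(default_factory=dict)  # id -> reason

    def __post_init__(self) -> None:
        if self.input_count != self.removed_count + self.retained_count:
            raise ValueError(
                f"stage {self.stage_name}: {self.input_count} != "
                f"{self.removed_count} + {self.retained_count}"
            )


@dataclass
class FilterLedger:
    """Per-stage accounting of the discovery cascade.

    Invariants: each stage conserves counts (input = removed + retained)
    and stages chain (stage i+1 input = stage i retained).
    """

    stages: list[LedgerStage] = field(default_factory=list)

    def add_stage(self, name: str, input_ids: list[str], removed: dict[str, str]) -> list[str]:
        retained = [t for t in input_ids if t not in removed]
        self.stages.append(
            LedgerStage(name, len(input_ids), len(removed), len(retained), dict(removed))
        )
        self.validate()
        return retained

    @classmethod
    def from_counts(cls, initial: int, removals: list[tuple[str, int]]) -> "FilterLedger":
        """Build a counts-only ledger from a starting total and per-stage removals."""
        ledger = cls()
        current = initial
        for name, removed in removals:
            ledger.stages.append(LedgerStage(name, current, removed, current - removed))
            current -= removed
        return ledger

    def validate(self) -> None:
        for prev, cur in zip(self.stages, self.stages[1:]):
            if cur.input_count != prev.retained_count:
                raise ValueError(
                    f"ledger break: {cur.stage_name} input {cur.input_count} != "
                    f"{prev.stage_name} retained {prev.retained_count}"
                )

    @property
    def final_retained_count(self) -> int:
        return self.stages[-1].retained_count if self.stages else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.stage_name,
                    "input": s.input_count,
                    "removed": s.removed_count,
                    "retained": s.retained_count,
                }
                for s in self.stages
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filter stages
# ---------------------------------------------------------------------------

def extract_intergenic(transcripts: list[TranscriptModel]):
    """Split transcripts into intergenic (class code 'u') and the rest."""
    retained = [t for t in transcripts if t.class_code == "u"]
    removed = {t.transcript_id: f"class_code={t.class_code or '?'}"
               for t in transcripts if t.class_code != "u"}
    return retained, removed


def filter_length(transcripts: list[TranscriptModel], min_exclusive: int = 200):
    """Retain transcripts with spliced length strictly greater than the bound."""
    retained, removed = [], {}
    for t in transcripts:
        if t.spliced_length > min_exclusive:
            retained.append(t)
        else:
            removed[t.transcript_id] = f"length={t.spliced_length}<= {min_exclusive}"
    return retained, removed


def filter_orf(
    transcripts: list[TranscriptModel],
    orf_results: dict[str, OrfResult],
    max_orf: int = 300,
):
    """Retain transcripts whose longest ORF is <= max_orf nt."""
    retained, removed = [], {}
    for t in transcripts:
        if t.transcript_id not in orf_results:
            raise ValueError(f"no ORF result for {t.transcript_id}")
        orf = orf_results[t.transcript_id]
        if orf.orf_length_nt > max_orf:
            removed[t.transcript_id] = f"orf={orf.orf_length_nt}>{max_orf}"
        else:
            retained.append(t)
    return retained, removed


def filter_evidence(
    transcripts: list[TranscriptModel],
    evidence: EvidenceTable,
    evalue_cutoff: float = 1e-3,
):
    """Remove protein-similarity hits, then domain hits, sequentially.

    The two removed sets are disjoint by construction: a transcript failing
    the protein stage never reaches the domain stage.
    """
    removed_protein, survivors = {}, []
    for t in transcripts:
        ev = evidence.protein_evalue.get(t.transcript_id)
        if ev is not None and ev <= evalue_cutoff:
            removed_protein[t.transcript_id] = f"protein_hit_evalue={ev:g}"
        else:
            survivors.append(t)
    removed_domain, retained = {}, []
    for t in survivors:
        ev = evidence.domain_evalue.get(t.transcript_id)
        if ev is not None and ev <= evalue_cutoff:
            removed_domain[t.transcript_id] = f"domain_hit_evalue={ev:g}"
        else:
            retained.append(t)
    return retained, removed_protein, removed_domain


def filter_cpc(
    transcripts: list[TranscriptModel],
    evidence: EvidenceTable,
    coding_threshold: float = 0.0,
):
    """Retain transcripts with coding-potential score <= threshold (default 0)."""
    retained, removed = [], {}
    for t in transcripts:
        if t.transcript_id not in evidence.cpc_score:
            raise ValueError(f"missing coding-potential score for {t.transcript_id}")
        score = evidence.cpc_score[t.transcript_id]
        if score > coding_threshold:
            removed[t.transcript_id] = f"cpc_score={score:g}"
        else:
            retained.append(t)
    return retained, removed


def filter_flanking(
    transcripts: list[TranscriptModel],
    genes: list[GeneLocus],
    window: int = 500,
):
    """Remove transcripts within `window` nt of any coding gene (strand-agnostic).

    The gap is measured between the transcript genomic span and the gene
    span; overlap counts as gap 0 and the boundary is inclusive (gap ==
    window removes).
    """
    by_chrom: dict[str, list[GeneLocus]] = {}
    for g in genes:
        if g.biotype == "coding":
            by_chrom.setdefault(g.chrom, []).append(g)
    retained, removed = [], {}
    for t in transcripts:
        ts, te = t.span
        min_gap = None
        for g in by_chrom.get(t.chrom, []):
            gs, ge = g.span
            gap = max(gs - te, ts - ge, 0)
            if min_gap is None or gap < min_gap:
                min_gap = gap
            if min_gap == 0:
                break
        if min_gap is not None and min_gap <= window:
            removed[t.transcript_id] = f"gene_gap={min_gap}<= {window}"
        else:
            retained.append(t)
    return retained, removed


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryConfig:
    min_length: int = 200       # retain strictly greater (nt)
    max_orf: int = 300          # retain <= (nt, stop codon included)
    evalue_cutoff: float = 1e-3
    cpc_threshold: float = 0.0  # retain <=
    flank_window: int = 500     # remove <= (nt)
    linc_prefix: str = "Ca_linc"


@dataclass
class LincRNARecord:
    linc_id: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    length_nt: int
    exon_count: int
    gc_fraction: float


def _gc_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def run_discovery(
    transcripts: list[TranscriptModel],
    sequences: dict[str, str],
    evidence: EvidenceTable,
    genes: list[GeneLocus],
    config: DiscoveryConfig | None = None,
) -> tuple[list[LincRNARecord], FilterLedger]:
    """Run the full cascade and assign lincRNA identifiers to survivors.

    Stage order: class code 'u' -> length -> ORF -> protein similarity ->
    protein domain -> coding potential -> gene proximity.  Identifiers are
    assigned in (chromosome, start, transcript_id) order.
    """
    cfg = config or DiscoveryConfig()
    ledger = FilterLedger()
    ids = [t.transcript_id for t in transcripts]

    current, removed = extract_intergenic(transcripts)
    ledger.add_stage("class_code_u", ids, removed)

    current, removed = filter_length(current, cfg.min_length)
    ledger.add_stage("length_gt_200", [t.transcript_id for t in current] + list(removed), removed)

    orfs = {}
    for t in current:
        seq = sequences.get(t.transcript_id)
        if seq is None:
            raise ValueError(f"no sequence for {t.transcript_id}")
        mode = "sense_only" if t.strand in ("+", "-") else "both"
        orfs[t.transcript_id] = find_longest_orf(seq, mode, t.transcript_id)
    pre = [t.transcript_id for t in current]
    current, removed = filter_orf(current, orfs, cfg.max_orf)
    ledger.add_stage("orf_le_300", pre, removed)

    pre = [t.transcript_id for t in current]
    current, rem_protein, rem_domain = filter_evidence(current, evidence, cfg.evalue_cutoff)
    ledger.add_stage("protein_similarity", pre, rem_protein)
    ledger.add_stage("protein_domain", [t for t in pre if t not in rem_protein], rem_domain)

    pre = [t.transcript_id for t in current]
    current, removed = filter_cpc(current, evidence, cfg.cpc_threshold)
    ledger.add_stage("coding_potential", pre, removed)

    pre = [t.transcript_id for t in current]
    current, removed = filter_flanking(current, genes, cfg.flank_window)
    ledger.add_stage("gene_flanking", pre, removed)

    survivors = sorted(current, key=lambda t: (t.chrom, t.start, t.transcript_id))
    records = []
    for i, t in enumerate(survivors, start=1):
        seq = sequences[t.transcript_id]
        records.append(
            LincRNARecord(
                linc_id=f"{cfg.linc_prefix}_{i:04d}",
                transcript_id=t.transcript_id,
                chrom=t.chrom,
                start=t.start,
                end=t.end,
                strand=t.strand,
                length_nt=t.spliced_length,
                exon_count=t.exon_count,
                gc_fraction=_gc_fraction(seq),
            )
        )
    return records, ledger


def compute_features(
    records: list[LincRNARecord],
    sequences: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-lincRNA feature table plus a summary of the set's characteristics.

    The summary carries mean length, mean exon count and length, the
    single-exon fraction, per-chromosome counts, and the cumulative AU
    (= 1 - GC) frequency curve used to show AU richness.
    """
    df = pd.DataFrame(
        [
            {
                "linc_id": r.linc_id,
                "transcript_id": r.transcript_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "length_nt": r.length_nt,
                "exon_count": r.exon_count,
                "gc_fraction": r.gc_fraction,
                "au_fraction": 1.0 - r.gc_fraction,
            }
            for r in records
        ]
    )
    if df.empty:
        return df, {
            "n": 0, "mean_length": 0.0, "mean_exon_count": 0.0,
            "mean_exon_length": 0.0, "fraction_single_exon": 0.0,
            "per_chromosome": {}, "au_cumulative": ([], []),
        }
    au_sorted = sorted(df["au_fraction"])
    cumfreq = [(i + 1) / len(au_sorted) for i in range(len(au_sorted))]
    summary = {
        "n": int(len(df)),
        "mean_length": float(df["length_nt"].mean()),
        "mean_exon_count": float(df["exon_count"].mean()),
        "mean_exon_length": float((df["length_nt"] / df["exon_count"]).mean()),
        "fraction_single_exon": float((df["exon_count"] == 1).mean()),
        "per_chromosome": df.groupby("chrom").size().to_dict(),
        "au_cumulative": (au_sorted, cumfreq),
    }
    return df, summary
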