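"""Seeded synthetic fixtures with planted ground truth for every stage.

The generators emulate the shape of the study data — an assembled
transcriptome over a small genome with coding genes, an 11-tissue FPKM
matrix, a modular PPI/GO structure, and miRNAs with planted binding
sites — at desk scale.  Every entity is planted in a named category so
that recovery can be checked exactly against the returned manifest, and
all outputs are byte-identical for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_analysis import TISSUE_LABELS
from .lincrna_discovery import STOP_CODONS, find_longest_orf
from .mirna_interaction import DEFAULT_SCHEME, ScoringScheme, score_site
from .transcript_io import (
    GeneLocus,
    TranscriptModel,
    write_fasta,
    write_gtf,
)

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)
_COMP = str.maketrans("ACGT", "TGCA")

__all__ = [
    "SimulationConfig",
    "generate_discovery_fixture",
    "generate_expression_fixture",
    "generate_network_fixture",
    "generate_mirna_fixture",
    "generate_all",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic fixtures (desk-scale defaults).

    Category counts mirror the discovery cascade: each planted category is
    built to survive every stage before its own and to fail exactly its
    own.  ``noise_cv`` is the coefficient of variation of the lognormal
    multiplicative expression noise.
    """

    seed: int = 42
    # genome / discovery
    n_chromosomes: int = 2
    n_coding_genes: int = 40
    n_true_linc: int = 30
    n_short: int = 10
    n_long_orf: int = 10
    n_protein_hit: int = 6
    n_domain_hit: int = 2
    n_cpc_positive: int = 5
    n_flanking: int = 7
    n_non_u: int = 15
    # expression
    tissues: tuple = tuple(TISSUE_LABELS)
    n_specific_profiles: int = 10
    n_housekeeping: int = 8
    n_background_lincs: int = 6
    noise_cv: float = 0.2
    # network / GO
    n_go_modules: int = 3
    go_module_size: int = 12
    lincs_per_module: int = 2
    n_background_mrnas: int = 30
    coexpr_percentile: float = 5.0   # fixture-scale analogue of the 0.5% study cut
    # miRNA
    n_mirnas: int = 8
    planted_site_expectations: tuple = (0.0, 0.0, 0.5, 2.0, 3.0, 3.5)

    @property
    def n_linc_rows(self) -> int:
        return (self.n_specific_profiles + self.n_housekeeping
                + self.n_go_modules * self.lincs_per_module + self.n_background_lincs)

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if name in ("tissues", "planted_site_expectations"):
                continue
            if isinstance(value, (int, float)) and value < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.tissues) < 2:
            raise ValueError("need at least 2 tissues")


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, au: float = 0.70) -> str:
    p = np.array([au / 2, (1 - au) / 2, (1 - au) / 2, au / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _clean_noncoding_seq(rng, length: int, strand: str, max_orf: int = 300) -> str:
    """AU-rich random sequence whose longest ORF (as the pipeline will scan
    it for this strand) is <= max_orf."""
    mode = "sense_only" if strand in ("+", "-") else "both"
    for _ in range(400):
        seq = _random_seq(rng, length)
        if find_longest_orf(seq, mode).orf_length_nt <= max_orf:
            return seq
    raise RuntimeError(f"could not draw an ORF-free sequence of length {length}")


def _long_orf_seq(rng, total: int, orf_len: int, strand: str) -> str:
    """Sequence of given length whose longest ORF is exactly ``orf_len`` nt."""
    if orf_len % 3 or orf_len < 9 or orf_len > total:
        raise ValueError("orf_len must be a multiple of 3 fitting the sequence")
    mode = "sense_only" if strand in ("+", "-") else "both"
    n_mid = orf_len // 3 - 2
    for _ in range(400):
        left = int(rng.integers(0, total - orf_len + 1))
        orf = ("ATG"
               + "".join(rng.choice(_NONSTOP_CODONS, size=n_mid))
               + str(rng.choice(sorted(STOP_CODONS))))
        seq = _random_seq(rng, left) + orf + _random_seq(rng, total - orf_len - left)
        if find_longest_orf(seq, mode).orf_length_nt == orf_len:
            return seq
    raise RuntimeError("could not plant an exact-length ORF")


def _linc_length(rng) -> int:
    # 201 + Gamma(2, 207): strictly >200 with mean ~= 615 nt
    return min(1800, 201 + int(round(rng.gamma(2.0, 207.0))))


# ---------------------------------------------------------------------------
# discovery fixture
# ---------------------------------------------------------------------------

def _exon_chain(rng, chrom_start: int, spliced_len: int) -> list[tuple[int, int]]:
    """Split a spliced length into 1-3 exons (single-exon biased, mean ~1.2)."""
    r = rng.random()
    n_exons = 1 if r < 0.81 else (2 if r < 0.97 else 3)
    n_exons = min(n_exons, max(1, spliced_len // 80))
    cuts = sorted(rng.choice(np.arange(40, spliced_len - 40), size=n_exons - 1,
                             replace=False)) if n_exons > 1 else []
    pieces = np.diff([0, *cuts, spliced_len])
    exons, pos = [], chrom_start
    for k, piece in enumerate(pieces):
        exons.append((pos, pos + int(piece)))
        pos += int(piece)
        if k < len(pieces) - 1:
            pos += int(rng.integers(60, 300))  # intron
    return exons


def generate_discovery_fixture(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Write GTF + FASTA + GFF3 + evidence TSVs with planted filter categories.

    Categories: ``non_u`` (gene-overlapping class codes), ``short``
    (length <= 200), ``long_orf`` (planted ORF > 300 nt), ``protein_hit``,
    ``domain_hit``, ``cpc_positive``, ``flanking`` (within 500 nt of a
    coding gene) and ``true_linc`` (clean survivors).  Returns the
    ground-truth manifest (also written as JSON).
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # gene geometry: uniform spacing with jitter
    genes: list[GeneLocus] = []
    per_chrom = max(1, config.n_coding_genes // config.n_chromosomes)
    slot = 12000
    gidx = 0
    chrom_genes: dict[str, list[GeneLocus]] = {}
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        chrom_genes[chrom] = []
        n_here = per_chrom if c < config.n_chromosomes - 1 else (
            config.n_coding_genes - per_chrom * (config.n_chromosomes - 1))
        for i in range(n_here):
            gidx += 1
            start = 6000 + i * slot + int(rng.integers(-800, 800))
            width = int(rng.integers(500, 2000))
            g = GeneLocus(f"Gene{gidx:04d}", chrom, "+" if rng.random() < 0.5 else "-",
                          (start, start + width), "coding")
            genes.append(g)
            chrom_genes[chrom].append(g)

    # intergenic placement slots, all > 500 nt from every gene
    slots: list[tuple[str, int]] = []
    for chrom, gl in chrom_genes.items():
        bounds = [(0, gl[0].span[0])] + [
            (a.span[1], b.span[0]) for a, b in zip(gl, gl[1:])
        ] + [(gl[-1].span[1], gl[-1].span[1] + slot)]
        for lo, hi in bounds:
            pos = lo + 600
            while pos + 2500 <= hi - 600:
                slots.append((chrom, pos))
                pos += 2500
    order = rng.permutation(len(slots))
    slots = [slots[i] for i in order]

    n_safe = (config.n_true_linc + config.n_short + config.n_long_orf
              + config.n_protein_hit + config.n_domain_hit + config.n_cpc_positive)
    if n_safe > len(slots):
        raise ValueError(
            f"impossible geometry: {n_safe} intergenic transcripts but only "
            f"{len(slots)} placement slots; add genes or chromosomes")

    transcripts: list[TranscriptModel] = []
    sequences: dict[str, str] = {}
    manifest: dict = {"categories": {}, "transcripts": {}, "true_lincs": []}
    evidence = {"protein": [], "domain": [], "cpc": []}
    tix = 0
    slot_iter = iter(slots)

    def _add(category: str, chrom: str, start: int, length: int, seq: str,
             strand: str, class_code: str, designed_orf: int | None = None):
        nonlocal tix
        tix += 1
        tid = f"TCONS_{tix:05d}"
        exons = _exon_chain(rng, start, length)
        t = TranscriptModel(tid, chrom, strand, exons, class_code, f"XLOC_{tix:05d}")
        transcripts.append(t)
        sequences[tid] = seq
        manifest["categories"][tid] = category
        manifest["transcripts"][tid] = {
            "category": category, "chrom": chrom, "start": t.start, "end": t.end,
            "length": length, "strand": strand, "class_code": class_code,
            "exon_count": t.exon_count,
            **({"designed_orf": designed_orf} if designed_orf is not None else {}),
        }
        return tid

    def _strand():
        return str(rng.choice(["+", "-", "."], p=[0.3, 0.3, 0.4]))

    for _ in range(config.n_true_linc):
        chrom, pos = next(slot_iter)
        strand, length = _strand(), _linc_length(rng)
        seq = _clean_noncoding_seq(rng, length, strand)
        tid = _add("true_linc", chrom, pos, length, seq, strand, "u")
        manifest["true_lincs"].append(tid)

    for _ in range(config.n_short):
        chrom, pos = next(slot_iter)
        strand = _strand()
        length = int(rng.integers(80, 201))  # <= 200 nt
        _add("short", chrom, pos, length, _random_seq(rng, length), strand, "u")

    for _ in range(config.n_long_orf):
        chrom, pos = next(slot_iter)
        strand = _strand()
        orf_len = 3 * int(rng.integers(101, 161))  # 303..480 nt, > 300
        length = orf_len + int(rng.integers(60, 300))
        seq = _long_orf_seq(rng, length, orf_len, strand)
        _add("long_orf", chrom, pos, length, seq, strand, "u", designed_orf=orf_len)

    for category, n, table in (("protein_hit", config.n_protein_hit, "protein"),
                               ("domain_hit", config.n_domain_hit, "domain")):
        for _ in range(n):
            chrom, pos = next(slot_iter)
            strand, length = _strand(), _linc_length(rng)
            seq = _clean_noncoding_seq(rng, length, strand)
            tid = _add(category, chrom, pos, length, seq, strand, "u")
            evidence[table].append((tid, 10.0 ** -rng.uniform(5, 30)))

    for _ in range(config.n_cpc_positive):
        chrom, pos = next(slot_iter)
        strand, length = _strand(), _linc_length(rng)
        seq = _clean_noncoding_seq(rng, length, strand)
        tid = _add("cpc_positive", chrom, pos, length, seq, strand, "u")
        evidence["cpc"].append((tid, float(rng.uniform(0.5, 3.0))))

    flank_genes = rng.choice(len(genes), size=config.n_flanking, replace=False)
    for gi in flank_genes:
        g = genes[int(gi)]
        gap = int(rng.integers(10, 480))
        strand, length = _strand(), int(rng.integers(210, 700))
        seq = _clean_noncoding_seq(rng, length, strand)
        _add("flanking", g.chrom, g.span[1] + gap, length, seq, strand, "u")

    non_u_codes = ["=", "j", "o", "x"]
    host_genes = rng.choice(len(genes), size=config.n_non_u, replace=True)
    for k, gi in enumerate(host_genes):
        g = genes[int(gi)]
        length = int(rng.integers(300, 1200))
        start = g.span[0] + int(rng.integers(0, max(1, (g.span[1] - g.span[0]) // 2)))
        seq = _random_seq(rng, length, au=0.45)  # mRNA-like, GC richer
        _add("non_u", g.chrom, start, length, seq, g.strand, non_u_codes[k % 4])

    # negative coding-potential scores for everything not planted positive
    cpc_positive = {tid for tid, _ in evidence["cpc"]}
    for t in transcripts:
        if t.transcript_id not in cpc_positive:
            evidence["cpc"].append((t.transcript_id, float(-rng.uniform(0.1, 3.0))))
    # decoy homology hits above the e-value cutoff (must NOT remove)
    decoys = [tid for tid in manifest["true_lincs"][:2]]
    for tid in decoys:
        evidence["protein"].append((tid, float(rng.uniform(0.01, 0.5))))
    manifest["protein_decoys"] = decoys

    write_gtf(transcripts, out_dir / "transcripts.gtf")
    write_fasta(sequences, out_dir / "transcripts.fa")
    with open(out_dir / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tsim\tgene\t{g.span[0] + 1}\t{g.span[1]}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id};biotype=protein_coding\n")
    for name, rows in (("protein_hits.tsv", evidence["protein"]),
                       ("domain_hits.tsv", evidence["domain"]),
                       ("cpc_scores.tsv", evidence["cpc"])):
        with open(out_dir / name, "w") as fh:
            for tid, val in rows:
                fh.write(f"{tid}\t{val:.6g}\n")
    manifest["counts"] = {
        cat: sum(1 for c in manifest["categories"].values() if c == cat)
        for cat in ("true_linc", "short", "long_orf", "protein_hit", "domain_hit",
                    "cpc_positive", "flanking", "non_u")
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# expression fixture
# ---------------------------------------------------------------------------

def _lognoise(rng, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2, sigma=sigma, size=size)


def generate_expression_fixture(
    config: SimulationConfig,
    out_dir: str | Path,
    linc_ids: list[str] | None = None,
    mrna_ids: list[str] | None = None,
) -> dict:
    """Write an FPKM matrix with planted expression archetypes.

    LincRNA rows are split into tissue-specific profiles (high in one
    tissue, ~0 elsewhere), housekeeping profiles (constant mean times
    lognormal noise), co-regulated module members sharing a latent tissue
    profile with module mRNAs, and low background.  mRNA rows are module
    members plus background.  The bulk of the matrix sits in the very-low
    expression class, as in real lincRNA surveys.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1_000_003)
    tissues = list(config.tissues)
    nT = len(tissues)

    n_module_lincs = config.n_go_modules * config.lincs_per_module
    n_lincs = config.n_linc_rows
    if linc_ids is None:
        linc_ids = [f"Linc_{i:04d}" for i in range(1, n_lincs + 1)]
    if len(linc_ids) != n_lincs:
        raise ValueError(
            f"config expects {n_lincs} lincRNA rows "
            f"(specific+housekeeping+module+background) but got {len(linc_ids)} ids")
    n_mrnas = config.n_go_modules * config.go_module_size + config.n_background_mrnas
    if mrna_ids is None:
        mrna_ids = [f"mRNA_{i:04d}" for i in range(1, n_mrnas + 1)]
    if len(mrna_ids) != n_mrnas:
        raise ValueError(f"config expects {n_mrnas} mRNA rows, got {len(mrna_ids)}")

    manifest: dict = {"specific": {}, "housekeeping": [], "background_lincs": [],
                      "modules": {}, "tissues": tissues}
    rows: dict[str, np.ndarray] = {}
    it = iter(linc_ids)

    for k in range(config.n_specific_profiles):
        tid = next(it)
        tissue = tissues[k % nT]
        x = rng.uniform(0.0, 0.05, size=nT)
        x[tissues.index(tissue)] = rng.uniform(10.0, 30.0)
        rows[tid] = x * _lognoise(rng, config.noise_cv, nT)
        manifest["specific"][tid] = tissue

    for _ in range(config.n_housekeeping):
        tid = next(it)
        rows[tid] = rng.uniform(1.0, 8.0) * _lognoise(rng, config.noise_cv, nT)
        manifest["housekeeping"].append(tid)

    # co-regulated modules: latent tissue profile shared by mRNAs and lincRNAs
    mit = iter(mrna_ids)
    for m in range(config.n_go_modules):
        term = f"GO:{7000000 + m:07d}"
        profile = rng.lognormal(mean=0.0, sigma=1.2, size=nT)
        profile /= profile.mean()
        members_m = [next(mit) for _ in range(config.go_module_size)]
        members_l = [next(it) for _ in range(config.lincs_per_module)]
        for tid in members_m + members_l:
            gain = rng.uniform(2.0, 10.0)
            rows[tid] = gain * profile * _lognoise(rng, config.noise_cv, nT)
        manifest["modules"][f"module_{m + 1}"] = {
            "term": term, "mrnas": members_m, "lincs": members_l}

    for _ in range(config.n_background_lincs):
        tid = next(it)
        rows[tid] = rng.uniform(0.05, 1.5) * _lognoise(rng, 0.6, nT)
        manifest["background_lincs"].append(tid)
    for tid in mit:
        rows[tid] = rng.uniform(0.05, 1.5) * _lognoise(rng, 0.6, nT)

    df = pd.DataFrame.from_dict(rows, orient="index", columns=tissues).round(4)
    df = df.loc[list(linc_ids) + list(mrna_ids)]
    df.index.name = "transcript_id"
    df.to_csv(out_dir / "fpkm.tsv", sep="\t")
    manifest["linc_ids"] = list(linc_ids)
    manifest["mrna_ids"] = list(mrna_ids)
    with open(out_dir / "expression_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# PPI / GO fixture
# ---------------------------------------------------------------------------

def generate_network_fixture(
    config: SimulationConfig,
    out_dir: str | Path,
    expression_manifest: dict,
) -> dict:
    """Write PPI and GO tables consistent with the expression modules.

    Intra-module PPI edges are dense with high scores; inter-module edges
    sparse with low scores.  Each module's mRNAs are annotated with the
    module's GO term.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 2_000_003)
    modules = expression_manifest["modules"]
    mrna_module = {}
    for mod in modules.values():
        if len(mod["mrnas"]) > len(expression_manifest["mrna_ids"]):
            raise ValueError("module size exceeds mRNA count")
        for g in mod["mrnas"]:
            mrna_module[g] = mod["term"]

    ppi, go_rows = [], []
    module_list = list(modules.values())
    for mod in module_list:
        ms = mod["mrnas"]
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                if rng.random() < 0.6:
                    ppi.append((ms[i], ms[j], float(rng.uniform(0.65, 0.95))))
        for g in ms:
            go_rows.append((g, mod["term"], "biological_process"))
    for a_mod in range(len(module_list)):
        for b_mod in range(a_mod + 1, len(module_list)):
            for ga in module_list[a_mod]["mrnas"]:
                for gb in module_list[b_mod]["mrnas"]:
                    if rng.random() < 0.03:
                        ppi.append((ga, gb, float(rng.uniform(0.05, 0.3))))

    with open(out_dir / "ppi.tsv", "w") as fh:
        for a, b, s in ppi:
            fh.write(f"{a}\t{b}\t{s:.4f}\n")
    with open(out_dir / "go_annotations.tsv", "w") as fh:
        for g, t, ns in go_rows:
            fh.write(f"{g}\t{t}\t{ns}\n")
    manifest = {"modules": modules, "n_ppi_edges": len(ppi)}
    with open(out_dir / "network_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# miRNA fixture
# ---------------------------------------------------------------------------

def _revcomp_dna(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _mutate_site(site: list[str], mirna: str, duplex_pos: int, kind: str, rng) -> None:
    """Edit the target site so duplex position ``duplex_pos`` scores as ``kind``."""
    M = len(mirna)
    j = M - 1 - duplex_pos  # site index facing miRNA position duplex_pos
    m = mirna[duplex_pos]
    if kind == "wobble":
        if m == "G":
            site[j] = "T"     # G:U pair (target read as RNA)
        elif m == "U":
            site[j] = "G"
        else:
            raise ValueError(f"no wobble partner for miRNA base {m}")
    elif kind == "mismatch":
        scheme = DEFAULT_SCHEME
        options = [b for b in "ACGT"
                   if scheme.base_penalty(m, b.replace("T", "U")) == scheme.mismatch]
        site[j] = str(rng.choice(options))
    else:
        raise ValueError(kind)


def generate_mirna_fixture(
    config: SimulationConfig,
    out_dir: str | Path,
    linc_sequences: dict[str, str],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> dict:
    """Write miRNA FASTA and lincRNA FASTA with planted binding sites.

    Sites are built by exact penalty arithmetic: starting from the perfect
    reverse complement of the miRNA, wobbles and mismatches are placed at
    chosen seed/non-seed positions to hit designed expectations (by
    default 0, 0, 0.5, 2.0, 3.0, 3.5).  Each construction is re-scored to
    confirm the designed value before the site is spliced into its host.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 3_000_003)
    M = 21

    mirnas: dict[str, str] = {}
    while len(mirnas) < config.n_mirnas:
        seq = "".join(rng.choice(np.array(list("ACGU")), size=M))
        tail = seq[scheme.seed_end:]  # positions outside the seed (3' half)
        if sum(tail.count(b) for b in "GU") >= 2:
            mirnas[f"cam-miR{len(mirnas) + 1:03d}"] = seq

    hosts = [tid for tid, s in sorted(linc_sequences.items()) if len(s) >= 120]
    if len(hosts) < len(config.planted_site_expectations):
        raise ValueError("not enough lincRNAs of sufficient length to host sites")
    host_order = [hosts[i] for i in rng.permutation(len(hosts))]
    sequences = dict(linc_sequences)
    planted = []
    mir_ids = list(mirnas)

    for k, designed in enumerate(config.planted_site_expectations):
        mir_id = mir_ids[k % len(mir_ids)]
        m = mirnas[mir_id]
        seed_positions = list(range(scheme.seed_start - 1, scheme.seed_end))
        nonseed = [p for p in range(M) if p not in seed_positions]
        wobble_ok = [p for p in nonseed if m[p] in "GU"]
        site = list(_revcomp_dna(m.replace("U", "T")))
        used: set[int] = set()

        def _pick(pool):
            pool = [p for p in pool if p not in used]
            p = int(rng.choice(pool))
            used.add(p)
            return p

        if designed >= 0.5 and designed != 2.0 and designed != 3.0:
            _mutate_site(site, m, _pick(wobble_ok), "wobble", rng)
        if designed >= 2.0:
            _mutate_site(site, m, _pick(seed_positions), "mismatch", rng)
        if designed >= 3.0:
            _mutate_site(site, m, _pick(nonseed), "mismatch", rng)
        site_seq = "".join(site)
        expectation, _ = score_site(m, site_seq, scheme)
        if expectation != designed:
            raise AssertionError(
                f"constructed site scores {expectation}, designed {designed}")

        host = host_order[k]
        hseq = sequences[host]
        offset = int(rng.integers(20, len(hseq) - M - 20))
        sequences[host] = hseq[:offset] + site_seq + hseq[offset + M:]
        planted.append({"linc_id": host, "mirna_id": mir_id, "offset": offset,
                        "designed_expectation": float(designed)})

    write_fasta(mirnas, out_dir / "mirnas.fa")
    write_fasta(sequences, out_dir / "lincs_with_sites.fa")
    manifest = {"planted_sites": planted, "mirna_ids": mir_ids}
    with open(out_dir / "mirna_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# everything
# ---------------------------------------------------------------------------

def generate_all(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Generate a coherent full-pipeline fixture set in one directory.

    The expression matrix rows for lincRNAs are the planted true lincRNAs
    of the discovery fixture (the fixture requires the category counts to
    line up), and the miRNA fixture plants sites into those same
    sequences.
    """
    out_dir = Path(out_dir)
    discovery = generate_discovery_fixture(config, out_dir)
    true_lincs = sorted(discovery["true_lincs"])
    if len(true_lincs) != config.n_linc_rows:
        raise ValueError(
            f"n_true_linc ({len(true_lincs)}) must equal the expression row "
            f"budget ({config.n_linc_rows}) for a coherent end-to-end fixture")
    expression = generate_expression_fixture(config, out_dir, linc_ids=true_lincs)
    network = generate_network_fixture(config, out_dir, expression)

    from .transcript_io import read_fasta

    seqs = read_fasta(out_dir / "transcripts.fa")
    linc_seqs = {tid: seqs[tid] for tid in true_lincs}
    mirna = generate_mirna_fixture(config, out_dir, linc_seqs)
    manifest = {"discovery": discovery, "expression": expression,
                "network": network, "mirna": mirna}
    with open(out_dir / "full_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
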