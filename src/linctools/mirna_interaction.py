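"""Plant-style miRNA target screening of lincRNAs.

A miRNA-target duplex is scored by an additive complementarity penalty
("expectation"): Watson-Crick pair 0, G:U wobble 0.5, mismatch 1.0,
single-nucleotide bulge 2.0, with every penalty doubled inside the seed
region (miRNA positions 2-13 counted from the 5' end).  Sites with
expectation <= 3 (the standard reporting cutoff) are reported; an optional
precomputed target-site accessibility (UPE) table can additionally filter
hits at UPE <= 25.  Reported pairs form a bipartite lincRNA-miRNA
interaction network whose connected components are classified by pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ScoringScheme",
    "MatureMiRNA",
    "TargetHit",
    "InteractionNetwork",
    "read_mirnas",
    "score_site",
    "scan_targets",
    "build_network",
    "dinucleotide_shuffle",
]

_RNA = str.maketrans("Tt", "Uu")
_IDX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}
# Watson-Crick pairs and the G:U wobble, on (miRNA base, target base); the
# target base is read in RNA alphabet (T == U).  N never pairs.
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 0.0
    wobble: float = 0.5
    mismatch: float = 1.0
    gap: float = 2.0
    seed_start: int = 2      # miRNA positions (1-based, 5'->3') with doubled penalties
    seed_end: int = 13
    seed_multiplier: float = 2.0

    def position_weight(self, pos0: int) -> float:
        """Weight for 0-based miRNA position."""
        return self.seed_multiplier if self.seed_start - 1 <= pos0 <= self.seed_end - 1 else 1.0

    def base_penalty(self, m: str, t: str) -> float:
        """Penalty of pairing miRNA base m with target base t (RNA alphabet)."""
        key = (m, t)
        if key in _WC:
            return self.match
        if key in _WOBBLE:
            return self.wobble
        return self.mismatch


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class MatureMiRNA:
    """A mature miRNA sequence (stored as RNA, 18-26 nt)."""

    mirna_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().translate(_RNA)
        if not set(seq) <= set("ACGU"):
            raise ValueError(f"{self.mirna_id}: invalid miRNA alphabet in {self.sequence!r}")
        if not 18 <= len(seq) <= 26:
            raise ValueError(f"{self.mirna_id}: miRNA length {len(seq)} outside 18-26")
        self.sequence = seq


def read_mirnas(path: str | Path) -> list[MatureMiRNA]:
    from Bio import SeqIO

    out = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate miRNA id {rec.id!r}")
        seen.add(rec.id)
        out.append(MatureMiRNA(rec.id, str(rec.seq)))
    return out


@dataclass
class TargetHit:
    """One miRNA binding-site call on a lincRNA."""

    linc_id: str
    mirna_id: str
    target_start: int        # 0-based on the transcript
    target_end: int
    expectation: float
    alignment: dict[str, str] = field(default_factory=dict)
    upe: float | None = None
    primary: bool = True


def _duplex_penalties(mirna: str, window: str, scheme: ScoringScheme) -> np.ndarray:
    """Penalty of miRNA position i against reversed-window position j."""
    m = mirna
    r = window.upper().translate(_RNA)[::-1]  # r[i] faces m[i] in the ungapped duplex
    P = np.empty((len(m), len(r)))
    for i, mb in enumerate(m):
        w = scheme.position_weight(i)
        for j, tb in enumerate(r):
            P[i, j] = scheme.base_penalty(mb, tb) * w
    return P


def score_site(
    mirna: str | MatureMiRNA,
    window: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    max_bulges: int = 1,
) -> tuple[float, dict[str, str]]:
    """Score one candidate duplex and return (expectation, alignment).

    The miRNA (5'->3') is aligned antiparallel against the target window;
    the window may be the miRNA length, or one shorter/longer to allow a
    single-nucleotide bulge on either strand (penalty 2.0, seed-doubled at
    the bulged miRNA position).  Ties prefer fewer gaps, then the 5'-most
    bulge placement.
    """
    if isinstance(mirna, MatureMiRNA):
        m = mirna.sequence
    else:
        m = mirna.upper().translate(_RNA)
        if not set(m) <= set("ACGU"):
            raise ValueError(f"invalid miRNA alphabet: {mirna!r}")
    w = window.upper().translate(_RNA)
    if not set(w) <= set("ACGUN"):
        raise ValueError(f"invalid target alphabet: {window!r}")
    M, W = len(m), len(w)
    P = _duplex_penalties(m, w, scheme)
    best = None  # (expectation, n_gaps, bulge_pos, kind)
    if W == M:
        best = (float(np.trace(P)), 0, -1, "ungapped")
    elif W == M + 1 and max_bulges >= 1:
        # one unpaired target base at reversed-window position b
        for b in range(W):
            total = scheme.gap * scheme.position_weight(min(b, M - 1))
            for i in range(M):
                total += P[i, i if i < b else i + 1]
            cand = (total, 1, b, "target_bulge")
            if best is None or cand[:3] < best[:3]:
                best = cand
    elif W == M - 1 and max_bulges >= 1:
        # one unpaired miRNA base at position b
        for b in range(M):
            total = scheme.gap * scheme.position_weight(b)
            for i in range(M):
                if i == b:
                    continue
                total += P[i, i if i < b else i - 1]
            cand = (total, 1, b, "mirna_bulge")
            if best is None or cand[:3] < best[:3]:
                best = cand
    else:
        raise ValueError(
            f"window length {W} incompatible with miRNA length {M} (max_bulges={max_bulges})"
        )
    expectation, _, bulge, kind = best
    return expectation, _alignment_strings(m, w, scheme, bulge, kind)


def _alignment_strings(m, w, scheme, bulge, kind) -> dict[str, str]:
    """Three-line duplex rendering: miRNA 5'->3' over the target read 3'->5'."""
    r = w[::-1]
    mi, ri = list(m), list(r)
    if kind == "target_bulge":
        mi.insert(bulge, "-")
    elif kind == "mirna_bulge":
        ri.insert(bulge, "-")
    symbols = []
    for a, b in zip(mi, ri):
        if a == "-" or b == "-":
            symbols.append("-")
        elif (a, b) in _WC:
            symbols.append("|")
        elif (a, b) in _WOBBLE:
            symbols.append("o")
        else:
            symbols.append(" ")
    return {
        "mirna_5to3": "".join(mi),
        "pairing": "".join(symbols),
        "target_3to5": "".join(ri),
    }


# ---------------------------------------------------------------------------
# Whole-transcript scanning (vectorized)
# ---------------------------------------------------------------------------

def _penalty_matrix(m: str, target: str, scheme: ScoringScheme) -> np.ndarray:
    """Q[i, j] = seed-weighted penalty of miRNA pos i against target pos j."""
    base = np.empty((5, 5))
    for a, ia in (("A", 0), ("C", 1), ("G", 2), ("U", 3), ("N", 4)):
        for b, ib in (("A", 0), ("C", 1), ("G", 2), ("U", 3), ("N", 4)):
            base[ia, ib] = scheme.base_penalty(a, b)
    mi = np.fromiter((_IDX[c] for c in m), dtype=np.intp)
    ti = np.fromiter((_IDX[c] for c in target), dtype=np.intp)
    weights = np.array([scheme.position_weight(i) for i in range(len(m))])
    return base[np.ix_(mi, ti)] * weights[:, None]


def _scan_one(m: str, target: str, scheme: ScoringScheme, max_bulges: int):
    """All candidate duplexes of one miRNA against one transcript.

    Yields (start, window_len, expectation) for every window of length
    M-1, M, M+1 at every start; the arithmetic mirrors :func:`score_site`
    exactly (anti-diagonal sums of the position penalty matrix).
    """
    M, L = len(m), len(target)
    if L < M:
        return
    Q = _penalty_matrix(m, target, scheme)
    weights = np.array([scheme.position_weight(i) for i in range(M)])

    # ungapped: miRNA i pairs target s + M - 1 - i
    nS = L - M + 1
    scores = np.zeros(nS)
    for i in range(M):
        scores += Q[i, M - 1 - i : M - 1 - i + nS]
    for s in range(nS):
        yield (s, M, float(scores[s]))

    if max_bulges < 1:
        return

    # target bulge (window M+1): for reversed-window bulge position b,
    # miRNA i pairs target s + M - i for i < b, and s + M - 1 - i for i >= b
    if L >= M + 1:
        nS = L - M
        A = np.zeros((M + 1, nS))  # prefix sums of the shifted diagonal
        B = np.zeros((M + 1, nS))  # suffix sums of the plain diagonal
        for i in range(M):
            A[i + 1] = A[i] + Q[i, M - i : M - i + nS]
        for i in range(M - 1, -1, -1):
            B[i] = B[i + 1] + Q[i, M - 1 - i : M - 1 - i + nS]
        for s in range(nS):
            vals = [
                A[b, s] + B[b, s] + scheme.gap * weights[min(b, M - 1)]
                for b in range(M + 1)
            ]
            yield (s, M + 1, float(min(vals)))

    # miRNA bulge (window M-1): skip miRNA position b,
    # miRNA i pairs target s + M - 2 - i for i < b, and s + M - 1 - i for i > b
    if M >= 2 and L >= M - 1:
        nS = L - (M - 1) + 1
        A = np.zeros((M + 1, nS))
        B = np.zeros((M + 1, nS))
        for i in range(M):
            shift = M - 2 - i
            if 0 <= shift:
                A[i + 1] = A[i] + Q[i, shift : shift + nS]
            else:  # i == M-1: pairs nothing on the left branch
                A[i + 1] = A[i]
        for i in range(M - 1, 0, -1):  # i == 0 can never sit right of the bulge
            shift = M - 1 - i
            B[i] = B[i + 1] + Q[i, shift : shift + nS]
        for s in range(nS):
            vals = [
                A[b, s] + B[b + 1, s] + scheme.gap * weights[b]
                for b in range(M)
            ]
            yield (s, M - 1, float(min(vals)))


def scan_targets(
    mirnas: list[MatureMiRNA] | dict[str, str],
    linc_sequences: dict[str, str],
    max_expectation: float = 3.0,
    upe_table: pd.DataFrame | None = None,
    max_upe: float = 25.0,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    max_bulges: int = 1,
) -> list[TargetHit]:
    """Scan every lincRNA for binding sites of every miRNA.

    All window placements (miRNA length +- 1 for a single bulge) are
    scored; sites with expectation <= ``max_expectation`` are reported.
    If a UPE (energy to unpair the target site) table is supplied, hits
    must additionally satisfy UPE <= ``max_upe``; without the table that
    filter is skipped with a logged notice.  Overlapping hits of one
    (lincRNA, miRNA) pair are collapsed: the best-scoring site is primary,
    the rest are kept as secondary.
    """
    if isinstance(mirnas, dict):
        mirnas = [MatureMiRNA(k, v) for k, v in mirnas.items()]
    upe_lookup: dict[tuple[str, str, int], float] = {}
    if upe_table is not None:
        for row in upe_table.itertuples(index=False):
            upe_lookup[(str(row.linc_id), str(row.mirna_id), int(row.start))] = float(row.upe)
    else:
        logger.info("no UPE table supplied; target-site accessibility filter skipped")

    hits: list[TargetHit] = []
    for linc_id, raw_seq in linc_sequences.items():
        target = raw_seq.upper().translate(_RNA)
        for mir in mirnas:
            pair_hits = []
            for start, wlen, exp in _scan_one(mir.sequence, target, scheme, max_bulges):
                if exp > max_expectation:
                    continue
                upe = upe_lookup.get((linc_id, mir.mirna_id, start))
                if upe_table is not None and upe is not None and upe > max_upe:
                    continue
                pair_hits.append(
                    TargetHit(linc_id, mir.mirna_id, start, start + wlen, exp, {}, upe)
                )
            # collapse overlapping sites: best (lowest expectation, 5'-most) wins
            pair_hits.sort(key=lambda h: (h.expectation, h.target_start))
            accepted: list[TargetHit] = []
            for h in pair_hits:
                overlaps = any(
                    h.target_start < a.target_end and a.target_start < h.target_end
                    for a in accepted
                )
                h.primary = not overlaps
                if not overlaps:
                    accepted.append(h)
                    window = raw_seq[h.target_start : h.target_end]
                    _, h.alignment = score_site(mir, window, scheme, max_bulges)
            hits.extend(pair_hits)
    hits.sort(key=lambda h: (h.linc_id, h.mirna_id, h.target_start))
    return hits


# ---------------------------------------------------------------------------
# Interaction network
# ---------------------------------------------------------------------------

@dataclass
class InteractionNetwork:
    """Bipartite lincRNA-miRNA network over distinct interacting pairs."""

    graph: nx.Graph
    n_lincs: int
    n_mirnas: int
    n_pairs: int
    component_patterns: list[str]
    pattern_counts: dict[str, int]

    def summary(self) -> dict:
        return {
            "n_lincRNAs": self.n_lincs,
            "n_miRNAs": self.n_mirnas,
            "n_pairs": self.n_pairs,
            "pattern_counts": dict(self.pattern_counts),
        }

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {"linc_id": a if self.graph.nodes[a]["kind"] == "lincRNA" else b,
             "mirna_id": b if self.graph.nodes[b]["kind"] == "miRNA" else a}
            for a, b in self.graph.edges
        ]
        return pd.DataFrame(rows, columns=["linc_id", "mirna_id"])

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))


def build_network(hits: list[TargetHit]) -> InteractionNetwork:
    """Collapse hits to distinct (lincRNA, miRNA) pairs and classify patterns.

    Component patterns follow the miRNA -> lincRNA direction: one miRNA
    with several lincRNA targets is ``one_to_many``, several miRNAs on one
    lincRNA is ``many_to_one``.
    """
    pairs = sorted({(h.linc_id, h.mirna_id) for h in hits})
    g = nx.Graph()
    for linc, mir in pairs:
        g.add_node(f"linc::{linc}", kind="lincRNA", name=linc)
        g.add_node(f"mir::{mir}", kind="miRNA", name=mir)
        g.add_edge(f"linc::{linc}", f"mir::{mir}")
    patterns = []
    for comp in nx.connected_components(g):
        lincs = sum(1 for n in comp if g.nodes[n]["kind"] == "lincRNA")
        mirs = len(comp) - lincs
        if lincs == 1 and mirs == 1:
            patterns.append("one_to_one")
        elif mirs == 1:
            patterns.append("one_to_many")
        elif lincs == 1:
            patterns.append("many_to_one")
        else:
            patterns.append("many_to_many")
    counts: dict[str, int] = {}
    for p in patterns:
        counts[p] = counts.get(p, 0) + 1
    return InteractionNetwork(
        graph=g,
        n_lincs=len({l for l, _ in pairs}),
        n_mirnas=len({m for _, m in pairs}),
        n_pairs=len(pairs),
        component_patterns=sorted(patterns),
        pattern_counts=counts,
    )


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving dinucleotide composition (Eulerian walk)."""
    if len(sequence) < 3:
        return sequence
    edges: dict[str, list[str]] = {}
    for a, b in zip(sequence, sequence[1:]):
        edges.setdefault(a, []).append(b)
    for a in edges:
        rng.shuffle(edges[a])

    # ensure the walk can end at the original last character: retrace from a
    # randomized edge ordering until a full-length walk is found
    last = sequence[-1]
    for _ in range(20):
        trial = {a: list(bs) for a, bs in edges.items()}
        walk = [sequence[0]]
        while trial.get(walk[-1]):
            walk.append(trial[walk[-1]].pop())
        if len(walk) == len(sequence) and walk[-1] == last:
            return "".join(walk)
        for a in edges:
            rng.shuffle(edges[a])
    return "".join(walk)  # rare fallback: composition-preserving but shorter walk
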