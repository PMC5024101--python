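"""GO annotation of lincRNAs by network propagation, plus GO enrichment.

A bicolor network joins mRNA and lincRNA nodes: co-expression edges (top
0.5% of |Spearman rho| over candidate pairs) may touch any node, while
protein-protein interaction edges exist only among mRNAs.  GO biological
process labels of mRNAs are diffused over the symmetrically normalized
weighted graph by the global propagation iteration

    F <- alpha * W' F + (1 - alpha) * Y,      W' = D^(-1/2) W D^(-1/2),

which converges for alpha < 1 to F = (1-alpha)(I - alpha W')^(-1) Y.  For
each GO term the top-ranked lincRNA nodes (default rank cutoff 100) with a
positive score receive the term.  Enrichment of lincRNA sets uses the
hypergeometric upper tail with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "BicolorNetwork",
    "PropagationScores",
    "EnrichmentResult",
    "load_ppi_edges",
    "load_go_annotations",
    "build_coexpression_edges",
    "normalize_scores_minmax",
    "combine_network",
    "seed_first_degree",
    "propagate",
    "assign_annotations",
    "enrich_go",
]


# ---------------------------------------------------------------------------
# Inputs
# ---------------------------------------------------------------------------

def load_ppi_edges(path: str | Path, normalize: bool = True) -> list[tuple[str, str, float]]:
    """Read a PPI edge TSV (protein_a, protein_b, score); min-max normalize scores."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["a", "b", "score"])
    scores = df["score"].astype(float).values
    if normalize and len(scores):
        scores = normalize_scores_minmax(scores)
    return [(str(a), str(b), float(s)) for a, b, s in zip(df["a"], df["b"], scores)]


def load_go_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a gene -> GO term mapping TSV (gene_id, term[, namespace])."""
    ann: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", header=None, comment="#").iloc[:, :2]
    for gene, term in df.itertuples(index=False):
        ann.setdefault(str(gene), set()).add(str(term))
    return ann


def build_coexpression_edges(
    pair_rho: dict[tuple[str, str], float],
    percentile: float = 0.5,
) -> list[tuple[str, str, float]]:
    """Keep the top `percentile`% of candidate pairs by |rho| as edges.

    The threshold is the (100 - percentile)-th percentile of |rho| over all
    candidate pairs; edges are kept when |rho| >= threshold and weighted by
    |rho|.  The candidate universe is whatever pairs the caller supplies
    (by default lincRNA-mRNA and mRNA-mRNA pairs; see the pipeline).
    """
    if not pair_rho:
        return []
    if len(pair_rho) < 200:
        warnings.warn(
            f"only {len(pair_rho)} candidate pairs; the {100 - percentile:g}th "
            "percentile threshold is unstable", stacklevel=2,
        )
    abs_rho = np.abs(np.fromiter(pair_rho.values(), dtype=float))
    threshold = np.percentile(abs_rho, 100.0 - percentile)
    edges = [
        (a, b, abs(r))
        for (a, b), r in pair_rho.items()
        if abs(r) >= threshold
    ]
    return edges


def normalize_scores_minmax(values) -> np.ndarray:
    """Min-max linear normalization to [0,1]; constant input maps to all 0."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot normalize an empty score vector")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Bicolor network
# ---------------------------------------------------------------------------

@dataclass
class BicolorNetwork:
    """Weighted graph over mRNA and lincRNA nodes with GO prior labels.

    ``W`` is the symmetric nonnegative adjacency (zero diagonal, weights in
    [0,1]); ``Y`` is the binary node x term prior (1 where an mRNA carries
    the term; lincRNA rows all 0).
    """

    nodes: list[str]
    colors: dict[str, str]            # node -> {"mRNA", "lincRNA"}
    W: np.ndarray
    terms: list[str] = field(default_factory=list)
    Y: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if self.W.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if self.W.min() < 0 or self.W.max() > 1 + 1e-12:
            raise ValueError("edge weights must lie in [0,1]")
        self.index = {node: i for i, node in enumerate(self.nodes)}

    @property
    def linc_nodes(self) -> list[str]:
        return [n for n in self.nodes if self.colors[n] == "lincRNA"]

    @property
    def mrna_nodes(self) -> list[str]:
        return [n for n in self.nodes if self.colors[n] == "mRNA"]

    def attach_go(self, annotations: dict[str, set[str]]) -> None:
        """Build the GO prior Y from an mRNA -> terms mapping.

        Terms with no annotated node in the network are dropped (every
        retained term column has at least one seed).
        """
        terms = sorted({t for g in self.mrna_nodes for t in annotations.get(g, ())})
        Y = np.zeros((len(self.nodes), len(terms)))
        tindex = {t: j for j, t in enumerate(terms)}
        for g in self.mrna_nodes:
            for t in annotations.get(g, ()):
                Y[self.index[g], tindex[t]] = 1.0
        self.terms, self.Y = terms, Y

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node, color=self.colors[node])
        ii, jj = np.nonzero(np.triu(self.W))
        for i, j in zip(ii, jj):
            g.add_edge(self.nodes[i], self.nodes[j], weight=float(self.W[i, j]))
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), str(path))


def combine_network(
    coexpr_edges: list[tuple[str, str, float]],
    ppi_edges: list[tuple[str, str, float]],
    colors: dict[str, str],
    combine: str = "max",
) -> BicolorNetwork:
    """Merge co-expression and PPI edge sets into one bicolor network.

    Both edge sets must already be on the [0,1] scale (co-expression |rho|
    is; PPI scores go through min-max normalization on load).  Overlapping
    pairs are combined by ``max`` (default) or ``mean``; PPI edges touching
    a lincRNA node are rejected.
    """
    for a, b, _ in ppi_edges:
        if colors.get(a) == "lincRNA" or colors.get(b) == "lincRNA":
            raise ValueError(f"PPI edge touches a lincRNA node: {a}-{b}")
    nodes = sorted(colors)
    index = {n: i for i, n in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    seen: dict[tuple[int, int], list[float]] = {}
    for a, b, w in list(coexpr_edges) + list(ppi_edges):
        if a == b:
            continue
        i, j = index[a], index[b]
        key = (min(i, j), max(i, j))
        seen.setdefault(key, []).append(float(w))
    for (i, j), ws in seen.items():
        w = max(ws) if combine == "max" else sum(ws) / len(ws)
        W[i, j] = W[j, i] = w
    return BicolorNetwork(nodes=nodes, colors=dict(colors), W=W)


def seed_first_degree(
    network: BicolorNetwork, annotations: dict[str, set[str]]
) -> dict[str, set[str]]:
    """First-pass annotation: each lincRNA inherits the union of GO terms
    of its directly connected mRNA neighbours."""
    out: dict[str, set[str]] = {}
    for linc in network.linc_nodes:
        i = network.index[linc]
        terms: set[str] = set()
        for j in np.nonzero(network.W[i])[0]:
            nb = network.nodes[j]
            if network.colors[nb] == "mRNA":
                terms |= annotations.get(nb, set())
        out[linc] = terms
    return out


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------

@dataclass
class PropagationScores:
    F: pd.DataFrame            # node x term association scores
    converged: bool
    n_iter: int
    residual: float            # final L1 change


def _normalized_adjacency(W: np.ndarray) -> np.ndarray:
    deg = W.sum(axis=1)
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])  # isolated nodes get all-zero rows
    return inv_sqrt[:, None] * W * inv_sqrt[None, :]


def propagate(
    network: BicolorNetwork,
    alpha: float = 0.8,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> PropagationScores:
    """Diffuse the GO priors over the network to score every (node, term).

    Iterates F <- alpha W' F + (1-alpha) Y from F = Y until the L1 change
    drops below ``tol``.  Symmetric normalization bounds the spectral
    radius of alpha W' below 1, so the iteration converges for any
    alpha in (0,1); hitting the iteration cap is flagged, never silent.
    """
    if network.Y is None:
        raise ValueError("attach_go must be called before propagation")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    Wn = _normalized_adjacency(network.W)
    Y = network.Y
    F = Y.copy()
    residual = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        F_new = alpha * (Wn @ F) + (1 - alpha) * Y
        residual = float(np.abs(F_new - F).sum())
        F = F_new
        if residual < tol:
            break
    return PropagationScores(
        F=pd.DataFrame(F, index=network.nodes, columns=network.terms),
        converged=residual < tol,
        n_iter=n_iter,
        residual=residual,
    )


def assign_annotations(
    scores: PropagationScores,
    network: BicolorNetwork,
    top_rank: int = 100,
) -> dict[str, set[str]]:
    """Annotate, per GO term, the top-ranked lincRNAs with positive score.

    Ranking is by descending propagation score, ties broken by node id;
    lincRNAs with score 0 for a term never receive it, even inside the top
    ranks.  Returns linc -> term set (possibly empty = unannotated).
    """
    lincs = network.linc_nodes
    out: dict[str, set[str]] = {l: set() for l in lincs}
    sub = scores.F.loc[lincs]
    for term in scores.F.columns:
        col = sub[term]
        ranked = sorted(col.items(), key=lambda kv: (-kv[1], str(kv[0])))
        for node, f in ranked[:top_rank]:
            if f > 0:
                out[str(node)].add(term)
    return out


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    term: str
    k: int          # study genes carrying the term
    n: int          # study size
    K: int          # population genes carrying the term
    N: int          # population size
    p_value: float
    p_adjusted: float
    significant: bool


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, pvals[idx] * m / rank)
        adj[idx] = running
    return np.maximum(adj, pvals)  # BH-adjusted p is never below the raw p


def enrich_go(
    study: set[str],
    population: set[str],
    annotations: dict[str, set[str]],
    p_threshold: float = 1e-10,
) -> list[EnrichmentResult]:
    """Hypergeometric GO-term over-representation of a study set.

    For each term annotated in the population, p = P(X >= k) under the
    hypergeometric null with parameters (N, K, n); results are sorted by
    p-value and carry a Benjamini-Hochberg adjusted p alongside the raw
    significance flag (default threshold 1e-10).
    """
    study = set(study)
    population = set(population)
    if not study:
        raise ValueError("empty study set")
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    N = len(population)
    n = len(study)
    term_pop: dict[str, set[str]] = {}
    for gene in population:
        for term in annotations.get(gene, ()):
            term_pop.setdefault(term, set()).add(gene)
    terms = sorted(term_pop)
    results = []
    pvals = []
    for term in terms:
        K = len(term_pop[term])
        k = len(term_pop[term] & study)
        p = float(hypergeom.sf(k - 1, N, K, n))
        pvals.append(min(max(p, 0.0), 1.0))
        results.append((term, k, K))
    adj = _bh_adjust(np.asarray(pvals)) if pvals else np.array([])
    out = [
        EnrichmentResult(term, k, n, K, N, p, float(min(a, 1.0)), p < p_threshold)
        for (term, k, K), p, a in zip(results, pvals, adj)
    ]
    out.sort(key=lambda r: (r.p_value, r.term))
    return out
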