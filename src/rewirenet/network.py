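"""Stage-wise weighted co-expression networks and topology diagnostics.

For one stage the network is built from the gene x gene Pearson
correlation matrix: each pair is tested against the null of zero
correlation with the exact t reference (t = r * sqrt((n-2)/(1-r^2)) on
n-2 degrees of freedom, two-sided), p-values are Benjamini-Hochberg
adjusted over the upper triangle, and an edge is kept iff r >= r_min and
adjusted p <= fdr_max (positive correlations only by default).

Degree-only evaluation of the same rule is available through
:func:`binary_adjacency` for the permutation machinery, which must
rebuild networks thousands of times: BH step-up on p-values that are a
monotone function of |r| is equivalent to a rank cutoff on |r|, so the
per-rank critical correlations are precomputed once per (n_samples,
n_pairs, fdr_max) and each rebuild reduces to one correlation matrix and
one sort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "StageNetwork",
    "TopologySummary",
    "build_network",
    "binary_adjacency",
    "topology_summary",
    "random_reference",
    "powerlaw_fit",
]


# ---------------------------------------------------------------------
# correlation and edge rule
# ---------------------------------------------------------------------

def _correlation_matrix(x: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlations; constant rows yield r = 0."""
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((xc ** 2).sum(axis=1))
    flat = norm == 0
    if flat.any():
        logger.warning("%d zero-variance genes: correlations set to 0", int(flat.sum()))
    norm[flat] = 1.0
    z = xc / norm[:, None]
    r = z @ z.T
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 0.0)
    return r


def correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values of the no-correlation t-test, elementwise."""
    if n <= 2:
        raise ValueError("need more than 2 samples for the correlation test")
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        t = np.abs(r) * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    return 2.0 * stats.t.sf(t, df=n - 2)


@lru_cache(maxsize=32)
def _bh_critical_r(n_samples: int, n_pairs: int, fdr_max: float) -> np.ndarray:
    """|r| needed at each BH rank k=1..m so that p(|r|) = k * fdr_max / m."""
    k = np.arange(1, n_pairs + 1, dtype=float)
    pthr = np.minimum(k * fdr_max / n_pairs, 1.0)
    df = n_samples - 2
    tcrit = stats.t.isf(pthr / 2.0, df=df)
    tcrit = np.maximum(tcrit, 0.0)
    return tcrit / np.sqrt(df + tcrit ** 2)


def binary_adjacency(x: np.ndarray, r_min: float = 0.5, fdr_max: float = 0.05,
                     absolute: bool = False) -> np.ndarray:
    """Boolean adjacency of the thresholded network for a genes x samples block.

    Equivalent to thresholding ``build_network``'s full matrices; used on
    the hot path (permutations) where only the adjacency is needed.
    """
    n_genes, n = x.shape
    r = _correlation_matrix(x)
    iu = np.triu_indices(n_genes, k=1)
    absr = np.abs(r[iu])
    m = absr.size
    rcrit = _bh_critical_r(n, m, fdr_max)
    sorted_desc = np.sort(absr)[::-1]
    passing = np.nonzero(sorted_desc >= rcrit)[0]
    if passing.size == 0:
        return np.zeros((n_genes, n_genes), dtype=bool)
    cutoff = sorted_desc[passing[-1]]
    sig = np.abs(r) >= cutoff
    strength = np.abs(r) if absolute else r
    adj = sig & (strength >= r_min)
    np.fill_diagonal(adj, False)
    return adj


@dataclass
class StageNetwork:
    """Thresholded weighted co-expression graph for one stage."""

    stage: str
    n_samples: int
    genes: list[str]
    r_matrix: np.ndarray
    p_matrix: np.ndarray
    fdr_matrix: np.ndarray
    adjacency: np.ndarray
    r_min: float = 0.5
    fdr_max: float = 0.05
    absolute: bool = False

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def degrees(self) -> pd.Series:
        return pd.Series(self.adjacency.sum(axis=1), index=self.genes, name="degree")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def neighbor_sets(self) -> dict[str, set[str]]:
        genes = np.asarray(self.genes)
        return {g: set(genes[self.adjacency[i]]) for i, g in enumerate(self.genes)}

    def edge_list(self) -> pd.DataFrame:
        """Edges as TSV-ready rows with gene_a < gene_b lexicographically."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        names = np.asarray(self.genes)
        a, b = names[ii], names[jj]
        swap = a > b
        a, b = np.where(swap, b, a), np.where(swap, a, b)
        df = pd.DataFrame({"gene_a": a, "gene_b": b,
                           "r": self.r_matrix[ii, jj],
                           "p": self.p_matrix[ii, jj],
                           "fdr": self.fdr_matrix[ii, jj]})
        return df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)

    def induced_adjacency(self, genes: list[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.genes)}
        ix = np.array([pos[g] for g in genes], dtype=int)
        return self.adjacency[np.ix_(ix, ix)]

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        g.add_edges_from((self.genes[i], self.genes[j]) for i, j in zip(ii, jj))
        return g


def build_network(data: ExpressionDataset, stage: str, r_min: float = 0.5,
                  fdr_max: float = 0.05, absolute: bool = False) -> StageNetwork:
    """Build the thresholded co-expression network for one stage.

    Requires more than 10 samples in the stage (validity domain of the
    correlation test at these thresholds).  Set ``absolute=True`` to keep
    strong negative correlations as edges too.
    """
    x = data.stage_matrix(stage)
    n = x.shape[1]
    if n <= 10:
        raise ValueError(f"stage {stage!r} has {n} samples; need > 10")
    r = _correlation_matrix(x)
    p = correlation_pvalues(r, n)
    # zero-variance rows were forced to r=0; make the test agree (p=1)
    flat = ~np.any(r != 0.0, axis=1)
    p[flat, :] = 1.0
    p[:, flat] = 1.0
    np.fill_diagonal(p, 1.0)
    iu = np.triu_indices(len(data.genes), k=1)
    adj_flat = multipletests(p[iu], method="fdr_bh")[1]
    fdr = np.ones_like(p)
    fdr[iu] = adj_flat
    fdr = np.minimum(fdr, fdr.T)
    strength = np.abs(r) if absolute else r
    adjacency = (strength >= r_min) & (fdr <= fdr_max)
    np.fill_diagonal(adjacency, False)
    adjacency &= adjacency.T  # symmetric by construction; assert shape
    return StageNetwork(stage=stage, n_samples=n, genes=data.genes,
                        r_matrix=r, p_matrix=p, fdr_matrix=fdr,
                        adjacency=adjacency, r_min=r_min, fdr_max=fdr_max,
                        absolute=absolute)


# ---------------------------------------------------------------------
# topology diagnostics
# ---------------------------------------------------------------------

@dataclass
class TopologySummary:
    stage: str
    n_nodes: int
    n_edges: int
    n_unconnected: int
    clustering_coefficient: float
    density: float
    degree_centralization: float

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_unconnected": self.n_unconnected,
            "clustering_coefficient": self.clustering_coefficient,
            "density": self.density,
            "degree_centralization": self.degree_centralization,
        }


def topology_summary(net: StageNetwork | nx.Graph, stage: str = "") -> TopologySummary:
    """Global transitivity, density, Freeman degree centralization, etc."""
    if isinstance(net, StageNetwork):
        graph = net.to_graph()
        stage = stage or net.stage
    else:
        graph = net
    n = graph.number_of_nodes()
    if n < 3:
        raise ValueError("centralization undefined for networks with < 3 nodes")
    degrees = np.array([d for _, d in graph.degree()])
    e = graph.number_of_edges()
    density = 2.0 * e / (n * (n - 1))
    transitivity = nx.transitivity(graph)
    centralization = float((degrees.max() - degrees).sum()) / ((n - 1) * (n - 2))
    return TopologySummary(stage=stage, n_nodes=n, n_edges=e,
                           n_unconnected=int((degrees == 0).sum()),
                           clustering_coefficient=float(transitivity),
                           density=float(density),
                           degree_centralization=float(centralization))


# ---------------------------------------------------------------------
# random reference networks (Erdos-Renyi) and power-law diagnostics
# ---------------------------------------------------------------------

@dataclass
class RandomReference:
    p: float
    replicate_degrees: list[np.ndarray]
    replicate_edges: list[set[tuple[int, int]]]
    ks_statistic: float
    ks_pvalue: float


def random_reference(net: StageNetwork, n_replicates: int = 100,
                     seed: int | None = None,
                     keep_edges: bool = False) -> RandomReference:
    """Erdos-Renyi G(N, p) replicates with p = <d>/N and a KS comparison.

    The two-sample Kolmogorov-Smirnov test compares the real degree
    distribution with the degrees pooled over all replicates.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    degrees = net.degrees.to_numpy()
    n = net.n_genes
    p = degrees.mean() / n
    if p > 1.0:
        raise ValueError(f"pathological edge probability p = {p:.3f} > 1")
    rng = np.random.default_rng(seed)
    rep_degrees: list[np.ndarray] = []
    rep_edges: list[set[tuple[int, int]]] = []
    for _ in range(n_replicates):
        g = nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
        rep_degrees.append(np.array([d for _, d in g.degree()]))
        if keep_edges:
            rep_edges.append({tuple(sorted(e)) for e in g.edges()})
    pooled = np.concatenate(rep_degrees)
    ks = stats.ks_2samp(degrees, pooled)
    return RandomReference(p=float(p), replicate_degrees=rep_degrees,
                           replicate_edges=rep_edges,
                           ks_statistic=float(ks.statistic),
                           ks_pvalue=float(ks.pvalue))


def powerlaw_fit(net: StageNetwork, n_bootstraps: int = 100,
                 seed: int | None = None):
    """Discrete power-law fit to the positive-degree distribution.

    Returns a :class:`rewirenet.powerlaw.PowerLawFit` with the maximum
    likelihood exponent, the KS-optimal lower cutoff, and a bootstrap
    goodness-of-fit p-value.  A small p (< 0.1 in the conventional
    reading) rejects the power-law model for the degree tail.
    """
    from .powerlaw import fit_power_law

    degrees = net.degrees.to_numpy()
    positive = degrees[degrees >= 1]
    if positive.size < 20:
        raise ValueError("need at least 20 nodes with degree >= 1")
    return fit_power_law(positive, n_bootstraps=n_bootstraps, seed=seed)
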