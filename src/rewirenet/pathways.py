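"""Gene-set enrichment, pathway co-membership and network relevance scoring.

Disease genes are tested against a GMT collection with one-sided
hypergeometric over-representation (BH-adjusted across sets).  For every
enriched pathway the enriched disease genes are mapped into the disease
and control stage networks and their induced sub-graph yields the
per-gene connectivity phi (mean induced degree) and the sub-network
density delta in both conditions.  Pathways sharing a statistically
significant number of member genes (one-sided Fisher's exact test,
BH-adjusted by default) are connected in a co-membership (cross-talk)
graph; a pathway's PC is its degree there.  The relevance score

    R = log10(PC) + (phi_d - phi_c) / phi_d + (delta_d - delta_c) / delta_d

ranks pathways by how much denser and more connected their disease genes
are in the disease network than in the control network, weighted by how
widely the pathway co-members with others.  Connected components of the
co-membership graph form integrated pathway clusters (IPCs), and a
gene's cross-talk frequency cf is the number of retained (optionally
signalling-tagged) pathways containing it.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import StageNetwork
from .rewiring import DiseaseGeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "enrich",
    "pathway_subnetwork_properties",
    "CrosstalkGraph",
    "pathway_connectivity",
    "r_score",
    "crosstalk_frequency",
    "hub_gene",
    "ipc_clusters",
    "score_pathways",
]


@dataclass
class GeneSetCollection:
    """Named gene sets filtered to a background universe."""

    sets: dict[str, list[str]]
    universe: list[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        uni = set(self.universe)
        filtered = {}
        for name, genes in self.sets.items():
            keep = [g for g in genes if g in uni]
            dropped = len(genes) - len(keep)
            if dropped:
                logger.info("set %s: dropped %d genes outside the universe", name, dropped)
            filtered[name] = keep
        self.sets = filtered

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_gmt(cls, path, universe: list[str]) -> "GeneSetCollection":
        from .io import read_gmt
        return cls(read_gmt(path), universe)

    def signalling_names(self, tags: list[str] | None = None) -> set[str]:
        """Pathways treated as signalling: an explicit tag list, or any
        name containing 'signal' (case-insensitive)."""
        if tags is not None:
            return set(tags) & set(self.sets)
        return {n for n in self.sets if "signal" in n.lower()}


# ---------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------

def enrich(genes: DiseaseGeneSet | set[str], collection: GeneSetCollection,
           adj_alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of the disease genes in each set.

    One-sided tail P(X >= overlap) with X ~ Hypergeom(|universe|, |set|,
    |zeta|); BH across sets.  Returns all sets with their overlap count,
    p, adj_p and an ``enriched`` flag (adj_p < adj_alpha and overlap >= 1).
    """
    zeta = genes.genes if isinstance(genes, DiseaseGeneSet) else set(genes)
    uni = set(collection.universe)
    zeta_u = zeta & uni
    if not zeta_u:
        raise ValueError("disease gene set does not overlap the universe")
    M = len(uni)
    n_draw = len(zeta_u)
    names, ns, ps = [], [], []
    for name, members in collection.sets.items():
        k_set = len(set(members))
        overlap = len(set(members) & zeta_u)
        # P(X >= overlap)
        p = stats.hypergeom.sf(overlap - 1, M, k_set, n_draw) if k_set else 1.0
        names.append(name)
        ns.append(overlap)
        ps.append(float(p))
    adj = multipletests(ps, method="fdr_bh")[1] if names else np.array([])
    out = pd.DataFrame({"pathway": names, "n": ns, "enrich_p": ps, "enrich_adj_p": adj})
    out["enriched"] = (out["enrich_adj_p"] < adj_alpha) & (out["n"] >= 1)
    return out


# ---------------------------------------------------------------------
# induced sub-network properties
# ---------------------------------------------------------------------

def _induced_stats(genes: list[str], net: StageNetwork) -> tuple[float, float, float]:
    """(phi, delta, transitivity) of the sub-graph induced by mapped genes."""
    mapped = [g for g in genes if g in set(net.genes)]
    k = len(mapped)
    if k < 2:
        return 0.0, 0.0, 0.0
    sub = net.induced_adjacency(mapped)
    deg = sub.sum(axis=1)
    phi = float(deg.mean())
    delta = float(sub.sum()) / (k * (k - 1))
    g = nx.from_numpy_array(sub)
    return phi, delta, float(nx.transitivity(g))


def pathway_subnetwork_properties(pathway_genes: list[str], disease: StageNetwork,
                                  control: StageNetwork) -> dict:
    """Induced sub-network properties of a pathway's (enriched) disease genes.

    phi is the mean within-sub-graph degree, delta the sub-graph density,
    in each network; im_clustering is the disease sub-graph transitivity.
    filter_pass requires n > 5 mapped genes, delta_d > 0 and
    im_clustering > 0.
    """
    unmapped = [g for g in pathway_genes if g not in set(disease.genes)]
    if unmapped:
        logger.debug("%d pathway genes not in the network universe", len(unmapped))
    phi_d, delta_d, im_clust = _induced_stats(pathway_genes, disease)
    phi_c, delta_c, _ = _induced_stats(pathway_genes, control)
    n = len([g for g in pathway_genes if g in set(disease.genes)])
    return {"n_mapped": n, "phi_d": phi_d, "phi_c": phi_c,
            "delta_d": delta_d, "delta_c": delta_c,
            "im_clustering": im_clust,
            "filter_pass": bool(n > 5 and delta_d > 0 and im_clust > 0)}


# ---------------------------------------------------------------------
# co-membership (cross-talk) graph
# ---------------------------------------------------------------------

@dataclass
class CrosstalkGraph:
    """Pathway co-membership graph with per-pair Fisher statistics."""

    nodes: list[str]
    edges: pd.DataFrame  # retained pairs: pathway_a, pathway_b, shared, fisher_p, adj_p
    memberships: dict[str, set[str]]
    signalling: set[str] = field(default_factory=set)
    pairs: pd.DataFrame | None = None  # every tested pair, kept or not

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(zip(self.edges["pathway_a"], self.edges["pathway_b"]))
        return g

    def pc(self, pathway: str) -> int:
        """Number of pathways significantly co-membered with ``pathway``."""
        e = self.edges
        return int(((e["pathway_a"] == pathway) | (e["pathway_b"] == pathway)).sum())

    def sig_pc(self, pathway: str) -> int:
        """Co-membership degree counted over signalling pathways only."""
        e = self.edges
        mask_a = (e["pathway_a"] == pathway) & e["pathway_b"].isin(self.signalling)
        mask_b = (e["pathway_b"] == pathway) & e["pathway_a"].isin(self.signalling)
        return int((mask_a | mask_b).sum())


def pathway_connectivity(pathways: dict[str, list[str]], universe: list[str],
                         fisher_alpha: float = 0.05,
                         multiplicity: str = "BH",
                         signalling: set[str] | None = None) -> CrosstalkGraph:
    """Connect pathway pairs sharing a significant number of member genes.

    For each pair a 2x2 one-sided Fisher's exact test asks whether
    membership in set A is enriched among members of set B over the gene
    universe.  An edge is kept iff the (BH-adjusted, unless
    ``multiplicity='raw'``) p-value is below ``fisher_alpha`` and at
    least one gene is shared.
    """
    names = [n for n in pathways if pathways[n]]
    if len(names) < 2:
        return CrosstalkGraph(nodes=names, memberships={n: set(pathways[n]) for n in names},
                              edges=pd.DataFrame(columns=["pathway_a", "pathway_b",
                                                          "shared", "fisher_p", "adj_p"]),
                              signalling=signalling or set())
    uni = set(universe)
    members = {n: set(pathways[n]) & uni for n in names}
    M = len(uni)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sa, sb = members[a], members[b]
            if not sa or not sb:
                continue
            shared = len(sa & sb)
            # one-sided Fisher == hypergeometric tail P(X >= shared)
            p = float(stats.hypergeom.sf(shared - 1, M, len(sa), len(sb)))
            rows.append((a, b, shared, p))
    df = pd.DataFrame(rows, columns=["pathway_a", "pathway_b", "shared", "fisher_p"])
    if multiplicity.upper() == "BH" and len(df):
        df["adj_p"] = multipletests(df["fisher_p"], method="fdr_bh")[1]
    else:
        df["adj_p"] = df["fisher_p"]
    kept = df[(df["adj_p"] < fisher_alpha) & (df["shared"] >= 1)].reset_index(drop=True)
    return CrosstalkGraph(nodes=names, edges=kept, memberships=members,
                          signalling=(signalling or set()) & set(names),
                          pairs=df)


def ipc_clusters(graph: CrosstalkGraph, net: StageNetwork | None = None) -> pd.DataFrame:
    """Integrated pathway clusters: connected components of the cross-talk graph.

    Each cluster row lists its member pathways and union gene set; when a
    stage network is supplied, the density and global transitivity of the
    union gene set's induced sub-graph are reported too.
    """
    components = list(nx.connected_components(graph.graph()))
    rows = []
    for i, comp in enumerate(sorted(components, key=lambda c: sorted(c)[0])):
        members = sorted(comp)
        union_genes = sorted(set().union(*(graph.memberships[m] for m in members)))
        row = {"ipc_id": f"IPC{i:03d}", "pathways": ";".join(members),
               "n_pathways": len(members), "n_genes": len(union_genes),
               "genes": ";".join(union_genes)}
        if net is not None and len(union_genes) >= 2:
            phi, delta, clust = _induced_stats(union_genes, net)
            row.update({"density": delta, "clustering": clust})
        rows.append(row)
    return pd.DataFrame(rows)


def crosstalk_frequency(graph: CrosstalkGraph, signalling_only: bool = True) -> pd.Series:
    """cf per gene: the number of retained pathways containing it.

    With ``signalling_only`` the count runs over the signalling-tagged
    pathways in the graph (when any are tagged), otherwise over all nodes.
    """
    names = graph.signalling if (signalling_only and graph.signalling) else set(graph.nodes)
    counts: dict[str, int] = {}
    for n in names:
        for g in graph.memberships[n]:
            counts[g] = counts.get(g, 0) + 1
    return pd.Series(counts, name="cf").sort_index()


# ---------------------------------------------------------------------
# R-score and hub genes
# ---------------------------------------------------------------------

def r_score(pc: int, phi_d: float, phi_c: float, delta_d: float, delta_c: float,
            log_base: float = 10.0) -> tuple[float, str]:
    """Pathway relevance score; returns (value, reason).

    R = log(PC) + (phi_d - phi_c)/phi_d + (delta_d - delta_c)/delta_d.
    Undefined (NaN with a reason code) when PC < 1, phi_d <= 0 or
    delta_d <= 0.
    """
    if pc < 1:
        return float("nan"), "pc_zero"
    if phi_d <= 0:
        return float("nan"), "phi_d_zero"
    if delta_d <= 0:
        return float("nan"), "delta_d_zero"
    val = (math.log(pc, log_base)
           + (phi_d - phi_c) / phi_d
           + (delta_d - delta_c) / delta_d)
    return float(val), "ok"


def hub_gene(pathway_genes: list[str], disease: StageNetwork) -> str | None:
    """Most connected gene within the pathway's induced disease sub-graph.

    Ties are broken by higher total network degree, then by lexicographic
    gene id.  Returns None when the induced sub-graph has no edges.
    """
    mapped = sorted(g for g in pathway_genes if g in set(disease.genes))
    if not mapped:
        return None
    sub = disease.induced_adjacency(mapped)
    deg = sub.sum(axis=1)
    if deg.max() == 0:
        return None
    total = disease.degrees
    best = sorted(range(len(mapped)),
                  key=lambda i: (-deg[i], -int(total[mapped[i]]), mapped[i]))[0]
    return mapped[best]


# ---------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------

def score_pathways(genes: DiseaseGeneSet | set[str], collection: GeneSetCollection,
                   disease: StageNetwork, control: StageNetwork,
                   enrich_alpha: float = 0.05, fisher_alpha: float = 0.05,
                   signalling_tags: list[str] | None = None,
                   log_base: float = 10.0) -> tuple[pd.DataFrame, CrosstalkGraph]:
    """Full pathway scoring for one disease stage.

    Enriches the disease genes against the collection, computes induced
    sub-network properties of the enriched disease genes per pathway,
    builds the co-membership graph over the enriched pathways (full
    member lists), and assembles the per-pathway score table with PC,
    R-score and hub gene.
    """
    zeta = genes.genes if isinstance(genes, DiseaseGeneSet) else set(genes)
    table = enrich(zeta, collection, adj_alpha=enrich_alpha)
    enriched = table[table["enriched"]]["pathway"].tolist()
    if not enriched:
        warnings.warn("no enriched pathways", stacklevel=2)
    graph = pathway_connectivity({n: collection.sets[n] for n in enriched},
                                 collection.universe, fisher_alpha=fisher_alpha,
                                 signalling=collection.signalling_names(signalling_tags))
    records = []
    for _, row in table.iterrows():
        name = row["pathway"]
        rec = {"pathway": name, "n": int(row["n"]),
               "enrich_p": row["enrich_p"], "enrich_adj_p": row["enrich_adj_p"],
               "enriched": bool(row["enriched"])}
        if row["enriched"]:
            sub_genes = sorted(set(collection.sets[name]) & zeta)
            props = pathway_subnetwork_properties(sub_genes, disease, control)
            pc = graph.pc(name)
            score, reason = r_score(pc, props["phi_d"], props["phi_c"],
                                    props["delta_d"], props["delta_c"],
                                    log_base=log_base)
            rec.update({"phi_d": props["phi_d"], "phi_c": props["phi_c"],
                        "delta_d": props["delta_d"], "delta_c": props["delta_c"],
                        "im_clustering": props["im_clustering"],
                        "filter_pass": props["filter_pass"],
                        "pc": pc, "sig_pc": graph.sig_pc(name),
                        "r_score": score, "r_reason": reason,
                        "hub_gene": hub_gene(sub_genes, disease)})
        else:
            rec.update({"phi_d": np.nan, "phi_c": np.nan, "delta_d": np.nan,
                        "delta_c": np.nan, "im_clustering": np.nan,
                        "filter_pass": False, "pc": 0, "sig_pc": 0,
                        "r_score": np.nan, "r_reason": "not_enriched",
                        "hub_gene": None})
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    out = out.sort_values(["r_score", "pathway"], ascending=[False, True],
                          na_position="last").reset_index(drop=True)
    out.attrs["log_base"] = log_base
    return out, graph
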