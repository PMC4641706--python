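"""Differential connectivity, edge rewiring and disease-gene selection.

A gene's differential connectivity is the signed change of its
thresholded-network degree between a disease-stage network and the
control network, dK = K_d - K_c.  Its significance is assessed with a
label-permutation null: sample labels are shuffled between the two
groups (sizes preserved), both networks are rebuilt with identical
thresholds, and the permutation p-value of gene i is the fraction of
permutations in which |dK#_i| strictly exceeds the observed |dK_i|.

Rewiring is finer than dK: per gene the neighbour sets of the two
networks are diffed into edges gained (EG, unique to disease), lost (EL,
unique to control), and common, with dK = EG - EL as an identity.  A
gene is called *rewired* when it is a significant DC gene and its EG
exceeds a novel-connectivity threshold, and the per-stage disease gene
set is (rewired union significantly up-regulated) minus significantly
down-regulated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionDataset
from .network import StageNetwork, binary_adjacency

logger = logging.getLogger(__name__)

__all__ = [
    "differential_connectivity",
    "permutation_dc_test",
    "edge_rewiring",
    "flag_rewired",
    "DiseaseGeneSet",
    "select_disease_genes",
    "differential_correlation_strength",
]


def _aligned_adjacency(control: StageNetwork, disease: StageNetwork):
    """Boolean adjacencies of both networks over the union gene universe."""
    gc, gd = set(control.genes), set(disease.genes)
    if not gc & gd:
        raise ValueError("networks share no genes")
    universe = sorted(gc | gd)
    pos = {g: i for i, g in enumerate(universe)}
    n = len(universe)

    def expand(net: StageNetwork) -> np.ndarray:
        out = np.zeros((n, n), dtype=bool)
        ix = np.array([pos[g] for g in net.genes], dtype=int)
        out[np.ix_(ix, ix)] = net.adjacency
        return out

    return universe, expand(control), expand(disease)


def differential_connectivity(control: StageNetwork, disease: StageNetwork) -> pd.DataFrame:
    """Per-gene degrees and dK = k_disease - k_control over the union universe.

    A gene absent from one network has degree 0 there.
    """
    universe, ac, ad = _aligned_adjacency(control, disease)
    kc = ac.sum(axis=1)
    kd = ad.sum(axis=1)
    return pd.DataFrame({"gene_id": universe,
                         "k_control": kc, "k_disease": kd,
                         "dK": kd - kc})


def edge_rewiring(control: StageNetwork, disease: StageNetwork,
                  keep_partners: bool = False) -> pd.DataFrame:
    """Per-gene gained (EG), lost (EL) and common edge counts.

    EG counts neighbours unique to the disease network, EL neighbours
    unique to the control network; dK = EG - EL always holds.
    """
    universe, ac, ad = _aligned_adjacency(control, disease)
    gained = ad & ~ac
    lost = ac & ~ad
    both = ac & ad
    out = pd.DataFrame({"gene_id": universe,
                        "eg": gained.sum(axis=1),
                        "el": lost.sum(axis=1),
                        "common": both.sum(axis=1)})
    if keep_partners:
        uni = np.asarray(universe)
        out["gained_partners"] = [",".join(sorted(uni[gained[i]])) for i in range(len(universe))]
        out["lost_partners"] = [",".join(sorted(uni[lost[i]])) for i in range(len(universe))]
    return out


def permutation_dc_test(data: ExpressionDataset, control_stage: str,
                        disease_stage: str, t: int = 1000,
                        seed: int | None = None, dc_alpha: float = 0.01,
                        r_min: float = 0.5, fdr_max: float = 0.05,
                        absolute: bool = False,
                        smoothed: bool = False) -> pd.DataFrame:
    """Permutation test of differential connectivity between two stages.

    For each of ``t`` permutations the sample labels of the two groups
    are shuffled (group sizes preserved), both networks are rebuilt with
    the identical edge rule, and dK# is recorded per gene.  The raw
    permutation p-value uses the strict inequality
    ``perm_p_i = #{|dK#_i| > |dK_i|} / t``; Benjamini-Hochberg adjustment
    is applied across genes and ``significant`` flags adj_p < dc_alpha.
    ``smoothed=True`` switches to the add-one estimate (1 + count)/(1 + t),
    which can never be exactly zero.

    Deterministic given ``seed``.
    """
    if t < 100:
        warnings.warn("t < 100 permutations gives p-value resolution too coarse "
                      "for BH selection at small alpha", stacklevel=2)
    xc = data.stage_matrix(control_stage)
    xd = data.stage_matrix(disease_stage)
    nc, nd = xc.shape[1], xd.shape[1]
    if nc <= 10 or nd <= 10:
        raise ValueError("both groups need more than 10 samples for the "
                         "correlation edge test")
    kc = binary_adjacency(xc, r_min, fdr_max, absolute).sum(axis=1)
    kd = binary_adjacency(xd, r_min, fdr_max, absolute).sum(axis=1)
    dk = kd - kc
    abs_dk = np.abs(dk)

    combined = np.concatenate([xc, xd], axis=1)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(data.genes), dtype=int)
    for _ in range(t):
        perm = rng.permutation(nc + nd)
        kc_p = binary_adjacency(combined[:, perm[:nc]], r_min, fdr_max, absolute).sum(axis=1)
        kd_p = binary_adjacency(combined[:, perm[nc:]], r_min, fdr_max, absolute).sum(axis=1)
        exceed += np.abs(kd_p - kc_p) > abs_dk
    perm_p = (1.0 + exceed) / (1.0 + t) if smoothed else exceed / t
    adj_p = multipletests(perm_p, method="fdr_bh")[1]
    out = pd.DataFrame({"gene_id": data.genes,
                        "k_control": kc, "k_disease": kd, "dK": dk,
                        "perm_p": perm_p, "adj_p": adj_p,
                        "significant": adj_p < dc_alpha})
    out.attrs["t"] = t
    out.attrs["dc_alpha"] = dc_alpha
    out.attrs["smoothed"] = smoothed
    return out


def fit_eg_threshold(eg: np.ndarray, tail_prob: float = 0.05) -> int:
    """Data-driven novel-connectivity threshold from the EG distribution.

    Fits a discrete power law to the positive EG values and returns the
    smallest EG whose estimated unconditional tail probability under the
    fit is below ``tail_prob``.
    """
    from .powerlaw import fit_power_law, powerlaw_survival

    positive = eg[eg > 0]
    fit = fit_power_law(positive, n_bootstraps=0)
    p_tail = fit.n_tail / positive.size
    for x in range(int(fit.x_min), int(positive.max()) + 2):
        if p_tail * powerlaw_survival(fit.alpha, fit.x_min, x) < tail_prob:
            return x
    return int(positive.max()) + 1


def flag_rewired(rw: pd.DataFrame, dc: pd.DataFrame,
                 dc_select_alpha: float = 0.05,
                 eg_threshold: int | str = 70) -> pd.DataFrame:
    """Flag genes as rewired: DC adj_p <= dc_select_alpha and EG > threshold.

    ``eg_threshold`` may be a number or ``"fit"``, in which case the
    threshold is derived from a power-law fit to the positive EG
    distribution (falling back to the fixed default 70, with a warning,
    when fewer than 20 genes have EG > 0).  The threshold actually used
    is recorded in ``attrs['eg_threshold']``.
    """
    merged = rw.merge(dc[["gene_id", "adj_p", "dK"]], on="gene_id", how="inner")
    if len(merged) != len(rw) or len(merged) != len(dc):
        raise ValueError("rewiring and DC tables are not aligned on genes")
    eg = merged["eg"].to_numpy()
    if eg_threshold == "fit":
        if (eg > 0).sum() < 20:
            warnings.warn("fewer than 20 genes with EG > 0; falling back to "
                          "fixed EG threshold 70", stacklevel=2)
            threshold = 70
        else:
            try:
                threshold = fit_eg_threshold(eg)
            except ValueError as exc:  # degenerate EG support
                warnings.warn(f"EG distribution not fittable ({exc}); falling "
                              "back to fixed EG threshold 70", stacklevel=2)
                threshold = 70
            else:
                logger.info("fitted EG threshold: %d", threshold)
    else:
        threshold = int(eg_threshold)
    merged["rewired"] = (merged["adj_p"] <= dc_select_alpha) & (eg > threshold)
    merged.attrs.update(rw.attrs)
    merged.attrs["eg_threshold"] = threshold
    merged.attrs["dc_select_alpha"] = dc_select_alpha
    return merged


@dataclass
class DiseaseGeneSet:
    """Per-stage disease genes: (rewired | up-regulated) minus down-regulated."""

    stage: str
    genes: set[str]
    provenance: dict[str, str]  # gene -> rewired | upregulated | both
    n_rewired_not_de: int = 0
    fraction_rewired_not_de: float = float("nan")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.genes)
        return pd.DataFrame({"gene_id": rows,
                             "provenance": [self.provenance[g] for g in rows],
                             "stage": self.stage})


def select_disease_genes(rw: pd.DataFrame, de: pd.DataFrame, stage: str) -> DiseaseGeneSet:
    """Assemble the disease gene set of a stage.

    zeta = (rewired union up-regulated) minus down-regulated, with
    per-gene provenance.  Also reports how many of the rewired genes are
    not differentially expressed at all (neither up nor down).
    """
    if "rewired" not in rw.columns:
        raise ValueError("rewiring table has no 'rewired' flags; run flag_rewired first")
    rewired = set(rw.loc[rw["rewired"], "gene_id"])
    up = set(de.loc[de["flag"] == "up", "gene_id"])
    down = set(de.loc[de["flag"] == "down", "gene_id"])
    genes = (rewired | up) - down
    provenance = {}
    for g in genes:
        if g in rewired and g in up:
            provenance[g] = "both"
        elif g in rewired:
            provenance[g] = "rewired"
        else:
            provenance[g] = "upregulated"
    not_de = rewired - up - down
    frac = len(not_de) / len(rewired) if rewired else float("nan")
    return DiseaseGeneSet(stage=stage, genes=genes, provenance=provenance,
                          n_rewired_not_de=len(not_de),
                          fraction_rewired_not_de=frac)


def differential_correlation_strength(control: StageNetwork, disease: StageNetwork,
                                      genes: DiseaseGeneSet | set[str],
                                      bin_width: float = 0.1) -> tuple[np.ndarray, pd.DataFrame]:
    """r_d - r_c for every disease edge between disease genes.

    The control correlation is read from the control r-matrix regardless
    of whether that pair passes the control thresholds.  Returns the raw
    differences and a histogram with bins of width ``bin_width`` on
    [-2, 2].
    """
    zeta = genes.genes if isinstance(genes, DiseaseGeneSet) else set(genes)
    if not zeta:
        warnings.warn("empty disease gene set: no edges to compare", stacklevel=2)
        return np.array([]), pd.DataFrame({"bin_left": [], "bin_right": [], "count": []})
    shared = sorted((set(disease.genes) & set(control.genes)) & zeta)
    pos_d = {g: i for i, g in enumerate(disease.genes)}
    pos_c = {g: i for i, g in enumerate(control.genes)}
    diffs = []
    for a_i, ga in enumerate(shared):
        for gb in shared[a_i + 1:]:
            i, j = pos_d[ga], pos_d[gb]
            if disease.adjacency[i, j]:
                diffs.append(disease.r_matrix[i, j] - control.r_matrix[pos_c[ga], pos_c[gb]])
    values = np.asarray(diffs, dtype=float)
    edges = np.round(np.arange(-2.0, 2.0 + bin_width / 2, bin_width), 10)
    counts, _ = np.histogram(values, bins=edges)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    return values, hist
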