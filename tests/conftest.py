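import numpy as np
import pandas as pd
import pytest

from rewirenet import (SimulationConfig, StageNetwork, build_network,
                       differential_expression, edge_rewiring, flag_rewired,
                       permutation_dc_test, select_disease_genes, simulate_dataset)

STANDARD_SEED = 20250915


def make_network(adj: np.ndarray, stage: str = "X", genes: list[str] | None = None,
                 r: np.ndarray | None = None) -> StageNetwork:
    """Wrap a boolean adjacency matrix as a StageNetwork for graph-level tests."""
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    genes = genes or [f"g{i:03d}" for i in range(n)]
    r_matrix = r if r is not None else adj.astype(float) * 0.9
    return StageNetwork(stage=stage, n_samples=100, genes=genes,
                        r_matrix=r_matrix, p_matrix=np.where(adj, 0.0, 1.0),
                        fdr_matrix=np.where(adj, 0.0, 1.0), adjacency=adj)


def random_adjacency(rng: np.random.Generator, n: int, p: float = 0.4) -> np.ndarray:
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    return adj | adj.T


@pytest.fixture(scope="session")
def standard_sim():
    """The standard 4-stage simulation used for recovery checks."""
    cfg = SimulationConfig(seed=STANDARD_SEED)
    data, truth = simulate_dataset(cfg)
    return cfg, data, truth


@pytest.fixture(scope="session")
def standard_analysis(standard_sim):
    """Full rewiring analysis of the standard simulation's CM stage."""
    cfg, data, truth = standard_sim
    control = build_network(data, "N")
    disease = build_network(data, "CM")
    dc = permutation_dc_test(data, "N", "CM", t=200, seed=STANDARD_SEED + 1)
    rw = flag_rewired(edge_rewiring(control, disease), dc,
                      eg_threshold=cfg.module_size // 2)
    de = differential_expression(data, "CM")
    zeta = select_disease_genes(rw, de, "CM")
    return {"config": cfg, "data": data, "truth": truth, "control": control,
            "disease": disease, "dc": dc, "rw": rw, "de": de, "zeta": zeta}


@pytest.fixture(scope="session")
def small_sim():
    """Small 2-stage simulation for fast unit tests."""
    cfg = SimulationConfig(n_genes=200, stages=("N", "CM"), samples_per_stage=100,
                           n_modules=4, module_size=20, n_rewired_genes=12,
                           n_de_genes=10, n_decoy_sets=3, seed=3)
    data, truth = simulate_dataset(cfg)
    return cfg, data, truth
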