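"""Synthetic multi-stage expression data with known ground truth.

The generator plants three orthogonal mechanisms on a shared gene
universe so that every downstream stage of the pipeline has a
parameter-recovery test surface:

* **co-expression modules** — blocks of genes driven by a shared latent
  factor, so that any two same-module genes have expected Pearson
  correlation ``c`` (``within_module_correlation``);
* **rewiring** — genes that are unattached noise in the control stage
  and join a module in every disease stage (edge gain without any mean
  change);
* **differential expression** — noise genes whose mean is shifted by
  ``+/- de_log_fc`` in the disease stages (mean change without any
  co-expression change).

Under a single-factor block model a module gene is ``lambda * f + eps``
with ``f ~ N(0,1)`` per sample, ``eps ~ N(0, noise_sd^2)`` and
``lambda = sqrt(c / (1 - c)) * noise_sd``, which gives the pairwise
correlation ``lambda^2 / (lambda^2 + noise_sd^2) = c`` exactly in
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionDataset
from . import io as rio

__all__ = ["SimulationConfig", "GroundTruth", "simulate_dataset", "write_ground_truth_gmt"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-structure simulation.

    The first entry of ``stages`` is the control stage.  Rewired genes
    join their target module in every disease stage; DE genes are
    shifted in every disease stage.
    """

    n_genes: int = 1200
    stages: tuple[str, ...] = ("N", "CnM", "CM", "LN")
    samples_per_stage: dict[str, int] | int = 100
    n_modules: int = 10
    module_size: int = 20
    within_module_correlation: float = 0.8
    n_rewired_genes: int = 60
    n_de_genes: int = 40
    de_log_fc: float = 1.5
    de_down_fraction: float = 0.25
    noise_sd: float = 1.0
    baseline: float = 8.0
    set_overlap: int = 10
    n_decoy_sets: int = 10
    seed: int = 0

    def samples_for(self, stage: str) -> int:
        if isinstance(self.samples_per_stage, int):
            return self.samples_per_stage
        return self.samples_per_stage[stage]

    def validate(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("invariant violated: n_modules * module_size <= n_genes")
        if not (0.0 < self.within_module_correlation < 1.0):
            raise ValueError("invariant violated: within_module_correlation in (0, 1) "
                             "(use simulate with c=0 via a zero-module config instead)")
        if len(self.stages) < 2:
            raise ValueError("invariant violated: need a control stage and >= 1 disease stage")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("invariant violated: duplicate stage names")
        for s in self.stages:
            if self.samples_for(s) < 10:
                raise ValueError(f"invariant violated: stage {s!r} has < 10 samples "
                                 "(correlation tests require n > 10)")
        pool = self.n_genes - self.n_modules * self.module_size
        if self.n_rewired_genes + self.n_de_genes > pool:
            raise ValueError("invariant violated: rewired + DE genes exceed the "
                             "non-module gene pool")
        if self.noise_sd <= 0:
            raise ValueError("invariant violated: noise_sd must be positive")
        if not (0.0 <= self.de_down_fraction <= 1.0):
            raise ValueError("invariant violated: de_down_fraction in [0, 1]")
        if self.set_overlap >= self.module_size:
            raise ValueError("invariant violated: set_overlap must be < module_size")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    module_assignment: dict[str, dict[str, int | None]]
    rewired_genes: set[str]
    de_genes: dict[str, dict[str, float]]  # gene -> stage -> true log fold-change
    planted_gene_sets: dict[str, list[str]]
    set_flags: dict[str, str] = field(default_factory=dict)  # name -> planted | decoy

    @property
    def de_gene_ids(self) -> set[str]:
        return set(self.de_genes)


def simulate_dataset(config: SimulationConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate a multi-stage expression dataset with planted structure.

    Deterministic given ``config.seed``: the same configuration always
    yields bit-identical matrices.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    n_member = config.n_modules * config.module_size
    control = config.stages[0]
    disease_stages = list(config.stages[1:])

    # control module assignment: first n_member genes in blocks
    control_module = {g: (i // config.module_size if i < n_member else None)
                      for i, g in enumerate(genes)}

    # rewired and DE genes from the non-module pool (orthogonal mechanisms)
    pool = genes[n_member:]
    pool_pick = rng.permutation(len(pool))
    rewired = [pool[i] for i in pool_pick[:config.n_rewired_genes]]
    de = [pool[i] for i in pool_pick[config.n_rewired_genes:
                                     config.n_rewired_genes + config.n_de_genes]]

    # balanced module targets: rewired gene j joins module j mod n_modules
    target_module = {g: j % config.n_modules for j, g in enumerate(rewired)}

    n_down = int(round(config.de_down_fraction * len(de)))
    de_sign = {g: (-1.0 if j < n_down else 1.0) for j, g in enumerate(de)}

    module_assignment: dict[str, dict[str, int | None]] = {control: dict(control_module)}
    for s in disease_stages:
        assign = dict(control_module)
        for g in rewired:
            assign[g] = target_module[g]
        module_assignment[s] = assign

    lam = np.sqrt(config.within_module_correlation /
                  (1.0 - config.within_module_correlation)) * config.noise_sd

    columns: list[str] = []
    stage_of: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    gene_index = {g: i for i, g in enumerate(genes)}
    for s in config.stages:
        n_s = config.samples_for(s)
        names = [f"{s}_{i:03d}" for i in range(n_s)]
        columns.extend(names)
        for nm in names:
            stage_of[nm] = s
        factors = rng.standard_normal((config.n_modules, n_s))
        eps = rng.standard_normal((config.n_genes, n_s)) * config.noise_sd
        x = eps
        assign = module_assignment[s]
        loading = np.zeros(config.n_genes)
        factor_row = np.zeros(config.n_genes, dtype=int)
        for g, m in assign.items():
            if m is not None:
                i = gene_index[g]
                loading[i] = lam
                factor_row[i] = m
        x = x + loading[:, None] * factors[factor_row, :]
        if s != control:
            for g in de:
                x[gene_index[g], :] += de_sign[g] * config.de_log_fc
        blocks.append(x)

    values = np.concatenate(blocks, axis=1) + config.baseline
    expr = pd.DataFrame(values, index=genes, columns=columns)
    data = ExpressionDataset(expr, pd.Series(stage_of), control_stage=control)

    de_genes = {g: {s: de_sign[g] * config.de_log_fc for s in disease_stages} for g in de}

    # planted gene sets: disease-stage membership of each module, plus an
    # overlap slice from the next module so sets co-member each other
    ref_stage = disease_stages[0]
    members_by_module: dict[int, list[str]] = {m: [] for m in range(config.n_modules)}
    for g in genes:
        m = module_assignment[ref_stage][g]
        if m is not None:
            members_by_module[m].append(g)
    planted_sets: dict[str, list[str]] = {}
    set_flags: dict[str, str] = {}
    for m in range(config.n_modules):
        nxt = members_by_module[(m + 1) % config.n_modules]
        shared = [nxt[i] for i in rng.permutation(len(nxt))[:config.set_overlap]]
        members = members_by_module[m] + [g for g in shared if g not in members_by_module[m]]
        name = f"PLANTED_{m:02d}"
        planted_sets[name] = members
        set_flags[name] = "planted"

    signal = set(rewired) | set(de)
    decoy_pool = [g for g in genes if g not in signal]
    decoy_size = config.module_size + config.set_overlap
    for j in range(config.n_decoy_sets):
        pick = rng.permutation(len(decoy_pool))[:decoy_size]
        name = f"DECOY_{j:02d}"
        planted_sets[name] = [decoy_pool[i] for i in pick]
        set_flags[name] = "decoy"

    truth = GroundTruth(module_assignment=module_assignment,
                        rewired_genes=set(rewired),
                        de_genes=de_genes,
                        planted_gene_sets=planted_sets,
                        set_flags=set_flags)
    return data, truth


def write_ground_truth_gmt(truth: GroundTruth, path) -> None:
    """Write the planted and decoy gene sets of a simulation to GMT."""
    rio.write_gmt(truth.planted_gene_sets, path, descriptions=truth.set_flags)
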