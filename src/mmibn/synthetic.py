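"""Synthetic multimodal datasets with known ground truth.

Mimics the statistical shape of a TCGA-style cohort — thousands of genes by
hundreds of patients, sparse binary mutation calls, continuous expression
and methylation — with a small set of planted genes whose components carry a
real association with the binary outcome.  Continuous components are drawn
standard normal; both the MMI estimator and equal-frequency binning are
rank-based, so the marginal shape is immaterial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    Modality,
    ModalityMatrix,
    MultiOmicsDataset,
    OutcomeVector,
    assemble_dataset,
)
from .discretize import DiscretizedDataset

__all__ = [
    "PlantedEffect",
    "SyntheticSpec",
    "generate",
    "generate_bn_fixture",
    "lgg_like_spec",
]


@dataclass(frozen=True)
class PlantedEffect:
    """Association of one planted gene with the outcome.

    ``e_shift``/``m_shift`` move the class-1 mean of the E/M component by
    that many SDs; ``s_odds_ratio`` multiplies the class-1 mutation odds.
    """

    e_shift: float = 0.0
    m_shift: float = 0.0
    s_odds_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.e_shift < 0 or self.m_shift < 0:
            raise ValueError("shifts must be nonnegative")
        if self.s_odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    n_samples: int = 300
    n_genes: int = 500
    planted_effects: tuple[PlantedEffect, ...] = ()
    s_prevalence: float = 0.05
    outcome_balance: float = 0.5
    outcome_name: str = "tumor_status"
    # (source component, target component, coupling in [0,1)); components
    # are "<gene>_<S|E|M>" names over the generated gene universe
    inter_gene_edges: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4 or self.n_genes < 1:
            raise ValueError("need n_samples >= 4 and n_genes >= 1")
        if len(self.planted_effects) > self.n_genes:
            raise ValueError("more planted effects than genes")
        if not 0.0 < self.s_prevalence < 1.0:
            raise ValueError("s_prevalence must be in (0,1)")
        if not 0.0 < self.outcome_balance < 1.0:
            raise ValueError("outcome_balance must be in (0,1)")
        for src, tgt, rho in self.inter_gene_edges:
            if not 0.0 <= rho < 1.0:
                raise ValueError(f"coupling for {src}->{tgt} must be in [0,1)")

    @property
    def n_planted(self) -> int:
        return len(self.planted_effects)


def lgg_like_spec(seed: int = 0, n_planted: int = 10) -> SyntheticSpec:
    """Cohort preset shaped like the LGG/tumor-status analysis
    (273 patients x 4782 genes)."""
    return SyntheticSpec(
        n_samples=273,
        n_genes=4782,
        planted_effects=tuple(
            PlantedEffect(m_shift=1.5) if i % 2 == 0 else PlantedEffect(e_shift=1.5)
            for i in range(n_planted)
        ),
        seed=seed,
    )


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _parse_component(name: str, genes: Sequence[str]) -> tuple[str, Modality]:
    gene, _, mod = name.rpartition("_")
    if gene not in genes or mod not in ("S", "E", "M"):
        raise ValueError(f"unknown gene component {name!r}")
    return gene, Modality(mod)


def generate(spec: SyntheticSpec) -> tuple[MultiOmicsDataset, dict]:
    """Draw a dataset from the spec; returns (dataset, ground truth).

    Planted genes occupy the head of the gene list.  The ground-truth dict
    records their names, effect sizes and any component couplings so that
    downstream tests never re-derive what was planted.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    samples = [f"P{i:04d}" for i in range(1, spec.n_samples + 1)]
    n, g = spec.n_samples, spec.n_genes

    y = (rng.random(n) < spec.outcome_balance).astype(np.int8)
    E = rng.standard_normal((g, n))
    M = rng.standard_normal((g, n))
    p_s = np.full((g, n), spec.s_prevalence)

    planted = {}
    for i, eff in enumerate(spec.planted_effects):
        gene = genes[i]
        cls1 = y == 1
        E[i, cls1] += eff.e_shift
        M[i, cls1] += eff.m_shift
        if eff.s_odds_ratio != 1.0:
            odds = spec.s_prevalence / (1 - spec.s_prevalence) * eff.s_odds_ratio
            p_s[i, cls1] = odds / (1 + odds)
        planted[gene] = asdict(eff)
    S = (rng.random((g, n)) < p_s).astype(float)

    arrays = {Modality.S: S, Modality.E: E, Modality.M: M}
    gene_index = {gname: i for i, gname in enumerate(genes)}
    for src, tgt, rho in spec.inter_gene_edges:
        sg, smod = _parse_component(src, genes)
        tg, tmod = _parse_component(tgt, genes)
        latent = arrays[smod][gene_index[sg]]
        # center the driving component (S becomes +/- around its mean)
        z = latent - latent.mean()
        sd = z.std()
        z = z / sd if sd > 0 else z
        ti = gene_index[tg]
        if tmod.is_discrete:
            base = np.log(spec.s_prevalence / (1 - spec.s_prevalence))
            logit = base + 3.0 * rho * z
            arrays[tmod][ti] = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        else:
            arrays[tmod][ti] = np.sqrt(1 - rho**2) * arrays[tmod][ti] + rho * z

    mats = {
        m: ModalityMatrix(m, pd.DataFrame(arr, index=genes, columns=samples))
        for m, arr in arrays.items()
    }
    outcome = OutcomeVector(spec.outcome_name, samples, y)
    ds = assemble_dataset(mats[Modality.S], mats[Modality.E], mats[Modality.M], outcome)
    truth = {
        "planted_genes": planted,
        "inter_gene_edges": [list(e) for e in spec.inter_gene_edges],
        "spec": {
            **{
                k: v
                for k, v in asdict(spec).items()
                if k not in ("planted_effects", "inter_gene_edges")
            },
        },
    }
    return ds, truth


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2))


def generate_bn_fixture(
    dag: Sequence[tuple[str, str]],
    cpds: Mapping[str, Mapping],
    n: int,
    seed: int = 0,
) -> DiscretizedDataset:
    """Ancestral sampling from an explicit discrete network.

    ``cpds[var]`` must provide ``levels`` (cardinality), ``parents`` (name
    list, matching the dag) and ``probs``: a (q, levels) row-stochastic
    array over mixed-radix parent configurations in the listed parent order.
    """
    variables = list(cpds)
    var_set = set(variables)
    for u, v in dag:
        if u not in var_set or v not in var_set:
            raise ValueError(f"dag edge ({u!r}, {v!r}) references an unknown variable")
    parents = {v: list(cpds[v].get("parents", [])) for v in variables}
    for v in variables:
        dag_parents = sorted(u for u, w in dag if w == v)
        if sorted(parents[v]) != dag_parents:
            raise ValueError(f"cpd parents for {v!r} disagree with the dag")

    order = _topological_order(variables, dag)

    rng = np.random.default_rng(seed)
    levels = {v: int(cpds[v]["levels"]) for v in variables}
    probs = {}
    for v in variables:
        q = int(np.prod([levels[p] for p in parents[v]])) if parents[v] else 1
        tab = np.asarray(cpds[v]["probs"], dtype=float).reshape(q, levels[v])
        if (tab < 0).any() or not np.allclose(tab.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError(f"cpd for {v!r} is not row-stochastic")
        probs[v] = tab

    data = {v: np.empty(n, dtype=np.int64) for v in variables}
    for v in order:
        cfg_idx = np.zeros(n, dtype=np.int64)
        for p in parents[v]:
            cfg_idx = cfg_idx * levels[p] + data[p]
        cum = probs[v].cumsum(axis=1)
        u = rng.random(n)
        data[v] = (u[:, None] > cum[cfg_idx]).sum(axis=1)

    return DiscretizedDataset(
        variables=variables,
        cardinalities=[levels[v] for v in variables],
        data=np.vstack([data[v] for v in variables]),
        sample_ids=[f"R{i:05d}" for i in range(1, n + 1)],
    )


def _topological_order(
    variables: Sequence[str], dag: Sequence[tuple[str, str]]
) -> list[str]:
    children: dict[str, list[str]] = {v: [] for v in variables}
    indeg = {v: 0 for v in variables}
    for u, v in dag:
        children[u].append(v)
        indeg[v] += 1
    queue = [v for v in variables if indeg[v] == 0]
    order: list[str] = []
    while queue:
        v = queue.pop()
        order.append(v)
        for c in children[v]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != len(variables):
        raise ValueError("dag contains a cycle")
    return order
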