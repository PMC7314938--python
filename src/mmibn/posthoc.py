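"""Markov-neighborhood extraction and post-hoc significance statistics.

Once a network is learned, the neighborhood of the clinical outcome node
(nodes within one, optionally two, undirected steps) is the working
candidate set.  Each member gene component is then re-tested directly
against the outcome: continuous E/M components with a two-sample
Kolmogorov-Smirnov test, discrete S components with a two-sided Fisher
exact test.  S components whose mutation counts are tiny in both outcome
groups are flagged excluded rather than interpreted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .bn import BayesianNetworkModel
from .datamodel import Modality, MultiOmicsDataset

__all__ = [
    "MarkovNeighborhood",
    "PosthocRow",
    "PosthocReport",
    "extract_mn",
    "ks_two_sample",
    "fisher_exact_2x2",
    "posthoc_table",
]


@dataclass
class MarkovNeighborhood:
    center: str
    radius: int
    members: frozenset[str]
    induced_edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.center in self.members:
            raise ValueError("center cannot be its own neighbor")
        if self.radius not in (1, 2):
            raise ValueError("radius must be 1 or 2")


def extract_mn(
    model: BayesianNetworkModel, center: str, radius: int = 1
) -> MarkovNeighborhood:
    """Nodes within ``radius`` undirected steps of ``center``.

    The induced edge list carries every model edge whose endpoints both lie
    in members ∪ {center}, with its strength.
    """
    if center not in model.nodes:
        raise KeyError(f"unknown center node {center!r}")
    if radius not in (1, 2):
        raise ValueError("radius must be 1 or 2")
    adj = model.undirected_adjacency()
    members: set[str] = set()
    frontier = {center}
    for _ in range(radius):
        frontier = set().union(*(adj[n] for n in frontier)) - members - {center}
        members |= frontier
    keep = members | {center}
    induced = [
        (u, v, model.edge_strengths.get((u, v), float("nan")))
        for u, v in model.edges
        if u in keep and v in keep
    ]
    return MarkovNeighborhood(center, radius, frozenset(members), induced)


def ks_two_sample(x0: np.ndarray, x1: np.ndarray) -> tuple[float, float]:
    """Two-sample KS statistic with the asymptotic Kolmogorov p-value.

    D is the exact supremum ECDF gap; the p-value uses the Kolmogorov
    limiting distribution at effective size n0*n1/(n0+n1).
    """
    x0 = np.sort(np.asarray(x0, dtype=float))
    x1 = np.sort(np.asarray(x1, dtype=float))
    n0, n1 = x0.size, x1.size
    if n0 < 2 or n1 < 2:
        raise ValueError("each group needs at least 2 observations")
    grid = np.concatenate([x0, x1])
    cdf0 = np.searchsorted(x0, grid, side="right") / n0
    cdf1 = np.searchsorted(x1, grid, side="right") / n1
    d = float(np.abs(cdf0 - cdf1).max())
    n_eff = n0 * n1 / (n0 + n1)
    p = float(special.kolmogorov(math.sqrt(n_eff) * d))
    return d, min(max(p, np.finfo(float).tiny), 1.0)


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p: total hypergeometric mass of all tables
    with the observed margins that are no more probable than the observed
    one.  A zero margin makes every table equally (un)informative: p = 1."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table < 0).any() or not np.all(np.equal(np.mod(table, 1), 0)):
        raise ValueError("cell counts must be nonnegative integers")
    table = table.astype(np.int64)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; p defined as 1", UserWarning)
        return 1.0
    return float(min(stats.fisher_exact(table, alternative="two-sided")[1], 1.0))


@dataclass
class PosthocRow:
    variable: str
    gene: str
    modality: Modality
    edge_strength: float
    test: str  # "ks" | "fisher"
    p_value: float
    p_adjusted: float = float("nan")
    significant: bool = False
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class PosthocReport:
    """Per-member test results, ordered by descending edge strength."""

    center: str
    alpha: float
    rows: list[PosthocRow]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_component": [r.variable for r in self.rows],
                "edge_strength": [r.edge_strength for r in self.rows],
                "test": [r.test for r in self.rows],
                "p_value": [r.p_value for r in self.rows],
                "p_value_bh": [r.p_adjusted for r in self.rows],
                "significant": [r.significant for r in self.rows],
                "excluded": [r.excluded for r in self.rows],
                "exclusion_reason": [r.exclusion_reason for r in self.rows],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        # cosmetic rendering of near-1 p-values, mirroring report convention
        df["p_value"] = [
            "~1.0" if p >= 0.995 else format(p, ".4g") for p in df["p_value"]
        ]
        df.to_csv(path, sep="\t", index=False)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    m = pvals.size
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        rank = i + 1
        running = min(running, pvals[order[i]] * m / rank)
        adj[order[i]] = running
    return adj


def posthoc_table(
    ds: MultiOmicsDataset,
    mn: MarkovNeighborhood,
    alpha: float = 0.05,
    min_count: int = 5,
) -> PosthocReport:
    """Test every MN gene component against the dataset outcome.

    E/M members: KS test between the two outcome groups.  S members: Fisher
    exact on the mutation-presence x outcome 2x2 table; if the mutated
    sample count is below ``min_count`` in both groups the row is flagged
    excluded (too few events to interpret) and never marked significant.
    """
    y = ds.outcome.labels
    strengths = _member_strengths(mn)
    rows: list[PosthocRow] = []
    for member in sorted(mn.members):
        if member == ds.outcome.name:
            continue
        gene, _, mod_str = member.rpartition("_")
        if not gene or mod_str not in ("S", "E", "M") or gene not in ds.genes:
            raise KeyError(
                f"MN member {member!r} does not map to a dataset gene component"
            )
        mod = Modality(mod_str)
        vals = ds.component(gene, mod)
        excluded = False
        reason = ""
        if mod.is_discrete:
            mut = vals.astype(np.int64)
            table = np.array(
                [
                    [int(((y == 0) & (mut == 1)).sum()), int(((y == 0) & (mut == 0)).sum())],
                    [int(((y == 1) & (mut == 1)).sum()), int(((y == 1) & (mut == 0)).sum())],
                ]
            )
            p = fisher_exact_2x2(table)
            test = "fisher"
            mut_counts = table[:, 0]
            if (mut_counts < min_count).all():
                excluded = True
                reason = (
                    f"mutated-sample counts {mut_counts.tolist()} below "
                    f"{min_count} in both outcome groups"
                )
        else:
            _, p = ks_two_sample(vals[y == 0], vals[y == 1])
            test = "ks"
        rows.append(
            PosthocRow(
                variable=member,
                gene=gene,
                modality=mod,
                edge_strength=strengths.get(member, 0.0),
                test=test,
                p_value=p,
                excluded=excluded,
                exclusion_reason=reason,
            )
        )

    if rows:
        adj = _bh_adjust(np.array([r.p_value for r in rows]))
        for r, a in zip(rows, adj):
            r.p_adjusted = float(a)
            r.significant = bool(r.p_value < alpha and not r.excluded)
    rows.sort(key=lambda r: (-r.edge_strength, r.variable))
    return PosthocReport(center=mn.center, alpha=alpha, rows=rows)


def _member_strengths(mn: MarkovNeighborhood) -> dict[str, float]:
    """Strength attributed to each member: its edge to the center when one
    exists, otherwise the strongest induced edge touching it."""
    direct: dict[str, float] = {}
    incident: dict[str, float] = {}
    for u, v, s in mn.induced_edges:
        if math.isnan(s):
            s = 0.0
        for a, b in ((u, v), (v, u)):
            if b == mn.center:
                direct[a] = max(direct.get(a, -math.inf), s)
            incident[a] = max(incident.get(a, -math.inf), s)
    return {m: direct.get(m, incident.get(m, 0.0)) for m in mn.members}
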