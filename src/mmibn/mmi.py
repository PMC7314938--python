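"""Mixed-type mutual information estimation and gene ranking/selection.

The estimator is the k-nearest-neighbor mutual information estimator for
discrete-continuous mixtures: distances are max-norm across coordinates,
with the 0/1 indicator metric on discrete coordinates and absolute
difference on continuous ones.  For each point i,

    rho_i = k-th smallest joint distance to the other points,
    k~_i  = k if rho_i > 0, else the number of points at joint distance 0,
    n_x,i / n_y,i = numbers of points within rho_i in each marginal,

and the estimate (in nats) is

    mean_i[ psi(k~_i) - log(n_x,i) - log(n_y,i) ] + log n ,

where the marginal counts n_x,i and n_y,i include the point itself: points
strictly inside rho_i when rho_i > 0, points at distance exactly 0 when
rho_i = 0 (in which case k~_i also counts the point itself).  The k~ rule
makes the estimator well defined when discrete coordinates (or tied
continuous values) produce many zero distances; values can dip slightly
below zero for independent data, which is expected estimator fluctuation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma

from .datamodel import MultiOmicsDataset

logger = logging.getLogger(__name__)

__all__ = [
    "MMIConfig",
    "GeneRankTable",
    "SelectionResult",
    "mixed_mi",
    "rank_genes",
    "select_top_cdf",
    "select_by_threshold",
    "jaccard_index",
    "jaccard_curve",
]

#: modality flags used when a gene's (S, E, M) components form the X block
GENE_COMPONENT_DISCRETE = (True, False, False)


@dataclass(frozen=True)
class MMIConfig:
    """Estimator settings. ``k`` is the neighbor count (default 15)."""

    k: int = 15
    standardize_continuous: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")


def _standardize(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    if sd == 0.0 or not np.isfinite(sd):
        warnings.warn(
            "zero-variance continuous column treated as constant "
            "(contributes no distance)",
            UserWarning,
            stacklevel=3,
        )
        return np.zeros_like(col)
    return col / sd

def _row_max_dist(
    X: np.ndarray, discrete: np.ndarray, rows: np.ndarray
) -> np.ndarray:
    """Max-norm distances from the given rows to all points: (len(rows), n)."""
    n = X.shape[0]
    out = np.zeros((rows.size, n))
    for j in range(X.shape[1]):
        col = X[:, j]
        if discrete[j]:
            dj = (col[rows, None] != col[None, :]).astype(float)
        else:
            dj = np.abs(col[rows, None] - col[None, :])
        np.maximum(out, dj, out=out)
    return out


def mixed_mi(
    X: np.ndarray,
    y: np.ndarray,
    discrete: Sequence[bool],
    cfg: MMIConfig = MMIConfig(),
    y_discrete: bool = True,
) -> float:
    """Estimate I(X; y) in nats for a mixed-type X block and a y vector.

    Parameters
    ----------
    X : (n, d) array; columns flagged by ``discrete`` use the 0/1 indicator
        metric, the rest absolute difference (standardized to unit variance
        when ``cfg.standardize_continuous``).
    y : length-n vector; indicator metric when ``y_discrete`` (the default,
        matching a clinical outcome), absolute difference otherwise.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    n, d = X.shape
    discrete = np.asarray(discrete, dtype=bool)
    if discrete.shape != (d,):
        raise ValueError("discrete flags must match the number of X columns")
    if y.shape != (n,):
        raise ValueError("y length must match X rows")
    if cfg.k >= n:
        raise ValueError(f"k={cfg.k} must be < n={n}")

    if cfg.standardize_continuous and (~discrete).any():
        X = X.copy()
        for j in np.flatnonzero(~discrete):
            X[:, j] = _standardize(X[:, j])

    if y_discrete:
        y_vals = pd.factorize(y)[0].astype(float)
    else:
        y_vals = y.astype(float)
        if cfg.standardize_continuous:
            y_vals = _standardize(y_vals)

    terms = np.empty(n)
    # block the O(n^2) distance computation to bound memory at large n
    block = max(1, int(2_000_000 // max(n, 1)))
    for start in range(0, n, block):
        rows = np.arange(start, min(start + block, n))
        dx = _row_max_dist(X, discrete, rows)
        if y_discrete:
            dy = (y_vals[rows, None] != y_vals[None, :]).astype(float)
        else:
            dy = np.abs(y_vals[rows, None] - y_vals[None, :])
        dj = np.maximum(dx, dy)
        dj[np.arange(rows.size), rows] = np.inf  # exclude self from the kNN
        rho = np.partition(dj, cfg.k - 1, axis=1)[:, cfg.k - 1]

        pos = rho > 0.0
        ktilde = np.full(rows.size, float(cfg.k))
        nx = np.empty(rows.size)
        ny = np.empty(rows.size)
        # marginal counts include the point itself (distance 0 to itself)
        nx[pos] = (dx[pos] < rho[pos, None]).sum(axis=1)
        ny[pos] = (dy[pos] < rho[pos, None]).sum(axis=1)
        if (~pos).any():
            z = ~pos
            ktilde[z] = (dj[z] == 0.0).sum(axis=1) + 1.0  # + self
            nx[z] = (dx[z] == 0.0).sum(axis=1)
            ny[z] = (dy[z] == 0.0).sum(axis=1)
        terms[rows] = digamma(ktilde) - np.log(nx) - np.log(ny)

    return float(terms.mean() + np.log(n))


@dataclass
class GeneRankTable:
    """Per-gene MMI with descending ranks and empirical CDF positions.

    ``cdf[g]`` is the fraction of genes whose MMI is <= the MMI of ``g``,
    so tied genes share one CDF value and rank 1 is the largest MMI.
    """

    table: pd.DataFrame  # columns: gene, mmi, rank, cdf

    @classmethod
    def from_scores(cls, gene_ids: Sequence[str], mmi: Sequence[float]) -> "GeneRankTable":
        gene_ids = list(gene_ids)
        mmi = np.asarray(mmi, dtype=float)
        if len(gene_ids) != mmi.size or mmi.size == 0:
            raise ValueError("gene_ids and mmi must be nonempty and equal length")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene IDs in rank table")
        order = np.argsort(-mmi, kind="stable")
        rank = np.empty(mmi.size, dtype=int)
        rank[order] = np.arange(1, mmi.size + 1)
        # empirical CDF: P(score <= mmi_g), ties share the upper value
        sorted_mmi = np.sort(mmi)
        cdf = np.searchsorted(sorted_mmi, mmi, side="right") / mmi.size
        df = pd.DataFrame({"gene": gene_ids, "mmi": mmi, "rank": rank, "cdf": cdf})
        return cls(df)

    def __post_init__(self) -> None:
        required = {"gene", "mmi", "rank", "cdf"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"rank table must have columns {sorted(required)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene"])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.sort_values("rank")
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneRankTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class SelectionResult:
    selected_genes: frozenset[str]
    rule: str  # "cdf_quantile" | "mmi_threshold"
    parameter: float

    def write(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(sorted(self.selected_genes)) + "\n")


def rank_genes(ds: MultiOmicsDataset, cfg: MMIConfig = MMIConfig()) -> GeneRankTable:
    """Score every gene's (S, E, M) block against the dataset outcome."""
    y = ds.outcome.labels
    scores = np.empty(len(ds.genes))
    for i, gene in enumerate(ds.genes):
        try:
            scores[i] = mixed_mi(ds.gene_matrix(gene), y, GENE_COMPONENT_DISCRETE, cfg)
        except Exception as exc:
            raise type(exc)(f"gene {gene!r}: {exc}") from exc
    return GeneRankTable.from_scores(ds.genes, scores)


def select_top_cdf(table: GeneRankTable, q: float) -> SelectionResult:
    """Keep genes whose empirical MMI CDF exceeds ``q``.

    With all-distinct scores this selects exactly ``N - floor(q*N)`` genes;
    genes tied at the boundary score are all included or all dropped.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0,1), got {q}")
    sel = table.table.loc[table.table["cdf"] > q, "gene"]
    return SelectionResult(frozenset(sel), "cdf_quantile", q)


def select_by_threshold(table: GeneRankTable, t: float) -> SelectionResult:
    """Keep genes with MMI strictly greater than ``t``."""
    sel = table.table.loc[table.table["mmi"] > t, "gene"]
    return SelectionResult(frozenset(sel), "mmi_threshold", t)


def jaccard_index(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """|A∩B| / |A∪B|; two empty sets count as identical (JI = 1)."""
    if not a and not b:
        return 1.0
    return len(set(a) & set(b)) / len(set(a) | set(b))


def jaccard_curve(
    ds: MultiOmicsDataset,
    k_range: Iterable[int],
    q: float,
    standardize_continuous: bool = True,
) -> list[tuple[int, float]]:
    """Selection-stability diagnostic across neighbor counts.

    For consecutive k values, JI(k) = |A∩B| / |A∪B| where A, B are the gene
    sets selected (CDF > q) at k and k+1 neighbors.  Two empty selections
    count as perfectly stable (JI = 1, logged).
    """
    ks = sorted(set(int(k) for k in k_range))
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("k_range must be a contiguous integer interval")
    sels: dict[int, frozenset[str]] = {}
    for k in ks:
        cfg = MMIConfig(k=k, standardize_continuous=standardize_continuous)
        sels[k] = select_top_cdf(rank_genes(ds, cfg), q).selected_genes
    out = []
    for a, b in zip(ks, ks[1:]):
        A, B = sels[a], sels[b]
        if not A and not B:
            logger.info("both selections empty at k=%d,%d; JI defined as 1", a, b)
        out.append((a, jaccard_index(A, B)))
    return out
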