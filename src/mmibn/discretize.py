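"""Equal-frequency (maximum-entropy) binning and S/E/M node expansion.

Continuous components are cut into 3 bins at empirical quantile boundaries,
which maximizes the marginal entropy of the binned variable.  Each selected
gene becomes three discrete nodes (``<gene>_S``, ``<gene>_E``, ``<gene>_M``)
and the outcome is appended as a final binary node.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import Modality, MultiOmicsDataset

__all__ = ["DiscretizedDataset", "me_discretize", "discretize_dataset"]


def me_discretize(x: np.ndarray, bins: int = 3) -> tuple[np.ndarray, tuple[float, ...]]:
    """Maximum-entropy discretization of a real vector.

    Boundaries sit at the ceil(n*i/bins)-th order statistics; intervals are
    lower-closed so the label is a function of the value alone.  Tied values
    all receive the same label, which can unbalance bin occupancies (a
    warning is emitted when they differ by more than 1).

    Returns (integer labels in 0..bins-1, interior boundary values).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector")
    n = x.size
    if n < bins:
        raise ValueError(f"need at least {bins} values, got {n}")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values cannot be discretized")
    if np.ptp(x) == 0.0:
        raise ValueError("constant vector has no informative bins")

    xs = np.sort(x)
    edges = tuple(float(xs[ceil(n * i / bins) - 1]) for i in range(1, bins))
    # side="left" puts boundary-valued ties into the lower bin
    labels = np.searchsorted(np.asarray(edges), x, side="left").astype(np.int64)
    occ = np.bincount(labels, minlength=bins)
    if occ.max() - occ.min() > 1:
        warnings.warn(
            f"tied values unbalance bin occupancies {occ.tolist()}",
            UserWarning,
            stacklevel=2,
        )
    return labels, edges


@dataclass
class DiscretizedDataset:
    """All-discrete variable-by-sample table ready for network learning."""

    variables: list[str]
    cardinalities: list[int]
    data: np.ndarray  # shape (n_variables, n_samples), small ints
    sample_ids: list[str]
    bin_edges: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int64)
        nv = len(self.variables)
        if len(set(self.variables)) != nv:
            raise ValueError("duplicate variable names")
        if len(self.cardinalities) != nv or self.data.shape != (nv, len(self.sample_ids)):
            raise ValueError("variables / cardinalities / data shapes disagree")
        for v, card, row in zip(self.variables, self.cardinalities, self.data):
            if card < 2:
                raise ValueError(f"variable {v!r} has cardinality {card} < 2")
            if row.min() < 0 or row.max() >= card:
                raise ValueError(f"variable {v!r} has values outside 0..{card - 1}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def index(self, variable: str) -> int:
        try:
            return self.variables.index(variable)
        except ValueError:
            raise KeyError(f"unknown variable {variable!r}") from None

    def column(self, variable: str) -> np.ndarray:
        return self.data[self.index(variable)]

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        df = pd.DataFrame(self.data, index=self.variables, columns=self.sample_ids)
        df.to_csv(path, sep="\t", index_label="variable")
        sidecar = {
            "cardinalities": dict(zip(self.variables, self.cardinalities)),
            "bin_edges": {v: list(e) for v, e in self.bin_edges.items()},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DiscretizedDataset":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        variables = [str(v) for v in df.index]
        return cls(
            variables=variables,
            cardinalities=[int(sidecar["cardinalities"][v]) for v in variables],
            data=df.to_numpy(dtype=np.int64),
            sample_ids=[str(c) for c in df.columns],
            bin_edges={v: tuple(e) for v, e in sidecar["bin_edges"].items()},
        )


def discretize_dataset(
    ds: MultiOmicsDataset, selected: Sequence[str] | frozenset[str], bins: int = 3
) -> DiscretizedDataset:
    """Expand selected genes into discrete S/E/M nodes plus the outcome.

    S components (already binary) and the outcome pass through; E and M are
    binned by :func:`me_discretize`.  |selected| genes yield 3*|selected|
    molecular variables followed by the outcome node.
    """
    selected_set = set(selected)
    missing = selected_set - set(ds.genes)
    if missing:
        raise KeyError(f"selected genes absent from dataset: {sorted(missing)}")
    genes = [g for g in ds.genes if g in selected_set]

    variables: list[str] = []
    cards: list[int] = []
    rows: list[np.ndarray] = []
    edges: dict[str, tuple[float, ...]] = {}
    for gene in genes:
        for mod in (Modality.S, Modality.E, Modality.M):
            name = f"{gene}_{mod.value}"
            vals = ds.component(gene, mod)
            if mod.is_discrete:
                labels, card = vals.astype(np.int64), 2
            else:
                try:
                    labels, bedges = me_discretize(vals, bins=bins)
                except ValueError as exc:
                    raise ValueError(f"{name}: {exc}") from exc
                edges[name] = bedges
                card = bins
            variables.append(name)
            cards.append(card)
            rows.append(labels)

    variables.append(ds.outcome.name)
    cards.append(2)
    rows.append(ds.outcome.labels.astype(np.int64))
    return DiscretizedDataset(
        variables=variables,
        cardinalities=cards,
        data=np.vstack(rows),
        sample_ids=list(ds.samples),
        bin_edges=edges,
    )
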