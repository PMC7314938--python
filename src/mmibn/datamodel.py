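"""Multimodal data model, delimited-text I/O and clinical preprocessing.

The analysis operates on three gene-by-sample modality matrices — a binary
somatic-mutation indicator (``S``), continuous expression (``E``) and
continuous promoter methylation (``M``) — aligned against one binary clinical
outcome per analysis (tumor status, or death within a survival cutoff).

Matrices are plain TSV/CSV with gene IDs in the first column and sample IDs
in the header row.  Cells that parse as one of the conventional missing
tokens become NaN; genes carrying any missing value in any modality are
dropped at assembly time (complete-case per gene).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Modality",
    "ModalityMatrix",
    "ClinicalRecord",
    "OutcomeVector",
    "MultiOmicsDataset",
    "load_modality",
    "load_clinical",
    "binarize_somatic",
    "dichotomize_survival",
    "encode_tumor_status",
    "assemble_dataset",
    "DataModelError",
]

#: cell contents interpreted as "missing" rather than a parse error
MISSING_TOKENS = {"", "na", "nan", "null", "n/a", "none", "."}

DEFAULT_SURVIVAL_CUTOFF_DAYS = 730.0


class DataModelError(ValueError):
    """Raised on malformed input data or violated data-model invariants."""


class Modality(str, Enum):
    S = "S"  # binary somatic mutation indicator
    E = "E"  # continuous mRNA expression
    M = "M"  # continuous promoter methylation

    @property
    def is_discrete(self) -> bool:
        return self is Modality.S


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise DataModelError(f"duplicate {what} ID(s): {sorted(set(dups))}")


@dataclass
class ModalityMatrix:
    """One gene-by-sample matrix of a single modality.

    ``values`` is a float DataFrame indexed by gene ID with sample-ID
    columns.  NaN marks an explicitly missing measurement; every non-missing
    entry must be finite, and S entries must be 0/1.
    """

    modality: Modality
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        arr = self.values.to_numpy(dtype=float, copy=False)
        finite_or_nan = np.isfinite(arr) | np.isnan(arr)
        if not finite_or_nan.all():
            g, s = np.argwhere(~finite_or_nan)[0]
            raise DataModelError(
                f"non-finite value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if self.modality.is_discrete:
            ok = np.isnan(arr) | (arr == 0.0) | (arr == 1.0)
            if not ok.all():
                g, s = np.argwhere(~ok)[0]
                raise DataModelError(
                    f"S matrix entry not in {{0,1}} at gene "
                    f"{self.values.index[g]!r}, sample {self.values.columns[s]!r}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def restrict(self, genes: Sequence[str], samples: Sequence[str]) -> "ModalityMatrix":
        return ModalityMatrix(self.modality, self.values.loc[list(genes), list(samples)])

    def to_tsv(self, path: str | Path) -> None:
        # %.17g guarantees float64 round-trip through text
        self.values.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


@dataclass
class ClinicalRecord:
    sample_id: str
    tumor_status: str | None = None
    vital_status: str | None = None
    survival_days: float | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise DataModelError("clinical record with empty sample_id")


@dataclass
class OutcomeVector:
    """Binary outcome labels plus the samples excluded by preprocessing."""

    name: str
    sample_ids: list[str]
    labels: np.ndarray
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (len(self.sample_ids),):
            raise DataModelError("labels length does not match sample_ids")
        if not np.isin(self.labels, (0, 1)).all():
            raise DataModelError("outcome labels must be 0/1")
        _check_unique(self.sample_ids, "outcome sample")
        kept = set(self.sample_ids)
        clash = kept & {s for s, _ in self.excluded}
        if clash:
            raise DataModelError(f"samples both labeled and excluded: {sorted(clash)}")

    @property
    def is_degenerate(self) -> bool:
        """True when fewer than two outcome classes are represented."""
        return len(np.unique(self.labels)) < 2

    def restrict(self, samples: Sequence[str]) -> "OutcomeVector":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        order = [idx[s] for s in samples]
        return OutcomeVector(
            self.name, list(samples), self.labels[order], list(self.excluded)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, self.name: self.labels})


@dataclass
class MultiOmicsDataset:
    """Aligned S/E/M matrices and one outcome over common genes and samples."""

    genes: list[str]
    samples: list[str]
    S: ModalityMatrix
    E: ModalityMatrix
    M: ModalityMatrix
    outcome: OutcomeVector
    assembly_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mm in (self.S, self.E, self.M):
            if mm.gene_ids != self.genes or mm.sample_ids != self.samples:
                raise DataModelError("modality matrix not aligned to dataset axes")
        if self.outcome.sample_ids != self.samples:
            raise DataModelError("outcome not aligned to dataset samples")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def modality(self, modality: Modality | str) -> ModalityMatrix:
        return {Modality.S: self.S, Modality.E: self.E, Modality.M: self.M}[
            Modality(modality)
        ]

    def component(self, gene: str, modality: Modality | str) -> np.ndarray:
        """Values of one gene component across samples (sample order)."""
        return self.modality(modality).values.loc[gene].to_numpy(dtype=float)

    def gene_matrix(self, gene: str) -> np.ndarray:
        """n_samples x 3 array of the (S, E, M) components of one gene."""
        return np.column_stack(
            [self.component(gene, m) for m in (Modality.S, Modality.E, Modality.M)]
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for m in (self.S, self.E, self.M):
            m.to_tsv(outdir / f"{m.modality.value}.tsv")
        self.outcome.to_frame().to_csv(outdir / "outcome.tsv", sep="\t", index=False)
        (outdir / "assembly_log.json").write_text(
            json.dumps(self.assembly_log, indent=2, default=str)
        )


def _infer_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_modality(
    path: str | Path, modality: Modality | str, sep: str | None = None
) -> ModalityMatrix:
    """Read a gene-by-sample delimited matrix (first column = gene IDs).

    Non-numeric cells (other than the conventional missing tokens, which
    become NaN) raise :class:`DataModelError` naming the offending cell.
    Somatic matrices are normalized so any nonzero count maps to 1.
    """
    path = Path(path)
    modality = Modality(modality)
    raw = pd.read_csv(path, sep=sep or _infer_sep(path), index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    _check_unique(list(raw.index), "gene")
    _check_unique(list(raw.columns), "sample")

    def _cell(v):
        # python float() is round-trip exact, unlike pandas' fast parser
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return math.nan
        if str(v).strip().lower() in MISSING_TOKENS:
            return math.nan
        try:
            return float(v)
        except ValueError:
            return v  # flagged below with coordinates

    num = raw.map(_cell)
    bad = num.map(lambda v: isinstance(v, str))
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise DataModelError(
            f"non-numeric cell {raw.iat[g, s]!r} at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r} in {path.name}"
        )
    num = num.astype(float)
    if modality.is_discrete:
        nz = num.notna() & (num != 0.0)
        num = num.where(~nz, 1.0)
    return ModalityMatrix(modality, num)


def load_clinical(path: str | Path, sep: str | None = None) -> list[ClinicalRecord]:
    """Read a clinical table with columns sample_id, tumor_status,
    vital_status, survival_days (extra columns ignored)."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep or _infer_sep(path), dtype=str)
    if "sample_id" not in df.columns:
        raise DataModelError(f"clinical table {path.name} lacks a sample_id column")
    records = []
    for _, row in df.iterrows():
        days_raw = row.get("survival_days")
        days: float | None = None
        if days_raw is not None and str(days_raw).strip().lower() not in MISSING_TOKENS:
            try:
                days = float(days_raw)
            except ValueError as exc:
                raise DataModelError(
                    f"non-numeric survival_days {days_raw!r} for sample "
                    f"{row['sample_id']!r}"
                ) from exc
        def _clean(v):
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            v = str(v).strip()
            return v or None
        records.append(
            ClinicalRecord(
                sample_id=str(row["sample_id"]),
                tumor_status=_clean(row.get("tumor_status")),
                vital_status=_clean(row.get("vital_status")),
                survival_days=days,
            )
        )
    return records


def binarize_somatic(
    calls: Iterable[tuple[str, str, bool]],
    genes: Sequence[str],
    samples: Sequence[str],
) -> ModalityMatrix:
    """Collapse per-call mutation records into the binary S matrix.

    ``S[g, s] = 1`` iff sample ``s`` carries at least one non-synonymous call
    in gene ``g``; synonymous-only calls and absent pairs yield 0.  Calls
    outside the supplied gene/sample universes are ignored.
    """
    _check_unique(genes, "gene")
    _check_unique(samples, "sample")
    gi = {g: i for i, g in enumerate(genes)}
    si = {s: i for i, s in enumerate(samples)}
    arr = np.zeros((len(genes), len(samples)))
    n_skipped = 0
    for sample_id, gene_id, is_nonsyn in calls:
        if not is_nonsyn:
            continue
        if gene_id not in gi or sample_id not in si:
            n_skipped += 1
            continue
        arr[gi[gene_id], si[sample_id]] = 1.0
    if n_skipped:
        logger.debug("ignored %d calls outside the gene/sample universe", n_skipped)
    return ModalityMatrix(
        Modality.S, pd.DataFrame(arr, index=list(genes), columns=list(samples))
    )


_DEAD = {"dead", "deceased"}
_ALIVE = {"alive", "living"}


def dichotomize_survival(
    records: Sequence[ClinicalRecord],
    cutoff_days: float = DEFAULT_SURVIVAL_CUTOFF_DAYS,
) -> OutcomeVector:
    """Encode death-within-cutoff as 1 (high risk), survival past it as 0.

    Patients alive with follow-up shorter than the cutoff are excluded
    (their class is unknowable), as are records with missing status/days.
    """
    if not records:
        raise DataModelError("no clinical records supplied")
    sample_ids: list[str] = []
    labels: list[int] = []
    excluded: list[tuple[str, str]] = []
    for rec in records:
        status = (rec.vital_status or "").strip().lower()
        days = rec.survival_days
        if days is not None and days < 0:
            raise DataModelError(
                f"negative survival_days for sample {rec.sample_id!r}"
            )
        if status not in _DEAD | _ALIVE or days is None:
            excluded.append((rec.sample_id, "no survival status"))
            continue
        if days >= cutoff_days:
            sample_ids.append(rec.sample_id)
            labels.append(0)
        elif status in _DEAD:
            sample_ids.append(rec.sample_id)
            labels.append(1)
        else:  # alive, but censored before the cutoff
            excluded.append((rec.sample_id, "insufficient follow-up"))
    return OutcomeVector("survival2y", sample_ids, np.array(labels), excluded)


def _norm_label(v: str | None) -> str:
    if v is None:
        return ""
    return " ".join("".join(c if c.isalnum() else " " for c in v.lower()).split())


def encode_tumor_status(records: Sequence[ClinicalRecord]) -> OutcomeVector:
    """Encode "with tumor" as 1 and "tumor free" as 0; anything else is
    excluded as ambiguous.  Matching ignores case and punctuation."""
    if not records:
        raise DataModelError("no clinical records supplied")
    sample_ids: list[str] = []
    labels: list[int] = []
    excluded: list[tuple[str, str]] = []
    for rec in records:
        label = _norm_label(rec.tumor_status)
        if label == "with tumor":
            sample_ids.append(rec.sample_id)
            labels.append(1)
        elif label == "tumor free":
            sample_ids.append(rec.sample_id)
            labels.append(0)
        else:
            excluded.append((rec.sample_id, "ambiguous or missing tumor status"))
    return OutcomeVector("tumor_status", sample_ids, np.array(labels), excluded)


def assemble_dataset(
    S: ModalityMatrix,
    E: ModalityMatrix,
    M: ModalityMatrix,
    outcome: OutcomeVector,
) -> MultiOmicsDataset:
    """Align the three matrices and the outcome on common genes/samples.

    Genes: intersection of the three gene sets, minus genes with any missing
    value in any modality.  Samples: intersection of the matrix samples and
    the non-excluded outcome samples.  Orderings follow the S matrix.
    """
    if Modality(S.modality) is not Modality.S:
        raise DataModelError("first matrix must be the S modality")
    mats = {Modality.S: S, Modality.E: E, Modality.M: M}
    for want, mm in mats.items():
        if Modality(mm.modality) is not want:
            raise DataModelError(f"expected modality {want.value}, got {mm.modality}")

    gene_sets = [set(mm.gene_ids) for mm in mats.values()]
    common_genes = [g for g in S.gene_ids if all(g in gs for gs in gene_sets)]
    sample_sets = [set(mm.sample_ids) for mm in mats.values()] + [set(outcome.sample_ids)]
    samples = [s for s in S.sample_ids if all(s in ss for ss in sample_sets)]
    if not common_genes or not samples:
        raise DataModelError("empty gene or sample intersection across modalities")

    restricted = {m: mm.restrict(common_genes, samples) for m, mm in mats.items()}
    incomplete = set()
    for mm in restricted.values():
        na = mm.values.isna().any(axis=1)
        incomplete |= set(mm.values.index[na])
    genes = [g for g in common_genes if g not in incomplete]
    if not genes:
        raise DataModelError("no complete-case genes left after assembly")
    if incomplete:
        restricted = {m: mm.restrict(genes, samples) for m, mm in restricted.items()}

    out = outcome.restrict(samples)
    counts = np.bincount(out.labels, minlength=2)
    if (counts < 2).any():
        raise DataModelError(
            f"outcome degenerate after assembly (class counts {counts.tolist()}); "
            "need at least 2 samples per class"
        )

    log = {
        "n_genes": len(genes),
        "n_samples": len(samples),
        "dropped_genes_not_shared": sorted(
            (set().union(*gene_sets)) - set(common_genes)
        ),
        "dropped_genes_incomplete": sorted(incomplete),
        "dropped_samples": sorted(
            (set().union(*sample_sets[:3])) - set(samples)
        ),
        "excluded_by_outcome": list(outcome.excluded),
        "class_counts": counts.tolist(),
        "outcome": outcome.name,
    }
    return MultiOmicsDataset(
        genes=genes,
        samples=samples,
        S=restricted[Modality.S],
        E=restricted[Modality.E],
        M=restricted[Modality.M],
        outcome=out,
        assembly_log=log,
    )
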