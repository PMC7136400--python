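"""Core data types and tab-delimited I/O.

All external tables are plain TSV:

* expression matrix — first column gene id, remaining columns samples,
  header row of sample ids; values are log2 expression;
* phenotype table — two columns (sample id, group label), group labels
  drawn from ``{high_BMD, low_BMD}``;
* interaction table — three columns (miRNA id, target id, target class),
  target class in ``{mRNA, lncRNA}``;
* probe map — two columns (probe id, gene id).

Floats are written with ``%.17g`` so that write/read round-trips are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cernet")

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")
TARGET_CLASSES = ("mRNA", "lncRNA")
GROUP_HIGH = "high_BMD"
GROUP_LOW = "low_BMD"
GROUPS = (GROUP_HIGH, GROUP_LOW)

FLOAT_FORMAT = "%.17g"


class ValidationError(ValueError):
    """Raised when an input table or configuration violates its contract."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Log2 expression values for one RNA class, genes x samples.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with sample ids as columns.
    rna_class
        One of ``mRNA``, ``lncRNA``, ``miRNA``.
    """

    data: pd.DataFrame
    rna_class: str

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValidationError(
                f"rna_class must be one of {RNA_CLASSES}, got {self.rna_class!r}"
            )
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate gene ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if values.size and not np.isfinite(values.astype(float)).all():
            rows, cols_ = np.where(~np.isfinite(values.astype(float)))
            g = self.data.index[rows[0]]
            s = self.data.columns[cols_[0]]
            raise ValidationError(f"non-finite value at gene {g!r}, sample {s!r}")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def restrict(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Subset to ``gene_ids`` in the given order; missing ids are an error."""
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)].copy(), self.rna_class)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.rna_class == other.rna_class
            and self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


def read_expression_matrix(path: str | Path, rna_class: str) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (genes in rows, header of sample ids)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"expression matrix file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: malformed header (no sample columns)")
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate gene ids {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        rows, cols = np.where(bad.to_numpy())
        g, s = df.index[rows[0]], df.columns[cols[0]]
        raise ValidationError(
            f"{path}: non-numeric value {df.iloc[rows[0], cols[0]]!r} "
            f"at gene {g!r}, sample {s!r}"
        )
    if numeric.isna().to_numpy().any():
        rows, cols = np.where(numeric.isna().to_numpy())
        g, s = df.index[rows[0]], df.columns[cols[0]]
        raise ValidationError(f"{path}: missing value at gene {g!r}, sample {s!r}")
    # pd.to_numeric is not correctly rounded; astype(float) is, which makes
    # write/read round-trips bit-exact at %.17g
    return ExpressionMatrix(df.astype(float), rna_class)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Phenotype labels
# ---------------------------------------------------------------------------


@dataclass
class GroupLabels:
    """Mapping sample id -> group, groups fixed to ``high_BMD`` / ``low_BMD``."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = sorted({g for g in self.mapping.values() if g not in GROUPS})
        if bad:
            raise ValidationError(f"unknown group labels {bad}; expected {GROUPS}")
        for group in GROUPS:
            if not any(g == group for g in self.mapping.values()):
                raise ValidationError(f"group {group!r} has no samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mapping)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.mapping.items() if g == group]

    def check_matches(self, sample_ids: Sequence[str]) -> None:
        if set(sample_ids) != set(self.mapping):
            missing = sorted(set(sample_ids) - set(self.mapping))
            extra = sorted(set(self.mapping) - set(sample_ids))
            raise ValidationError(
                f"labels do not cover matrix samples (missing={missing}, extra={extra})"
            )

    def binary(self, sample_ids: Sequence[str], positive: str) -> np.ndarray:
        """0/1 vector over ``sample_ids``, 1 where the sample is in ``positive``."""
        self.check_matches(sample_ids)
        return np.array([1 if self.mapping[s] == positive else 0 for s in sample_ids])

    def equals(self, other: "GroupLabels") -> bool:
        return self.mapping == other.mapping


def read_group_labels(path: str | Path) -> GroupLabels:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: phenotype table needs two columns")
    sample_col, group_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        dups = sorted(df[sample_col][df[sample_col].duplicated()])
        raise ValidationError(f"{path}: duplicate sample ids {dups}")
    return GroupLabels(dict(zip(df[sample_col], df[group_col])))


def write_group_labels(labels: GroupLabels, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(labels.mapping), "group": list(labels.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# miRNA-target interactions
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Interaction:
    mirna_id: str
    target_id: str
    target_class: str


@dataclass
class InteractionTable:
    """Deduplicated set of validated miRNA -> target records."""

    records: frozenset[Interaction]
    _by_target: dict[tuple[str, str], set[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.records = frozenset(self.records)
        for rec in self.records:
            if rec.target_class not in TARGET_CLASSES:
                raise ValidationError(
                    f"bad target class {rec.target_class!r} for "
                    f"({rec.mirna_id}, {rec.target_id}); expected {TARGET_CLASSES}"
                )
        by_target: dict[tuple[str, str], set[str]] = {}
        for rec in self.records:
            by_target.setdefault((rec.target_id, rec.target_class), set()).add(
                rec.mirna_id
            )
        self._by_target = by_target

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rec: Interaction) -> bool:
        return rec in self.records

    def mirnas_targeting(self, target_id: str, target_class: str) -> set[str]:
        return set(self._by_target.get((target_id, target_class), set()))

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.records)
        return pd.DataFrame(
            {
                "mirna_id": [r.mirna_id for r in rows],
                "target_id": [r.target_id for r in rows],
                "target_class": [r.target_class for r in rows],
            }
        )

    def equals(self, other: "InteractionTable") -> bool:
        return self.records == other.records


def read_interaction_table(path: str | Path) -> InteractionTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"mirna_id", "target_id", "target_class"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    records = frozenset(
        Interaction(m, t, c)
        for m, t, c in zip(df["mirna_id"], df["target_id"], df["target_class"])
    )
    return InteractionTable(records)


def write_interaction_table(table: InteractionTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Probe maps
# ---------------------------------------------------------------------------


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (probe id, gene id); many probes may map to one gene."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: probe map needs two columns")
    probe_col, gene_col = df.columns[:2]
    if df[gene_col].isna().any() or (df[gene_col] == "").any():
        raise ValidationError(f"{path}: empty gene id in probe map")
    return dict(zip(df[probe_col], df[gene_col]))


def collapse_probes(
    matrix: ExpressionMatrix, probe_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    For genes with several probes the probe with the highest sample variance
    is kept.  Unmapped probes are dropped (count is logged).  Ties are broken
    by probe id so the result is deterministic.
    """
    present = [p for p in matrix.gene_ids if p in probe_map]
    if not present:
        raise ValidationError("probe map covers no probe in the matrix")
    dropped = matrix.n_genes - len(present)
    if dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", dropped)
    variances = matrix.data.var(axis=1, ddof=1)
    best: dict[str, str] = {}
    for probe in sorted(present):
        gene = probe_map[probe]
        if gene not in best or variances[probe] > variances[best[gene]]:
            best[gene] = probe
    genes = sorted(best)
    collapsed = matrix.data.loc[[best[g] for g in genes]].copy()
    collapsed.index = pd.Index(genes, name="gene_id")
    return ExpressionMatrix(collapsed, matrix.rna_class)
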