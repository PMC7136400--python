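"""Synthetic paired expression datasets with planted ground truth.

The generator emits three paired expression matrices (mRNA, lncRNA, miRNA)
over two sample groups, an interaction table, and the ground truth needed to
score downstream recovery:

* planted differentially expressed genes — group means shifted by
  ``de_effect`` on the log2 scale;
* planted ceRNA triplets — a shared per-sample Gaussian latent factor loads
  ``+coupling`` on the triplet's mRNA and lncRNA and ``-coupling`` on its
  miRNA, so lncRNA-mRNA correlation is positive and both miRNA correlations
  are negative, with magnitude increasing in ``coupling``;
* decoy interactions — uniform draws from non-functional (miRNA, target)
  pairs, never coinciding with planted-triplet pairs.

Triplet members are always marked differentially expressed (the triplet's
mRNA and lncRNA share one direction, its miRNA takes the opposite), because
the network stage only sees differentially expressed genes.  A gene belongs
to at most one planted triplet.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .io import (
    GROUP_HIGH,
    GROUP_LOW,
    ExpressionMatrix,
    GroupLabels,
    Interaction,
    InteractionTable,
    ValidationError,
    read_expression_matrix,
    read_group_labels,
    read_interaction_table,
    write_expression_matrix,
    write_group_labels,
    write_interaction_table,
)

GROUND_TRUTH_HEADER = "# cernet ground truth v1"

_CLASS_PREFIX = {"mRNA": "MRNA", "lncRNA": "LNC", "miRNA": "MIR"}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic generator.  All expression is log2 scale."""

    n_per_group: int = 5
    n_mrna: int = 40
    n_lncrna: int = 40
    n_mirna: int = 12
    n_de_per_class: int = 10
    de_effect: float = 2.0
    n_triplets: int = 5
    coupling: float = 0.8
    n_decoy_interactions: int = 50
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_mrna": self.n_mrna,
            "n_lncrna": self.n_lncrna,
            "n_mirna": self.n_mirna,
            "n_de_per_class": self.n_de_per_class,
            "n_triplets": self.n_triplets,
            "n_decoy_interactions": self.n_decoy_interactions,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")
        if self.n_per_group < 3:
            raise ValidationError(
                f"n_per_group must be >= 3 (correlation needs >= 3 points), "
                f"got {self.n_per_group}"
            )
        if not 0.0 <= self.coupling <= 1.0:
            raise ValidationError(f"coupling must be in [0, 1], got {self.coupling}")
        if self.noise_sd <= 0:
            raise ValidationError(f"noise_sd must be > 0, got {self.noise_sd}")
        limit = min(self.n_mrna, self.n_lncrna, self.n_mirna)
        if self.n_triplets > limit:
            raise ValidationError(
                f"n_triplets must be <= min(n_mrna, n_lncrna, n_mirna) = {limit}, "
                f"got {self.n_triplets}"
            )
        for name, size in (
            ("n_mrna", self.n_mrna),
            ("n_lncrna", self.n_lncrna),
            ("n_mirna", self.n_mirna),
        ):
            if self.n_de_per_class > size:
                raise ValidationError(
                    f"n_de_per_class ({self.n_de_per_class}) exceeds {name} ({size})"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Planted answers: DE genes, ceRNA triplets, and their interactions."""

    de_genes: frozenset[tuple[str, str, str]]  # (gene id, rna class, direction)
    triplets: frozenset[tuple[str, str, str]]  # (lncRNA id, mRNA id, miRNA id)
    functional_interactions: frozenset[Interaction]

    def de_ids(self, rna_class: str) -> set[str]:
        return {g for g, c, _ in self.de_genes if c == rna_class}


@dataclass
class SyntheticDataset:
    mrna: ExpressionMatrix
    lncrna: ExpressionMatrix
    mirna: ExpressionMatrix
    labels: GroupLabels
    interactions: InteractionTable
    truth: GroundTruth
    config: SynthConfig

    def matrices(self) -> Iterator[ExpressionMatrix]:
        yield from (self.mrna, self.lncrna, self.mirna)

    def equals(self, other: "SyntheticDataset") -> bool:
        return (
            self.mrna.equals(other.mrna)
            and self.lncrna.equals(other.lncrna)
            and self.mirna.equals(other.mirna)
            and self.labels.equals(other.labels)
            and self.interactions.equals(other.interactions)
            and self.truth == other.truth
        )


def _gene_ids(rna_class: str, n: int) -> list[str]:
    prefix = _CLASS_PREFIX[rna_class]
    return [f"{prefix}{i + 1:04d}" for i in range(n)]


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Generate a dataset per ``config``; identical config reproduces it exactly."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    samples = [f"high_{i + 1}" for i in range(n)] + [f"low_{i + 1}" for i in range(n)]
    group_sign = np.array([+0.5] * n + [-0.5] * n)  # +/- de_effect/2 around baseline
    labels = GroupLabels(
        {s: (GROUP_HIGH if i < n else GROUP_LOW) for i, s in enumerate(samples)}
    )

    ids = {c: _gene_ids(c, getattr(config, f"n_{_ATTR[c]}")) for c in _CLASS_PREFIX}

    # DE bookkeeping: triplet members occupy the first slots of each class and
    # are always DE; extra planted DE genes fill up to n_de_per_class.
    n_de = {c: max(config.n_de_per_class, config.n_triplets) for c in _CLASS_PREFIX}
    for c, count in n_de.items():
        if count > len(ids[c]):
            raise ValidationError(
                f"need {count} DE genes in class {c} but only {len(ids[c])} genes"
            )

    # per-triplet direction sign: +1 -> lncRNA/mRNA up, miRNA down (in high group)
    trip_sign = np.where(rng.random(config.n_triplets) < 0.5, 1.0, -1.0)

    directions: dict[str, dict[str, float]] = {c: {} for c in _CLASS_PREFIX}
    for t in range(config.n_triplets):
        directions["lncRNA"][ids["lncRNA"][t]] = trip_sign[t]
        directions["mRNA"][ids["mRNA"][t]] = trip_sign[t]
        directions["miRNA"][ids["miRNA"][t]] = -trip_sign[t]
    for c in _CLASS_PREFIX:
        for j in range(config.n_triplets, n_de[c]):
            directions[c][ids[c][j]] = 1.0 if j % 2 == 0 else -1.0

    # shared latent factor per triplet, one value per sample
    factors = rng.standard_normal((config.n_triplets, 2 * n))

    matrices: dict[str, ExpressionMatrix] = {}
    for c in _CLASS_PREFIX:
        n_genes = len(ids[c])
        baseline = rng.normal(8.0, 1.0, size=n_genes)
        values = baseline[:, None] + rng.normal(0.0, config.noise_sd, (n_genes, 2 * n))
        for gene, sign in directions[c].items():
            row = ids[c].index(gene)
            values[row] += sign * config.de_effect * group_sign
        loading = {"mRNA": +1.0, "lncRNA": +1.0, "miRNA": -1.0}[c]
        for t in range(config.n_triplets):
            values[t] += loading * config.coupling * factors[t]
        matrices[c] = ExpressionMatrix(
            pd.DataFrame(values, index=pd.Index(ids[c], name="gene_id"), columns=samples),
            c,
        )

    de_genes = frozenset(
        (gene, c, "up" if sign > 0 else "down")
        for c in _CLASS_PREFIX
        for gene, sign in directions[c].items()
    )
    triplets = frozenset(
        (ids["lncRNA"][t], ids["mRNA"][t], ids["miRNA"][t])
        for t in range(config.n_triplets)
    )
    functional = frozenset(
        rec
        for l, m, i in triplets
        for rec in (Interaction(i, m, "mRNA"), Interaction(i, l, "lncRNA"))
    )

    # decoys: uniform over non-functional (miRNA, target) pairs
    all_pairs = [
        Interaction(i, t, c)
        for i in ids["miRNA"]
        for c in ("mRNA", "lncRNA")
        for t in ids[c]
    ]
    candidates = [p for p in all_pairs if p not in functional]
    if config.n_decoy_interactions > len(candidates):
        raise ValidationError(
            f"n_decoy_interactions ({config.n_decoy_interactions}) exceeds the "
            f"{len(candidates)} available non-functional pairs"
        )
    chosen = rng.choice(
        len(candidates), size=config.n_decoy_interactions, replace=False
    )
    decoys = frozenset(candidates[int(k)] for k in chosen)

    truth = GroundTruth(de_genes, triplets, functional)
    table = InteractionTable(functional | decoys)
    return SyntheticDataset(
        mrna=matrices["mRNA"],
        lncrna=matrices["lncRNA"],
        mirna=matrices["miRNA"],
        labels=labels,
        interactions=table,
        truth=truth,
        config=config,
    )


_ATTR = {"mRNA": "mrna", "lncRNA": "lncrna", "miRNA": "mirna"}


# ---------------------------------------------------------------------------
# On-disk layout
# ---------------------------------------------------------------------------

FILENAMES = {
    "mRNA": "mrna.tsv",
    "lncRNA": "lncrna.tsv",
    "miRNA": "mirna.tsv",
    "phenotype": "phenotype.tsv",
    "interactions": "interactions.tsv",
    "truth": "ground_truth.tsv",
}


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write all dataset components as TSV files; returns the path of each part."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {key: directory / name for key, name in FILENAMES.items()}
    try:
        write_expression_matrix(dataset.mrna, paths["mRNA"])
        write_expression_matrix(dataset.lncrna, paths["lncRNA"])
        write_expression_matrix(dataset.mirna, paths["miRNA"])
        write_group_labels(dataset.labels, paths["phenotype"])
        write_interaction_table(dataset.interactions, paths["interactions"])
        write_ground_truth(dataset.truth, paths["truth"])
    except OSError as exc:  # pragma: no cover - depends on filesystem state
        raise ValidationError(f"failed writing dataset under {directory}: {exc}") from exc
    return paths


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    lines = [GROUND_TRUTH_HEADER, "record\tfield1\tfield2\tfield3"]
    for gene, cls, direction in sorted(truth.de_genes):
        lines.append(f"de_gene\t{gene}\t{cls}\t{direction}")
    for l, m, i in sorted(truth.triplets):
        lines.append(f"triplet\t{l}\t{m}\t{i}")
    for rec in sorted(truth.functional_interactions):
        lines.append(
            f"interaction\t{rec.mirna_id}\t{rec.target_id}\t{rec.target_class}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    lines = Path(path).read_text().splitlines()
    rows = [ln for ln in lines if ln and not ln.startswith("#")]
    if not rows or rows[0].split("\t")[0] != "record":
        raise ValidationError(f"{path}: missing ground-truth header row")
    de, triplets, inter = set(), set(), set()
    for ln in rows[1:]:
        kind, f1, f2, f3 = ln.split("\t")
        if kind == "de_gene":
            de.add((f1, f2, f3))
        elif kind == "triplet":
            triplets.add((f1, f2, f3))
        elif kind == "interaction":
            inter.add(Interaction(f1, f2, f3))
        else:
            raise ValidationError(f"{path}: unknown record kind {kind!r}")
    return GroundTruth(frozenset(de), frozenset(triplets), frozenset(inter))


def read_dataset(directory: str | Path, config: SynthConfig | None = None) -> SyntheticDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    paths = {key: directory / name for key, name in FILENAMES.items()}
    return SyntheticDataset(
        mrna=read_expression_matrix(paths["mRNA"], "mRNA"),
        lncrna=read_expression_matrix(paths["lncRNA"], "lncRNA"),
        mirna=read_expression_matrix(paths["miRNA"], "miRNA"),
        labels=read_group_labels(paths["phenotype"]),
        interactions=read_interaction_table(paths["interactions"]),
        truth=read_ground_truth(paths["truth"]),
        config=config if config is not None else SynthConfig(),
    )
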