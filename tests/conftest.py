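"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from cernet.io import (
    GROUP_HIGH,
    GROUP_LOW,
    ExpressionMatrix,
    GroupLabels,
    Interaction,
    InteractionTable,
)
from cernet.synthetic import SynthConfig, generate_dataset


def make_labels(n_per_group: int) -> GroupLabels:
    mapping = {f"high_{i + 1}": GROUP_HIGH for i in range(n_per_group)}
    mapping.update({f"low_{i + 1}": GROUP_LOW for i in range(n_per_group)})
    return GroupLabels(mapping)


def make_matrix(
    values: np.ndarray, rna_class: str = "mRNA", prefix: str = "G"
) -> ExpressionMatrix:
    n_genes, n_samples = values.shape
    half = n_samples // 2
    samples = [f"high_{i + 1}" for i in range(half)] + [
        f"low_{i + 1}" for i in range(n_samples - half)
    ]
    genes = [f"{prefix}{i + 1:03d}" for i in range(n_genes)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), rna_class
    )


def planted_feature_matrix(
    seed: int,
    n_per_group: int = 10,
    n_features: int = 70,
    n_informative: int = 5,
    effect: float = 2.5,
    noise_sd: float = 1.0,
) -> tuple[ExpressionMatrix, GroupLabels, set[str]]:
    """lncRNA matrix with the first ``n_informative`` features group-shifted."""
    rng = np.random.default_rng(seed)
    n_informative = min(n_informative, n_features)
    values = rng.normal(8.0, noise_sd, (n_features, 2 * n_per_group))
    shift = np.r_[
        np.full(n_per_group, effect / 2.0), np.full(n_per_group, -effect / 2.0)
    ]
    for i in range(n_informative):
        values[i] += shift if i % 2 == 0 else -shift
    matrix = make_matrix(values, "lncRNA", prefix="LNC")
    return matrix, make_labels(n_per_group), set(matrix.gene_ids[:n_informative])


def brute_force_triplets(
    lncrna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    interactions: InteractionTable,
    de_lnc: set[str],
    de_mrna: set[str],
    de_mirna: set[str],
    pcc_threshold: float = 0.5,
    neg_threshold: float = 0.0,
) -> set[tuple[str, str, str]]:
    """Exhaustive (lncRNA, mRNA, miRNA) enumeration with scipy's pearsonr.

    Independent of the pipeline's vectorized correlation path; re-checks
    every filter condition from scratch.
    """
    found = set()
    for l in sorted(de_lnc):
        lv = lncrna.data.loc[l].to_numpy()
        for m in sorted(de_mrna):
            mv = mrna.data.loc[m].to_numpy()
            if lv.std() == 0 or mv.std() == 0:
                continue
            r_lm = pearsonr(lv, mv)[0]
            if not r_lm > pcc_threshold:
                continue
            for i in sorted(de_mirna):
                if Interaction(i, m, "mRNA") not in interactions:
                    continue
                if Interaction(i, l, "lncRNA") not in interactions:
                    continue
                iv = mirna.data.loc[i].to_numpy()
                if iv.std() == 0:
                    continue
                if pearsonr(iv, mv)[0] < neg_threshold and pearsonr(iv, lv)[0] < neg_threshold:
                    found.add((l, m, i))
    return found


def pair_counting_auc(scores, truth) -> float:
    """AUC oracle: exhaustive case-control pair counting with half-credit ties."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


@pytest.fixture
def small_dataset():
    """Dataset with strong planted structure for recovery-style tests."""
    return generate_dataset(
        SynthConfig(
            n_per_group=10,
            n_mrna=30,
            n_lncrna=30,
            n_mirna=10,
            n_de_per_class=8,
            de_effect=2.0,
            n_triplets=5,
            coupling=0.9,
            n_decoy_interactions=60,
            noise_sd=0.3,
            seed=7,
        )
    )


@pytest.fixture
def labels_5v5():
    return make_labels(5)
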