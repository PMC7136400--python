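"""Two-group differential expression and expression-pattern clustering.

The test statistic is an empirical-Bayes moderated t: each gene's pooled
variance is shrunk toward a prior ``(d0, s0^2)`` estimated by moment
matching on the log-variance distribution, and the statistic is referred to
a t distribution with ``d + d0`` degrees of freedom.  ``prior_df=0``
degenerates to the ordinary pooled two-sample t; ``prior_df=inf`` uses the
common (mean) variance across genes.

Differential-expression filtering uses the raw p-value with a strict
inequality (``p < alpha``); Benjamini-Hochberg q-values are reported
alongside but not used by the default filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .io import GROUP_HIGH, GROUP_LOW, ExpressionMatrix, GroupLabels, ValidationError

DE_COLUMNS = [
    "gene_id",
    "rna_class",
    "mean_high",
    "mean_low",
    "log2fc",
    "direction",
    "t_stat",
    "p_value",
    "q_value",
]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return y


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-matching fit of the scaled-F prior on per-gene variances.

    Returns ``(d0, s0^2)``; ``d0`` may be ``inf`` when the observed
    log-variance spread is no wider than expected from sampling alone.
    """
    positive = s2[s2 > 0]
    if positive.size == 0:
        return 0.0, 0.0
    z = np.log(positive)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    if positive.size < 2:
        return np.inf, float(np.exp(e_mean))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t_test(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated t-test of high_BMD vs low_BMD.

    Parameters
    ----------
    matrix
        Expression matrix for one RNA class.
    labels
        Two-group sample labels covering exactly the matrix's samples.
    prior_df
        ``None`` estimates the prior degrees of freedom from the data;
        ``0`` gives the ordinary pooled two-sample t; ``inf`` uses the
        common variance across genes.

    Returns
    -------
    DataFrame with one row per gene (columns :data:`DE_COLUMNS`), sorted by
    p-value then gene id.  ``log2fc`` is mean(high) - mean(low) and
    ``direction`` is ``up`` when that difference is positive.
    """
    labels.check_matches(matrix.sample_ids)
    high = [s for s in matrix.sample_ids if labels.mapping[s] == GROUP_HIGH]
    low = [s for s in matrix.sample_ids if labels.mapping[s] == GROUP_LOW]
    n1, n2 = len(high), len(low)
    if n1 < 2 or n2 < 2:
        raise ValidationError(
            f"each group needs >= 2 samples (high={n1}, low={n2})"
        )
    if prior_df is not None and prior_df < 0:
        raise ValidationError(f"prior_df must be >= 0, got {prior_df}")

    x1 = matrix.data[high].to_numpy()
    x2 = matrix.data[low].to_numpy()
    mean1 = x1.mean(axis=1)
    mean2 = x2.mean(axis=1)
    diff = mean1 - mean2
    df_resid = n1 + n2 - 2
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) + ((x2 - mean2[:, None]) ** 2).sum(
        axis=1
    )
    s2 = ss / df_resid

    if prior_df is None:
        d0, s0_sq = _fit_variance_prior(s2, df_resid)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    elif np.isinf(prior_df):
        d0, s0_sq = np.inf, float(np.mean(s2))
    else:
        d0 = float(prior_df)
        positive = s2[s2 > 0]
        if positive.size:
            e = np.log(positive) - digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
            s0_sq = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            s0_sq = 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    # zero posterior variance: identical constant genes -> t=0/p=1; a nonzero
    # difference with literally zero variance is a perfect separation -> p=0
    degenerate = (se == 0) & (diff != 0)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.sign(diff) * np.inf, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    p = np.where(degenerate, 0.0, p)
    q = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "rna_class": matrix.rna_class,
            "mean_high": mean1,
            "mean_low": mean2,
            "log2fc": diff,
            "direction": np.where(diff > 0, "up", "down"),
            "t_stat": t,
            "p_value": p,
            "q_value": q,
        }
    )
    return table.sort_values(["p_value", "gene_id"], kind="stable").reset_index(
        drop=True
    )


def filter_de(records: pd.DataFrame, alpha: float, use_q: bool = False) -> pd.DataFrame:
    """Retain records with p < alpha (strict); ``use_q`` filters on q instead."""
    if not 0 < alpha <= 1:
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    column = "q_value" if use_q else "p_value"
    return records[records[column] < alpha].reset_index(drop=True)


def write_de_table(records: pd.DataFrame, path) -> None:
    records[DE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Hierarchical clustering of samples
# ---------------------------------------------------------------------------


@dataclass
class DendrogramResult:
    """Average-linkage tree over samples with a two-cluster cut.

    Distance is 1 - Pearson correlation between sample expression vectors
    over the selected gene set.  ``agreement`` is the best achievable match
    between the two-cluster cut and the phenotype groups (max over the two
    cluster-to-group assignments); ``None`` when no labels were supplied.
    """

    linkage: np.ndarray
    sample_ids: list[str]
    cluster_labels: dict[str, int]
    agreement: float | None = None


def hierarchical_cluster(
    matrix: ExpressionMatrix, labels: GroupLabels | None = None
) -> DendrogramResult:
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    if matrix.n_samples < 2:
        raise ValidationError("clustering needs >= 2 samples")
    if matrix.n_genes < 1:
        raise ValidationError("clustering needs >= 1 gene")
    values = matrix.values
    sds = values.std(axis=0)
    if matrix.n_genes < 2 or (sds == 0).any():
        constant = [s for s, sd in zip(matrix.sample_ids, sds) if sd == 0]
        raise ValidationError(
            "sample correlation undefined (constant expression vectors: "
            f"{constant if constant else matrix.sample_ids})"
        )
    corr = np.corrcoef(values.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    tree = linkage(squareform(dist, checks=False), method="average")
    cut = fcluster(tree, t=2, criterion="maxclust")
    cluster_labels = dict(zip(matrix.sample_ids, (int(c) for c in cut)))

    agreement = None
    if labels is not None:
        labels.check_matches(matrix.sample_ids)
        truth = np.array(
            [1 if labels.mapping[s] == GROUP_HIGH else 2 for s in matrix.sample_ids]
        )
        match = float(np.mean(cut == truth))
        agreement = max(match, 1.0 - match) if set(cut) == {1, 2} else max(
            float(np.mean(truth == c)) for c in set(cut)
        )
    return DendrogramResult(tree, matrix.sample_ids, cluster_labels, agreement)
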