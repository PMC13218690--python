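"""Between-subtype comparisons.

Two families of statistics characterize the subtypes: Wilcoxon rank-sum
comparisons of per-sample scores (NES of each gene set, or any clinical
score) between the two TES groups, and a differential analysis of the
propagated gene profiles with a |log2 fold change| > 1 and p < 0.05 filter.
Raw p-values are reported by default, matching common practice for these
screens; Benjamini-Hochberg correction is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import TesError

STAR_THRESHOLDS = (0.05, 0.01, 0.001)


def stars(p: float) -> str:
    """Significance stars: ns / * / ** / *** at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    median_1: float
    median_2: float
    statistic: float  # Mann-Whitney U of group 1
    p_value: float
    significance: str


@dataclass(frozen=True)
class DifferentialGene:
    gene: str
    log2_fold_change: float
    p_value: float
    passes_filter: bool
    degenerate: bool = False  # both group means were zero


def wilcoxon_compare(values: pd.Series, groups: pd.Series, feature: str | None = None
                     ) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test between two groups.

    Exact enumeration is used when both groups have <= 10 observations and
    the data are tie-free; otherwise the normal approximation with tie
    correction.  Groups are taken in sorted label order (group 1 = smaller
    label, i.e. TES 1).
    """
    values = values.loc[groups.index]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"wilcoxon_compare needs exactly 2 groups, got {len(labels)}")
    a = values[groups == labels[0]].to_numpy(dtype=float)
    b = values[groups == labels[1]].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise TesError(f"non-finite values in feature {feature!r}")
    method = "exact" if (len(a) <= 10 and len(b) <= 10) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return GroupComparison(
        feature=feature or (values.name or "feature"),
        median_1=float(np.median(a)),
        median_2=float(np.median(b)),
        statistic=float(res.statistic),
        p_value=p,
        significance=stars(p),
    )


def compare_features(matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Wilcoxon comparison of every column of a samples x features matrix.

    This is the per-gene-set NES comparison between TESs; the same routine
    serves clinical scores or immune-checkpoint NES (supply the relevant
    columns).
    """
    rows = []
    for col in matrix.columns:
        c = wilcoxon_compare(matrix[col], groups, feature=str(col))
        rows.append({
            "feature": c.feature, "median_tes1": c.median_1, "median_tes2": c.median_2,
            "statistic": c.statistic, "p_value": c.p_value, "significance": c.significance,
        })
    return pd.DataFrame(rows).set_index("feature")


def differential_genes(
    profile: pd.DataFrame,
    groups: pd.Series,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Differential propagated genes between two subtypes.

    Per gene, log2FC = log2((mean_1 + eps) / (mean_2 + eps)) with eps equal
    to the smallest positive profile value times 1e-3 (propagated
    probabilities can be exactly 0 for unreachable genes); p-values come
    from the Wilcoxon rank-sum test.  A gene passes when |log2FC| >
    ``lfc_threshold`` and p < ``p_threshold``.  Output columns include
    volcano-plot-ready ``log2_fold_change`` and ``neg_log10_p``.
    """
    groups = groups.loc[profile.index]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("differential analysis needs exactly 2 groups")
    g1 = profile.loc[groups == labels[0]]
    g2 = profile.loc[groups == labels[1]]
    vals = profile.to_numpy(dtype=float)
    positive = vals[vals > 0]
    eps = float(positive.min()) * 1e-3 if positive.size else 1e-12

    m1 = g1.mean(axis=0).to_numpy()
    m2 = g2.mean(axis=0).to_numpy()
    degenerate = (m1 == 0) & (m2 == 0)
    with np.errstate(divide="ignore"):
        lfc = np.log2((m1 + eps) / (m2 + eps))
    lfc[degenerate] = 0.0

    pvals = np.ones(profile.shape[1])
    a, b = g1.to_numpy(dtype=float), g2.to_numpy(dtype=float)
    for j in range(profile.shape[1]):
        col_a, col_b = a[:, j], b[:, j]
        if np.all(col_a == col_a[0]) and np.all(col_b == col_a[0]):
            pvals[j] = 1.0  # constant gene: no evidence either way
            continue
        method = "exact" if (len(col_a) <= 10 and len(col_b) <= 10) else "asymptotic"
        pvals[j] = stats.mannwhitneyu(col_a, col_b, alternative="two-sided",
                                      method=method).pvalue
    pvals = np.minimum(pvals, 1.0)
    p_for_filter = _benjamini_hochberg(pvals) if bh_correct else pvals

    out = pd.DataFrame({
        "log2_fold_change": lfc,
        "p_value": pvals,
        "neg_log10_p": -np.log10(np.maximum(pvals, np.finfo(float).tiny)),
        "passes_filter": (np.abs(lfc) > lfc_threshold) & (p_for_filter < p_threshold),
        "degenerate": degenerate,
    }, index=profile.columns)
    if bh_correct:
        out["p_adjusted"] = p_for_filter
    out.index.name = "gene"
    return out


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    n = len(pvals)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((pvals[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)
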