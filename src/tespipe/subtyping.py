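"""Survival-aware subtyping of patients from NES profiles.

Gene sets are first filtered by univariate Cox association with overall
survival (Wald p < 0.05 by default).  Patients are then clustered by
K-means on the retained NES columns for every k in 2..10, the k with the
highest mean silhouette width is selected, and cluster labels are oriented
so that TES 1 is the better-prognosis cluster (largest restricted-mean
survival), matching the field's convention that subtype numbering encodes
prognosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import ClusteringError, FilterError
from .geneset_scoring import NESMatrix
from .survival import CoxResult, SurvivalTable, cox_univariate, restricted_mean_survival

DEFAULT_P_THRESHOLD = 0.05
DEFAULT_K_RANGE = tuple(range(2, 11))
DEFAULT_N_INIT = 25


@dataclass
class SubtypeResult:
    """Outcome of the clustering stage.

    labels are 1-based TES labels after orientation; ``silhouette_by_k``
    is the full selection trace; ``orientation`` records the
    restricted-mean survival per original cluster and the applied
    relabeling.
    """

    labels: pd.Series = field(repr=False)
    selected_k: int = 0
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    kept_genesets: list[str] = field(default_factory=list)
    orientation: dict = field(default_factory=dict)
    seed: int | None = None

    def write(self, labels_path, trace_path=None) -> None:
        self.labels.rename("tes_label").to_csv(labels_path, sep="\t")
        if trace_path is not None:
            pd.Series(self.silhouette_by_k, name="mean_silhouette").rename_axis("k").to_csv(
                trace_path, sep="\t")


def filter_prognostic_genesets(
    nes: NESMatrix | pd.DataFrame,
    survival: SurvivalTable,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> tuple[list[str], dict[str, CoxResult]]:
    """Keep gene sets whose NES is associated with survival (Wald p < threshold).

    Each set is scored by a univariate Cox fit of survival on its NES
    column; the returned CoxResults carry the risk/protective direction.
    """
    scores = nes.scores if isinstance(nes, NESMatrix) else nes
    missing = set(scores.index) - set(survival.sample_ids)
    if missing:
        raise FilterError(f"{len(missing)} NES samples lack survival data")
    surv = survival.subset(scores.index)
    results: dict[str, CoxResult] = {}
    kept: list[str] = []
    for name in scores.columns:
        res = cox_univariate(surv, scores[name])
        results[name] = res
        if res.p_value < p_threshold:
            kept.append(name)
    if not kept:
        raise FilterError(
            f"no gene set passed the Cox filter at p < {p_threshold}; "
            "consider raising the threshold"
        )
    return kept, results


def mean_silhouette(points: np.ndarray | pd.DataFrame, labels: Sequence[int]) -> float:
    """Mean silhouette width s(i) = (b - a) / max(a, b), Euclidean distance.

    Singleton clusters contribute s = 0 (scikit-learn's convention, which
    matches the standard definition's limit).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_score(np.asarray(points, dtype=float), labels,
                                  metric="euclidean"))


def fit_subtypes(
    nes: NESMatrix | pd.DataFrame,
    survival: SurvivalTable | None = None,
    kept_genesets: Sequence[str] | None = None,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    n_init: int = DEFAULT_N_INIT,
    seed: int = 0,
    standardize: bool = True,
) -> SubtypeResult:
    """K-means subtyping with silhouette-selected k and prognosis-oriented labels.

    For each k in ``k_range``, K-means (k-means++ initialization, ``n_init``
    restarts, fixed seed) is run on the (optionally z-scored) NES columns
    and the mean silhouette width recorded; the k maximizing it is
    selected.  When ``survival`` is given, labels are oriented so TES 1 has
    the best prognosis; otherwise clusters are numbered by decreasing size.
    """
    scores = nes.scores if isinstance(nes, NESMatrix) else nes
    if kept_genesets is not None:
        scores = scores[list(kept_genesets)]
    x = scores.to_numpy(dtype=float)
    if x.shape[0] <= max(k_range):
        raise ClusteringError(
            f"need more than {max(k_range)} samples to scan k up to {max(k_range)}")
    std = x.std(axis=0)
    if np.all(std == 0):
        raise ClusteringError("NES matrix has zero variance in every column")
    if standardize:
        keep = std > 0
        x = (x[:, keep] - x[:, keep].mean(axis=0)) / std[keep]

    trace: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(x)
        labels_by_k[k] = lab
        trace[k] = mean_silhouette(x, lab) if len(np.unique(lab)) > 1 else float("nan")
    selected_k = max(trace, key=lambda k: (trace[k], -k))
    raw = pd.Series(labels_by_k[selected_k], index=scores.index, name="cluster")

    result = SubtypeResult(labels=raw, selected_k=selected_k, silhouette_by_k=trace,
                           kept_genesets=list(kept_genesets or scores.columns), seed=seed)
    if survival is not None:
        return orient_labels(result, survival)
    # no survival: order clusters by size (desc), then original index
    sizes = raw.value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    mapping = {c: i + 1 for i, c in enumerate(order)}
    result.labels = raw.map(mapping)
    result.orientation = {"criterion": "cluster_size", "mapping": mapping}
    return result


def orient_labels(result: SubtypeResult, survival: SurvivalTable) -> SubtypeResult:
    """Name clusters by prognosis: TES 1 = largest restricted-mean survival.

    The restriction horizon is the largest observed time in the cohort.
    Ties are broken by cluster size (larger first), then original label
    index — a deterministic canonical orientation, so any permutation of
    input label names yields the same output.
    """
    raw = result.labels
    surv = survival.subset(raw.index)
    horizon = float(surv.time.max())
    sizes = raw.value_counts()
    rmst = {c: restricted_mean_survival(surv.subset(raw.index[raw == c]), horizon=horizon)
            for c in sizes.index}
    order = sorted(rmst, key=lambda c: (-round(rmst[c], 12), -sizes[c], c))
    mapping = {c: i + 1 for i, c in enumerate(order)}
    result.labels = raw.map(mapping).rename("tes_label")
    result.orientation = {
        "criterion": "restricted_mean_survival",
        "horizon": horizon,
        "rmst_by_cluster": {str(c): float(v) for c, v in rmst.items()},
        "mapping": {str(c): int(v) for c, v in mapping.items()},
    }
    return result
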