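"""Single-sample gene set enrichment (ssGSEA) on propagated profiles.

For one sample, genes are ranked by propagated value in decreasing order
and assigned the rank-from-bottom statistic (the top gene gets rank N).
Walking down the ranking, an in-set gene advances a weighted in-set ECDF by
rank^alpha / sum(in-set rank^alpha) and an out-of-set gene advances the
uniform out-of-set ECDF by 1 / (N - |S|).  The enrichment score is the
integrated (summed) difference of the two ECDFs over all positions — the
classical ssGSEA statistic with exponent alpha = 0.25.  Raw scores are
normalized to NES by dividing the whole matrix by its global range, which
keeps scores comparable across samples (a requirement for clustering).

Ties in profile values are broken by gene-name lexicographic order for
determinism (propagated values of unreachable genes are commonly 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, NormalizationError

DEFAULT_ALPHA = 0.25


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> ordered unique gene list."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class NESMatrix:
    """Samples x gene-sets normalized enrichment scores."""

    scores: pd.DataFrame = field(repr=False)
    alpha: float = DEFAULT_ALPHA
    normalization_constant: float = 1.0

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def geneset_names(self) -> list[str]:
        return list(self.scores.columns)

    def write(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line as name, description, genes...

    Duplicate genes within a set are removed (first occurrence kept);
    duplicate set names are a format error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            name, desc, *genes = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            genes = list(dict.fromkeys(g.strip() for g in genes if g.strip()))
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = genes
            descriptions[name] = desc
    if not sets:
        raise FormatError(f"empty GMT file: {path}")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def _ranked_order(values: pd.Series) -> np.ndarray:
    """Positions of genes sorted by decreasing value, ties by gene name ascending."""
    frame = pd.DataFrame({"v": values.to_numpy(), "g": values.index})
    order = frame.sort_values(["v", "g"], ascending=[False, True], kind="mergesort")
    return order.index.to_numpy()


def ssgsea_es(profile_row: pd.Series, geneset: Iterable[str],
              alpha: float = DEFAULT_ALPHA) -> float:
    """Raw ssGSEA enrichment score of one gene set on one profile row.

    Returns NaN when the set shares no gene with the profile (the caller
    reports such pairs as missing).
    """
    genes = pd.Index(profile_row.index)
    if len(genes) < 2:
        raise ValueError("profile row must cover at least 2 genes")
    in_set = genes.isin(set(geneset))
    n_hit = int(in_set.sum())
    n = len(genes)
    if n_hit == 0 or n_hit == n:
        return float("nan")
    order = _ranked_order(profile_row)
    ranks = np.empty(n)
    ranks[order] = np.arange(n, 0, -1)  # rank-from-bottom: top value gets N
    hit_sorted = in_set[order]
    rank_sorted = ranks[order]
    w = np.where(hit_sorted, rank_sorted**alpha, 0.0)
    cum_in = np.cumsum(w) / w.sum()
    cum_out = np.cumsum(~hit_sorted) / (n - n_hit)
    return float(np.sum(cum_in - cum_out))


def ssgsea_matrix(
    profile: pd.DataFrame,
    collection: GeneSetCollection | Mapping[str, list[str]],
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw ES for every (sample, gene set) pair, plus a coverage report.

    ``profile`` is samples x genes (e.g. a PropagatedProfile ``values``
    frame).  Genes of a set absent from the profile are ignored, standard
    GSEA behavior; the coverage report gives per-set overlap counts.
    Vectorized over sets within each sample.
    """
    sets = collection.sets if isinstance(collection, GeneSetCollection) else dict(collection)
    genes = profile.columns
    n = len(genes)
    membership = np.zeros((len(sets), n), dtype=bool)
    coverage = []
    for k, (name, members) in enumerate(sets.items()):
        mask = genes.isin(set(members))
        membership[k] = mask
        coverage.append({"geneset": name, "size": len(members),
                         "in_profile": int(mask.sum())})
    n_hit = membership.sum(axis=1)

    values = profile.to_numpy(dtype=float)
    gene_names = genes.to_numpy()
    scores = np.full((profile.shape[0], len(sets)), np.nan)
    for i in range(values.shape[0]):
        order = np.lexsort((gene_names, -values[i]))
        ranks = np.arange(n, 0, -1, dtype=float)  # at sorted positions
        hit = membership[:, order]  # sets x positions
        w = np.where(hit, ranks[None, :] ** alpha, 0.0)
        wsum = w.sum(axis=1)
        ok = (n_hit > 0) & (n_hit < n)
        cum_in = np.cumsum(w, axis=1)
        cum_out = np.cumsum(~hit, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            es = (cum_in / wsum[:, None] - cum_out / (n - n_hit)[:, None]).sum(axis=1)
        scores[i, ok] = es[ok]
    raw = pd.DataFrame(scores, index=profile.index, columns=list(sets))
    return raw, pd.DataFrame(coverage).set_index("geneset")


def normalize_nes(raw: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> NESMatrix:
    """NES = ES / (max ES - min ES), range taken over the entire matrix."""
    flat = raw.to_numpy(dtype=float)
    finite = flat[np.isfinite(flat)]
    if finite.size == 0:
        raise NormalizationError("no finite enrichment scores to normalize")
    spread = float(finite.max() - finite.min())
    if spread == 0.0:
        raise NormalizationError("degenerate enrichment-score range (max == min)")
    return NESMatrix(scores=raw / spread, alpha=alpha, normalization_constant=spread)


def score_profile(
    profile: pd.DataFrame,
    collection: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[NESMatrix, pd.DataFrame]:
    """Convenience: raw ssGSEA then global range normalization."""
    raw, coverage = ssgsea_matrix(profile, collection, alpha=alpha)
    return normalize_nes(raw, alpha=alpha), coverage


def read_nes_tsv(path: str | Path) -> NESMatrix:
    scores = pd.read_csv(path, sep="\t", index_col=0)
    return NESMatrix(scores=scores)
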