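"""Protein-interaction network loading and the RWR transition matrix.

Edges come from a STRING-style links file (``protein1 protein2
combined_score`` on a 0-1000 confidence scale).  Only edges with score
strictly greater than the threshold (default 700, i.e. STRING "high
confidence") are kept.  The transition matrix W is the column-normalized
adjacency, so each column is a probability distribution over neighbors —
the operator the random walk with restart requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import FormatError, ThresholdError

DEFAULT_SCORE_THRESHOLD = 700.0


@dataclass
class GeneNetwork:
    """Undirected weighted gene network with an optional transition matrix.

    nodes are unique gene symbols in lexicographic order; ``edges`` holds one
    row per unordered pair (node1 < node2) with its combined score.  The
    node strings of the input file are used verbatim — any protein-to-gene
    identifier mapping is an upstream concern.
    """

    nodes: list[str]
    edges: pd.DataFrame = field(repr=False)  # columns: node1, node2, score
    transition: sp.csc_matrix | None = field(default=None, repr=False)
    weighted: bool | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}

    def adjacency(self, weighted: bool = False) -> sp.csr_matrix:
        """Symmetric adjacency; entries are 1 (unweighted) or the scores."""
        idx = self.node_index()
        i = self.edges["node1"].map(idx).to_numpy()
        j = self.edges["node2"].map(idx).to_numpy()
        w = self.edges["score"].to_numpy(dtype=float) if weighted else np.ones(len(i))
        n = self.n_nodes
        a = sp.coo_matrix((w, (i, j)), shape=(n, n))
        return (a + a.T).tocsr()


def read_string_links(
    path: str | Path,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> GeneNetwork:
    """Load a STRING protein-links file, keeping edges with score > threshold.

    The file is whitespace- or tab-separated with columns node1, node2,
    score and an optional header.  Duplicate and reciprocal pairs are merged
    keeping the maximum score; self-loops are dropped; nodes with no
    surviving edge do not appear.
    """
    path = Path(path)
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw = parts[0], parts[1], parts[2]
            try:
                score = float(raw)
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise FormatError(f"{path}:{lineno}: malformed score {raw!r}") from None
            if a == b:
                continue
            if score > score_threshold:
                lo, hi = sorted((a, b))
                rows.append((lo, hi, score))
    if not rows:
        raise ThresholdError(
            f"no edges with score > {score_threshold} in {path}; lower --min-score"
        )
    edges = (
        pd.DataFrame(rows, columns=["node1", "node2", "score"])
        .groupby(["node1", "node2"], as_index=False)["score"]
        .max()
        .sort_values(["node1", "node2"], ignore_index=True)
    )
    nodes = sorted(set(edges["node1"]) | set(edges["node2"]))
    return GeneNetwork(nodes=nodes, edges=edges)


def network_from_edges(edges: pd.DataFrame) -> GeneNetwork:
    """Build a GeneNetwork from an in-memory (node1, node2, score) frame."""
    edges = edges.copy()
    lo = edges[["node1", "node2"]].min(axis=1)
    hi = edges[["node1", "node2"]].max(axis=1)
    edges["node1"], edges["node2"] = lo, hi
    edges = (
        edges[edges["node1"] != edges["node2"]]
        .groupby(["node1", "node2"], as_index=False)["score"]
        .max()
        .sort_values(["node1", "node2"], ignore_index=True)
    )
    if edges.empty:
        raise ThresholdError("edge list is empty")
    nodes = sorted(set(edges["node1"]) | set(edges["node2"]))
    return GeneNetwork(nodes=nodes, edges=edges)


def build_transition_matrix(network: GeneNetwork, weighted: bool = False) -> GeneNetwork:
    """Attach the column-stochastic transition matrix W to the network.

    Column j of W is adjacency column j divided by its sum.  With
    ``weighted=False`` (default) retained edges contribute 1 regardless of
    score; with ``weighted=True`` the scores enter the adjacency.  Isolated
    nodes cannot occur (they are excluded at read time), so every column
    sums to exactly 1.
    """
    adj = network.adjacency(weighted=weighted).astype(float)
    col_sums = np.asarray(adj.sum(axis=0)).ravel()
    inv = sp.diags(1.0 / col_sums)
    network.transition = (adj @ inv).tocsc()
    network.weighted = weighted
    return network


def write_string_links(network: GeneNetwork, path: str | Path) -> None:
    """Write the edge list in STRING protein-links format."""
    out = network.edges.rename(
        columns={"node1": "protein1", "node2": "protein2", "score": "combined_score"}
    )
    out.to_csv(path, sep="\t", index=False)
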