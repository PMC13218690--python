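"""Random walk with restart (RWR) network propagation.

Each patient's binary mutation vector is turned into a uniform seed
distribution p0 over their mutated genes that are present in the network,
then smoothed by iterating

    p_{t+1} = (1 - r) W p_t + r p0

with restart probability r (0.75 by default) and column-stochastic W,
starting from p = p0, until the L1 residual ||p_{t+1} - p_t||_1 drops below
the tolerance (1e-6 by default).  The steady state spreads each sample's
mutation mass onto network neighbors, converting the sparse binary profile
into a continuous one.  Because W is column-stochastic and p0 sums to 1,
total probability mass is conserved at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import json
import numpy as np
import pandas as pd

from .errors import ConvergenceError, PipelineError
from .mutation_io import MutationMatrix
from .ppi_network import GeneNetwork

DEFAULT_RESTART = 0.75
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 10_000


@dataclass(frozen=True)
class SeedVector:
    """Normalized restart distribution for one sample."""

    sample_id: str
    probabilities: np.ndarray  # over network nodes, sums to 1
    n_seed_genes: int  # m, the in-network mutated genes


@dataclass
class PropagatedProfile:
    """Steady-state RWR profiles for a cohort.

    ``values`` is samples x network-nodes; every row sums to 1 (within
    1e-9).  ``diagnostics`` records per-sample iteration counts, final
    residuals and seed sizes; ``excluded`` lists samples whose mutated
    genes were all absent from the network (they are reported, never
    silently dropped).
    """

    values: pd.DataFrame = field(repr=False)
    diagnostics: pd.DataFrame = field(repr=False)
    excluded: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def write(self, profile_path: str | Path, diagnostics_path: str | Path | None = None) -> None:
        self.values.to_csv(profile_path, sep="\t")
        if diagnostics_path is not None:
            payload = {
                "excluded_samples": self.excluded,
                "per_sample": self.diagnostics.to_dict(orient="index"),
            }
            Path(diagnostics_path).write_text(json.dumps(payload, indent=2))


def make_seed(mutated_genes: set[str] | list[str], network: GeneNetwork,
              sample_id: str = "") -> SeedVector | None:
    """Uniform seed over the sample's in-network mutated genes.

    Genes absent from the network are ignored.  Returns ``None`` when no
    mutated gene is in the network; callers must report such samples.
    """
    idx = network.node_index()
    hits = sorted(g for g in mutated_genes if g in idx)
    if not hits:
        return None
    p0 = np.zeros(network.n_nodes)
    p0[[idx[g] for g in hits]] = 1.0 / len(hits)
    return SeedVector(sample_id=sample_id, probabilities=p0, n_seed_genes=len(hits))


def rwr(
    seed: SeedVector | np.ndarray,
    network: GeneNetwork,
    r: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, int, float]:
    """Iterate the RWR update for one seed; returns (p_inf, iterations, residual)."""
    if not (0.0 < r <= 1.0):
        raise ValueError(f"restart probability must be in (0, 1], got {r}")
    if network.transition is None:
        raise PipelineError("network has no transition matrix; call build_transition_matrix")
    p0 = seed.probabilities if isinstance(seed, SeedVector) else np.asarray(seed, dtype=float)
    W = network.transition
    p = p0.copy()
    for it in range(1, max_iter + 1):
        p_next = (1.0 - r) * (W @ p) + r * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            return p, it, residual
    raise ConvergenceError(
        f"RWR did not converge in {max_iter} iterations (L1 residual {residual:.3e})"
    )


def propagate_cohort(
    matrix: MutationMatrix,
    network: GeneNetwork,
    r: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PropagatedProfile:
    """Propagate every sample of a mutation matrix over the network.

    All seeds are iterated as one dense block (mathematically identical to
    per-sample iteration; each sample's convergence is tracked with the same
    per-sample L1 stopping rule).  Deterministic: no randomness is involved.
    """
    if not (0.0 < r <= 1.0):
        raise ValueError(f"restart probability must be in (0, 1], got {r}")
    if network.transition is None:
        raise PipelineError("network has no transition matrix; call build_transition_matrix")

    binary = matrix.binarized()
    idx = network.node_index()
    shared = [g for g in binary.columns if g in idx]
    excluded: list[str] = []
    seeds: dict[str, np.ndarray] = {}
    seed_sizes: dict[str, int] = {}

    sub = binary[shared].to_numpy(dtype=float)
    cols = np.array([idx[g] for g in shared], dtype=int)
    for row, sample in zip(sub, binary.index):
        m = int(row.sum())
        if m == 0:
            excluded.append(sample)
            continue
        p0 = np.zeros(network.n_nodes)
        p0[cols[row > 0]] = 1.0 / m
        seeds[sample] = p0
        seed_sizes[sample] = m
    if not seeds:
        raise PipelineError("every sample was excluded: no mutated gene overlaps the network")

    samples = list(seeds)
    P0 = np.column_stack([seeds[s] for s in samples])  # nodes x samples
    W = network.transition
    P = P0.copy()
    iters = np.zeros(len(samples), dtype=int)
    resid = np.full(len(samples), np.inf)
    active = np.ones(len(samples), dtype=bool)
    for it in range(1, max_iter + 1):
        # converged columns are frozen so the block iteration is exactly the
        # per-sample iteration run in parallel
        idx = np.flatnonzero(active)
        P_next = (1.0 - r) * (W @ P[:, idx]) + r * P0[:, idx]
        step = np.abs(P_next - P[:, idx]).sum(axis=0)
        P[:, idx] = P_next
        resid[idx] = step
        newly = idx[step < tol]
        iters[newly] = it
        active[newly] = False
        if not active.any():
            break
    else:
        raise ConvergenceError(
            f"RWR did not converge for {int(active.sum())} samples within {max_iter} "
            f"iterations (max L1 residual {resid[active].max():.3e})"
        )

    values = pd.DataFrame(P.T, index=pd.Index(samples, name="sample_id"),
                          columns=network.nodes)
    diagnostics = pd.DataFrame(
        {
            "iterations": iters,
            "final_residual": resid,
            "n_seed_genes": [seed_sizes[s] for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return PropagatedProfile(values=values, diagnostics=diagnostics, excluded=excluded)
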