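"""Synthetic cohorts with the statistical structure the pipeline assumes.

Real MSK-IMPACT-style cohorts cannot be redistributed, so every downstream
stage is exercised on generated data instead:

* a scale-free interaction network grown by preferential attachment
  (PPI degree distributions are heavy-tailed, and RWR behavior depends on
  hubs), with integer confidence scores drawn above the high-confidence
  threshold so every generated edge survives loading;
* per-subtype driver modules: connected neighborhoods of the network,
  disjoint across subtypes, whose genes mutate at an elevated rate in
  samples of that subtype while every gene carries a background rate;
* tumor-ecosystem-style gene sets: each subtype's driver module is planted
  inside its own subset of gene sets, the rest are random draws, which
  makes the prognostic filter and the clustering signal controllable;
* exponential survival with a multiplicative per-subtype hazard and
  independent exponential censoring — the proportional-hazards world the
  Cox filter assumes, with closed-form oracles for testing.

All randomness flows from a single integer seed; outputs are reproducible
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError
from .geneset_scoring import GeneSetCollection, write_gmt
from .mutation_io import MutationMatrix, matrix_from_frame, write_matrix_tsv
from .ppi_network import GeneNetwork, build_transition_matrix, network_from_edges, \
    write_string_links
from .survival import SurvivalTable

_RESAMPLE_CAP = 100


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters.

    Defaults describe a desk-scale two-subtype cohort with a strong planted
    signal: 300 samples over a 300-gene scale-free network, 68 ecosystem
    gene sets, driver mutation probability 0.8 against a 0.02 background,
    and a hazard ratio of 3 between subtypes.  Hazard rates are per month:
    baseline 0.01 (median survival ~69 months) with censoring rate 0.005
    (about one third of follow-ups censored in the baseline group).
    """

    n_genes: int = 300
    n_samples: int = 300
    n_subtypes: int = 2
    attachment_edges: int = 3
    n_genesets: int = 68
    geneset_size_range: tuple[int, int] = (10, 30)
    n_drivers_per_subtype: int = 10
    n_planted_sets_per_subtype: int = 8
    background_mutation_rate: float = 0.02
    driver_mutation_rate: float = 0.8
    baseline_hazard: float = 0.01
    subtype_hazard_ratio: float = 3.0
    censoring_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples, self.n_subtypes, self.attachment_edges,
               self.n_genesets, self.n_drivers_per_subtype) < 1:
            raise ConfigurationError("all sizes must be positive integers")
        if self.n_genes < self.attachment_edges + 1:
            raise ConfigurationError("n_genes must exceed attachment_edges")
        lo, hi = self.geneset_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ConfigurationError("geneset_size_range must satisfy 1 <= min <= max <= n_genes")
        for name in ("background_mutation_rate", "driver_mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be a probability, got {v}")
        if self.driver_mutation_rate <= self.background_mutation_rate:
            raise ConfigurationError("driver_mutation_rate must exceed background_mutation_rate")
        if self.baseline_hazard <= 0 or self.subtype_hazard_ratio <= 0:
            raise ConfigurationError("hazard parameters must be positive")
        if self.censoring_rate < 0:
            raise ConfigurationError("censoring_rate must be non-negative")
        if self.n_subtypes * self.n_drivers_per_subtype > self.n_genes:
            raise ConfigurationError("driver modules cannot cover more genes than exist")
        if self.n_subtypes * self.n_planted_sets_per_subtype > self.n_genesets:
            raise ConfigurationError("planted gene sets cannot exceed n_genesets")


@dataclass
class SyntheticCohort:
    mutation_matrix: MutationMatrix
    network: GeneNetwork
    genesets: GeneSetCollection
    survival: SurvivalTable
    true_labels: pd.Series = field(repr=False)
    driver_genes: dict[int, list[str]] = field(default_factory=dict)
    config: SyntheticConfig | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_matrix_tsv(self.mutation_matrix, outdir / "mutations.tsv")
        write_string_links(self.network, outdir / "network_links.tsv")
        write_gmt(self.genesets, outdir / "genesets.gmt")
        self.survival.write(outdir / "survival.tsv")
        self.true_labels.rename("true_subtype").to_csv(outdir / "true_labels.tsv", sep="\t")


def generate_network(n_genes: int, attachment_edges: int = 3, seed: int = 0
                     ) -> GeneNetwork:
    """Scale-free gene network by preferential attachment.

    Nodes are named G0001..; each edge gets an integer combined score drawn
    uniformly from 701..1000, above the default high-confidence threshold.
    The graph is connected and deterministic under a fixed seed.
    """
    if n_genes < attachment_edges + 1:
        raise ConfigurationError(
            f"n_genes={n_genes} must exceed attachment_edges={attachment_edges}")
    g = nx.barabasi_albert_graph(n_genes, attachment_edges, seed=int(seed))
    rng = np.random.default_rng(seed)
    names = {i: f"G{i + 1:04d}" for i in g.nodes}
    rows = [(names[a], names[b], int(rng.integers(701, 1001)))
            for a, b in sorted(g.edges())]
    network = network_from_edges(pd.DataFrame(rows, columns=["node1", "node2", "score"]))
    return build_transition_matrix(network)


def _driver_modules(network: GeneNetwork, n_subtypes: int, size: int,
                    rng: np.random.Generator) -> dict[int, list[str]]:
    """Disjoint connected modules, one per subtype, grown by BFS from random roots."""
    g = nx.Graph()
    g.add_edges_from(zip(network.edges["node1"], network.edges["node2"]))
    used: set[str] = set()
    modules: dict[int, list[str]] = {}
    nodes = list(network.nodes)
    for s in range(1, n_subtypes + 1):
        module: list[str] = []
        for _ in range(_RESAMPLE_CAP):
            root = nodes[rng.integers(len(nodes))]
            if root in used:
                continue
            module = []
            frontier = [root]
            seen = set(used)
            while frontier and len(module) < size:
                node = frontier.pop(0)
                if node in seen:
                    continue
                seen.add(node)
                module.append(node)
                frontier.extend(sorted(n for n in g.neighbors(node) if n not in seen))
            if len(module) == size:
                break
        if len(module) < size:
            raise GenerationError(
                f"could not place a disjoint driver module of size {size} for subtype {s}; "
                "lower n_drivers_per_subtype or n_subtypes")
        used.update(module)
        modules[s] = sorted(module)
    return modules


def _genesets(config: SyntheticConfig, genes: list[str],
              modules: dict[int, list[str]], rng: np.random.Generator
              ) -> GeneSetCollection:
    lo, hi = config.geneset_size_range
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for s, drivers in modules.items():
        for j in range(config.n_planted_sets_per_subtype):
            size = max(int(rng.integers(lo, hi + 1)), len(drivers))
            fill = [g for g in genes if g not in drivers]
            extra = list(rng.choice(fill, size=size - len(drivers), replace=False))
            name = f"planted_s{s}_{j + 1:02d}"
            sets[name] = sorted(set(drivers) | set(extra))
            descriptions[name] = f"contains the subtype-{s} driver module"
    n_random = config.n_genesets - len(sets)
    for j in range(n_random):
        size = int(rng.integers(lo, hi + 1))
        name = f"random_{j + 1:02d}"
        sets[name] = sorted(rng.choice(genes, size=size, replace=False))
        descriptions[name] = "random background gene set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort (network, mutations, gene sets, survival).

    Each sample's subtype is drawn uniformly; the sample then mutates every
    gene with the background rate and its subtype's driver genes with the
    driver rate.  Samples that end up with zero mutations are resampled (up
    to a cap) so the cohort keeps exactly ``n_samples`` rows.  Survival
    times are Exponential with hazard ``baseline_hazard *
    subtype_hazard_ratio**(subtype - 1)``, censored by an independent
    Exponential(``censoring_rate``) follow-up limit.
    """
    rng = np.random.default_rng(config.seed)
    network = generate_network(config.n_genes, config.attachment_edges, seed=config.seed)
    genes = list(network.nodes)
    modules = _driver_modules(network, config.n_subtypes,
                              config.n_drivers_per_subtype, rng)
    genesets = _genesets(config, genes, modules, rng)

    sample_ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    labels = rng.integers(1, config.n_subtypes + 1, size=config.n_samples)
    gene_idx = {g: i for i, g in enumerate(genes)}
    driver_cols = {s: np.array([gene_idx[g] for g in m]) for s, m in modules.items()}

    counts = np.zeros((config.n_samples, len(genes)), dtype=np.int64)
    for i, s in enumerate(labels):
        for attempt in range(_RESAMPLE_CAP):
            row = rng.random(len(genes)) < config.background_mutation_rate
            row[driver_cols[s]] |= rng.random(len(driver_cols[s])) < config.driver_mutation_rate
            if row.any():
                counts[i] = row.astype(np.int64)
                break
        else:
            raise GenerationError(
                "a sample drew zero mutations in "
                f"{_RESAMPLE_CAP} attempts; background_mutation_rate="
                f"{config.background_mutation_rate} and driver_mutation_rate="
                f"{config.driver_mutation_rate} are too low")

    matrix = matrix_from_frame(pd.DataFrame(counts, index=sample_ids, columns=genes))

    hazards = config.baseline_hazard * config.subtype_hazard_ratio ** (labels - 1.0)
    death = rng.exponential(1.0 / hazards)
    if config.censoring_rate > 0:
        censor = rng.exponential(1.0 / config.censoring_rate, size=config.n_samples)
    else:
        censor = np.full(config.n_samples, np.inf)
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    survival = SurvivalTable(pd.DataFrame(
        {"time": time, "event": event},
        index=pd.Index(sample_ids, name="sample_id")))

    true_labels = pd.Series(labels, index=pd.Index(sample_ids, name="sample_id"),
                            name="true_subtype")
    return SyntheticCohort(mutation_matrix=matrix, network=network, genesets=genesets,
                           survival=survival, true_labels=true_labels,
                           driver_genes=modules, config=config)
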