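"""End-to-end orchestration of the four-step subtyping workflow.

The clinical workflow is: (1) ingest somatic mutation profiles, (2) smooth
them by RWR propagation over the interaction network, (3) score the
propagated profiles against the ecosystem gene sets as NES, and (4) either
cluster into TESs (training) or feed the NES into a pre-trained classifier
(new samples).  ``run_pipeline`` executes the training path —
ingest -> propagate -> score -> Cox-filter -> subtype -> characterize ->
train — writing every artifact with a JSON run manifest so a rerun with the
same config is bit-identical for the deterministic stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import hashlib
import json

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .characterization import compare_features, differential_genes
from .classifier import ClassifierSpec, train_cv
from .errors import ConfigurationError, PipelineError, TesError
from .geneset_scoring import read_gmt, score_profile
from .mutation_io import read_maf_table, build_mutation_matrix, read_matrix_tsv
from .ppi_network import read_string_links, build_transition_matrix
from .propagation import propagate_cohort
from .subtyping import filter_prognostic_genesets, fit_subtypes
from .survival import logrank_test, read_survival_tsv

TRAIN_FRACTION = 0.7


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run; loadable from YAML."""

    mutations: str = ""              # MAF-like TSV, or a matrix TSV with matrix_input
    network: str = ""                # STRING-style links file
    gmt: str = ""                    # ecosystem gene sets
    survival: str = ""               # sample_id / time / event TSV
    matrix_input: bool = False       # mutations path is a precomputed count matrix
    min_score: float = 700.0
    weighted_transition: bool = False
    restart: float = 0.75
    tol: float = 1e-6
    alpha: float = 0.25
    k_min: int = 2
    k_max: int = 10
    p_threshold: float = 0.05
    n_init: int = 25
    standardize: bool = True
    train_fraction: float | None = None  # None: no split, subtype the whole cohort
    train_classifier: bool = False
    seed: int = 0
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        spec = raw.pop("classifier", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if spec:
            cfg.classifier = ClassifierSpec(**spec)
        return cfg

    def validate_paths(self) -> None:
        for name in ("mutations", "network", "gmt", "survival"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise ConfigurationError(f"config path {name!r} missing or not found: {p!r}")


def train_test_split_ids(sample_ids, train_fraction: float = TRAIN_FRACTION,
                         seed: int = 0) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive split with training size = floor(n * fraction).

    A 7:3 split of 2,526 samples gives exactly 1,768 training and 758
    testing samples.  Shuffling uses the given seed.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ConfigurationError(f"train_fraction must be in (0,1), got {train_fraction}")
    ids = list(sample_ids)
    n_train = int(np.floor(len(ids) * train_fraction))
    perm = np.random.default_rng(seed).permutation(len(ids))
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return train, test


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the training workflow; returns a summary dict (also written).

    Every stage failure is re-raised as a PipelineError naming the stage
    and keeping the original message as the remediation hint.
    """
    config.validate_paths()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except TesError as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    def load_mutations():
        if config.matrix_input:
            return read_matrix_tsv(config.mutations)
        return build_mutation_matrix(read_maf_table(config.mutations))

    matrix = stage("ingest", load_mutations)
    network = stage("network", lambda: build_transition_matrix(
        read_string_links(config.network, score_threshold=config.min_score),
        weighted=config.weighted_transition))
    genesets = stage("genesets", lambda: read_gmt(config.gmt))
    survival = stage("survival", lambda: read_survival_tsv(config.survival))

    profile = stage("propagate", lambda: propagate_cohort(
        matrix, network, r=config.restart, tol=config.tol))
    profile.write(outdir / "propagated.tsv", outdir / "propagation_diagnostics.json")

    nes, coverage = stage("score", lambda: score_profile(
        profile.values, genesets, alpha=config.alpha))
    nes.write(outdir / "nes.tsv")
    coverage.to_csv(outdir / "geneset_coverage.tsv", sep="\t")

    ids = [s for s in nes.sample_ids if s in set(survival.sample_ids)]
    if not ids:
        raise PipelineError("stage 'filter' failed: no sample has survival data")
    if config.train_fraction:
        train_ids, test_ids = train_test_split_ids(ids, config.train_fraction, config.seed)
    else:
        train_ids, test_ids = ids, []

    nes_train = nes.scores.loc[train_ids]
    surv_train = survival.subset(train_ids)
    kept, cox_results = stage("filter", lambda: filter_prognostic_genesets(
        nes_train, surv_train, p_threshold=config.p_threshold))
    pd.DataFrame(
        [{"geneset": n, "beta": r.beta, "hazard_ratio": r.hazard_ratio,
          "p_value": r.p_value, "direction": r.direction, "kept": n in kept}
         for n, r in cox_results.items()]
    ).set_index("geneset").to_csv(outdir / "cox_filter.tsv", sep="\t")

    result = stage("subtype", lambda: fit_subtypes(
        nes_train, surv_train, kept_genesets=kept,
        k_range=range(config.k_min, config.k_max + 1),
        n_init=config.n_init, seed=config.seed, standardize=config.standardize))
    result.write(outdir / "tes_labels.tsv", outdir / "silhouette_trace.tsv")

    summary: dict = {
        "n_samples": matrix.n_samples,
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "excluded_samples": profile.excluded,
        "n_kept_genesets": len(kept),
        "selected_k": result.selected_k,
        "silhouette_by_k": result.silhouette_by_k,
        "orientation": result.orientation,
    }

    if result.labels.nunique() == 2:
        stat, p = logrank_test(surv_train, result.labels)
        summary["logrank_statistic"], summary["logrank_p"] = stat, p
        compare_features(nes_train, result.labels).to_csv(
            outdir / "nes_comparisons.tsv", sep="\t")
        differential_genes(profile.values.loc[train_ids], result.labels).to_csv(
            outdir / "differential_genes.tsv", sep="\t")

    if config.train_classifier:
        clf, report = stage("train", lambda: train_cv(
            nes_train, result.labels, config.classifier))
        clf.save(outdir / "classifier.json")
        summary["cv_accuracy_mean"] = report.cv_accuracy_mean
        summary["cv_accuracy_pooled"] = report.cv_accuracy_pooled
        summary["roc_auc"] = report.roc_auc
        report.feature_importance.to_csv(outdir / "feature_importance.tsv", sep="\t")

    manifest = {
        "tespipe_version": __version__,
        "config": _jsonable(asdict(config)),
        "config_hash": hashlib.sha256(
            json.dumps(_jsonable(asdict(config)), sort_keys=True).encode()).hexdigest(),
        "summary": _jsonable(summary),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
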