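"""End-to-end orchestration: simulate -> filter -> Rapp -> features -> train
-> score -> cluster -> stats, with a single serializable configuration and a
machine-readable summary.

Every stage is the corresponding library function; this module only wires
them together, logs per-stage timing and record counts, and writes the run
artifacts (feature table, ROC table, edge list, complex list, stats,
summary JSON, manifest) into the output directory. Reruns with the same
configuration produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import (
    calibration,
    complex_detection,
    network_stats,
    pair_features,
    ppi_classifier,
    profiles,
    reference_complexes,
    synthetic_data,
)
from .errors import ConfigurationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters plus the global seed. Unknown keys are rejected."""

    simulation: synthetic_data.SimulationConfig = field(
        default_factory=synthetic_data.SimulationConfig
    )
    min_psm: int = 2
    smooth_window: int = 3
    prefilter: float = 0.5
    mi_bins: int = 5
    bayes_alpha: float = 1.0
    negative_ratio: float = 5.0
    n_folds: int = 5
    learner: str = "forest"
    n_trees: int = 500
    threshold_policy: str = "precision"  # "precision" or "fixed"
    target_precision: float = 0.9
    edge_threshold: float = 0.5  # used when threshold_policy == "fixed"
    penalty: float = 2.0
    merge_threshold: float = 0.8
    min_size: int = 3
    min_density: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_policy not in ("precision", "fixed"):
            raise ConfigurationError(
                f"unknown threshold_policy {self.threshold_policy!r}"
            )
        if self.learner not in ("forest", "logistic"):
            raise ConfigurationError(f"unknown learner {self.learner!r}")
        if not 0.0 < self.target_precision <= 1.0:
            raise ConfigurationError("target_precision must be in (0, 1]")
        if not 0.0 <= self.edge_threshold <= 1.0:
            raise ConfigurationError("edge_threshold must be in [0, 1]")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        sim_data = data.pop("simulation", {})
        known_sim = {f.name for f in dataclasses.fields(synthetic_data.SimulationConfig)}
        unknown = set(sim_data) - known_sim
        if unknown:
            raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
        if "experiments" in sim_data:
            sim_data["experiments"] = tuple(
                (str(t), int(n)) for t, n in sim_data["experiments"]
            )
        for tup_key in ("complex_size_range", "mass_range_kda"):
            if tup_key in sim_data:
                sim_data[tup_key] = tuple(sim_data[tup_key])
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline keys: {sorted(unknown)}")
        sim_data.setdefault("seed", data.get("seed", 0))
        return cls(simulation=synthetic_data.SimulationConfig(**sim_data), **data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("pipeline config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        out["simulation"]["experiments"] = [
            list(e) for e in out["simulation"]["experiments"]
        ]
        out["simulation"]["complex_size_range"] = list(
            out["simulation"]["complex_size_range"]
        )
        out["simulation"]["mass_range_kda"] = list(out["simulation"]["mass_range_kda"])
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class _StageTimer:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, *exc):
        log.info("stage %s: done in %.2fs", self.name, time.perf_counter() - self.t0)
        return False


def run_pipeline(config: PipelineConfig, out_dir) -> dict[str, Any]:
    """Execute all stages; returns the summary dict (also written as JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {}

    with _StageTimer("simulate"):
        truth = synthetic_data.generate_ground_truth(config.simulation)
        matrices = synthetic_data.simulate_dataset(truth, config.simulation)
        data_dir = out_dir / "data"
        synthetic_data.write_fixture(truth, matrices, data_dir)
    summary["n_proteins"] = len(truth.proteins)
    summary["n_planted_complexes"] = len(truth.complexes)

    with _StageTimer("filter"):
        retained, _reasons = profiles.filter_min_psm(matrices, config.min_psm)
    summary["n_retained"] = len(retained)

    with _StageTimer("rapp"):
        masses = truth.monomer_mass
        tables = []
        for m in matrices:
            if m.technique != "SEC":
                continue
            standards = calibration.read_standards(
                data_dir / f"{m.experiment_id}_standards.tsv"
            )
            model = calibration.fit_calibration(standards)
            tables.append(
                calibration.rapp_table(m, model, masses, window=config.smooth_window)
            )
        states = calibration.combine_states(tables)
        degraded = {p for p, s in states.items() if s == calibration.DEGRADED}
    summary["n_degraded"] = len(degraded)

    with _StageTimer("features"):
        scoring_universe = retained - degraded
        table = pair_features.build_feature_table(
            matrices,
            scoring_universe,
            prefilter=config.prefilter,
            n_bins=config.mi_bins,
            alpha=config.bayes_alpha,
            window=config.smooth_window,
        )
        pair_features.write_feature_table(table, out_dir / "features.tsv")
    summary["n_candidate_pairs"] = int(len(table))

    with _StageTimer("train"):
        refset = reference_complexes.read_complex_file(
            data_dir / synthetic_data.REFERENCE_COMPLEX_FILE,
            universe=scoring_universe,
        )
        candidates = list(zip(table["protein_a"], table["protein_b"]))
        labels = reference_complexes.derive_labels(
            refset, candidates, max_negative_ratio=config.negative_ratio,
            seed=config.seed,
        )
        folds = reference_complexes.complex_level_folds(
            refset, k=min(config.n_folds, len(refset)), seed=config.seed
        )
        pair_folds = reference_complexes.assign_pair_folds(labels, refset, folds)
        model = ppi_classifier.train(
            table, labels, seed=config.seed, learner=config.learner,
            n_trees=config.n_trees,
        )
        evaluation = ppi_classifier.evaluate(model, table, labels, pair_folds)
        roc = out_dir / "roc.tsv"
        with open(roc, "w") as fh:
            fh.write("fpr\ttpr\n")
            for f, t in zip(evaluation.fpr, evaluation.tpr):
                fh.write(f"{f:.6f}\t{t:.6f}\n")
    summary["n_positive"] = model.n_positive
    summary["n_negative"] = model.n_negative
    summary["auc"] = round(float(evaluation.auc), 6)

    with _StageTimer("score"):
        if config.threshold_policy == "precision":
            threshold = ppi_classifier.precision_targeting_threshold(
                evaluation, config.target_precision
            )
        elif config.threshold_policy == "fixed":
            threshold = config.edge_threshold
        else:
            raise ConfigurationError(
                f"unknown threshold_policy {config.threshold_policy!r}"
            )
        summary["edge_threshold_used"] = round(float(threshold), 6)
        network = ppi_classifier.score_all(model, table, threshold)
        network_stats.write_edge_list(network.retained, out_dir / "network_edges.tsv")
        graph = network.to_graph()
    summary["n_edges"] = int(len(network.retained))
    summary["n_network_proteins"] = int(graph.number_of_nodes())

    with _StageTimer("cluster"):
        predicted = complex_detection.detect_complexes(
            graph,
            penalty=config.penalty,
            merge_threshold=config.merge_threshold,
            min_size=config.min_size,
            min_density=config.min_density,
        ) if graph.number_of_nodes() else []
        complex_detection.write_complexes(predicted, out_dir / "complexes.tsv")
        supported = complex_detection.complex_supported_pairs(graph, predicted)
        network_stats.write_pair_list(supported, out_dir / "complex_ppis.tsv")
    summary["n_complexes"] = len(predicted)
    summary["n_complex_ppis"] = len(supported)

    with _StageTimer("stats"):
        degrees, _ = network_stats.degree_distribution(graph)
        degrees.to_csv(out_dir / "degrees.tsv", sep="\t", index=False)
        true_pairs = truth.true_pairs()
        if len(network.retained):
            edge_pairs = list(
                zip(network.retained["protein_a"], network.retained["protein_b"])
            )
            overlap = network_stats.overlap_with_reference(edge_pairs, true_pairs)
            summary["edge_true_fraction"] = round(overlap["fraction"], 6)
        else:
            summary["edge_true_fraction"] = None
        recovery, _best = complex_detection.complex_recovery(
            [c.members for c in predicted],
            truth.reference_complexes(),
            min_size=config.min_size,
        )
        summary["complex_recovery"] = round(recovery, 6)

    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return summary
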