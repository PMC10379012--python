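"""End-to-end orchestration: split, encode, graph, embed, train, evaluate.

The protocol is transductive for the graph stage and inductive for the
classifier: the bi-profile Bayes profiles are fitted on training rows
only, all rows are then encoded, the similarity graph and embeddings are
computed over every sample (train and test together), and the boosted
ensemble is fitted on the training rows alone before being scored on the
held-out rows.  An ``--inductive``-style switch instead builds the graph
on training rows only and attaches each test row to its nearest training
samples; the switch changes the protocol, never the math.

A single master seed fans out deterministically into named per-stage
substreams (split, flnsa, walks, skip-gram, training, simulate), so any
stage can be re-run independently yet reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import (PredictionResult, PromoterBoostedClassifier,
                         TrainingConfig, assemble_features, predict,
                         train_ensemble)
from .embeddings import SCALE_ORDER, EmbeddingMatrix, MultiScaleEmbedder
from .encoders import LOCAL_PARTS, LocalEncoder
from .evaluation import MetricsReport, evaluate_predictions
from .flnsa import FLNSA, SequenceGraph
from .io import DataSplit, PromoterDataset, stratified_split
from .simulate import SyntheticConfig, generate_dataset

_STAGES = ("simulate", "split", "flnsa", "walks", "skipgram", "training")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic named substream seed derived from the master seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(master_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class FlnsaConfig:
    neighborhood_ratio: float = 0.1
    mu: float = 1.0
    tol: float = 1e-6
    max_iter: int = 500
    backbone_c: int = 3
    min_edge_weight: float = 0.0


@dataclass
class EmbedConfig:
    scales: tuple[str, ...] = SCALE_ORDER
    node_dim: int = 64
    p: float = 1.0
    q: float = 1.0
    walks_per_node: int = 10
    walk_length: int = 40
    window: int = 5
    epochs: int = 5
    negative: int = 5
    community_k: int = 16
    global_max_step: int = 4
    global_dim_per_step: int = 16


@dataclass
class ExperimentConfig:
    """Everything one end-to-end run depends on, seeded by ``seed``."""

    test_fraction: float = 0.2
    parts: tuple[str, ...] = LOCAL_PARTS
    pseudocount: float = 1.0
    flnsa: FlnsaConfig = field(default_factory=FlnsaConfig)
    embed: EmbedConfig = field(default_factory=EmbedConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    threshold: float = 0.5
    transductive: bool = True
    seed: int = 0


@dataclass
class ExperimentResult:
    """All artifacts of one end-to-end run."""

    config: ExperimentConfig
    split: DataSplit
    encoder: LocalEncoder
    graph: SequenceGraph
    embedding: EmbeddingMatrix
    table: pd.DataFrame
    model: PromoterBoostedClassifier
    predictions: PredictionResult
    metrics: MetricsReport
    timings: dict[str, float]


def _attach_test_rows(graph: SequenceGraph, X_train: np.ndarray,
                      X_test: np.ndarray, test_pos: np.ndarray,
                      n_total: int, train_pos: np.ndarray,
                      backbone_c: int) -> SequenceGraph:
    """Inductive placement: link each test row to its nearest train rows."""
    from scipy.spatial.distance import cdist

    adj = np.zeros((n_total, n_total))
    adj[np.ix_(train_pos, train_pos)] = graph.adjacency
    positive = graph.adjacency[graph.adjacency > 0]
    floor = float(positive.min()) if positive.size else 1e-6
    dist = cdist(X_test, X_train)
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :backbone_c]
    provenance = {
        (int(train_pos[i]), int(train_pos[j])): tag
        for (i, j), tag in graph.provenance.items()
    }
    for row, i in enumerate(test_pos):
        for j_loc in nearest[row]:
            j = int(train_pos[j_loc])
            adj[i, j] = adj[j, i] = floor
            provenance[(min(i, j), max(i, j))] = "connectivity_backbone"
    return SequenceGraph(adjacency=adj, provenance=provenance)


def run_experiment(
    dataset: PromoterDataset,
    config: ExperimentConfig | None = None,
    split: DataSplit | None = None,
) -> ExperimentResult:
    """Run split -> BPB fit (train only) -> encode -> graph -> embed ->
    train -> evaluate on the held-out rows."""
    config = config or ExperimentConfig()
    labels = dataset.labels
    sequences = dataset.sequences
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if split is None:
        split = stratified_split(
            dataset, config.test_fraction, stage_seed(config.seed, "split")
        )
    timings["split"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    train_idx = split.train_indices
    test_idx = split.test_indices
    encoder = LocalEncoder(parts=config.parts, pseudocount=config.pseudocount)
    encoder.fit(
        [sequences[i] for i in train_idx],
        labels[train_idx],
        ids=[dataset.records[i].identifier for i in train_idx],
    )
    X_local = encoder.transform(sequences)
    local_df = pd.DataFrame(X_local, columns=encoder.feature_names_)
    timings["encode"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fl = FLNSA(
        neighborhood_ratio=config.flnsa.neighborhood_ratio,
        mu=config.flnsa.mu,
        tol=config.flnsa.tol,
        max_iter=config.flnsa.max_iter,
        backbone_c=config.flnsa.backbone_c,
        min_edge_weight=config.flnsa.min_edge_weight,
        seed=stage_seed(config.seed, "flnsa"),
    )
    if config.transductive:
        fl.fit(X_local)
        graph = fl.graph_
    else:
        fl.fit(X_local[train_idx])
        graph = _attach_test_rows(
            fl.graph_, X_local[train_idx], X_local[test_idx], test_idx,
            len(dataset), train_idx, config.flnsa.backbone_c,
        )
    timings["flnsa"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    embedder = MultiScaleEmbedder(
        scales=config.embed.scales,
        node_dim=config.embed.node_dim,
        p=config.embed.p,
        q=config.embed.q,
        walks_per_node=config.embed.walks_per_node,
        walk_length=config.embed.walk_length,
        window=config.embed.window,
        epochs=config.embed.epochs,
        negative=config.embed.negative,
        community_k=config.embed.community_k,
        global_max_step=config.embed.global_max_step,
        global_dim_per_step=config.embed.global_dim_per_step,
        seed=stage_seed(config.seed, "walks"),
    )
    embedding = embedder.fit_transform(graph)
    timings["embed"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    emb_part = embedding if embedding.dim > 0 else None
    table = assemble_features(local_df, emb_part)
    # train/test hygiene: the BPB profiles must come from the split's train rows
    if encoder.bpb_ is not None:
        manifest = set(encoder.bpb_.model_.fit_manifest)
        assert len(manifest) == len(train_idx), "BPB fitted outside the train split"
    model = train_ensemble(
        table, labels, train_idx, config.training,
        seed=stage_seed(config.seed, "training"),
    )
    timings["train"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    predictions = predict(model, table, test_idx, config.threshold)
    metrics = evaluate_predictions(
        labels[test_idx], predictions.scores, config.threshold
    )
    timings["evaluate"] = time.perf_counter() - t0

    return ExperimentResult(
        config=config, split=split, encoder=encoder, graph=graph,
        embedding=embedding, table=table, model=model,
        predictions=predictions, metrics=metrics, timings=timings,
    )


@dataclass
class RunConfig:
    """Disk-level run description: data source plus experiment settings."""

    synthetic: SyntheticConfig | None = None
    positives_fasta: str | None = None
    negatives_fasta: str | None = None
    window_length: int = 300
    tss_index: int = 249
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    out_dir: str = "runs/run"

    def resolve_dataset(self) -> PromoterDataset:
        if self.synthetic is not None:
            return generate_dataset(self.synthetic)[0]
        if not (self.positives_fasta and self.negatives_fasta):
            raise ValueError("need either a synthetic config or two FASTA paths")
        from .io import read_fasta, validate_dataset

        records = read_fasta(self.positives_fasta, 1) + read_fasta(
            self.negatives_fasta, 0
        )
        dataset, _report = validate_dataset(
            records, self.window_length, self.tss_index, "drop"
        )
        return dataset


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full run and persist every artifact under ``out_dir``.

    Writes metrics.json, predictions.tsv, graph_edges.tsv, embeddings.tsv,
    the fitted BPB tables, the config echo and a manifest with versions,
    per-stage seeds, timings and artifact checksums.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = config.resolve_dataset()
    result = run_experiment(dataset, config.experiment)

    metrics_path = out / "metrics.json"
    metrics_path.write_text(json.dumps(result.metrics.to_dict(), indent=1, sort_keys=True))

    preds_path = out / "predictions.tsv"
    with open(preds_path, "w") as fh:
        fh.write("id\tscore\tlabel\n")
        for row, idx in enumerate(result.split.test_indices):
            rec = dataset.records[idx]
            fh.write(f"{rec.identifier}\t{result.predictions.scores[row]:.10g}"
                     f"\t{result.predictions.labels[row]}\n")

    graph_path = out / "graph_edges.tsv"
    result.graph.write_edge_list(graph_path)

    emb_path = out / "embeddings.tsv"
    pd.DataFrame(
        result.embedding.vectors, columns=result.embedding.column_names
    ).to_csv(emb_path, sep="\t", index=False)

    artifacts = [metrics_path, preds_path, graph_path, emb_path]
    if result.encoder.bpb_ is not None:
        bpb_path = out / "bpb_model.json"
        result.encoder.bpb_.model_.to_json(bpb_path)
        artifacts.append(bpb_path)

    config_path = out / "config.json"
    config_path.write_text(json.dumps(asdict(config), indent=1, default=str))
    artifacts.append(config_path)

    import lightgbm
    import scipy
    import sklearn

    manifest = {
        "versions": {
            "promgraph": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
            "lightgbm": lightgbm.__version__,
            "pandas": pd.__version__,
        },
        "master_seed": config.experiment.seed,
        "stage_seeds": {s: stage_seed(config.experiment.seed, s) for s in _STAGES},
        "timings_sec": result.timings,
        "n_records": len(dataset),
        "checksums": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
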