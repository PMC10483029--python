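"""End-to-end orchestration: features -> mimics -> ensemble -> consensus -> outputs.

:func:`run_cluster` wires the whole pipeline and writes every artifact a run
produces — the assignment TSV, the metrics JSON, the per-member loss-trace
CSV, a run manifest with the full configuration, and (optionally) static
plots.  Given identical inputs, configuration and seed, every output byte
is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as gio
from .deep import ModelConfig, TrainParams, write_loss_trace
from .ensemble import EnsembleResult, train_ensemble
from .features import featurize_dataset
from .metrics import evaluate
from .mimics import MutationModel, make_pairs
from .nonparametric import density_cluster, resolve_noise

__all__ = ["RunConfig", "RunResult", "run_cluster"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a clustering run.

    Exactly one of ``n_clusters`` (parametric mode) or ``nonparametric=True``
    must be active.  In nonparametric mode the cluster head still needs a
    width for training; ``head_width`` sets it and the final number of
    clusters comes from density clustering of the embedding.
    """

    fasta: str
    labels: Optional[str] = None
    out_dir: str = "genosig_out"
    # features
    k: int = 6
    add_rev_comp: bool = False
    # mimics
    p_transition: float = 1e-2
    p_transversion: float = 0.5e-2
    p_indel: float = 0.0
    fragment_fraction: float = 1.0
    n_mimics: int = 3
    # model / training
    n_clusters: Optional[int] = None
    nonparametric: bool = False
    head_width: int = 32
    hidden_dims: tuple[int, ...] = (128,)
    embed_dim: int = 32
    proj_dim: int = 32
    n_heads: int = 4
    epochs: int = 40
    batch_size: int = 512
    learning_rate: float = 1e-3
    lam: float = 1.0
    temperature: float = 0.5
    n_voters: int = 10
    min_cluster_size: Optional[int] = None
    seed: int = 0
    plots: bool = False
    metrics_on_features: bool = False

    def __post_init__(self) -> None:
        if (self.n_clusters is None) == (not self.nonparametric):
            raise ValueError(
                "exactly one of n_clusters (parametric) or nonparametric mode "
                "must be selected"
            )

    def mutation_model(self) -> MutationModel:
        return MutationModel(
            p_transition=self.p_transition,
            p_transversion=self.p_transversion,
            p_indel=self.p_indel,
            fragment_fraction=self.fragment_fraction,
        )


@dataclass
class RunResult:
    dataset: gio.Dataset
    ensemble: EnsembleResult
    labels: np.ndarray
    confidence: np.ndarray
    report: MetricsReport
    out_dir: Path
    n_clusters_found: Optional[int] = None
    noise_fraction: Optional[float] = None


class StageError(RuntimeError):
    """An error in a named pipeline stage."""


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def run_cluster(config: RunConfig) -> RunResult:
    """Run the full clustering pipeline and write all outputs.

    On error the stage name is prefixed to the message and partial outputs
    are removed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, out_dir, written)
    except Exception:
        for path in written:
            try:
                path.unlink(missing_ok=True)
            except OSError:
                pass
        raise


def _run(config: RunConfig, out_dir: Path, written: list[Path]) -> RunResult:
    with _stage("sequence_io"):
        dataset = gio.read_fasta(config.fasta)
        if config.labels:
            dataset = gio.read_labels(config.labels, dataset)
        stats = dataset.stats()

    with _stage("features"):
        features = featurize_dataset(dataset, k=config.k, add_rev_comp=config.add_rev_comp)

    with _stage("mimics"):
        seed_seq = np.random.SeedSequence(config.seed)
        mimic_seed, model_seed = (int(s) for s in seed_seq.generate_state(2) % (2**31))
        pairs = make_pairs(
            dataset,
            config.mutation_model(),
            n_mimics=config.n_mimics,
            k=config.k,
            add_rev_comp=config.add_rev_comp,
            seed=mimic_seed,
        )

    with _stage("deep_clustering"):
        k_c = config.n_clusters if config.n_clusters is not None else config.head_width
        model_config = ModelConfig(
            input_dim=4**config.k,
            n_clusters=int(k_c),
            hidden_dims=tuple(config.hidden_dims),
            embed_dim=config.embed_dim,
            proj_dim=config.proj_dim,
            n_heads=config.n_heads,
            seed=model_seed,
        )
        params = TrainParams(
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            lam=config.lam,
            temperature=config.temperature,
        )
        result, traces = train_ensemble(
            features, pairs, model_config, params, n_members=config.n_voters
        )

    n_found: Optional[int] = None
    noise_fraction: Optional[float] = None
    if config.nonparametric:
        with _stage("nonparametric"):
            emb = result.reference_embedding
            dens = density_cluster(emb, config.min_cluster_size)
            n_found = dens.n_clusters_found
            noise_fraction = dens.noise_fraction
            resolved = resolve_noise(dens, emb)
            labels = resolved.labels
            confidence = np.ones(len(dataset))
            if resolved.noise_index.size:
                # heuristic: resolved noise points get 1 - normalized distance rank
                ranks = np.argsort(np.argsort(resolved.noise_distance))
                confidence[resolved.noise_index] = 1.0 - (ranks + 1) / (
                    resolved.noise_index.size + 1
                )
    else:
        labels = result.consensus_labels
        confidence = result.confidence

    with _stage("metrics"):
        embedding = (
            features if config.metrics_on_features else result.reference_embedding
        )
        report = evaluate(dataset, labels, embedding=embedding)

    with _stage("outputs"):
        assign_path = out_dir / "assignments.tsv"
        out = EnsembleResult(
            members=result.members,
            consensus_labels=np.asarray(labels),
            confidence=np.asarray(confidence),
            reference_index=result.reference_index,
        )
        gio.write_assignments(dataset, out, assign_path)
        written.append(assign_path)

        metrics_path = out_dir / "metrics.json"
        report.to_json(metrics_path)
        written.append(metrics_path)

        trace_path = out_dir / "loss_trace.csv"
        write_loss_trace(traces, trace_path)
        written.append(trace_path)

        manifest = {
            "config": _jsonable(dataclasses.asdict(config)),
            "dataset": {
                "count": stats.count,
                "min_length": stats.min_length,
                "avg_length": stats.avg_length,
                "max_length": stats.max_length,
            },
            "n_clusters_found": n_found,
            "noise_fraction": noise_fraction,
        }
        manifest_path = out_dir / "manifest.json"
        with open(manifest_path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(manifest_path)

    if config.plots:
        try:
            from .plots import export_plots

            export_plots(
                out_dir,
                embedding=result.reference_embedding,
                labels=np.asarray(labels),
                posterior=result.members[result.reference_index].posterior,
                traces=traces,
            )
        except Exception as exc:  # plots must never fail a run
            warnings.warn(f"plot export failed: {exc}", stacklevel=2)

    return RunResult(
        dataset=dataset,
        ensemble=result,
        labels=np.asarray(labels),
        confidence=np.asarray(confidence),
        report=report,
        out_dir=out_dir,
        n_clusters_found=n_found,
        noise_fraction=noise_fraction,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
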