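"""High-level pipelines: configuration in, output files out.

This is the programmatic equivalent of a command-line front end: a
:class:`RunConfig` selects one of four pipelines (``mst``, ``greedy``,
``eval``, ``simulate``) and :func:`run` executes it, writing the cluster
file, MST file, metrics JSON or simulated FASTA as appropriate.  Resolved
parameters (k, S or P, d_max) are logged, and a warning is issued when the
requested threshold exceeds the resolvable maximum d_max.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import evaluation, greedy_cluster, mst_cluster, simulate, sketching
from .clustering import Clustering, write_clusters
from .errors import UsageError
from .genome_io import read_genome_list, read_single_fasta, write_fasta
from .sketching import MODE_CONTAINMENT, MODE_RESEMBLANCE

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline invocation.

    ``subcommand``: mst | greedy | eval | simulate.  ``input_path`` is a
    FASTA (or, with ``list_mode``, a file of FASTA paths).  ``mst_file``
    re-cuts a stored MST instead of re-sketching (mst only).  For eval,
    ``input_path`` is a cluster file and ``labels_path`` the truth TSV.
    """

    subcommand: str
    input_path: str | None = None
    list_mode: bool = False
    threshold: float | None = None
    k: int | None = None
    sketch_size: int | None = None
    proportion: float | None = None
    mst_file: str | None = None
    labels_path: str | None = None
    output_prefix: str = "sketchclust"
    rng_seed: int = 0
    scheme: str = "seed_mutant"
    sim_kwargs: dict = field(default_factory=dict)


def _provenance(cfg: RunConfig, params: sketching.SketchParams | None) -> list[str]:
    lines = [f"sketchclust {cfg.subcommand}"]
    if params is not None:
        size = (
            f"S={params.sketch_size}"
            if params.mode == MODE_RESEMBLANCE
            else f"P={params.proportion!r}"
        )
        lines.append(
            f"params k={params.k} mode={params.mode} {size} "
            f"hash_seed={params.hash_seed} threshold={params.threshold!r}"
        )
    return lines


def _load_genomes(cfg: RunConfig):
    if cfg.input_path is None:
        raise UsageError(f"{cfg.subcommand} requires an input path")
    reader = read_genome_list if cfg.list_mode else read_single_fasta
    return reader(cfg.input_path)


def _check_threshold(params, lengths) -> None:
    d_max = sketching.max_threshold(
        params,
        min_length=min(lengths) if params.mode == MODE_CONTAINMENT else None,
    )
    logger.info("maximum resolvable distance threshold d_max=%.5g", d_max)
    if params.threshold > d_max:
        logger.warning(
            "distance threshold %g exceeds d_max=%.5g; clusters beyond that "
            "scale are not resolvable at this sketch granularity",
            params.threshold, d_max,
        )


def run(config: RunConfig) -> dict:
    """Execute the configured pipeline; returns a dict of output paths
    plus the in-memory results."""
    sub = config.subcommand
    if sub == "mst":
        return _run_mst(config)
    if sub == "greedy":
        return _run_greedy(config)
    if sub == "eval":
        return _run_eval(config)
    if sub == "simulate":
        return _run_simulate(config)
    raise UsageError(f"unknown subcommand: {config.subcommand}")


def _run_mst(cfg: RunConfig) -> dict:
    if cfg.mst_file is not None:
        state = mst_cluster.load_mst(cfg.mst_file)
        clusters, state = mst_cluster.clust_mst(
            mst_state=state, threshold=cfg.threshold
        )
        params = state.params
        lengths = dict(zip(state.ids, state.lengths))
    else:
        genomes = _load_genomes(cfg)
        params = sketching.resolve_params(
            genomes,
            k=cfg.k,
            mode=MODE_RESEMBLANCE,
            sketch_size=cfg.sketch_size,
            threshold=cfg.threshold,
        )
        _check_threshold(params, [g.length for g in genomes])
        sketches = sketching.sketch_genomes(genomes, params)
        clusters, state = mst_cluster.clust_mst(
            sketches, params, threshold=params.threshold
        )
        lengths = {g.id: g.length for g in genomes}
    cluster_path = f"{cfg.output_prefix}.clusters.tsv"
    mst_path = f"{cfg.output_prefix}.mst"
    write_clusters(clusters, lengths, cluster_path, _provenance(cfg, params))
    mst_cluster.save_mst(state, mst_path)
    return {
        "clusters": clusters,
        "state": state,
        "cluster_file": cluster_path,
        "mst_file": mst_path,
    }


def _run_greedy(cfg: RunConfig) -> dict:
    genomes = _load_genomes(cfg)
    params = sketching.resolve_params(
        genomes,
        k=cfg.k,
        mode=MODE_RESEMBLANCE if cfg.sketch_size is not None else MODE_CONTAINMENT,
        sketch_size=cfg.sketch_size,
        proportion=cfg.proportion,
        threshold=cfg.threshold,
    )
    _check_threshold(params, [g.length for g in genomes])
    sketches = sketching.sketch_genomes(genomes, params)
    clusters = greedy_cluster.clust_greedy(
        sketches, params.threshold, mode=params.mode
    )
    cluster_path = f"{cfg.output_prefix}.clusters.tsv"
    lengths = {g.id: g.length for g in genomes}
    write_clusters(clusters, lengths, cluster_path, _provenance(cfg, params))
    return {"clusters": clusters, "cluster_file": cluster_path}


def _run_eval(cfg: RunConfig) -> dict:
    from .clustering import read_clusters

    if cfg.input_path is None or cfg.labels_path is None:
        raise UsageError("eval requires a cluster file and a truth-label TSV")
    pred = read_clusters(cfg.input_path)
    truth = evaluation.read_labels_tsv(cfg.labels_path)
    metrics = {
        "n_genomes": len(pred.labels),
        "n_clusters": pred.n_clusters,
        "purity": evaluation.purity(pred, truth),
        "nmi": evaluation.nmi(pred, truth),
        "coverage": evaluation.coverage(pred),
    }
    metrics_path = f"{cfg.output_prefix}.metrics.json"
    impurity_path = f"{cfg.output_prefix}.impurity.tsv"
    evaluation.write_metrics_json(metrics, metrics_path)
    evaluation.write_impurity_tsv(
        evaluation.impurity_report(pred, truth), impurity_path
    )
    return {
        "metrics": metrics,
        "metrics_file": metrics_path,
        "impurity_file": impurity_path,
    }


def _run_simulate(cfg: RunConfig) -> dict:
    rng = np.random.default_rng(cfg.rng_seed)
    if cfg.scheme == "seed_mutant":
        genomes, truth = simulate.make_seed_mutant_dataset(rng=rng, **cfg.sim_kwargs)
    elif cfg.scheme == "fragment_containment":
        genomes, truth = simulate.make_containment_dataset(rng=rng, **cfg.sim_kwargs)
    else:
        raise UsageError(f"unknown simulation scheme: {cfg.scheme}")
    fasta_path = f"{cfg.output_prefix}.fasta"
    labels_path = f"{cfg.output_prefix}.labels.tsv"
    write_fasta(genomes, fasta_path)
    simulate.write_labels_tsv(truth, labels_path)
    return {
        "genomes": genomes,
        "truth": truth,
        "fasta_file": fasta_path,
        "labels_file": labels_path,
    }
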