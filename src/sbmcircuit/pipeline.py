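"""End-to-end orchestration of the circuit-analysis pipeline.

``run_core`` executes binarize -> per-graph spectral clustering ->
consensus -> block model -> circuit -> walks in memory; ``run_pipeline``
adds metadata-dependent stages (biomarker annotation, growth), persists
every artifact under a run directory and writes a manifest that suffices
to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from sbmcircuit import annotate, growth, io, metrics
from sbmcircuit.binarize import choose_p_conn, sample_binary_ensemble, strength_to_probability
from sbmcircuit.blockmodel import estimate_block_probabilities, floor_to_circuit
from sbmcircuit.consensus import consensus_cluster, ensemble_from_graph_labels
from sbmcircuit.embed import cluster_single_graph
from sbmcircuit.walks import WalkCircuit, percentile_flags, walk_stats

log = logging.getLogger("sbmcircuit")


@dataclass(frozen=True)
class PipelineConfig:
    """The five model parameters plus execution knobs.

    Defaults mirror the full-scale reference parameterization
    ``{p_conn=0.15, d=11, G=100, tau=0.95, c_size=100}``; ``p_conn=None``
    selects the grid value whose mean nonzero connection probability is
    closest to 0.5, and ``d=None`` selects the embedding dimension by
    profile likelihood per graph.
    """

    p_conn: float | None = 0.15
    d: int | None = 11
    G: int = 100
    tau: float = 0.95
    c_size: int = 100
    m: int = 100_000
    seed: int = 0
    k_max: int = 20
    elbow: int = 1
    covariance: str = "full"
    enum_cap: int = 10
    hub_quantile: float = 0.9
    save_similarity: bool = False

    def __post_init__(self):
        if self.p_conn is not None and not 0.0 < self.p_conn <= 1.0:
            raise ValueError(f"p_conn must lie in (0, 1], got {self.p_conn}")
        if self.G < 1:
            raise ValueError(f"G must be >= 1, got {self.G}")
        if not 0.0 < self.tau <= 1.0:
            raise ValueError(f"tau must lie in (0, 1], got {self.tau}")
        if self.c_size < 1:
            raise ValueError(f"c_size must be >= 1, got {self.c_size}")


@dataclass
class PipelineResult:
    config: PipelineConfig
    p_conn: float
    ensemble: object
    clusterings: object
    partition: object
    block_probabilities: object
    circuit: object
    stats: object = None
    similarity: np.ndarray = field(default=None, repr=False)


def run_core(strengths, config: PipelineConfig) -> PipelineResult:
    """Strength matrix to circuit and walk statistics, in memory."""
    strengths = sp.csr_matrix(strengths)
    n = strengths.shape[0]
    ss = np.random.SeedSequence(config.seed)
    seed_ensemble, seed_cluster, seed_walks = ss.spawn(3)

    p_conn = config.p_conn if config.p_conn is not None else choose_p_conn(strengths)
    log.info("binarize: p_conn=%.4f, G=%d", p_conn, config.G)
    probs = strength_to_probability(strengths, p_conn)
    ensemble = sample_binary_ensemble(probs, config.G, seed=seed_ensemble)
    if ensemble.degenerate:
        raise RuntimeError("binarize: some stochastic realization trimmed to empty")

    cluster_seeds = seed_cluster.spawn(config.G)
    per_graph = []
    for l, (A, retained) in enumerate(zip(ensemble.graphs, ensemble.retained)):
        t0 = time.perf_counter()
        result = cluster_single_graph(
            A,
            d=config.d,
            k_max=config.k_max,
            seed=int(cluster_seeds[l].generate_state(1)[0]),
            elbow=config.elbow,
            covariance=config.covariance,
        )
        log.info(
            "cluster graph %d/%d: k=%d (%.1fs)",
            l + 1,
            config.G,
            result.k,
            time.perf_counter() - t0,
        )
        per_graph.append((result.labels, retained))

    clusterings = ensemble_from_graph_labels(per_graph, n)
    partition, similarity = consensus_cluster(clusterings, tau=config.tau, c_size=config.c_size)
    log.info(
        "consensus: kappa=%d, assigned %.1f%%", partition.kappa, 100 * partition.assigned_fraction
    )
    if partition.kappa == 0:
        raise RuntimeError("consensus: every component fell below c_size")

    bpm = estimate_block_probabilities(partition, ensemble)
    circuit = floor_to_circuit(bpm)
    stats = None
    if circuit.kappa >= 2:
        stats = walk_stats(
            WalkCircuit.from_circuit(circuit),
            m=config.m,
            seed=seed_walks,
            enum_cap=config.enum_cap,
        )
    return PipelineResult(
        config=config,
        p_conn=p_conn,
        ensemble=ensemble,
        clusterings=clusterings,
        partition=partition,
        block_probabilities=bpm,
        circuit=circuit,
        stats=stats,
        similarity=similarity,
    )


def run_pipeline(
    strengths,
    out_dir,
    config: PipelineConfig | None = None,
    metadata: pd.DataFrame | None = None,
) -> Path:
    """Full run with artifact persistence; returns the run directory."""
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "binarize/cluster/consensus"
    try:
        result = run_core(strengths, config)

        stage = "persist"
        neuron_ids = (
            metadata["neuron_id"].tolist()
            if metadata is not None and "neuron_id" in metadata
            else None
        )
        io.save_partition(result.partition, out_dir / "partition.csv", neuron_ids=neuron_ids)
        ids = neuron_ids or [f"neuron_{i:06d}" for i in range(result.clusterings.n)]
        rows = []
        for g, labels in enumerate(result.clusterings.labels):
            present = labels != -1
            rows.append(
                pd.DataFrame(
                    {
                        "neuron_id": np.asarray(ids, dtype=object)[present],
                        "graph_index": g,
                        "cluster_label": labels[present],
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(out_dir / "graph_labels.csv", index=False)
        if config.save_similarity:
            from scipy.io import mmwrite

            mmwrite(
                str(out_dir / "similarity.mtx"),
                sp.coo_matrix(result.similarity),
                field="real",
                symmetry="symmetric",
            )
        io.save_matrix_csv(result.block_probabilities.p_hat, out_dir / "block_probabilities.csv")
        io.save_circuit(
            result.circuit,
            graphml_path=out_dir / "circuit.graphml",
            edgelist_path=out_dir / "circuit_edges.csv",
        )
        if result.stats is not None:
            io.save_matrix_csv(result.stats.absorption, out_dir / "absorption.csv")
            io.save_matrix_csv(result.stats.shortest, out_dir / "shortest_path.csv")
            io.save_matrix_csv(result.stats.driftiness, out_dir / "driftiness.csv")
            flags = percentile_flags(result.stats)
            io.save_json(
                {k: np.asarray(v).tolist() for k, v in flags.items()},
                out_dir / "walk_flags.json",
            )

        stage = "metrics"
        if result.circuit.kappa >= 3:
            report = metrics.hub_report(result.circuit, quantile=config.hub_quantile)
            pd.DataFrame(
                {
                    "class_id": np.arange(1, result.circuit.kappa + 1),
                    "weighted_degree": report.weighted_degree,
                    "betweenness": report.betweenness,
                    "hub": report.hubs,
                }
            ).to_csv(out_dir / "hubs.csv", index=False)
        io.save_json(metrics.connectome_summary(strengths), out_dir / "summary.json")

        stage = "annotate"
        if metadata is not None:
            labels = result.partition.labels
            assigned = labels > 0
            schemes = {"connectivity": labels[assigned].astype(str)}
            for col in ("neurotransmitter", "community", "birthtime"):
                if col in metadata:
                    values = metadata[col].to_numpy()[assigned]
                    schemes[col] = values
                    table = annotate.posterior_table(labels[assigned].astype(str), values)
                    table.to_csv(out_dir / f"posterior_{col}.csv")
            annotate.nmi_matrix(schemes).to_csv(out_dir / "nmi_matrix.csv")

        stage = "growth"
        if metadata is not None and "birthtime" in metadata:
            series = growth.build_daily_series(
                result.partition.labels, metadata["birthtime"].to_numpy()
            )
            profile = growth.growth_percentages(series)
            pd.DataFrame(
                profile.g,
                index=[f"class_{k + 1}" for k in range(profile.g.shape[0])],
                columns=[f"day_{d}" for d in profile.days],
            ).to_csv(out_dir / "growth.csv")
            periods = growth.critical_periods(profile)
            pd.DataFrame(
                {
                    "class_id": np.arange(1, len(periods) + 1),
                    "critical_days": [";".join(str(d) for d in days) for days in periods],
                }
            ).to_csv(out_dir / "critical_periods.csv", index=False)

        manifest = {
            "config": dataclasses.asdict(config),
            "p_conn": result.p_conn,
            "kappa": result.partition.kappa,
            "assigned_fraction": result.partition.assigned_fraction,
            "n_edges": result.circuit.n_edges,
            "floor_threshold": result.circuit.floor_threshold,
            "version": "0.1.0",
        }
        io.save_json(manifest, out_dir / "manifest.json")
    except Exception as exc:
        record = {"stage": stage, "error": type(exc).__name__, "message": str(exc)}
        try:
            io.save_json(record, out_dir / "error.json")
        except OSError:
            pass
        raise
    return out_dir
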