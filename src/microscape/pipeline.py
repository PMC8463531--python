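"""Top-level workflows: landscape analysis of a table, and the
simulation + metastability-statistics study.

Every run writes its resolved configuration, seeds and a stage log
next to its outputs, so a run directory is self-describing and exactly
reproducible from the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import betadiv_stats, simulator, table_io
from .landscape import (
    CoverSpec,
    MapperLandscape,
    occupancy_summary,
)

__all__ = ["RunConfig", "run_landscape_workflow", "run_simulation_workflow"]

logger = logging.getLogger("microscape")


@dataclass
class RunConfig:
    """Resolved parameters of one run; defaults are the study settings."""

    # landscape
    intervals: int = 15
    overlap: float = 0.70
    bins: int = 10
    knn: str = "auto"  # "auto" or an integer as text
    occupancy_keys: tuple[str, ...] = ()
    # simulation
    species: int = 50
    individuals: int = 500
    timesteps: int = 600
    replicates: int = 450
    connectivity: tuple[float, ...] = (0.0, 0.01, 0.1)
    n_fixed: tuple[int, ...] = (0, 100, 200)
    extinction_prob: float = 0.1
    growth_prob: float = 0.5
    response: str = "auto"
    # bookkeeping
    seed: int = 0

    def dump(self, path: Path) -> None:
        payload = dataclasses.asdict(self)
        payload = {k: (list(v) if isinstance(v, tuple) else v) for k, v in payload.items()}
        path.write_text(json.dumps(payload, indent=2) + "\n")


def _setup_run_dir(out_dir, config: RunConfig) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.dump(out / "config.json")
    for old in [h for h in logger.handlers if isinstance(h, logging.FileHandler)]:
        logger.removeHandler(old)
        old.close()
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return out


def run_landscape_workflow(
    table_path,
    out_dir,
    metadata_path=None,
    config: RunConfig = None,
    orientation: str = "samples-in-rows",
) -> Path:
    """Full landscape analysis of an abundance table.

    Writes the JSD matrix, the ordination with its relative-eigenvalue
    table, the Mapper graph (GraphML), the attractor partition (JSON)
    and, when metadata is available, occupancy tables per requested
    key.  A missing metadata file skips the occupancy stage with a
    warning; every other stage still runs.
    """
    config = config or RunConfig()
    out = _setup_run_dir(out_dir, config)
    stage = "read_table"
    try:
        table = table_io.read_abundance_table(table_path, orientation=orientation)
        logger.info("read table %s: %d samples x %d features",
                    table_path, table.n_samples, table.n_features)

        stage = "landscape"
        knn_k = "auto" if config.knn == "auto" else int(config.knn)
        model = MapperLandscape(
            n_intervals=config.intervals,
            overlap=config.overlap,
            n_bins=config.bins,
            knn_k=knn_k,
        ).fit(table)

        stage = "write_outputs"
        dm = model.distance_matrix_
        pd.DataFrame(dm.D, index=dm.sample_ids, columns=dm.sample_ids).to_csv(
            out / "jsd.tsv", sep="\t"
        )
        ordn = model.ordination_
        coords = pd.DataFrame(
            ordn.coordinates,
            index=ordn.sample_ids,
            columns=[f"PCo{i + 1}" for i in range(ordn.n_axes)],
        )
        coords.to_csv(out / "ordination.tsv", sep="\t")
        eig = pd.DataFrame(
            {
                "PCo": np.arange(1, ordn.n_axes + 1),
                "eigenvalue": ordn.eigenvalues,
                "relative_eigenvalue": ordn.relative_eigenvalues,
            }
        )
        eig.to_csv(out / "relative_eigenvalues.tsv", sep="\t", index=False)
        nx.write_graphml(_decorated_graph(model), out / "mapper.graphml")
        (out / "attractors.json").write_text(model.partition_.to_json() + "\n")
        logger.info("landscape: %d nodes, %d attractors",
                    model.graph_.n_nodes, model.n_attractors_)

        stage = "occupancy"
        if metadata_path is not None and Path(metadata_path).exists():
            metadata = table_io.read_metadata(metadata_path)
            missing = set(metadata.sample_ids) - set(table.sample_ids)
            if missing:
                logger.warning("metadata references %d sample(s) absent from the table",
                               len(missing))
            keys = config.occupancy_keys or [
                c for c in ("generation", "timepoint", "group", "treatment",
                            "start_mode", "birth_mode", "tissue")
                if c in metadata.columns
            ]
            for key in keys:
                occ = occupancy_summary(model.partition_, metadata, [key])
                occ.to_csv(out / f"occupancy_by_{key}.tsv", sep="\t", index=False)
        else:
            logger.warning("no metadata provided; occupancy stage skipped")
    except Exception as err:  # noqa: BLE001 - annotate with failing stage
        raise RuntimeError(f"landscape workflow failed at stage {stage!r} "
                           f"(input {table_path})") from err
    return out


def _decorated_graph(model: MapperLandscape) -> nx.Graph:
    g = model.graph_.to_networkx()
    for node in g.nodes:
        g.nodes[node]["attractor"] = model.partition_.basin_of_node.get(node, -1)
        g.nodes[node]["members"] = ",".join(g.nodes[node].pop("members"))
    return g


def run_simulation_workflow(out_dir, config: RunConfig = None) -> Path:
    """Simulation grid + Morisita pairing + GLM ranking + deviance test."""
    config = config or RunConfig()
    out = _setup_run_dir(out_dir, config)
    stage = "simulate"
    try:
        sim_config = simulator.SimConfig(
            S=config.species,
            I=config.individuals,
            timesteps=config.timesteps,
            replicates=config.replicates,
            extinction_prob=config.extinction_prob,
            growth_prob=config.growth_prob,
        )
        results = simulator.run_experiment(
            config.connectivity, config.n_fixed, sim_config, seed=config.seed
        )
        simulator.results_to_dataframe(results).to_csv(
            out / "simulations.tsv", sep="\t", index=False
        )
        logger.info("simulated %d replicates over %d combinations",
                    len(results), len(config.connectivity) * len(config.n_fixed))

        stage = "metastability_analysis"
        pairs, ranking, test, kind = betadiv_stats.metastability_analysis(
            results, seed=config.seed, response=config.response
        )
        pairs.to_csv(out / "morisita_pairs.tsv", sep="\t", index=False)
        ranking.table.to_csv(out / "model_ranking.tsv", sep="\t", index=False)
        report = {
            "response": kind,
            "best_model": ranking.best,
            "deviance": test.deviance,
            "df": test.df,
            "p_value": test.p_value,
        }
        (out / "deviance_test.json").write_text(json.dumps(report, indent=2) + "\n")
        logger.info("best model %s; deviance test p=%.4f", ranking.best, test.p_value)
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"simulation workflow failed at stage {stage!r}") from err
    return out
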