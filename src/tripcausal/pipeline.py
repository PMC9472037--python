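"""Config-driven orchestration of the full causal-analysis workflow.

``run_pipeline`` executes, from one YAML/JSON config: trip-table input (a CSV
or a synthetic-generation block) -> complete-case filter -> standardization ->
a-priori forbidden edges -> DAG learning -> backdoor identification ->
adjusted-regression effect table -> random-confounder robustness -> artifact
export. One seed in the config fans out deterministically to every stochastic
stage, so a rerun reproduces the outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .graph import CausalDAG
from .model import CausalEffectsModel, CausalEffectsResults
from .notears import NotearsOptions
from .sem import STUDY_CATEGORIES, generate_sem_spec, simulate_trips

__all__ = ["PipelineError", "load_config", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage-labelled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def load_config(path) -> dict:
    """Read a YAML or JSON pipeline config."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage labelling boundary
                raise PipelineError(name, str(exc)) from exc

        return inner

    return wrap


@_stage("input")
def _load_table(config: dict, seed: int, out: Path | None) -> tuple[pd.DataFrame, dict]:
    if "synthetic" in config:
        block = dict(config["synthetic"])
        n = int(block.pop("n", 1638))
        scale = block.pop("scale", "standardized")
        spec = generate_sem_spec(block, seed=seed)
        table = simulate_trips(spec, n, seed=seed, scale=scale)
        categories = dict(spec.categories)
        if out is not None:
            spec.to_json(out / "sem.json")
            table.to_csv(out / "trips.csv", index=False)
        logger.info("simulated %d trips (%s scale)", n, scale)
    elif "input_csv" in config:
        table = pd.read_csv(config["input_csv"])
        categories = dict(config.get("categories", {}))
        if not categories and set(table.columns) <= set(STUDY_CATEGORIES):
            categories = {c: STUDY_CATEGORIES[c] for c in table.columns}
        logger.info("loaded %d trips from %s", len(table), config["input_csv"])
    else:
        raise ValueError("config needs an 'input_csv' path or a 'synthetic' block")
    non_numeric = [c for c in table.columns if not pd.api.types.is_numeric_dtype(table[c])]
    if non_numeric:
        raise ValueError(f"non-numeric column(s) in trip table: {non_numeric}")
    return table, categories


def _options(config: dict) -> NotearsOptions:
    return NotearsOptions(**config.get("notears", {}))


def run_pipeline(
    config: dict,
    out_dir=None,
    seed: int | None = None,
    stop_after: str | None = None,
) -> CausalEffectsResults | CausalDAG | pd.DataFrame:
    """Run the workflow described by ``config``.

    Config keys: ``input_csv`` or ``synthetic`` (generator block with
    ``preset``/``n``/``scale``), ``categories``, ``forbidden`` ("temporal",
    a pair list, or null), ``notears`` (hyperparameter block), ``refute``
    (``n_repeats``), ``alpha``, ``seed``. ``seed`` as an argument overrides
    the config. ``stop_after`` in {"simulate", "learn"} truncates the run and
    returns the trip table or the learned DAG; the default runs everything
    and returns :class:`CausalEffectsResults`.
    """
    if seed is None:
        seed = int(config.get("seed", 0))
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
    _log_params(config, seed, out)

    table, categories = _load_table(config, seed, out)
    if stop_after == "simulate":
        return table

    try:
        model = CausalEffectsModel(
            table,
            categories=categories,
            forbidden=config.get("forbidden", "temporal" if categories else None),
            options=_options(config),
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("validation", str(exc)) from exc

    graph = None
    if "graph_csv" in config:
        edges = pd.read_csv(config["graph_csv"])
        graph = CausalDAG.from_edges(
            edges[["source", "target", "weight"]].itertuples(index=False),
            nodes=list(table.columns),
            categories=categories,
        )

    if stop_after == "learn":
        prepared, std = _stage("standardize")(model.prepare)()
        mask = model.forbidden.mask(model.columns)
        from dataclasses import replace

        from .notears import notears_fit, threshold_graph

        opts = replace(model.options, forbidden_mask=mask)
        W = _stage("learn")(notears_fit)(prepared[model.columns].to_numpy(float), opts)
        dag = _stage("threshold")(threshold_graph)(
            W, opts.omega, model.columns, categories=categories
        )
        if out is not None:
            dag.to_edge_csv(out / "dag_edges.csv")
            dag.to_graphml(out / "dag.graphml")
            dag.to_dot_file(out / "dag.dot")
            if std is not None:
                std.to_json(out / "standardization.json")
        return dag

    refute_cfg = config.get("refute", {})
    results = _stage("fit")(model.fit)(
        graph=graph,
        seed=seed,
        refute=refute_cfg.get("enabled", True),
        n_refute=int(refute_cfg.get("n_repeats", 20)),
        alpha=float(config.get("alpha", 0.05)),
        bh_correction=bool(config.get("bh_correction", False)),
    )
    if out is not None:
        results.save(out)
        logger.info("artifacts written to %s", out)
    return results


def _log_params(config: dict, seed: int, out: Path | None) -> None:
    effective = {
        "seed": seed,
        "alpha": config.get("alpha", 0.05),
        "forbidden": config.get("forbidden", "temporal"),
        "notears": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in vars(_options(config)).items()
            if k != "forbidden_mask"
        },
        "refute": {"n_repeats": config.get("refute", {}).get("n_repeats", 20)},
        "input": config.get("input_csv", config.get("synthetic")),
    }
    logger.info("effective parameters: %s", json.dumps(effective, sort_keys=True))
    if out is not None:
        with open(out / "run_log.json", "w") as fh:
            json.dump(effective, fh, indent=2, sort_keys=True)
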