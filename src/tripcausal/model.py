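"""Model/Results interface for the causal driving/well-being analysis.

:class:`CausalEffectsModel` holds a trip table plus the a-priori knowledge
(variable categories, forbidden edges, optimizer settings); ``fit()`` runs the
three-step workflow — learn the causal DAG by continuous optimization,
identify each edge's backdoor adjustment set, estimate each effect by
adjusted regression — plus the random-confounder robustness check, and
returns a :class:`CausalEffectsResults` with the effect table, the learned
graph, and a printable summary.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import prep
from .effects import CausalEstimate, effect_table, estimates_frame
from .graph import CausalDAG
from .notears import (
    ForbiddenEdgeSet,
    NotearsOptions,
    notears_fit,
    temporal_forbidden_set,
    threshold_graph,
)
from .refute import refute_random_confounder

__all__ = ["CausalEffectsModel", "CausalEffectsResults"]


class CausalEffectsModel:
    """Causal-effect analysis of a trip table.

    Parameters
    ----------
    data
        Trip table (rows = trips, columns = study variables). Raw or already
        standardized; with ``standardize=True`` (default) the model
        standardizes every analysis column to mean 0, SD 1.
    categories
        Optional node -> causal stage map (see :data:`tripcausal.sem.CATEGORIES`);
        needed for the temporal forbidden-edge policy and for ordering the
        effect table by the study's groupings.
    forbidden
        ``"temporal"`` (default, requires categories) derives the a-priori
        exclusions from the temporal ordering of the stages; alternatively a
        :class:`ForbiddenEdgeSet` / iterable of (source, target) pairs, or
        ``None`` for no exclusions.
    options
        :class:`NotearsOptions` for the structure-learning stage.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        categories: dict[str, str] | None = None,
        forbidden="temporal",
        options: NotearsOptions | None = None,
        *,
        standardize: bool = True,
        drop_missing: bool = True,
    ):
        non_numeric = [
            c for c in data.columns if not pd.api.types.is_numeric_dtype(data[c])
        ]
        if non_numeric:
            raise TypeError(f"non-numeric column(s) in trip table: {non_numeric}")
        self.raw_data = data
        self.columns = list(data.columns)
        self.categories = dict(categories or {})
        self.options = options or NotearsOptions()
        self._standardize = standardize
        self._drop_missing = drop_missing
        self.forbidden = self._resolve_forbidden(forbidden)

    def _resolve_forbidden(self, forbidden) -> ForbiddenEdgeSet:
        if forbidden is None:
            return ForbiddenEdgeSet()
        if isinstance(forbidden, str):
            if forbidden != "temporal":
                raise ValueError(f"unknown forbidden-edge policy {forbidden!r}")
            if not self.categories:
                raise ValueError(
                    "the temporal forbidden-edge policy needs node categories"
                )
            cats = {c: self.categories[c] for c in self.columns if c in self.categories}
            return temporal_forbidden_set(cats)
        return ForbiddenEdgeSet(tuple(p) for p in forbidden)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "CausalEffectsModel":
        return cls(data, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CausalEffectsModel":
        return cls(pd.read_csv(path), **kwargs)

    # -- fitting -----------------------------------------------------------

    def prepare(self) -> tuple[pd.DataFrame, prep.StandardizationParams | None]:
        """Complete-case filter + standardization, as used by ``fit``."""
        table = self.raw_data
        if self._drop_missing:
            table = prep.drop_incomplete(table)
        params = None
        if self._standardize:
            table, params = prep.standardize(table)
        return table, params

    def fit(
        self,
        *,
        graph: CausalDAG | None = None,
        seed: int = 0,
        refute: bool = True,
        n_refute: int = 20,
        alpha: float = 0.05,
        bh_correction: bool = False,
    ) -> "CausalEffectsResults":
        """Run the full workflow and return the results object.

        ``graph`` skips structure learning and estimates effects on the
        supplied DAG instead (e.g. a ground-truth structure in simulation
        studies). ``seed`` drives the random-confounder draws of the
        robustness stage.
        """
        table, std_params = self.prepare()
        if graph is None:
            mask = self.forbidden.mask(self.columns)
            opts = replace(self.options, forbidden_mask=mask)
            W = notears_fit(table[self.columns].to_numpy(float), opts)
            dag = threshold_graph(W, opts.omega, self.columns, categories=self.categories)
        else:
            W = graph.weight_matrix(self.columns)
            dag = graph
        estimates = effect_table(table, dag, alpha=alpha, bh_correction=bh_correction)
        if refute:
            rng = np.random.default_rng(seed)
            refreshed = []
            for est in estimates:
                if est.identifiable:
                    delta = refute_random_confounder(
                        table,
                        est.source,
                        est.target,
                        est.adjustment,
                        seed=int(rng.integers(2**31)),
                        n_repeats=n_refute,
                    )
                    est = replace(est, robustness_delta=delta)
                refreshed.append(est)
            estimates = refreshed
        return CausalEffectsResults(
            model=self,
            table=table,
            weights=W,
            dag=dag,
            estimates=estimates,
            std_params=std_params,
            seed=seed,
        )


class CausalEffectsResults:
    """Fitted causal analysis: learned DAG, effect estimates, diagnostics."""

    def __init__(self, model, table, weights, dag, estimates, std_params, seed):
        self.model = model
        self.table = table
        self.weights = np.asarray(weights, dtype=float)
        self.dag: CausalDAG = dag
        self.estimates: list[CausalEstimate] = estimates
        self.std_params = std_params
        self.seed = seed

    @property
    def frame(self) -> pd.DataFrame:
        """Effect table as a DataFrame (one row per DAG edge)."""
        return estimates_frame(self.estimates)

    def summary(self) -> str:
        """Printable effect table in the style of the study's results table."""
        lines = [
            "Causal effect estimates (standardized, SD per SD)",
            f"  trips: {len(self.table)}    edges: {self.dag.n_edges}"
            f"    refutation seed: {self.seed}",
            "",
            f"{'source':<16}{'target':<16}{'CE':>7}  {'95% CI':>16}"
            f"  {'P':>7}  {'robust.':>9}  adjustment",
            "-" * 88,
        ]
        for r in self.estimates:
            if not r.identifiable:
                lines.append(
                    f"{r.source:<16}{r.target:<16}{'--':>7}  {'not identifiable':>16}"
                )
                continue
            ci = f"[{r.ci_low:.2f}, {r.ci_high:.2f}]"
            p = "<.001" if r.p_value < 0.001 else f"{r.p_value:.3f}"
            delta = "" if np.isnan(r.robustness_delta) else f"{r.robustness_delta:+.5f}"
            adj = str(r.adjustment) or "(empty)"
            lines.append(
                f"{r.source:<16}{r.target:<16}{r.ce:>7.2f}  {ci:>16}"
                f"  {p:>7}  {delta:>9}  {adj}"
            )
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Write the exportable artifact set (CSV, GraphML, DOT, JSON)."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(out / "effects.csv", index=False)
        self.dag.to_edge_csv(out / "dag_edges.csv")
        self.dag.to_graphml(out / "dag.graphml")
        self.dag.to_dot_file(out / "dag.dot")
        if self.std_params is not None:
            self.std_params.to_json(out / "standardization.json")

    def plot_dag(self, ax=None):
        return self.dag.plot(ax=ax)

    def __repr__(self) -> str:
        return (
            f"<CausalEffectsResults: {len(self.table)} trips, "
            f"{self.dag.n_edges} edges>"
        )
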