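"""Adjusted-regression causal-effect estimation.

Each directed edge of the causal DAG gets one estimate: OLS of the target on
the source plus the source's minimal backdoor adjustment set (all variables
standardized), so the coefficient of the source is the causal effect size in
SD-per-SD units, with a t-based 95% CI and two-sided p value. The assembled
rows are the machine-readable twin of the study's results table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .graph import AdjustmentSet, CausalDAG, IdentificationError, minimal_backdoor_set

__all__ = ["CausalEstimate", "EstimationError", "estimate_effect", "effect_table"]

ALPHA = 0.05

# ordering of the result rows mirrors the study's category groupings
_GROUP_ORDER = [
    ("emotion_before", "behavior"),
    ("emotion_before", "trip_factor"),
    ("behavior", "emotion_after"),
    ("trip_factor", "emotion_after"),
    ("predetermined", "emotion_before"),
    ("predetermined", "emotion_after"),
    ("emotion_before", "emotion_before"),
    ("emotion_before", "emotion_after"),
    ("emotion_after", "emotion_after"),
]


class EstimationError(ValueError):
    """Degenerate regression design (e.g. collinear covariates)."""


@dataclass(frozen=True)
class CausalEstimate:
    """One effect-table row: standardized effect with CI, p, and robustness."""

    source: str
    target: str
    ce: float
    ci_low: float
    ci_high: float
    p_value: float
    adjustment: AdjustmentSet
    robustness_delta: float = math.nan
    identifiable: bool = True
    significant: bool | None = None

    def __post_init__(self) -> None:
        if self.identifiable:
            if not (self.ci_low <= self.ce <= self.ci_high):
                raise ValueError("CI must bracket the point estimate")
            if not (0.0 <= self.p_value <= 1.0):
                raise ValueError("p value must lie in [0, 1]")


def _check_design(Xmat: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(Xmat)
    if rank == Xmat.shape[1]:
        return
    offending = []
    for k in range(Xmat.shape[1]):
        sub = np.delete(Xmat, k, axis=1)
        if np.linalg.matrix_rank(sub) == rank:
            offending.append(names[k])
    raise EstimationError(
        "rank-deficient regression design; collinear column(s): "
        + ", ".join(offending or names)
    )


def estimate_effect(
    table: pd.DataFrame,
    x: str,
    y: str,
    Z: AdjustmentSet | None = None,
    *,
    alpha: float = ALPHA,
    cluster: pd.Series | None = None,
) -> CausalEstimate:
    """OLS of y on {x} + Z with intercept; the x coefficient is the effect.

    The CI and p value come from the coefficient's standard error and the
    t distribution with n - |Z| - 2 degrees of freedom. ``cluster`` switches
    to cluster-robust (driver-level) standard errors; the published analysis
    pools trips, so it is off by default.
    """
    if Z is None:
        Z = AdjustmentSet(x, y, frozenset())
    covariates = Z.sorted_labels()
    missing = [c for c in [x, y, *covariates] if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    n = len(table)
    if n <= len(covariates) + 2:
        raise ValueError(f"n={n} too small for |Z|={len(covariates)} covariates")
    names = [x, *covariates]
    design = sm.add_constant(table[names].to_numpy(float), has_constant="add")
    _check_design(design, ["const", *names])
    yv = table[y].to_numpy(float)
    model = sm.OLS(yv, design)
    if cluster is not None:
        res = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(cluster)})
    else:
        res = model.fit()
    ci = res.conf_int(alpha=alpha)
    return CausalEstimate(
        source=x,
        target=y,
        ce=float(res.params[1]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        p_value=float(res.pvalues[1]),
        adjustment=Z,
        significant=bool(res.pvalues[1] < alpha),
    )


def _group_rank(G: CausalDAG, source: str, target: str) -> int:
    cats = G.categories
    key = (cats.get(source), cats.get(target))
    try:
        return _GROUP_ORDER.index(key)
    except ValueError:
        return len(_GROUP_ORDER)


def effect_table(
    table: pd.DataFrame,
    G: CausalDAG,
    *,
    alpha: float = ALPHA,
    bh_correction: bool = False,
    cluster: pd.Series | None = None,
) -> list[CausalEstimate]:
    """One adjusted estimate per directed edge of G.

    Each edge uses its minimal backdoor adjustment set. Edges whose effect is
    not backdoor-identifiable are retained with ``identifiable=False`` and
    NaN statistics. Rows are ordered by the study's category groupings; raw
    p values are compared against alpha unless the (off-by-default)
    Benjamini-Hochberg switch is on.
    """
    edges = sorted(
        G.edges(),
        key=lambda e: (_group_rank(G, e[0], e[1]), e[0], e[1]),
    )
    rows: list[CausalEstimate] = []
    for s, t, _w in edges:
        try:
            Z = minimal_backdoor_set(G, s, t)
        except IdentificationError:
            rows.append(
                CausalEstimate(
                    source=s,
                    target=t,
                    ce=math.nan,
                    ci_low=math.nan,
                    ci_high=math.nan,
                    p_value=math.nan,
                    adjustment=AdjustmentSet(s, t, frozenset()),
                    identifiable=False,
                    significant=None,
                )
            )
            continue
        rows.append(estimate_effect(table, s, t, Z, alpha=alpha, cluster=cluster))
    if bh_correction:
        idx = [i for i, r in enumerate(rows) if r.identifiable]
        if idx:
            reject, _, _, _ = multipletests(
                [rows[i].p_value for i in idx], alpha=alpha, method="fdr_bh"
            )
            for i, rej in zip(idx, reject):
                rows[i] = replace(rows[i], significant=bool(rej))
    return rows


def estimates_frame(rows: list[CausalEstimate]) -> pd.DataFrame:
    """Effect table as a DataFrame (CSV twin of the study's results table)."""
    return pd.DataFrame(
        {
            "source": [r.source for r in rows],
            "target": [r.target for r in rows],
            "ce": [r.ce for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "p_value": [r.p_value for r in rows],
            "adjustment_set": [str(r.adjustment) for r in rows],
            "robustness_delta": [r.robustness_delta for r in rows],
            "identifiable": [r.identifiable for r in rows],
            "significant": [r.significant for r in rows],
        }
    )
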