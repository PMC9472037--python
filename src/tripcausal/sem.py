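"""Linear-Gaussian structural equation models for synthetic trip tables.

The field data behind the driving/well-being analysis are not public, so the
package ships a generator that emulates their statistical structure: a linear
SEM over the study's four variable categories (emotions before driving, driving
behavior, trip-dependent factors, predetermined factors, emotions after
driving), with binary exogenous factors (weekend / occupants / commute flags)
and affect variables reported on a 0-100 slider.

The ``table1`` preset sets the direct standardized edge weights to the
significant causal-effect sizes reported by the field study, solves the noise
scales so that every node has unit marginal variance, and can emit either
standardized or raw-scale tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SEMSpec",
    "SEMSpecError",
    "CATEGORIES",
    "STUDY_NODES",
    "STUDY_CATEGORIES",
    "TABLE1_EDGES",
    "generate_sem_spec",
    "table1_spec",
    "random_sem_spec",
    "simulate_trips",
]

#: The five causal stages, in temporal order.
CATEGORIES = (
    "predetermined",
    "emotion_before",
    "behavior",
    "trip_factor",
    "emotion_after",
)

#: All variables named by the study: 4 emotions (arousal/valence before and
#: after driving), 3 driving-behavior variables, 3 trip-dependent factors and
#: 4 predetermined factors.
STUDY_NODES = (
    "before_arousal",
    "before_valence",
    "steering",
    "braking",
    "sudden_events",
    "length",
    "speed",
    "flow",
    "sun",
    "weekend",
    "occupants",
    "commute",
    "after_arousal",
    "after_valence",
)

STUDY_CATEGORIES = {
    "before_arousal": "emotion_before",
    "before_valence": "emotion_before",
    "steering": "behavior",
    "braking": "behavior",
    "sudden_events": "behavior",
    "length": "trip_factor",
    "speed": "trip_factor",
    "flow": "trip_factor",
    "sun": "predetermined",
    "weekend": "predetermined",
    "occupants": "predetermined",
    "commute": "predetermined",
    "after_arousal": "emotion_after",
    "after_valence": "emotion_after",
}

#: The 15 statistically significant standardized effects of the field study,
#: (source, target, effect in SD per SD).
TABLE1_EDGES = (
    ("before_arousal", "steering", 0.13),
    ("before_arousal", "sudden_events", -0.06),
    ("before_arousal", "speed", -0.11),
    ("braking", "after_arousal", 0.10),
    ("speed", "after_arousal", -0.17),
    ("sun", "before_arousal", 0.12),
    ("sun", "after_arousal", 0.14),
    ("occupants", "before_valence", 0.38),
    ("occupants", "after_valence", 0.37),
    ("length", "after_arousal", -0.13),
    ("before_arousal", "before_valence", 0.18),
    ("before_arousal", "after_arousal", 0.74),
    ("before_arousal", "after_valence", 0.19),
    ("before_valence", "after_valence", 0.77),
    ("after_valence", "after_arousal", 0.13),
)

#: Printed affective-slider moments (mean, SD on the raw 0-100 scale).
AFFECT_RAW_MOMENTS = {
    "before_arousal": (73.66, 18.24),
    "before_valence": (69.76, 16.74),
    "after_arousal": (71.53, 19.58),
    "after_valence": (69.26, 16.91),
}

#: Binary-factor prevalences: weekend = 1 - 0.82 weekday share, commute = 0.24
#: (both printed); occupant prevalence is not printed, default 0.30.
STUDY_PREVALENCES = {"weekend": 0.18, "occupants": 0.30, "commute": 0.24}

#: Affect sliders are bounded; raw simulation clips these columns to [0, 100].
AFFECT_BOUNDS = (0.0, 100.0)


class SEMSpecError(ValueError):
    """Invalid SEM specification (cycle, forbidden edge, or infeasible noise)."""


@dataclass(frozen=True)
class SEMSpec:
    """Ground-truth weighted DAG plus noise model for trip-table simulation.

    Parameters
    ----------
    nodes
        Ordered variable names; index order fixes the weight-matrix layout.
    weights
        ``weights[i, j]`` is the direct standardized effect of ``nodes[i]`` on
        ``nodes[j]`` (SD per SD). Must be acyclic.
    categories
        Node -> causal stage (one of :data:`CATEGORIES`); optional.
    noise_scales
        Per-node noise SDs. Binary nodes carry 0 (their variance comes from
        the standardized Bernoulli draw).
    binary_nodes
        Node -> prevalence for Bernoulli exogenous factors.
    raw_transform
        Node -> (mean, SD) affine map from standardized to raw units.
    noise_dist
        "gaussian" (default) or "laplace" for heavier-tailed robustness
        experiments; scales are calibrated so noise variance is unchanged.
    floor_infeasible_noise
        When the noise scales are being solved for unit marginal variances,
        a node whose parents already explain >= 1 unit of variance admits no
        nonnegative noise scale. The default is to raise; with this flag the
        node's noise is floored at zero and its marginal variance exceeds 1
        by exactly the excess explained variance (see
        :attr:`supra_unit_nodes`).
    """

    nodes: tuple[str, ...]
    weights: np.ndarray
    categories: dict[str, str] = field(default_factory=dict)
    noise_scales: np.ndarray = None  # type: ignore[assignment]
    binary_nodes: dict[str, float] = field(default_factory=dict)
    raw_transform: dict[str, tuple[float, float]] = field(default_factory=dict)
    noise_dist: str = "gaussian"
    floor_infeasible_noise: bool = False

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        d = len(self.nodes)
        if W.shape != (d, d):
            raise SEMSpecError(f"weights must be {d}x{d}, got {W.shape}")
        object.__setattr__(self, "weights", W)
        if not _support_is_acyclic(W):
            raise SEMSpecError("weight matrix supports a directed cycle")
        if self.categories:
            bad = _forbidden_violations(self.nodes, self.categories, W)
            if bad:
                raise SEMSpecError(
                    "weights on temporally forbidden pairs: "
                    + ", ".join(f"{s}->{t}" for s, t in bad)
                )
        for b in self.binary_nodes:
            i = self.index(b)
            if np.any(W[:, i] != 0):
                raise SEMSpecError(f"binary node {b!r} must be exogenous (no parents)")
        if self.noise_scales is None:
            object.__setattr__(self, "noise_scales", self._solve_unit_variance())
        else:
            ns = np.asarray(self.noise_scales, dtype=float)
            if ns.shape != (d,) or np.any(ns < 0):
                raise SEMSpecError("noise_scales must be length-d nonnegative")
            object.__setattr__(self, "noise_scales", ns)
        if self.noise_dist not in ("gaussian", "laplace"):
            raise SEMSpecError(f"unknown noise_dist {self.noise_dist!r}")

    # -- structure ---------------------------------------------------------

    def index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        """Nonzero directed edges as (source, target, weight)."""
        out = []
        for i, j in zip(*np.nonzero(self.weights)):
            out.append((self.nodes[i], self.nodes[j], float(self.weights[i, j])))
        return out

    def topological_order(self) -> list[int]:
        """Node indices ordered parents-before-children (Kahn's algorithm)."""
        A = self.weights != 0
        indeg = A.sum(axis=0).astype(int)
        order, stack = [], sorted(np.flatnonzero(indeg == 0).tolist())
        while stack:
            i = stack.pop(0)
            order.append(i)
            for j in np.flatnonzero(A[i]):
                indeg[j] -= 1
                if indeg[j] == 0:
                    stack.append(int(j))
        if len(order) != self.n_nodes:  # unreachable given the acyclicity check
            raise SEMSpecError("cyclic structure")
        return order

    # -- moments -----------------------------------------------------------

    def _solve_unit_variance(self) -> np.ndarray:
        """Noise SDs giving every node marginal variance 1.

        Walks the DAG in topological order maintaining the covariance of the
        already-visited nodes; the explained variance of node j is w' Sigma w
        over its parents, so sigma_j^2 = 1 - w' Sigma w.
        """
        d = self.n_nodes
        W = self.weights
        Sigma = np.zeros((d, d))
        scales = np.zeros(d)
        binary = {self.index(b) for b in self.binary_nodes}
        for j in self.topological_order():
            w = W[:, j]
            explained = float(w @ Sigma @ w)
            if j in binary:
                var_j = 1.0  # standardized Bernoulli root
            elif explained >= 1.0 - 1e-12:
                if not self.floor_infeasible_noise:
                    raise SEMSpecError(
                        f"node {self.nodes[j]!r}: explained variance "
                        f"{explained:.4f} >= 1, no nonnegative noise scale exists"
                    )
                var_j = explained  # zero-noise floor; marginal variance > 1
            else:
                scales[j] = np.sqrt(1.0 - explained)
                var_j = 1.0
            Sigma[:, j] = Sigma @ w
            Sigma[j, :] = Sigma[:, j]
            Sigma[j, j] = var_j
        return scales

    @property
    def supra_unit_nodes(self) -> list[str]:
        """Continuous nodes whose marginal variance exceeds 1 (zero-noise floor)."""
        var = np.diag(self.covariance())
        binary = {self.index(b) for b in self.binary_nodes}
        return [
            self.nodes[j]
            for j in range(self.n_nodes)
            if j not in binary and var[j] > 1.0 + 1e-9
        ]

    def covariance(self) -> np.ndarray:
        """Closed-form covariance (I - W')^-1 D (I - W')^-T of the SEM.

        D has the noise variances, with 1 in the slots of (unit-variance,
        standardized) binary roots.
        """
        d = self.n_nodes
        D = self.noise_scales**2
        for b in self.binary_nodes:
            D = D.copy()
            D[self.index(b)] = 1.0
        A = np.linalg.inv(np.eye(d) - self.weights.T)
        return A @ np.diag(D) @ A.T

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "categories": dict(self.categories),
            "edges": [[s, t, w] for s, t, w in self.edges()],
            "noise_scales": self.noise_scales.tolist(),
            "binary_nodes": dict(self.binary_nodes),
            "raw_transform": {k: list(v) for k, v in self.raw_transform.items()},
            "noise_dist": self.noise_dist,
            "floor_infeasible_noise": self.floor_infeasible_noise,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, payload: dict) -> "SEMSpec":
        nodes = tuple(payload["nodes"])
        W = np.zeros((len(nodes), len(nodes)))
        for s, t, w in payload["edges"]:
            W[nodes.index(s), nodes.index(t)] = w
        ns = payload.get("noise_scales")
        return cls(
            nodes=nodes,
            weights=W,
            categories=payload.get("categories", {}),
            noise_scales=None if ns is None else np.asarray(ns, float),
            binary_nodes=payload.get("binary_nodes", {}),
            raw_transform={k: tuple(v) for k, v in payload.get("raw_transform", {}).items()},
            noise_dist=payload.get("noise_dist", "gaussian"),
            floor_infeasible_noise=payload.get("floor_infeasible_noise", False),
        )

    @classmethod
    def from_json(cls, path) -> "SEMSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _support_is_acyclic(W: np.ndarray) -> bool:
    """Kahn-style check on the support of W (exact, weight-scale free)."""
    A = W != 0
    indeg = A.sum(axis=0).astype(int)
    stack = list(np.flatnonzero(indeg == 0))
    seen = 0
    while stack:
        i = stack.pop()
        seen += 1
        for j in np.flatnonzero(A[i]):
            indeg[j] -= 1
            if indeg[j] == 0:
                stack.append(int(j))
    return seen == W.shape[0]


def _forbidden_violations(nodes, categories, W) -> list[tuple[str, str]]:
    from .notears import temporal_forbidden_set

    forbidden = temporal_forbidden_set(categories)
    bad = []
    for i, j in zip(*np.nonzero(W)):
        pair = (nodes[i], nodes[j])
        if pair in forbidden:
            bad.append(pair)
    return bad


# ---------------------------------------------------------------------------
# constructors


def table1_spec(
    *,
    occupant_prevalence: float = STUDY_PREVALENCES["occupants"],
    noise_dist: str = "gaussian",
) -> SEMSpec:
    """The study's significant causal structure as a simulation ground truth.

    Direct standardized weights equal the published significant effect sizes;
    noise scales are solved for unit marginal variances; weekend and commute
    prevalences are the published shares (0.18 and 0.24); affect variables get
    the published raw slider moments.

    One caveat: the published effects are total effects, and using them as
    direct weights makes the parents of ``after_valence`` (occupants,
    before_arousal, before_valence) explain 1.035 units of variance — more
    than a unit-variance node can carry. The preset floors that node's noise
    at zero, so ``after_valence`` has marginal SD 1.0174 instead of 1; every
    other node is exactly unit variance. Downstream estimates are unaffected
    because the analysis standardizes columns empirically.
    """
    nodes = STUDY_NODES
    W = np.zeros((len(nodes), len(nodes)))
    for s, t, w in TABLE1_EDGES:
        W[nodes.index(s), nodes.index(t)] = w
    prev = dict(STUDY_PREVALENCES)
    prev["occupants"] = occupant_prevalence
    return SEMSpec(
        nodes=nodes,
        weights=W,
        categories=dict(STUDY_CATEGORIES),
        binary_nodes=prev,
        raw_transform=dict(AFFECT_RAW_MOMENTS),
        noise_dist=noise_dist,
        floor_infeasible_noise=True,
    )


def random_sem_spec(
    n_nodes: int,
    n_edges: int,
    seed: int,
    *,
    weight_range: tuple[float, float] = (0.5, 1.5),
    noise_range: tuple[float, float] = (0.8, 1.2),
) -> SEMSpec:
    """Random DAG benchmark spec: uniform-signed weights, unequal noise SDs.

    Edges are drawn uniformly among the pairs admissible under a random node
    permutation, weights uniform on ``+-[weight_range]``, noise SDs uniform on
    ``noise_range`` (so marginal variances are NOT unit; structure-learning
    benchmarks use the raw simulated scale).
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_nodes)
    pairs = [
        (int(order[i]), int(order[j]))
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
    ]
    if n_edges > len(pairs):
        raise SEMSpecError("more edges requested than the DAG can hold")
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    W = np.zeros((n_nodes, n_nodes))
    lo, hi = weight_range
    for k in chosen:
        i, j = pairs[int(k)]
        W[i, j] = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
    scales = rng.uniform(*noise_range, size=n_nodes)
    nodes = tuple(f"x{i}" for i in range(n_nodes))
    return SEMSpec(nodes=nodes, weights=W, noise_scales=scales)


def generate_sem_spec(config: dict, seed: int = 0) -> SEMSpec:
    """Build a :class:`SEMSpec` from a generator-config mapping.

    ``config["preset"] == "table1"`` returns the study ground truth;
    ``config["preset"] == "random"`` draws a benchmark DAG (uses ``seed``);
    otherwise the config must name ``nodes`` and ``edges`` explicitly
    (``categories``, ``binary_nodes``, ``raw_transform``, ``noise_scales``
    optional; noise scales default to the unit-marginal-variance solution).
    """
    preset = config.get("preset")
    if preset == "table1":
        kwargs = {}
        if "occupant_prevalence" in config:
            kwargs["occupant_prevalence"] = config["occupant_prevalence"]
        if "noise_dist" in config:
            kwargs["noise_dist"] = config["noise_dist"]
        return table1_spec(**kwargs)
    if preset == "random":
        return random_sem_spec(
            config["n_nodes"],
            config["n_edges"],
            seed,
            weight_range=tuple(config.get("weight_range", (0.5, 1.5))),
            noise_range=tuple(config.get("noise_range", (0.8, 1.2))),
        )
    if preset is not None:
        raise SEMSpecError(f"unknown preset {preset!r}")
    nodes = tuple(config["nodes"])
    W = np.zeros((len(nodes), len(nodes)))
    for s, t, w in config.get("edges", []):
        if s not in nodes or t not in nodes:
            raise SEMSpecError(f"edge {s}->{t} references unknown node")
        W[nodes.index(s), nodes.index(t)] = w
    ns = config.get("noise_scales")
    return SEMSpec(
        nodes=nodes,
        weights=W,
        categories=config.get("categories", {}),
        noise_scales=None if ns is None else np.asarray(ns, float),
        binary_nodes=config.get("binary_nodes", {}),
        raw_transform={k: tuple(v) for k, v in config.get("raw_transform", {}).items()},
        noise_dist=config.get("noise_dist", "gaussian"),
    )


# ---------------------------------------------------------------------------
# simulation


def simulate_trips(
    spec: SEMSpec,
    n: int,
    seed: int,
    scale: str = "standardized",
) -> pd.DataFrame:
    """Ancestral sampling of ``n`` trips from the SEM.

    Binary nodes are drawn Bernoulli at their prevalence and centered/scaled
    to unit variance before feeding children, so the closed-form SEM
    covariance holds exactly for them too. With ``scale="raw"`` each column is
    mapped back through its affine raw transform (binary columns revert to
    0/1 flags; affect columns are clipped to the 0-100 slider range).
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if scale not in ("standardized", "raw"):
        raise ValueError(f"scale must be 'standardized' or 'raw', got {scale!r}")
    rng = np.random.default_rng(seed)
    d = spec.n_nodes
    X = np.zeros((n, d))
    raw = {}
    binary = {spec.index(b): p for b, p in spec.binary_nodes.items()}
    for j in spec.topological_order():
        if j in binary:
            p = binary[j]
            flags = (rng.random(n) < p).astype(float)
            raw[j] = flags
            X[:, j] = (flags - p) / np.sqrt(p * (1 - p))
            continue
        s = spec.noise_scales[j]
        if spec.noise_dist == "laplace":
            eps = rng.laplace(0.0, s / np.sqrt(2.0), size=n)
        else:
            eps = rng.normal(0.0, s, size=n)
        X[:, j] = X @ spec.weights[:, j] + eps
    cols = {}
    for j, name in enumerate(spec.nodes):
        if scale == "raw":
            if j in binary:
                cols[name] = raw[j]
            else:
                mu, sd = spec.raw_transform.get(name, (0.0, 1.0))
                v = mu + sd * X[:, j]
                if name in AFFECT_RAW_MOMENTS:
                    v = np.clip(v, *AFFECT_BOUNDS)
                cols[name] = v
        else:
            cols[name] = X[:, j]
    df = pd.DataFrame(cols, columns=list(spec.nodes))
    df.attrs["scale"] = scale
    return df
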