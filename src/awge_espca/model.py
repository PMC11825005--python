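"""Sparse PCA model family: L0 (SPCA), edge-group (ESPCA) and adaptive
weighted edge-group (AWGE-ESPCA).

All three solve the rank-1 problem

    maximize  u' X v   s.t.  ||u||_2 <= 1, ||v||_2 <= 1, u sparse

by alternating power iterations: ``u <- normalize(P(X v))`` and
``v <- normalize(X' u)``, where ``P`` is the model's sparse projection
(top-s magnitudes, top-k edge groups, or the adaptive weighted pipeline).
Further components come from Hotelling deflation ``X <- X - d u v'``.

The AWGE variant adds two mechanisms.  The adaptive regularizer fences the
current loading vector with Tukey-style quantile fences and *eliminates* the
fenced probes: within one component's fit, a probe flagged as an
expression-scale outlier stays excluded from all subsequent iterations (each
component re-assesses outliers on the deflated matrix).  The weighted network
rescales every edge score by each endpoint's min-max-normalised count of
target-relevant pathways, steering selection toward annotated regions.  Edge
selection is greedy with optional exploration: the pool is the top
``ceil((1+omega)k)`` edges, ``k`` are sampled uniformly, and ``omega`` decays
by ``rho`` per iteration; convergence is only declared once ``omega = 0``.

Models are built from data and fitted via ``fit()``, which returns a
:class:`SparsePCAResults` carrying loadings, scores, singular values,
objective traces and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import DegenerateFitError, ExpressionMatrix, GeneNetwork, PathwayWeights, normalize_weights
from .projection import (
    EdgeSelection,
    all_edge_norms,
    decay_omega,
    select_edges,
    sparse_project,
)
from .regularizer import DEFAULT_LQ, outlier_mask


@dataclass
class FitConfig:
    """Hyperparameters shared across the model family.

    Parameters
    ----------
    k : int
        Edge budget per component (number of edge groups kept); for the
        plain L0 model this is the probe budget ``s`` instead.
    lq : float in (0, 0.5)
        Quantile level of the adaptive regularizer's fences.
    omega : float >= 0
        Initial exploration rate of the randomised edge sampler.
    rho : float >= 0
        Per-iteration decay of ``omega``.
    a, b : float
        Target range of the min-max pathway-weight normalisation
        (``a=1, b=2`` keeps unannotated probes at nonzero weight).
    """

    k: int = 6
    lq: float = DEFAULT_LQ
    omega: float = 0.5
    rho: float = 0.1
    a: float = 1.0
    b: float = 2.0
    n_components: int = 2
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0
    use_lar: bool = True
    use_weights: bool = True
    lar_mode: str = "absolute"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("edge budget k must be a positive integer")
        if not 0.0 < self.lq < 0.5:
            raise ValueError(f"lq must lie in (0, 0.5), got {self.lq}")
        if self.omega < 0 or self.rho < 0:
            raise ValueError("omega and rho must be >= 0")
        if not self.a < self.b:
            raise ValueError("normalisation range requires a < b")
        if self.n_components < 1 or self.max_iter < 1:
            raise ValueError("n_components and max_iter must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.lar_mode not in ("absolute", "signed"):
            raise ValueError("lar_mode must be 'absolute' or 'signed'")


@dataclass
class ComponentResult:
    """One extracted sparse component."""

    u: np.ndarray
    v: np.ndarray
    d: float
    support: np.ndarray
    selected_edges: np.ndarray
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    excluded_probes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    support_trace: list = field(default_factory=list, repr=False)

    @classmethod
    def zero(cls, m: int, n: int) -> "ComponentResult":
        """All-zero component; deflating by it leaves the matrix unchanged."""
        return cls(
            u=np.zeros(m),
            v=np.zeros(n),
            d=0.0,
            support=np.array([], dtype=int),
            selected_edges=np.empty((0, 2), dtype=int),
            objective_trace=np.array([]),
            n_iter=0,
            converged=True,
        )


def _as_matrix(X) -> ExpressionMatrix:
    if isinstance(X, ExpressionMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        return ExpressionMatrix.from_dataframe(X)
    X = np.asarray(X, dtype=float)
    return ExpressionMatrix(
        X,
        [f"probe_{i + 1}" for i in range(X.shape[0])],
        [f"sample_{j + 1}" for j in range(X.shape[1])],
    )


def deflate(X, component: ComponentResult):
    """Hotelling deflation: ``X - d u v'``.

    Accepts and returns either a plain array or an :class:`ExpressionMatrix`.
    """
    if isinstance(X, ExpressionMatrix):
        resid = deflate(X.values, component)
        return ExpressionMatrix(resid, X.probe_ids, X.sample_ids)
    X = np.asarray(X, dtype=float)
    if X.shape != (len(component.u), len(component.v)):
        raise ValueError(
            f"component of shape ({len(component.u)}, {len(component.v)}) "
            f"does not match matrix of shape {X.shape}"
        )
    return X - component.d * np.outer(component.u, component.v)


class SparsePCAResults:
    """Fitted results: components, loadings/scores tables, summary."""

    def __init__(self, model, components: list[ComponentResult]):
        self.model = model
        self.components = components

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def singular_values(self) -> np.ndarray:
        return np.array([c.d for c in self.components])

    @property
    def loadings(self) -> pd.DataFrame:
        data = {f"PC{i + 1}": c.u for i, c in enumerate(self.components)}
        return pd.DataFrame(data, index=self.model.data.probe_ids)

    @property
    def scores(self) -> pd.DataFrame:
        data = {f"PC{i + 1}": c.v for i, c in enumerate(self.components)}
        return pd.DataFrame(data, index=self.model.data.sample_ids)

    def supports(self) -> list[np.ndarray]:
        return [c.support for c in self.components]

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} fit: "
            f"{self.model.data.n_probes} probes x {self.model.data.n_samples} samples, "
            f"{self.n_components} component(s)",
            "-" * 72,
            f"{'component':>10} {'sing.value':>12} {'|support|':>10} "
            f"{'n_iter':>7} {'converged':>10} {'excluded':>9}",
        ]
        for i, c in enumerate(self.components):
            lines.append(
                f"{'PC' + str(i + 1):>10} {c.d:>12.4f} {len(c.support):>10d} "
                f"{c.n_iter:>7d} {str(c.converged):>10} {len(c.excluded_probes):>9d}"
            )
        lines.append("-" * 72)
        probe_ids = self.model.data.probe_ids
        for i, c in enumerate(self.components):
            members = ", ".join(
                f"{probe_ids[p]}={c.u[p]:+.3f}" for p in c.support
            )
            lines.append(f"PC{i + 1} support: {members if members else '(empty)'}")
        return "\n".join(lines)


class _BaseSparsePCA:
    """Shared alternating-iteration driver."""

    def __init__(self, X, config: FitConfig | None = None, **overrides):
        self.data = _as_matrix(X)
        base = config if config is not None else FitConfig()
        self.config = replace(base, **overrides) if overrides else base

    # subclasses implement one u-update given the current z = X v
    def _project(self, z: np.ndarray, state: dict, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def _init_state(self) -> dict:
        return {}

    def _fit_component(self, X: np.ndarray, rng: np.random.Generator) -> ComponentResult:
        cfg = self.config
        m, n = X.shape
        if not np.any(X):
            raise DegenerateFitError("expression matrix is all-zero")
        v = rng.standard_normal(n)
        v /= np.linalg.norm(v)
        state = self._init_state()
        trace: list[float] = []
        support_trace: list[tuple[int, ...]] = []
        obj_prev: float | None = None
        converged = False
        n_iter = 0
        for n_iter in range(1, cfg.max_iter + 1):
            z = X @ v
            u = self._project(z, state, rng)
            nu = np.linalg.norm(u)
            if nu == 0.0:
                raise DegenerateFitError(
                    "loading vector collapsed to zero after projection "
                    "(all candidate probes fenced out or edge budget too small)"
                )
            u = u / nu
            vhat = X.T @ u
            nv = np.linalg.norm(vhat)
            if nv == 0.0:
                raise DegenerateFitError("score vector collapsed to zero")
            v = vhat / nv
            obj = float(u @ X @ v)
            trace.append(obj)
            support_trace.append(tuple(int(i) for i in np.flatnonzero(u)))
            settled = self._advance(state)
            if settled and obj_prev is not None and abs(obj - obj_prev) < cfg.tol:
                converged = True
                break
            obj_prev = obj
        support = np.flatnonzero(u)
        sel = state.get("selection")
        selected_edges = (
            self.network.edges[sel.selected]
            if sel is not None and getattr(self, "network", None) is not None
            else np.empty((0, 2), dtype=int)
        )
        excluded = np.flatnonzero(state.get("excluded", np.zeros(m, dtype=bool)))
        return ComponentResult(
            u=u,
            v=v,
            d=float(u @ X @ v),
            support=support,
            selected_edges=selected_edges,
            objective_trace=np.array(trace),
            n_iter=n_iter,
            converged=converged,
            excluded_probes=excluded,
            support_trace=support_trace,
        )

    def _advance(self, state: dict) -> bool:
        """Per-iteration schedule update; returns True once the update rule
        is deterministic and convergence may be declared."""
        return True

    def fit(self) -> SparsePCAResults:
        rng = np.random.default_rng(self.config.seed)
        X = self.data.values.copy()
        components: list[ComponentResult] = []
        for _ in range(self.config.n_components):
            comp = self._fit_component(X, rng)
            components.append(comp)
            X = deflate(X, comp)
        return SparsePCAResults(self, components)


class SparsePCA(_BaseSparsePCA):
    """Classical L0-constrained sparse PCA: keep the top-``s`` loadings."""

    def __init__(self, X, s: int | None = None, config: FitConfig | None = None, **overrides):
        super().__init__(X, config, **overrides)
        self.s = int(s) if s is not None else self.config.k
        if not 1 <= self.s <= self.data.n_probes:
            raise ValueError(f"s must lie in [1, {self.data.n_probes}], got {self.s}")

    def _project(self, z, state, rng):
        return sparse_project(z, self.s)


class EdgeSparsePCA(_BaseSparsePCA):
    """Edge-group sparse PCA: keep the top-``k`` network edges."""

    def __init__(self, X, network: GeneNetwork, k: int | None = None,
                 config: FitConfig | None = None, **overrides):
        super().__init__(X, config, **overrides)
        if network.n_probes is not None and network.n_probes != self.data.n_probes:
            raise ValueError("network and expression matrix disagree on probe count")
        if network.edges.max() >= self.data.n_probes:
            raise ValueError("network references probes beyond the expression matrix")
        self.network = network
        self.k = int(k) if k is not None else self.config.k
        if not 1 <= self.k <= network.n_edges:
            raise ValueError(f"k must lie in [1, {network.n_edges}], got {self.k}")

    def _project(self, z, state, rng):
        norms = all_edge_norms(z, self.network)
        selection = select_edges(norms, self.k, omega=0.0)
        state["selection"] = selection
        keep = np.zeros(len(z), dtype=bool)
        keep[np.unique(self.network.edges[selection.selected])] = True
        return np.where(keep, z, 0.0)


class AWGESparsePCA(EdgeSparsePCA):
    """Adaptive weighted edge-group sparse PCA.

    Adds the fence-based noise-elimination regularizer and the
    pathway-weighted network to the edge-group model, with greedy randomised
    edge sampling at decaying exploration rate.
    """

    def __init__(self, X, network: GeneNetwork, pathway_counts=None,
                 k: int | None = None, config: FitConfig | None = None, **overrides):
        super().__init__(X, network, k, config, **overrides)
        m = self.data.n_probes
        if pathway_counts is None:
            self.weights = PathwayWeights.uniform(m, self.config.a, self.config.b)
        elif isinstance(pathway_counts, PathwayWeights):
            self.weights = pathway_counts
        else:
            counts = np.asarray(pathway_counts, dtype=float)
            if len(counts) != m:
                raise ValueError("pathway counts length does not match probe count")
            self.weights = normalize_weights(counts, self.config.a, self.config.b)

    @classmethod
    def from_frames(cls, expr: pd.DataFrame, edges: list[tuple[str, str]],
                    pathway_counts: dict[str, int] | None = None,
                    config: FitConfig | None = None, **overrides) -> "AWGESparsePCA":
        """Build from a probes-x-samples DataFrame, a probe-ID edge list and
        an optional probe -> pathway-count mapping (missing probes count 0).
        """
        data = ExpressionMatrix.from_dataframe(expr)
        network = GeneNetwork.from_probe_ids(edges, data.probe_index())
        counts = None
        if pathway_counts is not None:
            counts = np.array([float(pathway_counts.get(p, 0)) for p in data.probe_ids])
        return cls(data, network, counts, config=config, **overrides)

    def _init_state(self) -> dict:
        return {
            "omega": self.config.omega,
            "excluded": np.zeros(self.data.n_probes, dtype=bool),
        }

    def _project(self, z, state, rng):
        cfg = self.config
        z = np.asarray(z, dtype=float).copy()
        excluded = state["excluded"]
        z[excluded] = 0.0
        if cfg.use_lar:
            alive = ~excluded
            if alive.sum() >= 2:
                flagged = outlier_mask(z[alive], cfg.lq, mode=cfg.lar_mode)
                newly = np.zeros_like(excluded)
                newly[alive] = flagged
                excluded |= newly
                z[newly] = 0.0
                state["excluded"] = excluded
        norms = all_edge_norms(z, self.network, self.weights if cfg.use_weights else None)
        selection = select_edges(norms, self.k, omega=state["omega"], rng=rng)
        state["selection"] = selection
        keep = np.zeros(len(z), dtype=bool)
        keep[np.unique(self.network.edges[selection.selected])] = True
        return np.where(keep, z, 0.0)

    def _advance(self, state) -> bool:
        state["omega"] = decay_omega(state["omega"], self.config.rho)
        return state["omega"] == 0.0


def fit_spca(X, s: int, max_iter: int = 100, tol: float = 1e-6, seed: int = 0) -> ComponentResult:
    """Fit one L0 sparse component (functional wrapper)."""
    model = SparsePCA(X, s=s, max_iter=max_iter, tol=tol, seed=seed, n_components=1)
    return model.fit().components[0]


def fit_espca(X, network: GeneNetwork, s: int, max_iter: int = 100,
              tol: float = 1e-6, seed: int = 0) -> ComponentResult:
    """Fit one edge-group sparse component (functional wrapper)."""
    model = EdgeSparsePCA(X, network, k=s, max_iter=max_iter, tol=tol, seed=seed,
                          n_components=1)
    return model.fit().components[0]


def fit_awge_espca(X, network: GeneNetwork, pathway_counts=None,
                   config: FitConfig | None = None, **overrides) -> list[ComponentResult]:
    """Fit ``config.n_components`` adaptive weighted edge-group components."""
    model = AWGESparsePCA(X, network, pathway_counts, config=config, **overrides)
    return model.fit().components
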