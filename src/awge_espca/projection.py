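"""Sparse projections: L0 top-s, edge-group, and weighted edge-group.

The L0 projection keeps the ``s`` largest-magnitude entries of a vector.  The
edge-group projection works on a gene network instead: each edge scores
``u_i^2 + u_j^2`` (optionally re-weighted by per-probe pathway weights,
``w_qi u_i^2 + w_qj u_j^2``), the top-``k`` edges are kept and every probe
incident to a kept edge survives.  Exploration is controlled by ``omega``:
the candidate pool is the top ``ceil((1 + omega) * k)`` edges and ``k`` of
them are sampled uniformly without replacement; ``omega = 0`` is the exact
deterministic top-k.  Ties in every ranking break toward the lower index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GeneNetwork, PathwayWeights
from .regularizer import DEFAULT_LQ, lar_regularize


def sparse_project(z: np.ndarray, s: int) -> np.ndarray:
    """Keep the ``s`` entries of ``z`` with largest magnitude, zero the rest.

    Equal magnitudes break toward the lower index.  The kept entries are
    returned unchanged.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 1:
        raise ValueError("z must be a 1-D vector")
    m = len(z)
    if not 1 <= s <= m:
        raise ValueError(f"s must lie in [1, {m}], got {s}")
    # stable sort on -|z| keeps lower indices first among ties
    order = np.argsort(-np.abs(z), kind="stable")
    out = np.zeros_like(z)
    keep = order[:s]
    out[keep] = z[keep]
    return out


def edge_norm(u: np.ndarray, edge: tuple[int, int]) -> float:
    """Edge score ``u_i^2 + u_j^2`` for one probe pair."""
    u = np.asarray(u, dtype=float)
    i, j = edge
    m = len(u)
    if not (0 <= i < m and 0 <= j < m):
        raise IndexError(f"edge ({i}, {j}) out of range for {m} probes")
    return float(u[i] ** 2 + u[j] ** 2)


def weighted_edge_norm(u: np.ndarray, edge: tuple[int, int], weights: PathwayWeights) -> float:
    """Pathway-weighted edge score ``w_qi u_i^2 + w_qj u_j^2``."""
    u = np.asarray(u, dtype=float)
    i, j = edge
    m = len(u)
    if not (0 <= i < m and 0 <= j < m):
        raise IndexError(f"edge ({i}, {j}) out of range for {m} probes")
    w = weights.normalized
    if len(w) != m:
        raise ValueError("pathway weights length does not match vector length")
    return float(w[i] * u[i] ** 2 + w[j] * u[j] ** 2)


def all_edge_norms(
    u: np.ndarray, network: GeneNetwork, weights: PathwayWeights | None = None
) -> np.ndarray:
    """Vectorised edge scores for every edge of the network."""
    u = np.asarray(u, dtype=float)
    i, j = network.edges[:, 0], network.edges[:, 1]
    if network.edges.max() >= len(u):
        raise IndexError("network references probes beyond the vector length")
    if weights is None:
        return u[i] ** 2 + u[j] ** 2
    w = np.asarray(weights.normalized, dtype=float)
    if len(w) != len(u):
        raise ValueError("pathway weights length does not match vector length")
    return w[i] * u[i] ** 2 + w[j] * u[j] ** 2


@dataclass
class EdgeSelection:
    """Outcome of one greedy (possibly randomised) edge selection."""

    candidate_pool: np.ndarray
    selected: np.ndarray
    omega: float = 0.0
    norms: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def select_edges(
    norms: np.ndarray,
    k: int,
    omega: float = 0.0,
    rng: np.random.Generator | None = None,
) -> EdgeSelection:
    """Greedy randomised top-k edge selection.

    The candidate pool is the ``ceil((1 + omega) * k)`` highest-scoring edges
    (clamped to the number of edges); ``k`` pool members are drawn uniformly
    without replacement.  With ``omega = 0`` the selection is the exact,
    deterministic top-k.
    """
    norms = np.asarray(norms, dtype=float)
    n_edges = len(norms)
    if not 1 <= k <= n_edges:
        raise ValueError(f"edge budget k must lie in [1, {n_edges}], got {k}")
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    pool_size = min(int(np.ceil((1.0 + omega) * k)), n_edges)
    order = np.argsort(-norms, kind="stable")
    pool = order[:pool_size]
    if pool_size > k and omega > 0:
        if rng is None:
            raise ValueError("randomised selection (omega > 0) needs an rng")
        selected = rng.choice(pool, size=k, replace=False)
    else:
        selected = pool[:k].copy()
    return EdgeSelection(candidate_pool=pool, selected=np.sort(selected), omega=omega, norms=norms)


def decay_omega(omega: float, rho: float) -> float:
    """One step of the exploration schedule: ``max(omega - rho, 0)``."""
    if omega < 0 or rho < 0:
        raise ValueError("omega and rho must be >= 0")
    return max(omega - rho, 0.0)


def _restrict_to_edges(z: np.ndarray, network: GeneNetwork, selection: EdgeSelection) -> np.ndarray:
    keep = np.zeros(len(z), dtype=bool)
    kept_vertices = np.unique(network.edges[selection.selected])
    keep[kept_vertices] = True
    return np.where(keep, z, 0.0)


def espca_project(z: np.ndarray, network: GeneNetwork, s: int) -> tuple[np.ndarray, EdgeSelection]:
    """Edge-group sparse projection: keep the top-``s`` edges by edge norm.

    Every probe incident to a kept edge survives with its value unchanged,
    so at most ``2 s`` probes remain.  Ties break toward the lower edge
    index.
    """
    z = np.asarray(z, dtype=float)
    norms = all_edge_norms(z, network)
    selection = select_edges(norms, s, omega=0.0)
    return _restrict_to_edges(z, network, selection), selection


def awge_project(
    z: np.ndarray,
    network: GeneNetwork,
    weights: PathwayWeights | None = None,
    k: int = 1,
    omega: float = 0.0,
    lq: float = DEFAULT_LQ,
    rng: np.random.Generator | None = None,
    use_lar: bool = True,
    use_weights: bool = True,
    lar_mode: str = "absolute",
) -> tuple[np.ndarray, EdgeSelection]:
    """Full adaptive weighted edge-group projection pipeline.

    1. optionally fence out outlier entries of ``z`` (LAR);
    2. score every edge, pathway-weighted when ``use_weights``;
    3. greedy randomised top-``k`` selection at exploration rate ``omega``;
    4. keep ``z`` on probes incident to the selected edges, zero elsewhere.

    With ``use_lar=False``, ``use_weights=False`` and ``omega=0`` this is
    exactly the plain edge-group projection.
    """
    z = np.asarray(z, dtype=float)
    if use_lar:
        z = lar_regularize(z, lq, mode=lar_mode)
    norms = all_edge_norms(z, network, weights if use_weights else None)
    selection = select_edges(norms, k, omega=omega, rng=rng)
    return _restrict_to_edges(z, network, selection), selection
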