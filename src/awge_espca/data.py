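"""Core data containers: expression matrix, gene network, pathway weights.

The expression matrix is probes x samples (rows are gene probes, columns are
samples), matching the convention of RNA-seq expression tables where each row
is one probe's FPKM profile.  The gene interaction network is an undirected
edge list over probe indices; a pair of interacting probes forms one
edge-group, the atomic unit of the edge-group sparsity constraint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class DegenerateFitError(RuntimeError):
    """Raised when a fit collapses to an all-zero loading vector."""


@dataclass
class ExpressionMatrix:
    """Dense probes x samples expression matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (m, n)
        Expression values (e.g. FPKM), one row per probe.
    probe_ids : sequence of str
        Unique probe identifiers, one per row.
    sample_ids : sequence of str
        Unique sample identifiers, one per column.
    """

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise ValueError(f"need at least 2 probes and 2 samples, got {m}x{n}")
        if len(self.probe_ids) != m:
            raise ValueError("probe_ids length does not match number of rows")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of columns")
        if len(set(self.probe_ids)) != m:
            raise ValueError("probe_ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains NaN or infinite values")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def probe_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.probe_ids)}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a DataFrame whose index holds probe IDs and whose
        columns hold sample IDs."""
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass
class GeneNetwork:
    """Undirected gene interaction network over probe indices.

    Edges are canonicalised to ``(min, max)`` index order; duplicates and
    self-edges are dropped with a logged warning.  ``n_probes``, when given,
    bounds the valid endpoint range.
    """

    edges: np.ndarray
    n_probes: int | None = None

    def __post_init__(self) -> None:
        raw = np.asarray(self.edges, dtype=int)
        if raw.size == 0:
            raise ValueError("gene network must contain at least one edge")
        if raw.ndim != 2 or raw.shape[1] != 2:
            raise ValueError("edges must be an (E, 2) array of probe index pairs")
        self_loops = raw[:, 0] == raw[:, 1]
        if self_loops.any():
            logger.warning("dropping %d self-edge(s)", int(self_loops.sum()))
            raw = raw[~self_loops]
        canon = np.sort(raw, axis=1)
        uniq, idx = np.unique(canon, axis=0, return_index=True)
        if len(uniq) < len(canon):
            logger.warning("dropping %d duplicate edge(s)", len(canon) - len(uniq))
        # preserve first-occurrence order so edge indices stay predictable
        self.edges = canon[np.sort(idx)]
        if len(self.edges) == 0:
            raise ValueError("gene network has no valid edges after canonicalisation")
        if (self.edges < 0).any():
            raise ValueError("edge endpoints must be non-negative probe indices")
        if self.n_probes is not None and (self.edges >= self.n_probes).any():
            raise ValueError("edge endpoint out of range for the expression matrix")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def vertices(self) -> np.ndarray:
        return np.unique(self.edges)

    @classmethod
    def from_probe_ids(
        cls,
        pairs: list[tuple[str, str]],
        probe_index: dict[str, int],
        on_unknown: str = "error",
    ) -> "GeneNetwork":
        """Resolve probe-ID pairs to index pairs via the expression matrix.

        ``on_unknown`` is ``"error"`` (default) or ``"skip"``.
        """
        resolved = []
        for a, b in pairs:
            if a not in probe_index or b not in probe_index:
                if on_unknown == "skip":
                    logger.warning("skipping edge with unknown probe: (%s, %s)", a, b)
                    continue
                raise KeyError(f"edge references unknown probe: ({a}, {b})")
            resolved.append((probe_index[a], probe_index[b]))
        if not resolved:
            raise ValueError("no resolvable edges in the edge list")
        return cls(np.array(resolved), n_probes=len(probe_index))


def normalize_weights(counts: np.ndarray, a: float = 1.0, b: float = 2.0) -> "PathwayWeights":
    """Min-max normalise per-probe pathway counts onto ``[a, b]``.

    ``w_i = a + (b - a) / (Max - Min) * (counts_i - Min)``.  Constant counts
    map to the midpoint ``(a + b) / 2`` so a flat annotation reduces the
    weighted edge norm to the unweighted one up to a constant factor.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 1:
        raise ValueError("counts must be a non-empty 1-D array")
    if (counts < 0).any():
        raise ValueError("pathway counts must be non-negative")
    if not a < b:
        raise ValueError(f"normalisation range requires a < b, got a={a}, b={b}")
    lo, hi = counts.min(), counts.max()
    if hi > lo:
        scale = (b - a) / (hi - lo)
        normalized = a + scale * (counts - lo)
    else:
        scale = 0.0
        normalized = np.full_like(counts, (a + b) / 2.0)
    return PathwayWeights(counts=counts, normalized=normalized, a=a, b=b, scale=scale)


@dataclass
class PathwayWeights:
    """Per-probe pathway counts and their min-max normalised weights.

    ``counts[i]`` is the number of target-relevant pathways annotated to
    probe ``i``; ``normalized`` is the affine map of the counts onto
    ``[a, b]``.  Probes missing from an annotation table get count 0.
    """

    counts: np.ndarray
    normalized: np.ndarray
    a: float = 1.0
    b: float = 2.0
    scale: float = field(default=0.0)

    @classmethod
    def uniform(cls, m: int, a: float = 1.0, b: float = 2.0) -> "PathwayWeights":
        """Flat annotation: every probe gets the midpoint weight."""
        return normalize_weights(np.zeros(m), a, b)

    @classmethod
    def from_counts(cls, counts: np.ndarray, a: float = 1.0, b: float = 2.0) -> "PathwayWeights":
        return normalize_weights(counts, a, b)

    def __len__(self) -> int:
        return len(self.counts)
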