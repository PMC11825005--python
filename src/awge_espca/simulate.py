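"""Synthetic data generator for the support-recovery study.

The canonical design plants two sparse rank-1 factors in a 12-probe x
100-sample expression matrix and adds a block of four pure-noise probes whose
expression is uniformly large (200-300), far above the signal scale:

    X = d1 u1 v1' + d2 u2 v2' + noise block + Gaussian perturbation

with loadings ``u1 = (1, 0.86, 0.66, 0.9, 0 x 8)`` and
``u2 = (0 x 4, 0.2, -0.55, -0.35, 0.17, 0 x 4)`` and scores ``v1, v2``
standard normal of length 100.  The gene network is the two K4 cliques on the
factor supports plus four decoy edges that join true-signal probes to noise
probes — (5,9), (6,10), (1,11), (3,12) in 1-based labels — planted to tempt
edge-group selection into admitting noise.

``simulate_general`` scales the same structure to arbitrary sizes for
property tests, and can emit pathway counts enriched on the true supports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionMatrix, GeneNetwork, PathwayWeights, normalize_weights

#: canonical design constants
N_PROBES = 12
N_SAMPLES = 100
NOISE_PROBES = (8, 9, 10, 11)  # 0-based rows of the uniform noise block


def make_true_loadings() -> tuple[np.ndarray, np.ndarray]:
    """The two planted loading patterns (length 12, disjoint supports)."""
    u1 = np.array([1.0, 0.86, 0.66, 0.9] + [0.0] * 8)
    u2 = np.array([0.0] * 4 + [0.2, -0.55, -0.35, 0.17] + [0.0] * 4)
    return u1, u2


def make_network() -> GeneNetwork:
    """The 16-edge decoy-augmented network of the canonical design."""
    y1 = [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4), (5, 9), (6, 10)]
    y2 = [(5, 6), (5, 7), (5, 8), (6, 7), (6, 8), (7, 8), (1, 11), (3, 12)]
    edges = np.array(y1 + y2) - 1  # to 0-based indices
    return GeneNetwork(edges, n_probes=N_PROBES)


@dataclass
class SimulationSpec:
    """Parameters of the canonical generator.

    ``d1``/``d2`` set the factor strengths: detectable above the unit
    Gaussian perturbation yet far below the 200-300 noise block, the noise
    regime the design probes.
    """

    d1: float = 10.0
    d2: float = 8.0
    n_samples: int = N_SAMPLES
    noise_block_range: tuple[float, float] = (200.0, 300.0)
    eps_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.noise_block_range
        if lo >= hi:
            raise ValueError("noise_block_range must satisfy low < high")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.eps_sd < 0:
            raise ValueError("eps_sd must be >= 0")


@dataclass
class SimulationTruth:
    """Ground truth for scoring support recovery."""

    factor_supports: list[np.ndarray]
    noise_probes: np.ndarray
    loadings: np.ndarray  # m x n_factors true loading patterns
    scores: np.ndarray  # n x n_factors true score vectors
    strengths: np.ndarray = field(default_factory=lambda: np.array([]))


def simulate_matrix(
    spec: SimulationSpec | None = None, rng: np.random.Generator | int | None = None
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Draw one canonical 12 x 100 instance.

    Rows 1-8 carry the two planted factors; rows 9-12 are replaced by the
    uniform noise block; i.i.d. Gaussian perturbation is added everywhere.
    """
    spec = spec if spec is not None else SimulationSpec()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(spec.seed if rng is None else int(rng))
    u1, u2 = make_true_loadings()
    n = spec.n_samples
    v1 = rng.standard_normal(n)
    v2 = rng.standard_normal(n)
    X = spec.d1 * np.outer(u1, v1) + spec.d2 * np.outer(u2, v2)
    lo, hi = spec.noise_block_range
    noise = list(NOISE_PROBES)
    X[noise, :] = rng.uniform(lo, hi, size=(len(noise), n))
    if spec.eps_sd > 0:
        X = X + spec.eps_sd * rng.standard_normal(X.shape)
    data = ExpressionMatrix(
        X,
        [f"Var{i + 1}" for i in range(N_PROBES)],
        [f"S{j + 1}" for j in range(n)],
    )
    truth = SimulationTruth(
        factor_supports=[np.arange(0, 4), np.arange(4, 8)],
        noise_probes=np.array(noise),
        loadings=np.column_stack([u1, u2]),
        scores=np.column_stack([v1, v2]),
        strengths=np.array([spec.d1, spec.d2]),
    )
    return data, truth


def simulate_general(
    m: int = N_PROBES,
    n_samples: int = N_SAMPLES,
    n_factors: int = 2,
    n_noise_probes: int = 4,
    block_size: int = 4,
    strengths: np.ndarray | None = None,
    noise_block_range: tuple[float, float] = (200.0, 300.0),
    eps_sd: float = 1.0,
    enriched_counts: bool = False,
    rng: np.random.Generator | int | None = None,
) -> tuple[ExpressionMatrix, GeneNetwork, PathwayWeights, SimulationTruth]:
    """Scalable generalisation of the canonical design.

    Factors occupy disjoint consecutive blocks of ``block_size`` probes, each
    block forming a clique in the network; every noise probe is joined to one
    true-signal probe by a decoy edge.  With the default arguments the
    canonical loadings and network are reproduced exactly.  When
    ``enriched_counts`` is set, pathway counts are drawn higher on the true
    supports (emulating annotation-enriched regions); otherwise counts are
    flat and the weighted norm reduces to the unweighted one.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if n_factors < 1 or block_size < 2 or n_noise_probes < 0:
        raise ValueError("need n_factors >= 1, block_size >= 2, n_noise_probes >= 0")
    n_signal = n_factors * block_size
    if n_signal + n_noise_probes > m:
        raise ValueError(
            f"{n_factors} factors of {block_size} probes plus {n_noise_probes} "
            f"noise probes do not fit in m={m}"
        )
    canonical = (
        m == N_PROBES
        and n_factors == 2
        and block_size == 4
        and n_noise_probes == 4
        and strengths is None
    )
    if canonical:
        # exact specialisation: same draws, loadings and network as the
        # canonical generator
        spec = SimulationSpec(
            n_samples=n_samples, noise_block_range=noise_block_range, eps_sd=eps_sd
        )
        data, truth = simulate_matrix(spec, rng)
        weights = normalize_weights(np.zeros(m))
        return data, make_network(), weights, truth
    if strengths is None:
        strengths = np.linspace(10.0, max(10.0 - 2.0 * (n_factors - 1), 4.0), n_factors)
    strengths = np.asarray(strengths, dtype=float)

    # loading patterns
    U = np.zeros((m, n_factors))
    supports = []
    for f in range(n_factors):
        block = np.arange(f * block_size, (f + 1) * block_size)
        mags = rng.uniform(0.2, 1.0, size=block_size)
        signs = np.ones(block_size) if f == 0 else rng.choice([-1.0, 1.0], size=block_size)
        U[block, f] = mags * signs
        supports.append(block)
    noise_probes = np.arange(m - n_noise_probes, m) if n_noise_probes else np.array([], dtype=int)

    # expression matrix
    V = rng.standard_normal((n_samples, n_factors))
    X = (U * strengths) @ V.T
    lo, hi = noise_block_range
    if n_noise_probes:
        X[noise_probes, :] = rng.uniform(lo, hi, size=(n_noise_probes, n_samples))
    if eps_sd > 0:
        X = X + eps_sd * rng.standard_normal(X.shape)
    data = ExpressionMatrix(
        X, [f"Var{i + 1}" for i in range(m)], [f"S{j + 1}" for j in range(n_samples)]
    )

    # network: per-factor cliques plus one decoy per noise probe
    edges = []
    for block in supports:
        edges.extend((int(i), int(j)) for a, i in enumerate(block) for j in block[a + 1:])
    signal_probes = np.concatenate(supports)
    for t, p in enumerate(noise_probes):
        edges.append((int(signal_probes[t % len(signal_probes)]), int(p)))
    network = GeneNetwork(np.array(edges), n_probes=m)

    # pathway counts
    if enriched_counts:
        counts = rng.poisson(1.0, size=m).astype(float)
        for block in supports:
            counts[block] += rng.poisson(5.0, size=len(block))
        counts[noise_probes] = 0.0
    else:
        counts = np.zeros(m)
    weights = normalize_weights(counts)

    truth = SimulationTruth(
        factor_supports=supports,
        noise_probes=noise_probes,
        loadings=U,
        scores=V,
        strengths=strengths,
    )
    return data, network, weights, truth
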