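"""Scoring and reporting: support recovery, top-k probes, target-pathway
proportion, and the ablation harness."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GeneNetwork, PathwayWeights
from .model import AWGESparsePCA, ComponentResult, FitConfig, SparsePCAResults
from .simulate import SimulationTruth


@dataclass
class RecoveryReport:
    """Set-overlap metrics of one estimated support against one true support."""

    true_positives: list[int]
    false_positives: list[int]
    false_negatives: list[int]
    precision: float
    recall: float
    f1: float
    noise_intrusions: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _set_metrics(est: set[int], true: set[int]) -> tuple[float, float, float]:
    tp = len(est & true)
    precision = tp / len(est) if est else 0.0
    recall = tp / len(true) if true else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def support_recovery(
    result: ComponentResult | np.ndarray,
    true_support: np.ndarray,
    noise_probes: np.ndarray | None = None,
    m: int | None = None,
) -> RecoveryReport:
    """Score an estimated support against the truth (sign-invariant: only the
    nonzero pattern of the loadings matters)."""
    if isinstance(result, ComponentResult):
        est_idx = result.support
        m_est = len(result.u)
    else:
        arr = np.asarray(result)
        est_idx = np.flatnonzero(arr) if arr.dtype != int or arr.ndim > 1 else arr
        m_est = m if m is not None else (len(arr) if arr.dtype != int else None)
    true_support = np.asarray(true_support, dtype=int)
    if m_est is not None and len(true_support) and true_support.max() >= m_est:
        raise ValueError("true support references probes beyond the fitted vector")
    est, true = set(map(int, est_idx)), set(map(int, true_support))
    precision, recall, f1 = _set_metrics(est, true)
    noise = set(map(int, noise_probes)) if noise_probes is not None else set()
    return RecoveryReport(
        true_positives=sorted(est & true),
        false_positives=sorted(est - true),
        false_negatives=sorted(true - est),
        precision=precision,
        recall=recall,
        f1=f1,
        noise_intrusions=len(est & noise),
    )


def score_fit(results: SparsePCAResults, truth: SimulationTruth) -> list[RecoveryReport]:
    """Per-component recovery reports, component ``i`` scored against factor ``i``."""
    reports = []
    for i, comp in enumerate(results.components):
        true = truth.factor_supports[i] if i < len(truth.factor_supports) else np.array([], dtype=int)
        reports.append(support_recovery(comp, true, truth.noise_probes))
    return reports


def noise_intrusion_count(results: SparsePCAResults, truth: SimulationTruth) -> int:
    """Number of noise probes appearing in any component's support."""
    est: set[int] = set()
    for comp in results.components:
        est |= set(map(int, comp.support))
    return len(est & set(map(int, truth.noise_probes)))


def top_k_probes(result: ComponentResult | np.ndarray, k: int,
                 probe_ids: list[str] | None = None) -> list:
    """Probes ranked by |PC1 loading| descending, ties toward the lower index.

    Returns probe IDs when given, else 0-based indices.
    """
    u = result.u if isinstance(result, ComponentResult) else np.asarray(result, dtype=float)
    if k > len(u):
        raise ValueError(f"k={k} exceeds the number of probes ({len(u)})")
    order = np.argsort(-np.abs(u), kind="stable")[:k]
    if probe_ids is not None:
        return [probe_ids[i] for i in order]
    return [int(i) for i in order]


@dataclass
class PathwayProportionReport:
    """Fraction of the top-n ranked probes annotated to the target pathways."""

    top_n: int
    n_target_genes: int
    proportion: float
    clamped: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def target_pathway_proportion(
    ranked_probes: list, annotation: dict, top_n: int = 500
) -> PathwayProportionReport:
    """Proportion of target-pathway genes among the ``top_n`` ranked probes.

    ``annotation`` maps probe -> truthy flag; probes missing from the mapping
    count as non-target.  ``top_n`` larger than the ranking is clamped.
    """
    clamped = top_n > len(ranked_probes)
    n = min(top_n, len(ranked_probes))
    if n == 0:
        raise ValueError("empty probe ranking")
    hits = sum(bool(annotation.get(p, False)) for p in ranked_probes[:n])
    return PathwayProportionReport(
        top_n=n, n_target_genes=hits, proportion=hits / n, clamped=clamped
    )


#: ablation variants of the full model, keyed by the published names
ABLATION_VARIANTS = {
    "full": {},
    "non_weighted": {"use_weights": False},
    "non_regularization": {"use_lar": False},
}


@dataclass
class AblationRow:
    variant: str
    reports: list[RecoveryReport]
    noise_intrusions: int
    supports: list[list[int]] = field(default_factory=list)


def run_ablation(
    X: ExpressionMatrix,
    network: GeneNetwork,
    pathway_counts: PathwayWeights | np.ndarray | None,
    config: FitConfig,
    truth: SimulationTruth | None = None,
) -> list[AblationRow]:
    """Fit the full model plus the two single-module ablations.

    The three rows share the same seed, so the full-model row is identical
    to a direct fit with that configuration.
    """
    rows = []
    for name, toggles in ABLATION_VARIANTS.items():
        model = AWGESparsePCA(X, network, pathway_counts, config=config, **toggles)
        results = model.fit()
        reports = score_fit(results, truth) if truth is not None else []
        intrusions = noise_intrusion_count(results, truth) if truth is not None else 0
        rows.append(
            AblationRow(
                variant=name,
                reports=reports,
                noise_intrusions=intrusions,
                supports=[[int(i) for i in c.support] for c in results.components],
            )
        )
    return rows


def ablation_table(rows: list[AblationRow]) -> pd.DataFrame:
    records = []
    for row in rows:
        rec = {"variant": row.variant, "noise_intrusions": row.noise_intrusions}
        for i, rep in enumerate(row.reports):
            rec[f"PC{i + 1}_f1"] = rep.f1
        records.append(rec)
    return pd.DataFrame(records)
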