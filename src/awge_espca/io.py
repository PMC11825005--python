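"""Readers and writers for the plain-text interchange formats.

Expression tables are TSV/CSV with probe IDs in the first column and sample
IDs in the header.  Networks are two-column edge lists of probe IDs.
Pathway tables are two columns: probe ID and count of target-relevant
pathways.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GeneNetwork
from .model import SparsePCAResults


def read_expression(path, sep: str = "\t") -> ExpressionMatrix:
    """Read a probes x samples expression table; rejects missing values."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise ValueError(f"empty expression table: {path}")
    if df.isna().any().any():
        raise ValueError(f"expression table contains missing values: {path}")
    return ExpressionMatrix.from_dataframe(df)


def write_expression(data: ExpressionMatrix, path, sep: str = "\t") -> None:
    data.to_dataframe().to_csv(path, sep=sep, index_label="probe_id")


def read_edge_list(path, probe_index: dict[str, int], sep: str = "\t",
                   on_unknown: str = "error") -> GeneNetwork:
    """Read a two-column probe-ID edge list and resolve against the matrix."""
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"edge list must have two columns: {path}")
    pairs = list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    return GeneNetwork.from_probe_ids(pairs, probe_index, on_unknown=on_unknown)


def write_edge_list(network: GeneNetwork, probe_ids: list[str], path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for i, j in network.edges:
            fh.write(f"{probe_ids[i]}{sep}{probe_ids[j]}\n")


def read_pathway_counts(path, probe_ids: list[str], sep: str = "\t") -> np.ndarray:
    """Read a probe_id / n_target_pathways table; absent probes count 0."""
    df = pd.read_csv(path, sep=sep, header=None, comment="#",
                     names=["probe_id", "n_target_pathways"], dtype={0: str})
    mapping = dict(zip(df["probe_id"].astype(str), df["n_target_pathways"].astype(float)))
    return np.array([mapping.get(p, 0.0) for p in probe_ids])


def write_pathway_counts(counts: np.ndarray, probe_ids: list[str], path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for p, c in zip(probe_ids, counts):
            fh.write(f"{p}{sep}{int(c)}\n")


def write_loadings(results: SparsePCAResults, path, sep: str = "\t") -> None:
    """Loadings TSV: probe_id, pc1_loading, pc2_loading, ..."""
    df = results.loadings
    df.columns = [f"pc{i + 1}_loading" for i in range(df.shape[1])]
    df.to_csv(path, sep=sep, index_label="probe_id")


def write_scores(results: SparsePCAResults, path, sep: str = "\t") -> None:
    df = results.scores
    df.columns = [f"pc{i + 1}_score" for i in range(df.shape[1])]
    df.to_csv(path, sep=sep, index_label="sample_id")


def write_selected_edges(results: SparsePCAResults, path, sep: str = "\t") -> None:
    probe_ids = results.model.data.probe_ids
    with open(path, "w") as fh:
        fh.write(f"component{sep}probe_a{sep}probe_b\n")
        for c, comp in enumerate(results.components):
            for i, j in comp.selected_edges:
                fh.write(f"PC{c + 1}{sep}{probe_ids[i]}{sep}{probe_ids[j]}\n")


def write_run_log(results: SparsePCAResults, path) -> None:
    """JSON run log with per-iteration objective traces and diagnostics."""
    payload = {
        "model": type(results.model).__name__,
        "config": vars(results.model.config),
        "components": [
            {
                "singular_value": comp.d,
                "n_iter": comp.n_iter,
                "converged": comp.converged,
                "support": [int(i) for i in comp.support],
                "excluded_probes": [int(i) for i in comp.excluded_probes],
                "objective_trace": [float(x) for x in comp.objective_trace],
            }
            for comp in results.components
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def report_to_json(obj, path) -> None:
    """Serialise any report dataclass (or list of them) to JSON."""
    def encode(o):
        if hasattr(o, "to_dict"):
            return o.to_dict()
        if isinstance(o, (list, tuple)):
            return [encode(x) for x in o]
        return o
    Path(path).write_text(json.dumps(encode(obj), indent=2))
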