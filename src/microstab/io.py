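"""Plain-TSV readers and writers for every table the pipeline consumes.

Everything is emitted as tab-separated text so that R, Gephi or a
spreadsheet can consume the outputs without conversion.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import CountTable, ScfaTable, StudyMetadata, ValidationError


class FormatError(ValueError):
    """A file does not parse as the expected TSV dialect."""


def read_count_table(path, **kwargs) -> CountTable:
    """Read a taxa-as-rows TSV OTU table.

    Dialect: first column = taxon ID, header row = sample IDs. Cells must be
    non-negative numbers; validation errors (duplicates, negatives) raise.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path} as a TSV count table: {exc}") from exc
    if frame.shape[1] == 0:
        raise FormatError(f"{path} has no sample columns")
    try:
        counts = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    return CountTable(
        taxon_ids=list(frame.index.astype(str)),
        sample_ids=list(frame.columns.astype(str)),
        counts=counts,
        **kwargs,
    )


def write_count_table(table: CountTable, path) -> None:
    frame = table.to_frame()
    frame.index.name = "taxon_id"
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_metadata(path) -> StudyMetadata:
    return StudyMetadata(pd.read_csv(path, sep="\t", dtype=str))


def write_metadata(meta: StudyMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False)


def read_scfa(path) -> ScfaTable:
    frame = pd.read_csv(path, sep="\t")
    frame["sample_id"] = frame["sample_id"].astype(str)
    return ScfaTable(frame)


def write_scfa(scfa: ScfaTable, path) -> None:
    scfa.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_network(net, edge_path, node_path=None) -> None:
    """Write a signed network as an edge list (+ optional node table).

    Edge list columns: source, target, sign (+1/-1), weight (|r|) — the
    format Gephi and igraph import directly. The node table carries degree
    and module membership when present.
    """
    g = net.graph
    rows = [
        {
            "source": u,
            "target": v,
            "sign": int(d["sign"]),
            "weight": float(d["weight"]),
        }
        for u, v, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "sign", "weight"]).to_csv(
        edge_path, sep="\t", index=False, float_format="%.10g"
    )
    if node_path is not None:
        nrows = [
            {
                "taxon_id": n,
                "degree": g.degree(n),
                "module_id": g.nodes[n].get("module", ""),
            }
            for n in sorted(g.nodes)
        ]
        pd.DataFrame(nrows, columns=["taxon_id", "degree", "module_id"]).to_csv(
            node_path, sep="\t", index=False
        )


def read_network(edge_path, threshold: float | None = None):
    """Rebuild a SignedNetwork from an edge-list TSV written by write_network."""
    import networkx as nx

    from .network import SignedNetwork

    frame = pd.read_csv(edge_path, sep="\t", dtype={"source": str, "target": str})
    g = nx.Graph()
    for row in frame.itertuples(index=False):
        g.add_edge(row.source, row.target, sign=int(row.sign), weight=float(row.weight))
    return SignedNetwork(graph=g, threshold=threshold)


def write_records(records, path) -> None:
    """Write a list of dataclass instances or dicts as tidy TSV."""
    import dataclasses

    rows = [
        dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_ground_truth(truth, path) -> None:
    """Serialize simulator ground truth as JSON (latent matrix as nested lists)."""
    payload = {
        "module_membership": [int(m) for m in truth.module_membership],
        "expected_shannon": {k: float(v) for k, v in truth.expected_shannon.items()},
        "bloom_taxa": [int(i) for i in truth.bloom_taxa],
        "beneficial_taxa": [int(i) for i in truth.beneficial_taxa],
        "scfa_coupling": {
            acid: {"taxa": [int(i) for i in taxa], "effect": float(eff)}
            for acid, (taxa, eff) in truth.scfa_coupling.items()
        },
        "latent_correlation": np.asarray(truth.latent_correlation).tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
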