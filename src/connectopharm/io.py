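"""Plain-text readers and writers for every pipeline artifact.

All formats are tab-separated text with ``#``-prefixed metadata lines, so
artifacts are diffable and round-trip exactly through the paired reader
(floats are written with shortest-repr precision, which Python parses back
to the identical IEEE-754 value).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import AssociationMatrix, BinaryGraph, TimeSeriesMatrix
from .cohort import SubjectRecord
from .hubs import HubSet
from .motion import MOTION_COLUMNS, MotionTrace

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_association",
    "write_association",
    "read_graph",
    "write_graph",
    "read_motion",
    "write_motion",
    "read_subjects",
    "write_subjects",
    "read_hubset",
    "write_hubset",
]


def _fmt(x: float) -> str:
    return repr(float(x))


def _read_meta(path: Path) -> tuple[dict, str]:
    meta: dict = {}
    body_lines = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
        else:
            body_lines.append(line)
    return meta, "\n".join(body_lines) + "\n"


def _meta_lines(meta: dict) -> str:
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


# -- time series -------------------------------------------------------------


def write_timeseries(ts: TimeSeriesMatrix, path, extra_meta: dict | None = None) -> None:
    """Nodes as rows, header row of volume indices, first column node label."""
    meta = {"tr_seconds": _fmt(ts.tr_seconds)}
    meta.update(extra_meta or {})
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        fh.write("node\t" + "\t".join(str(t) for t in range(ts.n_volumes)) + "\n")
        for label, row in zip(ts.node_labels, ts.values):
            fh.write(label + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_timeseries(path) -> TimeSeriesMatrix:
    meta, body = _read_meta(Path(path))
    df = pd.read_csv(_io.StringIO(body), sep="\t", index_col=0, float_precision="round_trip")
    return TimeSeriesMatrix(
        df.to_numpy(dtype=float),
        tr_seconds=float(meta["tr_seconds"]),
        node_labels=[str(i) for i in df.index],
    )


# -- association matrices ----------------------------------------------------


def write_association(assoc: AssociationMatrix, path, extra_meta: dict | None = None) -> None:
    """Square delimited matrix with a node-label header row and column."""
    meta = {"kind": assoc.kind, "scale": "" if assoc.scale is None else str(assoc.scale)}
    meta.update(extra_meta or {})
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        fh.write("node\t" + "\t".join(assoc.node_labels) + "\n")
        for label, row in zip(assoc.node_labels, assoc.values):
            fh.write(label + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_association(path) -> AssociationMatrix:
    meta, body = _read_meta(Path(path))
    df = pd.read_csv(_io.StringIO(body), sep="\t", index_col=0, float_precision="round_trip")
    scale = meta.get("scale") or None
    return AssociationMatrix(
        df.to_numpy(dtype=float),
        kind=meta.get("kind", "r"),
        scale=int(scale) if scale else None,
        node_labels=[str(i) for i in df.index],
    )


# -- graphs ------------------------------------------------------------------


def write_graph(graph: BinaryGraph, path, extra_meta: dict | None = None) -> None:
    """Edge list: node_a, node_b, weight at selection; node set in metadata."""
    meta = {"n_nodes": str(graph.n_nodes), "nodes": ",".join(graph.node_labels)}
    meta.update(extra_meta or {})
    weights = (
        graph.edge_weights
        if graph.edge_weights is not None
        else np.full(graph.n_edges, np.nan)
    )
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        fh.write("node_a\tnode_b\tweight_at_selection\n")
        for (i, j), w in zip(graph.edges, weights):
            fh.write(f"{graph.node_labels[i]}\t{graph.node_labels[j]}\t{_fmt(w)}\n")


def read_graph(path) -> BinaryGraph:
    meta, body = _read_meta(Path(path))
    labels = meta["nodes"].split(",") if meta.get("nodes") else []
    n_nodes = int(meta["n_nodes"])
    index = {lab: i for i, lab in enumerate(labels)}
    df = pd.read_csv(_io.StringIO(body), sep="\t", dtype={"node_a": str, "node_b": str}, float_precision="round_trip")
    edges = np.array(
        [[index[a], index[b]] for a, b in zip(df.node_a, df.node_b)], dtype=int
    ).reshape(-1, 2)
    swap = edges[:, 0] > edges[:, 1]
    edges[swap] = edges[swap][:, ::-1]
    return BinaryGraph(
        n_nodes=n_nodes,
        edges=edges,
        node_labels=labels,
        edge_weights=df.weight_at_selection.to_numpy(dtype=float),
    )


# -- motion ------------------------------------------------------------------


def write_motion(trace: MotionTrace, path, extra_meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_lines(extra_meta or {}))
        fh.write("\t".join(MOTION_COLUMNS) + "\n")
        for t_row, r_row in zip(trace.translations, trace.rotations):
            fh.write("\t".join(_fmt(v) for v in (*t_row, *r_row)) + "\n")


def read_motion(path) -> MotionTrace:
    _, body = _read_meta(Path(path))
    df = pd.read_csv(_io.StringIO(body), sep="\t", float_precision="round_trip")
    return MotionTrace.from_frame(df)


# -- subject metadata --------------------------------------------------------

_SUBJECT_COLS = [
    "subject_id",
    "group",
    "session",
    "updrs_iii",
    "led_mg_day",
    "plasma_ng_ml",
    "category_fluency",
    "ssrt_ms",
    "age_years",
]


def write_subjects(records: list[SubjectRecord], path, extra_meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_lines(extra_meta or {}))
        fh.write("\t".join(_SUBJECT_COLS) + "\n")
        for r in records:
            vals = [getattr(r, c) for c in _SUBJECT_COLS]
            fh.write(
                "\t".join(v if isinstance(v, str) else _fmt(v) for v in vals) + "\n"
            )


def read_subjects(path) -> list[SubjectRecord]:
    _, body = _read_meta(Path(path))
    df = pd.read_csv(_io.StringIO(body), sep="\t", float_precision="round_trip")
    return [
        SubjectRecord(
            subject_id=str(row.subject_id),
            group=str(row.group),
            session=str(row.session),
            updrs_iii=float(row.updrs_iii),
            led_mg_day=float(row.led_mg_day),
            plasma_ng_ml=float(row.plasma_ng_ml),
            category_fluency=float(row.category_fluency),
            ssrt_ms=float(row.ssrt_ms),
            age_years=float(row.age_years),
        )
        for row in df.itertuples()
    ]


# -- hub sets ----------------------------------------------------------------


def write_hubset(
    hubs: HubSet, path, node_labels: list[str] | None = None, extra_meta: dict | None = None
) -> None:
    """Small structured text file: hub ids plus decision provenance."""
    payload = {
        "hub_nodes": [int(i) for i in hubs.hub_nodes],
        "hub_labels": [node_labels[i] for i in hubs.hub_nodes] if node_labels else None,
        "definition_cohort": list(hubs.definition_cohort),
        "evaluation_cohort": list(hubs.evaluation_cohort),
        "threshold": float(hubs.threshold),
        "k": float(hubs.k),
        "mean_degree": [float(v) for v in hubs.mean_degree],
        "meta": extra_meta or {},
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_hubset(path) -> HubSet:
    payload = yaml.safe_load(Path(path).read_text())
    return HubSet(
        hub_nodes=np.asarray(payload["hub_nodes"], dtype=int),
        definition_cohort=list(payload["definition_cohort"]),
        evaluation_cohort=list(payload["evaluation_cohort"]),
        threshold=float(payload["threshold"]),
        mean_degree=np.asarray(payload["mean_degree"], dtype=float),
        k=float(payload["k"]),
    )
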