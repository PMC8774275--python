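"""Readers and writers for the pipeline's file formats.

Formats are deliberately plain: expression matrices and DE tables as
TSV/CSV, PPI edge lists as three-column TSV (accepting STRING's 0-1000
combined-score convention or plain [0, 1] scores), networks as GraphML
or SIF, modules as JSON.  Malformed rows are reported with their line
number; an ambiguous score scale is an explicit error.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, GeneDEStats, de_stats_frame
from .network import IntegratedNetwork
from .optimizer import ModuleResult, AgentPath

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


class DataFormatError(ValueError):
    """A file does not conform to one of the documented dialects."""


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path, annotation_path: str | Path) -> ExpressionMatrix:
    """Read an expression matrix plus its two-column sample annotation.

    The matrix file has gene ids in the first column and a header row of
    sample ids; the annotation file has columns (sample_id, group) with
    group in {normal, tumour}.
    """
    path, annotation_path = Path(path), Path(annotation_path)
    try:
        mat = pd.read_csv(path, sep=_sep(path), index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataFormatError(f"{path}: cannot parse expression matrix: {exc}") from exc
    if mat.empty:
        raise DataFormatError(f"{path}: empty expression matrix")
    non_numeric = [c for c in mat.columns if not np.issubdtype(mat[c].dtype, np.number)]
    if non_numeric:
        raise DataFormatError(f"{path}: non-numeric sample columns {non_numeric[:3]}")
    ann = pd.read_csv(annotation_path, sep=_sep(annotation_path))
    if ann.shape[1] < 2:
        raise DataFormatError(f"{annotation_path}: expected columns sample_id, group")
    ann = ann.iloc[:, :2]
    ann.columns = ["sample_id", "group"]
    groups = dict(zip(ann["sample_id"].astype(str), ann["group"].astype(str)))
    missing = [s for s in mat.columns if s not in groups]
    if missing:
        raise DataFormatError(f"{annotation_path}: samples without annotation: {missing[:5]}")
    return ExpressionMatrix(
        gene_ids=[str(g) for g in mat.index],
        values=mat.to_numpy(dtype=float),
        sample_groups=[groups[s] for s in mat.columns],
    )


def write_expression(path: str | Path, expr: ExpressionMatrix) -> None:
    path = Path(path)
    samples = [f"S{i+1:03d}" for i in range(len(expr.sample_groups))]
    pd.DataFrame(expr.values, index=pd.Index(expr.gene_ids, name="gene_id"),
                 columns=samples).to_csv(path, sep=_sep(path), float_format="%.6g")


def write_annotation(path: str | Path, expr: ExpressionMatrix) -> None:
    path = Path(path)
    samples = [f"S{i+1:03d}" for i in range(len(expr.sample_groups))]
    pd.DataFrame({"sample_id": samples, "group": expr.sample_groups}).to_csv(
        path, sep=_sep(path), index=False
    )


def read_ppi(path: str | Path) -> dict[Edge, float]:
    """Read a scored PPI edge list (protein1, protein2, combined_score).

    Scores are accepted either in STRING's 0-1000 integer convention or
    already in [0, 1]; the scale is auto-detected (any score > 1 means
    the 0-1000 convention) and normalised to [0, 1].  Duplicate and
    reciprocal rows collapse to the maximum score; self-loops are
    dropped.
    """
    path = Path(path)
    edges: dict[Edge, float] = {}
    raw: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("," if _sep(path) == "," else "\t")
            if lineno == 1 and _looks_like_header(parts):
                continue
            if len(parts) < 3:
                raise DataFormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            u, v, s = parts[0].strip(), parts[1].strip(), parts[2].strip()
            if not _is_number(s):
                raise DataFormatError(f"{path}:{lineno}: non-numeric score {s!r}")
            raw.append((u, v, float(s)))
    if not raw:
        raise DataFormatError(f"{path}: no edges")
    scores = np.array([s for _, _, s in raw])
    if scores.min() < 0:
        raise DataFormatError(f"{path}: negative association score {scores.min()}")
    if scores.max() > 1000:
        raise DataFormatError(
            f"{path}: score {scores.max()} exceeds 1000; neither the [0,1] "
            "nor the 0-1000 convention applies"
        )
    scale = 1000.0 if scores.max() > 1.0 else 1.0
    for u, v, s in raw:
        if u == v:
            logger.warning("dropping self-loop %s-%s", u, v)
            continue
        e = (u, v) if u <= v else (v, u)
        val = s / scale
        edges[e] = max(val, edges.get(e, 0.0))
    return edges


_HEADER_FIRST = {"protein1", "node1", "source", "gene1"}
_HEADER_LAST = {"combined_score", "score", "weight"}


def _looks_like_header(parts: list[str]) -> bool:
    if not parts:
        return False
    first = parts[0].strip().lower()
    last = parts[-1].strip().lower()
    return first in _HEADER_FIRST or last in _HEADER_LAST


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_ppi(path: str | Path, edges: dict[Edge, float]) -> None:
    path = Path(path)
    rows = [(u, v, f"{s:.6g}") for (u, v), s in sorted(edges.items())]
    pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]).to_csv(
        path, sep=_sep(path), index=False
    )


def write_de_table(path: str | Path, stats: list[GeneDEStats]) -> None:
    """Write the DE table (gene_id, log_fc, t, p_value, adj_p_value)."""
    de_stats_frame(stats).to_csv(Path(path), sep="\t", index=False, float_format="%.8g")


def read_de_table(path: str | Path) -> list[GeneDEStats]:
    df = pd.read_csv(Path(path), sep="\t")
    required = {"gene_id", "log_fc", "t", "p_value", "adj_p_value"}
    if not required <= set(df.columns):
        raise DataFormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return [
        GeneDEStats(str(r.gene_id), float(r.t), float(r.log_fc),
                    float(r.p_value), float(r.adj_p_value))
        for r in df.itertuples()
    ]


def write_graphml(path: str | Path, net: IntegratedNetwork) -> None:
    g = net.graph.copy()
    g.graph.update({k: float(v) for k, v in net.params.items()})
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> IntegratedNetwork:
    g = nx.read_graphml(str(path))
    params = {k: float(v) for k, v in g.graph.items() if k in {"c1", "c2", "d1", "d2"}}
    return IntegratedNetwork(graph=nx.Graph(g), params=params)


def write_sif(path: str | Path, net: IntegratedNetwork) -> None:
    """SIF export (node pair per line, relation 'pp'); weights are lost."""
    with open(path, "w") as fh:
        for u, v in sorted(net.graph.edges):
            fh.write(f"{u}\tpp\t{v}\n")


def write_module_json(path: str | Path, result: ModuleResult) -> None:
    Path(path).write_text(result.to_json())


def read_module_json(path: str | Path) -> ModuleResult:
    payload = json.loads(Path(path).read_text())
    return ModuleResult(
        nodes=list(payload["nodes"]),
        edges=[tuple(e) for e in payload["edges"]],
        objective=float(payload["objective"]),
        agent_paths=[
            AgentPath(
                agent_id=p["agent_id"], start=p["start"], nodes=list(p["nodes"]),
                accumulated=list(p["accumulated"]),
                terminated_early=bool(p["terminated_early"]),
            )
            for p in payload.get("agent_paths", [])
        ],
        params=payload.get("params", {}),
        seed=int(payload.get("seed", 0)),
        restart_index=int(payload.get("restart_index", 0)),
        per_restart_objective=list(payload.get("per_restart_objective", [])),
    )


def write_module_tsv(path: str | Path, result: ModuleResult, net: IntegratedNetwork | None = None) -> None:
    rows = []
    for n in result.nodes:
        w = float(net.graph.nodes[n].get("weight", np.nan)) if net is not None else np.nan
        rows.append({"gene_id": n, "weight": w})
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False, float_format="%.8g")
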