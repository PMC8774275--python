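"""End-to-end orchestration: expression -> network -> SDA -> evaluation.

``pipeline_run`` executes the full flow on file inputs and writes every
intermediate artifact plus a manifest that makes the run reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import io as sio
from .evaluation import local_modularity
from .expression import ExpressionMatrix, GeneDEStats, compute_de_stats, filter_de_genes
from .network import (
    IntegratedNetwork,
    build_gene_layer,
    build_protein_layer,
    integrate,
)
from .optimizer import ModuleResult, SDAParams, run_sda

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


class ConfigError(ValueError):
    """Invalid run configuration (bad paths or out-of-range parameters)."""


class AlgorithmError(RuntimeError):
    """The optimisation stage could not produce a module."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from YAML."""

    expression: str
    annotation: str
    ppi: str
    out_dir: str
    adj_p_cut: float = 0.01
    abs_lfc_cut: float = 1.0
    score_cut: float = 0.4
    c1: float = 0.5
    c2: float = 0.5
    d1: float = 0.5
    d2: float = 0.5
    normalise: str = "minmax"
    module_size: int = 60
    n_agents: int = 8
    delta: float = 0.5
    restarts: int = 10
    seed: int = 42
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("expression", "annotation", "ppi"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigError(f"{name} file not found: {p}")
        if not (self.adj_p_cut > 0 and self.abs_lfc_cut > 0):
            raise ConfigError("DE thresholds must be positive")
        if not 0.0 <= self.score_cut <= 1.0:
            raise ConfigError("score_cut must lie in [0, 1]")

    def sda_params(self) -> SDAParams:
        return SDAParams(
            module_size=self.module_size,
            n_agents=self.n_agents,
            delta=self.delta,
            smell_c1=self.c1,
            smell_c2=self.c2,
            seed=self.seed,
            restarts=self.restarts,
        )


def build_network(
    expr: ExpressionMatrix,
    stats: list[GeneDEStats],
    ppi_edges: dict[Edge, float],
    de_genes: list[str] | None = None,
    score_cut: float = 0.4,
    c1: float = 0.5,
    c2: float = 0.5,
    d1: float = 0.5,
    d2: float = 0.5,
    normalise: str = "minmax",
) -> IntegratedNetwork:
    """Assemble the integrated network from expression stats and a PPI.

    PPI edges below ``score_cut`` are discarded; when ``de_genes`` is
    given, only edges whose two endpoints are both DE genes survive.
    DE genes absent from the surviving PPI are dropped at integration.
    """
    keep = set(de_genes) if de_genes is not None else None
    edges = {
        e: s
        for e, s in ppi_edges.items()
        if s >= score_cut and (keep is None or (e[0] in keep and e[1] in keep))
    }
    if not edges:
        raise AlgorithmError("no PPI edge survives the score threshold / DE restriction")
    use_stats = [s for s in stats if keep is None or s.gene_id in keep]
    pl = build_protein_layer(edges)
    gl = build_gene_layer(expr, use_stats, edges, normalise=normalise)
    return integrate(gl, pl, c1, c2, d1, d2, stats={s.gene_id: s for s in use_stats})


def pipeline_run(config: RunConfig) -> ModuleResult:
    """Run all stages and write artifacts + manifest to ``config.out_dir``.

    Stage failures abort with the stage name; artifacts written so far
    are listed in a partial manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    manifest = {
        "config": asdict(config),
        "stages": [],
        "artifacts": written,
    }

    def _fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise exc

    t0 = time.perf_counter()
    # stage 1: differential expression
    try:
        expr = sio.read_expression(config.expression, config.annotation)
        stats = compute_de_stats(expr)
        de_genes = filter_de_genes(stats, config.adj_p_cut, config.abs_lfc_cut)
        sio.write_de_table(out / "de_table.tsv", stats)
        written.append("de_table.tsv")
        manifest["stages"].append({"name": "expression_stats", "n_de_genes": len(de_genes)})
    except (sio.DataFormatError, ConfigError):
        raise
    except Exception as exc:
        _fail("expression_stats", AlgorithmError(f"expression_stats failed: {exc}"))

    # stage 2: network integration
    try:
        ppi = sio.read_ppi(config.ppi)
        in_ppi = {p for e in ppi for p in e}
        absent = sorted(set(de_genes) - in_ppi)
        if absent:
            (out / "de_genes_without_ppi.txt").write_text("\n".join(absent) + "\n")
            written.append("de_genes_without_ppi.txt")
            logger.info("%d DE genes have no PPI entry", len(absent))
        net = build_network(
            expr, stats, ppi, de_genes=de_genes, score_cut=config.score_cut,
            c1=config.c1, c2=config.c2, d1=config.d1, d2=config.d2,
            normalise=config.normalise,
        )
        sio.write_graphml(out / "network.graphml", net)
        sio.write_sif(out / "network.sif", net)
        written += ["network.graphml", "network.sif"]
        manifest["stages"].append(
            {"name": "network_integration",
             "n_nodes": net.graph.number_of_nodes(),
             "n_edges": net.graph.number_of_edges()}
        )
    except sio.DataFormatError:
        raise
    except Exception as exc:
        _fail("network_integration", AlgorithmError(f"network_integration failed: {exc}"))

    # stage 3: SDA optimisation
    try:
        result = run_sda(net, config.sda_params())
        sio.write_module_json(out / "module.json", result)
        sio.write_module_tsv(out / "module.tsv", result, net)
        written += ["module.json", "module.tsv"]
        manifest["stages"].append(
            {"name": "sda_optimizer", "objective": result.objective,
             "module_size": len(result.nodes)}
        )
    except Exception as exc:
        _fail("sda_optimizer", AlgorithmError(f"sda_optimizer failed: {exc}"))

    # stage 4: evaluation
    try:
        dec = local_modularity(result.nodes, net)
        m = len(result.nodes)
        q = len(result.edges)
        density = 0.0 if m < 2 else 2.0 * q / (m * (m - 1))
        with open(out / "evaluation.tsv", "w") as fh:
            fh.write("F\tR\tm\tq\tdensity\n")
            fh.write(f"{result.objective:.8g}\t{dec.R:.8g}\t{m}\t{q}\t{density:.8g}\n")
        written.append("evaluation.tsv")
        manifest["stages"].append({"name": "module_evaluation", "R": dec.R})
    except Exception as exc:
        _fail("module_evaluation", AlgorithmError(f"module_evaluation failed: {exc}"))

    manifest["wall_time_s"] = time.perf_counter() - t0
    written.append("manifest.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result
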