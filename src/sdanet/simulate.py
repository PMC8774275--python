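"""Synthetic two-group expression + PPI benchmark with a planted module.

The generator emulates the statistical structure the subnetwork search
assumes: a small gene set that is (a) differentially expressed between
tumour and normal samples, (b) strongly co-expressed in normal tissue
but de-correlated in tumour (rewired co-expression), and (c) densely
interacting with high association scores, embedded in a null background.
Ground truth is returned so recovery can be scored exactly.

Co-expression of the planted module uses a single latent factor per
group: in normal samples every planted gene loads on a shared factor
with loading sqrt(r_high), giving pairwise correlation ~ r_high; in
tumour the loading drops to sqrt(r_high - corr_shift), so the default
corr_shift = r_high removes the co-expression entirely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .expression import ExpressionMatrix

Edge = tuple[str, str]

__all__ = ["SyntheticSpec", "generate", "make_fixture_suite"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-module benchmark generator.

    Defaults describe a clearly detectable but not degenerate instance:
    300 genes, 20 samples per group, a 30-gene module shifted by 2 log2
    units in tumour, normal-tissue co-expression r ~ 0.8 lost in tumour,
    a 0.6-dense high-score interaction module over a 0.02-dense
    background graph.
    """

    n_genes: int = 300
    n_normal: int = 20
    n_tumour: int = 20
    planted_size: int = 30
    lfc_effect: float = 2.0
    r_high: float = 0.8
    corr_shift: float = 0.8
    planted_density: float = 0.6
    background_density: float = 0.02
    score_high: tuple[float, float] = (0.7, 0.95)
    score_low: tuple[float, float] = (0.4, 0.7)
    noise_sd: float = 0.5
    base_mean_range: tuple[float, float] = (6.0, 10.0)
    require_connected: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.planted_size < self.n_genes:
            raise ValueError("planted_size must lie strictly between 0 and n_genes")
        for name in ("planted_density", "background_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.r_high <= 1.0:
            raise ValueError("r_high outside [0, 1]")
        if self.corr_shift < 0 or self.corr_shift > self.r_high:
            raise ValueError("corr_shift must lie in [0, r_high]")
        if self.n_normal < 3 or self.n_tumour < 3:
            raise ValueError("need >=3 samples per group")

    @classmethod
    def null(cls, **overrides) -> "SyntheticSpec":
        """Null instance: the 'planted' genes carry no signal of any kind."""
        defaults = dict(
            lfc_effect=0.0,
            r_high=0.0,
            corr_shift=0.0,
            planted_density=0.02,
            background_density=0.02,
            score_high=(0.4, 0.7),
            score_low=(0.4, 0.7),
            require_connected=False,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        return asdict(self)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _draw_expression(spec: SyntheticSpec, rng: np.random.Generator) -> ExpressionMatrix:
    genes = _gene_ids(spec.n_genes)
    n_samp = spec.n_normal + spec.n_tumour
    groups = ["normal"] * spec.n_normal + ["tumour"] * spec.n_tumour
    base = rng.uniform(*spec.base_mean_range, size=spec.n_genes)
    values = base[:, None] + spec.noise_sd * rng.standard_normal((spec.n_genes, n_samp))

    planted = slice(0, spec.planted_size)
    nor = slice(0, spec.n_normal)
    tum = slice(spec.n_normal, n_samp)
    r_nor, r_tum = spec.r_high, spec.r_high - spec.corr_shift
    # latent-factor co-expression: x = base + sd * (sqrt(r) f + sqrt(1-r) e)
    for cols, r in ((nor, r_nor), (tum, r_tum)):
        if r <= 0:
            continue
        width = cols.stop - cols.start
        factor = rng.standard_normal(width)
        eps = rng.standard_normal((spec.planted_size, width))
        values[planted, cols] = (
            base[planted, None]
            + spec.noise_sd * (np.sqrt(r) * factor[None, :] + np.sqrt(1.0 - r) * eps)
        )
    values[planted, tum] += spec.lfc_effect
    return ExpressionMatrix(genes, values, groups)


def _draw_ppi(spec: SyntheticSpec, rng: np.random.Generator) -> dict[Edge, float]:
    genes = _gene_ids(spec.n_genes)
    planted = set(genes[: spec.planted_size])
    edges: dict[Edge, float] = {}
    n = spec.n_genes
    for i in range(n):
        for j in range(i + 1, n):
            u, v = genes[i], genes[j]
            inside = u in planted and v in planted
            dens = spec.planted_density if inside else spec.background_density
            if rng.random() < dens:
                lo, hi = spec.score_high if inside else spec.score_low
                edges[(u, v)] = float(rng.uniform(lo, hi))
    return edges


def generate(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[ExpressionMatrix, dict[Edge, float], set[str]]:
    """Draw one benchmark instance: (expression, PPI edges, truth set).

    When ``spec.require_connected`` is set the planted module's induced
    PPI subgraph must come out connected; up to 20 redraws of the edge
    set are attempted before the spec is rejected as infeasible.
    ``seed`` overrides ``spec.seed``; the output is a deterministic
    function of (spec, seed).
    """
    use_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)
    expr = _draw_expression(spec, rng)
    truth = set(_gene_ids(spec.n_genes)[: spec.planted_size])
    for _ in range(20):
        edges = _draw_ppi(spec, rng)
        if not spec.require_connected:
            break
        sub = nx.Graph((u, v) for (u, v) in edges if u in truth and v in truth)
        if len(sub) == spec.planted_size and nx.is_connected(sub):
            break
    else:
        raise ValueError(
            "infeasible spec: planted module cannot be connected at "
            f"planted_density={spec.planted_density}"
        )
    return expr, edges, truth


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the two standard fixed-seed fixtures used by tests and docs.

    A 30-gene instance (seconds-scale smoke input) and a 300-gene
    instance (full default benchmark), each as expression TSV,
    sample-annotation TSV, PPI TSV and truth JSON.  Deterministic:
    the same seed yields byte-identical files.
    """
    from . import io as sio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    specs = {
        "small": SyntheticSpec(
            n_genes=30, n_normal=10, n_tumour=10, planted_size=8,
            background_density=0.08, seed=seed,
        ),
        "large": SyntheticSpec(seed=seed),
    }
    for label, spec in specs.items():
        expr, edges, truth = generate(spec)
        base = out / label
        base.mkdir(exist_ok=True)
        sio.write_expression(base / "expression.tsv", expr)
        sio.write_annotation(base / "annotation.tsv", expr)
        sio.write_ppi(base / "ppi.tsv", edges)
        truth_payload = {"planted": sorted(truth), "spec": spec.to_dict()}
        (base / "truth.json").write_text(json.dumps(truth_payload, indent=2, sort_keys=True))
        written[label] = base
    return written
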