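"""Differential-expression statistics for two-group expression matrices.

Computes per-gene pooled-variance two-sample t statistics, log2 fold
changes and Benjamini-Hochberg adjusted p-values, and filters gene lists
by the usual (adjusted p, |log2 FC|) thresholds.  The classical pooled t
is used rather than a moderated (empirical-Bayes) variant: downstream
node weights only require a t statistic, and the pooled form needs no
prior.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

NORMAL = "normal"
TUMOUR = "tumour"

__all__ = [
    "ExpressionMatrix",
    "GeneDEStats",
    "compute_de_stats",
    "filter_de_genes",
    "merge_de_lists",
    "de_stats_frame",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2-scale intensities with group labels.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per matrix row.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_groups))``.
    sample_groups
        Per-sample label, each ``"normal"`` or ``"tumour"``.
    """

    gene_ids: list[str]
    values: np.ndarray
    sample_groups: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_groups)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_groups)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicated gene ids: {dupes[:5]}")
        bad = set(self.sample_groups) - {NORMAL, TUMOUR}
        if bad:
            raise ValueError(f"unknown sample group labels: {sorted(bad)}")
        if NORMAL not in self.sample_groups or TUMOUR not in self.sample_groups:
            raise ValueError("both 'normal' and 'tumour' groups must be non-empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing/non-finite values")

    @property
    def normal_mask(self) -> np.ndarray:
        return np.array([g == NORMAL for g in self.sample_groups])

    @property
    def tumour_mask(self) -> np.ndarray:
        return np.array([g == TUMOUR for g in self.sample_groups])

    def subset(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Row-subset the matrix to ``gene_ids`` (in the given order)."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), self.values[rows], list(self.sample_groups))


@dataclass
class GeneDEStats:
    """Per-gene differential-expression record.

    ``log_fc`` is mean(tumour) - mean(normal) on the log2 scale.  A gene
    whose within-group variance is zero in both groups but whose means
    differ gets ``t_value = +/-inf`` and ``zero_variance=True``.
    """

    gene_id: str
    t_value: float
    log_fc: float
    p_value: float
    adj_p_value: float = field(default=float("nan"))
    zero_variance: bool = False


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Pooled-variance two-sample t of x (tumour) vs y (normal).

    Returns (t, p, zero_variance_flag).  A zero pooled variance with a
    zero mean difference is the degenerate identical-values case
    (t=0, p=1); with a non-zero difference t is signed infinity.
    """
    nx, ny = len(x), len(y)
    diff = x.mean() - y.mean()
    ssq = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    df = nx + ny - 2
    sp2 = ssq / df
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0, False
        return math.copysign(math.inf, diff), 0.0, True
    t = diff / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, p, False


def compute_de_stats(expr: ExpressionMatrix) -> list[GeneDEStats]:
    """Compute per-gene t, log2 FC, p and BH-adjusted p (tumour vs normal).

    Requires at least two samples in each group.  BH adjustment runs over
    all genes of the matrix.
    """
    nmask, tmask = expr.normal_mask, expr.tumour_mask
    if nmask.sum() < 2 or tmask.sum() < 2:
        raise ValueError(
            f"each group needs >=2 samples (normal={int(nmask.sum())}, "
            f"tumour={int(tmask.sum())})"
        )
    out: list[GeneDEStats] = []
    for i, gid in enumerate(expr.gene_ids):
        tum = expr.values[i, tmask]
        nor = expr.values[i, nmask]
        t, p, zv = _pooled_t(tum, nor)
        if zv:
            logger.warning("gene %s has zero within-group variance; t is infinite", gid)
        out.append(GeneDEStats(gid, t, float(tum.mean() - nor.mean()), p, zero_variance=zv))
    pvals = np.array([s.p_value for s in out])
    adj = multipletests(pvals, method="fdr_bh")[1]
    for s, a in zip(out, adj):
        s.adj_p_value = float(a)
    return out


def de_stats_frame(stats: list[GeneDEStats]) -> pd.DataFrame:
    """Tabulate DE records as a DataFrame indexed by gene id."""
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in stats],
            "log_fc": [s.log_fc for s in stats],
            "t": [s.t_value for s in stats],
            "p_value": [s.p_value for s in stats],
            "adj_p_value": [s.adj_p_value for s in stats],
        }
    ).set_index("gene_id", drop=False)


def filter_de_genes(
    stats: list[GeneDEStats], adj_p_cut: float, abs_lfc_cut: float
) -> list[str]:
    """Genes with adj_p < ``adj_p_cut`` and |log FC| >= ``abs_lfc_cut``.

    Ordered by |log FC| descending (stable).  An empty result is logged,
    not raised.
    """
    if adj_p_cut <= 0 or abs_lfc_cut < 0:
        raise ValueError("adj_p_cut must be positive and abs_lfc_cut non-negative")
    kept = [s for s in stats if s.adj_p_value < adj_p_cut and abs(s.log_fc) >= abs_lfc_cut]
    kept.sort(key=lambda s: -abs(s.log_fc))
    if not kept:
        logger.warning(
            "no genes pass adj_p<%g and |logFC|>=%g", adj_p_cut, abs_lfc_cut
        )
    return [s.gene_id for s in kept]


def merge_de_lists(
    list_a: list[GeneDEStats],
    list_b: list[GeneDEStats],
    strict_lfc_cut: float = 1.5,
) -> list[str]:
    """Merge DE results from two independent datasets.

    Returns the union of (genes present in both lists) with (genes whose
    |log FC| exceeds ``strict_lfc_cut`` in either list), the combining
    rule used when two cohorts of the same disease are analysed jointly.
    Order: intersection genes first (by max |log FC| desc), then the
    strict-cut extras (same key), duplicates removed.
    """
    a_ids = {s.gene_id for s in list_a}
    b_ids = {s.gene_id for s in list_b}
    lfc: dict[str, float] = {}
    for s in [*list_a, *list_b]:
        lfc[s.gene_id] = max(abs(s.log_fc), lfc.get(s.gene_id, 0.0))
    common = a_ids & b_ids
    strict = {g for g, v in lfc.items() if v > strict_lfc_cut}
    merged = common | strict
    return sorted(merged, key=lambda g: (-lfc[g], g))
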