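"""Differential expression by density-based pruning in (A, M) feature space.

Per gene, within one exposure group, two coordinates are computed from
log-expression: A, the mean over all of the group's pre and post samples
(average expression), and M, mean(post) - mean(pre) (average difference).
Genes without expression change sit in the dense core of this 2D cloud;
differentially expressed genes lie in its sparse boundary. The detector
makes that geometric idea concrete:

1. optionally standardize A and M to unit variance;
2. estimate each point's local density with a k-nearest-neighbour estimate
   density_i = k / (n * pi * r_k^2), r_k the distance to the k-th neighbour
   (k = ceil(sqrt(n)) by default);
3. points whose density exceeds the ``density_quantile`` quantile form the
   dense core; the remainder is the boundary;
4. a boundary point is called DE iff its |M| exceeds the
   ``effect_quantile`` quantile of |M| among core points, so boundary
   points that are merely extreme in average expression are not called.

The procedure is deterministic and p-value free; all constants are exposed
in :class:`DEParams`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .io import design_samples


@dataclass
class DEParams:
    """Tuning constants of the boundary detector."""

    knn_k: int | str = "auto"
    density_quantile: float = 0.05
    effect_quantile: float = 0.95
    standardize: bool = True

    def __post_init__(self) -> None:
        for name in ("density_quantile", "effect_quantile"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.knn_k != "auto" and (not isinstance(self.knn_k, int) or self.knn_k < 1):
            raise ValueError("knn_k must be 'auto' or a positive integer")


class VennSummary(NamedTuple):
    """Overlap partition of two DE gene sets."""

    n1_only: int
    common: int
    n2_only: int
    genes1_only: frozenset[str]
    genes_common: frozenset[str]
    genes2_only: frozenset[str]


def compute_feature_space(
    expr: pd.DataFrame, design: pd.DataFrame, group: str
) -> pd.DataFrame:
    """Per-gene (A, M) coordinates for one group.

    ``expr`` is a log2-expression matrix (genes x samples). A is the mean
    over the group's pre and post samples; M is mean(post) - mean(pre).
    Gene order follows the input.
    """
    sub = design[design["group"] == group]
    subjects = sub["subject_id"].unique()
    if len(subjects) < 2:
        raise ValueError(f"group {group!r} needs >= 2 subjects with paired samples")
    for subj in subjects:
        tps = set(sub.loc[sub["subject_id"] == subj, "timepoint"])
        if tps != {"pre", "post"}:
            raise ValueError(f"subject {subj!r} is not paired (timepoints {sorted(tps)})")
    pre = design_samples(design, group, "pre")
    post = design_samples(design, group, "post")
    x_pre = expr[pre].to_numpy(dtype=float)
    x_post = expr[post].to_numpy(dtype=float)
    a = np.concatenate([x_pre, x_post], axis=1).mean(axis=1)
    m = x_post.mean(axis=1) - x_pre.mean(axis=1)
    return pd.DataFrame({"A": a, "M": m}, index=expr.index)


def knn_density(points: np.ndarray, k: int) -> np.ndarray:
    """kNN density estimate k / (n * pi * r_k^2) per point (self excluded).

    Points with duplicates inside their k-neighbourhood (r_k = 0) get
    infinite density.
    """
    n = len(points)
    if k >= n:
        raise ValueError(f"knn_k={k} must be smaller than the number of points ({n})")
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=k + 1)  # first neighbour is the point itself
    r_k = dist[:, -1]
    with np.errstate(divide="ignore"):
        return k / (n * np.pi * r_k**2)


def detect_boundary_de(points: pd.DataFrame, params: DEParams | None = None) -> pd.DataFrame:
    """Call DE genes from (A, M) points by core/boundary density pruning.

    Returns the input table augmented with ``density``, ``score`` (a
    monotone density-plus-effect ranking useful for ROC analysis),
    ``direction`` and ``is_de``.
    """
    params = params or DEParams()
    n = len(points)
    if n < 50:
        raise ValueError("need >= 50 points for meaningful density estimation")
    k = int(np.ceil(np.sqrt(n))) if params.knn_k == "auto" else params.knn_k

    x = points[["A", "M"]].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("feature-space coordinates must be finite")
    if params.standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd

    density = knn_density(x, k)
    abs_m = np.abs(points["M"].to_numpy(dtype=float))

    out = points.copy()
    out["density"] = density
    # combined rank: large |M| and low density both push a gene towards DE
    out["score"] = (rankdata(abs_m) + rankdata(-density)) / (2.0 * n)
    out["direction"] = np.where(points["M"].to_numpy() > 0, "up", "down")

    if np.isinf(density).all():
        warnings.warn("all points coincide; no boundary exists, no DE called")
        out["is_de"] = False
        return out

    core = density > np.quantile(density, params.density_quantile)
    m_threshold = np.quantile(abs_m[core], params.effect_quantile)
    out["is_de"] = (~core) & (abs_m > m_threshold)
    return out


def compare_de_sets(set1: frozenset[str] | set[str], set2: frozenset[str] | set[str]) -> VennSummary:
    """Exact Venn partition of two DE gene sets over a shared universe."""
    s1, s2 = frozenset(set1), frozenset(set2)
    common = s1 & s2
    return VennSummary(
        n1_only=len(s1 - s2),
        common=len(common),
        n2_only=len(s2 - s1),
        genes1_only=s1 - s2,
        genes_common=common,
        genes2_only=s2 - s1,
    )


class DensityBoundaryDE:
    """Boundary-density DE model for one group of a paired design.

    Parameters
    ----------
    expr : DataFrame
        log2 expression, genes x samples.
    design : DataFrame
        sample design table (subject_id, group, timepoint; index = sample).
    group : str
        which group's pre/post contrast to analyse.

    Examples
    --------
    >>> model = DensityBoundaryDE(log_expr, design, group="AMS")
    >>> res = model.fit()
    >>> res.de_genes  # doctest: +SKIP
    """

    def __init__(self, expr: pd.DataFrame, design: pd.DataFrame, group: str):
        self.expr = expr
        self.design = design
        self.group = group
        self.feature_space = compute_feature_space(expr, design, group)

    def fit(self, params: DEParams | None = None) -> "DEResults":
        params = params or DEParams()
        table = detect_boundary_de(self.feature_space, params)
        return DEResults(model=self, params=params, table=table)


class DEResults:
    """DE calls for one group, with the per-gene feature-space table."""

    def __init__(self, model: DensityBoundaryDE, params: DEParams, table: pd.DataFrame):
        self.model = model
        self.params = params
        self.table = table

    @property
    def de_genes(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["is_de"]])

    @property
    def n_de(self) -> int:
        return int(self.table["is_de"].sum())

    def summary(self) -> str:
        t = self.table
        up = int(((t["direction"] == "up") & t["is_de"]).sum())
        down = self.n_de - up
        lines = [
            "Density-boundary differential expression",
            "========================================",
            f"group:            {self.model.group}",
            f"genes analysed:   {len(t)}",
            f"DE genes called:  {self.n_de} ({up} up, {down} down)",
            f"density quantile: {self.params.density_quantile}",
            f"effect quantile:  {self.params.effect_quantile}",
            f"kNN k:            {self.params.knn_k}",
        ]
        return "\n".join(lines)
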