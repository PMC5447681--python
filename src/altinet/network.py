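"""Per-group co-expression networks and differential connectivity.

A group's network is built from its expression matrix in three steps:

* adjacency  a_ij = |cor(x_i, x_j)|**beta  (unsigned soft threshold,
  default beta = 6; beta = 1 gives a raw-correlation network);
* topological overlap   t_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)
  with l_ij = sum_u a_iu a_uj over u != i, j and k_i the adjacency row sum,
  which upweights gene pairs that share neighbours;
* connectivity  k_i = sum_{j != i} t_ij, the sum of a gene's connection
  strengths with all other genes, max-normalized within each network so
  that connectivities are comparable across networks of different overall
  density.

Differential connectivity between two groups is the per-gene difference of
connectivities (adjacency-based by default, TOM-based optional — see
:class:`DifferentialConnectivity`), tested by permutation: samples are
pooled and randomly re-split into groups of the original sizes, the
difference recomputed each time, and the two-sided permutation p-value
Benjamini–Hochberg corrected across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass
class AdjacencyMatrix:
    gene_ids: list[str]
    a: np.ndarray
    beta: float

    def __post_init__(self) -> None:
        if self.a.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValueError("adjacency shape does not match gene ids")
        if not np.allclose(self.a, self.a.T):
            raise ValueError("adjacency must be symmetric")
        if (self.a < -1e-12).any() or (self.a > 1 + 1e-12).any():
            raise ValueError("adjacency entries must lie in [0, 1]")


@dataclass
class TOMatrix:
    gene_ids: list[str]
    t: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.t, self.t.T):
            raise ValueError("TOM must be symmetric")


def adjacency(expr: pd.DataFrame, beta: float = 6.0) -> AdjacencyMatrix:
    """Unsigned power adjacency |cor|^beta from a genes x samples matrix.

    Zero-variance genes (correlation undefined) are excluded with a warning.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if expr.shape[1] < 4:
        raise ValueError("need >= 4 samples to estimate correlations")
    x = expr.to_numpy(dtype=float)
    variances = x.var(axis=1)
    keep = variances > 0
    if not keep.all():
        dropped = list(expr.index[~keep][:5])
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance gene(s), e.g. {dropped}")
        x = x[keep]
    genes = list(expr.index[keep])
    c = np.corrcoef(x)
    a = np.abs(c) ** beta
    np.fill_diagonal(a, 0.0)
    a = np.clip(a, 0.0, 1.0)
    return AdjacencyMatrix(gene_ids=genes, a=a, beta=beta)


def tom(adj: AdjacencyMatrix) -> TOMatrix:
    """Topological overlap matrix of an adjacency matrix (unit diagonal)."""
    a = adj.a
    l = a @ a  # zero diagonal of a makes the u = i, j terms vanish
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore"):
        t = (l + a) / denom
    np.fill_diagonal(t, 1.0)
    return TOMatrix(gene_ids=adj.gene_ids, t=t)


def connectivity(net: TOMatrix | AdjacencyMatrix) -> pd.DataFrame:
    """Per-gene connectivity k_i = sum of off-diagonal strengths, plus the
    max-normalized version (zero when the network is empty)."""
    if isinstance(net, TOMatrix):
        m, genes = net.t, net.gene_ids
        k = m.sum(axis=1) - np.diag(m)
    else:
        m, genes = net.a, net.gene_ids
        k = m.sum(axis=1)
    kmax = k.max() if len(k) else 0.0
    norm = k / kmax if kmax > 0 else np.zeros_like(k)
    return pd.DataFrame({"k": k, "normalized_k": norm}, index=pd.Index(genes, name="gene_id"))


def _connectivity_from_samples(
    x: np.ndarray, beta: float, statistic: str, normalize: bool
) -> np.ndarray:
    """Per-gene connectivity straight from a genes x samples array.

    ``statistic`` selects the network the row sums are taken over:
    ``"adjacency"`` (sum of |cor|^beta) or ``"tom"`` (sum of topological
    overlaps). Optionally max-normalized within the network.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    c = np.nan_to_num(c, nan=0.0)
    a = np.abs(c) ** beta
    np.fill_diagonal(a, 0.0)
    if statistic == "adjacency":
        kt = a.sum(axis=1)
    else:
        l = a @ a
        k = a.sum(axis=1)
        denom = np.minimum.outer(k, k) + 1.0 - a
        t = (l + a) / denom
        np.fill_diagonal(t, 0.0)
        kt = t.sum(axis=1)
    if not normalize:
        return kt
    kmax = kt.max()
    return kt / kmax if kmax > 0 else np.zeros_like(kt)


class DifferentialConnectivity:
    """Cross-group differential gene connectivity model.

    Parameters
    ----------
    expr1, expr2 : DataFrame
        Expression matrices (genes x samples) for the two groups, over the
        same genes — typically the post-exposure samples of each group.
    beta : float
        Soft-threshold exponent of the underlying adjacency.
    statistic : {"adjacency", "tom"}
        Network whose connectivity is differenced. The default,
        ``"adjacency"``, is the specific choice: TOM connectivity of a gene
        rises whenever its *neighbours* gain a module (the shared-neighbour
        term counts correlated neighbours even when the gene's own edges are
        noise-level), so a TOM-based test flags genes adjacent to a
        differential module along with its members. Adjacency connectivity
        changes only through a gene's own edges.
    normalize : bool
        Max-normalize connectivities within each network before differencing.
        Off by default: normalization ties every gene's statistic to the
        network's single most-connected gene, so a strong module in one group
        shifts the difference of *every* gene and destroys per-gene
        specificity. Turn on to compare networks of very different overall
        density at the cost of that coupling.
    """

    def __init__(
        self,
        expr1: pd.DataFrame,
        expr2: pd.DataFrame,
        beta: float = 6.0,
        statistic: str = "adjacency",
        normalize: bool = False,
    ):
        if statistic not in ("adjacency", "tom"):
            raise ValueError("statistic must be 'adjacency' or 'tom'")
        if list(expr1.index) != list(expr2.index):
            raise ValueError("the two groups must cover the same gene set, same order")
        if expr1.shape[1] < 4 or expr2.shape[1] < 4:
            raise ValueError("need >= 4 samples per group")
        self.expr1 = expr1
        self.expr2 = expr2
        self.beta = beta
        self.statistic = statistic
        self.normalize = normalize
        self.gene_ids = list(expr1.index)

    def fit(
        self, n_perm: int = 1000, seed: int | None = None, alpha: float = 0.05
    ) -> "DifferentialConnectivityResults":
        """Permutation test of per-gene connectivity differences.

        The null re-splits the pooled samples into the two original group
        sizes ``n_perm`` times; the two-sided p-value per gene is
        ``(1 + #{|diff*| >= |diff|}) / (n_perm + 1)``, BH-corrected across
        genes; ``significant`` flags q <= alpha.
        """
        if n_perm < 20:
            raise ValueError("n_perm < 20 gives too coarse a null")
        rng = np.random.default_rng(seed)
        x1 = self.expr1.to_numpy(dtype=float)
        x2 = self.expr2.to_numpy(dtype=float)
        n1 = x1.shape[1]
        pooled = np.hstack([x1, x2])
        n_total = pooled.shape[1]

        args = (self.beta, self.statistic, self.normalize)
        k1 = _connectivity_from_samples(x1, *args)
        k2 = _connectivity_from_samples(x2, *args)
        observed = k1 - k2

        exceed = np.zeros(len(self.gene_ids), dtype=int)
        for _ in range(n_perm):
            idx = rng.permutation(n_total)
            p1 = _connectivity_from_samples(pooled[:, idx[:n1]], *args)
            p2 = _connectivity_from_samples(pooled[:, idx[n1:]], *args)
            exceed += np.abs(p1 - p2) >= np.abs(observed)
        perm_p = (1.0 + exceed) / (n_perm + 1.0)
        _, q, _, _ = multipletests(perm_p, method="fdr_bh")

        table = pd.DataFrame(
            {
                "k_group1": k1,
                "k_group2": k2,
                "diff": observed,
                "perm_p": perm_p,
                "q": q,
                "significant": q <= alpha,
            },
            index=pd.Index(self.gene_ids, name="gene_id"),
        )
        return DifferentialConnectivityResults(self, table, n_perm=n_perm, alpha=alpha)


class DifferentialConnectivityResults:
    def __init__(
        self,
        model: DifferentialConnectivity,
        table: pd.DataFrame,
        n_perm: int,
        alpha: float,
    ):
        self.model = model
        self.table = table
        self.n_perm = n_perm
        self.alpha = alpha

    @property
    def significant_genes(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["significant"]])

    def summary(self) -> str:
        t = self.table
        lines = [
            "Differential gene connectivity (permutation test)",
            "=================================================",
            f"genes:               {len(t)}",
            f"samples (g1, g2):    {self.model.expr1.shape[1]}, {self.model.expr2.shape[1]}",
            f"beta:                {self.model.beta}",
            f"statistic:           {self.model.statistic} connectivity",
            f"permutations:        {self.n_perm}",
            f"significant (BH {self.alpha:g}): {len(self.significant_genes)}",
            f"largest |diff|:      {t['diff'].abs().max():.4f}",
        ]
        return "\n".join(lines)


def export_edges(net: TOMatrix, threshold: float, path: str | Path) -> int:
    """Write a VisANT-compatible three-column edge list of t_ij >= threshold.

    Each undirected edge is written once, gene pair in lexicographic order.
    Returns the number of edges written.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    genes = net.gene_ids
    n_written = 0
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                w = net.t[i, j]
                if w >= threshold:
                    ga, gb = sorted((genes[i], genes[j]))
                    fh.write(f"{ga}\t{gb}\t{w:.10g}\n")
                    n_written += 1
    return n_written
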