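"""Term enrichment and functional-annotation clustering.

Enrichment of a query gene list against user-supplied gene sets (GMT) uses
the hypergeometric upper tail P[X >= k] and its conservative jackknifed
variant (the EASE score: the same tail with the overlap reduced by one, so
a single-gene overlap is never significant). Enriched terms are then
grouped by the agreement of their gene memberships, measured by Cohen's
kappa on the query-restricted membership matrix: terms with enough
high-kappa partners seed groups, and groups sharing enough members are
merged to a fixed point. Each cluster is scored by

    enrichment_score = -log10(geometric mean of member EASE p-values)

and kept when the score is >= 1.3, i.e. when the geometric-mean p-value is
at most 10**-1.3 ~ 0.05. Terms may belong to several clusters (the
clustering is fuzzy). No multiple-testing correction is applied beyond the
score filter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GeneSetCollection

KEEP_SCORE = 1.3


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def ease_p(k: int, K: int, n: int, N: int) -> float:
    """Jackknifed hypergeometric tail: overlap reduced by one."""
    return hypergeom_tail(max(k - 1, 0), K, n, N)


def enrich(query: set[str] | frozenset[str], sets: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric / EASE enrichment of a query gene set.

    Query genes outside the collection's universe are dropped with a
    warning. Terms with zero overlap are reported with p = 1. Results are
    sorted by EASE p-value.
    """
    universe = sets.universe
    query = frozenset(query)
    dropped = query - universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} query gene(s) absent from the background universe "
            f"were dropped (e.g. {sorted(dropped)[:3]})"
        )
        query = query & universe
    if not query:
        raise ValueError("query is empty after restriction to the universe")
    N, n = len(universe), len(query)
    rows = []
    for tid, (name, genes) in sets.terms.items():
        genes = genes & universe
        K = len(genes)
        k = len(genes & query)
        rows.append(
            {
                "term_id": tid,
                "term_name": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_hyper": hypergeom_tail(k, K, n, N),
                "p_ease": ease_p(k, K, n, N),
            }
        )
    out = pd.DataFrame(rows).set_index("term_id")
    return out.sort_values(["p_ease", "p_hyper"])


def cohen_kappa(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's kappa between two binary membership vectors."""
    t = len(x)
    if t == 0:
        return 0.0
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    d = t - a - b - c
    observed = (a + d) / t
    expected = ((a + b) * (a + c) + (c + d) * (b + d)) / (t * t)
    if expected == 1.0:
        return 1.0 if observed == 1.0 else 0.0
    return (observed - expected) / (1.0 - expected)


@dataclass
class TermCluster:
    members: tuple[str, ...]
    enrichment_score: float

    @property
    def kept(self) -> bool:
        return self.enrichment_score >= KEEP_SCORE


def enrichment_score(p_values: np.ndarray | list[float]) -> float:
    """-log10 geometric mean of a cluster's member p-values."""
    logs = np.log10(np.asarray(p_values, dtype=float))
    return float(-logs.mean())


def cluster_terms(
    results: pd.DataFrame,
    sets: GeneSetCollection,
    query: set[str] | frozenset[str] | None = None,
    kappa_threshold: float = 0.50,
    seed_size: int = 3,
    linkage: float = 0.50,
) -> list[TermCluster]:
    """Group enriched terms by membership agreement (kappa clustering).

    Parameters mirror a "medium" classification stringency: terms need at
    least ``seed_size`` partners at kappa >= ``kappa_threshold`` to seed a
    group, and groups sharing at least a ``linkage`` fraction of the smaller
    group's members merge until a fixed point. Terms seeding no group are
    reported as singleton clusters. The outcome is independent of the order
    of the input terms.

    Kappa is computed on the membership matrix restricted to ``query`` when
    given (how the terms agree on the genes actually under study), else to
    the union of the terms' members.
    """
    if results.empty:
        raise ValueError("no enrichment results to cluster")
    term_ids = sorted(results.index)
    if query is not None:
        gene_pool: set[str] = set(query)
    else:
        gene_pool = set()
        for tid in term_ids:
            gene_pool |= set(sets.members(tid))
    gene_list = sorted(gene_pool)
    membership = {
        tid: np.array([g in sets.members(tid) for g in gene_list], dtype=bool)
        for tid in term_ids
    }
    p_ease = results["p_ease"].to_dict()

    if len(term_ids) == 1:
        tid = term_ids[0]
        return [TermCluster((tid,), enrichment_score([p_ease[tid]]))]

    kappa = {
        (a, b): cohen_kappa(membership[a], membership[b])
        for i, a in enumerate(term_ids)
        for b in term_ids[i + 1 :]
    }

    def kap(a: str, b: str) -> float:
        return kappa[(a, b)] if (a, b) in kappa else kappa[(b, a)]

    # seed groups
    groups: set[frozenset[str]] = set()
    clustered: set[str] = set()
    for tid in term_ids:
        partners = [o for o in term_ids if o != tid and kap(tid, o) >= kappa_threshold]
        if len(partners) >= seed_size:
            groups.add(frozenset([tid, *partners]))

    # merge to fixed point, scanning pairs in canonical order so the result
    # does not depend on input order
    merged = True
    while merged:
        merged = False
        ordered = sorted(groups, key=lambda g: tuple(sorted(g)))
        for i, g1 in enumerate(ordered):
            for g2 in ordered[i + 1 :]:
                shared = len(g1 & g2)
                if shared and shared / min(len(g1), len(g2)) >= linkage:
                    groups.discard(g1)
                    groups.discard(g2)
                    groups.add(g1 | g2)
                    merged = True
                    break
            if merged:
                break

    clusters = []
    for g in sorted(groups, key=lambda g: tuple(sorted(g))):
        clustered |= g
        members = tuple(sorted(g))
        clusters.append(TermCluster(members, enrichment_score([p_ease[t] for t in members])))
    for tid in term_ids:
        if tid not in clustered:
            clusters.append(TermCluster((tid,), enrichment_score([p_ease[tid]])))
    clusters.sort(key=lambda c: (-c.enrichment_score, c.members))
    return clusters


def clusters_to_frame(clusters: list[TermCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster": np.arange(1, len(clusters) + 1),
            "enrichment_score": [c.enrichment_score for c in clusters],
            "kept": [c.kept for c in clusters],
            "n_terms": [len(c.members) for c in clusters],
            "members": [";".join(c.members) for c in clusters],
        }
    ).set_index("cluster")
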