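"""Disease-module detection by connectivity significance (DIAMOnD).

Starting from a set of seed proteins in an undirected interactome, the
algorithm grows a module one node at a time: at every iteration the
candidate with the most significant number of links to the current
module — measured by a hypergeometric tail probability — is absorbed.
A seed weight ``alpha`` (integer >= 1) makes links to seed nodes count
alpha-fold:

    N' = N + (alpha - 1) * s0      s0' = alpha * s0
    k' = k + (alpha - 1) * ks      ks' = alpha * ks

    p  = sum_{i = ks'}^{min(k', s0')} C(s0', i) C(N' - s0', k' - i) / C(N', k')

where N is the interactome size, s0 the current module size, k the
candidate's degree and ks its links into the module. Binomial
coefficients are evaluated in log space (gammaln) so genome-scale
interactomes do not overflow.

Parameter selection follows a grid search over module size n and alpha,
scoring each candidate module by the hypergeometric overlap p against an
independently derived biological-validation gene list; the lowest
validation p wins, ties resolved by parsimony (smaller n, then smaller
alpha).

Deterministic tie-breaking during expansion (larger ks, then larger
degree, then lexicographic node id) makes module construction exactly
reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

log = logging.getLogger(__name__)


@dataclass
class ConnectivitySignificance:
    """Weighted hypergeometric tail for one candidate node."""

    N: int
    s0: int
    k: int
    ks: int
    alpha: int
    p: float

    def __post_init__(self) -> None:
        if self.ks > self.k:
            raise ValueError("ks cannot exceed k")
        if self.s0 > self.N:
            raise ValueError("module cannot exceed the graph")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must lie in (0, 1]")


@dataclass
class DiamondModule:
    seeds: list[str]
    added: list[tuple[str, float, int]]  # (node, p at addition, iteration)
    n_requested: int
    alpha: int
    validation_p: float | None = None
    exhausted: bool = False  # candidate pool ran out before n_requested

    @property
    def added_nodes(self) -> list[str]:
        return [node for node, _, _ in self.added]

    @property
    def nodes(self) -> list[str]:
        return list(self.seeds) + self.added_nodes

    def prefix(self, n: int) -> "DiamondModule":
        """The nested module after only the first n additions."""
        return DiamondModule(seeds=list(self.seeds), added=self.added[:n],
                             n_requested=n, alpha=self.alpha,
                             exhausted=self.exhausted and len(self.added) < n)

    def hub_ranking(self, graph: nx.Graph) -> pd.DataFrame:
        """Module nodes ranked by degree within the induced subgraph."""
        sub = graph.subgraph(self.nodes)
        rows = [(n, sub.degree(n), "seed" if n in set(self.seeds) else "added")
                for n in self.nodes]
        frame = pd.DataFrame(rows, columns=["node", "module_degree", "origin"])
        return frame.sort_values(["module_degree", "node"],
                                 ascending=[False, True]).reset_index(drop=True)


def _log_binom(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def hypergeom_tail(N: int, K: int, n: int, k_min: int) -> float:
    """P(X >= k_min) for X ~ Hypergeometric(N, K, n), exact, in log space."""
    upper = min(n, K)
    if k_min <= 0:
        return 1.0
    if k_min > upper:
        return 0.0
    i = np.arange(k_min, upper + 1)
    log_terms = (_log_binom(K, i) + _log_binom(N - K, n - i)
                 - _log_binom(N, n))
    m = log_terms.max()
    return float(min(1.0, math.exp(m) * np.exp(log_terms - m).sum()))


def _weighted_tail(N: int, s0: int, k: int, ks: int, alpha: int,
                   exact: bool = False):
    Nw = N + (alpha - 1) * s0
    s0w = alpha * s0
    kw = k + (alpha - 1) * ks
    ksw = alpha * ks
    if exact:
        return _exact_tail(Nw, s0w, kw, ksw)
    return hypergeom_tail(Nw, s0w, kw, ksw)


def _exact_tail(N: int, K: int, n: int, k_min: int) -> Fraction:
    """Rational-arithmetic tail for small problems, so candidate ordering
    has no floating-point ambiguity."""
    upper = min(n, K)
    if k_min <= 0:
        return Fraction(1)
    if k_min > upper:
        return Fraction(0)
    total = sum(math.comb(K, i) * math.comb(N - K, n - i)
                for i in range(k_min, upper + 1))
    return min(Fraction(total, math.comb(N, n)), Fraction(1))


def connectivity_pvalue(
    graph: nx.Graph, module: set[str], candidate, alpha: int = 1
) -> ConnectivitySignificance:
    """Connectivity significance of `candidate` against `module`.

    An isolated candidate (degree 0) gets p = 1 by convention.
    """
    if candidate in module:
        raise ValueError("candidate is already in the module")
    if candidate not in graph:
        raise ValueError(f"candidate {candidate!r} not in graph")
    if alpha < 1 or int(alpha) != alpha:
        raise ValueError("alpha must be an integer >= 1")
    N = graph.number_of_nodes()
    s0 = len(module)
    k = graph.degree(candidate)
    ks = sum(1 for nb in graph.neighbors(candidate) if nb in module)
    if k == 0:
        log.debug("isolated candidate %r: p = 1 by convention", candidate)
        p = 1.0
    else:
        p = max(_weighted_tail(N, s0, k, ks, int(alpha)), 5e-324)
    return ConnectivitySignificance(N=N, s0=s0, k=k, ks=ks,
                                    alpha=int(alpha), p=min(p, 1.0))


def run_diamond(
    graph: nx.Graph, seeds: set[str], n_iter: int, alpha: int = 1
) -> DiamondModule:
    """Greedy module expansion by smallest connectivity p-value.

    Ties break on larger ks, then larger degree, then lexicographic node
    id, so the output is fully deterministic. Candidates are restricted
    to nodes with at least one link to the module (any ks = 0 node has
    p = 1 and cannot win). If the frontier empties early, the partial
    module is returned with ``exhausted=True``.
    """
    seeds = set(seeds)
    absent = sorted((s for s in seeds if s not in graph), key=str)
    if absent:
        raise ValueError(f"seeds not in graph: {absent[:5]}")
    seeds = sorted(seeds, key=str)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if alpha < 1 or int(alpha) != alpha:
        raise ValueError("alpha must be an integer >= 1")
    alpha = int(alpha)
    N = graph.number_of_nodes()
    module = set(seeds)
    # frontier: node -> number of links into the module
    ks: dict = {}
    for s in seeds:
        for nb in graph.neighbors(s):
            if nb not in module:
                ks[nb] = ks.get(nb, 0) + 1

    added: list[tuple[str, float, int]] = []
    exhausted = False
    # exact rational tails on small problems remove any risk of a
    # floating-point near-tie reordering the greedy choice
    exact = N + (alpha - 1) * (len(module) + n_iter) <= 400
    cache: dict = {}
    for it in range(1, n_iter + 1):
        if not ks:
            exhausted = True
            break
        s0 = len(module)
        best = None
        for node in ks:
            key = (graph.degree(node), ks[node], s0)
            p = cache.get(key)
            if p is None:
                p = _weighted_tail(N, s0, key[0], key[1], alpha, exact=exact)
                cache[key] = p
            cand = (p, -key[1], -key[0], str(node), node)
            if best is None or cand < best:
                best = cand
        p_best, _, _, _, node = best
        module.add(node)
        del ks[node]
        for nb in graph.neighbors(node):
            if nb not in module:
                ks[nb] = ks.get(nb, 0) + 1
        added.append((node, float(max(p_best, 5e-324)), it))
    if len(added) < n_iter and not exhausted:
        exhausted = not ks
    if exhausted:
        log.warning("candidate frontier exhausted after %d of %d iterations",
                    len(added), n_iter)
    return DiamondModule(seeds=list(seeds), added=added, n_requested=n_iter,
                         alpha=alpha, exhausted=exhausted)


def biological_validation_pvalue(
    module: DiamondModule, validation_genes: set[str], background: set[str]
) -> float:
    """Hypergeometric overlap p between the module and a validation list."""
    if not validation_genes:
        raise ValueError("empty validation gene set")
    background = set(background)
    stray = set(validation_genes) - background
    if stray:
        raise ValueError(
            f"validation genes outside background: {sorted(stray)[:5]}")
    nodes = set(module.nodes) & background
    overlap = len(nodes & set(validation_genes))
    return hypergeom_tail(len(background), len(set(validation_genes)),
                          len(nodes), overlap) if nodes else 1.0


def grid_search(
    graph: nx.Graph,
    seeds: set[str],
    n_grid: list[int],
    alpha_grid: list[int],
    validation_genes: set[str],
    background: set[str],
) -> tuple[DiamondModule, pd.DataFrame]:
    """Select (module size, alpha) minimizing the biological-validation p.

    For each alpha, DIAMOnD runs once to max(n_grid); the module at any
    smaller n is its prefix (greedy nestedness). Ties in validation p
    prefer the smaller n (parsimony), then the smaller alpha.
    """
    if not n_grid or not alpha_grid:
        raise ValueError("grids must be non-empty")
    n_grid = sorted(set(int(n) for n in n_grid))
    alpha_grid = sorted(set(int(a) for a in alpha_grid))
    rows = []
    best: tuple | None = None
    for alpha in alpha_grid:
        full = run_diamond(graph, seeds, max(n_grid), alpha)
        for n in n_grid:
            mod = full.prefix(n)
            p = biological_validation_pvalue(mod, validation_genes, background)
            mod.validation_p = p
            rows.append({"n": n, "alpha": alpha, "validation_p": p,
                         "module_size": len(mod.nodes)})
            cand = (p, n, alpha, mod)
            if best is None or cand[:3] < best[:3]:
                best = cand
    table = pd.DataFrame(rows, columns=["n", "alpha", "validation_p",
                                        "module_size"])
    return best[3], table


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_module(module: DiamondModule, path: str | Path) -> None:
    rows = [(s, "seed", 0, math.nan) for s in module.seeds]
    rows += [(n, "added", it, p) for n, p, it in module.added]
    pd.DataFrame(rows, columns=["node", "origin", "iteration",
                                "p_at_addition"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


__all__ = [
    "ConnectivitySignificance",
    "DiamondModule",
    "hypergeom_tail",
    "connectivity_pvalue",
    "run_diamond",
    "biological_validation_pvalue",
    "grid_search",
    "write_module",
]
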