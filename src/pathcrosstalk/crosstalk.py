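"""Pathway cross-talk scoring by random walk with restart (RWR).

For each ordered pair of risk pathways, the candidate genes of one are the
information sources and those of the other the targets. A random walk with
restart is run on the PPI largest connected component,

    P_{t+1} = (1 - r) A P_t + r P0,

with A the column-normalized adjacency (column sums 1), P0 uniform over the
mapped source genes and r the restart probability. The cross-talk strength
is the mean steady-state probability over the target genes; the symmetric
score of an unordered pair is the mean of the two directions.

Significance comes from an empirical null: the PPI is rewired by degree-
preserving double edge swaps (one rewired network per permutation index,
shared by all pairs), all pair scores are recomputed on each rewired
network, and the empirical p-value (b+1)/(N+1) is BH-adjusted jointly
across pairs. Pairs below the FDR cut form the undirected pathway
cross-talk network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import sparse

from .io_formats import PpiNetwork
from .stats import bh_adjust, permutation_pvalue

logger = logging.getLogger(__name__)

__all__ = [
    "RwrParams",
    "CrosstalkResult",
    "column_normalize",
    "rwr",
    "crosstalk_score",
    "degree_preserving_rewire",
    "permutation_pvalue",
    "score_pathway_pairs",
    "crosstalk_significance",
    "build_crosstalk_network",
]

# dense linear algebra beats sparse overhead below this node count
_DENSE_LIMIT = 300


@dataclass
class RwrParams:
    """Random-walk and permutation-null parameters.

    ``r`` is the restart probability (default 0.7, the standard choice in
    RWR gene-prioritization work); convergence is declared when the L1
    change falls below ``tol``.
    """

    r: float = 0.7
    tol: float = 1e-10
    max_iter: int = 1000
    n_permutations: int = 1000
    fdr_cut: float = 0.05
    seed: int = 0
    raw_empirical_p: bool = False
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.r <= 1):
            raise ValueError("restart probability r must lie in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class CrosstalkResult:
    """One scored pathway pair with its permutation null."""

    pathway_a: str
    pathway_b: str
    score_ab: float
    score_ba: float
    score: float
    n_source_in_net: int
    n_target_in_net: int
    null_scores: np.ndarray | None = None
    p_value: float | None = None
    fdr: float | None = None


# ---------------------------------------------------------------------------
# transition structure


def column_normalize(net: PpiNetwork):
    """Column-stochastic transition matrix of the network.

    Returns ``(A, nodes)`` where ``A[i, j] = 1/degree(j)`` for neighbors,
    ``nodes`` fixing the row/column order. Isolated nodes are an error
    (their column cannot be normalized).
    """
    g = net.graph
    nodes = sorted(g.nodes)
    degs = np.array([g.degree(n) for n in nodes], dtype=float)
    if (degs == 0).any():
        isolated = nodes[int(np.argmin(degs))]
        raise ValueError(f"cannot column-normalize: isolated node {isolated!r}")
    A = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csr", dtype=float)
    A = A @ sparse.diags(1.0 / degs)
    if len(nodes) <= _DENSE_LIMIT:
        A = A.toarray()
    return A, nodes


def _rwr_solve(A, P0: np.ndarray, params: RwrParams) -> np.ndarray:
    """Iterate the RWR recursion to its fixed point; P0 may have many columns."""
    r = params.r
    if r == 1.0:
        return P0.copy()
    P = P0.copy()
    for _ in range(params.max_iter):
        P_next = (1.0 - r) * (A @ P) + r * P0
        resid = np.abs(P_next - P).sum(axis=0).max()
        P = P_next
        if resid < params.tol:
            return P
    raise RuntimeError(
        f"RWR did not converge in {params.max_iter} iterations (L1 residual {resid:.3g})"
    )


def _source_distribution(nodes: list, index: dict, sources, label: str = "source set") -> np.ndarray:
    mapped = [index[s] for s in sources if s in index]
    n_drop = len(set(sources)) - len(mapped)
    if n_drop:
        logger.info("%s: %d gene(s) not in the network, dropped", label, n_drop)
    if not mapped:
        raise ValueError(f"no gene of {label} maps into the network")
    P0 = np.zeros(len(nodes))
    P0[mapped] = 1.0 / len(mapped)
    return P0


def rwr(net: PpiNetwork, sources, params: RwrParams | None = None) -> pd.Series:
    """Steady-state RWR probability over all network nodes.

    ``P0`` is uniform over the source genes that map into the network
    (missing ones are dropped with a log line; an empty mapping is an
    error). The returned vector is nonnegative and sums to 1.
    """
    params = params or RwrParams()
    A, nodes = column_normalize(net)
    index = {n: i for i, n in enumerate(nodes)}
    P0 = _source_distribution(nodes, index, sources)
    P = _rwr_solve(A, P0, params)
    return pd.Series(P, index=nodes)


def crosstalk_score(net: PpiNetwork, sources, targets, params: RwrParams | None = None) -> CrosstalkResult:
    """Directional and symmetric cross-talk scores for one pathway pair.

    ``score_ab`` is the mean steady-state probability over the mapped
    target genes when ``sources`` seed the walk; ``score_ba`` swaps the
    roles; ``score`` is their mean.
    """
    params = params or RwrParams()
    A, nodes = column_normalize(net)
    index = {n: i for i, n in enumerate(nodes)}
    Pa0 = _source_distribution(nodes, index, sources, "sources")
    Pb0 = _source_distribution(nodes, index, targets, "targets")
    P = _rwr_solve(A, np.column_stack([Pa0, Pb0]), params)
    ia = np.flatnonzero(Pa0)
    ib = np.flatnonzero(Pb0)
    score_ab = float(P[ib, 0].mean())
    score_ba = float(P[ia, 1].mean())
    return CrosstalkResult(
        pathway_a="a", pathway_b="b",
        score_ab=score_ab, score_ba=score_ba,
        score=(score_ab + score_ba) / 2.0,
        n_source_in_net=len(ia), n_target_in_net=len(ib),
    )


# ---------------------------------------------------------------------------
# degree-preserving null


def _rewire_edge_arrays(eu: list, ev: list, n_nodes: int, rng: np.random.Generator,
                        n_attempts: int) -> None:
    """In-place double edge swaps on canonical (u < v) edge lists.

    Swaps creating self-loops or duplicate edges are rejected, so the
    per-node degree vector is preserved exactly and the graph stays simple.
    """
    m = len(eu)
    eset = {u * n_nodes + v for u, v in zip(eu, ev)}
    ii = rng.integers(0, m, size=n_attempts).tolist()
    jj = rng.integers(0, m, size=n_attempts).tolist()
    ff = rng.integers(0, 2, size=n_attempts).tolist()
    for i, j, f in zip(ii, jj, ff):
        if i == j:
            continue
        a, b = eu[i], ev[i]
        c, d = eu[j], ev[j]
        if f:
            c, d = d, c
        # propose (a,b),(c,d) -> (a,c),(b,d)
        if a == c or b == d:
            continue
        p, q = (a, c) if a < c else (c, a)
        r, s = (b, d) if b < d else (d, b)
        k1 = p * n_nodes + q
        k2 = r * n_nodes + s
        if k1 == k2 or k1 in eset or k2 in eset:
            continue
        eset.remove(a * n_nodes + b)
        eset.remove(c * n_nodes + d if c < d else d * n_nodes + c)
        eset.add(k1)
        eset.add(k2)
        eu[i], ev[i] = p, q
        eu[j], ev[j] = r, s


def degree_preserving_rewire(net: PpiNetwork, params: RwrParams,
                             permutation_index: int = 0) -> PpiNetwork:
    """One degree-preserving randomization of the network.

    Runs a double-edge-swap Markov chain for ``10 * |edges|`` attempted
    swaps, seeded deterministically by ``(params.seed, permutation_index)``.
    Graphs with fewer than 2 edges are returned unchanged (warning).
    """
    g = net.graph
    if g.number_of_edges() < 2:
        logger.warning("network has < 2 edges; rewiring is a no-op")
        return PpiNetwork(graph=g.copy(), provenance=net.provenance)
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    eu, ev = [], []
    for u, v in g.edges:
        iu, iv = index[u], index[v]
        if iu > iv:
            iu, iv = iv, iu
        eu.append(iu)
        ev.append(iv)
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), int(permutation_index)]))
    _rewire_edge_arrays(eu, ev, len(nodes), rng, 10 * len(eu))
    out = nx.Graph()
    out.add_nodes_from(nodes)
    out.add_edges_from((nodes[u], nodes[v]) for u, v in zip(eu, ev))
    return PpiNetwork(graph=out, provenance=net.provenance)


# ---------------------------------------------------------------------------
# all-pairs scoring


def _pair_scores_on_net(graph: nx.Graph, source_sets: dict[str, set],
                        params: RwrParams) -> pd.DataFrame:
    """Directional + symmetric scores for every unordered pathway pair.

    One batched RWR solve (one column per pathway-as-source) serves all
    pairs on this network.
    """
    net = PpiNetwork(graph=graph)
    A, nodes = column_normalize(net)
    index = {n: i for i, n in enumerate(nodes)}
    ids = sorted(source_sets)
    P0 = np.column_stack([
        _source_distribution(nodes, index, source_sets[pid], f"pathway {pid}") for pid in ids
    ])
    P = _rwr_solve(A, P0, params)
    target_idx = {pid: np.flatnonzero(P0[:, k]) for k, pid in enumerate(ids)}
    rows = []
    for i, pa in enumerate(ids):
        for pb in ids[i + 1:]:
            s_ab = float(P[target_idx[pb], i].mean())
            s_ba = float(P[target_idx[pa], ids.index(pb)].mean())
            rows.append((pa, pb, s_ab, s_ba, (s_ab + s_ba) / 2.0,
                         len(target_idx[pa]), len(target_idx[pb])))
    return pd.DataFrame(
        rows,
        columns=["pathway_a", "pathway_b", "score_ab", "score_ba", "score",
                 "n_source_in_net", "n_target_in_net"],
    )


def score_pathway_pairs(net: PpiNetwork, source_sets: dict[str, set],
                        params: RwrParams | None = None) -> pd.DataFrame:
    """Score all C(n, 2) unordered pairs of pathways on the observed network."""
    params = params or RwrParams()
    if len(source_sets) < 2:
        raise ValueError("need at least two pathways to score pairs")
    return _pair_scores_on_net(net.graph, source_sets, params)


def _null_scores_for_index(net: PpiNetwork, source_sets: dict[str, set],
                           params: RwrParams, k: int) -> np.ndarray:
    rewired = degree_preserving_rewire(net, params, permutation_index=k)
    return _pair_scores_on_net(rewired.graph, source_sets, params)["score"].to_numpy()


def crosstalk_significance(net: PpiNetwork, source_sets: dict[str, set],
                           params: RwrParams | None = None,
                           return_null: bool = False):
    """Observed scores plus permutation p-values and joint BH FDR.

    One rewired network per permutation index is shared by all pairs; the
    empirical p-value of each pair compares its observed symmetric score
    with its own null scores. Results are independent of ``n_jobs``.
    """
    params = params or RwrParams()
    obs = score_pathway_pairs(net, source_sets, params)
    n_perm = params.n_permutations
    if params.n_jobs != 1:
        cols = Parallel(n_jobs=params.n_jobs)(
            delayed(_null_scores_for_index)(net, source_sets, params, k)
            for k in range(n_perm)
        )
    else:
        cols = [_null_scores_for_index(net, source_sets, params, k) for k in range(n_perm)]
    null = np.array(cols)          # (n_perm, n_pairs)
    pvals = np.array([
        permutation_pvalue(obs["score"].iloc[j], null[:, j], raw=params.raw_empirical_p)
        for j in range(len(obs))
    ])
    obs = obs.assign(p=pvals, fdr=bh_adjust(pvals))
    obs = obs.sort_values(["fdr", "p", "pathway_a", "pathway_b"]).reset_index(drop=True)
    if return_null:
        return obs, null
    return obs


def build_crosstalk_network(results: pd.DataFrame, params: RwrParams | None = None) -> nx.Graph:
    """Assemble the undirected cross-talk network of significant pairs.

    Nodes are risk subpathways appearing in >= 1 surviving pair; edges
    carry ``score``, ``p`` and ``fdr`` attributes. Empty networks are
    allowed.
    """
    params = params or RwrParams()
    g = nx.Graph()
    sig = results[results["fdr"] < params.fdr_cut]
    for row in sig.itertuples(index=False):
        g.add_edge(row.pathway_a, row.pathway_b,
                   score=float(row.score), p=float(row.p), fdr=float(row.fdr))
    return g
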