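"""Candidate-dense subpathway location and enrichment.

Within each pathway graph, candidate genes closer than a shortest-path
radius ``n`` are merged together with the genes lying on their shortest
paths; each connected component of the induced subgraph with at least
``s`` members is a subpathway. Subpathways are scored by the upper-tail
hypergeometric probability of their candidate content against a common
background and BH-adjusted jointly; survivors at FDR < 0.05 are the
"risk pathways" passed to the cross-talk stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .io_formats import PathwayGraph
from .stats import bh_adjust, hypergeom_upper_tail

logger = logging.getLogger(__name__)

__all__ = [
    "SubpathwayParams",
    "Subpathway",
    "locate_subpathways",
    "hypergeometric_enrichment",
    "score_subpathways",
    "call_risk_pathways",
]


@dataclass
class SubpathwayParams:
    """Subpathway location and enrichment parameters.

    ``n`` is the shortest-path merge radius and ``s`` the minimum
    subgraph size (both default 5). ``strategy`` selects how genes are
    merged around candidates: ``"shortest_paths"`` takes the union of all
    shortest paths between candidate pairs at distance <= n;
    ``"radius"`` takes every gene within distance n of any candidate.
    ``strict`` replaces the distance condition <= n by < n.
    """

    n: int = 5
    s: int = 5
    fdr_cut: float = 0.05
    strategy: str = "shortest_paths"
    strict: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.s < 2:
            raise ValueError("s must be >= 2")
        if self.strategy not in ("shortest_paths", "radius"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclass
class Subpathway:
    """A connected candidate-dense region of one pathway."""

    id: str
    parent_pathway_id: str
    member_genes: frozenset
    candidate_members: frozenset
    p_value: float | None = None
    fdr: float | None = None

    def __post_init__(self) -> None:
        if not self.candidate_members <= self.member_genes:
            raise ValueError("candidate_members must be a subset of member_genes")

    @property
    def size(self) -> int:
        return len(self.member_genes)


def locate_subpathways(
    pw: PathwayGraph,
    candidates: set[str],
    params: SubpathwayParams,
) -> list[Subpathway]:
    """Locate the candidate-dense subpathways of one pathway (unscored).

    Components are ordinal-suffixed ``_1, _2, ...`` in decreasing size,
    ties broken by lexicographically smallest member gene.
    """
    g = pw.graph
    cand = sorted(candidates & pw.nodes)
    if not cand:
        return []
    if g.number_of_edges() == 0:
        logger.info("pathway %s has no edges; no subpathways", pw.pathway_id)
        return []

    limit = params.n - 1 if params.strict else params.n
    dist = {c: nx.single_source_shortest_path_length(g, c, cutoff=limit) for c in cand}
    selected: set[str] = set(cand)
    if params.strategy == "radius":
        for c in cand:
            selected.update(dist[c])
    else:
        for i, ci in enumerate(cand):
            di = dist[ci]
            for cj in cand[i + 1:]:
                d = di.get(cj)
                if d is None:
                    continue
                # nodes on any shortest ci-cj path: d(ci,x) + d(x,cj) == d
                dj = dist[cj]
                selected.update(x for x, dx in di.items() if dj.get(x, -1) == d - dx)

    sub = g.subgraph(selected)
    comps = [c for c in nx.connected_components(sub) if len(c) >= params.s]
    comps.sort(key=lambda c: (-len(c), min(c)))
    out = []
    for ordinal, comp in enumerate(comps, start=1):
        out.append(
            Subpathway(
                id=f"{pw.pathway_id}_{ordinal}",
                parent_pathway_id=pw.pathway_id,
                member_genes=frozenset(comp),
                candidate_members=frozenset(comp & set(cand)),
            )
        )
    return out


def hypergeometric_enrichment(k: int, K: int, m: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``k`` candidates among the ``m`` subpathway members, drawn from a
    background of ``N`` genes of which ``K`` are candidates.
    """
    return hypergeom_upper_tail(k, K, m, N)


def score_subpathways(
    subpathways: list[Subpathway],
    candidates: set[str],
    background: set[str],
) -> list[Subpathway]:
    """Attach hypergeometric p-values against a common background.

    The background is the gene universe enrichment is judged against —
    by convention all genes appearing in >= 1 pathway graph intersected
    with the measured genes; ``K`` is the candidate count inside it.
    Subpathway members outside the background are ignored for counting.
    """
    N = len(background)
    K = len(candidates & background)
    scored = []
    for sp in subpathways:
        members = sp.member_genes & background
        m = len(members)
        k = len(sp.candidate_members & background)
        p = hypergeom_upper_tail(k, K, m, N)
        scored.append(
            Subpathway(
                id=sp.id,
                parent_pathway_id=sp.parent_pathway_id,
                member_genes=sp.member_genes,
                candidate_members=sp.candidate_members,
                p_value=p,
            )
        )
    return scored


def call_risk_pathways(
    subpathways: list[Subpathway],
    params: SubpathwayParams,
) -> list[Subpathway]:
    """BH-adjust jointly across all scored subpathways and keep FDR < cut.

    Survivors are sorted by (fdr, id).
    """
    if not subpathways:
        return []
    if any(sp.p_value is None for sp in subpathways):
        raise ValueError("subpathways must be scored before calling risk pathways")
    fdrs = bh_adjust([sp.p_value for sp in subpathways])
    out = []
    for sp, fdr in zip(subpathways, fdrs):
        if fdr < params.fdr_cut:
            out.append(
                Subpathway(
                    id=sp.id,
                    parent_pathway_id=sp.parent_pathway_id,
                    member_genes=sp.member_genes,
                    candidate_members=sp.candidate_members,
                    p_value=sp.p_value,
                    fdr=float(fdr),
                )
            )
    out.sort(key=lambda sp: (sp.fdr, sp.id))
    logger.info("risk pathways: %d of %d subpathways at FDR<%g",
                len(out), len(subpathways), params.fdr_cut)
    return out
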