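"""Linker and leader classification for cross-talking pathway pairs.

For a significant pair of risk pathways, *linkers* are genes altered at
>= 1 molecular level that mediate the two pathways in the PPI network, and
*leaders* are candidate genes inside the pathways that directly connect
the linkers. Three situations are distinguished:

* situation i — a non-member altered gene adjacent to >= 1 candidate of
  each pathway is a linker; the adjacent candidates are leaders;
* situation ii — a direct PPI edge between a candidate of one pathway and
  a candidate of the other makes both genes linker and leader;
* situation iii — a candidate shared by both pathways is linker and leader.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import PpiNetwork

__all__ = ["LinkerLeaderAssignment", "classify_linkers_leaders", "summarize_linkers"]

SITUATIONS = ("i", "ii", "iii")


@dataclass
class LinkerLeaderAssignment:
    """Linkers and leaders of one cross-talking pathway pair.

    ``linkers`` and ``leaders`` map gene -> set of situation labels; a gene
    can satisfy several situations for the same pair.
    """

    pathway_a: str
    pathway_b: str
    linkers: dict[str, set] = field(default_factory=dict)
    leaders: dict[str, set] = field(default_factory=dict)
    alteration_flags: dict[str, tuple] = field(default_factory=dict)

    def _add(self, which: dict, gene: str, situation: str) -> None:
        which.setdefault(gene, set()).add(situation)

    @property
    def n_linkers(self) -> int:
        return len(self.linkers)

    @property
    def n_leaders(self) -> int:
        return len(self.leaders)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        genes = sorted(set(self.linkers) | set(self.leaders))
        for g in genes:
            in_l, in_d = g in self.linkers, g in self.leaders
            role = "both" if in_l and in_d else ("linker" if in_l else "leader")
            sits = sorted(self.linkers.get(g, set()) | self.leaders.get(g, set()))
            rows.append(
                (self.pathway_a, self.pathway_b, g, role, ";".join(sits),
                 ";".join(self.alteration_flags.get(g, ())))
            )
        return pd.DataFrame(
            rows,
            columns=["pathway_a", "pathway_b", "gene", "role", "situation",
                     "alteration_flags"],
        )


def classify_linkers_leaders(
    pair: tuple[str, str],
    cand_a: set[str],
    cand_b: set[str],
    members_a: set[str],
    members_b: set[str],
    altered: set[str],
    net: PpiNetwork,
    flags: dict[str, tuple] | None = None,
) -> LinkerLeaderAssignment:
    """Classify the linkers and leaders of one pathway pair.

    ``altered`` is the registry of genes with >= 1-level alteration (a
    superset of the candidates); ``members_a/b`` are the risk-subpathway
    member genes used for the situation-i non-membership condition;
    ``net`` is the PPI largest connected component. The output is
    symmetric under swapping the two pathways.
    """
    g = net.graph
    asg = LinkerLeaderAssignment(pathway_a=pair[0], pathway_b=pair[1])
    in_net_a = cand_a & net.nodes
    in_net_b = cand_b & net.nodes

    # situation iii: shared candidates
    for gene in cand_a & cand_b:
        asg._add(asg.linkers, gene, "iii")
        asg._add(asg.leaders, gene, "iii")

    # situation ii: direct candidate-candidate edges across the pair
    for x in in_net_a:
        for y in set(g.neighbors(x)) & in_net_b:
            if x == y:
                continue
            for gene in (x, y):
                asg._add(asg.linkers, gene, "ii")
                asg._add(asg.leaders, gene, "ii")

    # situation i: altered non-member bridges
    members = members_a | members_b
    bridge_candidates = set()
    for x in in_net_a:
        bridge_candidates.update(g.neighbors(x))
    for gene in bridge_candidates:
        if gene in members or gene not in altered:
            continue
        nbrs = set(g.neighbors(gene))
        hit_a = nbrs & in_net_a
        hit_b = nbrs & in_net_b
        if hit_a and hit_b:
            asg._add(asg.linkers, gene, "i")
            for leader in hit_a | hit_b:
                asg._add(asg.leaders, leader, "i")

    if flags:
        for gene in set(asg.linkers) | set(asg.leaders):
            if gene in flags:
                asg.alteration_flags[gene] = tuple(flags[gene])
    return asg


def summarize_linkers(assignments: list[LinkerLeaderAssignment]) -> dict:
    """Per-pair counts and global tallies over all cross-talking pairs."""
    per_pair = pd.DataFrame(
        [(a.pathway_a, a.pathway_b, a.n_linkers, a.n_leaders) for a in assignments],
        columns=["pathway_a", "pathway_b", "n_linkers", "n_leaders"],
    )
    uniq_linkers = set().union(*(a.linkers.keys() for a in assignments)) if assignments else set()
    uniq_leaders = set().union(*(a.leaders.keys() for a in assignments)) if assignments else set()
    stats = {}
    for col in ("n_linkers", "n_leaders"):
        vals = per_pair[col]
        stats[col] = {
            "min": int(vals.min()) if len(vals) else 0,
            "max": int(vals.max()) if len(vals) else 0,
            "mean": float(vals.mean()) if len(vals) else 0.0,
        }
    return {
        "per_pair": per_pair,
        "n_unique_linkers": len(uniq_linkers),
        "n_unique_leaders": len(uniq_leaders),
        "per_pair_stats": stats,
    }
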