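"""Seeded synthetic study generator.

Emulates the statistical structure the pipeline assumes in real data:
a scale-free-like PPI, pathways grown as connected subgraphs of the PPI,
tumor/normal mean shifts in log2 expression, beta-value shifts in
methylation, sign-consistent copy-number and mutation overlaps, and a
planted cross-talk pair mediated by non-member linker genes wired to
candidates on both sides (the situation-i topology).

All generation is deterministic per seed; each stage draws from its own
named substream so adding a stage never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import (
    CnaCallSet,
    ExpressionMatrix,
    MethylationMatrix,
    MutationTable,
    OmicsBundle,
    PathwayGraph,
    PpiNetwork,
)

__all__ = [
    "PlantedEffect",
    "PlantedCrosstalk",
    "SimulationConfig",
    "SyntheticStudy",
    "generate_ppi",
    "generate_pathways",
    "plant_crosstalk",
    "generate_omics",
    "simulate_study",
    "write_bundle",
]

_STREAMS = {"ppi": 1, "pathways": 2, "crosstalk": 3, "omics": 4, "design": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass(frozen=True)
class PlantedEffect:
    """One planted alteration: a gene set, the layer it hits, the effect size.

    ``effect`` is signed: SD units of class mean shift for expression,
    Δβ for methylation, +1/-1 (amplified/deleted) for cna, and the
    fraction of tumor samples carrying a non-silent mutation for mutation.
    """

    genes: tuple
    layer: str          # expression | methylation | cna | mutation
    effect: float

    def __post_init__(self) -> None:
        if self.layer not in ("expression", "methylation", "cna", "mutation"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if not np.isfinite(self.effect):
            raise ValueError("effect size must be finite")


@dataclass(frozen=True)
class PlantedCrosstalk:
    pathway_a: str
    pathway_b: str
    n_linkers: int = 8


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Defaults describe the scaled fixture used throughout the test suite:
    a 2000-gene preferential-attachment PPI with mean degree ~4, 20
    pathways of 10-20 genes grown on it, 30 tumor and 18 normal samples,
    ten candidate-dense pathways with six planted candidates each
    (group i/ii/iii patterns cycling, expression shift 4 SD, Δβ 0.25),
    and one planted cross-talk pair bridged by three linkers.
    """

    n_genes: int = 2000
    n_tumor: int = 30
    n_normal: int = 18
    n_pathways: int = 20
    pathway_size_range: tuple = (10, 20)
    ppi_model: str = "scale_free"          # scale_free | configuration
    ppi_mean_degree: float = 4.0
    degree_sequence: tuple | None = None   # required for configuration model
    planted: list = dc_field(default_factory=list)        # PlantedEffect items
    planted_crosstalk: list = dc_field(default_factory=list)  # PlantedCrosstalk items
    noise_sd: float = 1.0
    beta_noise_sd: float = 0.05
    pathway_overlap: float = 0.0
    #: fraction of pathway edges rewired away from the PPI topology
    inconsistency: float = 0.0
    silent_fraction: float = 0.3
    seed: int = 0

    # planted-design knobs used by simulate_study
    n_risk_pathways: int = 10
    candidates_per_pathway: int = 6
    de_effect_sd: float = 4.0
    delta_beta_effect: float = 0.25
    mutation_fraction: float = 0.3

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tumor", "n_normal", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.ppi_model not in ("scale_free", "configuration"):
            raise ValueError(f"unknown ppi_model {self.ppi_model!r}")


def _gene_name(i: int, width: int) -> str:
    return f"G{i:0{width}d}"


def generate_ppi(cfg: SimulationConfig) -> PpiNetwork:
    """Generate the synthetic PPI under the configured model.

    ``scale_free`` uses preferential attachment (heavy-tailed degrees);
    ``configuration`` realizes ``cfg.degree_sequence`` exactly
    (Havel-Hakimi construction followed by seeded degree-preserving
    rewiring), erroring on a non-graphical sequence.
    """
    rng = _rng(cfg.seed, "ppi")
    if cfg.ppi_model == "scale_free":
        m = max(1, int(round(cfg.ppi_mean_degree / 2)))
        g = nx.barabasi_albert_graph(cfg.n_genes, m, seed=int(rng.integers(2**31)))
    else:
        if cfg.degree_sequence is None:
            raise ValueError("configuration model requires cfg.degree_sequence")
        seq = list(cfg.degree_sequence)
        if not nx.is_graphical(seq):
            raise ValueError(f"degree sequence {seq} is not graphical")
        g = nx.havel_hakimi_graph(seq)
        from .crosstalk import RwrParams, degree_preserving_rewire
        net = PpiNetwork(graph=g)
        net = degree_preserving_rewire(
            net, RwrParams(seed=int(rng.integers(2**31))), permutation_index=0
        )
        g = net.graph
    width = len(str(max(cfg.n_genes - 1, 9)))
    g = nx.relabel_nodes(g, {i: _gene_name(i, width) for i in g.nodes})
    return PpiNetwork(graph=g, provenance=f"synthetic:{cfg.ppi_model}")


def generate_pathways(cfg: SimulationConfig, ppi: PpiNetwork) -> list[PathwayGraph]:
    """Grow pathways as connected subgraphs of the PPI by seeded random BFS.

    With ``pathway_overlap == 0`` the pathways are pairwise disjoint *and*
    non-adjacent: growth avoids the one-hop PPI neighborhood of every
    earlier pathway, so no two pathways share a direct edge. This margin
    makes unplanted pathway pairs a genuine cross-talk null — without it,
    chance candidate-candidate edges between touching pathways dominate
    any planted linker bridge. With ``pathway_overlap > 0`` growth may
    re-enter already-used genes with that probability (no margin).
    ``inconsistency > 0`` rewires that fraction of each pathway's edges to
    random member pairs, emulating curated pathway graphs that disagree
    with the PPI.
    """
    rng = _rng(cfg.seed, "pathways")
    g = ppi.graph
    lo, hi = cfg.pathway_size_range
    used: set = set()
    blocked: set = set()            # used plus their one-hop neighborhoods
    out = []
    all_nodes = sorted(g.nodes)
    for pidx in range(cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = None
        for _attempt in range(200):
            start = all_nodes[int(rng.integers(len(all_nodes)))]
            if cfg.pathway_overlap == 0.0 and start in blocked:
                continue
            grown = {start}
            frontier = set(g.neighbors(start))
            while len(grown) < size and frontier:
                if cfg.pathway_overlap > 0.0:
                    allowed = [
                        n for n in frontier
                        if n not in grown
                        and (n not in used or rng.random() < cfg.pathway_overlap)
                    ]
                else:
                    allowed = [n for n in frontier if n not in grown and n not in blocked]
                if not allowed:
                    break
                pick = sorted(allowed)[int(rng.integers(len(allowed)))]
                grown.add(pick)
                frontier.update(g.neighbors(pick))
                frontier.discard(pick)
            if len(grown) == size:
                members = grown
                break
        if members is None:
            raise RuntimeError(
                f"could not grow pathway {pidx} of size {size}; "
                "PPI too small or too fragmented for these settings"
            )
        used |= members
        blocked |= members
        for n in members:
            blocked.update(g.neighbors(n))
        sub = nx.Graph(g.subgraph(members))
        if cfg.inconsistency > 0.0:
            edges = sorted(tuple(sorted(e)) for e in sub.edges)
            n_rewire = int(round(cfg.inconsistency * len(edges)))
            mem = sorted(members)
            for e in [edges[i] for i in rng.choice(len(edges), size=n_rewire, replace=False)]:
                sub.remove_edge(*e)
                while True:
                    u, v = (mem[int(rng.integers(len(mem)))] for _ in range(2))
                    if u != v and not sub.has_edge(u, v):
                        sub.add_edge(u, v)
                        break
        pid = f"PW{pidx:02d}"
        out.append(PathwayGraph(pathway_id=pid, name=f"synthetic pathway {pidx}", graph=sub))
    return out


def plant_crosstalk(
    ppi: PpiNetwork,
    pathway_a: PathwayGraph,
    pathway_b: PathwayGraph,
    n_linkers: int,
    cfg: SimulationConfig,
    cand_a: set[str] | None = None,
    cand_b: set[str] | None = None,
    exclude: set[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PpiNetwork, list[str]]:
    """Wire ``n_linkers`` non-member genes between two pathways.

    Each linker becomes a common direct neighbor of the two candidate
    sets: it gains edges to up to six candidate genes of each pathway
    (candidates default to all members), creating concentrated length-2
    bridges — the situation-i topology. Returns the augmented network and
    the linker ids.
    """
    if n_linkers == 0:
        return PpiNetwork(graph=ppi.graph.copy(), provenance=ppi.provenance), []
    rng = rng if rng is not None else _rng(cfg.seed, "crosstalk")
    cand_a = sorted(cand_a or pathway_a.nodes)
    cand_b = sorted(cand_b or pathway_b.nodes)
    forbidden = pathway_a.nodes | pathway_b.nodes | (exclude or set())
    pool = sorted(set(ppi.graph.nodes) - forbidden)
    if len(pool) < n_linkers:
        raise ValueError("not enough non-member genes to plant linkers")
    linkers = [pool[i] for i in rng.choice(len(pool), size=n_linkers, replace=False)]
    g = ppi.graph.copy()
    for lk in linkers:
        for side in (cand_a, cand_b):
            k = min(6, len(side))
            for j in rng.choice(len(side), size=k, replace=False):
                g.add_edge(lk, side[j])
    return PpiNetwork(graph=g, provenance=ppi.provenance), linkers


def generate_omics(cfg: SimulationConfig, genes: list[str],
                   planted: list[PlantedEffect] | None = None) -> OmicsBundle:
    """Generate the four data layers for ``genes`` with planted effects.

    Expression: per-gene Gaussian baseline (log2 scale) with class mean
    shifts of ``effect * noise_sd`` on tumors. Methylation: clipped
    Gaussian betas around a per-gene baseline with planted Δβ on tumors.
    CNA and mutation records are assigned to planted genes; background
    silent mutations exercise the silent filter.
    """
    planted = list(cfg.planted) + list(planted or [])
    gene_set = set(genes)
    for eff in planted:
        missing = set(eff.genes) - gene_set
        if missing:
            raise ValueError(f"planted gene(s) not in universe: {sorted(missing)[:5]}")

    rng = _rng(cfg.seed, "omics")
    n_g, n_t, n_n = len(genes), cfg.n_tumor, cfg.n_normal
    tumor_ids = [f"T{i:03d}" for i in range(n_t)]
    normal_ids = [f"N{i:03d}" for i in range(n_n)]
    samples = tumor_ids + normal_ids
    class_map = {s: "tumor" for s in tumor_ids} | {s: "normal" for s in normal_ids}
    gene_index = {g: i for i, g in enumerate(genes)}

    base_expr = rng.normal(8.0, 1.0, size=n_g)
    expr = base_expr[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n_g, n_t + n_n))
    base_beta = rng.uniform(0.2, 0.8, size=n_g)
    beta = base_beta[:, None] + rng.normal(0.0, cfg.beta_noise_sd, size=(n_g, n_t + n_n))

    cna_calls: dict[str, str] = {}
    mut_rows: list[tuple] = []
    for eff in planted:
        idx = [gene_index[g] for g in eff.genes]
        if eff.layer == "expression":
            expr[np.ix_(idx, range(n_t))] += eff.effect * cfg.noise_sd
        elif eff.layer == "methylation":
            beta[np.ix_(idx, range(n_t))] += eff.effect
        elif eff.layer == "cna":
            d = "amplified" if eff.effect > 0 else "deleted"
            for g in eff.genes:
                cna_calls[g] = d
        else:
            k = max(1, int(round(eff.effect * n_t)))
            classes = ("missense", "nonsense", "frameshift")
            for g in eff.genes:
                hit = rng.choice(n_t, size=min(k, n_t), replace=False)
                for s in hit:
                    mut_rows.append((g, tumor_ids[s], classes[int(rng.integers(3))]))

    # background silent mutations (never affect the non-silent gene set)
    n_bg = max(3, n_g // 200)
    for i in rng.choice(n_g, size=n_bg, replace=False):
        if rng.random() < cfg.silent_fraction * 2:
            mut_rows.append((genes[int(i)], tumor_ids[int(rng.integers(n_t))], "silent"))

    beta = np.clip(beta, 0.01, 0.99)
    sample_class = pd.Series(class_map)
    expression = ExpressionMatrix(
        values=pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples),
        sample_class=sample_class,
    )
    methylation = MethylationMatrix(
        values=pd.DataFrame(beta, index=pd.Index(genes, name="gene"), columns=samples),
        sample_class=sample_class,
    )
    mutations = MutationTable(
        records=pd.DataFrame(mut_rows, columns=["gene", "sample", "mutation_class"])
    )
    return OmicsBundle(
        expression=expression,
        methylation=methylation,
        cna=CnaCallSet(calls=cna_calls),
        mutations=mutations,
    )


@dataclass
class SyntheticStudy:
    """A complete generated study with its ground truth."""

    cfg: SimulationConfig
    ppi: PpiNetwork
    pathways: list
    bundle: OmicsBundle
    class_map: dict
    truth: dict


# the planted candidate patterns cycle through the three dysregulated groups
_PATTERNS = (
    ("i", +1), ("ii", -1), ("iii", +1),
    ("i", -1), ("ii", +1), ("iii", -1),
)


def simulate_study(cfg: SimulationConfig | None = None) -> SyntheticStudy:
    """Generate a full synthetic study with planted candidates and cross-talk.

    The first ``cfg.n_risk_pathways`` pathways each receive
    ``cfg.candidates_per_pathway`` planted candidate genes (a connected
    cluster of members, patterns cycling through groups i/ii/iii with both
    signs); the first two risk pathways are bridged by planted situation-i
    linkers altered at a single level (mutation only).
    """
    cfg = cfg or SimulationConfig()
    ppi = generate_ppi(cfg)
    pathways = generate_pathways(cfg, ppi)
    rng = _rng(cfg.seed, "design")

    n_risk = min(cfg.n_risk_pathways, len(pathways))
    planted_effects: list[PlantedEffect] = []
    planted_candidates: dict[str, list] = {}
    gene_groups: dict[str, str] = {}
    for pw in pathways[:n_risk]:
        # connected cluster of members: BFS from a random member
        mem = sorted(pw.nodes)
        start = mem[int(rng.integers(len(mem)))]
        order = [start] + [v for _, v in nx.bfs_edges(pw.graph, start)]
        cands = order[: cfg.candidates_per_pathway]
        planted_candidates[pw.pathway_id] = cands
        for j, gene in enumerate(cands):
            group, sign = _PATTERNS[j % len(_PATTERNS)]
            gene_groups[gene] = group
            planted_effects.append(
                PlantedEffect((gene,), "expression", sign * cfg.de_effect_sd)
            )
            if group == "i":
                # sign-consistent: over-expression with hypomethylation etc.
                planted_effects.append(
                    PlantedEffect((gene,), "methylation", -sign * cfg.delta_beta_effect)
                )
            elif group == "ii":
                planted_effects.append(PlantedEffect((gene,), "cna", float(sign)))
            else:
                planted_effects.append(
                    PlantedEffect((gene,), "mutation", cfg.mutation_fraction)
                )

    crosstalks = list(cfg.planted_crosstalk)
    if not crosstalks and n_risk >= 2:
        crosstalks = [PlantedCrosstalk(pathways[0].pathway_id, pathways[1].pathway_id)]
    by_id = {pw.pathway_id: pw for pw in pathways}
    all_members = set().union(*(pw.nodes for pw in pathways)) if pathways else set()
    planted_linkers: dict[tuple, list] = {}
    net = ppi
    rng_ct = _rng(cfg.seed, "crosstalk")
    for ct in crosstalks:
        pa, pb = by_id[ct.pathway_a], by_id[ct.pathway_b]
        net, linkers = plant_crosstalk(
            net, pa, pb, ct.n_linkers, cfg,
            cand_a=set(planted_candidates.get(ct.pathway_a, pa.nodes)),
            cand_b=set(planted_candidates.get(ct.pathway_b, pb.nodes)),
            exclude=all_members | set().union(*planted_linkers.values(), set()),
            rng=rng_ct,
        )
        planted_linkers[(ct.pathway_a, ct.pathway_b)] = linkers
        # linkers are altered at exactly one level (mutation), not candidates
        if linkers:
            planted_effects.append(
                PlantedEffect(tuple(linkers), "mutation", cfg.mutation_fraction)
            )

    genes = sorted(net.graph.nodes)
    bundle = generate_omics(cfg, genes, planted_effects)
    class_map = dict(bundle.expression.sample_class)
    truth = {
        "planted_candidates": planted_candidates,
        "gene_groups": gene_groups,
        "planted_crosstalk": [(c.pathway_a, c.pathway_b) for c in crosstalks],
        "planted_linkers": {f"{a}|{b}": v for (a, b), v in planted_linkers.items()},
        "risk_pathway_ids": [pw.pathway_id for pw in pathways[:n_risk]],
    }
    return SyntheticStudy(cfg=cfg, ppi=net, pathways=pathways, bundle=bundle,
                          class_map=class_map, truth=truth)


def write_bundle(study: SyntheticStudy, out_dir) -> dict[str, Path]:
    """Write the study as the exact file set the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "methylation": out / "methylation.tsv",
        "cna": out / "cna.tsv",
        "mutations": out / "mutations.tsv",
        "classes": out / "classes.tsv",
        "ppi": out / "ppi.tsv",
        "gmt": out / "pathways.gmt",
        "pathway_edges": out / "pathway_edges.tsv",
        "truth": out / "truth.json",
    }
    study.bundle.expression.values.to_csv(paths["expression"], sep="\t", float_format="%.6f")
    study.bundle.methylation.values.to_csv(paths["methylation"], sep="\t", float_format="%.6f")
    with open(paths["cna"], "w") as fh:
        for g, d in sorted(study.bundle.cna.calls.items()):
            fh.write(f"{g}\t{d}\n")
    study.bundle.mutations.records.to_csv(paths["mutations"], sep="\t", index=False)
    with open(paths["classes"], "w") as fh:
        for s, c in study.class_map.items():
            fh.write(f"{s}\t{c}\n")
    with open(paths["ppi"], "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in study.ppi.graph.edges):
            fh.write(f"{u}\t{v}\n")
    with open(paths["gmt"], "w") as fh:
        for pw in study.pathways:
            fh.write("\t".join([pw.pathway_id, pw.name] + sorted(pw.nodes)) + "\n")
    with open(paths["pathway_edges"], "w") as fh:
        for pw in study.pathways:
            for u, v in sorted(tuple(sorted(e)) for e in pw.graph.edges):
                fh.write(f"{pw.pathway_id}\t{u}\t{v}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(study.truth, fh, indent=1, sort_keys=True)
    return paths
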