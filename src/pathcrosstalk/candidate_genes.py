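"""Multi-level candidate-gene calling.

Tumor/normal cohorts are typically badly unbalanced (e.g. 304 tumors vs 18
normals), so differential expression and differential methylation are called
by a resampling scheme: in each of ``n_resamples`` rounds a fixed-size tumor
subsample (default 18, matching the normal count) is compared against all
normals with a Welch t-test, BH-adjusted across genes, and filtered on
effect size. A gene is called when it is significant in more than
``freq_cut`` of the rounds, with its direction taken by majority sign.

The called layers are then integrated into three sign-consistent
dysregulated groups:

* group i  — differential expression + opposite-direction methylation
  change (over-expressed & hypomethylated, or under-expressed &
  hypermethylated);
* group ii — differential expression + same-sign copy-number alteration
  (over-expressed & amplified, or under-expressed & deleted);
* group iii — differential expression (either direction) + at least one
  non-silent somatic mutation.

The union of the three groups is the candidate-gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CnaCallSet, ExpressionMatrix, MethylationMatrix, MutationTable
from .stats import bh_adjust, welch_t_test

logger = logging.getLogger(__name__)

__all__ = [
    "ResamplingParams",
    "ResampledCallResult",
    "CandidateGeneSet",
    "resampled_differential_test",
    "filter_nonsilent_mutations",
    "integrate_candidates",
]


@dataclass
class ResamplingParams:
    """Parameters of the resampled differential test.

    Defaults are the study conditions: 1000 resamples of 18 tumors against
    all normals, BH FDR < 0.001 with fold change > 2 (expression) or
    |Δβ| > 0.1 (methylation), and a calling frequency strictly above 10%.
    """

    n_resamples: int = 1000
    subsample_size: int = 18
    fdr_cut: float = 0.001
    fc_cut: float = 2.0
    delta_beta: float = 0.1
    freq_cut: float = 0.10
    seed: int = 0
    #: set True if expression values are linear-scale (they are log2 by default)
    linear_scale: bool = False

    def __post_init__(self) -> None:
        if self.n_resamples < 1 or self.subsample_size < 2:
            raise ValueError("n_resamples >= 1 and subsample_size >= 2 required")
        if not (0 < self.fdr_cut < 1 and 0 < self.freq_cut < 1):
            raise ValueError("fdr_cut and freq_cut must lie in (0, 1)")
        if self.fc_cut <= 0:
            raise ValueError("fc_cut must be positive")


@dataclass
class ResampledCallResult:
    """Per-gene calling frequencies and majority directions."""

    table: pd.DataFrame     # index gene; columns frequency, direction, called
    layer: str              # "expression" | "methylation"
    params: ResamplingParams

    @property
    def called(self) -> pd.DataFrame:
        return self.table[self.table["called"]]

    def called_with_direction(self, direction: str) -> set[str]:
        t = self.table
        return set(t.index[t["called"] & (t["direction"] == direction)])


def resampled_differential_test(
    matrix: ExpressionMatrix | MethylationMatrix,
    params: ResamplingParams,
) -> ResampledCallResult:
    """Call differentially expressed/methylated genes by tumor resampling.

    Each round draws ``subsample_size`` tumors without replacement, keeps
    all normals, and marks a gene significant when its BH-adjusted Welch
    p-value is below ``fdr_cut`` *and* the effect criterion holds
    (|Δ log2 mean| > log2(fc_cut) for expression, |Δ mean β| > delta_beta
    for methylation). Identical seeds give identical output.
    """
    if isinstance(matrix, MethylationMatrix):
        layer = "methylation"
    elif isinstance(matrix, ExpressionMatrix):
        layer = "expression"
    else:
        raise TypeError(f"unsupported matrix type {type(matrix).__name__}")

    tumor, normal = matrix.split_classes()
    n_tumor, n_normal = tumor.shape[1], normal.shape[1]
    if n_tumor == 0 or n_normal == 0:
        raise ValueError("both tumor and normal classes must be nonempty")
    if params.subsample_size > n_tumor:
        raise ValueError(
            f"subsample_size={params.subsample_size} exceeds tumor count {n_tumor}"
        )

    if layer == "expression":
        vals_t, vals_n = tumor, normal
        if params.linear_scale:
            if (vals_t <= 0).any() or (vals_n <= 0).any():
                raise ValueError("linear-scale expression must be positive")
            vals_t, vals_n = np.log2(vals_t), np.log2(vals_n)
        effect_cut = np.log2(params.fc_cut)
    else:
        vals_t, vals_n = tumor, normal
        effect_cut = params.delta_beta

    n_genes = vals_t.shape[0]
    rng = np.random.default_rng(params.seed)
    up = np.zeros(n_genes, dtype=np.int64)
    down = np.zeros(n_genes, dtype=np.int64)
    mean_n = vals_n.mean(axis=1)

    for _ in range(params.n_resamples):
        idx = rng.choice(n_tumor, size=params.subsample_size, replace=False)
        sub = vals_t[:, idx]
        _, p = welch_t_test(sub, vals_n)
        padj = bh_adjust(p)
        delta = sub.mean(axis=1) - mean_n
        sig = (padj < params.fdr_cut) & (np.abs(delta) > effect_cut)
        up += sig & (delta > 0)
        down += sig & (delta < 0)

    freq = (up + down) / params.n_resamples
    direction = np.where(up > down, "up", np.where(down > up, "down", "none"))
    called = (freq > params.freq_cut) & (direction != "none")
    table = pd.DataFrame(
        {"frequency": freq, "direction": direction, "called": called},
        index=pd.Index(matrix.gene_ids, name="gene"),
    )
    logger.info("%s: %d of %d genes called", layer, int(called.sum()), n_genes)
    return ResampledCallResult(table=table, layer=layer, params=params)


def filter_nonsilent_mutations(tbl: MutationTable) -> set[str]:
    """Genes with at least one non-silent mutation record (case-insensitive)."""
    if tbl.records.empty:
        return set()
    nonsilent = tbl.records["mutation_class"].str.lower() != "silent"
    return set(tbl.records.loc[nonsilent, "gene"])


@dataclass
class CandidateGeneSet:
    """Per-gene alteration flags, dysregulated-group membership and the union."""

    flags: pd.DataFrame         # boolean columns over the gene universe
    groups: pd.DataFrame        # boolean columns i_meth, ii_cna, iii_mut
    candidates: list[str] = field(default_factory=list)

    FLAG_COLS = ("over_expr", "under_expr", "hyper_meth", "hypo_meth", "amp", "del", "mut")
    GROUP_COLS = ("i_meth", "ii_cna", "iii_mut")

    def genes_in_group(self, group: str) -> set[str]:
        return set(self.groups.index[self.groups[group]])

    @property
    def altered(self) -> set[str]:
        """Genes altered at >= 1 molecular level (not necessarily candidates)."""
        return set(self.flags.index[self.flags.any(axis=1)])


def integrate_candidates(
    de: ResampledCallResult,
    dm: ResampledCallResult,
    cna: CnaCallSet,
    mut: set[str],
) -> CandidateGeneSet:
    """Combine the four layers into the three sign-consistent groups.

    Sign-inconsistent combinations (e.g. over-expressed & hypermethylated)
    are excluded from group i, but the gene may still qualify through
    another group. Output is invariant to input gene order.
    """
    universe = sorted(
        set(de.table.index) | set(dm.table.index) | set(cna.calls) | set(mut)
    )
    other = set(dm.table.index) | set(cna.calls) | set(mut)
    if other and not (set(de.table.index) & other):
        raise ValueError(
            "expression genes share no identifiers with the other layers — "
            "likely a gene-namespace mismatch"
        )

    idx = pd.Index(universe, name="gene")
    flags = pd.DataFrame(False, index=idx, columns=list(CandidateGeneSet.FLAG_COLS))
    flags.loc[list(de.called_with_direction("up") & set(universe)), "over_expr"] = True
    flags.loc[list(de.called_with_direction("down") & set(universe)), "under_expr"] = True
    flags.loc[list(dm.called_with_direction("up") & set(universe)), "hyper_meth"] = True
    flags.loc[list(dm.called_with_direction("down") & set(universe)), "hypo_meth"] = True
    flags.loc[list(cna.amplified & set(universe)), "amp"] = True
    flags.loc[list(cna.deleted & set(universe)), "del"] = True
    flags.loc[list(mut & set(universe)), "mut"] = True

    groups = pd.DataFrame(False, index=idx, columns=list(CandidateGeneSet.GROUP_COLS))
    groups["i_meth"] = (flags["over_expr"] & flags["hypo_meth"]) | (
        flags["under_expr"] & flags["hyper_meth"]
    )
    groups["ii_cna"] = (flags["over_expr"] & flags["amp"]) | (
        flags["under_expr"] & flags["del"]
    )
    groups["iii_mut"] = (flags["over_expr"] | flags["under_expr"]) & flags["mut"]

    candidates = sorted(groups.index[groups.any(axis=1)])
    logger.info(
        "candidate integration: i=%d, ii=%d, iii=%d, union=%d",
        int(groups["i_meth"].sum()), int(groups["ii_cna"].sum()),
        int(groups["iii_mut"].sum()), len(candidates),
    )
    return CandidateGeneSet(flags=flags, groups=groups, candidates=candidates)
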