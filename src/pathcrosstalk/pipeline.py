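"""Pipeline orchestration: candidates -> risk pathways -> cross-talk -> linkers.

A single YAML config names the input files and the stage parameters; every
run writes a manifest recording the config snapshot, per-stage input/output
hashes, timings and warnings. Reruns with identical config and inputs
reproduce identical output hashes, and up-to-date stages are skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats as iof
from .candidate_genes import (
    CandidateGeneSet,
    ResamplingParams,
    filter_nonsilent_mutations,
    integrate_candidates,
    resampled_differential_test,
)
from .crosstalk import (
    RwrParams,
    build_crosstalk_network,
    crosstalk_significance,
)
from .linkers import classify_linkers_leaders, summarize_linkers
from .subpathways import (
    SubpathwayParams,
    call_risk_pathways,
    locate_subpathways,
    score_subpathways,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_stage", "run_all", "discover_crosstalk", "STAGES"]

STAGES = ("candidates", "subpathways", "crosstalk", "linkers")

_INPUT_KEYS = ("expression", "methylation", "cna", "mutations", "classes",
               "ppi", "gmt", "pathway_edges")


@dataclass
class RunConfig:
    """Resolved run configuration (paths + stage parameters + seed)."""

    inputs: dict
    out_dir: Path
    seed: int = 0
    resampling: ResamplingParams = field(default_factory=ResamplingParams)
    subpathway: SubpathwayParams = field(default_factory=SubpathwayParams)
    rwr: RwrParams = field(default_factory=RwrParams)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None, out_dir=None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent
        inputs = {
            k: str((base / v).resolve()) if not Path(v).is_absolute() else v
            for k, v in (raw.get("inputs") or {}).items()
        }
        cfg = cls(
            inputs=inputs,
            out_dir=Path(out_dir or raw.get("out_dir", "results")),
            seed=int(seed if seed is not None else raw.get("seed", 0)),
            resampling=ResamplingParams(**(raw.get("resampling") or {})),
            subpathway=SubpathwayParams(**(raw.get("subpathway") or {})),
            rwr=RwrParams(**(raw.get("rwr") or {})),
        )
        return cfg

    def validate_inputs(self, keys) -> None:
        missing = [k for k in keys if k not in self.inputs]
        if missing:
            raise ValueError(f"config is missing input path(s): {missing}")
        absent = [self.inputs[k] for k in keys if not Path(self.inputs[k]).exists()]
        if absent:
            raise FileNotFoundError(f"input file(s) do not exist: {absent}")

    def stage_seed(self, stage: str) -> int:
        """Named per-stage substream of the single config seed."""
        h = np.random.SeedSequence(
            [int(self.seed), STAGES.index(stage) + 101]
        ).generate_state(1)[0]
        return int(h % (2**31))

    def snapshot(self) -> dict:
        return {
            "inputs": dict(self.inputs),
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "resampling": asdict(self.resampling),
            "subpathway": asdict(self.subpathway),
            "rwr": asdict(self.rwr),
        }


# ---------------------------------------------------------------------------
# manifest


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest_path(cfg: RunConfig) -> Path:
    return cfg.out_dir / "run_manifest.json"


def _load_manifest(cfg: RunConfig) -> dict:
    p = _manifest_path(cfg)
    if p.exists():
        with open(p) as fh:
            return json.load(fh)
    return {"config": cfg.snapshot(), "stages": {}}


def _save_manifest(cfg: RunConfig, manifest: dict) -> None:
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    with open(_manifest_path(cfg), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


_STAGE_INPUTS = {
    "candidates": ["expression", "methylation", "cna", "mutations", "classes"],
    "subpathways": ["gmt", "pathway_edges"],
    "crosstalk": ["ppi"],
    "linkers": ["ppi"],
}
_STAGE_UPSTREAM = {
    "candidates": [],
    "subpathways": ["candidates.tsv"],
    "crosstalk": ["candidates.tsv", "risk_pathways.tsv"],
    "linkers": ["candidates.tsv", "risk_pathways.tsv", "crosstalk.tsv"],
}
_STAGE_OUTPUTS = {
    "candidates": ["candidates.tsv"],
    "subpathways": ["risk_pathways.tsv", "background.txt"],
    "crosstalk": ["crosstalk.tsv", "crosstalk.graphml"],
    "linkers": ["linkers_leaders.tsv"],
}


def _stage_input_hashes(cfg: RunConfig, stage: str) -> dict:
    hashes = {}
    for key in _STAGE_INPUTS[stage]:
        hashes[key] = _sha256(cfg.inputs[key])
    for fname in _STAGE_UPSTREAM[stage]:
        p = cfg.out_dir / fname
        hashes[fname] = _sha256(p) if p.exists() else None
    return hashes


def _stage_is_current(cfg: RunConfig, manifest: dict, stage: str) -> bool:
    rec = manifest["stages"].get(stage)
    if rec is None:
        return False
    if rec.get("config") != _stage_config(cfg, stage):
        return False
    if rec.get("inputs") != _stage_input_hashes(cfg, stage):
        return False
    for fname, digest in rec.get("outputs", {}).items():
        p = cfg.out_dir / fname
        if not p.exists() or _sha256(p) != digest:
            return False
    return True


def _stage_config(cfg: RunConfig, stage: str) -> dict:
    sel = {
        "candidates": ("resampling",),
        "subpathways": ("subpathway",),
        "crosstalk": ("rwr",),
        "linkers": ("rwr",),
    }[stage]
    snap = cfg.snapshot()
    return {k: snap[k] for k in sel} | {"seed": cfg.seed}


def _check_upstream_fresh(cfg: RunConfig, manifest: dict, stage: str) -> None:
    """A standalone stage run refuses stale upstream outputs."""
    for fname in _STAGE_UPSTREAM[stage]:
        p = cfg.out_dir / fname
        if not p.exists():
            raise RuntimeError(
                f"stage {stage!r} needs {fname}, which does not exist; "
                f"rerun the upstream stage first"
            )
        producer = next(s for s, outs in _STAGE_OUTPUTS.items() if fname in outs)
        rec = manifest["stages"].get(producer)
        recorded = (rec or {}).get("outputs", {}).get(fname)
        if recorded is None or _sha256(p) != recorded:
            raise RuntimeError(
                f"stage {stage!r}: upstream output {fname} is stale or untracked; "
                f"rerun stage {producer!r} first"
            )


# ---------------------------------------------------------------------------
# stage bodies


def _run_candidates(cfg: RunConfig) -> CandidateGeneSet:
    class_map = iof.read_class_map(cfg.inputs["classes"])
    expr = iof.read_expression_matrix(cfg.inputs["expression"], class_map)
    meth = iof.read_methylation_matrix(cfg.inputs["methylation"], class_map)
    cna = iof.read_cna_calls(cfg.inputs["cna"])
    mut_tbl = iof.read_mutation_table(cfg.inputs["mutations"])

    seed = cfg.stage_seed("candidates")
    rp = cfg.resampling
    de = resampled_differential_test(
        expr, ResamplingParams(**{**asdict(rp), "seed": seed}))
    dm = resampled_differential_test(
        meth, ResamplingParams(**{**asdict(rp), "seed": seed + 1}))
    mut = filter_nonsilent_mutations(mut_tbl)
    cand = integrate_candidates(de, dm, cna, mut)

    table = cand.flags.astype(int).join(cand.groups.astype(int))
    table["candidate"] = table.index.isin(cand.candidates).astype(int)
    de_t = de.table.add_prefix("expr_")
    dm_t = dm.table.add_prefix("meth_")
    table = table.join(de_t, how="left").join(dm_t, how="left")
    table.to_csv(cfg.out_dir / "candidates.tsv", sep="\t")
    return cand


def _load_candidates(cfg: RunConfig) -> pd.DataFrame:
    return pd.read_csv(cfg.out_dir / "candidates.tsv", sep="\t", index_col=0)


def _run_subpathways(cfg: RunConfig) -> None:
    tbl = _load_candidates(cfg)
    candidates = set(tbl.index[tbl["candidate"] == 1])
    pathways = iof.read_pathway_collection(cfg.inputs["gmt"], cfg.inputs["pathway_edges"])
    measured = set(tbl.index)
    background = set().union(*(pw.nodes for pw in pathways)) & measured if pathways else set()

    located = []
    for pw in pathways:
        located.extend(locate_subpathways(pw, candidates, cfg.subpathway))
    scored = score_subpathways(located, candidates, background)
    risk = call_risk_pathways(scored, cfg.subpathway)

    rows = []
    for sp in risk:
        rows.append((
            sp.id, sp.parent_pathway_id, sp.size, len(sp.candidate_members),
            sp.p_value, sp.fdr,
            ";".join(sorted(sp.member_genes)),
            ";".join(sorted(sp.candidate_members)),
        ))
    pd.DataFrame(
        rows,
        columns=["subpathway_id", "parent", "size", "n_candidates", "p", "fdr",
                 "members", "candidate_members"],
    ).to_csv(cfg.out_dir / "risk_pathways.tsv", sep="\t", index=False)
    with open(cfg.out_dir / "background.txt", "w") as fh:
        fh.write(f"# background: pathway genes intersected with measured genes\n")
        fh.write(f"# N={len(background)} K={len(candidates & background)}\n")
        for g in sorted(background):
            fh.write(g + "\n")


def _load_risk(cfg: RunConfig) -> pd.DataFrame:
    return pd.read_csv(cfg.out_dir / "risk_pathways.tsv", sep="\t")


def _source_sets(risk: pd.DataFrame) -> dict[str, set]:
    return {
        row.subpathway_id: set(str(row.candidate_members).split(";")) - {"", "nan"}
        for row in risk.itertuples(index=False)
    }


def _run_crosstalk(cfg: RunConfig) -> None:
    risk = _load_risk(cfg)
    net = iof.largest_connected_component(iof.read_ppi(cfg.inputs["ppi"]))
    sources = _source_sets(risk)
    if len(sources) < 2:
        logger.warning("fewer than two risk pathways; empty cross-talk output")
        pd.DataFrame(columns=["pathway_a", "pathway_b", "score_ab", "score_ba",
                              "score", "n_source_in_net", "n_target_in_net",
                              "p", "fdr"]).to_csv(
            cfg.out_dir / "crosstalk.tsv", sep="\t", index=False)
        iof.write_network(build_crosstalk_network(
            pd.DataFrame(columns=["pathway_a", "pathway_b", "score", "p", "fdr"]),
            cfg.rwr), cfg.out_dir / "crosstalk.graphml", "graphml")
        return
    params = RwrParams(**{**asdict(cfg.rwr), "seed": cfg.stage_seed("crosstalk")})
    results = crosstalk_significance(net, sources, params)
    results.to_csv(cfg.out_dir / "crosstalk.tsv", sep="\t", index=False,
                   float_format="%.8g")
    g = build_crosstalk_network(results, params)
    iof.write_network(g, cfg.out_dir / "crosstalk.graphml", "graphml")


def _run_linkers(cfg: RunConfig) -> None:
    tbl = _load_candidates(cfg)
    risk = _load_risk(cfg)
    ct = pd.read_csv(cfg.out_dir / "crosstalk.tsv", sep="\t")
    net = iof.largest_connected_component(iof.read_ppi(cfg.inputs["ppi"]))

    flag_cols = list(CandidateGeneSet.FLAG_COLS)
    altered = set(tbl.index[tbl[flag_cols].any(axis=1)])
    flags = {
        g: tuple(c for c in flag_cols if tbl.at[g, c])
        for g in altered
    }
    members = {r.subpathway_id: set(str(r.members).split(";")) for r in risk.itertuples(index=False)}
    sources = _source_sets(risk)

    sig = ct[ct["fdr"] < cfg.rwr.fdr_cut] if len(ct) else ct
    assignments = []
    for row in sig.itertuples(index=False):
        a, b = row.pathway_a, row.pathway_b
        assignments.append(classify_linkers_leaders(
            (a, b), sources[a], sources[b], members[a], members[b],
            altered, net, flags=flags,
        ))
    frames = [a.to_frame() for a in assignments]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["pathway_a", "pathway_b", "gene", "role", "situation",
                 "alteration_flags"])
    out.to_csv(cfg.out_dir / "linkers_leaders.tsv", sep="\t", index=False)
    summary = summarize_linkers(assignments)
    with open(cfg.out_dir / "linkers_summary.json", "w") as fh:
        json.dump({
            "n_unique_linkers": summary["n_unique_linkers"],
            "n_unique_leaders": summary["n_unique_leaders"],
            "per_pair_stats": summary["per_pair_stats"],
        }, fh, indent=1)


_STAGE_FUNCS = {
    "candidates": _run_candidates,
    "subpathways": _run_subpathways,
    "crosstalk": _run_crosstalk,
    "linkers": _run_linkers,
}


# ---------------------------------------------------------------------------
# in-memory end-to-end


def discover_crosstalk(bundle, pathways, ppi, resampling=None, subpathway=None,
                       rwr_params=None, seed=0):
    """Run the whole discovery chain in memory on already-loaded objects.

    Convenience mirror of :func:`run_all` without files: candidate calling,
    subpathway enrichment, cross-talk significance. Returns a dict with the
    candidate set, risk subpathways, the scored pair table and the PPI LCC.
    """
    resampling = resampling or ResamplingParams()
    subpathway = subpathway or SubpathwayParams()
    rwr_params = rwr_params or RwrParams()

    de = resampled_differential_test(
        bundle.expression, ResamplingParams(**{**asdict(resampling), "seed": seed}))
    dm = resampled_differential_test(
        bundle.methylation, ResamplingParams(**{**asdict(resampling), "seed": seed + 1}))
    mut = filter_nonsilent_mutations(bundle.mutations)
    cand = integrate_candidates(de, dm, bundle.cna, mut)

    candidates = set(cand.candidates)
    located = []
    for pw in pathways:
        located.extend(locate_subpathways(pw, candidates, subpathway))
    background = (
        set().union(*(pw.nodes for pw in pathways)) & set(bundle.expression.gene_ids)
        if pathways else set()
    )
    risk = call_risk_pathways(
        score_subpathways(located, candidates, background), subpathway)

    net = iof.largest_connected_component(ppi)
    sources = {sp.id: set(sp.candidate_members) for sp in risk}
    results = None
    if len(sources) >= 2:
        results = crosstalk_significance(
            net, sources, RwrParams(**{**asdict(rwr_params), "seed": seed + 2}))
    return {
        "candidates": cand,
        "risk_subpathways": risk,
        "crosstalk": results,
        "network": net,
        "sources": sources,
    }


# ---------------------------------------------------------------------------
# drivers


def run_stage(cfg: RunConfig, stage: str, force: bool = False,
              _manifest: dict | None = None) -> bool:
    """Run one stage; returns True if work was done, False if up to date.

    Validates input paths before any computation and refuses to run on
    stale upstream outputs when invoked standalone.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    cfg.validate_inputs(_STAGE_INPUTS[stage])
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _manifest if _manifest is not None else _load_manifest(cfg)
    _check_upstream_fresh(cfg, manifest, stage)
    if not force and _stage_is_current(cfg, manifest, stage):
        logger.info("stage %s is up to date; skipping", stage)
        return False
    t0 = time.perf_counter()
    in_hashes = _stage_input_hashes(cfg, stage)
    _STAGE_FUNCS[stage](cfg)
    manifest["stages"][stage] = {
        "config": _stage_config(cfg, stage),
        "inputs": in_hashes,
        "outputs": {f: _sha256(cfg.out_dir / f) for f in _STAGE_OUTPUTS[stage]},
        "seconds": round(time.perf_counter() - t0, 3),
    }
    manifest["config"] = cfg.snapshot()
    _save_manifest(cfg, manifest)
    return True


def run_all(cfg: RunConfig, force: bool = False) -> dict:
    """Run all stages in order; the manifest is written even on failure."""
    cfg.validate_inputs(_INPUT_KEYS)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(cfg)
    for stage in STAGES:
        try:
            run_stage(cfg, stage, force=force, _manifest=manifest)
        except Exception:
            manifest.setdefault("failed_stage", stage)
            _save_manifest(cfg, manifest)
            logger.error("pipeline aborted in stage %r", stage)
            raise
    manifest.pop("failed_stage", None)
    _save_manifest(cfg, manifest)
    return manifest
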