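"""End-to-end orchestration: simulate → consensus → tracks → enrichment →
landscape → stabilise → cluster, from one configuration.

Each stage records its parameters and the SHA-256 of every file it writes
into a JSON run report, so a rerun with the same configuration can be
verified byte-for-byte.  Stages are cached by a content hash of their inputs
and parameters (disable with ``no_cache=True``); a failed stage aborts the
run and leaves partial outputs under a ``failed`` marker in the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .clustering import cluster_summary, pam_cluster, preprocess_matrix
from .enrichment import permutation_enrichment
from .intervals import (
    GenomicInterval,
    IntervalSet,
    k_of_n_consensus,
    overlap_count,
    overlap_percent,
    promoter_windows,
    read_bed,
    read_chrom_sizes,
    read_gene_table,
    venn3_counts,
    write_bed,
)
from .landscape import build_integration_matrix, transition_distribution
from .simulate import SimulationConfig, simulate_all
from .stabilisation import stability_report
from .tracks import binned_rpm, median_track, tss_metaprofile

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters for one pipeline run.

    ``simulation`` drives the synthetic-data stage; alternatively
    ``inputs`` may point at existing files (chrom_sizes, genes, peaks per
    cell/replicate, marks, expression, de) with the same layout the
    simulator writes.
    """

    outdir: str = "g4scape_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    inputs: dict | None = None
    k_tech: int = 2
    k_bio: int = 2
    n_perm: int = 1000
    enrichment_seed: int = 0
    flank: int = 1000
    cluster_k: int = 6
    cluster_seed: int = 0
    metaprofile_window: int = 1000

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], Mapping):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    def validate(self) -> None:
        if self.inputs is not None:
            required = ("chrom_sizes", "genes", "peaks", "marks", "expression", "de")
            for key in required:
                if key not in self.inputs:
                    raise ValueError(f"inputs.{key} is missing")
            for key in ("chrom_sizes", "genes"):
                if not Path(self.inputs[key]).exists():
                    raise ValueError(f"inputs.{key}: no such file {self.inputs[key]!r}")
            for cell, reps in self.inputs["peaks"].items():
                for rep, path in reps.items():
                    if not Path(path).exists():
                        raise ValueError(
                            f"inputs.peaks.{cell}.{rep}: no such file {path!r}"
                        )
            for cell, marks in self.inputs["marks"].items():
                for mk, path in marks.items():
                    if not Path(path).exists():
                        raise ValueError(
                            f"inputs.marks.{cell}.{mk}: no such file {path!r}"
                        )
        if not (1 <= self.k_tech and 1 <= self.k_bio):
            raise ValueError("k_tech and k_bio must be >= 1")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(params: Mapping[str, Any], input_hashes: list[str]) -> str:
    payload = json.dumps(
        {"params": params, "inputs": sorted(input_hashes)}, sort_keys=True, default=str
    )
    return hashlib.sha256(payload.encode()).hexdigest()


class _Reporter:
    def __init__(self, outdir: Path, no_cache: bool):
        self.outdir = outdir
        self.no_cache = no_cache
        self.stages: dict[str, dict] = {}
        self.cache_path = outdir / ".stage_cache.json"
        self.cache: dict[str, str] = {}
        if not no_cache and self.cache_path.exists():
            try:
                self.cache = json.loads(self.cache_path.read_text())
            except json.JSONDecodeError:
                self.cache = {}

    def cached(self, stage: str, key: str, outputs: list[Path]) -> bool:
        return (
            not self.no_cache
            and self.cache.get(stage) == key
            and all(p.exists() for p in outputs)
        )

    def record(self, stage: str, params: Mapping, outputs: list[Path],
               key: str, elapsed: float, extra: Mapping | None = None) -> None:
        self.stages[stage] = {
            "params": dict(params),
            "outputs": {str(p.relative_to(self.outdir)): _sha256(p) for p in outputs},
            "elapsed_s": round(elapsed, 3),
        }
        if extra:
            self.stages[stage].update(extra)
        self.cache[stage] = key
        self.cache_path.write_text(json.dumps(self.cache, indent=2))


def run_pipeline(config: RunConfig, no_cache: bool = False) -> dict:
    """Run all stages in dependency order; return (and write) the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rep = _Reporter(outdir, no_cache)
    report: dict = {"version": __version__, "outdir": str(outdir), "stages": rep.stages}
    current = "?"
    try:
        ctx: dict[str, Any] = {}
        for current, fn in (
            ("simulate", _stage_simulate),
            ("consensus", _stage_consensus),
            ("tracks", _stage_tracks),
            ("enrichment", _stage_enrichment),
            ("landscape", _stage_landscape),
            ("stabilise", _stage_stabilise),
            ("cluster", _stage_cluster),
        ):
            t0 = time.perf_counter()
            fn(config, outdir, rep, ctx, t0)
    except Exception as exc:
        report["failed"] = {"stage": current, "error": str(exc)}
        (outdir / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
        raise
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


# --------------------------------------------------------------------------- stages


def _resolve_paths(node: Any, base: Path) -> Any:
    """Prefix every path-valued leaf of a manifest with the base directory."""
    if isinstance(node, dict):
        return {k: _resolve_paths(v, base) for k, v in node.items()}
    if isinstance(node, list):
        return [_resolve_paths(v, base) for v in node]
    if isinstance(node, str):
        return str(base / node)
    return node


def _stage_simulate(config: RunConfig, outdir: Path, rep: _Reporter, ctx: dict, t0: float) -> None:
    sim = config.simulation
    if config.inputs is not None:
        ctx["manifest"] = config.inputs
        return
    sim_dir = outdir / "sim"
    params = sim.to_dict()
    key = _params_hash(params, [])
    manifest_path = sim_dir / "manifest.json"
    if rep.cached("simulate", key, [manifest_path]):
        ctx["manifest"] = _resolve_paths(json.loads(manifest_path.read_text()), sim_dir)
        rep.stages["simulate"] = {"params": params, "outputs": {}, "cached": True}
        return
    manifest = simulate_all(sim, sim_dir)
    manifest_path.write_text(json.dumps(manifest, indent=2))
    ctx["manifest"] = _resolve_paths(manifest, sim_dir)
    outputs = [manifest_path, sim_dir / manifest["chrom_sizes"], sim_dir / manifest["genes"]]
    rep.record("simulate", params, outputs, key, time.perf_counter() - t0)


def _load_common(config: RunConfig, ctx: dict) -> None:
    if "assembly" in ctx:
        return
    man = ctx["manifest"]
    ctx["assembly"] = read_chrom_sizes(man["chrom_sizes"])
    ctx["genes"] = read_gene_table(man["genes"])


def _stage_consensus(config: RunConfig, outdir: Path, rep: _Reporter, ctx: dict, t0: float) -> None:
    _load_common(config, ctx)
    man = ctx["manifest"]
    assembly = ctx["assembly"]
    cons_dir = outdir / "consensus"
    cons_dir.mkdir(exist_ok=True)
    params = {"k_tech": config.k_tech, "k_bio": config.k_bio}
    in_hashes = [
        _sha256(p) for reps in man["peaks"].values() for p in reps.values()
    ]
    key = _params_hash(params, in_hashes)
    cells = list(man["peaks"])
    out_paths = [cons_dir / f"{cell}_consensus.bed" for cell in cells]
    summary_path = cons_dir / "overlap_summary.tsv"
    if rep.cached("consensus", key, out_paths + [summary_path]):
        ctx["consensus"] = {
            cell: read_bed(p, assembly, f"{cell}_consensus")
            for cell, p in zip(cells, out_paths)
        }
        rep.stages["consensus"] = {"params": params, "outputs": {}, "cached": True}
        return

    consensus: dict[str, IntervalSet] = {}
    for cell in cells:
        by_bio: dict[int, list[IntervalSet]] = {}
        for rep_name, path in man["peaks"][cell].items():
            if rep_name == "truth" or "truth" in str(path):
                continue
            b = int(rep_name.split("t")[0].lstrip("b"))
            by_bio.setdefault(b, []).append(read_bed(path, assembly))
        bio_consensus = [
            k_of_n_consensus(techs, config.k_tech) for _, techs in sorted(by_bio.items())
        ]
        consensus[cell] = k_of_n_consensus(bio_consensus, config.k_bio)
        consensus[cell].name = f"{cell}_consensus"
    for cell, path in zip(cells, out_paths):
        write_bed(consensus[cell], path)
    ctx["consensus"] = consensus

    # pairwise overlap percentages and three-way tallies
    rows = []
    for a in cells:
        for b in cells:
            if a == b:
                continue
            c = overlap_count(consensus[a], consensus[b])
            rows.append(
                {
                    "query": a,
                    "target": b,
                    "n_query": len(consensus[a].dedup()),
                    "n_overlapping": c,
                    "percent": overlap_percent(c, len(consensus[a].dedup())),
                }
            )
    pd.DataFrame(rows).to_csv(summary_path, sep="\t", index=False)
    extra = {}
    if len(cells) == 3:
        venn = venn3_counts(*(consensus[c] for c in cells))
        extra["venn3"] = {p: dict(v) for p, v in venn.items()}
        (cons_dir / "venn3.json").write_text(json.dumps(extra["venn3"], indent=2))
    rep.record(
        "consensus",
        params,
        out_paths + [summary_path],
        key,
        time.perf_counter() - t0,
        extra,
    )


def _stage_tracks(config: RunConfig, outdir: Path, rep: _Reporter, ctx: dict, t0: float) -> None:
    _load_common(config, ctx)
    man = ctx["manifest"]
    assembly = ctx["assembly"]
    sim = config.simulation
    tracks_dir = outdir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    params = {"bin_size": sim.bin_size, "window": config.metaprofile_window}
    reads_map = man.get("reads", {})
    in_hashes = [_sha256(p) for paths in reads_map.values() for p in paths]
    key = _params_hash(params, in_hashes)

    # per-cell bin-wise median across replicate tracks (kept in memory for the
    # integration matrix; only the metaprofiles are materialised)
    ctx["g4_tracks"] = {}
    out_paths = []
    for cell, paths in reads_map.items():
        reps = [
            binned_rpm(read_bed(p, assembly), sim.bin_size, sim.library_size)
            for p in paths
        ]
        ctx["g4_tracks"][cell] = median_track(reps) if len(reps) > 1 else reps[0]
        offsets, profile, excluded = tss_metaprofile(
            ctx["g4_tracks"][cell], ctx["genes"], config.metaprofile_window
        )
        path = tracks_dir / f"{cell}_tss_metaprofile.tsv"
        pd.DataFrame({"offset": offsets, "median_rpm": profile}).to_csv(
            path, sep="\t", index=False
        )
        out_paths.append(path)
    if out_paths:
        rep.record("tracks", params, out_paths, key, time.perf_counter() - t0)
    else:
        rep.stages["tracks"] = {"params": params, "outputs": {}, "skipped": "no reads"}


def _stage_enrichment(config: RunConfig, outdir: Path, rep: _Reporter, ctx: dict, t0: float) -> None:
    _load_common(config, ctx)
    assembly = ctx["assembly"]
    enr_dir = outdir / "enrichment"
    enr_dir.mkdir(exist_ok=True)
    params = {"n_perm": config.n_perm, "seed": config.enrichment_seed,
              "flank": config.flank}
    key = _params_hash(params, [rep.cache.get("consensus", "")])
    path = enr_dir / "enrichment.tsv"

    workspace = IntervalSet(
        [GenomicInterval(c, 0, L) for c, L in assembly.items()], assembly, "genome"
    )
    promoters, _ = promoter_windows(ctx["genes"], assembly, config.flank)
    rows = []
    for cell, cons in ctx["consensus"].items():
        res = permutation_enrichment(
            cons, promoters, workspace,
            n_perm=config.n_perm, seed=config.enrichment_seed,
        )
        rows.append({"query": f"{cell}_G4_consensus", "annotation": "promoters",
                     **res.as_row()})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    rep.record("enrichment", params, [path], key, time.perf_counter() - t0)


def _read_expression(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def _stage_landscape(config: RunConfig, outdir: Path, rep: _Reporter, ctx: dict, t0: float) -> None:
    _load_common(config, ctx)
    man = ctx["manifest"]
    assembly = ctx["assembly"]
    land_dir = outdir / "landscape"
    land_dir.mkdir(exist_ok=True)
    params = {"flank": config.flank}
    key = _params_hash(params, [rep.cache.get("consensus", "")])

    k4 = {c: read_bed(m["k4"], assembly) for c, m in man["marks"].items()}
    k27 = {c: read_bed(m["k27"], assembly) for c, m in man["marks"].items()}
    expr = {c: _read_expression(p) for c, p in man["expression"].items()}
    matrix = build_integration_matrix(
        ctx["genes"],
        assembly,
        ctx["consensus"],
        k4,
        k27,
        expression=expr,
        g4_tracks=ctx.get("g4_tracks") or None,
        embryonic=config.simulation.embryonic,
        flank=config.flank,
    )
    matrix_path = land_dir / "integration_matrix.tsv"
    matrix.to_csv(matrix_path, sep="\t")
    ctx["matrix"] = matrix

    out_paths = [matrix_path]
    emb = config.simulation.embryonic
    for daughter in [c for c in ctx["consensus"] if c != emb]:
        for start in ("bivalent", "H3K4me3"):
            tbl = transition_distribution(matrix, start, daughter, embryonic=emb)
            p = land_dir / f"transitions_{start}_{daughter}.tsv"
            tbl.to_csv(p, sep="\t", index=False)
            out_paths.append(p)
    rep.record("landscape", params, out_paths, key, time.perf_counter() - t0)


def _stage_stabilise(config: RunConfig, outdir: Path, rep: _Reporter, ctx: dict, t0: float) -> None:
    man = ctx["manifest"]
    stab_dir = outdir / "stabilise"
    stab_dir.mkdir(exist_ok=True)
    params = {}
    key = _params_hash(params, [rep.cache.get("landscape", "")])
    matrix = ctx["matrix"]
    emb = config.simulation.embryonic
    out_paths = []
    summary: dict[str, dict] = {}
    for daughter, de_path in man["de"].items():
        de = pd.read_csv(de_path, sep="\t", comment="#", index_col=0)
        report = stability_report(matrix, daughter, embryonic=emb, de_table=de)
        p = stab_dir / f"{daughter}_groups.tsv"
        report.group_stats.to_csv(p, sep="\t")
        out_paths.append(p)
        if report.de_proportions is not None:
            p2 = stab_dir / f"{daughter}_de_proportions.tsv"
            report.de_proportions.to_csv(p2, sep="\t")
            out_paths.append(p2)
        summary[daughter] = {
            "r2_ranking": report.r2_ranking(),
            "comparisons": [
                {
                    "reference": c.group_a,
                    "group": c.group_b,
                    "F": c.F,
                    "p_one_tailed": c.p_one_tailed,
                }
                for c in report.comparisons
            ],
        }
        ctx.setdefault("stability", {})[daughter] = report
    summary_path = stab_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    out_paths.append(summary_path)
    rep.record("stabilise", params, out_paths, key, time.perf_counter() - t0)


def _stage_cluster(config: RunConfig, outdir: Path, rep: _Reporter, ctx: dict, t0: float) -> None:
    clus_dir = outdir / "cluster"
    clus_dir.mkdir(exist_ok=True)
    params = {"k": config.cluster_k, "seed": config.cluster_seed}
    key = _params_hash(params, [rep.cache.get("landscape", "")])
    matrix = ctx["matrix"]
    cells = list(ctx["consensus"])
    cols = [f"tpm_{c}" for c in cells] + [
        f"g4_rpm_{c}" for c in cells if f"g4_rpm_{c}" in matrix.columns
    ]
    cols = [c for c in cols if c in matrix.columns]
    values = matrix[cols].to_numpy(dtype=float)
    ok = ~np.isnan(values).any(axis=1)
    values = values[ok]
    gene_ids = matrix.index[ok]
    std = preprocess_matrix(values)
    result = pam_cluster(std, k=config.cluster_k, seed=config.cluster_seed)
    assign_path = clus_dir / "assignments.tsv"
    pd.DataFrame(
        {"gene_id": gene_ids, "cluster": result.assignments}
    ).to_csv(assign_path, sep="\t", index=False)
    summary_path = clus_dir / "cluster_summary.tsv"
    cluster_summary(values, result.assignments, cols).to_csv(
        summary_path, sep="\t", index=False
    )
    rep.record(
        "cluster",
        params,
        [assign_path, summary_path],
        key,
        time.perf_counter() - t0,
        {"total_cost": result.total_cost, "n_swaps": result.n_swaps},
    )
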