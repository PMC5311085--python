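"""Reproducible simulate -> stats -> design -> coreset -> evaluate pipeline.

A single YAML config holds one section per stage so that every threshold
(missingness 5%, 100 kb coverage window, r^2 0.1 in a 50-SNP window, MAF
0.05, K genotyping bins, B genetic bins) lives in one auditable place.
Reruns with the same config and seed reproduce byte-identical TSV outputs;
the manifest records the config snapshot, seeds, output digests, stage
timings and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coreset import CoreSetSelector, differential_locus_rate
from .design import DesignConfig, PanelDesign, assemble_panel, even_coverage_select, filter_candidates
from .errors import ConfigError, PipelineError
from .matrix import GenotypeMatrix, write_matrix_tsv, write_vcf
from .simulate import SimConfig, simulate_panel
from .stats import folded_sfs_2d, ibs_distance_matrix, ld_decay_curve, sample_rates, variant_stats

log = logging.getLogger("snppanel")

_SECTIONS = {"simulate", "stats", "design", "coreset", "evaluate"}


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    digests: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping of stage sections")
    unknown = set(raw) - _SECTIONS - {"seed"}
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    for section, cls in (("simulate", SimConfig), ("design", DesignConfig)):
        params = raw.get(section) or {}
        legal = {f.name for f in dataclasses.fields(cls)}
        bad = set(params) - legal
        if bad:
            raise ConfigError(f"unknown field(s) in [{section}]: {sorted(bad)}")
    return raw


def _write_tsv(df, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")


def run_pipeline(config_path: str | Path, out_dir: str | Path, seed: int | None = None) -> RunManifest:
    """Execute all five stages, leaving TSV artifacts and a manifest in out_dir."""
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    manifest = RunManifest(config=cfg, seed=seed, version=__version__)
    t0 = time.time()

    # --- simulate ---
    sim_cfg = SimConfig(**(cfg.get("simulate") or {}))
    sim_cfg.seed = seed
    matrix, truth = simulate_panel(sim_cfg)
    write_matrix_tsv(matrix, out / "matrix.tsv")
    write_vcf(matrix, out / "matrix.vcf")
    truth_df = pd.DataFrame(
        {
            "variant_id": matrix.variant_ids,
            "chrom": truth.chroms,
            "pos": truth.positions,
            "ancestral_freq": truth.ancestral_freq,
            "freq_temperate": truth.pop_freq_temperate,
            "freq_tropical": truth.pop_freq_tropical,
        }
    ).set_index("variant_id")
    _write_tsv(truth_df, out / "truth.tsv")
    manifest.timings["simulate"] = time.time() - t0
    manifest.stage_counts["simulated_variants"] = matrix.n_variants
    log.info("simulate: %d samples x %d variants", matrix.n_samples, matrix.n_variants)

    # --- stats ---
    t1 = time.time()
    stats_cfg = cfg.get("stats") or {}
    vstats = variant_stats(matrix)
    _write_tsv(vstats, out / "variant_stats.tsv")
    per_sample, _ = sample_rates(matrix)
    _write_tsv(per_sample, out / "sample_stats.tsv")
    dm = ibs_distance_matrix(matrix)
    _write_tsv(dm.to_dataframe(), out / "ibs_distance.tsv")
    sfs = folded_sfs_2d(matrix, n_bins=int(stats_cfg.get("sfs_bins", 20)))
    _write_tsv(pd.DataFrame(sfs), out / "sfs_2d.tsv")
    curve = ld_decay_curve(
        matrix,
        max_distance=int(stats_cfg.get("ld_max_distance", 500_000)),
        bin_width=int(stats_cfg.get("ld_bin_width", 50_000)),
    )
    _write_tsv(curve.to_dataframe(), out / "ld_curve.tsv")
    manifest.timings["stats"] = time.time() - t1

    # --- design ---
    t2 = time.time()
    design_cfg = DesignConfig(**(cfg.get("design") or {}))
    candidates = filter_candidates(matrix, design_cfg)
    manifest.stage_counts["design_filtered"] = len(candidates)
    covered, gaps = even_coverage_select(matrix, candidates, design_cfg)
    manifest.stage_counts["design_coverage"] = len(covered)
    sources = {v.id: v.source for v in matrix.variants}
    by_source: dict = {}
    for vid in covered:
        by_source.setdefault(sources[vid], []).append(vid)
    panel = assemble_panel(sorted(by_source.items(), key=lambda kv: kv[0].value), matrix, design_cfg)
    if not panel.selected:
        raise PipelineError("design stage produced an empty panel")
    manifest.stage_counts["design_panel"] = len(panel.selected)
    pd.DataFrame({"id": panel.selected}).to_csv(out / "panel.tsv", sep="\t", index=False)
    panel.provenance.to_csv(out / "provenance.tsv", sep="\t", index=False)
    with open(out / "coverage_gaps.bed", "w") as fh:
        for chrom, start, end in gaps:
            fh.write(f"{chrom}\t{start}\t{end}\n")
    log.info("design: %d candidates -> %d covered -> %d panel", len(candidates), len(covered), len(panel.selected))
    manifest.timings["design"] = time.time() - t2

    # --- coreset ---
    t3 = time.time()
    core_cfg = cfg.get("coreset") or {}
    selector = CoreSetSelector(
        k=int(core_cfg.get("k", 100)),
        b=int(core_cfg.get("b", 200)),
        n_sets=int(core_cfg.get("n_sets", 2)),
        iterations=int(core_cfg.get("iterations", 1000)),
        complementary=bool(core_cfg.get("complementary", True)),
        random_state=seed,
    )
    panel_matrix = matrix.subset(variant_ids=panel.selected)
    selector.fit(panel_matrix)
    result = selector.result_
    sets_df = pd.DataFrame(
        [(s_i, vid) for s_i, ids in enumerate(result.sets) for vid in ids],
        columns=["set", "id"],
    )
    sets_df.to_csv(out / "core_sets.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "set": list(range(len(result.sets))) + ["union"],
            "genotyping_coverage": result.genotyping_coverage + [result.genotyping_coverage_union],
            "genetic_coverage": result.genetic_coverage + [result.genetic_coverage_union],
        }
    ).to_csv(out / "core_coverage.tsv", sep="\t", index=False)
    traj_df = pd.DataFrame(
        [(s_i, t_i, f) for s_i, tr in enumerate(result.fitness_trajectories) for t_i, f in enumerate(tr)],
        columns=["set", "iteration", "fitness"],
    )
    traj_df.to_csv(out / "core_trajectory.tsv", sep="\t", index=False)
    manifest.stage_counts["core_set_size"] = len(result.sets[0]) if result.sets else 0
    manifest.timings["coreset"] = time.time() - t3

    # --- evaluate ---
    t4 = time.time()
    core_ids = sorted({vid for ids in result.sets for vid in ids})
    _, core_summary = differential_locus_rate(matrix, core_ids)
    _, full_summary = differential_locus_rate(matrix, panel.selected)
    pd.DataFrame(
        [
            {"marker_set": "core_union", **core_summary},
            {"marker_set": "full_panel", **full_summary},
        ]
    ).to_csv(out / "evaluation.tsv", sep="\t", index=False)
    manifest.timings["evaluate"] = time.time() - t4

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest.digests[f.name] = _sha256(f)
    manifest.write(out / "manifest.json")
    return manifest
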