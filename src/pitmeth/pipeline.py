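"""End-to-end orchestration of the methylome and CNV analyses.

Stages run in the fixed order probe filter -> shared-probe intersection ->
BMIQ normalization -> SVD covariate screen -> batch correction ->
{clustering, PCA, differential methylation} -> GSEA, with the CNV branch
(log ratios -> bins -> segments -> arm calls -> cumulative / burden /
Jaccard / oscillation summaries) running off the intensity matrix. A run
manifest records the configuration hash, seed, and per-output checksums so
identical configurations reproduce identical results.
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

from . import cluster as _cluster
from . import cnv as _cnv
from . import dmp as _dmp
from . import gsea as _gsea
from . import io as _io
from . import preprocess as _pre

logger = logging.getLogger("pitmeth")

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the published analysis settings."""

    # input paths
    beta_path: str | None = None
    detection_path: str | None = None
    intensity_path: str | None = None
    sheet_path: str | None = None
    manifest_path: str | None = None
    arms_path: str | None = None
    gmt_path: str | None = None
    output_dir: str = "pitmeth_out"

    # preprocessing
    detection_p_threshold: float = 0.01
    batch_field: str = "slide"
    protect_field: str = "group"
    n_svd_components: int = 5

    # clustering / DMP
    top_k: int = 5000
    p_threshold: float = 1.3e-7
    delta_threshold: float = 0.2
    contrasts: tuple = ((("APT", "PC"), ("benign",)), (("PC",), ("APT",)))

    # CNV
    cnv_reference_group: str = "benign"
    bin_size: int = 500_000
    min_bins: int = 5
    segment_alpha: float = 0.01
    segment_permutations: int = 200
    gain_cut: float = 0.1
    loss_cut: float = -0.1
    arm_fraction: float = 0.5
    frequent_pct: float = 50.0
    min_switches: int = 10

    # GSEA
    n_perm: int = 1000
    min_size: int = 15
    max_size: int = 500
    fdr: float = 0.05

    # run control
    first_surgery_only: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "contrasts" in raw:
            raw["contrasts"] = tuple(
                (tuple(a), tuple(b)) for a, b in raw["contrasts"]
            )
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    version: str
    config_hash: str
    seed: int
    started: str
    finished: str = ""
    stages: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _contrast_name(contrast) -> str:
    a, b = contrast
    return "+".join(a) + "_vs_" + "+".join(b)


def run_pipeline(
    config: PipelineConfig,
    *,
    beta: _pre.BetaMatrix | None = None,
    intensity: pd.DataFrame | None = None,
    sheet: pd.DataFrame | None = None,
    manifest: pd.DataFrame | None = None,
    arms: pd.DataFrame | None = None,
    collections: dict | None = None,
) -> dict:
    """Execute every stage; returns in-memory results and writes all outputs.

    Inputs may be passed in memory or loaded from the paths in ``config``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    run = RunManifest(
        version=__version__,
        config_hash=config.digest(),
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if beta is None:
        beta = _io.read_beta(config.beta_path, config.detection_path)
    if sheet is None:
        sheet = _io.read_sample_sheet(config.sheet_path)
    else:
        sheet = _pre.validate_sample_sheet(sheet)
    if manifest is None:
        manifest = _io.read_manifest(config.manifest_path)
    if intensity is None and config.intensity_path:
        intensity = _io.read_matrix(config.intensity_path)
    if arms is None and config.arms_path:
        arms = _io.read_arms_bed(config.arms_path)
    if collections is None and config.gmt_path:
        collections = _io.read_gmt(config.gmt_path)

    if config.first_surgery_only:
        keep = sheet.loc[sheet["first_surgery"].astype(bool), "sample"]
        sheet = sheet[sheet["sample"].isin(keep)].reset_index(drop=True)
        beta = beta.subset_samples(keep)
        if intensity is not None:
            intensity = intensity[list(keep)]
        logger.info("first-surgery mode: %d samples retained", len(keep))

    results: dict = {"config": config, "sheet": sheet}

    # --- methylome branch -------------------------------------------------
    filtered, report = _pre.filter_probes(beta, manifest, config.detection_p_threshold)
    run.stages.append("filter")
    results["filter_report"] = report
    _io.write_json(report.to_dict(), outdir / "filter_report.json")

    shared = _pre.shared_probes([filtered], manifest)
    run.stages.append("intersect")

    normalized = _pre.bmiq_normalize(shared, manifest)
    run.stages.append("normalize")

    n_comp = min(config.n_svd_components, len(normalized.samples) - 1)
    screen = _pre.svd_covariate_screen(normalized, sheet, n_comp)
    screen.to_csv(outdir / "svd_screen.csv")
    results["svd_screen"] = screen
    run.stages.append("svd_screen")

    n_batches = sheet[config.batch_field].nunique()
    if n_batches >= 2:
        corrected = _pre.combat_correct(
            normalized, sheet, config.batch_field, config.protect_field
        )
    else:
        corrected = normalized
    results["beta"] = corrected
    run.stages.append("batch_correct")

    top = _cluster.select_top_variable(corrected, config.top_k)
    dendro = _cluster.cluster_samples(top)
    (outdir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    pca = _cluster.pca_embed(top, n_components=3)
    pca.coordinates.assign(
        **{f"var_pct_{i+1}": v for i, v in enumerate(pca.variance_explained)}
    ).to_csv(outdir / "pca.csv")
    results.update(dendrogram=dendro, pca=pca)
    run.stages.append("cluster")

    results["dmp"] = {}
    cfg = _dmp.DMPConfig(config.p_threshold, config.delta_threshold)
    for contrast in config.contrasts:
        name = _contrast_name(contrast)
        stats = _dmp.moderated_stats(corrected, sheet, contrast, manifest=manifest)
        table, counts = _dmp.call_dmps(stats, cfg)
        table.to_csv(outdir / f"dmp_{name}.csv", index_label="probe")
        _dmp.volcano_data(table).to_csv(outdir / f"volcano_{name}.csv", index_label="probe")
        results["dmp"][name] = {"table": table, "counts": counts}
        logger.info("contrast %s: %d significant DMPs (%d hyper / %d hypo), n=%d vs %d",
                    name, counts["total"], counts["hyper"], counts["hypo"],
                    int(table["n_a"].iloc[0]), int(table["n_b"].iloc[0]))
    run.stages.append("dmp")

    if collections:
        contrast = config.contrasts[-1]
        name = _contrast_name(contrast)
        ranked = _gsea.build_ranked_genes(results["dmp"][name]["table"], manifest)
        gsea_table = _gsea.run_gsea(
            ranked, collections, n_perm=config.n_perm, min_size=config.min_size,
            max_size=config.max_size, fdr=config.fdr, seed=config.seed,
        )
        gsea_table.to_csv(outdir / f"gsea_{name}.csv", index=False)
        results["gsea"] = gsea_table
        run.stages.append("gsea")

    # --- CNV branch -------------------------------------------------------
    if intensity is not None and arms is not None:
        ref = sheet.loc[sheet["group"] == config.cnv_reference_group, "sample"]
        lr = _cnv.compute_log_ratios(intensity, ref)
        binned = _cnv.bin_signal(lr, manifest, config.bin_size)
        segments = _cnv.segment_bins(
            binned, config.min_bins, config.segment_alpha,
            config.segment_permutations, seed=config.seed,
        )
        _io.write_seg(_cnv.segments_to_frame(segments), outdir / "segments.seg")
        calls = _cnv.call_arm_states(
            segments, arms, config.gain_cut, config.loss_cut,
            config.arm_fraction, samples=list(beta.samples),
        )
        calls.to_csv(outdir / "arm_calls.csv", index=False)
        profile = _cnv.cumulative_profile(calls, sheet)
        profile.to_csv(outdir / "cumulative_profile.csv", index=False)
        burden, burden_summary = _cnv.arm_burden_summary(calls, sheet)
        burden.to_csv(outdir / "arm_burden.csv")
        burden_summary.to_csv(outdir / "arm_burden_summary.csv", index=False)
        dist, cnv_dendro = _cnv.jaccard_cluster(calls)
        dist.to_csv(outdir / "jaccard_distance.csv")
        (outdir / "cnv_dendrogram.nwk").write_text(cnv_dendro.to_newick() + "\n")
        flags = _cnv.chromothripsis_flags(segments, config.min_switches,
                                          config.gain_cut, config.loss_cut)
        flags.to_csv(outdir / "chromothripsis_flags.csv", index=False)
        results.update(
            segments=segments, arm_calls=calls, cumulative_profile=profile,
            arm_burden=burden, arm_burden_summary=burden_summary,
            jaccard_distance=dist, cnv_dendrogram=cnv_dendro,
            chromothripsis=flags,
        )
        run.stages.append("cnv")

    run.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    run.checksums = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "run_manifest.json"
    }
    _io.write_json(run.to_dict(), outdir / "run_manifest.json")
    results["run_manifest"] = run
    return results
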