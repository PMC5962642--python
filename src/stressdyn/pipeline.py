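"""End-to-end orchestration of the screen analysis.

Stages run in a fixed order — annotation → (simulate) → descriptors →
timecourse → bmc → classify → report — each reading the previous stage's
delimited outputs from the run directory and writing its own, plus a JSON run
manifest capturing the configuration snapshot, master seed, package version,
and content hashes of every stage output. A stage whose inputs and
configuration hash to the same values as in an existing manifest is skipped
and its cached outputs reused, so the slow classifier stage can be re-run
alone. Re-running a completed pipeline with the same seed reproduces
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import load_packaged_annotations, read_compound_table, to_frame
from .classify import ClassifierConfig, run_iterations, stability_report
from .descriptors import compute_cytotox_summary, compute_descriptor_table, max_summary_table
from .dose_response import bmc_class_lm, bmc_class_welch, fit_bmc_table
from .features import build_feature_matrix
from .simulate import EffectConfig, LayoutConfig, read_cells, simulate_screen, write_cells
from .timecourse import (
    CONTROL_COMPOUNDS,
    HEADLINE_DESCRIPTOR,
    anova_table,
    condense_descriptor_table,
    courses_by_reporter,
    linkage_to_newick,
    multireporter_distance,
    ward_cluster,
)

STAGES = ["annotation", "simulate", "descriptors", "timecourse", "bmc", "classify"]


@dataclass
class PipelineConfig:
    out_dir: str | Path = "pipeline_out"
    seed: int = 0
    annotation_path: str | Path | None = None  # None -> packaged compound set
    simulate: bool = True
    cells_path: str | Path | None = None  # required when simulate is False
    n_compounds: int | None = None  # subsample (stratified head) for speed
    effect: EffectConfig = field(default_factory=EffectConfig)
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    n_perm: int = 999
    n_clusters: int = 4
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    n_iterations: int = 200
    test_fraction: float = 0.2


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_dict(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        return obj

    return enc(config)


def run_pipeline(config: PipelineConfig, resume: bool = True) -> dict:
    """Execute all stages and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "run_manifest.json"
    previous = {}
    if resume and manifest_path.exists():
        previous = json.loads(manifest_path.read_text())

    cfg = _config_dict(config)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": cfg,
        "stages": [],
    }

    def stage_key(name: str, inputs: list[Path]) -> str:
        h = hashlib.sha256()
        h.update(json.dumps(cfg.get(name, cfg), sort_keys=True, default=str).encode())
        h.update(json.dumps(cfg, sort_keys=True, default=str).encode())
        for p in inputs:
            h.update(_file_hash(p).encode())
        return h.hexdigest()

    def cached(name: str, key: str, outputs: list[Path]) -> bool:
        for st in previous.get("stages", []):
            if st["name"] == name and st["key"] == key:
                return all(Path(p).exists() for p in st["outputs"])
        return False

    def record(name: str, key: str, inputs: list[Path], outputs: list[Path]) -> None:
        manifest["stages"].append(
            {
                "name": name,
                "key": key,
                "inputs": {str(p): _file_hash(p) for p in inputs},
                "outputs": [str(p) for p in outputs],
                "output_hashes": {str(p): _file_hash(p) for p in outputs},
            }
        )
        manifest_path.write_text(json.dumps(manifest, indent=2))

    def run_stage(name: str, inputs: list[Path], outputs: list[Path], fn) -> None:
        key = stage_key(name, inputs)
        if not cached(name, key, outputs):
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise StageError(name, exc) from exc
        record(name, key, inputs, outputs)

    # --- annotation ---------------------------------------------------------
    ann_out = out / "annotations.csv"
    counts_out = out / "class_counts.csv"

    def _annotation():
        if config.annotation_path is not None:
            anns = read_compound_table(config.annotation_path)
        else:
            anns = load_packaged_annotations()
        df = to_frame(anns)
        if config.n_compounds is not None:
            drugs = df[~df["is_control"]]
            picked = (
                drugs.groupby("severity", group_keys=False)
                .apply(
                    lambda g: g.head(
                        max(1, round(config.n_compounds * len(g) / len(drugs)))
                    ),
                    include_groups=False,
                )
            )
            df = pd.concat([df.loc[picked.index], df[df["is_control"]]])
        df.to_csv(ann_out, index=False)
        counts = (
            df[~df["is_control"]].groupby(["dili_concern", "severity"]).size()
            .rename("n").reset_index()
        )
        counts.to_csv(counts_out, index=False)

    inputs = [Path(config.annotation_path)] if config.annotation_path else []
    run_stage("annotation", inputs, [ann_out, counts_out], _annotation)

    # --- simulate -----------------------------------------------------------
    cells_out = out / "cells.csv"
    truth_out = out / "truth.csv"

    if config.simulate:
        def _simulate():
            anns = read_compound_table(ann_out)
            cells, truth = simulate_screen(
                anns, config.effect, config.layout, rng_seed=config.seed
            )
            write_cells(cells, cells_out)
            truth.to_csv(truth_out, index=False)

        run_stage("simulate", [ann_out], [cells_out, truth_out], _simulate)
        cells_path = cells_out
    else:
        if config.cells_path is None:
            raise StageError(
                "simulate", ValueError("simulation disabled and no cells_path given")
            )
        cells_path = Path(config.cells_path)

    # --- descriptors --------------------------------------------------------
    desc_out = out / "descriptors.csv"
    cyto_out = out / "cytotox.csv"

    def _descriptors():
        cells = read_cells(cells_path)
        compute_descriptor_table(cells).to_csv(desc_out, index=False)
        compute_cytotox_summary(cells).to_csv(cyto_out, index=False)

    run_stage("descriptors", [cells_path], [desc_out, cyto_out], _descriptors)

    # --- timecourse ---------------------------------------------------------
    cond_out = out / "condensed.csv"
    anova_out = out / "anova.csv"
    dist_out = out / "distance_matrix.txt"
    clust_out = out / "clusters.csv"
    tree_out = out / "dendrogram.nwk"

    def _timecourse():
        desc = pd.read_csv(desc_out)
        condensed = condense_descriptor_table(desc)
        condensed.to_csv(cond_out, index=False)
        anova_table(desc, n_perm=config.n_perm, rng_seed=config.seed).to_csv(
            anova_out, index=False
        )
        courses = courses_by_reporter(condensed)
        dist = multireporter_distance(courses)
        dist.to_csv(dist_out, sep="\t")
        labels, z = ward_cluster(dist, k=min(config.n_clusters, len(dist) - 1))
        pd.DataFrame({"compound": dist.index, "cluster": labels}).to_csv(
            clust_out, index=False
        )
        tree_out.write_text(linkage_to_newick(z, list(dist.index)) + "\n")

    run_stage(
        "timecourse", [desc_out], [cond_out, anova_out, dist_out, clust_out, tree_out],
        _timecourse,
    )

    # --- bmc ----------------------------------------------------------------
    bmc_out = out / "bmc.csv"
    bmc_stats_out = out / "bmc_class_stats.csv"

    def _bmc():
        desc = pd.read_csv(desc_out)
        ann = pd.read_csv(ann_out)
        cmax = dict(zip(ann["abbreviation"], ann["cmax_uM"]))
        severity = dict(zip(ann["abbreviation"], ann["severity"]))
        summaries = max_summary_table(desc)
        summaries = summaries[~summaries["compound"].isin(CONTROL_COMPOUNDS)]
        head = summaries[
            summaries.apply(
                lambda r: HEADLINE_DESCRIPTOR.get(r["reporter"]) == r["descriptor"],
                axis=1,
            )
        ]
        table = fit_bmc_table(head, cmax)
        table["severity"] = table["compound"].map(severity)
        table.to_csv(bmc_out, index=False)
        rows = []
        for reporter, sub in table.groupby("reporter"):
            welch = bmc_class_welch(sub["bmc_over_cmax"], sub["severity"])
            row = {"reporter": reporter, **{f"welch_{k}": v for k, v in welch.items()}}
            try:
                lm = bmc_class_lm(
                    sub["bmc_xcmax"],
                    sub["compound"].map(cmax),
                    sub["severity"],
                )
                row.update({f"lm_{k}": v for k, v in lm.items()})
            except ValueError:
                pass
            rows.append(row)
        pd.DataFrame(rows).to_csv(bmc_stats_out, index=False)

    run_stage("bmc", [desc_out, ann_out], [bmc_out, bmc_stats_out], _bmc)

    # --- classify -----------------------------------------------------------
    feat_out = out / "features.csv"
    manifest_feat_out = out / "feature_manifest.csv"
    clf_out = out / "classifier_summary.json"
    stab_out = out / "feature_stability.csv"
    pred_out = out / "compound_predictions.csv"

    def _classify():
        condensed = pd.read_csv(cond_out)
        cyto = pd.read_csv(cyto_out)
        bmc = pd.read_csv(bmc_out)
        ann = pd.read_csv(ann_out)
        cmax = dict(zip(ann["abbreviation"], ann["cmax_uM"]))
        x, feat_manifest = build_feature_matrix(condensed, cyto, bmc, cmax)
        x.to_csv(feat_out)
        feat_manifest.to_csv(manifest_feat_out, index=False)
        severity = ann.set_index("abbreviation")["severity"]
        y = severity.loc[x.index]
        runs, summary = run_iterations(
            x, y, n_iter=config.n_iterations, test_fraction=config.test_fraction,
            rng_seed=config.seed, config=config.classifier,
        )
        report = stability_report(runs, x.columns, x.index)
        clf_out.write_text(json.dumps(summary, indent=2))
        report.selection_counts.rename("selected").to_frame().assign(
            stable=lambda d: d["selected"] > 0.75 * len(runs)
        ).to_csv(stab_out)
        report.compound_correct_fraction.rename("correct_fraction").to_csv(pred_out)

    run_stage(
        "classify", [cond_out, cyto_out, bmc_out, ann_out],
        [feat_out, manifest_feat_out, clf_out, stab_out, pred_out], _classify,
    )

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
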