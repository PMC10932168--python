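"""End-to-end pipeline: simulate -> score -> associate -> express -> tree -> select.

Orchestrates the analysis stages over a cohort table (generated or read
from CSV), writing every result as tab-separated text with a comment
header carrying the seed and configuration hash, plus a JSON run
manifest.  Identical configuration and seed produce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, association, cohort, expression, scoring, selection, tree

STAGES = ("simulate", "score", "associate", "express", "tree", "select")


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    Either ``cohort_csv`` points at an existing cohort table or
    ``simulation`` configures the generator.  ``rank_mode`` picks the
    repair-rank scale (``quartile`` = rebuilt from the cohort's controls,
    ``fixed`` = published edges); ``zero_cell`` picks the odds-ratio
    zero-cell policy (``na`` or ``haldane``).
    """

    out_dir: str | Path = "results"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    cohort_csv: str | Path | None = None
    simulation: cohort.CohortConfig | None = None
    rank_mode: str = "quartile"
    zero_cell: str = "na"
    max_splits: int = 20
    selection_methods: tuple[str, ...] = ("sfs", "sbs", "chi2", "mrmr",
                                          "relieff")

    def resolved_simulation(self) -> cohort.CohortConfig:
        if self.simulation is not None:
            return self.simulation
        config = cohort.default_config(seed=self.seed)
        config.seed = self.seed
        return config


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _config_hash(run: RunConfig) -> str:
    sim = run.resolved_simulation() if (run.simulation or not run.cohort_csv) \
        else None
    blob = json.dumps({
        "seed": run.seed, "stages": list(run.stages),
        "rank_mode": run.rank_mode, "zero_cell": run.zero_cell,
        "max_splits": run.max_splits,
        "selection": list(run.selection_methods),
        "cohort_csv": str(run.cohort_csv) if run.cohort_csv else None,
        "simulation": cohort.config_to_yaml(sim) if sim else None,
    }, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_tsv(frame: pd.DataFrame, path: Path, header_meta: str) -> None:
    with open(path, "w") as fh:
        fh.write(header_meta)
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def build_feature_matrix(frame: pd.DataFrame, scored: pd.DataFrame,
                         snp_ids=None):
    """Integer-coded feature matrix for the classifier.

    ``x1`` is the repair-rank code 0-3 (3 = no repair); each SNP becomes
    one feature coded by its genotype's index in the observed sorted
    genotype list (reference-numbered-genotype coding).  Returns
    ``(X, y, feature_names, codings)``.
    """
    if snp_ids is None:
        snp_ids = [c for c in frame.columns if c.startswith("rs")]
    merged = frame.merge(scored[["subject_id", "x1"]], on="subject_id")
    columns = [merged["x1"].to_numpy(int)]
    names = ["x1"]
    codings: dict[str, dict] = {"x1": {i: i for i in range(4)}}
    for pos, snp in enumerate(snp_ids, start=2):
        levels = sorted(merged[snp].unique())
        mapping = {g: i for i, g in enumerate(levels)}
        columns.append(merged[snp].map(mapping).to_numpy(int))
        name = f"x{pos}"
        names.append(name)
        codings[name] = {"snp": snp, "levels": levels}
    X = np.column_stack(columns)
    y = (merged["arm"] == "case").to_numpy(int)
    return X, y, names, codings


def run_pipeline(run: RunConfig) -> dict:
    """Execute the toggled stages and return the manifest dictionary."""
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_hash = _config_hash(run)
    meta = f"# dsbrepair {__version__}  seed={run.seed}  config={config_hash}\n"
    manifest: dict = {
        "package": "dsbrepair", "version": __version__,
        "seed": run.seed, "config_hash": config_hash,
        "stages": list(run.stages), "rank_mode": run.rank_mode,
        "zero_cell": run.zero_cell, "max_splits": run.max_splits,
        "outputs": {},
    }

    def register(name: str, path: Path):
        manifest["outputs"][name] = {
            "path": path.name,
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }

    # --- cohort ---------------------------------------------------------
    stage = "simulate"
    try:
        if run.cohort_csv is not None:
            frame = cohort.read_cohort_csv(run.cohort_csv)
        else:
            sim = run.resolved_simulation()
            frame = cohort.generate_cohort_frame(sim)
            if stage in run.stages:
                path = out / "cohort.csv"
                cohort.write_cohort_csv(frame, path)
                cohort.config_to_yaml(sim, out / "cohort_config.yaml")
                register("cohort", path)
                register("cohort_config", out / "cohort_config.yaml")
    except Exception as exc:  # noqa: BLE001 - stage-named abort
        raise StageError(stage, exc) from exc

    scored = None
    if {"score", "associate", "tree", "select"} & set(run.stages):
        stage = "score"
        try:
            scored = scoring.score_cohort(frame, mode=run.rank_mode)
            counts = scoring.group_count_table(scored)
            if stage in run.stages:
                path = out / "scores.csv"
                scored.to_csv(path, index=False, float_format="%.6g")
                register("scores", path)
                table = counts.reset_index(names="arm")
                _write_tsv(table, out / "group_counts.tsv", meta)
                register("group_counts", out / "group_counts.tsv")
        except Exception as exc:
            raise StageError(stage, exc) from exc

    if "associate" in run.stages:
        stage = "associate"
        try:
            rows = []
            for res in association.repeff_crude_ors(
                    counts, zero_cell=run.zero_cell):
                rows.append({"factor": "RepEff", "level": res.label,
                             "reference": res.reference_label,
                             "or": res.or_value, "ci_low": res.ci_low,
                             "ci_high": res.ci_high,
                             "display": association.format_or(res)})
            _write_tsv(pd.DataFrame(rows), out / "repeff_or.tsv", meta)
            register("repeff_or", out / "repeff_or.tsv")

            rows = []
            snp_ids = [c for c in frame.columns if c.startswith("rs")]
            for snp in snp_ids:
                table = association.genotype_counts_from_cohort(frame, snp)
                if (table.sum(axis=1) == 0).all():
                    continue
                try:
                    results = association.genotype_or_table(
                        table, zero_cell=run.zero_cell)
                except ValueError as err:
                    warnings.warn(f"{snp}: {err}")
                    continue
                for res in results:
                    rows.append({
                        "snp": snp, "genotype": res.label,
                        "reference": res.reference_label,
                        "n_control": int(table.loc[res.label, "control"]),
                        "n_case": int(table.loc[res.label, "case"]),
                        "or": res.or_value, "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "display": association.format_or(res)})
            _write_tsv(pd.DataFrame(rows), out / "genotype_or.tsv", meta)
            register("genotype_or", out / "genotype_or.tsv")
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc

    if "express" in run.stages:
        stage = "express"
        try:
            genes = sorted({c[:-len("_ct_target")] for c in frame.columns
                            if c.endswith("_ct_target")})
            summary = expression.expression_summary(frame, genes)
            _write_tsv(summary, out / "expression.tsv", meta)
            register("expression", out / "expression.tsv")
        except Exception as exc:
            raise StageError(stage, exc) from exc

    X = y = names = None
    if {"tree", "select"} & set(run.stages):
        X, y, names, codings = build_feature_matrix(frame, scored)

    if "tree" in run.stages:
        stage = "tree"
        try:
            fitted = tree.fit_tree(X, y, max_splits=run.max_splits,
                                   feature_names=names)
            (out / "tree_rules.txt").write_text(
                meta + tree.tree_to_rules(fitted) + "\n")
            register("tree_rules", out / "tree_rules.txt")
            (out / "tree.json").write_text(fitted.to_json(indent=2) + "\n")
            register("tree", out / "tree.json")
            metrics = tree.loocv(X, y, max_splits=run.max_splits)
            metrics_frame = pd.DataFrame([{"inputs": "all", **metrics.as_dict()}])
            x1_metrics = tree.loocv(X[:, [0]], y, max_splits=run.max_splits)
            metrics_frame = pd.concat([
                pd.DataFrame([{"inputs": "x1", **x1_metrics.as_dict()}]),
                metrics_frame], ignore_index=True)
            _write_tsv(metrics_frame, out / "metrics.tsv", meta)
            register("metrics", out / "metrics.tsv")
            (out / "feature_coding.json").write_text(
                json.dumps(codings, default=str, indent=2) + "\n")
            register("feature_coding", out / "feature_coding.json")
        except Exception as exc:
            raise StageError(stage, exc) from exc

    if "select" in run.stages:
        stage = "select"
        try:
            evaluator = selection.dt_loocv_evaluator(run.max_splits)
            if "sfs" in run.selection_methods:
                trace = selection.sfs(X, y, evaluator)
                _write_tsv(trace.to_frame(), out / "sfs_trace.tsv", meta)
                register("sfs_trace", out / "sfs_trace.tsv")
            if "sbs" in run.selection_methods:
                trace = selection.sbs(X, y, evaluator)
                _write_tsv(trace.to_frame(), out / "sbs_trace.tsv", meta)
                register("sbs_trace", out / "sbs_trace.tsv")
            score_frames = []
            for method, func in (("chi2", selection.chi2_scores),
                                 ("mrmr", selection.mrmr_rank),
                                 ("relieff", selection.relieff_weights)):
                if method not in run.selection_methods:
                    continue
                scores = func(X, y, feature_names=names)
                sf = scores.to_frame()
                sf.insert(0, "method", method)
                score_frames.append(sf)
            if score_frames:
                _write_tsv(pd.concat(score_frames, ignore_index=True),
                           out / "feature_scores.tsv", meta)
                register("feature_scores", out / "feature_scores.tsv")
        except Exception as exc:
            raise StageError(stage, exc) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True)
                             + "\n")
    return manifest
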