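"""Pipeline driver: configuration, stage ordering and artifact writing.

The pipeline mirrors the study flow: simulate (or load) a cohort, derive FRET
covariates from lifetime images, fit the latent-class survival model, reduce
covariates, build and evaluate the class-prediction signature, and test class
overlap by permutation.  Each stage draws its randomness from a named
substream of the single global seed, so rerunning a stage reproduces its
output regardless of which other stages ran.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._rng import child_seed
from .cohort import Cohort
from . import io as io_mod
from . import latent_class, permutation, reduction, signature, survival, synthetic

log = logging.getLogger("flimlca")

__all__ = ["PipelineConfig", "run_pipeline"]

_KNOWN_KEYS = {
    "cohort_path", "image_dir", "outdir", "seed", "stages",
    "simulate", "flim", "lca", "reduce", "signature", "permtest",
}
_STAGES = ("simulate", "flim", "lca", "reduce", "signature", "permtest")


@dataclass
class PipelineConfig:
    outdir: str
    cohort_path: str | None = None
    image_dir: str | None = None
    seed: int = 0
    stages: list = field(default_factory=lambda: list(_STAGES))
    simulate: dict = field(default_factory=dict)   # n_patients, separation ...
    flim: dict = field(default_factory=dict)       # window, min_pixels ...
    lca: dict = field(default_factory=dict)        # covariates, k, n_bins ...
    reduce: dict = field(default_factory=dict)
    signature: dict = field(default_factory=dict)
    permtest: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in _KNOWN_KEYS if hasattr(self, k)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # hash the analysis configuration, not where it is written
    cfg = {k: v for k, v in config.to_dict().items()
           if k not in ("outdir", "cohort_path", "image_dir")}
    seed = int(config.seed)
    manifest: dict = {"stages": {}}
    failed: set[str] = set()

    def record(stage, status, t0, **extra):
        manifest["stages"][stage] = {"status": status,
                                     "seconds": round(_time.time() - t0, 3),
                                     **extra}

    cohort: Cohort | None = None

    # --- simulate ---------------------------------------------------------
    if "simulate" in config.stages:
        t0 = _time.time()
        try:
            opts = dict(config.simulate)
            spec = synthetic.coin_os_spec(
                n_patients=int(opts.pop("n_patients", 398)),
                separation=float(opts.pop("separation", 1.0)),
                seed=child_seed(seed, "simulate"))
            cohort = synthetic.simulate_cohort(spec)
            io_mod.write_cohort(cohort, outdir / "cohort.tsv")
            record("simulate", "ok", t0, n=cohort.n)
        except Exception as exc:
            log.exception("simulate failed")
            record("simulate", f"failed: {exc}", t0)
            failed.add("simulate")
    if cohort is None and config.cohort_path:
        cohort = io_mod.read_cohort(config.cohort_path)
    if cohort is None and "simulate" not in failed and "simulate" not in config.stages:
        raise ValueError("no cohort: enable the simulate stage or set cohort_path")

    # --- flim -------------------------------------------------------------
    if "flim" in config.stages and cohort is not None:
        t0 = _time.time()
        try:
            from . import flim as flim_mod
            opts = dict(config.flim)
            window = tuple(opts.get("window", flim_mod.DEFAULT_LIFETIME_WINDOW))
            # regenerate matched image pairs for each patient from the cohort's
            # FRET covariate and re-derive the covariate through the image chain
            results = {}
            fret_col = cohort.covariates(["fret"]) if "fret" in cohort.table else None
            for i, pid in enumerate(cohort.patient_id):
                e_true = float(fret_col.iloc[i, 0]) if fret_col is not None else 0.01
                scene = synthetic.coin_os_flim_scene(
                    max(e_true, 0.0), seed=child_seed(seed, "flim", i),
                    shape=tuple(opts.get("shape", (48, 48))))
                pair, _truth = synthetic.simulate_flim_pair(scene)
                filtered, _rep = flim_mod.filter_lifetimes(pair, window)
                results[pid] = flim_mod.fret_efficiency(filtered)
            per_region = flim_mod.fret_results_table(results)
            per_region.to_csv(outdir / "fret_regions.tsv", sep="\t", index=False)
            per_patient = flim_mod.patient_fret_covariates(results)
            per_patient.rename(columns={"fret": "fret_imaged"}, inplace=True)
            cohort = cohort.with_columns(
                per_patient[["patient_id", "fret_imaged"]])
            io_mod.write_cohort(cohort, outdir / "cohort.tsv")
            record("flim", "ok", t0, n_patients=len(results))
        except Exception as exc:
            log.exception("flim failed")
            record("flim", f"failed: {exc}", t0)
            failed.add("flim")

    # --- lca --------------------------------------------------------------
    model = assignment = None
    if "lca" in config.stages and cohort is not None:
        t0 = _time.time()
        try:
            opts = dict(config.lca)
            covs = opts.pop("covariates",
                            ["trt", "ras_mut", "fret", "fret_x_her3"])
            model, assignment = latent_class.fit_latent_class_model(
                cohort, covs, k=int(opts.pop("k", 2)),
                n_bins=int(opts.pop("n_bins", 4)),
                n_restarts=int(opts.pop("n_restarts", 8)),
                seed=child_seed(seed, "lca"), **opts)
            io_mod.write_report({"model": model.to_dict()},
                                outdir / "lca_model.json", seed=seed, config=cfg)
            assignment.table(cohort.patient_id).to_csv(
                outdir / "lca_assignment.tsv", sep="\t", index=False)
            hr = latent_class.hazard_ratios(model)
            hr.to_csv(outdir / "lca_hazard_ratios.tsv", sep="\t", index=False)
            record("lca", "ok", t0, bic=model.bic)
        except Exception as exc:
            log.exception("lca failed")
            record("lca", f"failed: {exc}", t0)
            failed.add("lca")

    # --- reduce -----------------------------------------------------------
    reduced = None
    if "reduce" in config.stages and cohort is not None:
        t0 = _time.time()
        try:
            opts = dict(config.reduce)
            covs = opts.pop("covariates", cohort.covariate_names)
            reduced = reduction.reduce_covariates(
                cohort, covs, folds=int(opts.pop("folds", 5)),
                repeats=int(opts.pop("repeats", 10)),
                seed=child_seed(seed, "reduce"), **opts)
            io_mod.write_report({
                "elimination_order": reduced.elimination_order,
                "selected": reduced.selected,
                "selection_frequency": reduced.selection_frequency,
                "cv_score_trace": reduced.cv_score_trace,
                "settings": reduced.settings,
            }, outdir / "reduction.json", seed=seed, config=cfg)
            record("reduce", "ok", t0, n_selected=len(reduced.selected))
        except Exception as exc:
            log.exception("reduce failed")
            record("reduce", f"failed: {exc}", t0)
            failed.add("reduce")

    # --- signature --------------------------------------------------------
    sig = None
    if "signature" in config.stages and cohort is not None:
        t0 = _time.time()
        if assignment is None and "lca" in config.stages:
            record("signature", "skipped: lca failed", t0)
        else:
            try:
                opts = dict(config.signature)
                covs = opts.pop("covariates", None)
                if covs is None:
                    covs = (reduced.selected if reduced and reduced.selected
                            else cohort.covariate_names)
                labels = assignment.map_label
                sig = signature.fit_signature(cohort, labels, covs)
                s = signature.score(sig, cohort)
                roc = signature.roc_youden(s, labels == 2)
                sig.threshold = roc.youden_threshold
                (outdir / "signature.json").write_text(sig.to_json())
                report = signature.evaluate_signature(
                    sig, cohort, arm_col="trt" if "trt" in cohort.table else None)
                report["roc"] = {"auc": roc.auc,
                                 "youden_threshold": roc.youden_threshold,
                                 "sensitivity": roc.youden_sensitivity,
                                 "specificity": roc.youden_specificity}
                io_mod.write_report(report, outdir / "signature_eval.json",
                                    seed=seed, config=cfg)
                record("signature", "ok", t0, auc=roc.auc)
            except Exception as exc:
                log.exception("signature failed")
                record("signature", f"failed: {exc}", t0)
                failed.add("signature")

    # --- permtest ---------------------------------------------------------
    if "permtest" in config.stages and cohort is not None:
        t0 = _time.time()
        if assignment is None or sig is None:
            record("permtest", "skipped: upstream stage missing", t0)
        else:
            try:
                opts = dict(config.permtest)
                pred = signature.predict_class(sig, cohort)
                res = permutation.overlap_test(
                    assignment.map_label, pred,
                    n_permutations=int(opts.pop("n_permutations", 10000)),
                    seed=child_seed(seed, "permtest"))
                io_mod.write_report({
                    "observed_statistic": res.observed_statistic,
                    "n_permutations": res.n_permutations,
                    "n_null_ge_observed": res.n_null_ge_observed,
                    "p_value": res.p_value,
                }, outdir / "permutation.json", seed=seed, config=cfg)
                record("permtest", "ok", t0, p=res.p_value)
            except Exception as exc:
                log.exception("permtest failed")
                record("permtest", f"failed: {exc}", t0)

    io_mod.write_report(manifest, outdir / "manifest.json", seed=seed, config=cfg)
    return manifest
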