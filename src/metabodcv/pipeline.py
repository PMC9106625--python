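"""End-to-end pipeline driver: simulate -> preprocess -> double-CV ->
downstream -> RT annotation, with a hashed run manifest.

Every intermediate artifact is delimited text written with fixed float
formatting, so re-running with the same configuration reproduces every
output hash bit-for-bit.  All randomness flows from the single global seed
through per-stage derived seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import preprocess as pp
from .annotation_rt import consistency_report, fit_rt_model, load_reference_lipids
from .dcv import DCVConfig, run_repeated_dcv, stability_select
from .downstream import associate_outcomes, cluster_metabolites, mediate, pca_profile
from .errors import MetabodcvError
from .synthetic import SimConfig, generate_study, inject_batch_and_drift
from .tables import (
    FLOAT_FORMAT,
    FeatureTable,
    clinical_changes,
    write_clinical_table,
    write_feature_table,
)

log = logging.getLogger(__name__)

#: outcomes entered into the mediation analysis (glycaemic insulin excluded:
#: profile scores summarize a lipid-driven contrast)
MEDIATION_OUTCOMES = ["total_c", "tg", "ldl_c", "hdl_c", "glucose"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    The default scale is a small demonstration study (25 subjects/arm, 150
    features, 30 double-CV repeats) that exercises every stage in about a
    minute; pass a custom :class:`SimConfig`/:class:`DCVConfig` for larger
    studies.
    """

    sim: SimConfig = field(
        default_factory=lambda: SimConfig(
            n_subjects_per_arm=25,
            n_features_per_mode=(75, 75),
            n_discriminating=10,
            n_blank_features=5,
            n_isotope_pairs=5,
        )
    )
    dcv: DCVConfig = field(default_factory=lambda: DCVConfig(n_repeats=30))
    blank_ratio: float = 0.5
    rt_min: float = 0.3
    rt_max: float = 9.42
    mz_tol: float = 0.01
    rt_tol: float = 0.01
    iso_corr_min: float = 0.7
    drift_span: float = 0.75
    group_rt_window: float = 0.01
    group_corr_min: float = 0.7
    n_boot: int = 2000
    seed: int = 0
    outdir: str = "metabodcv_run"

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim = SimConfig(**raw.pop("sim", {}))
        if isinstance(sim.n_features_per_mode, list):
            sim.n_features_per_mode = tuple(sim.n_features_per_mode)
        dcv = DCVConfig(**raw.pop("dcv", {}))
        return cls(sim=sim, dcv=dcv, **raw)


def derive_stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Per-stage seeds derived from the single global seed (all < 2^31)."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1, np.uint64)[0] % 2**31) for c in children]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read().replace(b"\r\n", b"\n"))
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir):
        self.outdir = outdir
        self.stages = []

    def record(self, stage, params, outputs, t0, status="ok", note=""):
        self.stages.append(
            {
                "stage": stage,
                "status": status,
                "note": note,
                "params": params,
                "outputs": {os.path.basename(p): _sha256(p) for p in outputs},
                "duration_s": round(time.time() - t0, 3),
            }
        )

    def write(self):
        path = os.path.join(self.outdir, "manifest.json")
        with open(path, "w") as fh:
            json.dump({"stages": self.stages}, fh, indent=1, sort_keys=True)
        return path

    @property
    def all_ok(self):
        return all(s["status"] == "ok" for s in self.stages)

    def output_hashes(self):
        return {s["stage"]: s["outputs"] for s in self.stages}


def _write_tsv(df: pd.DataFrame, path: str, index=True):
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def preprocess_table(table: FeatureTable, cfg: RunConfig):
    """Run the full cleanup on a two-mode feature table.

    Each ionization mode is filtered (blank -> RT window -> mass defect ->
    isotopes/duplicates), batch- and drift-corrected and grouped separately;
    the modes are then concatenated and baseline-subtracted.  Returns the
    change table and the list of filter reports.
    """
    reports = []
    per_mode = []
    for mode in ("positive", "negative"):
        sub = table.subset_features(table.features.index[table.features["mode"] == mode])
        if len(sub.features) == 0:
            continue
        sub, rep = pp.filter_blank_features(sub, cfg.blank_ratio)
        reports.append((mode, rep))
        sub, rep = pp.filter_rt_window(sub, cfg.rt_min, cfg.rt_max)
        reports.append((mode, rep))
        sub, rep = pp.filter_early_mass_defect(sub)
        reports.append((mode, rep))
        sub, rep = pp.remove_isotopes_duplicates(sub, cfg.mz_tol, cfg.rt_tol, cfg.iso_corr_min)
        reports.append((mode, rep))
        sub = pp.batch_correct(sub)
        sub = pp.drift_correct(sub, cfg.drift_span)
        sub, rep = pp.group_features(sub, cfg.group_rt_window, cfg.group_corr_min)
        reports.append((mode, rep))
        per_mode.append(sub)
    if len(per_mode) == 2:
        merged = pp.concatenate_modes(per_mode[0], per_mode[1])
    else:
        merged = per_mode[0]
    change = pp.baseline_subtract(merged)
    return change, reports


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict.

    A stage failure is recorded in the manifest (status ``failed``) and
    aborts the remaining stages; partial outputs are retained.
    """
    os.makedirs(config.outdir, exist_ok=True)
    manifest = _Manifest(config.outdir)
    seeds = derive_stage_seeds(config.seed)
    results: dict = {}

    def path(name):
        return os.path.join(config.outdir, name)

    try:
        # ---- simulate ----------------------------------------------------
        t0 = time.time()
        sim_cfg = SimConfig(**{**asdict(config.sim), "rng_seed": seeds[0]})
        sim_cfg.n_features_per_mode = tuple(sim_cfg.n_features_per_mode)
        table, clinical, truth = generate_study(sim_cfg)
        table = inject_batch_and_drift(table, sim_cfg)
        write_feature_table(table, path("features.tsv"), path("samples.tsv"))
        write_clinical_table(clinical, path("clinical.tsv"))
        truth.to_json(path("ground_truth.json"))
        manifest.record(
            "simulate",
            {"seed": seeds[0], "n_subjects_per_arm": sim_cfg.n_subjects_per_arm},
            [path(f) for f in ("features.tsv", "samples.tsv", "clinical.tsv", "ground_truth.json")],
            t0,
        )
        results["truth"] = truth

        # ---- preprocess --------------------------------------------------
        t0 = time.time()
        change, reports = preprocess_table(table, config)
        write_feature_table(change, path("change_matrix.tsv"), path("change_samples.tsv"))
        rep_frames = []
        for mode, rep in reports:
            df = rep.to_frame()
            df.insert(0, "mode", mode)
            rep_frames.append(df)
        _write_tsv(pd.concat(rep_frames, ignore_index=True), path("filter_reports.tsv"), index=False)
        manifest.record(
            "preprocess",
            {"blank_ratio": config.blank_ratio, "rt_window": [config.rt_min, config.rt_max]},
            [path(f) for f in ("change_matrix.tsv", "change_samples.tsv", "filter_reports.tsv")],
            t0,
        )
        results["change"] = change

        # ---- double cross-validation ------------------------------------
        t0 = time.time()
        X = change.intensities.T  # subjects x features
        arm = change.samples.loc[X.index, "arm"]
        y = np.where(arm == "Ex", 1.0, -1.0)
        dcv_cfg = DCVConfig(**{**asdict(config.dcv), "rng_seed": seeds[1]})
        dcv_res = run_repeated_dcv(
            X.to_numpy(float), y, dcv_cfg,
            subject_ids=list(X.index), variable_ids=list(X.columns),
        )
        panel = stability_select(dcv_res)
        _write_tsv(dcv_res.per_repeat_frame(), path("dcv_repeats.tsv"), index=False)
        _write_tsv(dcv_res.selection_frequency.to_frame(), path("selection_frequency.tsv"))
        pd.Series(panel, name="feature_id").to_csv(path("panel.tsv"), sep="\t", index=False)
        manifest.record(
            "dcv",
            {"seed": seeds[1], "n_repeats": dcv_cfg.n_repeats,
             "mean_test_er": round(dcv_res.mean_er, 6),
             "mean_test_auc": round(dcv_res.mean_auc, 6),
             "panel_size": len(panel)},
            [path(f) for f in ("dcv_repeats.tsv", "selection_frequency.tsv", "panel.tsv")],
            t0,
        )
        results["dcv"] = dcv_res
        results["panel"] = panel

        # ---- downstream --------------------------------------------------
        t0 = time.time()
        if len(panel) < 2:  # too small for a profile; fall back to top-frequency features
            panel_eff = list(dcv_res.selection_frequency.nlargest(10).index)
            log.warning("stability panel has %d features; using top-10 frequency set", len(panel))
        else:
            panel_eff = panel
        profile = pca_profile(X[panel_eff])
        changes = clinical_changes(clinical)
        assoc = associate_outcomes(profile, changes)
        med_rows = []
        t = (changes.loc[profile.scores.index, "arm"] == "Ex").astype(float).to_numpy()
        for comp in profile.scores.columns:
            for outcome in MEDIATION_OUTCOMES:
                m = mediate(
                    t,
                    profile.scores[comp].to_numpy(),
                    changes.loc[profile.scores.index, outcome].to_numpy(),
                    n_boot=config.n_boot,
                    seed=seeds[2],
                )
                med_rows.append(
                    {"outcome": outcome, "mediator": comp, "acme": m.acme,
                     "acme_lo": m.acme_ci[0], "acme_hi": m.acme_ci[1],
                     "ade": m.ade, "total": m.total, "prop_mediated": m.prop_mediated}
                )
        rho, mask, Z, leaves = cluster_metabolites(X[panel_eff])
        _write_tsv(profile.scores, path("profile_scores.tsv"))
        _write_tsv(assoc, path("associations.tsv"), index=False)
        _write_tsv(pd.DataFrame(med_rows), path("mediation.tsv"), index=False)
        _write_tsv(rho, path("panel_spearman.tsv"))
        _write_tsv(pd.DataFrame(Z, columns=["left", "right", "dist", "size"]), path("panel_linkage.tsv"), index=False)
        manifest.record(
            "downstream",
            {"seed": seeds[2],
             "pc12_variance_pct": round(100 * float(profile.explained_variance_ratio[:2].sum()), 3)},
            [path(f) for f in ("profile_scores.tsv", "associations.tsv", "mediation.tsv",
                               "panel_spearman.tsv", "panel_linkage.tsv")],
            t0,
        )
        results["profile"] = profile
        results["associations"] = assoc
        results["mediation"] = pd.DataFrame(med_rows)

        # ---- RT annotation ----------------------------------------------
        t0 = time.time()
        species = load_reference_lipids()
        rt_model = fit_rt_model(species, "PC")
        report = consistency_report(rt_model, species[species["lipid_class"] == "PC"])
        coef = pd.DataFrame(
            {"term": ["intercept", "carbons", "double_bonds"],
             "estimate": [rt_model.intercept, rt_model.beta_carbons, rt_model.beta_double_bonds],
             "se": rt_model.se}
        )
        _write_tsv(coef, path("rt_model.tsv"), index=False)
        _write_tsv(report, path("rt_consistency.tsv"), index=False)
        manifest.record(
            "annotate_rt",
            {"lipid_class": "PC", "beta_carbons": round(rt_model.beta_carbons, 6),
             "beta_double_bonds": round(rt_model.beta_double_bonds, 6)},
            [path(f) for f in ("rt_model.tsv", "rt_consistency.tsv")],
            t0,
        )
        results["rt_model"] = rt_model
    except MetabodcvError as exc:
        manifest.stages.append(
            {"stage": "failed", "status": "failed", "note": str(exc), "params": {},
             "outputs": {}, "duration_s": 0.0}
        )
        manifest.write()
        raise
    manifest.write()
    out = {"stages": manifest.stages, "all_ok": manifest.all_ok, "results": results}
    return out
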