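"""End-to-end orchestration: simulate -> preprocess -> TFR -> GLM/cluster
statistics -> coupling -> behaviour -> clinical correlation.

:func:`analyze_cohort` is the library entry point: it streams a simulated
cohort subject by subject (constant memory), runs every analysis stage and
returns a structured result; :func:`run_pipeline` wraps it with a validated
:class:`RunConfig`, artifact checksums and a machine-readable JSON report so
a run can be reproduced exactly from its report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from .core import CLINICAL_TESTS, ClinicalScores
from .coupling import (PACGrid, fit_trial_coupling_model, group_coupling_stats,
                       trial_granger, trial_pac)
from .glm import cluster_permutation, fit_single_trial_glm
from .preprocess import (CsdParams, bandpass_filter, csd_operator,
                         csd_transform, drop_artifact_trials)
from .simulate import EffectConfig, iter_cohort
from .spectral import db_baseline, morlet_tfr

__all__ = ["RunConfig", "analyze_cohort", "run_pipeline"]

DEFAULT_GLM_CHANNELS = ("Fz", "CP3", "P3", "Pz", "O1")


@dataclass
class RunConfig:
    """Parameters of a full pipeline run. Every random stage is seeded."""

    seed: int
    n_per_group: int = 2
    sfreq: float = 500.0
    effects: dict = field(default_factory=dict)
    filter_low: float = 0.1
    filter_high: float = 100.0
    artifact_threshold: float = 100.0
    csd_m: int = 4
    csd_lambda: float = 1e-5
    tfr_fmin: float = 2.0
    tfr_fmax: float = 20.0
    tfr_step: float = 1.0
    tfr_cycles: float = 5.0
    tfr_decim: int = 10
    glm_channels: tuple = DEFAULT_GLM_CHANNELS
    n_perm: int = 1000
    p_init: float = 0.05
    p_cluster: float = 0.05
    pac_grid: str = "reduced"
    pac_p_cluster: float = 0.01
    gc_window: tuple = (1.8, 3.8)
    gc_max_order: int = 10
    gc_fixed_order: int | None = None
    out_dir: str = "wmosc_run"
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if "seed" not in d:
            raise ValueError("config must provide an explicit seed")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["glm_channels"] = list(self.glm_channels)
        d["gc_window"] = list(self.gc_window)
        return d


def _checksum(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def analyze_cohort(config: RunConfig, progress: bool = False) -> dict:
    """Run the full analysis on a freshly simulated cohort.

    Returns a dict with per-subject first-level results (GLM t-maps, coupling
    model t-values), group-level cluster statistics for the memory-load and
    success regressors, GC/PAC group reports, behavioural reports and the
    clinical correlation. Group-level stages that need more subjects than the
    cohort provides are skipped with a reason rather than failing.
    """
    effects = EffectConfig.from_dict(config.effects) if config.effects \
        else EffectConfig()
    freqs = np.arange(config.tfr_fmin, config.tfr_fmax + 1e-9, config.tfr_step)
    csd_params = CsdParams(m=config.csd_m, lam=config.csd_lambda)
    grid = PACGrid.full() if config.pac_grid == "full" else PACGrid.reduced()
    pair = ("Fz", "CP3")

    subjects, groups = [], []
    ml_maps, smp_maps = [], []
    gc_models, pac_models, pac_means = [], [], []
    metas, clin_rows = {}, []
    retained = {}
    valid_mask = None

    for rec in iter_cohort(config.n_per_group, effects, seed=config.seed,
                           sfreq=config.sfreq):
        if progress:
            print(f"  subject {rec.subject} ({rec.group})")
        epochs = bandpass_filter(rec.epochs, config.filter_low,
                                 config.filter_high)
        epochs, n_dropped = drop_artifact_trials(epochs,
                                                 config.artifact_threshold)
        epochs = csd_transform(epochs, csd_params)
        retained[rec.subject] = epochs.n_trials

        tfr = morlet_tfr(epochs, freqs, n_cycles=config.tfr_cycles,
                         decim=config.tfr_decim,
                         channels=list(config.glm_channels))
        # baselines go through the same CSD operator as the epochs
        ch_idx = [epochs.channel_index(c) for c in config.glm_channels]
        op = csd_operator(epochs.montage, csd_params)
        base = dataclasses.replace(
            rec.baseline,
            segments=[(op @ s)[ch_idx] for s in rec.baseline.segments])
        tfr_db = db_baseline(tfr, base, n_cycles=config.tfr_cycles)
        glm_res = fit_single_trial_glm(tfr_db, epochs.meta)
        valid_mask = glm_res.valid
        ml_maps.append(glm_res.tmap("ml"))
        smp_maps.append(glm_res.tmap("smp"))

        gct = trial_granger(epochs, pair, window=tuple(config.gc_window),
                            max_order=config.gc_max_order,
                            fixed_order=config.gc_fixed_order)
        gc_models.append(fit_trial_coupling_model(gct.delta, epochs.meta))
        pac = trial_pac(epochs, pair, grid=grid)
        pac_models.append(fit_trial_coupling_model(pac.data, epochs.meta))
        pac_means.append(pac.data.mean(axis=0))

        subjects.append(rec.subject)
        groups.append(rec.group)
        metas[rec.subject] = epochs.meta
        clin_rows.append(rec.clinical.rename(rec.subject))

    groups_arr = np.asarray(groups)
    ml_maps = np.stack(ml_maps)       # (subj, ch, f, t)
    smp_maps = np.stack(smp_maps)
    result: dict = {
        "subjects": subjects, "groups": groups,
        "trials_retained": retained,
        "freqs": freqs, "glm_channels": list(config.glm_channels),
        "ml_tmaps": ml_maps, "smp_tmaps": smp_maps,
        "glm_valid": valid_mask,
    }

    enough = min((groups_arr == g).sum() for g in set(groups)) >= 5
    rng = np.random.default_rng(config.seed + 1)
    if enough:
        ml_clusters, smp_within = {}, {}
        hc = ml_maps[groups_arr == "HC"]
        ms = ml_maps[groups_arr == "MS"]
        for ci, ch in enumerate(config.glm_channels):
            ml_clusters[ch] = cluster_permutation(
                hc[:, ci], "between_groups", subject_maps_b=ms[:, ci],
                n_perm=config.n_perm, p_init=config.p_init,
                p_cluster=config.p_cluster, valid=valid_mask, rng=rng)
            smp_within[ch] = {
                g: cluster_permutation(
                    smp_maps[groups_arr == g][:, ci], "within_group_vs_zero",
                    n_perm=config.n_perm, p_init=config.p_init,
                    p_cluster=config.p_cluster, valid=valid_mask, rng=rng)
                for g in ("HC", "MS")}
        result["ml_between_clusters"] = ml_clusters
        result["smp_within_clusters"] = smp_within
        result["gc_group"] = group_coupling_stats(
            gc_models, groups, seed=config.seed + 2, n_perm=config.n_perm)
        result["pac_group"] = group_coupling_stats(
            pac_models, groups, seed=config.seed + 3, n_perm=config.n_perm,
            p_init=config.p_init, p_cluster=config.pac_p_cluster)
    else:
        reason = {"skipped": "fewer than 5 subjects per group"}
        result["ml_between_clusters"] = reason
        result["smp_within_clusters"] = reason
        result["gc_group"] = reason
        result["pac_group"] = reason
    result["gc_models"] = gc_models
    result["pac_models"] = pac_models
    result["pac_mean_maps"] = np.stack(pac_means)
    result["pac_grid"] = grid

    group_of = dict(zip(subjects, groups))
    result["accuracy"] = beh.accuracy_by_load(metas, group_of)
    result["rt"] = beh.rt_by_category(metas, group_of, load=6)

    clin = pd.DataFrame(clin_rows)
    scores = ClinicalScores(clin[["group"] + CLINICAL_TESTS]
                            if "group" in clin else clin)
    coupling_score = pd.Series(
        [m.tval("ml_x_smp") for m in gc_models], index=subjects)
    ms_subjects = [s for s, g in group_of.items() if g == "MS"]
    result["clinical"] = beh.clinical_correlation(
        coupling_score.loc[ms_subjects],
        ClinicalScores(scores.table.loc[ms_subjects]))
    result["clinical_all"] = beh.clinical_correlation(coupling_score, scores)
    return result


def _stage_summary(result: dict) -> dict:
    """JSON-serialisable per-stage summary of an analysis result."""
    def cluster_summary(cr):
        if isinstance(cr, dict):
            return cr
        return {"n_clusters": len(cr.clusters),
                "significant": [{"mass": c.mass, "p": c.p,
                                 "n_bins": len(c.bins)}
                                for c in cr.significant()]}

    summary = {
        "subjects": result["subjects"],
        "groups": result["groups"],
        "trials_retained": result["trials_retained"],
    }
    for key in ("ml_between_clusters", "smp_within_clusters"):
        val = result[key]
        if isinstance(val, dict) and "skipped" in val:
            summary[key] = val
        elif key == "ml_between_clusters":
            summary[key] = {ch: cluster_summary(cr) for ch, cr in val.items()}
        else:
            summary[key] = {ch: {g: cluster_summary(cr)
                                 for g, cr in d.items()}
                            for ch, d in val.items()}
    for key in ("gc_group", "pac_group"):
        val = result[key]
        if "skipped" in val:
            summary[key] = val
        else:
            out = {}
            for reg in val["regressors"]:
                out[reg] = {}
                for lab, entry in val[reg].items():
                    out[reg][lab] = {
                        k: v for k, v in entry.items()
                        if k != "cluster_result"}
            summary[key] = out
    summary["gc_interaction_t"] = {
        s: float(m.tval("ml_x_smp"))
        for s, m in zip(result["subjects"], result["gc_models"])}
    summary["clinical"] = result["clinical"]
    summary["accuracy_vs_chance"] = result["accuracy"]["vs_chance"]
    summary["rt_error_vs_correct"] = result["rt"]["error_vs_correct"]
    return summary


def run_pipeline(config: RunConfig, progress: bool = False) -> dict:
    """Execute the full pipeline and write a machine-readable run report.

    The report records every parameter and a checksum per major artifact;
    rerunning with the same config reproduces identical checksums. A stage
    failure is recorded in the report and downstream stages are skipped.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}}
    try:
        result = analyze_cohort(config, progress=progress)
    except Exception as err:  # noqa: BLE001 - reported, not swallowed silently
        report["stages"]["analysis"] = {"status": "failed", "error": str(err)}
        report["stages"]["downstream"] = {"status": "skipped"}
        (out_dir / "run_report.json").write_text(json.dumps(report, indent=2))
        raise
    report["stages"]["analysis"] = {"status": "ok"}
    report["checksums"] = {
        "ml_tmaps": _checksum(result["ml_tmaps"]),
        "smp_tmaps": _checksum(result["smp_tmaps"]),
        "gc_interaction_t": _checksum(np.array(
            [m.tval("ml_x_smp") for m in result["gc_models"]])),
    }
    report["summary"] = _stage_summary(result)
    (out_dir / "run_report.json").write_text(
        json.dumps(report, indent=2, default=_json_default))
    report["result"] = result
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serialisable: {type(obj)}")
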