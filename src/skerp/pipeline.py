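"""End-to-end orchestration: simulate, preprocess, classify, analyze.

A run is fully described by a :class:`RunConfig` (loadable from YAML) and a
master seed.  The master seed fans out deterministically: participant ``i``
draws its parameters from ``SeedSequence([master_seed, i + 1, 7])`` and
stores ``seed_i = SeedSequence([master_seed, i + 1])``; behavioral draws use
stream ``[seed_i, 1]``, EEG synthesis ``[seed_i, 2]``, direct epoch synthesis
``[seed_i, 3]`` and ICA ``[seed_i, 4]``.  Two runs with the same config and
seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, classify_trials, erp_stats, preprocess, synth_cohort
from .eeg_io import (EEGRecording, read_brainvision, read_trial_table,
                     write_brainvision, write_trial_table)
from .erp_stats import Window
from .synth_cohort import CohortConfig, ParticipantSpec

__all__ = ["PreprocessConfig", "ClassifyConfig", "StatsConfig", "RunConfig",
           "run_all", "simulate_stage", "preprocess_recording",
           "preprocess_stage"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    filter_enabled: bool = True
    filter_low: float = 0.2
    filter_high: float = 30.0
    filter_order: int = 2
    ocular_method: str | None = "infomax"  # 'infomax' | 'regression' | None
    amp_limit: float = 100.0
    grad_limit: float = 50.0


@dataclass(frozen=True)
class ClassifyConfig:
    hit_max: float = 0.05
    err_min: float = 0.12
    cap: int = 50
    min_n: int = 20
    screen_k: float = 2.0
    errors_from: str = "largest"


@dataclass(frozen=True)
class StatsConfig:
    frac: float = 0.5
    search1: tuple[float, float] = (0.10, 0.35)
    manual_windows: tuple[tuple[float, float], tuple[float, float]] | None = None


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, sub):
            fields = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - fields
            if unknown:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            sub = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in sub.items()}
            return klass(**sub)

        return cls(
            cohort=build(CohortConfig, d.get("cohort", {})),
            preprocess=build(PreprocessConfig, d.get("preprocess", {})),
            classify=build(ClassifyConfig, d.get("classify", {})),
            stats=build(StatsConfig, d.get("stats", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self, cohort=dataclasses.replace(self.cohort, master_seed=seed))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _ica_seed(spec: ParticipantSpec) -> int:
    return int(np.random.SeedSequence([spec.seed, 4]).generate_state(1)[0]
               % (2 ** 31))


def preprocess_recording(rec: EEGRecording, spec: ParticipantSpec,
                         pcfg: PreprocessConfig) -> EEGRecording:
    """Conditioning chain on one continuous recording: band-pass filter,
    averaged-mastoids re-reference, ocular-artifact removal."""
    if pcfg.filter_enabled:
        rec = preprocess.bandpass_filter(rec, pcfg.filter_low,
                                         pcfg.filter_high, pcfg.filter_order)
    rec = preprocess.rereference_avg_mastoids(rec)
    if pcfg.ocular_method:
        rec = preprocess.remove_ocular(rec, method=pcfg.ocular_method,
                                       seed=_ica_seed(spec))
    return rec


@dataclass
class ParticipantResult:
    spec: ParticipantSpec
    n_trials: int
    hit_percentage: float
    angle_sd: float
    assignment: classify_trials.CategoryAssignment
    counts: tuple[int, int]  # surviving (hits, errors) after rejection
    median_t_kr: float
    averages: dict  # (sync, category) -> ERPWaveform
    n_rejected: int
    rejections: list = field(default_factory=list)


def _analyze_participant(spec, trials, rec, cfg: RunConfig,
                         condition: bool = True) -> ParticipantResult:
    if condition:
        rec = preprocess_recording(rec, spec, cfg.preprocess)
    assign = classify_trials.categorize(
        trials, cfg.classify.hit_max, cfg.classify.err_min, cfg.classify.cap,
        cfg.classify.errors_from)
    averages = {}
    counts = (0, 0)
    n_rejected = 0
    rejections = []
    for sync in ("release", "feedback"):
        es = preprocess.extract_epochs(rec, sync)
        es = preprocess.baseline_correct(es)
        per_cat = {}
        for cat, ids in (("hit", assign.hit_ids), ("error", assign.error_ids)):
            sub = es.select(ids)
            n_before = sub.n_epochs
            log_before = len(sub.rejection_log)
            sub = preprocess.reject_artifacts(sub, cfg.preprocess.amp_limit,
                                              cfg.preprocess.grad_limit)
            for row in sub.rejection_log[log_before:]:
                rejections.append({"participant": spec.id, "sync": sync,
                                   "category": cat, **row})
            if sync == "release":
                n_rejected += n_before - sub.n_epochs
            per_cat[cat] = sub
            if sub.n_epochs:
                averages[(sync, cat)] = erp_stats.average_epochs(sub, cat)
        if sync == "release":
            counts = (per_cat["hit"].n_epochs, per_cat["error"].n_epochs)
    cat_ids = assign.hit_ids + assign.error_ids
    cat_tkr = trials[trials["trial"].isin(cat_ids)]["t_kr"]
    return ParticipantResult(
        spec=spec, n_trials=len(trials),
        hit_percentage=100.0 * float((trials["label"] == "hit").mean()),
        angle_sd=float(trials["theta"].std(ddof=1)),
        assignment=assign, counts=counts,
        median_t_kr=float(cat_tkr.median()), averages=averages,
        n_rejected=n_rejected, rejections=rejections)


def _window_to_dict(w: Window | None):
    if w is None:
        return None
    return {"start": w.start, "end": w.end, "defined": w.defined,
            "peak_time": w.peak_time, "peak_amplitude": w.peak_amplitude}


def _stats_block(included: list[ParticipantResult], sync: str,
                 cfg: RunConfig, kr_bounds) -> dict:
    """Difference waves, windows and tests for one synchronization scheme."""
    usable = [r for r in included
              if (sync, "hit") in r.averages and (sync, "error") in r.averages]
    diffs = {r.spec.id: erp_stats.difference_wave(r.averages[(sync, "error")],
                                                  r.averages[(sync, "hit")])
             for r in usable}
    out = {"sync": sync, "n": len(usable), "computable": len(usable) >= 2}
    if not out["computable"]:
        out["reason"] = "fewer than 2 included participants"
        return out
    gd = erp_stats.grand_average(list(diffs.values()))
    manual = None
    if cfg.stats.manual_windows is not None:
        manual = tuple(Window(a, b) for a, b in cfg.stats.manual_windows)
    w1, w2 = erp_stats.detect_windows(gd, kr_bounds, cfg.stats.frac,
                                      cfg.stats.search1
                                      if sync == "release" else None,
                                      manual=manual)
    out["window1"], out["window2"] = _window_to_dict(w1), _window_to_dict(w2)
    hit_pct = np.array([r.hit_percentage for r in usable])
    for name, w in (("window1", w1), ("window2", w2)):
        if not w.defined:
            out[f"{name}_stats"] = {"defined": False}
            continue
        amps = np.array([erp_stats.mean_amplitude(diffs[r.spec.id], w)
                         for r in usable])
        ws = erp_stats.window_stats(amps, w, hit_pct)
        out[f"{name}_stats"] = {
            "defined": True, "t": ws.t, "df": ws.df, "p": ws.p,
            "r": ws.r, "p_r": ws.p_r,
            "mean_amplitude": float(amps.mean()),
            "amplitudes": {r.spec.id: float(a)
                           for r, a in zip(usable, amps)},
        }
    return out


def run_all(cfg: RunConfig, outdir, write_raw: bool = True) -> dict:
    """Full study run; returns the manifest (also written to disk).

    Stages: cohort simulation (behavior + EEG, written as trial-table TSVs
    and BrainVision triplets), signal conditioning, epoching and rejection,
    categorization with the two-level exclusion procedure, difference-wave
    statistics for both synchronization schemes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    specs = synth_cohort.sample_cohort(cfg.cohort)
    results: list[ParticipantResult] = []
    for spec in specs:
        trials = synth_cohort.generate_behavior(spec, config=cfg.cohort)
        rec = synth_cohort.generate_eeg(spec, trials, cfg.cohort)
        write_trial_table(trials, outdir / f"{spec.id}_trials.tsv")
        if write_raw:
            write_brainvision(rec, outdir / f"{spec.id}_raw")
        r = _analyze_participant(spec, trials, rec, cfg)
        results.append(r)
        log.info("%s: %d trials, %.1f%% hits, counts=%s, rejected=%d",
                 spec.id, r.n_trials, r.hit_percentage, r.counts, r.n_rejected)

    # two-level exclusion: trial counts, then cohort screening
    included, excluded = _exclusions(results, cfg)

    kr_meds = [r.median_t_kr for r in included]
    kr_bounds = ((min(kr_meds), max(kr_meds)) if kr_meds else (0.8, 0.9))
    stats = {sync: _stats_block(included, sync, cfg, kr_bounds)
             for sync in ("release", "feedback")}

    manifest = {
        "skerp_version": __version__,
        "config": cfg.to_dict(),
        "participants": {
            r.spec.id: {
                "skill": r.spec.skill, "n_trials": r.n_trials,
                "hit_percentage": r.hit_percentage, "angle_sd": r.angle_sd,
                "n_hits": r.counts[0], "n_errors": r.counts[1],
                "n_rejected": r.n_rejected,
                "median_t_kr": r.median_t_kr,
                "included": r.spec.id not in excluded,
            } for r in results},
        "excluded": excluded,
        "n_generated": len(results),
        "n_included": len(included),
        "kr_bounds": list(kr_bounds),
        "stats": stats,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    amp_rows = []
    for sync, block in stats.items():
        for wname in ("window1", "window2"):
            s = block.get(f"{wname}_stats") or {}
            for pid, a in (s.get("amplitudes") or {}).items():
                amp_rows.append({"sync": sync, "window": wname,
                                 "participant": pid, "amplitude": a})
    pd.DataFrame(amp_rows).to_csv(outdir / "window_amplitudes.tsv",
                                  sep="\t", index=False)
    rej_rows = [row for r in results for row in r.rejections]
    pd.DataFrame(rej_rows, columns=["participant", "sync", "category",
                                    "trial", "reason"]).to_csv(
        outdir / "rejection_log.tsv", sep="\t", index=False)
    return manifest


def simulate_stage(cfg: RunConfig, outdir) -> list[ParticipantSpec]:
    """Cohort simulation only: trial tables + raw BrainVision triplets."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    specs = synth_cohort.sample_cohort(cfg.cohort)
    provenance = {"config": cfg.to_dict(),
                  "participants": [dataclasses.asdict(s) for s in specs]}
    (outdir / "cohort.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True))
    for spec in specs:
        trials = synth_cohort.generate_behavior(spec, config=cfg.cohort)
        rec = synth_cohort.generate_eeg(spec, trials, cfg.cohort)
        write_trial_table(trials, outdir / f"{spec.id}_trials.tsv")
        write_brainvision(rec, outdir / f"{spec.id}_raw")
    return specs


def _load_specs(outdir) -> list[ParticipantSpec]:
    cohort = json.loads((Path(outdir) / "cohort.json").read_text())
    specs = []
    for pdict in cohort["participants"]:
        specs.append(ParticipantSpec(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in pdict.items()}))
    return specs


def _results_from_disk(cfg: RunConfig, outdir) -> list[ParticipantResult]:
    outdir = Path(outdir)
    results = []
    for spec in _load_specs(outdir):
        trials = read_trial_table(outdir / f"{spec.id}_trials.tsv")
        rec = read_brainvision(outdir / f"{spec.id}_clean")
        results.append(_analyze_participant(spec, trials, rec, cfg,
                                            condition=False))
    return results


def _exclusions(results: list[ParticipantResult], cfg: RunConfig):
    assigns = [r.assignment for r in results]
    classify_trials.apply_trial_count_rule(
        assigns, {r.spec.id: r.counts for r in results}, cfg.classify.min_n)
    stage1 = [r for r in results if r.assignment.included]
    excluded = {r.spec.id: r.assignment.reason
                for r in results if not r.assignment.included}
    if len(stage1) >= 3:
        screen = classify_trials.screen_cohort(pd.DataFrame({
            "participant": [r.spec.id for r in stage1],
            "hit_percentage": [r.hit_percentage for r in stage1],
            "angle_sd": [r.angle_sd for r in stage1],
        }), cfg.classify.screen_k)
        for _, row in screen.loc[~screen["included"]].iterrows():
            excluded[row["participant"]] = row["reason"]
        included = [r for r in stage1
                    if r.spec.id not in set(
                        screen.loc[~screen["included"], "participant"])]
    else:
        included = stage1
    return included, excluded


def classify_stage(cfg: RunConfig, outdir) -> pd.DataFrame:
    """Categorize preprocessed data on disk; writes ``classification.tsv``."""
    outdir = Path(outdir)
    results = _results_from_disk(cfg, outdir)
    included, excluded = _exclusions(results, cfg)
    table = pd.DataFrame({
        "participant": [r.spec.id for r in results],
        "n_trials": [r.n_trials for r in results],
        "hit_percentage": [r.hit_percentage for r in results],
        "angle_sd": [r.angle_sd for r in results],
        "n_hits": [r.counts[0] for r in results],
        "n_errors": [r.counts[1] for r in results],
        "included": [r.spec.id not in excluded for r in results],
        "reason": [excluded.get(r.spec.id, "") for r in results],
    })
    table.to_csv(outdir / "classification.tsv", sep="\t", index=False)
    return table


def erp_stage(cfg: RunConfig, outdir) -> dict:
    """Difference-wave statistics from preprocessed data on disk; writes
    ``stats.json``."""
    outdir = Path(outdir)
    results = _results_from_disk(cfg, outdir)
    included, _ = _exclusions(results, cfg)
    kr_meds = [r.median_t_kr for r in included]
    kr_bounds = ((min(kr_meds), max(kr_meds)) if kr_meds else (0.8, 0.9))
    stats = {sync: _stats_block(included, sync, cfg, kr_bounds)
             for sync in ("release", "feedback")}
    (outdir / "stats.json").write_text(
        json.dumps(stats, indent=2, sort_keys=True))
    return stats


def preprocess_stage(cfg: RunConfig, outdir) -> None:
    """Condition every raw triplet in ``outdir`` to a ``*_clean`` triplet."""
    outdir = Path(outdir)
    for spec in _load_specs(outdir):
        rec = read_brainvision(outdir / f"{spec.id}_raw")
        rec = preprocess_recording(rec, spec, cfg.preprocess)
        write_brainvision(rec, outdir / f"{spec.id}_clean")
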