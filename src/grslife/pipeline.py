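"""End-to-end pipeline: QC -> score -> growth -> associations -> mediation."""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, grs, growth, io, mediation, qc

log = logging.getLogger("grslife")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    genotypes: str
    weights: str
    anthro: str
    lms: str
    labels: str | None = None
    out_dir: str = "grslife_out"
    thresholds: qc.QcThresholds = field(default_factory=qc.QcThresholds)
    missing_policy: str = "impute"
    bootstrap_B: int = 1000
    seed: int = 13
    age_tolerance: float = 0.5
    outcome_age: float = 18.0

    def validate(self) -> None:
        paths = [self.genotypes, self.weights, self.anthro, self.lms]
        if self.labels is not None:
            paths.append(self.labels)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"input file(s) not found: {missing}")

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={cfg.seed} config={cfg.digest()}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dict.

    Stages: genotype QC; weight alignment and wGRS/wGRSz scoring; BMI
    Z-scores and conditional weight gain; per-age, mixed-model and (when
    labels are supplied) trajectory associations; per-period mediation of
    the score's effect on BMI Z at the outcome age. Deterministic given the
    config seed.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage(name):
        log.info("stage %-14s %6.1fs", name, time.time() - t0)

    g = io.read_genotypes(cfg.genotypes)
    weights = io.read_weights(cfg.weights)
    anthro = io.read_anthro(cfg.anthro)
    lms = io.read_lms(cfg.lms)
    labels = io.read_labels(cfg.labels) if cfg.labels else None

    clean, report = qc.run_qc(g, cfg.thresholds)
    stage("qc")
    rep_rows = [
        {"filter": e.filter_name, "axis": e.axis, "threshold": e.threshold,
         "n_removed": e.n_removed, "removed_ids": ";".join(map(str, e.removed_ids))}
        for e in report.entries
    ]
    _write_tsv(pd.DataFrame(rep_rows), out / "qc_report.tsv", cfg)

    aligned, kept_w, _ = grs.align_weights(clean, weights)
    scores = grs.standardize(grs.compute_wgrs(aligned, kept_w, cfg.missing_policy))
    _write_tsv(scores.to_frame(), out / "scores.tsv", cfg)
    stage("score")

    anthro_z = growth.add_bmi_zscores(anthro, lms)
    score_df = scores.to_frame()[["subject_id", "wgrsz"]]
    long_table = anthro_z.merge(score_df, on="subject_id", how="inner")
    long_table = long_table.rename(columns={"wgrsz": "grsz"})

    periods = growth.default_periods()
    anchor_ages = sorted({a for p in periods for a in p.anchor_ages})
    wide = growth.select_period_measurements(anthro, anchor_ages, cfg.age_tolerance)
    gains_frames = [growth.conditional_weight_gain(wide, p) for p in periods]
    gains_long = pd.concat(gains_frames, ignore_index=True)
    _write_tsv(gains_long[["subject_id", "period", "sr"]], out / "gains.tsv", cfg)
    stage("growth")

    profile = association.age_profile(long_table, tolerance=cfg.age_tolerance)
    _write_tsv(profile, out / "per_age_assoc.tsv", cfg)
    mixed = association.mixed_longitudinal(long_table)
    _write_tsv(
        pd.DataFrame([r.__dict__ for r in mixed]), out / "mixed_model.tsv", cfg
    )
    traj = None
    if labels is not None:
        ld = labels.merge(score_df, on="subject_id", how="inner")
        sex_map = anthro[["subject_id", "sex"]].drop_duplicates("subject_id")
        ld = ld.merge(sex_map, on="subject_id", how="left")
        traj = association.trajectory_multinomial(
            ld["class"], ld["wgrsz"], ld["sex"]
        )
        _write_tsv(traj, out / "trajectory_assoc.tsv", cfg)
    stage("associate")

    at18 = long_table[
        (long_table["age_years"] - cfg.outcome_age).abs() <= cfg.age_tolerance
    ].drop_duplicates("subject_id")
    base = at18[["subject_id", "grsz", "bmi_z", "sex"]]
    gains_wide = gains_long.pivot_table(
        index="subject_id", columns="period", values="sr", aggfunc="first"
    ).reset_index()
    med_in = base.merge(gains_wide, on="subject_id", how="inner")
    gains_map = {
        p.name: med_in[p.name].to_numpy()
        for p in periods if p.name in med_in.columns
    }
    sex_ind = (med_in["sex"] == "M").astype(float).to_numpy()
    med = mediation.mediation_pipeline(
        med_in["grsz"].to_numpy(), gains_map, med_in["bmi_z"].to_numpy(),
        covariates=sex_ind, B=cfg.bootstrap_B, seed=cfg.seed,
    )
    _write_tsv(med, out / "mediation.tsv", cfg)
    stage("mediate")

    manifest = {
        "seed": cfg.seed,
        "config_digest": cfg.digest(),
        "thresholds": cfg.thresholds.__dict__,
        "counts": {
            "variants_before": report.variants_before,
            "variants_after": report.variants_after,
            "samples_before": report.samples_before,
            "samples_after": report.samples_after,
            "scored_subjects": int(len(scores.wgrs)),
            "anthro_records": int(len(anthro)),
            "mediation_n": int(len(med_in)),
        },
        "skipped_qc_stages": list(report.skipped_stages),
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
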