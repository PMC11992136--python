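"""End-to-end orchestration: simulate -> preprocess -> features -> normative -> stats.

Each stage writes its artifact plus a JSON provenance block (config
hash, parameters, counts) into the run directory; a rerun with an
identical config is bit-identical.  Subject-level stages depend only on
that subject's inputs and the config; the normative and stats stages
are cohort-level and run last.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .bands import BandScheme
from .config import RunConfig
from .connectivity import subject_connectivity_features
from .csd import apply_csd
from .normative import normative_z_table
from .preprocessing import preprocess
from .spectral import welch_psd, subject_spectral_features
from .stats import group_stats, fit_glm
from .synthetic import (
    sample_cohort,
    synthesize_recording,
    default_coupled_pairs,
    truths_to_frame,
)
from .types import default_montage, Epochs, Montage

log = logging.getLogger("restingnorm")


def _provenance(run_dir: Path, stage: str, config: RunConfig, **counts) -> None:
    path = run_dir / "provenance.json"
    prov = json.loads(path.read_text()) if path.exists() else {}
    prov[stage] = {"config_hash": config.hash(), **counts}
    path.write_text(json.dumps(prov, indent=2, sort_keys=True))


def simulate_stage(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    """Write montage, per-subject EDFs, cohort CSV and truth CSV."""
    run_dir.mkdir(parents=True, exist_ok=True)
    montage = default_montage(config.n_channels, config.n_excluded)
    rio.write_montage_file(montage, run_dir / "montage.txt")
    (run_dir / "exclusion.txt").write_text(
        "\n".join(sorted(montage.exclusion_set)) + "\n"
    )
    pairs = default_coupled_pairs(montage, config.effects.n_coupled_pairs)
    cohort, truths = sample_cohort(
        config.n_ctrl,
        config.n_del,
        config.n_dup,
        config.effects,
        seed=config.seed,
        coupled_pairs=pairs,
    )
    rio.validate_cohort(cohort)
    cohort.to_csv(run_dir / "cohort.csv", index=False, float_format="%.17g")
    truths_to_frame(truths).to_csv(
        run_dir / "truth.csv", index=False, float_format="%.17g"
    )
    edf_dir = run_dir / "edf"
    edf_dir.mkdir(exist_ok=True)
    for truth in truths:
        rec = synthesize_recording(
            truth, montage, duration_s=config.duration_s, rate=config.rate
        )
        rio.write_edf(rec, edf_dir / f"{truth.subject_id}.edf")
    log.info("simulate: wrote %d recordings", len(truths))
    _provenance(run_dir, "simulate", config, n_subjects=len(truths))
    return cohort


def _select_epochs(epochs: Epochs, montage: Montage) -> Epochs:
    """Restrict epochs to the montage's analysis channels."""
    keep = [l for l in epochs.montage.labels if l not in montage.exclusion_set]
    idx = [epochs.montage.index_of(l) for l in keep]
    sub = epochs.montage.subset(keep)
    sub = Montage(labels=sub.labels, positions=sub.positions)
    out = epochs.copy_with()
    out.data = epochs.data[:, idx, :]
    out.montage = sub
    return out


def features_stage(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    """Preprocess each EDF and extract spectral + connectivity features.

    Also refreshes the cohort's quality_ratio column with the measured
    fraction of rejected epochs.
    """
    montage = rio.read_montage_file(
        run_dir / "montage.txt",
        exclusion_set=(run_dir / "exclusion.txt").read_text().split(),
    )
    cohort = pd.read_csv(run_dir / "cohort.csv")
    bands = BandScheme(dict(config.bands))
    rows = []
    reports_dir = run_dir / "preproc"
    reports_dir.mkdir(exist_ok=True)
    quality = {}
    for sid in cohort["subject_id"]:
        rec = rio.read_edf(run_dir / "edf" / f"{sid}.edf", montage)
        epochs, report = preprocess(
            rec,
            epoch_length_s=config.epoch_length_s,
            reject_k=config.reject_k,
            interp_k=config.interp_k,
            ica_corr_threshold=config.ica_corr_threshold,
            ica_max_remove=config.ica_max_remove,
            seed=config.seed,
        )
        quality[sid] = report.quality_ratio
        analysis = _select_epochs(epochs, montage)
        rep_dict = report.as_dict()
        rep_dict["n_channels_analysis"] = len(montage.analysis_labels)
        rep_dict["n_channels_kept"] = analysis.data.shape[1]
        (reports_dir / f"{sid}.json").write_text(json.dumps(rep_dict, indent=2))
        log.info(
            "%s: kept %d/%d channels, %d/%d seconds",
            sid,
            analysis.data.shape[1],
            len(montage.analysis_labels),
            int(analysis.n_kept * config.epoch_length_s),
            int(analysis.n_epochs * config.epoch_length_s),
        )
        csd_epochs = apply_csd(analysis, params=config.csd)
        spectra = welch_psd(csd_epochs)
        feats = subject_spectral_features(spectra, config.specparam, bands)
        conn_src = csd_epochs if config.use_csd_for_connectivity else analysis
        feats.update(subject_connectivity_features(conn_src, bands))
        for name, value in feats.items():
            rows.append({"subject_id": sid, "feature": name, "value": value})
    rio.write_feature_table(rows, run_dir / "features.csv")
    cohort["quality_ratio"] = cohort["subject_id"].map(quality)
    cohort.to_csv(run_dir / "cohort.csv", index=False, float_format="%.17g")
    (run_dir / "features_settings.json").write_text(
        json.dumps(
            {"specparam": config.specparam.__dict__ | {
                "peak_width_limits": list(config.specparam.peak_width_limits)},
             "bands": {k: list(v) for k, v in config.bands.items()}},
            indent=2,
        )
    )
    _provenance(run_dir, "features", config, n_rows=len(rows))
    return rio.read_feature_table(run_dir / "features.csv")


def normative_stage(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    features = rio.read_feature_table(run_dir / "features.csv")
    cohort = pd.read_csv(run_dir / "cohort.csv")
    z_table, reports = normative_z_table(
        features,
        cohort,
        rule=config.outlier,
        seed=config.seed,
        min_train=config.min_train,
    )
    z_table.to_csv(run_dir / "zscores.csv", index=False, float_format="%.17g")
    (run_dir / "normative_report.json").write_text(json.dumps(reports, indent=2))
    _provenance(run_dir, "normative", config, n_rows=len(z_table))
    return z_table


def stats_stage(config: RunConfig, run_dir: Path) -> None:
    """ANOVA/Tukey tables per feature plus the two interaction GLMs."""
    z_table = pd.read_csv(run_dir / "zscores.csv")
    cohort = pd.read_csv(run_dir / "cohort.csv")
    merged = z_table.merge(cohort, on="subject_id")
    anova_rows, tukey_rows, glm_rows = [], [], []
    for feat, block in merged.groupby("feature", sort=True):
        if block.groupby("group").size().min() < 2 or block["group"].nunique() < 2:
            continue
        res = group_stats(block["z"].to_numpy(), block["group"].to_numpy(), feat)
        a = res.anova
        anova_rows.append(
            {"feature": feat, "ss_between": a.ss_between, "df1": a.df1,
             "ss_within": a.ss_within, "df2": a.df2, "F": a.F, "p": a.p,
             "eta_p_sq": a.eta_p_sq}
        )
        for pw in res.pairwise:
            tukey_rows.append(
                {"feature": feat, "pair": f"{pw.pair[0]} - {pw.pair[1]}",
                 "mean_diff": pw.mean_diff, "p": pw.p_tukey,
                 "ci_low": pw.ci_low, "ci_high": pw.ci_high,
                 "cohens_d": pw.cohens_d}
            )
        for model_id in (1, 2):
            try:
                table = fit_glm(model_id, block["z"].to_numpy(), block)
            except ValueError:
                continue
            for _, r in table.iterrows():
                glm_rows.append({"feature": feat, "model": model_id, **r.to_dict()})
    pd.DataFrame(anova_rows).to_csv(run_dir / "stats_anova.csv", index=False,
                                    float_format="%.17g")
    pd.DataFrame(tukey_rows).to_csv(run_dir / "stats_tukey.csv", index=False,
                                    float_format="%.17g")
    pd.DataFrame(glm_rows).to_csv(run_dir / "stats_glm.csv", index=False,
                                  float_format="%.17g")
    _provenance(run_dir, "stats", config, n_features=len(anova_rows))


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in order; returns the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    for stage in (simulate_stage, features_stage, normative_stage, stats_stage):
        try:
            stage(config, run_dir)
        except Exception as e:
            raise RuntimeError(f"stage {stage.__name__} failed: {e}") from e
    (run_dir / "retention.txt").write_text(stage_report(run_dir))
    return run_dir


def stage_report(run_dir) -> str:
    """Per-group retention summary in the form
    '<group>: 99/100 (99%) good channels and 109/152 (72%) seconds'."""
    run_dir = Path(run_dir)
    cohort = pd.read_csv(run_dir / "cohort.csv")
    reports_dir = run_dir / "preproc"
    if not reports_dir.exists():
        return "incomplete run: no preprocessing reports\n"
    per_subject, excluded = {}, []
    for sid in cohort["subject_id"]:
        path = reports_dir / f"{sid}.json"
        if not path.exists():
            excluded.append(f"{sid}: no report (incomplete run)")
            continue
        rep = json.loads(path.read_text())
        if rep["n_epochs_kept"] == 0:
            excluded.append(f"{sid}: all epochs rejected")
            continue
        per_subject[sid] = rep
    lines = []
    epoch_s = 2.0
    for group in ("DEL", "DUP", "CTRL"):
        sids = [s for s in cohort[cohort["group"] == group]["subject_id"]
                if s in per_subject]
        if not sids:
            continue
        reps = [per_subject[s] for s in sids]
        kept_ch = np.mean([r.get("n_channels_kept", np.nan) for r in reps])
        tot_ch = np.mean([r.get("n_channels_analysis", np.nan) for r in reps])
        kept_s = np.mean([r["n_epochs_kept"] * epoch_s for r in reps])
        tot_s = np.mean([r["n_epochs_total"] * epoch_s for r in reps])
        ch_part = (
            f"{kept_ch:.0f}/{tot_ch:.0f} ({100 * kept_ch / tot_ch:.0f}%) good channels"
            if np.isfinite(kept_ch) and tot_ch
            else "channels n/a"
        )
        lines.append(
            f"{group}: {ch_part} and "
            f"{kept_s:.0f}/{tot_s:.0f} ({100 * kept_s / tot_s:.0f}%) seconds"
        )
    if excluded:
        lines.append("excluded: " + "; ".join(excluded))
    return "\n".join(lines) + "\n"
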