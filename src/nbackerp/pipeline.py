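"""Pipeline orchestration: simulate -> preprocess -> clean -> erp -> stats.

Each stage reads its inputs from the run directory, writes its outputs there,
and records the configuration hash in a stage marker; re-running with an
unchanged configuration hits the cache and leaves outputs untouched.  The
final report echoes the seed, the configuration hash, and per-subject
cleaning/rejection counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import erp, ica, preprocess, stats
from .config import RunConfig
from .containers import load_container, save_container
from .montage import make_montage
from .simulate import (
    EffectConfig,
    NoiseConfig,
    default_effects,
    simulate_behavioral_sessions,
    simulate_cohort,
    simulate_eeg_session,
)
from .task import EEGSequenceConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "clean", "erp", "stats")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _marker(out: Path, stage: str) -> Path:
    return out / f".{stage}.done.json"


def _cached(out: Path, stage: str, cfg: RunConfig) -> bool:
    m = _marker(out, stage)
    if not m.exists():
        return False
    try:
        return json.loads(m.read_text()).get("config_hash") == cfg.config_hash()
    except (json.JSONDecodeError, OSError):
        return False


def _mark(out: Path, stage: str, cfg: RunConfig, **extra) -> None:
    _marker(out, stage).write_text(
        json.dumps(dict(config_hash=cfg.config_hash(), seed=cfg.seed, **extra))
    )


def _noise(cfg: RunConfig) -> NoiseConfig:
    return dataclasses.replace(NoiseConfig(), **cfg.noise)


def stage_simulate(cfg: RunConfig, effects: EffectConfig | None = None) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = make_montage()
    subjects, gt = simulate_cohort(cfg.n_per_group, effects or default_effects(),
                                   seed=cfg.seed)
    subjects.to_csv(out / "subjects.csv", index=False)
    gt.to_csv(out / "ground_truth.csv", index=False)
    behav = simulate_behavioral_sessions(subjects, seed=cfg.seed + 1)
    behav.to_csv(out / "behavioral.tsv", sep="\t", index=False)
    seq_cfg = EEGSequenceConfig(n_trials=cfg.n_trials_per_block,
                                n_targets=cfg.n_targets_per_block)
    for i, (_, row) in enumerate(gt.iterrows()):
        rec = simulate_eeg_session(row, montage, _noise(cfg), seed=cfg.seed * 100003 + i,
                                   blocks=cfg.blocks, sequence_config=seq_cfg)
        save_container(rec, out / f"raw_{row['subject']}.h5")
        rec.events.to_csv(out / f"events_{row['subject']}.tsv", sep="\t", index=False)
    _mark(out, "simulate", cfg, n_subjects=len(gt))


def stage_preprocess(cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    gt = pd.read_csv(out / "ground_truth.csv")
    for _, row in gt.iterrows():
        rec = load_container(out / f"raw_{row['subject']}.h5")
        rec = preprocess.rereference(rec)
        rec = preprocess.filter_resample(rec, cfg.highpass_hz, cfg.lowpass_hz,
                                         cfg.notch_band_hz, cfg.target_rate_hz)
        epochs = preprocess.epoch_baseline(rec, cfg.epoch_window_ms, cfg.baseline_ms)
        save_container(epochs, out / f"epochs_{row['subject']}.h5")
        save_container(rec, out / f"filtered_{row['subject']}.h5")
    _mark(out, "preprocess", cfg)


def stage_clean(cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    gt = pd.read_csv(out / "ground_truth.csv")
    montage = make_montage()
    report_rows = []
    for _, row in gt.iterrows():
        subject = row["subject"]
        epochs = load_container(out / f"epochs_{subject}.h5")
        filtered = load_container(out / f"filtered_{subject}.h5")
        model = ica.fit_ica(epochs, n_components=min(cfg.n_components,
                                                     len(montage.scalp_labels)),
                            seed=cfg.seed)
        blinks = ica.detect_blinks_and_topography(filtered)
        veog = ica._epochs_to_matrix(epochs, ["VEOG"])[0]
        heog = ica._epochs_to_matrix(epochs, ["HEOG"])[0]
        ica.score_components(model, veog, heog, blinks.topography, epochs.sfreq,
                             suspect_z=cfg.ic_z_threshold)
        removed = ica.select_removal(model, min_abs_corr=cfg.confirm_min_abs_corr)
        bad = ica.detect_bad_channels(epochs, threshold_z=cfg.bad_channel_z,
                                      force=cfg.force_bad_channels)
        cleaning = ica.build_cleaning_montage(model, removed, montage, bad)
        cleaned = ica.apply_cleaning(epochs, cleaning)
        save_container(cleaned, out / f"clean_{subject}.h5")
        save_container(model, out / f"ica_{subject}.h5")
        save_container(cleaning, out / f"cleaning_{subject}.h5")
        report_rows.append(dict(subject=subject, n_components_removed=len(removed),
                                removed=",".join(map(str, removed)),
                                n_bad_channels=len(bad), bad_channels=",".join(bad),
                                n_blinks=len(blinks.events)))
    pd.DataFrame(report_rows).to_csv(out / "cleaning_report.tsv", sep="\t", index=False)
    _mark(out, "clean", cfg)


def stage_erp(cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    gt = pd.read_csv(out / "ground_truth.csv")
    montage = make_montage()
    all_measures = []
    counts = []
    for _, row in gt.iterrows():
        subject = row["subject"]
        epochs = load_container(out / f"clean_{subject}.h5")
        epochs = preprocess.crop(epochs, cfg.crop_ms)
        epochs = preprocess.baseline_correct(epochs, cfg.baseline_ms)
        epochs.data = preprocess._sos_filter(epochs.data, epochs.sfreq, "lowpass",
                                             cfg.erp_lowpass_hz)
        epochs = erp.select_valid_trials(epochs, cfg.rejection_threshold_uv,
                                         eeg_channels=list(montage.scalp_labels))
        epochs = erp.balance_nontargets(epochs)
        if not epochs.valid.any():
            raise StageError("erp", f"no valid trials for subject {subject}")
        evokeds = {}
        meta = epochs.metadata
        for level in sorted(meta["level"].unique()):
            for is_t, name in ((True, "target"), (False, "nontarget")):
                mask = (meta["level"] == level) & (meta["is_target"] == is_t)
                cond = f"{level}back/{name}"
                if not (epochs.valid & mask.to_numpy()).any():
                    logger.warning("subject %s: no valid trials for %s", subject, cond)
                    continue
                evokeds[cond] = erp.average_evoked(epochs, cond, mask.to_numpy())
        measures = erp.measure_p300(evokeds, montage, subject=subject,
                                    group=row["group"])
        all_measures.append(measures)
        counts.append(dict(subject=subject, n_valid=int(epochs.valid.sum()),
                           n_total=epochs.n_trials))
        for cond, ev in evokeds.items():
            save_container(ev, out / f"evoked_{subject}_{cond.replace('/', '_')}.h5")
    if not all_measures:
        raise StageError("erp", "no valid trials in any subject")
    pd.concat(all_measures).to_csv(out / "measures.csv", index=False)
    pd.DataFrame(counts).to_csv(out / "trial_counts.csv", index=False)
    _mark(out, "erp", cfg)


def _parse_condition(measures: pd.DataFrame) -> pd.DataFrame:
    m = measures.copy()
    m["nback"] = m["condition"].str.extract(r"^(\d)back").astype(int)
    m["stimulus"] = m["condition"].str.extract(r"/(\w+)$")
    return m


def stage_stats(cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    subjects = pd.read_csv(out / "subjects.csv")
    behav = pd.read_csv(out / "behavioral.tsv", sep="\t")
    measures = _parse_condition(pd.read_csv(out / "measures.csv"))
    measures = measures.merge(subjects[["subject", "age"]], on="subject")

    lines = [f"nbackerp stats report  (seed={cfg.seed}, config={cfg.config_hash()})", ""]
    results = []

    # canonical Pz analyses: 2 (group) x 2 (n-back) ANCOVA with age covariate
    pz = measures[(measures["site"] == "Pz") & (measures["window"] == "full")
                  & (measures["stimulus"] == "target")]
    for dv, label in (("amplitude_uV", "P300 amplitude (Pz)"),
                      ("latency_ms", "P300 latency (Pz)")):
        sub = pz.dropna(subset=[dv])
        anc = stats.mixed_ancova(sub, dv=dv, subject="subject", between="group",
                                 within=["nback"], covariate="age", alpha=cfg.alpha)
        lines.append(f"== {label} ==  (covariate {'kept' if anc.covariate_used else 'dropped'})")
        for e in anc.effects:
            results.append(dict(analysis=label, **vars(e)))
            lines.append(f"  {e.effect}: F(1,{e.df2})={e.F:.3f}, p={e.p:.4f}, "
                         f"eta_p^2={e.eta_p_sq:.3f}")
        lines.append("")

    # topographic 4-within-factor ANCOVA per time window
    roi = measures[measures["site"].str.contains(" ")].copy()
    roi["fp"] = roi["site"].str.split().str[1]
    roi["lr"] = roi["site"].str.split().str[0]
    for window in ("early", "late"):
        sub = roi[roi["window"] == window]
        anc = stats.mixed_ancova(sub, dv="amplitude_uV", subject="subject",
                                 between="group", within=["nback", "stimulus", "fp", "lr"],
                                 covariate="age", alpha=cfg.alpha)
        label = f"topographic {window} window"
        lines.append(f"== {label} ==")
        for e in anc.effects:
            results.append(dict(analysis=label, **vars(e)))
            if "group" in e.effect:
                lines.append(f"  {e.effect}: F(1,{e.df2})={e.F:.3f}, p={e.p:.4f}, "
                             f"eta_p^2={e.eta_p_sq:.3f}")
        lines.append("")

    # behavioral Kaplan-Meier / log-rank on achieved mean n-back
    km = stats.km_logrank({g: d["mean_nback"].to_numpy()
                           for g, d in behav.groupby("group")})
    lines.append(f"== behavioral mean n-back ==\n  log-rank chi2={km.chi_square:.3f}, "
                 f"df={km.df}, p={km.p:.4f}\n")
    results.append(dict(analysis="behavioral mean n-back", effect="log-rank",
                        F=km.chi_square, df1=km.df, df2=0, p=km.p, eta_p_sq=np.nan))

    # correlations: 2-back target latency at Pz vs behavioral scores, BH-FDR
    lat = pz[pz["nback"] == 2].dropna(subset=["latency_ms"])
    merged = lat.merge(subjects, on=["subject", "group"])
    corr_rows = []
    for score in ("vineland_abc", "teach_sky_search", "conners_inattention",
                  "conners_hyperactivity", "mean_nback_auditory"):
        try:
            cc = stats.correlate_and_compare(merged[score], merged["latency_ms"],
                                             merged["group"])
        except ValueError as e:
            logger.warning("correlation for %s skipped: %s", score, e)
            continue
        for gname, v in cc.by_group.items():
            corr_rows.append(dict(score=score, group=gname, **v))
    if corr_rows:
        corr = pd.DataFrame(corr_rows)
        # FDR applied within each behavioral measure's set of correlations
        corr["fdr_survives"] = corr.groupby("score")["p"].transform(
            lambda p: stats.bh_fdr(p.to_numpy(), q=cfg.fdr_q)
        )
        corr.to_csv(out / "correlations.csv", index=False)
        lines.append("== latency-behavior correlations (BH-FDR q="
                     f"{cfg.fdr_q}) ==")
        for _, r in corr.iterrows():
            star = " *" if r["fdr_survives"] else ""
            lines.append(f"  {r['score']} [{r['group']}]: r={r['r']:+.3f}, "
                         f"p={r['p']:.4f}{star}")
        lines.append("")

    pd.DataFrame(results).to_csv(out / "stats_results.csv", index=False)
    report = out / "report.txt"
    report.write_text("\n".join(lines))
    _mark(out, "stats", cfg)


_STAGE_FN = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "clean": stage_clean,
    "erp": stage_erp,
    "stats": stage_stats,
}


def run_pipeline(cfg: RunConfig, stages=STAGES, force: bool = False) -> Path:
    """Run the requested stages in order, honoring the cache; returns the run dir.

    Raises :class:`StageError` (with stage context) on any failure.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    executed = []
    for stage in STAGES:
        if stage not in stages:
            continue
        if not force and _cached(out, stage, cfg):
            logger.info("stage %s: cache hit, skipping", stage)
            executed.append((stage, "cached"))
            continue
        try:
            _STAGE_FN[stage](cfg)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001 - stage context is the contract
            raise StageError(stage, str(e)) from e
        executed.append((stage, "run"))
    log = out / "pipeline_log.txt"
    log.write_text("\n".join(f"{s}\t{state}" for s, state in executed) + "\n")
    return out
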