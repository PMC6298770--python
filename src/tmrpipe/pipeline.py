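"""End-to-end pipeline orchestration.

Stages run in order (simulate -> sleep GLM -> searchlight -> sensitivity
mask -> reactivation -> behavior -> group -> spectral -> ppi -> report),
each writing its outputs under the working directory.  Stages are
idempotent and resumable: a stage whose outputs already exist is skipped
on re-run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import connectivity as conn
from . import glm
from . import phantom
from . import reactivation as react
from . import spectral
from .io import (
    PipelineConfig,
    save_volume,
    read_events,
    read_hypnogram,
    read_motion,
    read_respiration,
    save_config,
    write_eeg,
    write_events,
    write_hypnogram,
    write_motion,
    write_respiration,
    read_eeg,
)
from .searchlight import CorrelationSearchlight, SphereSpec, group_sensitivity_mask

__all__ = ["run_pipeline", "emit_report", "STAGES", "MissingStageInputError"]

STAGES = (
    "simulate",
    "glm",
    "searchlight",
    "mask",
    "reactivate",
    "behavior",
    "group",
    "spectral",
    "ppi",
    "report",
)

FIR_OFFSETS = list(range(-3, 7))


class MissingStageInputError(RuntimeError):
    """A stage was asked to run before its inputs were produced."""


def _derive_seed(base: int, *keys: int) -> int:
    return int(np.random.SeedSequence([int(base), *map(int, keys)]).generate_state(1)[0] % 2**31)


def _subject_dir(out: Path, s: int) -> Path:
    return out / f"sub-{s:02d}"


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingStageInputError(f"stage '{stage}' requires missing input: {path}")
    return path


def _space_from_config(config: PipelineConfig) -> phantom.PhantomSpace:
    return phantom.make_phantom_space(config.dims, seed=_derive_seed(config.seed, 1), voxel_size=config.voxel_size_mm)


# ---------------------------------------------------------------- stages


def stage_simulate(config: PipelineConfig, out: Path) -> None:
    marker = out / "simulate.done"
    if marker.exists():
        return
    space = _space_from_config(config)
    templates = phantom.make_category_templates(space, seed=_derive_seed(config.seed, 2))
    truth = phantom.make_ground_truth(
        n_subjects=config.n_subjects,
        rho_range=config.rho_range,
        behavior_coupling=config.behavior_coupling,
        seed=_derive_seed(config.seed, 3),
        wake_noise_sd=config.wake_noise_sd,
        sleep_pattern_sd=config.sleep_pattern_sd,
        sleep_noise_sd=config.sleep_noise_sd,
        behavior_noise_sd=config.behavior_noise_sd,
    )
    np.savez_compressed(
        out / "space.npz",
        brain_mask=space.brain_mask,
        **{f"region_{k}": v for k, v in space.region_labels.items()},
    )
    np.save(out / "templates.npy", templates.astype(np.float32))
    (out / "truth.json").write_text(
        json.dumps(
            {
                "cued_categories": [list(c) for c in truth.cued_categories],
                "rho": truth.rho.tolist(),
                "behavior_coupling": list(truth.behavior_coupling),
                "seed": truth.seed,
            }
        )
    )
    tables_all = phantom.simulate_behavior(truth, seed=_derive_seed(config.seed, 4))
    eeg_schedule = phantom.make_odor_schedule(config.n_blocks_per_odor, start_s=phantom.EEG_CUEING_START_S)
    for s in range(config.n_subjects):
        sdir = _subject_dir(out, s)
        sdir.mkdir(parents=True, exist_ok=True)
        wake = phantom.simulate_wake_runs(
            space, templates, config.n_wake_runs, config.wake_noise_sd, seed=_derive_seed(config.seed, 10, s)
        )
        np.save(sdir / "wake_betas.npy", wake.astype(np.float32))
        session = phantom.simulate_sleep_session(
            space,
            templates,
            truth.cued_categories[s],
            truth.rho[s],
            design=phantom.SleepDesign(tr=config.tr_s, n_blocks_per_odor=config.n_blocks_per_odor),
            pattern_sd=config.sleep_pattern_sd,
            noise_sd=config.sleep_noise_sd,
            seed=_derive_seed(config.seed, 11, s),
        )
        np.save(sdir / "sleep_bold.npy", session.bold.astype(np.float32))
        write_events(sdir / "events.tsv", session.events)
        write_motion(sdir / "motion.txt", session.motion)
        write_respiration(sdir / "respiration.tsv", session.respiration)
        for phase, table in tables_all[s].items():
            table.to_csv(sdir / f"recall_{phase}.csv", index=False)
        eeg, hypnogram = phantom.simulate_eeg_and_hypnogram(
            schedule=eeg_schedule, seed=_derive_seed(config.seed, 12, s)
        )
        write_eeg(sdir / "eeg.tsv", eeg, fs=100.0, channel="Fpz")
        write_hypnogram(sdir / "hypnogram.tsv", hypnogram)
    save_config(config, out / "config.yaml")
    marker.touch()


def _load_space(out: Path) -> phantom.PhantomSpace:
    data = np.load(_need(out / "space.npz", "glm"))
    labels = {k[len("region_") :]: data[k] for k in data.files if k.startswith("region_")}
    # voxel size / dims are in config.yaml; reconstruct minimally
    mask = data["brain_mask"]
    return phantom.PhantomSpace(mask.shape, 2.0, mask, labels)


def stage_glm(config: PipelineConfig, out: Path) -> None:
    """Sleep GLM per subject: odor betas (canonical HRF) and FIR betas."""
    marker = out / "glm.done"
    if marker.exists():
        return
    space = _load_space(out)
    for s in range(config.n_subjects):
        sdir = _subject_dir(out, s)
        bold = np.load(_need(sdir / "sleep_bold.npy", "glm")).astype(float)
        events = read_events(_need(sdir / "events.tsv", "glm"))
        motion = read_motion(sdir / "motion.txt")
        respiration = read_respiration(sdir / "respiration.tsv")
        n_vol = bold.shape[0]
        tr = config.tr_s

        triggers = events["onset"].to_numpy()
        adjusted, _ = glm.align_onsets_to_inhalation(triggers, respiration)
        events = events.assign(onset=np.minimum(adjusted, (n_vol - 1) * tr - events["duration"]))

        first_vol = int(events["onset"].min() // tr)
        last_vol = int(np.ceil((events["onset"] + events["duration"]).max() / tr))
        lo, hi = glm.trim_sleep_volumes(n_vol, first_vol, min(last_vol, n_vol - 1))
        keep = slice(lo, hi + 1)

        nuisance = glm.build_nuisance_matrix(
            motion,
            space.to_4d(bold),
            respiration,
            tr,
            fd_spike_threshold=config.fd_spike_threshold_factor * config.voxel_size_mm,
        )
        nuis = nuisance.matrix[keep]
        nuis = nuis[:, nuis.std(axis=0) > 0]  # drop empty spike columns after trimming

        shifted = events.assign(onset=events["onset"] - lo * tr)
        design = glm.build_block_design(shifted, hi - lo + 1, tr)
        betas, _ = glm.fit_glm(bold[keep], design, nuis)
        np.save(sdir / "sleep_betas.npy", betas.astype(np.float32))

        onsets_by_odor = {o: shifted.loc[shifted["trial_type"] == o, "onset"].to_numpy() for o in sorted(shifted["trial_type"].unique())}
        fir = glm.build_fir_design(onsets_by_odor, hi - lo + 1, tr)
        fir_betas, _ = glm.fit_glm(bold[keep], fir, nuis)
        np.save(sdir / "fir_betas.npy", fir_betas.astype(np.float32))
        (sdir / "fir_columns.json").write_text(json.dumps(fir.task_columns))
    marker.touch()


def stage_searchlight(config: PipelineConfig, out: Path) -> None:
    """Wake category-discrimination searchlight map per subject (smoothed)."""
    marker = out / "searchlight.done"
    if marker.exists():
        return
    space = _load_space(out)
    sl = CorrelationSearchlight(config.sphere_radius_vox, config.min_sphere_voxels)
    for s in range(config.n_subjects):
        sdir = _subject_dir(out, s)
        wake = np.load(_need(sdir / "wake_betas.npy", "searchlight")).astype(float)
        sl.fit(wake, space.brain_mask)
        smoothed = glm.smooth_volume(
            sl.stat_map_.values, config.group_smoothing_fwhm_mm, config.voxel_size_mm
        )
        np.save(sdir / "discrimination_map.npy", smoothed.astype(np.float32))
        np.save(sdir / "discrimination_valid.npy", sl.valid_mask_)
    marker.touch()


def stage_mask(config: PipelineConfig, out: Path) -> None:
    """Group sensitivity mask: voxels with category information at learning."""
    marker = out / "mask.done"
    if marker.exists():
        return
    maps, valids = [], []
    for s in range(config.n_subjects):
        sdir = _subject_dir(out, s)
        maps.append(np.load(_need(sdir / "discrimination_map.npy", "mask")))
        valids.append(np.load(sdir / "discrimination_valid.npy"))
    sens = group_sensitivity_mask(np.stack(maps), alpha=config.sensitivity_alpha)
    sens &= np.all(np.stack(valids), axis=0)
    np.save(out / "sensitivity_mask.npy", sens)
    save_volume(out / "sensitivity_mask.nii.gz", sens.astype(np.float32), config.voxel_size_mm)
    marker.touch()


def stage_reactivate(config: PipelineConfig, out: Path) -> None:
    """Per-subject reactivation searchlight maps (main + FIR time points)."""
    marker = out / "reactivate.done"
    if marker.exists():
        return
    space = _load_space(out)
    truth = json.loads(_need(out / "truth.json", "reactivate").read_text())
    sphere = SphereSpec(config.sphere_radius_vox, config.min_sphere_voxels)
    for s in range(config.n_subjects):
        sdir = _subject_dir(out, s)
        wake = np.load(_need(sdir / "wake_betas.npy", "reactivate")).astype(float)
        sleep_betas = np.load(_need(sdir / "sleep_betas.npy", "reactivate")).astype(float)
        cued = tuple(truth["cued_categories"][s])
        templates = react.build_category_templates(wake)
        stat = react.reactivation_map_fast(sleep_betas, templates, cued, space.brain_mask, sphere)
        smoothed = glm.smooth_volume(stat.values, config.group_smoothing_fwhm_mm, config.voxel_size_mm)
        np.save(sdir / "reactivation_map.npy", smoothed.astype(np.float32))
        np.save(sdir / "reactivation_valid.npy", stat.valid)
    marker.touch()


def stage_behavior(config: PipelineConfig, out: Path) -> None:
    marker = out / "behavior.done"
    if marker.exists():
        return
    truth = json.loads(_need(out / "truth.json", "behavior").read_text())
    benefits, rows = [], []
    rt_cued, rt_noncued = [], []
    for s in range(config.n_subjects):
        sdir = _subject_dir(out, s)
        pre = pd.read_csv(_need(sdir / "recall_pretest.csv", "behavior"))
        post = pd.read_csv(sdir / "recall_posttest.csv")
        interference = pd.read_csv(sdir / "recall_interference.csv")
        cued = tuple(truth["cued_categories"][s])
        score = beh.score_recall_and_benefit(pre, post, cued)
        benefits.append(score.benefit)
        rows.append(
            dict(
                subject=s,
                retention_cued=score.retention_cued,
                retention_noncued=score.retention_noncued,
                benefit=score.benefit,
                flagged=score.flagged,
            )
        )
        rt_cued.append(interference.loc[interference["cued"], "rt"].to_numpy())
        rt_noncued.append(interference.loc[~interference["cued"], "rt"].to_numpy())
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "benefits.csv", index=False)

    diffs = np.asarray(benefits)
    results = [
        beh.wilcoxon_one_tailed(diffs),
        beh.exact_binomial_one_tailed(int((diffs > 0).sum()), diffs.size),
        beh.paired_log_rt_test(rt_cued, rt_noncued),
    ]
    beh.write_test_results(results, out / "behavior_stats.csv")
    sem = beh.within_subject_sem(frame[["retention_cued", "retention_noncued"]].to_numpy())
    (out / "behavior.json").write_text(
        json.dumps(
            {
                "mean_benefit": float(diffs.mean()),
                "n_positive": int((diffs > 0).sum()),
                "wilcoxon_z": results[0].statistic,
                "wilcoxon_p": results[0].p,
                "binomial_p": results[1].p,
                "rt_t": results[2].statistic,
                "rt_p": results[2].p,
                "within_subject_sem": sem.tolist(),
            }
        )
    )
    marker.touch()


def stage_group(config: PipelineConfig, out: Path) -> None:
    """Group models: benefit correlation, main effect, univariate activation."""
    marker = out / "group.done"
    if marker.exists():
        return
    space = _load_space(out)
    sens = np.load(_need(out / "sensitivity_mask.npy", "group"))
    benefits = pd.read_csv(_need(out / "benefits.csv", "group"))["benefit"].to_numpy()
    maps, valids, contrasts = [], [], []
    for s in range(config.n_subjects):
        sdir = _subject_dir(out, s)
        maps.append(np.load(_need(sdir / "reactivation_map.npy", "group")))
        valids.append(np.load(sdir / "reactivation_valid.npy"))
        betas = np.load(sdir / "sleep_betas.npy").astype(float)
        contrast = space.to_volume(betas.mean(axis=0))
        contrasts.append(glm.smooth_volume(contrast, config.group_smoothing_fwhm_mm, config.voxel_size_mm))
    maps = np.stack(maps)
    explicit = sens & np.all(np.stack(valids), axis=0)
    if not explicit.any():
        explicit = np.all(np.stack(valids), axis=0)

    seed = _derive_seed(config.seed, 20)
    result = react.group_covariate_correlation(maps, benefits, explicit, n_perm=config.n_permutations, seed=seed)
    main = react.main_effect_reactivation(maps, explicit, n_perm=config.n_permutations, seed=seed + 1)
    roi = space.region_labels["hippocampus_like"]
    uni = react.univariate_odor_activation(np.stack(contrasts), roi, n_perm=config.n_permutations, seed=seed + 2)

    np.save(out / "group_t_map.npy", result.stat_map.astype(np.float32))
    np.save(out / "group_r_map.npy", result.r_map.astype(np.float32))
    save_volume(out / "group_t_map.nii.gz", np.nan_to_num(result.stat_map), config.voxel_size_mm)
    save_volume(out / "group_r_map.nii.gz", np.nan_to_num(result.r_map), config.voxel_size_mm)
    cluster = np.zeros(space.brain_mask.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        # follow-up cluster: p < 0.001 uncorrected on the covariate model
        from scipy import stats as sps

        tcrit = sps.t.ppf(1 - 0.001, df=config.n_subjects - 2)
        cluster[np.nan_to_num(result.stat_map, nan=-np.inf) > tcrit] = True
    if not cluster.any():  # fall back to the peak voxel so follow-ups stay defined
        cluster[result.peak_index] = True
    np.save(out / "cluster.npy", cluster)

    def _res_dict(res: react.GroupResult) -> dict:
        return {
            "peak_index": list(res.peak_index),
            "peak_t": res.peak_stat,
            "peak_r": res.peak_r,
            "p_uncorrected": res.p_uncorrected,
            "p_fwe": res.p_fwe,
            "n_permutations": res.n_permutations,
            "n_subjects": res.n_subjects,
        }

    (out / "group.json").write_text(
        json.dumps(
            {
                "covariate": _res_dict(result),
                "main_effect": _res_dict(main),
                "univariate": _res_dict(uni),
                "seed": seed,
            }
        )
    )

    # FIR time-resolved follow-up within the cluster
    truth = json.loads((out / "truth.json").read_text())
    sphere = SphereSpec(config.sphere_radius_vox, config.min_sphere_voxels)
    vec_index = np.zeros(space.brain_mask.shape, dtype=int)
    vec_index[space.brain_mask] = np.arange(space.n_voxels)
    cluster_vec = vec_index[cluster & space.brain_mask]
    tp_maps = []
    for s in range(config.n_subjects):
        sdir = _subject_dir(out, s)
        fir = np.load(sdir / "fir_betas.npy").astype(float)
        cols = json.loads((sdir / "fir_columns.json").read_text())
        wake = np.load(sdir / "wake_betas.npy").astype(float)
        cued = tuple(truth["cued_categories"][s])
        templates = react.build_category_templates(wake)
        odors = sorted({c.rsplit("_t", 1)[0] for c in cols})
        per_tp = []
        for off in FIR_OFFSETS:
            pair = np.stack([fir[cols.index(f"{o}_t{off:+d}")] for o in odors])
            stat = react.reactivation_map_fast(pair, templates, cued, space.brain_mask, sphere)
            per_tp.append(stat.values[space.brain_mask])
        tp_maps.append(per_tp)
    tp_maps = np.asarray(tp_maps).transpose(1, 0, 2)  # (tp, subj, vox)
    tc = react.fir_timecourse_correlation(tp_maps, benefits, cluster_vec)
    (out / "fir_timecourse.json").write_text(
        json.dumps({"offsets_volumes": FIR_OFFSETS, "r": [r for r, _ in tc], "ci90": [list(ci) for _, ci in tc]})
    )
    marker.touch()


def stage_spectral(config: PipelineConfig, out: Path) -> None:
    marker = out / "spectral.done"
    if marker.exists():
        return
    schedule = phantom.make_odor_schedule(config.n_blocks_per_odor, start_s=phantom.EEG_CUEING_START_S)
    psds, summaries, included = [], [], []
    for s in range(config.n_subjects):
        sdir = _subject_dir(out, s)
        eeg, fs, _ = read_eeg(_need(sdir / "eeg.tsv", "spectral"))
        hypnogram = read_hypnogram(sdir / "hypnogram.tsv")
        psds.append(spectral.condition_block_psd(eeg, fs, schedule))
        summaries.append(spectral.sleep_stage_summary(hypnogram).set_index("stage")["minutes"])
        gates = spectral.cueing_gates(hypnogram, schedule)
        included.append(gates.included and gates.first_block_eligible)
    table, result = spectral.condition_psd_contrast(np.stack(psds))
    stage_means = pd.concat(summaries, axis=1).mean(axis=1)
    (out / "spectral.json").write_text(
        json.dumps(
            {
                "interaction_F": result.statistic,
                "df_interaction": result.df,
                "df_error_classical": result.extra["df_error_classical"],
                "p_gg": result.p,
                "p_uncorrected": result.extra["p_uncorrected"],
                "stage_minutes_mean": stage_means.to_dict(),
                "n_included": int(np.sum(included)),
            }
        )
    )
    marker.touch()


def stage_ppi(config: PipelineConfig, out: Path) -> None:
    marker = out / "ppi.done"
    if marker.exists():
        return
    space = _load_space(out)
    group = json.loads(_need(out / "group.json", "ppi").read_text())
    cluster = np.load(_need(out / "cluster.npy", "ppi"))
    peak = tuple(group["univariate"]["peak_index"])
    vec_index = np.zeros(space.brain_mask.shape, dtype=int)
    vec_index[space.brain_mask] = np.arange(space.n_voxels)
    cluster_vec = vec_index[cluster & space.brain_mask]
    betas = []
    for s in range(config.n_subjects):
        sdir = _subject_dir(out, s)
        bold = np.load(_need(sdir / "sleep_bold.npy", "ppi")).astype(float)
        events = read_events(sdir / "events.tsv")
        motion = read_motion(sdir / "motion.txt")
        seed_series = conn.extract_seed_series(bold, peak, 5.0, config.voxel_size_mm, space.brain_mask)
        nuisance = glm.build_nuisance_matrix(motion, None, None, config.tr_s)
        model = conn.PPIModel().fit(bold, seed_series, events, config.tr_s, nuisance.matrix[:, :24])
        betas.append(model.cluster_mean(cluster_vec))
    result = conn.ppi_group_test(np.asarray(betas))
    (out / "ppi.json").write_text(
        json.dumps({"t": result.statistic, "df": result.df, "p": result.p, "cluster_betas": betas})
    )
    marker.touch()


def stage_report(config: PipelineConfig, out: Path) -> None:
    marker = out / "report.done"
    if marker.exists() and (out / "report.json").exists():
        return
    report = emit_report(out)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    lines = ["tmrpipe report", "=" * 40]
    cov = report["group"]["covariate"]
    lines.append(
        f"benefit~reactivation peak: r={cov['peak_r']:.3f} t={cov['peak_t']:.2f} "
        f"p_unc={cov['p_uncorrected']:.4g} p_FWE={cov['p_fwe']:.4g} "
        f"(n_perm={cov['n_permutations']})"
    )
    lines.append(
        f"behavior: mean benefit={report['behavior']['mean_benefit']:.2f} pts, "
        f"Wilcoxon Z={report['behavior']['wilcoxon_z']:.2f} (p={report['behavior']['wilcoxon_p']:.4g}), "
        f"binomial p={report['behavior']['binomial_p']:.4g}"
    )
    lines.append(
        f"EEG PSD interaction: F={report['spectral']['interaction_F']:.3f} p_GG={report['spectral']['p_gg']:.3f}"
    )
    lines.append(f"PPI: t={report['ppi']['t']:.2f} p={report['ppi']['p']:.4g}")
    lines.append(f"seed={config.seed}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    marker.touch()


def emit_report(out: Path) -> dict:
    """Aggregate all stage JSONs into one report dictionary."""
    out = Path(out)
    required = ["group.json", "behavior.json", "spectral.json", "ppi.json"]
    missing = [f for f in required if not (out / f).exists()]
    if missing:
        raise MissingStageInputError(f"report requires missing outputs: {missing}")
    report = {
        "group": json.loads((out / "group.json").read_text()),
        "behavior": json.loads((out / "behavior.json").read_text()),
        "spectral": json.loads((out / "spectral.json").read_text()),
        "ppi": json.loads((out / "ppi.json").read_text()),
        "fir_timecourse": json.loads((out / "fir_timecourse.json").read_text()),
        "config": json.loads(json.dumps(yaml_config_dict(out))),
    }
    return report


def yaml_config_dict(out: Path) -> dict:
    import yaml

    with open(out / "config.yaml") as fh:
        return yaml.safe_load(fh)


_STAGE_FNS = {
    "simulate": stage_simulate,
    "glm": stage_glm,
    "searchlight": stage_searchlight,
    "mask": stage_mask,
    "reactivate": stage_reactivate,
    "behavior": stage_behavior,
    "group": stage_group,
    "spectral": stage_spectral,
    "ppi": stage_ppi,
    "report": stage_report,
}


def run_stage(name: str, config: PipelineConfig, out: Path) -> None:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    _STAGE_FNS[name](config, out)


def run_pipeline(config: PipelineConfig, out: Path) -> dict:
    """Run every stage in order and return the aggregated report."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    for name in STAGES:
        run_stage(name, config, out)
    return json.loads((out / "report.json").read_text())
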