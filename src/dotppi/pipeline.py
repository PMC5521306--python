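"""End-to-end driver: simulate a session, run every analysis stage, and
write all maps, tables and figures to a report directory.

Stages (in order): synthetic session -> preprocessing -> first-level
GLM and fixed effects -> group random effects with permutation cluster
correction -> canonical and subject-specific seeds -> gPPI at both
interaction levels -> seed-to-ROI matrices (canonical vs
subject-specific TIC, TDC contrasts) -> deconvolution comparison ->
scrambled-signal control.  Every random draw descends from the single
configured seed, and the log records parameters and per-stage timing.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import experiments, glm, preprocess
from .config import PipelineConfig
from .connectivity import build_matrix, compare_deconv, matrix_correlation
from .hemodynamics import build_canonical_hrf
from .ppi import ppi_contrast
from .seeds import canonical_seeds, local_maxima, seeds_to_tsv, subject_seed
from .synth import RegionLayout, generate_design
from .validation import chi2_two_sample, scrambled_control
from .volume import write_image

log = logging.getLogger(__name__)

SENTENCES_CONTRAST = {"easy": 0.5, "complex": 0.5}
COMPLEXITY_CONTRAST = {"complex": 1.0, "easy": -1.0}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage %s: FAILED after %.1f s: %s", name, dt, exc)
                raise StageError(name, exc) from exc
            log.info("stage %s: done in %.1f s", name, dt)
            return False

    return _Timer()


def _group_tdc_map(fits_by_subject, cond_a, cond_b, mask, affine, stats_cfg, seed):
    subj_maps = [ppi_contrast(f, cond_a, cond_b).values for f in fits_by_subject]
    group = glm.random_effects(subj_maps, mask=mask, affine=affine)
    if stats_cfg.use_thresholded_matrices:
        nulls = glm.signflip_null_maps(subj_maps, stats_cfg.n_permutations,
                                       seed=seed, mask=mask)
        group = glm.threshold_cluster(group, stats_cfg.voxel_p,
                                      stats_cfg.cluster_p, nulls)
    return group


def run_all(config: PipelineConfig, out_dir) -> Path:
    """Run the full procedure on synthetic data; returns the report dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "log.txt", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("dotppi")
    root_logger.addHandler(fh)
    root_logger.setLevel(logging.INFO)
    try:
        return _run_all(config, out)
    finally:
        root_logger.removeHandler(fh)
        fh.close()


def _run_all(cfg: PipelineConfig, out: Path) -> Path:
    cfg.to_yaml(out / "config.yaml")
    log.info("master seed %d", cfg.seed)

    with _stage("simulate"):
        layout = RegionLayout.default(cfg.sim.voxel_size_mm)
        truth = experiments.battery_truth(layout)
        designs = generate_design(cfg.sim.n_runs, seed=cfg.seed,
                                  isi_range=cfg.sim.isi_range_s,
                                  stim_duration=cfg.sim.stim_duration_s)
        pd.concat([d.to_frame() for d in designs]).to_csv(
            out / "designs.tsv", sep="\t", index=False)
        hrf_acq = build_canonical_hrf(cfg.hrf.rate, cfg.hrf.duration_s,
                                      delay_s=cfg.hrf.delay_s, peak_s=cfg.hrf.peak_s,
                                      undershoot_s=cfg.hrf.undershoot_s,
                                      undershoot_ratio=cfg.hrf.undershoot_ratio)
        hrf_out = build_canonical_hrf(cfg.filter.target_rate_hz, cfg.hrf.duration_s,
                                      delay_s=cfg.hrf.delay_s, peak_s=cfg.hrf.peak_s,
                                      undershoot_s=cfg.hrf.undershoot_s,
                                      undershoot_ratio=cfg.hrf.undershoot_ratio)
        hrf_acq.to_text(out / "hrf.tsv")
        root = np.random.SeedSequence(cfg.seed)
        subj_seeds = [int(np.random.default_rng(ss).integers(2**31))
                      for ss in root.spawn(cfg.sim.n_subjects)]
        recordings = [
            experiments.simulate_subject(
                designs, layout, truth, hrf_acq, seed=s,
                superficial_amp=cfg.sim.superficial_amp,
                pink_amp=cfg.sim.pink_amp, white_amp=cfg.sim.white_amp,
                neural_noise_sd=cfg.sim.neural_noise_sd,
                neural_noise_tau_s=cfg.sim.neural_noise_tau_s)
            for s in subj_seeds
        ]
        write_image(recordings[0].sensitivity, layout.affine,
                    out / "sensitivity.nii.gz")

    with _stage("preprocess"):
        subjects = [experiments.preprocess_recording(
            rec, cfg.filter.low_hz, cfg.filter.high_hz, cfg.filter.target_rate_hz)
            for rec in recordings]
        group_mask = preprocess.group_fov([s[0].mask for s in subjects])
        for series in subjects:
            for s in series:
                s.mask = group_mask
        write_image(group_mask, layout.affine, out / "group_fov.nii.gz")

    with _stage("glm"):
        rate = cfg.filter.target_rate_hz
        subject_maps = {"sentences": [], "complexity": []}
        for series in subjects:
            band = (cfg.filter.low_hz, cfg.filter.high_hz)
            run_fits = [
                glm.fit_glm(s, glm.build_design(d, hrf_out, rate, s.n_timepoints,
                                                match_band=band))
                for s, d in zip(series, designs)
            ]
            subject_maps["sentences"].append(
                glm.fixed_effects(run_fits, SENTENCES_CONTRAST, affine=layout.affine))
            subject_maps["complexity"].append(
                glm.fixed_effects(run_fits, COMPLEXITY_CONTRAST, affine=layout.affine))
        for name, maps in subject_maps.items():
            vals = [m.values for m in maps]
            group = glm.random_effects(vals, mask=group_mask, affine=layout.affine)
            if cfg.stats.n_permutations <= 0:
                raise ValueError("cluster thresholding requires n_permutations > 0; "
                                 "set stats.n_permutations")
            nulls = glm.signflip_null_maps(vals, cfg.stats.n_permutations,
                                           seed=cfg.seed + 1, mask=group_mask)
            thr = glm.threshold_cluster(group, cfg.stats.voxel_p,
                                        cfg.stats.cluster_p, nulls)
            write_image(group.values, layout.affine, out / f"group_{name}_z.nii.gz")
            write_image(thr.values, layout.affine,
                        out / f"group_{name}_z_thresholded.nii.gz")
            overlap = glm.overlap_map(maps, cfg.stats.overlap_z)
            write_image(overlap, layout.affine, out / f"overlap_{name}.nii.gz")

    with _stage("seeds"):
        canon = canonical_seeds(radius_mm=cfg.seeds.mask_radius_mm)
        seeds_to_tsv(canon, out / "seeds_canonical.tsv")
        subj_specific = []
        for i, smap in enumerate(subject_maps["sentences"]):
            peaks = local_maxima(smap, min_z=cfg.seeds.peak_min_z)
            specific = [subject_seed(c, peaks, cfg.seeds.max_peak_dist_mm)
                        for c in canon]
            subj_specific.append(specific)
            seeds_to_tsv(specific, out / f"seeds_subject_{i:02d}.tsv")

    sig_radius = max(cfg.seeds.signal_radius_mm,
                     layout.voxel_size * np.sqrt(3.0) / 2.0 + 0.1)
    cube = max(9.0, layout.voxel_size)

    with _stage("ppi"):
        fits = {lvl: [] for lvl in cfg.interaction_levels}   # level -> [subj][seed]
        fits_subjspec = []                                   # [subj][seed], hemodynamic
        for series, specific in zip(subjects, subj_specific):
            for lvl in cfg.interaction_levels:
                fits[lvl].append([
                    experiments.subject_ppi(series, designs, hrf_out, sd, lvl,
                                            sig_radius)
                    for sd in canon
                ])
            fits_subjspec.append([
                experiments.subject_ppi(series, designs, hrf_out, sd,
                                        "hemodynamic", sig_radius)
                for sd in specific
            ])

    with _stage("matrices"):
        def tic_group_map(fit_rows, k):
            maps = [glm_fits[k].zmap({"tic": 1.0}).values for glm_fits in fit_rows]
            group = glm.random_effects(maps, mask=group_mask, affine=layout.affine)
            if cfg.stats.use_thresholded_matrices:
                nulls = glm.signflip_null_maps(maps, cfg.stats.n_permutations,
                                               seed=cfg.seed + 2, mask=group_mask)
                group = glm.threshold_cluster(group, cfg.stats.voxel_p,
                                              cfg.stats.cluster_p, nulls)
            return group

        lvl0 = cfg.interaction_levels[0]
        tic_canon = build_matrix(
            [(canon[k], tic_group_map(fits[lvl0], k)) for k in range(len(canon))],
            canon, cube, kind="TIC")
        tic_subj = build_matrix(
            [(canon[k], tic_group_map(fits_subjspec, k)) for k in range(len(canon))],
            canon, cube, kind="TIC")
        tic_canon.to_tsv(out / "matrix_TIC_canonical.tsv")
        tic_subj.to_tsv(out / "matrix_TIC_subject_specific.tsv")
        tic_canon.plot(out / "matrix_TIC_canonical.png")
        tic_subj.plot(out / "matrix_TIC_subject_specific.png")
        r = matrix_correlation(tic_canon, tic_subj)
        pd.DataFrame([{"comparison": "TIC canonical vs subject-specific",
                       "pearson_r": r}]).to_csv(
            out / "matrix_correlation.tsv", sep="\t", index=False)
        log.info("TIC matrix correlation (canonical vs subject-specific): r=%.3f", r)

        for lvl in cfg.interaction_levels:
            for cond_a, cond_b, tag in [("complex", "noise", "sentences_vs_noise"),
                                        ("complex", "easy", "complex_vs_easy")]:
                tdc = build_matrix(
                    [(canon[k], _group_tdc_map([row[k] for row in fits[lvl]],
                                               cond_a, cond_b, group_mask,
                                               layout.affine, cfg.stats,
                                               cfg.seed + 3))
                     for k in range(len(canon))],
                    canon, cube, kind="TDC")
                tdc.to_tsv(out / f"matrix_TDC_{tag}_{lvl}.tsv")
                tdc.plot(out / f"matrix_TDC_{tag}_{lvl}.png")

    with _stage("deconv_comparison"):
        if set(cfg.interaction_levels) >= {"hemodynamic", "neural"}:
            from .connectivity import roi_average

            k_true = [s.label for s in canon].index(experiments.TRUE_SOURCE)
            rows = {lvl: [] for lvl in ("neural", "hemodynamic")}
            for lvl in ("neural", "hemodynamic"):
                for row in fits[lvl]:
                    cmap = ppi_contrast(row[k_true], "complex", "easy")
                    rows[lvl].append([roi_average(cmap, r.center_mm, cube)
                                      for r in canon])
            table = compare_deconv(np.asarray(rows["neural"]),
                                   np.asarray(rows["hemodynamic"]),
                                   cfg.stats.alpha_family,
                                   pair_labels=[s.label for s in canon])
            table.to_csv(out / "deconv_comparison.tsv", sep="\t", index=False)

    with _stage("scrambled_control"):
        pooled = {"TIC": {"real": [], "scrambled": []},
                  "TDC": {"real": [], "scrambled": []}}
        for i, series in enumerate(subjects):
            real, scram, _, _ = scrambled_control(
                series, designs, canon, canon, hrf_out,
                rate=cfg.filter.target_rate_hz, level="hemodynamic",
                cube_side_mm=cube, signal_radius_mm=sig_radius,
                seed=cfg.seed + 10 + i)
            for kind in ("TIC", "TDC"):
                pooled[kind]["real"].append(real[kind].values.ravel())
                pooled[kind]["scrambled"].append(scram[kind].values.ravel())
        rows = []
        for kind in ("TIC", "TDC"):
            cmp_ = chi2_two_sample(np.concatenate(pooled[kind]["real"]),
                                   np.concatenate(pooled[kind]["scrambled"]))
            rows.append({"comparison": kind, "chi2": cmp_.chi2,
                         "dof": cmp_.dof, "p": cmp_.p})
            log.info("scrambled control %s: chi2(%d)=%.1f, p=%.3g",
                     kind, cmp_.dof, cmp_.chi2, cmp_.p)
        pd.DataFrame(rows).to_csv(out / "scrambled_control.tsv", sep="\t",
                                  index=False)

    log.info("pipeline complete; outputs in %s", out)
    return out
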