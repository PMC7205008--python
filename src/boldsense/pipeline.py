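"""End-to-end orchestration: simulate -> HRF -> CBF -> sensitize -> stats.

The pipeline mirrors the study's analysis flow.  For every subject the
sparse-sampled BOLD series is scaled to percent change, motion censored and
deconvolved with the tent basis; the signed area under the estimated block
response is computed per segment and z-transformed over the junction mask
(the intersection of BOLD and CBF coverage).  The pCASL series is censored
pairwise, subtracted, averaged and quantified to absolute CBF.  Per
segment, the group-level voxel-wise regression of measured activity on CBF
yields the sensitized (residual) maps, together with the age-corrected-CBF
("unsensitized") variant and the division-normalized comparator.  Group
t-maps are thresholded by Monte-Carlo cluster extent, clusters are
classified FP / FN / R across standard versus sensitized analyses, and
activity-behaviour relationships plus leave-one-out model comparisons are
reported for the task-responsive cluster.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from . import cbf as cbf_mod
from . import hrf as hrf_mod
from . import sensitize as sens_mod
from . import stats as stats_mod
from . import synthetic as syn_mod
from .errors import ConfigError
from .grid import VolumeGrid, junction_mask
from .io import save_json, save_nifti, save_table


@dataclass
class AnalysisConfig:
    """Group-analysis settings."""

    voxel_p: float = 0.01
    fpr_target: float = 0.05
    n_cluster_sims: int = 200
    smoothness_fwhm_mm: float = 4.0
    bold_motion_threshold_mm: float = 0.3
    asl_motion_threshold_mm: float = 0.5
    asl_max_censor_fraction: float = 0.25
    division_floor: float = 1.0
    segments: tuple = (1, 2, 3, "full")
    alpha: float = 0.01
    power_alpha: float = 0.05


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seeds, version, outputs."""

    seed: int
    config: dict
    version: str = __version__
    outputs: dict = field(default_factory=dict)
    hashes: dict = field(default_factory=dict)

    def record(self, name: str, path: Path) -> None:
        self.outputs[name] = str(path)
        self.hashes[name] = hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config,
            "version": self.version,
            "outputs": self.outputs,
            "hashes": self.hashes,
        }


@dataclass
class SubjectDerived:
    """Per-subject derived quantities on the cohort junction mask."""

    subject_id: str
    group: str
    age: float
    zauc: dict  # segment key -> flat measured Z(AUC) over junction mask
    cbf: np.ndarray  # flat CBF over junction mask
    accuracy: dict  # behaviour segment (1, 2) -> % accuracy
    censored_bold: int = 0
    asl_qc: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# per-subject stages
# ---------------------------------------------------------------------------

def bold_segment_aucs(
    subject: syn_mod.SubjectData,
    basis: hrf_mod.TentBasis,
    mask: np.ndarray,
    segments: dict,
    motion_threshold_mm: float = 0.3,
) -> tuple[dict, int]:
    """Scale, censor, deconvolve one subject; signed AUC per segment.

    Returns ``({segment_key: flat AUC over mask}, n_censored)``.
    """
    series = subject.bold
    scaled = hrf_mod.scale_to_percent_change(series)
    keep = hrf_mod.censor_volumes(series.motion, motion_threshold_mm)
    X, n_basis = hrf_mod.build_design(
        basis,
        series.block_onsets,
        series.volume_times,
        run_starts=series.run_starts,
        tr=series.tr,
    )
    Y = scaled[mask].T  # (n_volumes, n_voxels)
    est = hrf_mod.deconvolve(Y, X, n_basis, basis, keep=keep)
    aucs = {key: hrf_mod.segment_auc(est, seg) for key, seg in segments.items()}
    return aucs, int((~keep).sum())


def cbf_for_subject(
    subject: syn_mod.SubjectData,
    grid: VolumeGrid,
    mask: np.ndarray,
    params: cbf_mod.CbfQuantParams,
    analysis: AnalysisConfig,
) -> tuple[cbf_mod.CbfMap, dict]:
    series = cbf_mod.PcaslSeries(
        volumes=subject.pcasl, motion=subject.pcasl_motion, m0=subject.m0
    )
    cbf_map, qc = cbf_mod.process_pcasl(
        series,
        grid,
        params,
        threshold_mm=analysis.asl_motion_threshold_mm,
        max_fraction=analysis.asl_max_censor_fraction,
        mask=mask,
    )
    return cbf_map, qc


def derive_cohort(
    cohort: syn_mod.SyntheticCohort,
    analysis: AnalysisConfig | None = None,
) -> tuple[list[SubjectDerived], np.ndarray]:
    """Run the per-subject BOLD and CBF stages for a whole cohort.

    Returns the per-subject derived records and the junction mask shared by
    every map (BOLD coverage AND CBF coverage).
    """
    analysis = analysis or AnalysisConfig()
    segments = {k: v for k, v in hrf_mod.standard_segments().items()
                if k in analysis.segments}
    raw = []
    cbf_masks = []
    for subject in cohort.subjects:
        aucs, n_censored = bold_segment_aucs(
            subject,
            cohort.basis,
            cohort.mask,
            segments,
            analysis.bold_motion_threshold_mm,
        )
        cbf_map, qc = cbf_for_subject(
            subject, cohort.grid, cohort.mask, cohort.asl_params, analysis
        )
        raw.append((subject, aucs, n_censored, cbf_map, qc))
        cbf_masks.append(cbf_map.mask)

    jmask = junction_mask([cohort.mask] + cbf_masks)
    keep_flat = jmask[cohort.mask]  # junction voxels within the BOLD mask

    derived = []
    for subject, aucs, n_censored, cbf_map, qc in raw:
        zauc = {}
        for key, seg in segments.items():
            z = hrf_mod.z_transform(aucs[key][keep_flat], jmask, seg)
            zauc[key] = z.values
        acc = {}
        for bseg in (1, 2):
            recs = stats_mod.segment_accuracy(subject.trials, bseg)
            acc[bseg] = recs[0].accuracy
        derived.append(
            SubjectDerived(
                subject_id=subject.subject_id,
                group=subject.group,
                age=subject.age,
                zauc=zauc,
                cbf=cbf_map.values[jmask],
                accuracy=acc,
                censored_bold=n_censored,
                asl_qc=qc,
            )
        )
    return derived, jmask


# ---------------------------------------------------------------------------
# group-level analysis
# ---------------------------------------------------------------------------

def _behaviour_segment(segment_key) -> int:
    """Behaviour measure paired with an HRF segment (Seg3/full use Seg2)."""
    return 1 if segment_key == 1 else 2


def analyze_segment(
    derived: list[SubjectDerived],
    jmask: np.ndarray,
    grid: VolumeGrid,
    segment_key,
    analysis: AnalysisConfig,
    cluster_mask: np.ndarray | None = None,
    extent_voxels: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Full group analysis of one segment.

    ``cluster_mask`` (e.g. the known task-responsive blob of a synthetic
    cohort) selects the voxels whose mean activity enters the
    activity-behaviour regressions and the leave-one-out comparison.
    """
    ages = np.array([d.age for d in derived])
    groups = np.array([d.group for d in derived])
    Z = np.vstack([d.zauc[segment_key] for d in derived])
    C = np.vstack([d.cbf for d in derived])
    seg = hrf_mod.standard_segments()[segment_key]

    fit, pred, resid = sens_mod.sensitize_group(Z, C, seg)
    cbf_age = sens_mod.age_correct_cbf(C, ages)
    fit_age, _, unsens = sens_mod.sensitize_group(Z, cbf_age, seg)
    divided = np.vstack(
        [sens_mod.divide_normalize(Z[k], C[k], analysis.division_floor)
         for k in range(Z.shape[0])]
    )

    def vol(stack_row):
        v = np.full(jmask.shape, np.nan)
        v[jmask] = stack_row
        return v

    # group maps (within-group, standard and sensitized)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if extent_voxels is None:
        extent_voxels = stats_mod.simulate_extent_threshold(
            jmask,
            analysis.smoothness_fwhm_mm,
            grid,
            analysis.voxel_p,
            analysis.fpr_target,
            analysis.n_cluster_sims,
            rng,
        )
    cluster_tables = {}
    classified = {}
    for gname in ("Y", "O"):
        sel = groups == gname
        if sel.sum() < 2:
            continue
        # For within-group inference the sensitized map keeps the
        # CBF-independent activation level: t-tests run on A + residual
        # (= Z - B*CBF), so the test targets the activation with the
        # CBF-driven component removed rather than the identically
        # mean-zero in-sample residuals.  Correlation-based analyses are
        # unaffected by the constant shift.
        sens_level = fit.intercept[None, :] + resid
        out = {}
        for label, stack in (("standard", Z), ("sensitized", sens_level)):
            tvals, df = stats_mod.group_map(stack[sel])
            tvol = vol(tvals)
            clusters, _ = stats_mod.cluster_threshold(
                tvol, jmask, df, grid, analysis.smoothness_fwhm_mm,
                analysis.voxel_p, analysis.fpr_target,
                analysis.n_cluster_sims, rng, extent_voxels=extent_voxels,
            )
            out[label] = clusters
        classified[gname] = stats_mod.classify_effectiveness(
            out["standard"], out["sensitized"], grid.shape
        )
        cluster_tables[gname] = {k: stats_mod.clusters_to_frame(v)
                                 for k, v in out.items()}

    # behaviour relationships at the analysis cluster
    behaviour = {}
    loo = {}
    power = {}
    if cluster_mask is not None and segment_key in (1, 2, "full", 3):
        cm = np.asarray(cluster_mask, dtype=bool)[jmask]
        if cm.sum() >= 1:
            acc = np.array(
                [d.accuracy[_behaviour_segment(segment_key)] for d in derived]
            )
            means = {
                "standard": Z[:, cm].mean(axis=1),
                "covariate": resid[:, cm].mean(axis=1),
                "unsensitized": unsens[:, cm].mean(axis=1),
                "division": np.nanmean(divided[:, cm], axis=1),
            }
            cbf_means = C[:, cm].mean(axis=1)
            for mode, vals in means.items():
                behaviour[mode] = stats_mod.bold_behavior_regression(vals, acc).as_dict()
            behaviour["cbf"] = stats_mod.bold_behavior_regression(
                cbf_means, acc
            ).as_dict()
            r2_std = behaviour["standard"]["r2"]
            r2_sens = behaviour["covariate"]["r2"]
            if r2_sens >= r2_std:
                behaviour["effect_size_f2"] = stats_mod.cohens_f2(r2_std, r2_sens)
            behaviour["bonferroni_threshold"] = stats_mod.bonferroni(
                analysis.alpha, max(len(means), 1)
            )
            # point-biserial age-group dependence of each activity variant
            behaviour["group_dependence"] = {
                mode: stats_mod.point_biserial(groups, vals).as_dict()
                for mode, vals in means.items()
            }
            # leave-one-out validation and model comparison
            cv = stats_mod.loo_cv(means["standard"], cbf_means)
            loo["coupling_cv"] = {
                "mean_cve": cv.mean_cve,
                "mean_pe": cv.mean_pe,
            }
            comp = stats_mod.compare_models_loo(
                means["standard"], cbf_means, acc
            )
            loo["behavior_comparison"] = {
                "mean_fisher_z": {
                    m: float(np.mean(v["fisher_z"]))
                    for m, v in comp["per_model"].items()
                },
                "paired_tests": comp["comparisons"],
            }
            # achieved power of the cluster-level coupling slope
            coupling = stats_mod._corr_summary(cbf_means, means["standard"])
            power = {
                "slope": coupling.slope,
                "power": stats_mod.achieved_power(
                    coupling.slope,
                    float(np.std(cbf_means, ddof=1)),
                    float(np.std(means["standard"], ddof=1)),
                    len(derived),
                    analysis.power_alpha,
                ),
            }

    return {
        "segment": segment_key,
        "fit": fit,
        "stacks": {
            "measured": Z,
            "predicted": pred,
            "residual": resid,
            "unsensitized": unsens,
            "divided": divided,
        },
        "extent_voxels": int(extent_voxels),
        "clusters": cluster_tables,
        "classified": classified,
        "behaviour": behaviour,
        "loo": loo,
        "power": power,
    }


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, out_dir: str | Path) -> tuple[RunManifest, dict]:
    """Run the whole synthetic-cohort pipeline and write its artifacts.

    ``config`` keys: ``seed`` (int), ``simulate`` (cohort overrides) and
    ``analysis`` (analysis overrides).  Deterministic: the same config
    produces identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if "simulate" not in config:
        raise ConfigError("only simulation-driven runs are supported: add a 'simulate' block")
    seed = int(config.get("seed", 0))
    cohort_cfg = syn_mod.config_from_dict({**config.get("simulate", {}), "seed": seed})
    analysis = AnalysisConfig(**config.get("analysis", {}))

    cohort = syn_mod.generate_cohort(cohort_cfg)
    derived, jmask = derive_cohort(cohort, analysis)

    manifest = RunManifest(seed=seed, config={
        "simulate": syn_mod.config_to_dict(cohort_cfg),
        "analysis": {**analysis.__dict__, "segments": list(analysis.segments)},
    })
    report: dict = {"seed": seed, "n_subjects": len(derived)}

    # shared artifacts
    demo = cohort.demographics()
    manifest.record("demographics", save_table(out_dir / "demographics.tsv", demo))
    manifest.record("trials", save_table(out_dir / "trials.tsv", cohort.trial_table()))
    manifest.record(
        "junction_mask",
        save_nifti(out_dir / "junction_mask.nii.gz", jmask.astype(np.float64), cohort.grid),
    )

    accuracy_rows = []
    for d in derived:
        for bseg, acc in d.accuracy.items():
            accuracy_rows.append({"subject": d.subject_id, "segment": bseg,
                                  "accuracy": acc})
    manifest.record(
        "behaviour", save_table(out_dir / "behaviour.tsv", pd.DataFrame(accuracy_rows))
    )
    report["behaviour"] = behavior_decay_summary(derived)

    # group CBF difference (young - old)
    groups = np.array([d.group for d in derived])
    C = np.vstack([d.cbf for d in derived])
    cbf_t, cbf_df = stats_mod.group_map(C[groups == "Y"], C[groups == "O"])
    cbf_vol = np.full(jmask.shape, np.nan)
    cbf_vol[jmask] = cbf_t
    manifest.record(
        "cbf_group_t", save_nifti(out_dir / "cbf_group_t.nii.gz", cbf_vol, cohort.grid)
    )
    blob_cbf = C[:, cohort.blob_mask[jmask]].mean(axis=1)
    report["cbf"] = {
        "group_difference_df": int(cbf_df),
        "young_mean": float(C[groups == "Y"].mean()),
        "old_mean": float(C[groups == "O"].mean()),
        "blob_point_biserial": stats_mod.point_biserial(groups, blob_cbf).as_dict(),
    }

    # shared Monte-Carlo extent threshold for all segment analyses
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**16 + 1]))
    extent = stats_mod.simulate_extent_threshold(
        jmask,
        analysis.smoothness_fwhm_mm,
        cohort.grid,
        analysis.voxel_p,
        analysis.fpr_target,
        analysis.n_cluster_sims,
        rng,
    )
    report["cluster_extent_voxels"] = int(extent)

    report["segments"] = {}
    for key in analysis.segments:
        res = analyze_segment(
            derived,
            jmask,
            cohort.grid,
            key,
            analysis,
            cluster_mask=cohort.blob_mask,
            extent_voxels=extent,
            seed=rng,
        )
        seg_name = f"seg-{key}"
        for role in ("measured", "residual"):
            mean_vol = np.full(jmask.shape, np.nan)
            mean_vol[jmask] = res["stacks"][role].mean(axis=0)
            manifest.record(
                f"{seg_name}_{role}_mean",
                save_nifti(out_dir / f"{seg_name}_{role}_mean.nii.gz", mean_vol, cohort.grid),
            )
        fit_vol = np.full((2,) + jmask.shape, np.nan)
        fit_vol[0][jmask] = res["fit"].intercept
        fit_vol[1][jmask] = res["fit"].slope
        manifest.record(
            f"{seg_name}_fit",
            save_nifti(
                out_dir / f"{seg_name}_fit.nii.gz",
                np.moveaxis(fit_vol, 0, -1),
                cohort.grid,
            ),
        )
        for gname, table in res["clusters"].items():
            for label, frame in table.items():
                manifest.record(
                    f"{seg_name}_{gname}_{label}_clusters",
                    save_table(
                        out_dir / f"{seg_name}_{gname}_{label}_clusters.tsv", frame
                    ),
                )
        for gname, classified in res["classified"].items():
            manifest.record(
                f"{seg_name}_{gname}_classification",
                save_table(
                    out_dir / f"{seg_name}_{gname}_classification.tsv",
                    stats_mod.clusters_to_frame(classified),
                ),
            )
        report["segments"][str(key)] = {
            "extent_voxels": res["extent_voxels"],
            "behaviour": res["behaviour"],
            "loo": res["loo"],
            "power": res["power"],
            "fpfnr_counts": {
                g: pd.Series(
                    [c.classification for c in cl]
                ).value_counts().to_dict()
                for g, cl in res["classified"].items()
            },
        }

    manifest.record("report", save_json(out_dir / "report.json", report))
    save_json(out_dir / "manifest.json", manifest.as_dict())
    return manifest, report


def behavior_decay_summary(derived: list[SubjectDerived]) -> dict:
    """Group-mean accuracy per segment and the within-subject Seg1-Seg2 drop."""
    acc1 = np.array([d.accuracy[1] for d in derived])
    acc2 = np.array([d.accuracy[2] for d in derived])
    t, p = sps.ttest_rel(acc1, acc2)
    return {
        "seg1_mean": float(acc1.mean()),
        "seg2_mean": float(acc2.mean()),
        "paired_t": float(t),
        "paired_p": float(p),
    }
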