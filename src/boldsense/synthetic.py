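"""Synthetic two-group cohorts with known ground truth.

Generates everything the downstream stages consume — sparse-sampled BOLD
series, interleaved pCASL control/label series with a proton-density (M0)
volume, motion-parameter tables, trial-level behaviour and demographics —
for a young/old cohort in which

* baseline CBF declines linearly with age (global scaling of a smooth
  spatial perfusion template),
* the per-voxel task response amplitude is coupled to baseline CBF through
  a linear term ``A* + B* * w * CBF`` — ``w`` a fixed spatial
  coupling-weight gradient emulating the vessel-size dependence of the
  BOLD-CBF relationship — plus a neural activation blob scaled by a
  per-subject neural amplitude, and
* in-scanner accuracy depends on the neural amplitude only and decays from
  the first to the second half of each block.

Because the injected block response is piecewise linear on the tent-basis
knots, a noiseless cohort passed through the deconvolution stage recovers
the injected knot amplitudes exactly, and every downstream claim can be
checked against stored ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import hrf as hrf_mod
from .errors import ConfigError
from .grid import VolumeGrid, ellipsoid_mask

# Demographic anchors of the emulated cohort (years).
YOUNG_MEAN_AGE, YOUNG_SD_AGE = 23.52, 3.08
OLD_MEAN_AGE, OLD_SD_AGE = 66.86, 4.37


# ---------------------------------------------------------------------------
# biphasic impulse response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HrfParams:
    """Biphasic impulse response: positive early lobe, late undershoot.

    Each lobe is a gamma density normalized to unit peak; the response is
    their difference.  Defaults place the peak near 6 s, the undershoot
    trough near 22 s, and the response within 1e-3 of zero well before
    48 s, matching the time an 8-trial block response needs to return to
    baseline.
    """

    peak_time: float = 6.0
    peak_shape: float = 6.0
    undershoot_time: float = 22.0
    undershoot_shape: float = 12.0
    undershoot_ratio: float = 0.35

    def __post_init__(self) -> None:
        vals = (
            self.peak_time,
            self.peak_shape,
            self.undershoot_time,
            self.undershoot_shape,
            self.undershoot_ratio,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ConfigError("non-finite HRF parameters")
        if self.peak_time <= 0 or self.undershoot_time <= 0:
            raise ConfigError("lobe peak times must be positive")
        if self.peak_shape <= 1 or self.undershoot_shape <= 1:
            raise ConfigError("lobe shapes must exceed 1")
        if self.undershoot_ratio < 0:
            raise ConfigError("undershoot ratio must be non-negative")


def _gamma_lobe(t: np.ndarray, mode: float, shape: float) -> np.ndarray:
    """Gamma-density lobe normalized to peak 1 at ``mode`` (0 for t <= 0)."""
    scale = mode / (shape - 1.0)
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    x = t[pos] / scale
    xm = mode / scale
    # ratio to the modal value, computed in log space for stability
    out[pos] = np.exp((shape - 1.0) * (np.log(x) - np.log(xm)) - (x - xm))
    return out


def biphasic_hrf(t: np.ndarray | float, params: HrfParams | None = None) -> np.ndarray:
    """Biphasic impulse response amplitude at time(s) ``t`` (seconds).

    Causal (0 for t <= 0), peak amplitude 1, negative undershoot of
    relative depth ``undershoot_ratio``; effectively back to baseline by
    48 s for the default parameters.
    """
    params = params or HrfParams()
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if not np.all(np.isfinite(t_arr)):
        raise ConfigError("non-finite time values")
    resp = _gamma_lobe(t_arr, params.peak_time, params.peak_shape)
    resp -= params.undershoot_ratio * _gamma_lobe(
        t_arr, params.undershoot_time, params.undershoot_shape
    )
    return resp if np.ndim(t) else float(resp[0])


def block_response_knots(
    basis: hrf_mod.TentBasis,
    n_trials: int = 8,
    trial_spacing: float = 4.0,
    params: HrfParams | None = None,
) -> np.ndarray:
    """Unit-peak 8-trial block response sampled at the basis knots.

    Linear superposition of one impulse response per trial, normalized so
    the largest knot value is 1.  This is the ground-truth response shape
    injected into synthetic BOLD series (scaled per voxel by the amplitude
    field), and is exactly representable by the tent basis.
    """
    onsets = np.arange(n_trials) * trial_spacing
    resp = np.zeros(basis.n_knots)
    for o in onsets:
        resp += biphasic_hrf(basis.knot_times - o, params)
    peak = np.max(np.abs(resp))
    if peak == 0:
        raise ConfigError("degenerate block response")
    return resp / peak


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-design and ground-truth parameters for a synthetic cohort.

    Design constants (TR = 4 s, 8 trials per block, 3 runs of 6 blocks,
    47 label/control pairs, 11 young + 13 old subjects) emulate the
    acquisition of the modelled study.  Ground-truth couplings:

    coupling_intercept, coupling_slope
        ``A*`` (%) and ``B*`` (% per mL/100 g/min): linear dependence of the
        peak block-response amplitude on baseline CBF at the same voxel,
        modulated by a fixed spatial coupling-weight gradient ``w`` (range
        ``coupling_weight_range``) that emulates the vessel-size dependence
        of BOLD-CBF coupling across the brain.
    neural_amp, neural_subject_sd
        Peak % amplitude of the neural activation blob, and the SD of the
        per-subject neural amplitude multiplier (mean 1).
    neural_effect
        Increase in per-trial success probability per unit of the subject
        neural amplitude deviation (behaviour depends on the neural term
        only, never on CBF directly).
    """

    n_young: int = 11
    n_old: int = 13
    grid_shape: tuple[int, int, int] = (10, 10, 8)
    voxel_size: tuple[float, float, float] = (2.2, 2.2, 2.0)
    tr: float = 4.0
    n_trials_per_block: int = 8
    n_blocks_per_run: int = 6
    n_runs: int = 3
    baseline_duration: float = 12.0
    # perfusion ground truth (mL/100 g/min)
    cbf_young_mean: float = 60.0
    cbf_old_mean: float = 45.0
    cbf_subject_sd: float = 8.0
    cbf_spatial_cv: float = 0.15
    # BOLD amplitude ground truth
    coupling_intercept: float = 0.5
    coupling_slope: float = -0.03
    coupling_weight_range: tuple[float, float] = (0.3, 1.7)
    neural_amp: float = 1.0
    neural_subject_sd: float = 0.2
    amp_noise_pct: float = 0.05
    # behaviour ground truth
    neural_effect: float = 0.30
    acc_seg1: float = 0.85
    acc_decay: float = 0.12
    # noise levels
    bold_noise_pct: float = 0.2
    drift_pct: float = 0.3
    motion_step_mm: float = 0.02
    motion_spike_frac: float = 0.03
    motion_spike_mm: float = 0.45
    # pCASL
    asl_pairs: int = 47
    asl_noise_frac: float = 1.0
    asl_motion_spike_frac: float = 0.03
    asl_motion_spike_mm: float = 0.7
    hrf_params: HrfParams = field(default_factory=HrfParams)
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_young,
            self.n_old,
            self.n_trials_per_block,
            self.n_blocks_per_run,
            self.n_runs,
            self.asl_pairs,
        )
        if any(int(c) < 1 for c in counts):
            raise ConfigError("all design counts must be >= 1")
        if any(n < 3 for n in self.grid_shape):
            raise ConfigError("grid needs >= 3 voxels per axis")
        if any(v <= 0 for v in self.voxel_size):
            raise ConfigError("voxel sizes must be positive")
        if self.tr <= 0:
            raise ConfigError("tr must be positive")
        for name in ("bold_noise_pct", "drift_pct", "asl_noise_frac",
                     "amp_noise_pct", "motion_step_mm"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0 < self.acc_seg1 <= 1 or self.acc_decay < 0:
            raise ConfigError("invalid behaviour parameters")

    @property
    def n_subjects(self) -> int:
        return self.n_young + self.n_old

    def noiseless(self) -> "CohortConfig":
        """Copy with every noise source (but not ground truth) at zero."""
        return replace(
            self,
            bold_noise_pct=0.0,
            drift_pct=0.0,
            amp_noise_pct=0.0,
            asl_noise_frac=0.0,
            motion_spike_frac=0.0,
            asl_motion_spike_frac=0.0,
        )


# ---------------------------------------------------------------------------
# cohort containers
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """All acquisitions and ground truth for one synthetic subject."""

    subject_id: str
    group: str  # "Y" or "O"
    age: float
    bold: hrf_mod.BoldSeries
    pcasl: np.ndarray  # 4D interleaved control/label
    pcasl_motion: pd.DataFrame
    m0: np.ndarray
    trials: pd.DataFrame
    # ground truth
    cbf_true: np.ndarray
    amplitude_true: np.ndarray  # peak % response per voxel
    neural_amplitude: float
    accuracy_true: tuple[float, float]  # per-segment success probabilities


@dataclass
class SyntheticCohort:
    """A generated cohort plus the shared lattice and ground truth."""

    config: CohortConfig
    grid: VolumeGrid
    mask: np.ndarray
    subjects: list[SubjectData]
    basis: hrf_mod.TentBasis
    shape_knots: np.ndarray  # unit-peak block response at knots
    cbf_template: np.ndarray  # spatial perfusion pattern, in-mask mean 1
    coupling_weight: np.ndarray  # fixed BOLD-CBF coupling-weight gradient
    neural_blob: np.ndarray  # spatial activation pattern, peak 1
    asl_params: "object" = None  # CbfQuantParams; set by generator

    @property
    def blob_mask(self) -> np.ndarray:
        """True task-responsive cluster (blob above half its peak)."""
        return self.neural_blob >= 0.5 * self.neural_blob.max()

    def demographics(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [s.subject_id for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "group": [s.group for s in self.subjects],
            }
        )

    def trial_table(self) -> pd.DataFrame:
        return pd.concat([s.trials for s in self.subjects], ignore_index=True)

    def true_segment_auc(self, subject: SubjectData, segment) -> np.ndarray:
        """Ground-truth signed segment area for every in-mask voxel."""
        coeffs = np.outer(self.shape_knots, subject.amplitude_true[self.mask])
        est = hrf_mod.HrfEstimate(coeffs, self.basis, drift_order=0)
        return hrf_mod.segment_auc(est, segment)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _smooth_field(shape, rng, sigma_vox=1.5):
    """Smooth zero-mean unit-SD Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _gaussian_blob(shape, centre_frac=(0.75, 0.45, 0.5), sigma_vox=1.2):
    axes = [np.arange(n) for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    c = [f * (n - 1) for f, n in zip(centre_frac, shape)]
    r2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
    return np.exp(-r2 / (2.0 * sigma_vox**2))


def _motion_table(n_vols, rng, step_mm, spike_frac, spike_mm):
    """Random-walk rigid-body parameters with occasional large steps."""
    steps = rng.normal(0.0, step_mm, size=(n_vols, 6))
    steps[:, 3:] /= hrf_mod.ROTATION_RADIUS_MM  # radians
    if spike_frac > 0 and n_vols > 1:
        n_spikes = int(round(spike_frac * n_vols))
        if n_spikes:
            idx = rng.choice(np.arange(1, n_vols), size=n_spikes, replace=False)
            steps[idx, 0] += spike_mm * rng.choice([-1.0, 1.0], size=n_spikes)
    params = np.cumsum(steps, axis=0)
    params[0] = 0.0
    return pd.DataFrame(params, columns=list(hrf_mod.MOTION_COLUMNS))


def _run_layout(cfg: CohortConfig, rng) -> tuple[np.ndarray, np.ndarray, int]:
    """Volume times, block onsets and total volume count for all runs.

    Each run: an initial active-baseline window, then blocks of
    ``n_trials_per_block`` task volumes separated by jittered control
    blocks of 3-5 volumes.
    """
    tr = cfg.tr
    n_base = int(np.ceil(cfg.baseline_duration / tr))
    onsets = []
    run_starts = []
    vol = 0
    for _ in range(cfg.n_runs):
        run_starts.append(vol * tr)
        vol += n_base
        for b in range(cfg.n_blocks_per_run):
            onsets.append(vol * tr)
            vol += cfg.n_trials_per_block
            jitter = int(rng.integers(3, 6))  # 3-5 control volumes
            vol += jitter
    return np.asarray(run_starts), np.asarray(onsets), vol


def generate_pcasl_series(
    cbf_truth: np.ndarray,
    m0: np.ndarray,
    params,
    noise_sd: float,
    seed: int | np.random.Generator,
    n_pairs: int = 47,
    base_fraction: float = 0.75,
) -> np.ndarray:
    """Interleaved control/label series consistent with a known CBF map.

    The control-label difference of each pair equals the single-compartment
    model's perfusion-weighted signal for ``cbf_truth`` (plus optional white
    noise), so quantifying the generated series recovers the truth exactly
    in the noiseless case and in expectation otherwise.

    Volumes are ordered control, label, control, label, ...
    """
    from .cbf import perfusion_signal  # local import to avoid a cycle

    if noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")
    cbf_truth = np.asarray(cbf_truth, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if cbf_truth.shape != m0.shape:
        raise ConfigError("cbf_truth and m0 must share a grid")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dm = perfusion_signal(cbf_truth, m0, params)
    base = base_fraction * m0
    series = np.empty(cbf_truth.shape + (2 * n_pairs,))
    for p in range(n_pairs):
        noise_c = rng.normal(0.0, noise_sd, cbf_truth.shape) if noise_sd else 0.0
        noise_l = rng.normal(0.0, noise_sd, cbf_truth.shape) if noise_sd else 0.0
        series[..., 2 * p] = base + dm / 2.0 + noise_c
        series[..., 2 * p + 1] = base - dm / 2.0 + noise_l
    return series


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a complete synthetic cohort with known ground truth.

    Deterministic under a fixed ``config.seed`` (bit-identical volumes and
    tables).  See the module docstring for the generative model.
    """
    from .cbf import CbfQuantParams

    cfg = config or CohortConfig()
    cfg.validate()

    ss = np.random.SeedSequence(cfg.seed)
    rng_shared, rng_subjects = [np.random.default_rng(s) for s in ss.spawn(2)]

    grid = VolumeGrid(cfg.grid_shape, cfg.voxel_size)
    mask = ellipsoid_mask(cfg.grid_shape)
    basis = hrf_mod.TentBasis.default()
    shape_knots = block_response_knots(
        basis, cfg.n_trials_per_block, cfg.tr, cfg.hrf_params
    )

    # spatial perfusion template (in-mask mean 1) and neural blob (peak 1)
    template = 1.0 + cfg.cbf_spatial_cv * _smooth_field(cfg.grid_shape, rng_shared)
    template = np.clip(template, 0.4, None)
    template[mask] /= template[mask].mean()
    template[~mask] = 0.0
    blob = _gaussian_blob(cfg.grid_shape)
    blob[~mask] = 0.0
    blob /= blob.max()

    # fixed coupling-weight gradient along the first axis (vessel-size proxy)
    w_lo, w_hi = cfg.coupling_weight_range
    i_ax = np.arange(cfg.grid_shape[0], dtype=float) / max(cfg.grid_shape[0] - 1, 1)
    weight = np.broadcast_to(
        (w_lo + (w_hi - w_lo) * i_ax)[:, None, None], cfg.grid_shape
    ).copy()
    weight[~mask] = 0.0

    # baseline image intensity pattern shared by all subjects
    bold_baseline = 1000.0 * (0.8 + 0.4 * template)
    m0_map = np.where(mask, 900.0 * (0.7 + 0.6 * template), 0.0)
    asl_params = CbfQuantParams()

    age_slope = (cfg.cbf_old_mean - cfg.cbf_young_mean) / (OLD_MEAN_AGE - YOUNG_MEAN_AGE)

    subjects: list[SubjectData] = []
    groups = ["Y"] * cfg.n_young + ["O"] * cfg.n_old
    subject_seeds = ss.spawn(len(groups))  # stable per-subject streams
    for k, (group, sseed) in enumerate(zip(groups, subject_seeds)):
        rng = np.random.default_rng(sseed)
        if group == "Y":
            age = float(np.clip(rng.normal(YOUNG_MEAN_AGE, YOUNG_SD_AGE), 18.0, 34.0))
        else:
            age = float(np.clip(rng.normal(OLD_MEAN_AGE, OLD_SD_AGE), 60.0, 89.0))

        # global perfusion level declines linearly with age
        level = (
            cfg.cbf_young_mean
            + age_slope * (age - YOUNG_MEAN_AGE)
            + rng.normal(0.0, cfg.cbf_subject_sd)
        )
        level = max(level, 10.0)
        cbf_true = np.where(mask, template * level, 0.0)

        nu = rng.normal(1.0, cfg.neural_subject_sd)
        amp = (
            cfg.coupling_intercept
            + cfg.coupling_slope * weight * cbf_true
            + cfg.neural_amp * blob * nu
        )
        if cfg.amp_noise_pct > 0:
            amp = amp + rng.normal(0.0, cfg.amp_noise_pct, amp.shape)
        amp = np.where(mask, amp, 0.0)

        # ---- BOLD series -------------------------------------------------
        run_starts, onsets, n_vols = _run_layout(cfg, rng)
        times = np.arange(n_vols) * cfg.tr
        Xb = hrf_mod.tent_design(basis, onsets, times, run_starts)
        truth_coeffs = np.outer(shape_knots, amp[mask])  # (n_knots, V)
        pct = Xb @ truth_coeffs  # (n_vols, V)
        if cfg.drift_pct > 0:
            edges = list(run_starts) + [np.inf]
            for r in range(len(run_starts)):
                in_run = (times >= edges[r]) & (times < edges[r + 1])
                u = np.linspace(-1.0, 1.0, int(in_run.sum()))
                c1, c2 = rng.normal(0.0, cfg.drift_pct, 2)
                pct[in_run] += (c1 * u + c2 * (u**2 - 1.0 / 3.0))[:, None]
        if cfg.bold_noise_pct > 0:
            pct = pct + rng.normal(0.0, cfg.bold_noise_pct, pct.shape)
        bold_vals = np.zeros(cfg.grid_shape + (n_vols,))
        bold_vals[mask] = (bold_baseline[mask, None] *
                           (1.0 + pct.T / 100.0))
        bold_motion = _motion_table(
            n_vols, rng, cfg.motion_step_mm, cfg.motion_spike_frac, cfg.motion_spike_mm
        )
        bold = hrf_mod.BoldSeries(
            values=bold_vals,
            tr=cfg.tr,
            block_onsets=onsets,
            motion=bold_motion,
            baseline_window=cfg.baseline_duration,
            run_starts=run_starts,
        )

        # ---- pCASL -------------------------------------------------------
        from .cbf import perfusion_signal

        dm_scale = float(np.mean(np.abs(perfusion_signal(cbf_true, m0_map, asl_params))[mask]))
        noise_sd = cfg.asl_noise_frac * dm_scale
        pcasl = generate_pcasl_series(
            cbf_true, m0_map, asl_params, noise_sd, rng, n_pairs=cfg.asl_pairs
        )
        pcasl_motion = _motion_table(
            2 * cfg.asl_pairs,
            rng,
            cfg.motion_step_mm,
            cfg.asl_motion_spike_frac,
            cfg.asl_motion_spike_mm,
        )

        # ---- behaviour ---------------------------------------------------
        p1 = float(np.clip(cfg.acc_seg1 + cfg.neural_effect * (nu - 1.0), 0.02, 0.98))
        p2 = float(np.clip(p1 - cfg.acc_decay, 0.02, 0.98))
        rows = []
        sid = f"sub-{k + 1:02d}"
        for run in range(1, cfg.n_runs + 1):
            for block in range(1, cfg.n_blocks_per_run + 1):
                for trial in range(1, cfg.n_trials_per_block + 1):
                    p = p1 if trial <= cfg.n_trials_per_block // 2 else p2
                    rows.append(
                        {
                            "subject": sid,
                            "run": run,
                            "block": block,
                            "trial_index": trial,
                            "correct": int(rng.random() < p),
                        }
                    )
        trials = pd.DataFrame(rows)

        subjects.append(
            SubjectData(
                subject_id=sid,
                group=group,
                age=age,
                bold=bold,
                pcasl=pcasl,
                pcasl_motion=pcasl_motion,
                m0=m0_map,
                trials=trials,
                cbf_true=cbf_true,
                amplitude_true=amp,
                neural_amplitude=nu,
                accuracy_true=(p1, p2),
            )
        )

    return SyntheticCohort(
        config=cfg,
        grid=grid,
        mask=mask,
        subjects=subjects,
        basis=basis,
        shape_knots=shape_knots,
        cbf_template=template,
        coupling_weight=weight,
        neural_blob=blob,
        asl_params=asl_params,
    )


def config_from_dict(d: dict) -> CohortConfig:
    """Build a :class:`CohortConfig` from a plain (e.g. YAML) mapping."""
    d = dict(d)
    if "hrf_params" in d and isinstance(d["hrf_params"], dict):
        d["hrf_params"] = HrfParams(**d["hrf_params"])
    for key in ("grid_shape", "voxel_size"):
        if key in d:
            d[key] = tuple(d[key])
    known = {f for f in CohortConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown cohort config keys: {sorted(unknown)}")
    return CohortConfig(**d)


def config_to_dict(cfg: CohortConfig) -> dict:
    d = asdict(cfg)
    d["grid_shape"] = list(cfg.grid_shape)
    d["voxel_size"] = list(cfg.voxel_size)
    return d
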