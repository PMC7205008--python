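"""Evaluation machinery for the sensitization method.

Covers the statistics the method is judged with: in-scanner segment
accuracy, point-biserial group tests, activity-behaviour regression with
Bonferroni correction and Cohen's f-squared effect sizes, Fisher-z based
model comparison under leave-one-out cross-validation, achieved power of
the voxel-wise slope test, voxel-wise group t-maps with Monte-Carlo
cluster-extent thresholding, and the false-positive / false-negative /
retained classification of clusters before versus after sensitization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .errors import ConfigError, GridError
from .grid import VolumeGrid


# ---------------------------------------------------------------------------
# regression summaries
# ---------------------------------------------------------------------------

@dataclass
class RegressionSummary:
    """Simple-regression (or correlation) summary: r, R^2, t, two-tailed p."""

    r: float
    n: int
    slope: float = np.nan
    intercept: float = np.nan

    @property
    def r2(self) -> float:
        return self.r**2

    @property
    def df(self) -> int:
        return self.n - 2

    @property
    def t(self) -> float:
        if abs(self.r) >= 1.0:
            return np.inf if self.r > 0 else -np.inf
        return self.r * np.sqrt(self.df) / np.sqrt(1.0 - self.r**2)

    @property
    def p(self) -> float:
        t = self.t
        if not np.isfinite(t):
            return 0.0
        return 2.0 * sps.t.sf(abs(t), self.df)

    def as_dict(self) -> dict:
        return {
            "r": float(self.r),
            "r2": float(self.r2),
            "t": float(self.t),
            "p": float(self.p),
            "n": int(self.n),
            "df": int(self.df),
            "slope": float(self.slope),
            "intercept": float(self.intercept),
        }


def _corr_summary(x: np.ndarray, y: np.ndarray) -> RegressionSummary:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ConfigError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ConfigError("need >= 3 observations")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0:
        raise ConfigError("zero predictor variance")
    if sy == 0:
        raise ConfigError("zero outcome variance")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = r * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    return RegressionSummary(r=r, n=n, slope=float(slope), intercept=intercept)


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

@dataclass
class BehaviorRecord:
    """Per-subject segment accuracy as % correct of the segment's trials."""

    subject: str
    segment: int | str
    n_correct: int
    n_trials: int

    @property
    def accuracy(self) -> float:
        return 100.0 * self.n_correct / self.n_trials


def segment_accuracy(
    trials: pd.DataFrame,
    segment: int,
    n_trials_per_block: int = 8,
    expected_total: int | None = None,
) -> list[BehaviorRecord]:
    """Percent accuracy per subject for one within-block segment.

    Segment 1 covers trials 1..half of each block (the first words of the
    block), segment 2 the remaining trials.  A trial with a missing
    ``correct`` flag (NaN) reduces the denominator; a trial row absent from
    the table counts as incorrect when ``expected_total`` is given (no
    response is an incorrect response).
    """
    if segment not in (1, 2):
        raise ConfigError("behaviour segments are 1 (first half) or 2 (last half)")
    half = n_trials_per_block // 2
    idx = trials["trial_index"].to_numpy()
    if idx.min() < 1 or idx.max() > n_trials_per_block:
        raise ConfigError("trial indices must lie in 1..n_trials_per_block")
    in_seg = idx <= half if segment == 1 else idx > half
    seg = trials.loc[in_seg]
    records = []
    for subject, sub in seg.groupby("subject", sort=True):
        flagged_missing = sub["correct"].isna()
        n_scored = int((~flagged_missing).sum())
        n_correct = int(sub.loc[~flagged_missing, "correct"].sum())
        n_total = n_scored
        if expected_total is not None:
            # absent rows count against the subject as incorrect
            n_total = expected_total - int(flagged_missing.sum())
        records.append(BehaviorRecord(str(subject), segment, n_correct, n_total))
    return records


# ---------------------------------------------------------------------------
# correlation machinery
# ---------------------------------------------------------------------------

def point_biserial(group: np.ndarray, values: np.ndarray) -> RegressionSummary:
    """Point-biserial correlation of a binary group label with a measure.

    Pearson correlation under 0/1 coding; |t| equals the equal-variance
    two-sample t statistic.
    """
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ConfigError(f"need exactly two groups, got {labels.size}")
    coded = (group == labels[1]).astype(float)
    return _corr_summary(coded, np.asarray(values, dtype=float))


def bold_behavior_regression(
    cluster_means: np.ndarray, accuracy: np.ndarray
) -> RegressionSummary:
    """Linear regression of segment % accuracy on cluster-mean activity."""
    return _corr_summary(cluster_means, accuracy)


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ConfigError("alpha must lie in (0, 1)")
    if m < 1:
        raise ConfigError("need >= 1 comparison")
    return alpha / m


def cohens_f2(r2_reduced: float, r2_full: float) -> float:
    """Cohen's f^2 for an increment in explained variance.

    ``f2 = (R2_full - R2_reduced) / (1 - R2_full)``.
    """
    if not 0 <= r2_reduced <= r2_full:
        raise ConfigError("require 0 <= r2_reduced <= r2_full")
    if r2_full >= 1:
        raise ConfigError("r2_full must be < 1")
    return (r2_full - r2_reduced) / (1.0 - r2_full)


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher's variance-stabilizing transform atanh(r)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ConfigError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    """Held-out squared errors (cve) and signed percent errors (PE)."""

    cve: np.ndarray
    pe: np.ndarray  # NaN where the observation was ~0 and PE is undefined
    predictions: np.ndarray

    @property
    def mean_cve(self) -> float:
        return float(self.cve.mean())

    @property
    def mean_pe(self) -> float:
        return float(np.nanmean(self.pe))


def loo_cv(zauc: np.ndarray, cbf: np.ndarray) -> CvResult:
    """Leave-one-out validation of the Z(AUC) ~ CBF coupling.

    For each held-out subject the intercept/slope are refit on the other
    n-1 subjects and the held-out activity is predicted from the held-out
    CBF; ``cve_k = (obs_k - pred_k)^2`` and ``PE_k = 100 (obs_k - pred_k)
    / obs_k``.  PE is undefined (NaN, with a warning) when the observation
    is numerically zero.
    """
    z = np.asarray(zauc, dtype=float)
    c = np.asarray(cbf, dtype=float)
    n = z.size
    if n < 4:
        raise ConfigError("leave-one-out needs >= 4 subjects")
    preds = np.empty(n)
    for k in range(n):
        keep = np.ones(n, dtype=bool)
        keep[k] = False
        fit = _corr_summary(c[keep], z[keep])
        preds[k] = fit.intercept + fit.slope * c[k]
    cve = (z - preds) ** 2
    pe = np.full(n, np.nan)
    ok = np.abs(z) > 1e-8
    pe[ok] = 100.0 * (z[ok] - preds[ok]) / z[ok]
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} folds dropped from the percent-error mean "
            "(observed value ~ 0)"
        )
    return CvResult(cve=cve, pe=pe, predictions=preds)


def _mode_values(zauc, cbf, model: str, keep: np.ndarray) -> np.ndarray:
    """Per-subject activity under one normalization model, fit on ``keep``."""
    z = np.asarray(zauc, dtype=float)
    c = np.asarray(cbf, dtype=float)
    if model == "standard":
        return z[keep]
    if model == "division":
        return z[keep] / c[keep]
    if model == "covariate":
        fit = _corr_summary(c[keep], z[keep])
        return z[keep] - (fit.intercept + fit.slope * c[keep])
    raise ConfigError(f"unknown model {model!r}")


def loo_behavior_r2(
    zauc: np.ndarray, cbf: np.ndarray, accuracy: np.ndarray, model: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-fold signed r and R^2 of the activity-behaviour regression.

    For each of the n folds the model is applied to the n-1 retained
    subjects (for the covariate model, the residualization is refit on
    exactly those subjects) and behaviour is regressed on the resulting
    activity.  Returns ``(r, r2)`` arrays of length n.
    """
    z = np.asarray(zauc, dtype=float)
    n = z.size
    if n < 4:
        raise ConfigError("leave-one-out needs >= 4 subjects")
    rs = np.empty(n)
    for k in range(n):
        keep = np.ones(n, dtype=bool)
        keep[k] = False
        vals = _mode_values(zauc, cbf, model, keep)
        rs[k] = _corr_summary(vals, np.asarray(accuracy, dtype=float)[keep]).r
    return rs, rs**2


def compare_models_loo(
    zauc: np.ndarray,
    cbf: np.ndarray,
    accuracy: np.ndarray,
    models: tuple[str, ...] = ("standard", "covariate", "division"),
) -> dict:
    """Fisher-z paired comparison of behaviour predictability across models.

    The per-fold correlations are Fisher-z transformed as atanh(r) with the
    sign of r retained (atanh of R^2 itself is not variance-stabilizing;
    recorded in the output metadata) and compared pairwise with paired
    t-tests over the n folds.
    """
    per_model = {}
    for m in models:
        r, r2 = loo_behavior_r2(zauc, cbf, accuracy, m)
        per_model[m] = {"r": r, "r2": r2, "fisher_z": fisher_z(r)}
    comparisons = {}
    names = list(models)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            t, p = sps.ttest_rel(per_model[a]["fisher_z"], per_model[b]["fisher_z"])
            comparisons[f"{a}_vs_{b}"] = {"t": float(t), "p": float(p)}
    return {
        "per_model": per_model,
        "comparisons": comparisons,
        "transform": "atanh(r), sign of r retained",
    }


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

def _sample_corr_pdf(r: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Density of the sample correlation under bivariate-normal sampling."""
    from scipy.special import gammaln, hyp2f1

    r = np.asarray(r, dtype=float)
    logc = (
        np.log(n - 2)
        + gammaln(n - 1)
        + 0.5 * (n - 1) * np.log1p(-(rho**2))
        - 0.5 * np.log(2 * np.pi)
        - gammaln(n - 0.5)
    )
    with np.errstate(divide="ignore"):
        logk = 0.5 * (n - 4) * np.log1p(-(r**2)) - (n - 1.5) * np.log1p(-rho * r)
    return np.exp(logc + logk) * hyp2f1(0.5, 0.5, n - 0.5, 0.5 * (1.0 + rho * r))


def achieved_power(
    slope: float,
    sd_x: float,
    sd_y: float,
    n: int,
    alpha: float = 0.05,
    method: str = "exact",
) -> float:
    """Achieved power of the two-sided t-test of zero regression slope.

    The slope and the marginal SDs imply a correlation
    ``rho = slope * sd_x / sd_y``.  ``method="exact"`` (default) integrates
    the exact bivariate-normal sampling density of the sample correlation
    over the rejection region ``|r| > r_crit``; ``method="approx"`` uses
    the classical noncentral-t approximation with
    ``delta = rho * sqrt(n) / sqrt(1 - rho^2)`` at df = n - 2 (slightly
    liberal because it ignores predictor sampling variability).
    """
    if sd_x <= 0 or sd_y <= 0:
        raise ConfigError("standard deviations must be positive")
    if n < 3:
        raise ConfigError("need n >= 3")
    if not 0 < alpha < 1:
        raise ConfigError("alpha must lie in (0, 1)")
    rho = slope * sd_x / sd_y
    if abs(rho) >= 1:
        raise ConfigError(f"implied correlation {rho:.3f} out of (-1, 1)")
    df = n - 2
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    if method == "approx":
        delta = rho * np.sqrt(n) / np.sqrt(1.0 - rho**2)
        return float(sps.nct.sf(tcrit, df, delta) + sps.nct.cdf(-tcrit, df, delta))
    if method != "exact":
        raise ConfigError("method must be 'exact' or 'approx'")
    from scipy.integrate import quad

    rcrit = tcrit / np.sqrt(df + tcrit**2)
    lo, _ = quad(_sample_corr_pdf, -1.0, -rcrit, args=(rho, n), limit=200)
    hi, _ = quad(_sample_corr_pdf, rcrit, 1.0, args=(rho, n), limit=200)
    return float(lo + hi)


# ---------------------------------------------------------------------------
# group maps and clusters
# ---------------------------------------------------------------------------

def group_map(
    maps_a: np.ndarray, maps_b: np.ndarray | None = None, welch: bool = False
) -> tuple[np.ndarray, int]:
    """Voxel-wise t-statistic map: one-sample vs 0 or two-sample A - B.

    ``maps_a``/``maps_b`` are (n_subjects, n_voxels) stacks.  Two-sample
    tests default to the pooled-variance statistic; Welch is available.
    Zero-variance voxels come back NaN.  Returns ``(t_values, df)``.
    """
    A = np.asarray(maps_a, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2:
        raise ConfigError("need a (n_subjects >= 2, n_voxels) stack")
    if maps_b is None:
        n = A.shape[0]
        sd = A.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = A.mean(axis=0) / (sd / np.sqrt(n))
        t[sd == 0] = np.nan
        return t, n - 1
    B = np.asarray(maps_b, dtype=float)
    if B.ndim != 2 or B.shape[0] < 2:
        raise ConfigError("both groups need >= 2 maps")
    na, nb = A.shape[0], B.shape[0]
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    diff = A.mean(axis=0) - B.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se = np.sqrt(va / na + vb / nb)
            t = diff / se
            df_arr = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
            df = int(np.floor(np.nanmedian(df_arr)))
        else:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            df = na + nb - 2
    t[(va == 0) & (vb == 0)] = np.nan
    return t, df


@dataclass
class ClusterReport:
    """One supra-threshold cluster of a thresholded statistic map."""

    label: int
    voxels: np.ndarray  # flat indices into the grid
    peak_ijk: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    peak_stat: float
    size_mm3: float
    sign: str  # "+" or "-"
    classification: str | None = None  # FP | FN | R

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.size)


_FACES = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _extract_clusters(
    stat: np.ndarray,
    mask: np.ndarray,
    stat_threshold: float,
    min_voxels: int,
    grid: VolumeGrid,
) -> list[ClusterReport]:
    """Signed 6-connected supra-threshold clusters of at least min_voxels."""
    out: list[ClusterReport] = []
    label_counter = 0
    finite = np.where(np.isfinite(stat) & mask, stat, 0.0)
    for sign, supra in (("+", finite >= stat_threshold), ("-", finite <= -stat_threshold)):
        labels, n = ndimage.label(supra, structure=_FACES)
        for lab in range(1, n + 1):
            vox = np.flatnonzero(labels.ravel() == lab)
            if vox.size < min_voxels:
                continue
            label_counter += 1
            vals = finite.ravel()[vox]
            peak_flat = vox[np.argmax(np.abs(vals))]
            ijk = np.unravel_index(peak_flat, stat.shape)
            out.append(
                ClusterReport(
                    label=label_counter,
                    voxels=vox,
                    peak_ijk=tuple(int(i) for i in ijk),
                    peak_mm=tuple(float(v) for v in grid.coords_mm(np.asarray(ijk))),
                    peak_stat=float(finite.ravel()[peak_flat]),
                    size_mm3=float(vox.size * grid.voxel_volume),
                    sign=sign,
                )
            )
    return sorted(out, key=lambda c: -c.n_voxels)


def simulate_extent_threshold(
    mask: np.ndarray,
    smoothness_fwhm_mm: float,
    grid: VolumeGrid,
    voxel_p: float = 0.01,
    fpr_target: float = 0.05,
    n_sims: int = 500,
    seed: int | np.random.Generator | None = None,
    two_sided: bool = True,
) -> int:
    """Monte-Carlo cluster-extent threshold (voxels) on smooth null fields.

    Simulates white Gaussian noise smoothed to the requested FWHM,
    standardized within the mask, thresholded at the voxel-wise p, and
    records the maximum supra-threshold 6-connected cluster size per
    simulation.  Returns the smallest extent k for which the simulated
    probability of any null cluster >= k is at most ``fpr_target``.
    """
    if n_sims < 100:
        raise ConfigError("need >= 100 simulations for a stable extent threshold")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = [
        smoothness_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v
        for v in grid.voxel_size
    ]
    zthr = (
        sps.norm.ppf(1.0 - voxel_p / 2.0) if two_sided else sps.norm.ppf(1.0 - voxel_p)
    )
    max_sizes = np.zeros(n_sims, dtype=int)
    mask = np.asarray(mask, dtype=bool)
    for s in range(n_sims):
        f = ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma)
        vals = f[mask]
        f = (f - vals.mean()) / vals.std()
        supra = mask & (f >= zthr)
        if two_sided:
            supra |= mask & (f <= -zthr)
        labels, n = ndimage.label(supra, structure=_FACES)
        if n:
            sizes = ndimage.sum_labels(supra, labels, index=np.arange(1, n + 1))
            max_sizes[s] = int(sizes.max())
    # smallest k with P(max cluster >= k) <= target
    for k in range(1, int(max_sizes.max()) + 2):
        if (max_sizes >= k).mean() <= fpr_target:
            return k
    return int(max_sizes.max()) + 1


def cluster_threshold(
    t_map: np.ndarray,
    mask: np.ndarray,
    df: int,
    grid: VolumeGrid,
    smoothness_fwhm_mm: float,
    voxel_p: float = 0.01,
    fpr_target: float = 0.05,
    n_sims: int = 500,
    seed: int | np.random.Generator | None = None,
    extent_voxels: int | None = None,
) -> tuple[list[ClusterReport], int]:
    """Threshold a t-map at the voxel p, then by Monte-Carlo cluster extent.

    ``extent_voxels`` may be supplied to reuse a precomputed threshold for
    the same mask/smoothness; otherwise it is simulated here.  Returns the
    surviving signed clusters and the extent threshold used.
    """
    t_map = np.asarray(t_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if t_map.shape != mask.shape or t_map.shape != tuple(grid.shape):
        raise GridError("t-map, mask and grid shapes must agree")
    if extent_voxels is None:
        extent_voxels = simulate_extent_threshold(
            mask, smoothness_fwhm_mm, grid, voxel_p, fpr_target, n_sims, seed
        )
    tthr = sps.t.ppf(1.0 - voxel_p / 2.0, df)
    clusters = _extract_clusters(t_map, mask, tthr, extent_voxels, grid)
    return clusters, int(extent_voxels)


def classify_effectiveness(
    clusters_standard: list[ClusterReport],
    clusters_sensitized: list[ClusterReport],
    grid_shape: tuple[int, int, int],
) -> list[ClusterReport]:
    """Label clusters as FP, FN or R by overlap before/after sensitization.

    A cluster significant only in the standard analysis is a false positive
    (FP: vascular variance masqueraded as activity); one significant only
    after sensitization is a recovered false negative (FN); clusters
    sharing at least one voxel across both analyses are retained (R).
    Returns new reports: FP clusters from the standard list, FN and R
    clusters from the sensitized list.
    """
    n_flat = int(np.prod(grid_shape))
    for cl in clusters_standard + clusters_sensitized:
        if cl.voxels.size and cl.voxels.max() >= n_flat:
            raise GridError("cluster voxel indices exceed the grid")
    std_sets = [set(c.voxels.tolist()) for c in clusters_standard]
    sens_sets = [set(c.voxels.tolist()) for c in clusters_sensitized]
    out: list[ClusterReport] = []
    for c, s in zip(clusters_standard, std_sets):
        overlaps = any(s & s2 for s2 in sens_sets)
        if not overlaps:
            out.append(ClusterReport(**{**c.__dict__, "classification": "FP"}))
    for c, s in zip(clusters_sensitized, sens_sets):
        overlaps = any(s & s2 for s2 in std_sets)
        out.append(
            ClusterReport(**{**c.__dict__, "classification": "R" if overlaps else "FN"})
        )
    return out


def clusters_to_frame(clusters: list[ClusterReport]) -> pd.DataFrame:
    """Tabular cluster report (one row per cluster)."""
    rows = []
    for c in clusters:
        rows.append(
            {
                "label": c.label,
                "n_voxels": c.n_voxels,
                "size_mm3": c.size_mm3,
                "peak_i": c.peak_ijk[0],
                "peak_j": c.peak_ijk[1],
                "peak_k": c.peak_ijk[2],
                "peak_x_mm": c.peak_mm[0],
                "peak_y_mm": c.peak_mm[1],
                "peak_z_mm": c.peak_mm[2],
                "peak_stat": c.peak_stat,
                "sign": c.sign,
                "classification": c.classification,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label", "n_voxels", "size_mm3", "peak_i", "peak_j", "peak_k",
            "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_stat", "sign",
            "classification",
        ],
    )
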