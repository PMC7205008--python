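"""BOLD sensitization: voxel-wise residualization of activity on CBF.

Task activity and baseline perfusion are coupled: the measured z-scored
segment activity of subject *j* at a voxel follows, across the group,

    Z(AUC)_measured,j = A + B * CBF_j + eps_j            (per voxel, per segment)

so part of the inter-subject variance in "standard" task activity is of
vascular, not neural, origin.  Sensitization fits the intercept/slope maps
(A, B) by voxel-wise ordinary least squares over subjects, predicts the
vascular component ``A + B * CBF_j`` and keeps the residual

    Z(AUC)_residual,j = Z(AUC)_measured,j - (A + B * CBF_j)

as the CBF-corrected ("sensitized") activity.  Because the model is linear
in its coefficients, the OLS closed form reaches the same optimum as an
iterative nonlinear least-squares fit, deterministically.

Two variants are provided for comparison: residualization on
*age-corrected* CBF (the age trend removed from CBF first, which leaves
age-related vascular variance inside the activity — the "unsensitized"
control condition), and per-subject voxel-wise *division* of activity by
CBF, the classical normalization whose failure to model the intercept A
inflates inter-subject variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .hrf import SegmentDef, ZAucMap


@dataclass
class SensitizationFit:
    """Per-voxel intercept/slope of the group Z(AUC) ~ CBF regression.

    ``intercept`` (z units) and ``slope`` (z per mL/100 g/min) are flat
    arrays over the junction-mask voxels; ``valid`` marks voxels with
    non-degenerate CBF variance where the fit is defined.
    """

    intercept: np.ndarray
    slope: np.ndarray
    residual_variance: np.ndarray
    valid: np.ndarray
    n_subjects: int
    segment: SegmentDef | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ConfigError("sensitization fit needs >= 3 subjects")
        for arr in (self.intercept, self.slope):
            if not np.all(np.isfinite(arr[self.valid])):
                raise ConfigError("non-finite fit coefficients on valid voxels")


def _stack(maps, attr: str = "values") -> np.ndarray:
    """Stack per-subject maps or arrays into (n_subjects, n_voxels)."""
    rows = []
    for m in maps:
        if isinstance(m, np.ndarray):
            rows.append(m.ravel())
        else:
            vals = getattr(m, attr)
            mask = getattr(m, "mask", None)
            if vals.ndim > 1 and mask is not None and vals.shape == mask.shape:
                vals = vals[mask]
            rows.append(np.asarray(vals, dtype=float).ravel())
    out = np.vstack(rows)
    return out


def fit_voxelwise(
    zauc_stack,
    cbf_stack,
    segment: SegmentDef | None = None,
) -> SensitizationFit:
    """Voxel-wise OLS of measured Z(AUC) on measured CBF across subjects.

    Inputs are per-subject maps (``ZAucMap`` / ``CbfMap`` restricted to the
    junction mask) or plain (n_subjects, n_voxels) arrays with matched
    subject order.  Voxels whose CBF has zero variance across subjects are
    flagged invalid and excluded.
    """
    Z = _stack(zauc_stack)
    C = _stack(cbf_stack)
    if Z.shape != C.shape:
        raise ConfigError(
            f"activity stack {Z.shape} and CBF stack {C.shape} do not match"
        )
    n = Z.shape[0]
    if n < 3:
        raise ConfigError("need >= 3 subjects for the voxel-wise regression")
    cmean = C.mean(axis=0)
    zmean = Z.mean(axis=0)
    dc = C - cmean
    dz = Z - zmean
    ssx = (dc**2).sum(axis=0)
    valid = ssx > 0
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} voxels with zero CBF variance excluded from fit"
        )
    slope = np.zeros(Z.shape[1])
    slope[valid] = (dc[:, valid] * dz[:, valid]).sum(axis=0) / ssx[valid]
    intercept = zmean - slope * cmean
    resid = Z - (intercept + slope * C)
    dof = max(n - 2, 1)
    rvar = (resid**2).sum(axis=0) / dof
    intercept[~valid] = np.nan
    slope[~valid] = np.nan
    rvar[~valid] = np.nan
    return SensitizationFit(
        intercept=intercept,
        slope=slope,
        residual_variance=rvar,
        valid=valid,
        n_subjects=n,
        segment=segment,
    )


def predict(fit: SensitizationFit, cbf) -> np.ndarray:
    """Vascular component ``A + B * CBF`` for one subject's CBF values.

    Voxels where the fit is undefined propagate NaN.
    """
    c = _stack([cbf])[0]
    if c.size != fit.intercept.size:
        raise ConfigError("CBF voxel count does not match the fit")
    return fit.intercept + fit.slope * c


def residualize(zauc, fit: SensitizationFit, cbf) -> np.ndarray:
    """Sensitized activity: measured minus the CBF-predicted component.

    For subjects included in the fit this is the in-sample OLS residual
    (sums to zero and is uncorrelated with CBF across those subjects); for
    a subject excluded from the fit it is the out-of-sample residual used
    by leave-one-out validation.
    """
    z = _stack([zauc])[0]
    pred = predict(fit, cbf)
    if z.size != pred.size:
        raise ConfigError("activity voxel count does not match the fit")
    return z - pred


def sensitize_group(zauc_stack, cbf_stack, segment=None):
    """Fit on all subjects and residualize each: (fit, predicted, residual).

    ``predicted`` and ``residual`` are (n_subjects, n_voxels) arrays.
    """
    fit = fit_voxelwise(zauc_stack, cbf_stack, segment)
    C = _stack(cbf_stack)
    Z = _stack(zauc_stack)
    pred = fit.intercept[None, :] + fit.slope[None, :] * C
    return fit, pred, Z - pred


def age_correct_cbf(cbf_values: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Remove the linear age trend from per-subject CBF values.

    ``cbf_values`` is (n_subjects,) or (n_subjects, n_voxels).  Returns the
    residual of CBF regressed on age, re-centred at the original mean, so
    the output is uncorrelated with age but keeps physiological units.
    """
    ages = np.asarray(ages, dtype=float)
    vals = np.asarray(cbf_values, dtype=float)
    squeeze = vals.ndim == 1
    if squeeze:
        vals = vals[:, None]
    if vals.shape[0] != ages.size:
        raise ConfigError("one age per subject required")
    if ages.size < 3:
        raise ConfigError("need >= 3 subjects")
    da = ages - ages.mean()
    ssa = (da**2).sum()
    if ssa == 0:
        raise ConfigError("constant ages: age correction undefined")
    mean = vals.mean(axis=0)
    slope = (da[:, None] * (vals - mean)).sum(axis=0) / ssa
    corrected = vals - da[:, None] * slope[None, :]
    return corrected[:, 0] if squeeze else corrected


def divide_normalize(zauc, cbf, floor: float = 1.0) -> np.ndarray:
    """Per-subject voxel-wise division of activity by CBF.

    The classical normalization comparator.  Voxels with |CBF| below
    ``floor`` (mL/100 g/min) are returned as NaN to avoid blow-ups; the
    caller receives a count via a warning.
    """
    z = _stack([zauc])[0]
    c = _stack([cbf])[0]
    if z.size != c.size:
        raise ConfigError("activity and CBF voxel counts differ")
    out = np.full_like(z, np.nan)
    ok = np.abs(c) >= floor
    out[ok] = z[ok] / c[ok]
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"{n_bad} voxels below the {floor} mL/100 g/min division floor")
    return out
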