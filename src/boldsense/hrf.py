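"""Hemodynamic response estimation from sparse-sampled task BOLD.

The task paradigm is a blocked overt word-generation design sampled sparsely
(one volume every TR = 4 s).  Each 8-trial block evokes a hemodynamic
response that is estimated voxel-wise with a finite-impulse-response
deconvolution using a piecewise-linear ("tent") basis: one basis function
per knot, equal to 1 at its knot and falling linearly to 0 at the adjacent
knots.  The default basis places 13 knots between -4 s and 44 s relative to
block onset, at the 4 s sampling interval.

The pipeline stages implemented here are

1. per-run scaling of the raw signal to percent change relative to the
   initial active-baseline window,
2. motion censoring of high-displacement volumes,
3. construction of the deconvolution design (tent columns summed over
   blocks plus per-run polynomial drift columns),
4. ordinary-least-squares deconvolution,
5. signed trapezoidal area under the estimated response over a time
   segment, and
6. z-transformation of the segment area across in-mask voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError, QCError

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")

#: Radius (mm) of the sphere used to convert rotations to displacements.
ROTATION_RADIUS_MM = 50.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TentBasis:
    """Evenly spaced piecewise-linear (tent) basis.

    ``knot_times`` are seconds relative to block onset.  Each basis function
    peaks at 1 on its own knot and is 0 at the neighbouring knots.
    """

    knot_times: np.ndarray

    def __post_init__(self) -> None:
        kt = np.asarray(self.knot_times, dtype=float)
        if kt.ndim != 1 or kt.size < 2:
            raise ConfigError("need at least two knots")
        d = np.diff(kt)
        if np.any(d <= 0):
            raise ConfigError("knots must be strictly increasing")
        if not np.allclose(d, d[0]):
            raise ConfigError("knots must be evenly spaced")
        self.knot_times = kt

    @classmethod
    def default(cls) -> "TentBasis":
        """13 knots from -4 s to 44 s at 4 s spacing."""
        return cls(np.linspace(-4.0, 44.0, 13))

    @property
    def spacing(self) -> float:
        return float(self.knot_times[1] - self.knot_times[0])

    @property
    def n_knots(self) -> int:
        return int(self.knot_times.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.knot_times[0]), float(self.knot_times[-1])

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Basis values at times ``t``: array (len(t), n_knots)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        u = (t[:, None] - self.knot_times[None, :]) / self.spacing
        return np.clip(1.0 - np.abs(u), 0.0, None)

    def interpolate(self, coefficients: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Piecewise-linear response at ``t`` given knot ``coefficients``.

        ``coefficients`` may be (n_knots,) or (n_knots, n_voxels).
        The response is 0 outside the basis span.
        """
        return self.evaluate(t) @ np.asarray(coefficients, dtype=float)


@dataclass
class SegmentDef:
    """Contiguous time interval of the block response.

    The standard segmentation of the 8-trial block response is
    Seg1 = (0, 16] s (first 4 trials), Seg2 = (16, 32] s (last 4 trials),
    Seg3 = (32, 44] s (post-stimulus), taken half-open so the segment areas
    are additive and knots on a boundary are not double counted.
    """

    index: int | str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ConfigError("segment must have positive length")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def standard_segments() -> dict[int | str, SegmentDef]:
    """Seg1-Seg3 plus the whole-response segment over (0, 44] s."""
    return {
        1: SegmentDef(1, 0.0, 16.0),
        2: SegmentDef(2, 16.0, 32.0),
        3: SegmentDef(3, 32.0, 44.0),
        "full": SegmentDef("full", 0.0, 44.0),
    }


@dataclass
class BoldSeries:
    """Sparse-sampled 4D BOLD series with its acquisition bookkeeping.

    ``values`` has shape ``grid.shape + (n_volumes,)``.  ``run_starts`` give
    the global time of the first volume of each run; scaling and drift
    modelling are per run.
    """

    values: np.ndarray
    tr: float
    block_onsets: np.ndarray
    motion: pd.DataFrame
    baseline_window: float = 12.0
    run_starts: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ConfigError("tr must be positive")
        self.block_onsets = np.asarray(self.block_onsets, dtype=float)
        self.run_starts = np.asarray(self.run_starts, dtype=float)
        if len(self.motion) != self.values.shape[-1]:
            raise ConfigError(
                f"motion table has {len(self.motion)} rows for "
                f"{self.values.shape[-1]} volumes"
            )
        t = self.volume_times
        if self.block_onsets.size and (
            self.block_onsets.min() < t.min() or self.block_onsets.max() > t.max()
        ):
            raise ConfigError("block onsets fall outside the series duration")

    @property
    def n_volumes(self) -> int:
        return int(self.values.shape[-1])

    @property
    def volume_times(self) -> np.ndarray:
        """Global acquisition time (s) of each volume, runs concatenated."""
        return np.arange(self.n_volumes) * self.tr


@dataclass
class HrfEstimate:
    """Per-voxel response amplitude (% BOLD change) at each basis knot."""

    coefficients: np.ndarray  # (n_knots, n_voxels)
    basis: TentBasis
    drift_order: int
    residual_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.coefficients.shape[0] != self.basis.n_knots:
            raise ConfigError("one coefficient per knot required")
        if not np.all(np.isfinite(self.coefficients)):
            raise ConfigError("non-finite deconvolution coefficients")


@dataclass
class ZAucMap:
    """Z-transformed segment area map for one subject and segment.

    ``role`` distinguishes the measured map, the CBF-based prediction, the
    residual ("sensitized") map, the age-corrected-CBF residual
    ("unsensitized") and the division-normalized comparator.
    """

    values: np.ndarray  # flat over mask voxels
    mask: np.ndarray
    segment: SegmentDef
    role: str = "measured"

    _ROLES = ("measured", "predicted", "residual", "unsensitized", "divided")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ConfigError(f"unknown role {self.role!r}; one of {self._ROLES}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != int(np.count_nonzero(self.mask)):
            raise ConfigError("values must be flat over in-mask voxels")

    def to_volume(self) -> np.ndarray:
        """Embed the flat in-mask values into a NaN-padded 3D volume."""
        vol = np.full(self.mask.shape, np.nan)
        vol[self.mask] = self.values
        return vol


# ---------------------------------------------------------------------------
# motion
# ---------------------------------------------------------------------------

def framewise_displacement(
    motion: pd.DataFrame | np.ndarray, radius_mm: float = ROTATION_RADIUS_MM
) -> np.ndarray:
    """Per-volume framewise displacement (mm).

    Defined as the maximum absolute backward difference across the six
    rigid-body parameters, with rotations (radians) converted to arc length
    on a sphere of ``radius_mm``.  The first volume has displacement 0.
    """
    if isinstance(motion, pd.DataFrame):
        params = motion[list(MOTION_COLUMNS)].to_numpy(dtype=float)
    else:
        params = np.asarray(motion, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ConfigError("motion table must have six rigid-body columns")
    if not np.all(np.isfinite(params)):
        raise ConfigError("non-finite motion parameters")
    params = params.copy()
    params[:, 3:] *= radius_mm
    fd = np.zeros(params.shape[0])
    fd[1:] = np.max(np.abs(np.diff(params, axis=0)), axis=1)
    return fd


def censor_volumes(
    motion: pd.DataFrame | np.ndarray, threshold_mm: float = 0.3
) -> np.ndarray:
    """Keep-mask over volumes: kept iff framewise displacement <= threshold.

    ``motion`` may be a six-column rigid-body table or a precomputed 1D
    displacement vector.  Raises :class:`QCError` if nothing survives.
    """
    arr = np.asarray(motion) if not isinstance(motion, pd.DataFrame) else None
    if arr is not None and arr.ndim == 1:
        fd = arr.astype(float)
        if not np.all(np.isfinite(fd)):
            raise ConfigError("non-finite displacements")
    else:
        fd = framewise_displacement(motion)
    keep = fd <= threshold_mm
    if not keep.any():
        raise QCError("motion censoring removed every volume")
    return keep


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def scale_to_percent_change(series: BoldSeries) -> np.ndarray:
    """Scale the raw signal to % change from the initial active baseline.

    Each run is scaled independently against the mean of its first
    ``baseline_window`` seconds of volumes:
    ``v' = 100 * (v - baseline_mean) / baseline_mean``.

    Returns an array shaped like ``series.values``.  Voxels whose baseline
    mean is zero (or nearly so) come back as NaN and should be dropped from
    the analysis mask.
    """
    vals = np.asarray(series.values, dtype=float)
    t = series.volume_times
    out = np.empty_like(vals)
    run_starts = series.run_starts
    run_edges = list(run_starts) + [np.inf]
    for r in range(len(run_starts)):
        in_run = (t >= run_edges[r]) & (t < run_edges[r + 1])
        base = in_run & (t < run_edges[r] + series.baseline_window)
        if base.sum() < 2:
            raise QCError(
                f"run {r}: baseline window holds {int(base.sum())} volumes (< 2)"
            )
        bmean = vals[..., base].mean(axis=-1)
        tiny = np.abs(bmean) < 1e-12 * np.nanmax(np.abs(bmean), initial=1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = 100.0 * (vals[..., in_run] - bmean[..., None]) / bmean[..., None]
        scaled[tiny] = np.nan
        out[..., in_run] = scaled
    return out


# ---------------------------------------------------------------------------
# design and deconvolution
# ---------------------------------------------------------------------------

def tent_design(
    basis: TentBasis,
    block_onsets: np.ndarray,
    volume_times: np.ndarray,
    run_starts: np.ndarray | None = None,
) -> np.ndarray:
    """Basis part of the design: tent columns summed over blocks.

    Entry (v, k) is the value at volume time ``t_v`` of tent ``k`` summed
    over every block onset, i.e. the regressor of the knot-``k`` response
    amplitude under linear superposition of block responses.  When
    ``run_starts`` is given (runs concatenated on a common clock), a
    block's response is confined to its own run: runs are acquired
    separately, so no response crosses a run boundary.
    """
    t = np.asarray(volume_times, dtype=float)
    onsets = np.asarray(block_onsets, dtype=float)
    X = np.zeros((t.size, basis.n_knots))
    if run_starts is None:
        edges = np.array([-np.inf, np.inf])
        run_of = lambda x: np.zeros(np.shape(x), dtype=int)  # noqa: E731
    else:
        starts = np.asarray(run_starts, dtype=float)
        edges = np.concatenate([starts, [np.inf]])
        run_of = lambda x: np.searchsorted(starts, x, side="right") - 1  # noqa: E731
    t_run = run_of(t)
    for onset, r in zip(onsets, np.atleast_1d(run_of(onsets))):
        in_run = t_run == r
        X[in_run] += basis.evaluate(t[in_run] - onset)
    return X


def drift_design(
    volume_times: np.ndarray,
    run_starts: np.ndarray,
    drift_order: int | None = None,
    tr: float | None = None,
) -> tuple[np.ndarray, int]:
    """Per-run Legendre polynomial drift columns.

    When ``drift_order`` is None it defaults to ``1 + floor(run_duration /
    150 s)`` per run (slow scanner drifts only).  Returns the column block
    and the order used.
    """
    t = np.asarray(volume_times, dtype=float)
    run_starts = np.asarray(run_starts, dtype=float)
    edges = list(run_starts) + [np.inf]
    cols = []
    order_used = 0
    for r in range(len(run_starts)):
        in_run = (t >= edges[r]) & (t < edges[r + 1])
        tr_run = t[in_run]
        dur = tr_run.max() - tr_run.min() + (tr or 0.0)
        order = drift_order if drift_order is not None else 1 + int(dur // 150.0)
        order_used = max(order_used, order)
        # map run time onto [-1, 1] for numerically stable polynomials
        u = np.zeros_like(tr_run)
        if tr_run.max() > tr_run.min():
            u = 2.0 * (tr_run - tr_run.min()) / (tr_run.max() - tr_run.min()) - 1.0
        for p in range(order + 1):
            c = np.zeros((t.size,))
            c[in_run] = np.polynomial.legendre.legval(u, [0.0] * p + [1.0])
            cols.append(c)
    return np.column_stack(cols), order_used


def build_design(
    basis: TentBasis,
    block_onsets: np.ndarray,
    volume_times: np.ndarray,
    drift_order: int | None = None,
    run_starts: np.ndarray | None = None,
    tr: float | None = None,
) -> tuple[np.ndarray, int]:
    """Full deconvolution design: tent columns then drift columns.

    Returns ``(X, n_basis)`` where the first ``n_basis`` columns are the
    tent regressors.  Raises :class:`DesignError` naming the offending
    columns if the design is rank deficient.
    """
    t = np.asarray(volume_times, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise DesignError("volume times must be strictly increasing")
    if run_starts is None:
        run_starts = np.array([t.min()])
    Xb = tent_design(basis, block_onsets, t, run_starts)
    Xd, _ = drift_design(t, run_starts, drift_order, tr)
    X = np.column_stack([Xb, Xd])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(j)
        raise DesignError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"dependent columns: {bad}"
        )
    return X, basis.n_knots


def deconvolve(
    scaled: np.ndarray,
    design: np.ndarray,
    n_basis: int,
    basis: TentBasis,
    keep: np.ndarray | None = None,
    drift_order: int = 0,
) -> HrfEstimate:
    """Voxel-wise OLS deconvolution of the scaled series.

    ``scaled`` is (n_volumes, n_voxels) percent-change data; ``design`` the
    matrix from :func:`build_design`.  ``keep`` removes censored volumes
    from both sides of the regression.  Residual variance is retained for
    quality control.
    """
    Y = np.asarray(scaled, dtype=float)
    if Y.ndim != 2:
        raise ConfigError("scaled data must be (n_volumes, n_voxels)")
    X = np.asarray(design, dtype=float)
    if keep is not None:
        keep = np.asarray(keep, dtype=bool)
        X = X[keep]
        Y = Y[keep]
    if X.shape[0] < X.shape[1]:
        raise DesignError(
            f"under-determined fit: {X.shape[0]} volumes for {X.shape[1]} regressors"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design is singular after censoring")
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = max(X.shape[0] - X.shape[1], 1)
    rvar = (resid**2).sum(axis=0) / dof
    return HrfEstimate(
        coefficients=coef[:n_basis],
        basis=basis,
        drift_order=drift_order,
        residual_variance=rvar,
    )


# ---------------------------------------------------------------------------
# segment quantification
# ---------------------------------------------------------------------------

def segment_auc(estimate: HrfEstimate, segment: SegmentDef) -> np.ndarray:
    """Signed area (%*s) under the piecewise-linear response over a segment.

    Exact for the tent model: the response is evaluated at the segment
    endpoints and every interior knot, and integrated with the trapezoid
    rule.  Deactivation contributes negatively.  Knots before time 0
    (anticipatory part of the window) never fall inside a standard segment.
    """
    lo, hi = estimate.basis.span
    if segment.t_start < lo - 1e-9 or segment.t_end > hi + 1e-9:
        raise ConfigError(
            f"segment ({segment.t_start}, {segment.t_end}] outside basis span {estimate.basis.span}"
        )
    knots = estimate.basis.knot_times
    interior = knots[(knots > segment.t_start) & (knots < segment.t_end)]
    pts = np.concatenate(([segment.t_start], interior, [segment.t_end]))
    resp = estimate.basis.interpolate(estimate.coefficients, pts)
    return np.trapezoid(resp, pts, axis=0)


def z_transform(
    auc: np.ndarray, mask: np.ndarray, segment: SegmentDef
) -> ZAucMap:
    """Z-transform a segment area map across in-mask voxels.

    Standardizes within subject and segment: ``(a - mean) / sd`` over the
    in-mask voxel population (sample SD, ddof=1), so group analyses compare
    like-scaled quantities across subjects.
    """
    mask = np.asarray(mask, dtype=bool)
    auc = np.asarray(auc, dtype=float)
    vals = auc[mask] if auc.shape == mask.shape else auc
    if vals.size < 2:
        raise ConfigError("z-transform needs >= 2 in-mask voxels")
    if not np.all(np.isfinite(vals)):
        raise ConfigError("non-finite segment areas inside mask")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ConfigError("zero variance: cannot z-transform a constant map")
    return ZAucMap((vals - vals.mean()) / sd, mask, segment, role="measured")
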