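"""Baseline cerebral blood flow quantification from pCASL.

A pseudo-continuous arterial spin labeling (pCASL) acquisition interleaves
control and label volumes; the pipeline censors motion-corrupted volumes
*pairwise* (a flagged volume always drops its partner), averages the
control-minus-label differences of the surviving pairs into a mean
perfusion-weighted image, and converts it to absolute CBF in
mL/100 g/min with the single-compartment kinetic model

    CBF = 6000 * lambda * dM * exp(PLD / T1b)
          -----------------------------------------
          2 * alpha * T1b * M0 * (1 - exp(-tau / T1b))

where ``dM`` is the perfusion-weighted difference signal, ``M0`` the fully
relaxed proton-density signal, ``tau`` the labeling duration, ``PLD`` the
post-labeling delay, ``T1b`` the longitudinal relaxation time of arterial
blood, ``alpha`` the labeling efficiency and ``lambda`` the blood-brain
partition coefficient.  Quantification constants default to the consensus
recommendations for 3 T pCASL and are recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError, GridError, QCError
from .grid import VolumeGrid
from .hrf import framewise_displacement


@dataclass(frozen=True)
class CbfQuantParams:
    """Single-compartment quantification constants.

    labeling_duration (tau, s), post_labeling_delay (PLD, s), blood_t1
    (T1b, s), labeling_efficiency (alpha) and partition_coefficient
    (lambda, mL/g).
    """

    labeling_duration: float = 1.5
    post_labeling_delay: float = 1.8
    blood_t1: float = 1.65
    labeling_efficiency: float = 0.85
    partition_coefficient: float = 0.9

    def __post_init__(self) -> None:
        vals = asdict(self)
        if any(not np.isfinite(v) or v <= 0 for v in vals.values()):
            raise ConfigError("quantification constants must be positive and finite")
        if not 0 < self.labeling_efficiency <= 1:
            raise ConfigError("labeling efficiency must lie in (0, 1]")

    @property
    def scale_factor(self) -> float:
        """Multiplier converting dM/M0 to mL/100 g/min."""
        tau, pld, t1b = self.labeling_duration, self.post_labeling_delay, self.blood_t1
        return (
            6000.0
            * self.partition_coefficient
            * np.exp(pld / t1b)
            / (2.0 * self.labeling_efficiency * t1b * (1.0 - np.exp(-tau / t1b)))
        )


@dataclass
class PcaslSeries:
    """Interleaved control/label series with its motion table and M0."""

    volumes: np.ndarray  # (..., 2 * n_pairs), control first within each pair
    motion: pd.DataFrame
    m0: np.ndarray
    control_first: bool = True

    def __post_init__(self) -> None:
        n = self.volumes.shape[-1]
        if n % 2:
            raise ConfigError("pCASL series must hold an even number of volumes")
        if len(self.motion) != n:
            raise ConfigError("motion table rows must match volume count")
        if self.m0.shape != self.volumes.shape[:-1]:
            raise GridError("M0 must share the pCASL grid")

    @property
    def n_pairs(self) -> int:
        return self.volumes.shape[-1] // 2

    def pair_volumes(self, pair: int) -> tuple[np.ndarray, np.ndarray]:
        """(control, label) volumes of a pair."""
        c, l = 2 * pair, 2 * pair + 1
        if not self.control_first:
            c, l = l, c
        return self.volumes[..., c], self.volumes[..., l]


@dataclass
class CbfMap:
    """Perfusion map in mL/100 g/min on a :class:`VolumeGrid`.

    ``variant`` records whether the map is as measured or has had the age
    trend removed.  ``flagged`` marks physiologically implausible voxels
    (negative or > 250 mL/100 g/min); they are reported, not silently
    altered.
    """

    values: np.ndarray
    grid: VolumeGrid
    mask: np.ndarray
    variant: str = "measured"
    flagged: np.ndarray | None = None

    PLAUSIBLE_MAX = 250.0

    def __post_init__(self) -> None:
        if self.values.shape != tuple(self.grid.shape):
            raise GridError("CBF values do not match the grid shape")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ConfigError("non-finite CBF inside mask")
        if self.flagged is None:
            self.flagged = self.mask & (
                (self.values < 0) | (self.values > self.PLAUSIBLE_MAX)
            )


# ---------------------------------------------------------------------------
# censoring and subtraction
# ---------------------------------------------------------------------------

def censor_pairs(
    series: PcaslSeries,
    threshold_mm: float = 0.5,
    max_fraction: float = 0.25,
) -> np.ndarray:
    """Indices of label/control pairs surviving motion censoring.

    A pair is dropped iff *either* member's framewise displacement exceeds
    ``threshold_mm`` — censoring never leaves an odd member.  If more than
    ``max_fraction`` of pairs would be discarded the dataset fails QC and a
    :class:`QCError` is raised.
    """
    fd = framewise_displacement(series.motion)
    bad_volume = fd > threshold_mm
    bad_pair = bad_volume.reshape(-1, 2).any(axis=1)
    dropped = int(bad_pair.sum())
    if dropped / series.n_pairs > max_fraction:
        raise QCError(
            f"{dropped}/{series.n_pairs} pairs "
            f"({100.0 * dropped / series.n_pairs:.1f}%) exceed the "
            f"{threshold_mm} mm threshold (limit {100 * max_fraction:.0f}%)"
        )
    return np.flatnonzero(~bad_pair)


def compute_perfusion(series: PcaslSeries, kept_pairs: np.ndarray) -> np.ndarray:
    """Mean control-minus-label difference volume over the kept pairs."""
    kept_pairs = np.asarray(kept_pairs, dtype=int)
    if kept_pairs.size == 0:
        raise QCError("no surviving label/control pairs")
    acc = np.zeros(series.volumes.shape[:-1])
    for p in kept_pairs:
        control, label = series.pair_volumes(int(p))
        acc += control - label
    return acc / kept_pairs.size


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def perfusion_signal(cbf: np.ndarray, m0: np.ndarray, params: CbfQuantParams) -> np.ndarray:
    """Forward model: perfusion-weighted difference signal for a CBF map."""
    return np.asarray(cbf, dtype=float) * np.asarray(m0, dtype=float) / params.scale_factor


def quantify_cbf(
    perfusion: np.ndarray,
    m0: np.ndarray,
    params: CbfQuantParams,
    grid: VolumeGrid,
    mask: np.ndarray | None = None,
) -> CbfMap:
    """Convert a mean perfusion-difference volume to absolute CBF.

    Voxels with non-positive M0 are excluded from the mask; implausible
    values are flagged in the returned map.
    """
    perfusion = np.asarray(perfusion, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if mask is None:
        mask = np.ones(perfusion.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool) & (m0 > 0)
    values = np.zeros_like(perfusion)
    with np.errstate(divide="ignore", invalid="ignore"):
        values[mask] = params.scale_factor * perfusion[mask] / m0[mask]
    return CbfMap(values=values, grid=grid, mask=mask, variant="measured")


def smooth_volume(
    volume: np.ndarray, fwhm_mm: float, voxel_size: tuple[float, float, float]
) -> np.ndarray:
    """Isotropic Gaussian smoothing with the kernel given as FWHM in mm."""
    if fwhm_mm <= 0:
        return np.asarray(volume, dtype=float)
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigmas = [sigma_mm / v for v in voxel_size]
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigmas)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_to_grid(cbf: CbfMap, target: VolumeGrid) -> CbfMap:
    """Trilinear resampling of a CBF map onto the analysis grid.

    The coverage mask is resampled with the same operator and thresholded
    at 0.5 so that downstream junction masking keeps CBF and activity maps
    on identical voxels.  Raises :class:`GridError` for disjoint fields of
    view.
    """
    if cbf.grid.same_geometry(target):
        return CbfMap(
            values=cbf.values.copy(),
            grid=target,
            mask=cbf.mask.copy(),
            variant=cbf.variant,
        )
    lo_s, hi_s = cbf.grid.bounds_mm()
    lo_t, hi_t = target.bounds_mm()
    if np.any(hi_s < lo_t) or np.any(hi_t < lo_s):
        raise GridError("source and target grids have disjoint fields of view")

    idx = np.indices(target.shape, dtype=float).reshape(3, -1).T
    mm = target.coords_mm(idx)
    src = (mm - np.asarray(cbf.grid.origin)) / np.asarray(cbf.grid.voxel_size)
    coords = src.T.reshape((3,) + tuple(target.shape))
    vals = ndimage.map_coordinates(cbf.values, coords, order=1, mode="constant", cval=0.0)
    mvals = ndimage.map_coordinates(
        cbf.mask.astype(float), coords, order=1, mode="constant", cval=0.0
    )
    return CbfMap(values=vals, grid=target, mask=mvals >= 0.5, variant=cbf.variant)


def process_pcasl(
    series: PcaslSeries,
    grid: VolumeGrid,
    params: CbfQuantParams | None = None,
    threshold_mm: float = 0.5,
    max_fraction: float = 0.25,
    smoothing_fwhm_mm: float = 0.0,
    mask: np.ndarray | None = None,
) -> tuple[CbfMap, dict]:
    """Censor, subtract, quantify; returns the CBF map and a QC record."""
    params = params or CbfQuantParams()
    kept = censor_pairs(series, threshold_mm, max_fraction)
    volumes = series.volumes
    m0 = series.m0
    if smoothing_fwhm_mm > 0:
        volumes = np.stack(
            [
                smooth_volume(volumes[..., i], smoothing_fwhm_mm, grid.voxel_size)
                for i in range(volumes.shape[-1])
            ],
            axis=-1,
        )
        m0 = smooth_volume(m0, smoothing_fwhm_mm, grid.voxel_size)
        series = PcaslSeries(volumes, series.motion, m0, series.control_first)
    perf = compute_perfusion(series, kept)
    cbf = quantify_cbf(perf, m0, params, grid, mask)
    qc = {
        "n_pairs": int(series.n_pairs),
        "kept_pairs": [int(k) for k in kept],
        "dropped_fraction": 1.0 - len(kept) / series.n_pairs,
        "quantification": asdict(params),
        "n_flagged_voxels": int(cbf.flagged.sum()),
    }
    return cbf, qc
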