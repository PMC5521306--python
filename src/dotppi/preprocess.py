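"""Denoising and standardization of volumetric ΔHbO time series.

Order of operations mirrors standard optical-tomography practice:
superficial (scalp) signal regression, zero-phase bandpass filtering
(0.02-0.5 Hz), temporal downsampling to 1 Hz, and field-of-view masking
from a flat-field sensitivity image.

Note the 0.5-Hz passband edge sits exactly at the 1-Hz output Nyquist
frequency; filtering happens at the acquisition rate before decimation,
and a warning is logged for the marginal band.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sp_signal

from .volume import VolumetricTimeSeries

__all__ = ["superficial_regress", "bandpass", "downsample", "fov_mask", "group_fov"]

log = logging.getLogger(__name__)


def superficial_regress(series: VolumetricTimeSeries, nuisance) -> VolumetricTimeSeries:
    """Remove a shared superficial signal from every voxel.

    Each voxel's series is replaced by the residual of a least-squares
    fit on [intercept, nuisance]; the output voxel-nuisance covariance
    is zero to numerical tolerance, and the operation is idempotent.
    """
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.ndim != 1 or nuisance.size != series.n_timepoints:
        raise ValueError(
            f"nuisance length {nuisance.size} != series length {series.n_timepoints}"
        )
    if np.ptp(nuisance) == 0:
        raise ValueError("nuisance regressor is constant; nothing to regress")
    X = np.column_stack([np.ones_like(nuisance), nuisance])
    V = series.flat()                                  # (voxels, T)
    beta = np.linalg.solve(X.T @ X, (V @ X).T)         # (2, voxels)
    resid = V - (X.astype(V.dtype) @ beta.astype(V.dtype)).T
    return series.with_data(resid.reshape(series.data.shape))


def bandpass(series: VolumetricTimeSeries, low: float = 0.02,
             high: float = 0.5, order: int = 3) -> VolumetricTimeSeries:
    """Zero-phase Butterworth bandpass along time.

    Forward-backward filtering (``sosfiltfilt``) doubles the effective
    order, giving >= 20 dB attenuation well outside the band while the
    maximally-flat passband stays within 1 dB.
    """
    nyq = series.rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    sos = sp_signal.butter(order, [low, high], btype="band", fs=series.rate,
                           output="sos")
    # float32 data is filtered in float32 (relative error ~1e-4, well below
    # the simulation noise floor); float64 stays float64
    if series.data.dtype == np.float32:
        sos = sos.astype(np.float32)
    log.info("bandpass %g-%g Hz, zero-phase Butterworth order %d", low, high, order)
    filtered = sp_signal.sosfiltfilt(sos, series.data, axis=-1)
    return series.with_data(filtered.astype(series.data.dtype, copy=False),
                            band=(low, high))


def downsample(series: VolumetricTimeSeries, target_rate: float = 1.0) -> VolumetricTimeSeries:
    """Decimate to ``target_rate`` by an integer factor.

    Anti-aliasing must be guaranteed by a prior bandpass; if the series
    was not filtered, or its upper band edge exceeds the new Nyquist
    frequency, a warning is logged (the standard 0.5-Hz edge at 1-Hz
    output is exactly marginal).
    """
    factor = series.rate / target_rate
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"rate {series.rate} Hz is not an integer multiple of target {target_rate} Hz"
        )
    new_nyq = target_rate / 2.0
    if series.band is None:
        log.warning("downsampling an unfiltered series: aliasing is not controlled")
    elif series.band[1] > new_nyq + 1e-12:
        log.warning(
            "band edge %g Hz is at or above the %g-Hz output Nyquist frequency",
            series.band[1], new_nyq,
        )
    data = series.data[..., :: int(round(factor))]
    return series.with_data(np.ascontiguousarray(data), rate=target_rate)


def fov_mask(sensitivity: np.ndarray, decades: float = 2.0) -> np.ndarray:
    """Field-of-view mask: voxels whose flat-field sensitivity lies
    within ``decades`` orders of magnitude of the maximum."""
    sens = np.asarray(sensitivity, dtype=float)
    if not np.any(sens > 0):
        raise ValueError("sensitivity image has no positive voxels")
    return sens >= sens.max() * 10.0 ** (-decades)


def group_fov(masks) -> np.ndarray:
    """Voxelwise AND of per-subject FOV masks."""
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one mask")
    out = np.asarray(masks[0], dtype=bool).copy()
    for m in masks[1:]:
        m = np.asarray(m, dtype=bool)
        if m.shape != out.shape:
            raise ValueError(f"mask shape {m.shape} != {out.shape}")
        out &= m
    return out
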