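"""Temporal and spatial alignment onto the common analysis support.

Temporal alignment puts every modality on the same 297 s window sampled at
20 Hz; the stimulus lag of a slow (hemodynamic) modality is estimated from
the cross-correlation between the stimulus audio envelope and the mean
response of the channels nearest an auditory region.  Spatial alignment
maps a volumetric support onto a source grid (nearest-coordinate pooling)
or onto an electrode montage (fixed-radius pooling).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist

from .containers import ChannelGeometry, Recording

__all__ = [
    "estimate_stimulus_lag",
    "trim_to_window",
    "map_volume_to_grid",
    "map_volume_to_electrodes",
]


def _lag_correlations(ref: np.ndarray, x: np.ndarray, max_lag: int) -> np.ndarray:
    """Pearson correlation of ``ref`` with ``x`` shifted by each lag in
    [-max_lag, max_lag].  Positive lag means ``x`` lags behind ``ref``."""
    T = len(ref)
    out = np.empty(2 * max_lag + 1)
    for i, lag in enumerate(range(-max_lag, max_lag + 1)):
        if lag >= 0:
            a, b = ref[: T - lag], x[lag:]
        else:
            a, b = ref[-lag:], x[: T + lag]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a @ a) * (b @ b))
        out[i] = (a @ b) / denom if denom > 0 else 0.0
    return out


def estimate_stimulus_lag(
    reference: np.ndarray,
    rec: Recording,
    geometry: ChannelGeometry,
    mask_tag: str = "auditory",
    n_nearest: int = 20,
    max_lag_s: float = 15.0,
    sign: str = "auto",
) -> float:
    """Lag (s) of ``rec`` relative to the stimulus ``reference`` envelope.

    The mean series of the ``n_nearest`` channels closest (Euclidean, mm)
    to the centroid of the ``mask_tag`` region is cross-correlated with the
    reference at every integer lag within +/- ``max_lag_s``; the argmax lag
    is returned.  ``sign='auto'`` maximizes the absolute correlation
    (hemodynamic coupling to band amplitude can be inverse at low
    frequencies); ``sign='positive'`` maximizes the signed correlation.

    Both series must share the sampling rate of ``rec``.
    """
    if max_lag_s <= 0:
        raise ValueError("max_lag_s must be positive")
    reference = np.asarray(reference, dtype=float)
    if np.ptp(reference) == 0:
        raise ValueError("flat reference envelope: lag is undefined")
    if len(reference) != rec.n_samples:
        raise ValueError("reference and recording must share length and rate")

    centroid = geometry.centroid_of_tag(mask_tag)
    dists = np.linalg.norm(geometry.coords - centroid, axis=1)
    if n_nearest > len(dists):
        warnings.warn(
            f"only {len(dists)} channels available; using all of them",
            RuntimeWarning,
            stacklevel=2,
        )
        n_nearest = len(dists)
    nearest = np.argsort(dists, kind="stable")[:n_nearest]
    mean_series = rec.data[nearest].mean(axis=0)

    max_lag = int(round(max_lag_s * rec.fs))
    corr = _lag_correlations(reference, mean_series, max_lag)
    score = np.abs(corr) if sign == "auto" else corr
    best = int(np.argmax(score))
    return (best - max_lag) / rec.fs


def trim_to_window(rec: Recording, t_start: float, duration: float) -> Recording:
    """Extract the ``[t_start, t_start + duration]`` window (s, relative to
    the start of the recording)."""
    if t_start < -1e-9 or t_start + duration > rec.duration_s + 0.5 / rec.fs:
        raise ValueError(
            f"window [{t_start}, {t_start + duration}] s outside recording of "
            f"{rec.duration_s} s"
        )
    i0 = int(round(t_start * rec.fs))
    n = int(round(duration * rec.fs))
    if i0 == 0 and n == rec.n_samples:
        return rec.copy_with()
    return rec.copy_with(data=rec.data[:, i0 : i0 + n].copy(), t0=rec.t0 + i0 / rec.fs)


def map_volume_to_grid(
    vol: Recording, vol_geom: ChannelGeometry, grid_geom: ChannelGeometry
) -> Recording:
    """Pool voxel series onto a source grid by nearest-coordinate assignment.

    Every voxel is assigned to its nearest grid point (Euclidean, mm; ties
    broken toward the lowest grid index) and each grid point receives the
    mean series of its assigned voxels.  Grid points with no assigned voxel
    are flagged missing in ``meta['missing_mask']``.
    """
    if vol_geom.n_channels == 0 or grid_geom.n_channels == 0:
        raise ValueError("empty geometry")
    if grid_geom.kind != "grid" or vol_geom.kind != "voxel":
        raise ValueError("expected grid_geom.kind='grid' and vol_geom.kind='voxel'")
    if vol.n_channels != vol_geom.n_channels:
        raise ValueError("volume channel count does not match its geometry")

    d = cdist(vol_geom.coords, grid_geom.coords)
    assign = np.argmin(d, axis=1)  # first minimum -> lowest grid index on ties
    n_grid = grid_geom.n_channels
    counts = np.bincount(assign, minlength=n_grid)
    sums = np.zeros((n_grid, vol.n_samples))
    np.add.at(sums, assign, vol.data)
    missing = counts == 0
    out = np.zeros_like(sums)
    out[~missing] = sums[~missing] / counts[~missing, None]
    return vol.copy_with(
        data=out,
        geometry=grid_geom,
        meta={"missing_mask": missing, "voxel_counts": counts},
    )


def map_volume_to_electrodes(
    vol: Recording,
    vol_geom: ChannelGeometry,
    montage_geom: ChannelGeometry,
    radius_mm: float = 6.0,
) -> Recording:
    """Pool voxel series onto electrodes: mean over voxels within
    ``radius_mm`` of each electrode.

    Per-electrode voxel counts are kept in ``meta['voxel_counts']``;
    electrodes with no voxel in range are flagged in
    ``meta['missing_mask']`` and must be excluded downstream.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    if vol_geom.n_channels == 0 or montage_geom.n_channels == 0:
        raise ValueError("empty geometry")
    if vol.n_channels != vol_geom.n_channels:
        raise ValueError("volume channel count does not match its geometry")

    d = cdist(montage_geom.coords, vol_geom.coords)
    within = d <= radius_mm
    counts = within.sum(axis=1)
    missing = counts == 0
    out = np.zeros((montage_geom.n_channels, vol.n_samples))
    for i in np.nonzero(~missing)[0]:
        out[i] = vol.data[within[i]].mean(axis=0)
    return vol.copy_with(
        data=out,
        geometry=montage_geom,
        meta={"missing_mask": missing, "voxel_counts": counts},
    )
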