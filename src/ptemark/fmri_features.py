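"""ALFF and ROI-connectivity features from 4-D time series.

ALFF (amplitude of low-frequency fluctuations) is computed as periodogram
band power in 0.01-0.1 Hz under the Parseval convention: summing the
periodogram over *all* bins recovers the series variance, so the in-band sum
is the portion of signal variance living in the band.  Connectivity is the
15x15 Pearson matrix of ROI-mean signals, vectorized over the strict upper
triangle after a Fisher z transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_cohort import CohortConfig, Parcellation

__all__ = [
    "ConnectivityFeatures",
    "roi_mean_timeseries",
    "alff",
    "voxel_alff",
    "lobe_alff",
    "connectivity",
    "upper_triangle_pairs",
    "Z_CLIP",
]

# |r| = 1 would give infinite Fisher z; clip to keep features finite.
Z_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class ConnectivityFeatures:
    """Pearson correlation matrix and its Fisher-z upper-triangle vector."""

    matrix: np.ndarray  # (n_roi, n_roi)
    z_vector: np.ndarray  # (n_roi * (n_roi - 1) / 2,), row-major upper triangle
    pair_names: tuple[tuple[str, str], ...]


def roi_mean_timeseries(ts: np.ndarray, parcellation: Parcellation) -> np.ndarray:
    """Arithmetic mean series over each ROI's member voxels, in ROI-table order.

    ``ts`` has shape ``grid_shape + (T,)``; the result is ``(n_roi, T)``.
    """
    if ts.shape[:3] != parcellation.label_volume.shape:
        raise ValueError(
            f"time-series grid {ts.shape[:3]} does not match parcellation grid "
            f"{parcellation.label_volume.shape}"
        )
    out = np.empty((len(parcellation.roi_table), ts.shape[-1]), dtype=np.float64)
    for k, (roi_id, name) in enumerate(parcellation.roi_table):
        sel = parcellation.label_volume == roi_id
        if not sel.any():
            raise ValueError(f"ROI {name!r} (label {roi_id}) has no voxels")
        out[k] = ts[sel].mean(axis=0)
    return out


def _band_bins(n: int, tr: float, band: tuple[float, float]) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=tr)
    nyquist = 1.0 / (2.0 * tr)
    if not (0.0 <= band[0] < band[1] <= nyquist):
        raise ValueError(f"band {band} outside (0, Nyquist={nyquist:g}) Hz")
    return (freqs >= band[0]) & (freqs <= band[1])


def _periodogram_power(x: np.ndarray) -> np.ndarray:
    """Per-bin power of demeaned rows, normalized so the bins sum to the
    (population) variance of each row."""
    t = x.shape[-1]
    xd = x - x.mean(axis=-1, keepdims=True)
    spectrum = np.fft.rfft(xd, axis=-1)
    p = np.abs(spectrum) ** 2 / t**2
    # double the interior bins (negative-frequency mirror); DC is zero after
    # demeaning, the Nyquist bin (even T) has no mirror
    scale = np.full(p.shape[-1], 2.0)
    scale[0] = 1.0
    if t % 2 == 0:
        scale[-1] = 1.0
    return p * scale


def alff(
    series: np.ndarray,
    repetition_interval: float,
    band: tuple[float, float] = (0.01, 0.1),
) -> float:
    """Band power of one series: sum of periodogram bins with f in [low, high].

    With the Parseval normalization used here the total over all bins equals
    the series variance, so a pure in-band sinusoid of amplitude A yields
    approximately A^2/2.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1:
        raise ValueError("series must be 1-D")
    if series.size < 16:
        raise ValueError("series too short (need >= 16 timepoints)")
    keep = _band_bins(series.size, repetition_interval, band)
    return float(_periodogram_power(series[None, :])[0, keep].sum())


def voxel_alff(
    ts: np.ndarray,
    repetition_interval: float,
    band: tuple[float, float] = (0.01, 0.1),
) -> np.ndarray:
    """Per-voxel ALFF over a ``grid + (T,)`` array (vectorized)."""
    t = ts.shape[-1]
    keep = _band_bins(t, repetition_interval, band)
    flat = ts.reshape(-1, t).astype(np.float64)
    p = _periodogram_power(flat)[:, keep].sum(axis=1)
    return p.reshape(ts.shape[:-1])


def lobe_alff(
    ts: np.ndarray, parcellation: Parcellation, config: CohortConfig
) -> np.ndarray:
    """Per-voxel ALFF averaged within each ROI, ordered per the ROI table."""
    if ts.shape[:3] != parcellation.label_volume.shape:
        raise ValueError("time-series grid does not match parcellation grid")
    amap = voxel_alff(ts, config.repetition_interval, config.alff_band)
    out = np.empty(len(parcellation.roi_table))
    for k, (roi_id, name) in enumerate(parcellation.roi_table):
        sel = parcellation.label_volume == roi_id
        if not sel.any():
            raise ValueError(f"ROI {name!r} (label {roi_id}) has no voxels")
        out[k] = amap[sel].mean()
    return out


def upper_triangle_pairs(names: tuple[str, ...]) -> tuple[tuple[str, str], ...]:
    """Row-major strict-upper-triangle ROI pairs: (1,2), (1,3), ..., (14,15)."""
    n = len(names)
    iu = np.triu_indices(n, k=1)
    return tuple((names[i], names[j]) for i, j in zip(*iu))


def connectivity(
    roi_ts: np.ndarray, roi_names: tuple[str, ...] | None = None
) -> ConnectivityFeatures:
    """Pearson matrix of ROI series plus its Fisher-z upper-triangle vector.

    Perfect correlations are clipped to |r| = 1 - 1e-7 before atanh so the
    feature vector stays finite.
    """
    roi_ts = np.asarray(roi_ts, dtype=np.float64)
    if roi_ts.ndim != 2 or roi_ts.shape[1] < 3:
        raise ValueError("roi_ts must be (n_roi, T) with T >= 3")
    sd = roi_ts.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        name = roi_names[bad] if roi_names else f"index {bad}"
        raise ValueError(f"constant time series in ROI {name}")
    r = np.corrcoef(roi_ts)
    iu = np.triu_indices(r.shape[0], k=1)
    z = np.arctanh(np.clip(r[iu], -Z_CLIP, Z_CLIP))
    names = roi_names if roi_names is not None else tuple(
        f"roi{k + 1}" for k in range(r.shape[0])
    )
    return ConnectivityFeatures(
        matrix=r, z_vector=z, pair_names=upper_triangle_pairs(names)
    )
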