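"""ADC time-course construction and temporal filtering.

An interleaved diffusion-weighted series alternating two b-values is split
into per-b-value series at half the sampling rate; the apparent diffusion
coefficient time course is then

    ADC(t) = ln(S_low(t) / S_high(t)) / (b_high - b_low)

which is algebraically the familiar 1/(b1-b2) * ln(S2/S1) written without a
negative denominator.  Any multiplicative factor common to both b-values
(T2-weighting, BOLD) cancels in the ratio — the property that makes the
ADC time course insensitive to hemodynamic T2* modulation.

A pairwise-interpolated ADC series at the original 1-s sampling is provided
for plotting epoch averages; statistical analysis uses the native 2-s
series only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .paradigm import AcquisitionScheme
from .phantom import VolumeSeries

__all__ = [
    "ADCSeries",
    "split_interleaved",
    "compute_adc",
    "interpolate_pairwise_adc",
    "highpass_filter",
    "drift_basis",
]


@dataclass
class ADCSeries:
    """4-D apparent-diffusion-coefficient time series (mm^2/s)."""

    data: np.ndarray
    tr_s: float
    b_pair: tuple[float, float]
    interpolated: bool = False
    valid_mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.data.shape[:3], dtype=bool)
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


def split_interleaved(
    series: VolumeSeries, scheme: AcquisitionScheme
) -> tuple[VolumeSeries, VolumeSeries]:
    """Split a strictly alternating two-b-value series per b-value.

    Returns ``(b_low_series, b_high_series)``, each with doubled TR and the
    original volume indices recorded in ``source_volume_indices``.
    """
    if series.contrast != "dw_interleaved":
        raise ValueError(f"expected dw_interleaved series, got {series.contrast!r}")
    bvals = series.bvals
    n = series.n_volumes
    if n % 2 != 0:
        raise ValueError(f"interleaved series must have even length, got {n}")
    expected = scheme.bval_vector(n)
    mismatch = np.nonzero(bvals != expected)[0]
    if len(mismatch):
        i = int(mismatch[0])
        raise ValueError(
            f"b-value vector does not alternate as configured at index {i}: "
            f"got {bvals[i]}, expected {expected[i]}"
        )
    low_first = bvals[0] == scheme.b_low
    lo_idx = np.arange(0 if low_first else 1, n, 2)
    hi_idx = np.arange(1 if low_first else 0, n, 2)

    def sub(idx: np.ndarray, b: float) -> VolumeSeries:
        return VolumeSeries(
            data=series.data[..., idx],
            tr_s=series.tr_s * 2,
            contrast="dw_single",
            bvals=np.full(len(idx), b),
            affine=series.affine,
            source_volume_indices=idx,
        )

    return sub(lo_idx, scheme.b_low), sub(hi_idx, scheme.b_high)


def reinterleave(low: VolumeSeries, high: VolumeSeries) -> VolumeSeries:
    """Inverse of :func:`split_interleaved` (uses the recorded indices)."""
    n = low.n_volumes + high.n_volumes
    data = np.empty((*low.shape3d, n), dtype=low.data.dtype)
    bvals = np.empty(n)
    for part in (low, high):
        data[..., part.source_volume_indices] = part.data
        bvals[part.source_volume_indices] = part.bvals
    return VolumeSeries(
        data=data, tr_s=low.tr_s / 2, contrast="dw_interleaved",
        bvals=bvals, affine=low.affine,
    )


def _check_compatible(low: VolumeSeries, high: VolumeSeries) -> None:
    if low.shape3d != high.shape3d:
        raise ValueError(f"geometry mismatch: {low.shape3d} vs {high.shape3d}")
    if low.n_volumes != high.n_volumes:
        raise ValueError(
            f"length mismatch: {low.n_volumes} vs {high.n_volumes} volumes"
        )
    if low.tr_s != high.tr_s:
        raise ValueError(f"TR mismatch: {low.tr_s} vs {high.tr_s}")


def compute_adc(
    low: VolumeSeries, high: VolumeSeries, b_pair: tuple[float, float]
) -> ADCSeries:
    """Native-resolution ADC time series from paired b-value series.

    Voxels with a nonpositive signal at any time point in either series are
    flagged invalid in ``valid_mask`` (and set to NaN) rather than clipped:
    magnitude noise at very low SNR can produce near-zero values, and such
    voxels must be excluded from inference, not silently altered.
    """
    _check_compatible(low, high)
    b_low, b_high = b_pair
    if not b_high > b_low:
        raise ValueError("need b_high > b_low")
    valid = np.all(low.data > 0, axis=3) & np.all(high.data > 0, axis=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc = np.log(low.data / high.data) / (b_high - b_low)
    adc[~valid] = np.nan
    return ADCSeries(
        data=adc, tr_s=low.tr_s, b_pair=(b_low, b_high),
        interpolated=False, valid_mask=valid, affine=low.affine,
    )


def interpolate_pairwise_adc(
    low: VolumeSeries, high: VolumeSeries, b_pair: tuple[float, float]
) -> ADCSeries:
    """ADC at the original (1-s) sampling from measured/interpolated pairs.

    Both per-b-value series are linearly interpolated onto the 1-s grid; at
    each time point the ADC is computed from one measured and one
    interpolated b-value.  Endpoints beyond the first/last measurement of a
    series use the nearest measurement.  Output length is
    ``2 * n_native - 1`` and the series is flagged ``interpolated``; it is
    meant for plotting epoch averages, never for GLM inference.
    """
    _check_compatible(low, high)
    b_low, b_high = b_pair
    n = low.n_volumes
    if low.source_volume_indices is None or high.source_volume_indices is None:
        raise ValueError("series must carry source_volume_indices from the split")
    lo_t = np.asarray(low.source_volume_indices, dtype=float)
    hi_t = np.asarray(high.source_volume_indices, dtype=float)
    t_out = np.arange(2 * n - 1, dtype=float)  # original-TR grid

    def interp(series_t: np.ndarray, data: np.ndarray) -> np.ndarray:
        flat = data.reshape(-1, n)
        out = np.empty((flat.shape[0], len(t_out)))
        for i, row in enumerate(flat):
            # np.interp clamps to the end values = nearest-measurement rule
            out[i] = np.interp(t_out, series_t, row)
        return out.reshape(*data.shape[:3], len(t_out))

    lo_full = interp(lo_t, low.data)
    hi_full = interp(hi_t, high.data)
    # measured samples overwrite interpolants at their own time points
    # (the final measurement of the later-sampled series falls past the
    # 2n-1 grid and is dropped)
    lo_in = lo_t < len(t_out)
    hi_in = hi_t < len(t_out)
    lo_full[..., lo_t[lo_in].astype(int)] = low.data[..., lo_in]
    hi_full[..., hi_t[hi_in].astype(int)] = high.data[..., hi_in]

    valid = np.all(lo_full > 0, axis=3) & np.all(hi_full > 0, axis=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc = np.log(lo_full / hi_full) / (b_high - b_low)
    adc[~valid] = np.nan
    return ADCSeries(
        data=adc, tr_s=low.tr_s / 2, b_pair=(b_low, b_high),
        interpolated=True, valid_mask=valid, affine=low.affine,
    )


def drift_basis(n: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Low-frequency drift basis spanning periods >= ``cutoff_s``.

    Discrete cosine *and* sine components at half-cycle frequencies
    ``k = 1 .. floor(2*n*tr_s / cutoff_s)`` (component ``k`` has period
    ``2*n*tr_s / k``).  Both quadratures are needed so that drift of
    arbitrary phase and non-integer frequency is removed, not merely
    attenuated.
    """
    order = int(np.floor(2.0 * n * tr_s / cutoff_s))
    if order < 1:
        return np.empty((n, 0))
    t = np.arange(n)
    cols = []
    for k in range(1, order + 1):
        arg = np.pi * k * (2 * t + 1) / (2.0 * n)
        cols.append(np.cos(arg))
        cols.append(np.sin(arg))
    return np.column_stack(cols)


def highpass_filter(data: np.ndarray, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Remove slow drifts by regressing out a cosine basis; keep the mean.

    Works on the last axis of any array (typically ``(x, y, z, t)``).
    Fluctuations with period longer than ``cutoff_s`` are removed without
    phase distortion; the temporal mean is restored so absolute signal
    levels (needed for baseline normalization) are preserved.  NaN voxels
    pass through unchanged.
    """
    if cutoff_s <= 2 * tr_s:
        raise ValueError(f"cutoff {cutoff_s} s must exceed twice the TR ({tr_s} s)")
    n = data.shape[-1]
    if n * tr_s < cutoff_s:
        warnings.warn(
            f"series of {n * tr_s} s shorter than the {cutoff_s}-s cutoff; "
            "high-pass filter skipped",
            stacklevel=2,
        )
        return data.copy()
    basis = drift_basis(n, tr_s, cutoff_s)
    if basis.shape[1] == 0:
        return data.copy()
    flat = data.reshape(-1, n)
    mean = flat.mean(axis=1, keepdims=True)
    centered = flat - mean
    # OLS projection onto the drift basis, removed from the data
    coef, *_ = np.linalg.lstsq(basis, centered.T, rcond=None)
    filtered = centered - (basis @ coef).T + mean
    return filtered.reshape(data.shape)
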