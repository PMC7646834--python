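"""Spectral preprocessing for MSI datasets.

The chain follows the common MALDI-TOF imaging recipe: per-pixel baseline
subtraction (rolling minimum + smoothing), TIC normalization to the dataset
mean total ion current, sparse peak picking on a stride of pixels followed
by greedy m/z alignment, and resampling of every pixel onto a common
feature axis — either peak-height extraction against the aligned peak list
("height" resampling) or dense linear-interpolation binning on a fixed m/z
grid (default 700–2500 Da, 0.25 Da steps, endpoints inclusive = 7201 bins).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks

from .msi_io import MSIDataset

__all__ = [
    "PeakList",
    "FeatureMatrix",
    "subtract_baseline",
    "subtract_baseline_dataset",
    "tic_normalize",
    "pick_peaks",
    "align_peaks",
    "resample_height",
    "bin_resample",
]


@dataclass
class PeakList:
    """Aligned (or raw) peaks: ascending m/z with intensity and SNR."""

    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray
    source_pixel_count: int = 0
    tolerance: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        self.snr = np.asarray(self.snr, dtype=np.float64)
        if np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz, self.intensity, self.snr = (
                self.mz[order], self.intensity[order], self.snr[order])
        if np.any(self.snr < 0):
            raise ValueError("SNR must be non-negative")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class FeatureMatrix:
    """Rows (pixels or samples) x features (m/z grid or protein ids).

    ``row_meta`` carries provenance: pixel coordinates, patient id and
    pathology label where known.
    """

    values: np.ndarray
    feature_axis: np.ndarray
    row_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.feature_axis = np.asarray(self.feature_axis)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_axis):
            raise ValueError("feature_axis length must match value columns")
        if np.issubdtype(self.feature_axis.dtype, np.number):
            if np.any(np.diff(self.feature_axis.astype(float)) <= 0):
                raise ValueError("numeric feature axis must be strictly increasing")
        if len(self.row_meta) and len(self.row_meta) != self.values.shape[0]:
            raise ValueError("row_meta length must match value rows")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @staticmethod
    def concat(matrices: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        if not matrices:
            raise ValueError("nothing to concatenate")
        axis0 = matrices[0].feature_axis
        for m in matrices[1:]:
            if not np.array_equal(m.feature_axis, axis0):
                raise ValueError("feature axes differ; resample to a common grid first")
        return FeatureMatrix(
            values=np.vstack([m.values for m in matrices]),
            feature_axis=axis0,
            row_meta=pd.concat([m.row_meta for m in matrices], ignore_index=True),
        )

    def save_hdf5(self, path: str | Path) -> Path:
        import h5py

        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            axis = self.feature_axis
            if not np.issubdtype(axis.dtype, np.number):
                axis = axis.astype("S")
            f.create_dataset("feature_axis", data=axis)
            meta = f.create_group("row_meta")
            for col in self.row_meta.columns:
                data = self.row_meta[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                meta.create_dataset(col, data=data)
        return path

    @staticmethod
    def load_hdf5(path: str | Path) -> "FeatureMatrix":
        import h5py

        with h5py.File(path, "r") as f:
            values = f["values"][...]
            axis = f["feature_axis"][...]
            if axis.dtype.kind == "S":
                axis = axis.astype(str)
            meta = {}
            for col in f["row_meta"]:
                data = f["row_meta"][col][...]
                if data.dtype.kind == "S":
                    data = data.astype(str)
                meta[col] = data
        return FeatureMatrix(values, axis, pd.DataFrame(meta))


# ---------------------------------------------------------------------------
# Baseline


def subtract_baseline(mz: np.ndarray, intensities: np.ndarray,
                      half_window: float = 25.0) -> np.ndarray:
    """Remove a slowly varying baseline from one spectrum.

    The baseline estimate is a rolling minimum over +-``half_window`` Da
    followed by a moving-average smooth of the same width, clipped from
    above by the original signal so the subtraction never goes negative.
    """
    mz = np.asarray(mz, dtype=np.float64)
    intensities = np.asarray(intensities, dtype=np.float64)
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    span = mz[-1] - mz[0]
    if 2 * half_window > span:
        raise ValueError(f"window {2 * half_window} Da wider than axis span {span} Da")
    step = np.median(np.diff(mz))
    w = max(int(round(half_window / step)) * 2 + 1, 3)
    baseline = minimum_filter1d(intensities, size=w, mode="nearest")
    baseline = uniform_filter1d(baseline, size=w, mode="nearest")
    baseline = np.minimum(baseline, intensities)
    return intensities - baseline


def subtract_baseline_dataset(dataset: MSIDataset, half_window: float = 25.0) -> MSIDataset:
    """Apply :func:`subtract_baseline` to every pixel."""
    out = dataset.copy()
    out.intensities = [
        subtract_baseline(mz, inten, half_window).astype(np.float32)
        for mz, inten in zip(out.mz_axes, out.intensities)
    ]
    return out


# ---------------------------------------------------------------------------
# TIC normalization


def tic_normalize(obj, target_sum: float | None = None):
    """Scale every spectrum so its total ion current equals the dataset mean.

    All spectra share one post-normalization sum: the mean TIC of the input
    (or ``target_sum`` if given, e.g. 1.0 for unit normalization).  Accepts
    an :class:`MSIDataset`, a :class:`FeatureMatrix` or a 2-D array (rows =
    spectra) and returns the same shape.  All-zero spectra are an error
    naming the pixel/row.
    """
    if isinstance(obj, MSIDataset):
        sums = np.array([float(np.sum(i)) for i in obj.intensities])
        _check_tics(sums, obj.coordinates)
        target = float(np.mean(sums)) if target_sum is None else float(target_sum)
        out = obj.copy()
        out.intensities = [
            (inten * (target / s)).astype(np.float32)
            for inten, s in zip(out.intensities, sums)
        ]
        return out
    if isinstance(obj, FeatureMatrix):
        vals = _tic_normalize_matrix(obj.values, target_sum,
                                     labels=list(obj.row_meta.index))
        return FeatureMatrix(vals, obj.feature_axis, obj.row_meta)
    arr = np.atleast_2d(np.asarray(obj, dtype=np.float64))
    return _tic_normalize_matrix(arr, target_sum, labels=list(range(arr.shape[0])))


def _check_tics(sums: np.ndarray, labels) -> None:
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise ValueError(f"all-zero spectrum at pixel {labels[zero[0]]}")


def _tic_normalize_matrix(vals: np.ndarray, target_sum, labels) -> np.ndarray:
    sums = vals.sum(axis=1)
    _check_tics(sums, labels)
    target = float(np.mean(sums)) if target_sum is None else float(target_sum)
    return vals * (target / sums)[:, None]


# ---------------------------------------------------------------------------
# Peak picking and alignment


def pick_peaks(dataset: MSIDataset, stride: int = 10, snr_min: float = 3.0) -> PeakList:
    """Collect local maxima with SNR >= ``snr_min`` from every ``stride``-th pixel.

    Noise is estimated per spectrum as 1.4826 x the median absolute
    deviation of the intensities (robust Gaussian sigma).  A noise-free
    spectrum (MAD 0) passes every positive local maximum.
    """
    if dataset.n_pixels == 0:
        raise ValueError("empty dataset")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if snr_min <= 0:
        raise ValueError("snr_min must be positive")
    mzs, heights, snrs = [], [], []
    indices = range(0, dataset.n_pixels, stride)
    for i in indices:
        mz, inten = dataset.spectrum(i)
        inten = np.asarray(inten, dtype=np.float64)
        mad = np.median(np.abs(inten - np.median(inten)))
        noise = 1.4826 * mad
        locs, _ = find_peaks(inten)
        if locs.size == 0:
            continue
        height = inten[locs]
        snr = height / noise if noise > 0 else np.full(locs.size, np.inf)
        keep = (snr >= snr_min) & (height > 0)
        mzs.append(mz[locs[keep]])
        heights.append(height[keep])
        snrs.append(np.where(np.isinf(snr[keep]), np.finfo(float).max, snr[keep]))
    if not mzs:
        return PeakList(np.array([]), np.array([]), np.array([]),
                        source_pixel_count=len(indices))
    return PeakList(np.concatenate(mzs), np.concatenate(heights),
                    np.concatenate(snrs), source_pixel_count=len(indices))


def align_peaks(peaklist: PeakList, tolerance: float = 0.25) -> PeakList:
    """Merge peaks within ``tolerance`` Da into intensity-weighted mean m/z.

    The merge is greedy in ascending m/z: a peak joins the current group
    while its m/z is within tolerance of the group's running
    intensity-weighted mean, otherwise it starts a new group.  Passes repeat
    until no further merge, so the output satisfies the minimum-separation
    invariant.  Merged intensity is the group maximum (peak height), SNR
    likewise.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    mz, inten, snr = peaklist.mz, peaklist.intensity, peaklist.snr
    while True:
        if len(mz) == 0:
            break
        new_mz, new_int, new_snr = [], [], []
        g_mz, g_w = mz[0] * max(inten[0], 1e-300), max(inten[0], 1e-300)
        g_int, g_snr = inten[0], snr[0]
        merged = False
        for m, h, s in zip(mz[1:], inten[1:], snr[1:]):
            if abs(m - g_mz / g_w) <= tolerance:
                w = max(h, 1e-300)
                g_mz += m * w
                g_w += w
                g_int = max(g_int, h)
                g_snr = max(g_snr, s)
                merged = True
            else:
                new_mz.append(g_mz / g_w)
                new_int.append(g_int)
                new_snr.append(g_snr)
                g_mz, g_w, g_int, g_snr = m * max(h, 1e-300), max(h, 1e-300), h, s
        new_mz.append(g_mz / g_w)
        new_int.append(g_int)
        new_snr.append(g_snr)
        mz = np.asarray(new_mz)
        inten = np.asarray(new_int)
        snr = np.asarray(new_snr)
        if not merged:
            break
    return PeakList(mz, inten, snr, source_pixel_count=peaklist.source_pixel_count,
                    tolerance=tolerance)


# ---------------------------------------------------------------------------
# Resampling


def _row_meta(dataset: MSIDataset) -> pd.DataFrame:
    return pd.DataFrame({
        "x": [c[0] for c in dataset.coordinates],
        "y": [c[1] for c in dataset.coordinates],
        "patient_id": dataset.patient_id,
        "condition": dataset.condition,
    })


def resample_height(dataset: MSIDataset, reference: PeakList,
                    tolerance: float = 0.125) -> FeatureMatrix:
    """Peak-height extraction: max intensity within +-tolerance of each
    reference m/z, 0 when no data point falls in the window."""
    if dataset.n_pixels == 0:
        raise ValueError("empty dataset")
    if len(reference) == 0:
        raise ValueError("empty reference peak list")
    ref = reference.mz
    values = np.zeros((dataset.n_pixels, len(ref)))
    for i in range(dataset.n_pixels):
        mz, inten = dataset.spectrum(i)
        lo = np.searchsorted(mz, ref - tolerance, side="left")
        hi = np.searchsorted(mz, ref + tolerance, side="right")
        for j, (a, b) in enumerate(zip(lo, hi)):
            if b > a:
                values[i, j] = float(np.max(inten[a:b]))
    return FeatureMatrix(values, ref, _row_meta(dataset))


def bin_resample(dataset: MSIDataset, mz_min: float = 700.0, mz_max: float = 2500.0,
                 step: float = 0.25) -> FeatureMatrix:
    """Dense resampling onto the grid mz_min, mz_min+step, ..., mz_max.

    Endpoints are inclusive (defaults give 7201 bins); values are linear
    interpolations of each spectrum, 0 outside its support.
    """
    if not mz_min < mz_max:
        raise ValueError("mz_min must be < mz_max")
    if step <= 0:
        raise ValueError("step must be positive")
    if dataset.n_pixels == 0:
        raise ValueError("empty dataset")
    n = int(round((mz_max - mz_min) / step)) + 1
    grid = mz_min + step * np.arange(n)
    values = np.empty((dataset.n_pixels, n))
    for i in range(dataset.n_pixels):
        mz, inten = dataset.spectrum(i)
        values[i] = np.interp(grid, mz, inten, left=0.0, right=0.0)
    return FeatureMatrix(values, grid, _row_meta(dataset))
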