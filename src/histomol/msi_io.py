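"""Reading, writing and slicing of mass spectrometry imaging datasets.

Datasets live in memory as :class:`MSIDataset`: a list of pixel coordinates
with one mass spectrum each, plus patient/condition metadata.  On disk the
interchange format is imzML 1.1 (continuous or processed binary mode), read
and written through :mod:`pyimzml`.

Coordinates follow the imzML convention: 1-based integer (x, y) positions on
the acquisition raster.  They are kept exactly as stored, never re-origined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["MSIDataset", "read_imzml", "write_imzml", "extract_pixels"]


@dataclass
class MSIDataset:
    """Pixel coordinates plus per-pixel mass spectra.

    Parameters
    ----------
    coordinates
        Sequence of (x, y) integer pixel positions, unique, 1-based.
    mz_axes
        In ``continuous`` mode a single ascending m/z array shared by every
        pixel (the same object); in ``processed`` mode one array per pixel.
    intensities
        One non-negative intensity array per pixel, same length as the
        pixel's m/z axis.
    mode
        ``"continuous"`` or ``"processed"``.
    metadata
        Free-form dict; recognised keys include ``patient_id`` and
        ``condition`` (pathology label).
    """

    coordinates: list[tuple[int, int]]
    mz_axes: list[np.ndarray]
    intensities: list[np.ndarray]
    mode: str = "continuous"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("continuous", "processed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (len(self.coordinates) == len(self.mz_axes) == len(self.intensities)):
            raise ValueError("coordinates, mz_axes and intensities must align")
        if len(set(self.coordinates)) != len(self.coordinates):
            raise ValueError("pixel coordinates must be unique")
        for mz in self.mz_axes:
            if len(mz) > 1 and not np.all(np.diff(mz) > 0):
                raise ValueError("m/z axes must be strictly increasing")
        for inten in self.intensities:
            if np.any(inten < 0):
                raise ValueError("intensities must be non-negative")
        if self.mode == "continuous" and self.n_pixels > 1:
            first = self.mz_axes[0]
            for mz in self.mz_axes[1:]:
                if mz is not first and not np.array_equal(mz, first):
                    raise ValueError("continuous mode requires one shared m/z axis")

    @property
    def n_pixels(self) -> int:
        return len(self.coordinates)

    @property
    def patient_id(self) -> str | None:
        return self.metadata.get("patient_id")

    @property
    def condition(self) -> str | None:
        return self.metadata.get("condition")

    def spectrum(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (m/z axis, intensities) of pixel ``i``."""
        return self.mz_axes[i], self.intensities[i]

    def copy(self) -> "MSIDataset":
        shared = self.mode == "continuous" and self.n_pixels > 0
        if shared:
            mz0 = self.mz_axes[0].copy()
            mzs = [mz0] * self.n_pixels
        else:
            mzs = [mz.copy() for mz in self.mz_axes]
        return MSIDataset(
            coordinates=list(self.coordinates),
            mz_axes=mzs,
            intensities=[x.copy() for x in self.intensities],
            mode=self.mode,
            metadata=dict(self.metadata),
        )


def read_imzml(path: str | Path) -> MSIDataset:
    """Load an imzML/ibd pair into an :class:`MSIDataset`.

    The binary mode (continuous vs. processed) is taken from the file's
    declared access type.  Raises ``FileNotFoundError`` when the .ibd
    companion is missing and ``ValueError`` on malformed/truncated binaries.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise FileNotFoundError(f"missing .ibd companion for {path}")
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # pragma: no cover - pyimzml error classes vary
        raise ValueError(f"cannot parse imzML file {path}: {exc}") from exc

    fd = parser.metadata.file_description.param_by_name
    mode = "continuous" if fd.get("continuous") else "processed"

    coords: list[tuple[int, int]] = []
    mzs: list[np.ndarray] = []
    intens: list[np.ndarray] = []
    shared_mz: np.ndarray | None = None
    try:
        for i, (x, y, _z) in enumerate(parser.coordinates):
            mz, inten = parser.getspectrum(i)
            mz = np.asarray(mz, dtype=np.float64)
            inten = np.asarray(inten, dtype=np.float32)
            if len(mz) != len(inten):
                raise ValueError(f"pixel {i}: m/z / intensity length mismatch")
            if mode == "continuous":
                if shared_mz is None:
                    shared_mz = mz
                mz = shared_mz
            coords.append((int(x), int(y)))
            mzs.append(mz)
            intens.append(np.maximum(inten, 0.0))
    except (ValueError,):
        raise
    except Exception as exc:
        raise ValueError(f"corrupt imzML binary data in {ibd}: {exc}") from exc
    finally:
        parser.m.close() if hasattr(parser, "m") and parser.m else None

    return MSIDataset(coords, mzs, intens, mode=mode)


def write_imzml(dataset: MSIDataset, path: str | Path) -> Path:
    """Write ``dataset`` to an imzML/ibd pair; returns the .imzML path.

    Intensities are stored as float32 and m/z as float64, the common vendor
    export dialect, so a read-back agrees within float32 rounding.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if dataset.n_pixels == 0:
        raise ValueError("refusing to write an empty MSI dataset")
    path = Path(path)
    with ImzMLWriter(str(path), mode=dataset.mode,
                     intensity_dtype=np.float32, mz_dtype=np.float64) as writer:
        for (x, y), mz, inten in zip(dataset.coordinates, dataset.mz_axes,
                                     dataset.intensities):
            writer.addSpectrum(mz, inten, (int(x), int(y), 1))
    return path if path.suffix == ".imzML" else path.with_suffix(".imzML")


def extract_pixels(dataset: MSIDataset, mask: Iterable[tuple[int, int]]) -> MSIDataset:
    """Subset ``dataset`` to the pixels in ``mask``, preserving order.

    ``mask`` must be a subset of the dataset's coordinates; the first
    offending coordinate is named in the error.  An empty mask is an error
    because every downstream stage needs at least one pixel.
    """
    mask = set(mask)
    if not mask:
        raise ValueError("empty pixel mask: downstream stages require >= 1 pixel")
    index = {c: i for i, c in enumerate(dataset.coordinates)}
    for c in mask:
        if c not in index:
            raise KeyError(f"coordinate {c} not present in dataset")
    keep = [i for i, c in enumerate(dataset.coordinates) if c in mask]
    out = MSIDataset(
        coordinates=[dataset.coordinates[i] for i in keep],
        mz_axes=[dataset.mz_axes[i] for i in keep],
        intensities=[dataset.intensities[i] for i in keep],
        mode=dataset.mode,
        metadata=dict(dataset.metadata),
    )
    if "ground_truth" in dataset.metadata:
        gt = dataset.metadata["ground_truth"]
        out.metadata["ground_truth"] = {c: gt[c] for c in out.coordinates if c in gt}
    return out
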