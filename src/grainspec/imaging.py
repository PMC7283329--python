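"""Hyperspectral image calibration, grain segmentation and spectrum extraction.

The camera records raw counts I0 together with a white reference W (a
high-reflectance standard) and a dark current image D. Relative reflectance is

    I = (I0 - D) / (W - D)

per pixel per band, so a pixel matching the white panel reads 1 and a pixel
with no signal above dark current reads 0. Grain pixels are found by
thresholding the band nearest a reference wavelength (default 750 nm, where
intact brown rice is brightest against the dark background), small connected
components are discarded as noise, and each remaining component is assigned to
a physical sample via a sample map. Per-sample mean spectra are the feature
matrix for all downstream chemometrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import (
    CalibrationError,
    ExtractionError,
    SegmentationError,
)

__all__ = [
    "HyperspectralCube",
    "ReferenceImages",
    "GrainMask",
    "SpectraTable",
    "calibrate",
    "segment_grains",
    "extract_spectra",
]


@dataclass
class HyperspectralCube:
    """Reflectance cube: ``values[row, col, band]`` with a wavelength axis in nm."""

    values: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube values must be 3-D (rows, cols, bands)")
        if self.values.shape[2] != self.wavelengths.size:
            raise ValueError("band count does not match wavelength count")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.wavelengths[0] < 390 or self.wavelengths[-1] > 1010:
            raise ValueError("wavelengths outside the instrument range [390, 1010] nm")

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    def band_index(self, nm: float) -> int:
        """Index of the band nearest ``nm`` (no interpolation; ~4 nm spacing)."""
        if nm < self.wavelengths[0] or nm > self.wavelengths[-1]:
            raise ValueError(f"{nm} nm outside wavelength range")
        return int(np.argmin(np.abs(self.wavelengths - nm)))


@dataclass
class ReferenceImages:
    """White and dark reference cubes in raw counts, same shape as the raw cube."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white)
        self.dark = np.asarray(self.dark)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark reference shapes differ")


@dataclass
class GrainMask:
    """Binary grain mask plus per-pixel sample labels (0 = background)."""

    mask: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.labels = np.asarray(self.labels)
        if self.mask.shape != self.labels.shape:
            raise ValueError("mask and labels shapes differ")
        if np.any(self.labels[~self.mask] != 0):
            raise ValueError("labels must be zero off the mask")


@dataclass
class SpectraTable:
    """Per-sample mean spectra: ``spectra[sample, band]``."""

    sample_ids: list
    spectra: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.spectra.shape[0] != len(self.sample_ids):
            raise ValueError("row count must equal sample count")
        if self.spectra.shape[1] != self.wavelengths.size:
            raise ValueError("column count must equal wavelength count")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra must be finite")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{w:g}" for w in self.wavelengths]
        return pd.DataFrame(self.spectra, index=pd.Index(self.sample_ids, name="sample_id"), columns=cols)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpectraTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            sample_ids=list(df.index),
            spectra=df.to_numpy(dtype=float),
            wavelengths=np.array([float(c) for c in df.columns]),
        )

    def subset_bands(self, index: np.ndarray) -> "SpectraTable":
        index = np.asarray(index)
        return SpectraTable(self.sample_ids, self.spectra[:, index], self.wavelengths[index])


def calibrate(
    raw: np.ndarray,
    refs: ReferenceImages,
    wavelengths: np.ndarray,
    clip: tuple[float, float] | None = None,
) -> HyperspectralCube:
    """White/dark balance raw counts into relative reflectance.

    Computes ``(raw - dark) / (white - dark)`` elementwise. By default the
    result is not clipped: reflectance slightly above 1 (specular pixels) or
    below 0 (noise) is preserved because derivative preprocessing downstream
    is sensitive to artificial flat regions.

    Raises
    ------
    CalibrationError
        If white - dark is non-positive anywhere; the message names the first
        offending (row, col, band) index.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape != refs.white.shape:
        raise ValueError("raw and reference shapes differ")
    denom = refs.white.astype(float) - refs.dark.astype(float)
    bad = denom <= 0
    if np.any(bad):
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise CalibrationError(
            f"white - dark is non-positive at (row, col, band)={idx}"
        )
    values = (raw - refs.dark) / denom
    if clip is not None:
        values = np.clip(values, clip[0], clip[1])
    return HyperspectralCube(values, wavelengths)


def segment_grains(
    cube: HyperspectralCube,
    roi_wavelength: float = 750.0,
    min_area: int = 50,
    threshold: float | None = None,
    sample_map: np.ndarray | None = None,
    grid: tuple[int, int] | None = None,
) -> GrainMask:
    """Segment grain pixels on the band nearest ``roi_wavelength``.

    The band is thresholded (Otsu by default, or a fixed ``threshold``),
    connected components smaller than ``min_area`` pixels are removed, and each
    surviving component is assigned a sample identifier: by majority vote over
    a per-pixel ``sample_map`` if given, by cell of an (n_rows, n_cols)
    ``grid`` over the image otherwise, or the component index itself if
    neither is supplied.
    """
    band = cube.values[:, :, cube.band_index(roi_wavelength)]
    if threshold is None:
        if np.ptp(band) == 0:
            raise SegmentationError("ROI band is constant; nothing to threshold")
        threshold = float(threshold_otsu(band))
    fg = band > threshold
    comps, n_comp = cc_label(fg, return_num=True, connectivity=2)
    # drop small components
    if n_comp:
        areas = np.bincount(comps.ravel())
        keep = np.flatnonzero(areas >= min_area)
        keep = keep[keep != 0]
        fg = np.isin(comps, keep)
        comps = np.where(fg, comps, 0)
    if not fg.any():
        raise SegmentationError(
            f"no grain component of at least {min_area} px above threshold"
        )

    labels = np.zeros(fg.shape, dtype=int)
    comp_ids = np.unique(comps[comps > 0])
    if sample_map is not None:
        sample_map = np.asarray(sample_map)
        for cid in comp_ids:
            where = comps == cid
            votes = sample_map[where]
            votes = votes[votes > 0]
            if votes.size == 0:
                continue  # component entirely off the map: left unassigned
            vals, counts = np.unique(votes, return_counts=True)
            labels[where] = vals[np.argmax(counts)]
    elif grid is not None:
        n_r, n_c = grid
        rows, cols = fg.shape
        for cid in comp_ids:
            rr, cc = np.nonzero(comps == cid)
            r_cell = min(int(rr.mean() * n_r / rows), n_r - 1)
            c_cell = min(int(cc.mean() * n_c / cols), n_c - 1)
            labels[comps == cid] = r_cell * n_c + c_cell + 1
    else:
        for i, cid in enumerate(comp_ids, start=1):
            labels[comps == cid] = i
    mask = labels > 0
    return GrainMask(mask=mask, labels=labels)


def extract_spectra(
    cube: HyperspectralCube,
    mask: GrainMask,
    sample_ids: dict[int, str] | None = None,
) -> SpectraTable:
    """Mean spectrum per sample over its masked pixels.

    ``sample_ids`` optionally maps label integers to sample names; labels
    without an entry keep their integer as the name. A requested sample with
    zero pixels raises :class:`ExtractionError` naming it.
    """
    if not mask.mask.any():
        raise ExtractionError("mask is empty")
    present = np.unique(mask.labels[mask.labels > 0])
    wanted = sorted(sample_ids) if sample_ids is not None else list(present)
    missing = [s for s in wanted if s not in present]
    if missing:
        raise ExtractionError(f"samples with zero masked pixels: {missing}")
    spectra = np.empty((len(wanted), cube.n_bands))
    names = []
    for i, lab in enumerate(wanted):
        where = mask.labels == lab
        spectra[i] = cube.values[where].mean(axis=0)
        names.append(sample_ids[lab] if sample_ids is not None else str(lab))
    return SpectraTable(sample_ids=names, spectra=spectra, wavelengths=cube.wavelengths)
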