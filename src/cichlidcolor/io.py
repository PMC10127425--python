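"""File I/O: spectra CSV, PNG images and masks, measurement tables."""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .visual_model import Spectrum

logger = logging.getLogger(__name__)


def load_spectrum_csv(path) -> Spectrum:
    """Read a two-column (wavelength_nm, value) CSV with a header row.

    Rows out of wavelength order are sorted with a warning; duplicate
    wavelengths or non-numeric rows raise, naming the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength, value)")
    wl_raw, val_raw = df.iloc[:, 0], df.iloc[:, 1]
    wl = pd.to_numeric(wl_raw, errors="coerce")
    val = pd.to_numeric(val_raw, errors="coerce")
    bad = np.flatnonzero(wl.isna() | val.isna())
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(f"{path}: non-numeric value on line {bad[0] + 2}")
    wl = wl.to_numpy(float)
    val = val.to_numpy(float)
    if np.unique(wl).size < wl.size:
        raise ValueError(f"{path}: duplicate wavelengths")
    if not np.all(np.diff(wl) > 0):
        logger.warning("%s: wavelengths out of order; sorting", path)
        order = np.argsort(wl)
        wl, val = wl[order], val[order]
    return Spectrum(wl, val)


def save_spectrum_csv(spectrum: Spectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "value": spectrum.values}
    ).to_csv(path, index=False)


def save_image(image: np.ndarray, path) -> None:
    """Write an 8-bit PNG (RGB image or single-channel boolean mask)."""
    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    elif arr.dtype != np.uint8:
        arr = np.clip(np.round(np.asarray(arr, float) * 255), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def load_image(path) -> np.ndarray:
    return iio.imread(Path(path))


def load_mask(path) -> np.ndarray:
    return iio.imread(Path(path)) > 127
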