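"""Image conditioning: contrast stretch, red-channel extraction, thresholding.

The conditioning chain mirrors a light-on-dark capture protocol: a mild
percentile contrast stretch, retention of the red channel only, and a
global threshold (automatic isodata by default, or a fixed grey level).
The output is a polarity-normalised binary mask in which foreground
always means fungal material, regardless of how the source was encoded.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.filters import threshold_isodata, threshold_otsu

from .errors import ConfigurationError
from .imaging_io import Calibration, ImageRecord

logger = logging.getLogger(__name__)

_AUTO_METHODS = {"isodata": threshold_isodata, "otsu": threshold_otsu}


@dataclass
class GreyRaster:
    """Single-channel 8-bit raster with its source path."""

    values: np.ndarray
    provenance: Path | None = None


@dataclass
class BinaryMask:
    """Boolean raster where True = fungal material (polarity normalised)."""

    values: np.ndarray
    calibration: Calibration
    provenance: Path | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def enhance_contrast(raster: np.ndarray, saturation: float = 0.05) -> np.ndarray:
    """Symmetric percentile stretch saturating ``saturation`` of all pixels.

    Intensities at or below the (saturation/2) quantile map to 0 and at or
    above the (1 - saturation/2) quantile map to 255, with a linear ramp in
    between (the common "enhance contrast by 5%" semantics). ``saturation=0``
    degenerates to a min–max stretch. A constant raster is returned
    unchanged with a warning.
    """
    if not (0 <= saturation < 1):
        raise ConfigurationError(f"saturation must be in [0, 1), got {saturation}")
    if raster.size == 0:
        raise ConfigurationError("empty raster")
    vals = raster.astype(np.float64)
    lo_q = 100.0 * saturation / 2.0
    lo, hi = np.percentile(vals, [lo_q, 100.0 - lo_q])
    if hi <= lo:
        # either a constant raster, or a dominant level swallowing both
        # percentiles (typical for sparse foreground on a flat background)
        if raster.min() == raster.max():
            logger.warning("constant-intensity raster: contrast stretch skipped")
        else:
            logger.debug("degenerate percentile range: contrast stretch skipped")
        return raster.copy()
    out = (vals - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def to_red_channel(record: ImageRecord) -> GreyRaster:
    """Keep the red channel of an RGB record, discarding green and blue."""
    return GreyRaster(values=record.raster[:, :, 0].copy(), provenance=record.path)


def binarize(
    gray: GreyRaster | np.ndarray,
    spec: int | str = "isodata",
    calibration: Calibration | None = None,
) -> BinaryMask:
    """Threshold an 8-bit grey raster into a foreground-is-fungus mask.

    ``spec`` is either a fixed grey-level cutoff or the name of an automatic
    histogram method ("isodata" or "otsu"). Foreground pixels are those
    strictly brighter than the cutoff (light structures on a dark
    background); the cutoff pixel itself is background. An automatic method
    on a constant image yields an all-background mask with a warning.
    """
    if isinstance(gray, GreyRaster):
        values, provenance = gray.values, gray.provenance
    else:
        values, provenance = gray, None
    if calibration is None:
        calibration = Calibration(1.0)
    if isinstance(spec, str):
        try:
            method = _AUTO_METHODS[spec]
        except KeyError:
            raise ConfigurationError(
                f"unknown threshold method {spec!r}; expected one of {sorted(_AUTO_METHODS)}"
            ) from None
        if values.min() == values.max():
            logger.warning("constant image: automatic threshold undefined, mask is all background")
            mask = np.zeros(values.shape, dtype=bool)
            return BinaryMask(mask, calibration, provenance)
        cutoff = float(method(values))
    else:
        cutoff = float(spec)
    mask = values > cutoff
    return BinaryMask(mask.astype(bool), calibration, provenance)


def preprocess_record(
    record: ImageRecord,
    calibration: Calibration,
    threshold_spec: int | str = "isodata",
    contrast_saturation: float = 0.05,
) -> BinaryMask:
    """Full conditioning chain: contrast stretch → red channel → threshold."""
    enhanced = enhance_contrast(record.raster, contrast_saturation)
    red = to_red_channel(ImageRecord(record.path, record.subdir, enhanced))
    return binarize(red, threshold_spec, calibration)
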