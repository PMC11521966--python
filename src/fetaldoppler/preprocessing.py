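"""Screen-capture pre-processing: region extraction, cleanup, calibration.

Converts a raw Doppler screen capture (DICOM or synthetic composite) into
standardized, calibrated B-mode (256x256) and spectral-Doppler (512x256)
grayscale regions, and extracts the amplitude features used to gate the
view classifiers: the extreme velocity magnitudes above and below the zero
line (``v_max``, ``v_min``) and their sum (``v_range``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .calibration import Calibration

log = logging.getLogger(__name__)

BMODE_SHAPE = (256, 256)
DOPPLER_SHAPE = (256, 512)

#: luminance weights for RGB -> grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])

DEFAULT_BINARIZE_THRESHOLD = 0.1
DEFAULT_GREY_TOLERANCE = 20.0 / 255.0


@dataclass(frozen=True)
class VelocityProfileFeatures:
    """Amplitude features of the binarized Doppler region (cm/s).

    ``v_max`` / ``v_min`` are magnitudes of the most extreme velocities
    above / below the zero line; ``v_range = v_max + v_min``.  ``row_span``
    is the tight (top, bottom) row range of the signal, used to crop the
    region around it.
    """

    v_max: float
    v_min: float
    v_range: float
    row_span: tuple[int, int]

    def as_array(self) -> np.ndarray:
        return np.array([self.v_min, self.v_range])


@dataclass
class DopplerStudyImage:
    """A standardized, calibrated study ready for the pipeline."""

    bmode: np.ndarray  # (256, 256) float in [0, 1]
    doppler: np.ndarray  # (256, 512) float in [0, 1]
    calibration: Calibration
    cursor_mask: np.ndarray | None = None
    source_id: str = ""
    is_single_frame: bool = True


# --------------------------------------------------------------------------
# region extraction
# --------------------------------------------------------------------------


def extract_regions(raw_image: np.ndarray, region_metadata: dict):
    """Crop the B-mode and spectral Doppler sub-images out of a composite.

    ``region_metadata`` must provide, per region, a bounding box
    ``(row0, col0, row1, col1)`` (half-open), and for the Doppler region the
    physical deltas ``time_per_px`` (ms), ``vel_per_px`` (cm/s) and
    ``zero_line_row`` (relative to the crop).  Raises when either region is
    missing or the capture is not single-frame.
    """
    if not region_metadata.get("is_single_frame", True):
        raise ValueError("single-frame required: multi-frame captures are not supported")
    for key in ("bmode", "doppler"):
        if key not in region_metadata:
            raise ValueError(f"region not found: {key!r} missing from region metadata")
    r0, c0, r1, c1 = region_metadata["bmode"]["box"]
    bmode_crop = raw_image[r0:r1, c0:c1]
    dm = region_metadata["doppler"]
    r0, c0, r1, c1 = dm["box"]
    doppler_crop = raw_image[r0:r1, c0:c1]
    if bmode_crop.size == 0 or doppler_crop.size == 0:
        raise ValueError("region not found: empty crop")
    cal = Calibration(
        time_per_px=float(dm["time_per_px"]),
        vel_per_px=float(dm["vel_per_px"]),
        zero_line_row=float(dm["zero_line_row"]),
    )
    return bmode_crop, doppler_crop, cal


def regions_from_dicom(ds) -> tuple[np.ndarray, dict]:
    """Build ``(raw_image, region_metadata)`` from a pydicom dataset.

    Uses the standard Sequence of Ultrasound Regions: region type 1 is
    tissue (B-mode), type 3 the spectral trace; ``PhysicalDeltaX`` is in
    seconds per pixel and ``PhysicalDeltaY`` in cm/s per pixel for the
    spectral region, with ``ReferencePixelY0`` locating the zero line.
    """
    raw = ds.pixel_array
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    meta: dict = {"is_single_frame": n_frames == 1}
    for reg in getattr(ds, "SequenceOfUltrasoundRegions", []):
        box = (
            int(reg.RegionLocationMinY0),
            int(reg.RegionLocationMinX0),
            int(reg.RegionLocationMaxY1) + 1,
            int(reg.RegionLocationMaxX1) + 1,
        )
        rtype = int(reg.RegionDataType)
        if rtype == 1 and "bmode" not in meta:
            meta["bmode"] = {"box": box}
        elif rtype == 3 and "doppler" not in meta:
            zero_rel = float(getattr(reg, "ReferencePixelY0", 0))
            meta["doppler"] = {
                "box": box,
                "time_per_px": float(reg.PhysicalDeltaX) * 1000.0,  # s -> ms
                "vel_per_px": abs(float(reg.PhysicalDeltaY)),
                "zero_line_row": zero_rel,
            }
    return raw, meta


# --------------------------------------------------------------------------
# cleanup
# --------------------------------------------------------------------------


def remove_burned_annotations(
    region: np.ndarray,
    vendor_palette: list[tuple[float, float, float]],
    tolerance: float = 0.12,
    drop_black: bool = True,
) -> np.ndarray:
    """Replace palette-coloured burned-in annotations by local grey texture
    and drop fully black rows/columns.

    Matching is per-channel within ``tolerance`` (on [0, 1] intensities);
    matched pixels take the median of their 5x5 grey neighbourhood.  A no-op
    when nothing matches.
    """
    region = np.asarray(region, dtype=float)
    if region.ndim == 2:
        region = np.repeat(region[:, :, None], 3, axis=2)
    out = region.copy()
    grey = region @ _LUMA
    mask = np.zeros(region.shape[:2], dtype=bool)
    for color in vendor_palette:
        c = np.asarray(color, dtype=float)
        mask |= np.all(np.abs(region - c[None, None, :]) <= tolerance, axis=2)
    if mask.any():
        background = np.where(mask, np.nan, grey)
        filled = ndimage.generic_filter(background, np.nanmedian, size=5, mode="nearest")
        # nested annotation blocks wider than the window: fall back to the
        # global grey median
        filled = np.where(np.isnan(filled), np.nanmedian(background), filled)
        out[mask] = filled[mask, None]
    if drop_black:
        grey_out = out @ _LUMA
        keep_rows = ~np.all(grey_out <= 1e-9, axis=1)
        keep_cols = ~np.all(grey_out <= 1e-9, axis=0)
        if keep_rows.any() and keep_cols.any():
            out = out[keep_rows][:, keep_cols]
    return out


def detect_cursor_mask(
    bmode_rgb: np.ndarray, grey_tolerance: float = DEFAULT_GREY_TOLERANCE
) -> np.ndarray:
    """Binary mask of non-grey (coloured) pixels — the Doppler cursor.

    A pixel is coloured when ``max(R,G,B) - min(R,G,B) > grey_tolerance``.
    An all-grey image yields an empty mask with a logged warning.
    """
    if bmode_rgb.ndim != 3 or bmode_rgb.shape[2] != 3:
        raise ValueError("detect_cursor_mask expects an RGB image")
    spread = bmode_rgb.max(axis=2) - bmode_rgb.min(axis=2)
    mask = spread > grey_tolerance
    if not mask.any():
        log.warning("no cursor detected: image is entirely grey")
    return mask


def combine_cursor(bmode_grey: np.ndarray, cursor_mask: np.ndarray) -> np.ndarray:
    """Burn the cursor mask into the grayscale B-mode at full intensity."""
    out = bmode_grey.copy()
    out[cursor_mask] = 1.0
    return out


# --------------------------------------------------------------------------
# amplitude features
# --------------------------------------------------------------------------


def binarize_doppler(doppler: np.ndarray, threshold: float = DEFAULT_BINARIZE_THRESHOLD) -> np.ndarray:
    """Simple thresholding of the normalized Doppler region."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return np.asarray(doppler) > threshold


def extract_velocity_metrics(
    binary: np.ndarray, calibration: Calibration
) -> VelocityProfileFeatures:
    """Extreme velocity magnitudes above/below the zero line of a binarized
    spectrogram, plus the tight row span of the signal."""
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        raise ValueError("no Doppler signal: binarized region is empty")
    rows = np.where(binary.any(axis=1))[0]
    z = calibration.zero_line_row
    above = rows[rows < z]
    below = rows[rows > z]
    v_max = float((z - above.min()) * calibration.vel_per_px) if above.size else 0.0
    v_min = float((below.max() - z) * calibration.vel_per_px) if below.size else 0.0
    return VelocityProfileFeatures(
        v_max=v_max,
        v_min=v_min,
        v_range=v_max + v_min,
        row_span=(int(rows.min()), int(rows.max())),
    )


def estimate_zero_line(binary: np.ndarray) -> int:
    """Fallback zero-line estimate when region metadata lacks it: the row
    about which the column-occupancy profile is most symmetric."""
    binary = np.asarray(binary, dtype=bool)
    occ = binary.sum(axis=1).astype(float)
    H = occ.size
    best_row, best_score = H // 2, -1.0
    for r in range(1, H - 1):
        d = min(r, H - 1 - r)
        score = float(np.minimum(occ[r - d : r][::-1], occ[r + 1 : r + 1 + d]).sum())
        if score > best_score:
            best_row, best_score = r, score
    return best_row


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------


def normalize_region(
    region: np.ndarray,
    target_shape: tuple[int, int],
    calibration: Calibration | None = None,
):
    """Grayscale conversion, min-max normalization to [0, 1] and bilinear
    resize to the standard shape.

    A constant image maps to all zeros.  When a calibration is given it is
    rescaled by the resize factors and returned alongside the raster.
    """
    region = np.asarray(region, dtype=float)
    grey = region @ _LUMA if region.ndim == 3 else region
    h0, w0 = grey.shape
    th, tw = target_shape
    out = resize(grey, target_shape, order=1, anti_aliasing=True, preserve_range=True)
    lo, hi = float(out.min()), float(out.max())
    if hi - lo < 1e-12:
        out = np.zeros(target_shape)
    else:
        out = (out - lo) / (hi - lo)
    if calibration is None:
        return out
    cal = calibration.rescaled(row_factor=th / h0, col_factor=tw / w0)
    return out, cal


# --------------------------------------------------------------------------
# full pre-processing of a synthetic or composite study
# --------------------------------------------------------------------------


def preprocess_study(
    raw_image: np.ndarray,
    region_metadata: dict,
    vendor_palette: list | None = None,
    combine_cursor_flag: bool = False,
    source_id: str = "",
) -> DopplerStudyImage:
    """Composite capture -> standardized :class:`DopplerStudyImage`."""
    bmode_crop, doppler_crop, cal = extract_regions(raw_image, region_metadata)
    if vendor_palette:
        bmode_crop = remove_burned_annotations(bmode_crop, vendor_palette)
        doppler_crop = remove_burned_annotations(doppler_crop, vendor_palette)
    if bmode_crop.ndim == 3:
        cursor = detect_cursor_mask(bmode_crop)
    else:
        cursor = np.zeros(bmode_crop.shape, dtype=bool)
    bmode = normalize_region(bmode_crop, BMODE_SHAPE)
    cursor_rs = (
        resize(cursor.astype(float), BMODE_SHAPE, order=0, preserve_range=True) > 0.5
    )
    if combine_cursor_flag:
        bmode = combine_cursor(bmode, cursor_rs)
    doppler, cal = normalize_region(doppler_crop, DOPPLER_SHAPE, cal)
    return DopplerStudyImage(
        bmode=bmode,
        doppler=doppler,
        calibration=cal,
        cursor_mask=cursor_rs,
        source_id=source_id,
        is_single_frame=bool(region_metadata.get("is_single_frame", True)),
    )
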