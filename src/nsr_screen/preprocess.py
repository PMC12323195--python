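"""Calibration and augmentation of arm photographs.

Photographs come from arbitrary consumer devices, so two device effects must
be removed before segmentation:

* **Colour cast** — corrected with the perfect-reflector method: the white
  patch of the arm label is a known reflectance-1 surface, so each channel is
  scaled by ``255 / mean_channel(white region)`` (clipped at 255).
* **Scale** — camera-to-arm distance varies; the arm label has a fixed
  physical size, so the image is rescaled until the label's major axis spans
  a fixed number of pixels, making pixel areas comparable across photographs.

After calibration, images are resized to the fixed network input shape
(128 x 512 by default).  Paired runtime augmentation applies one random
geometric transform identically to image and mask (rotation, shift, scale,
flips) plus photometric jitter (brightness / contrast / saturation) to the
image only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.measure import label as cc_label
from skimage.transform import AffineTransform, rescale, resize, warp

from .io_consensus import BinaryMask, NsrImage


@dataclass
class CalibrationSpec:
    """Parameters of the white-balance / scale-normalisation step.

    ``target_label_px`` is the pixel length the label's major axis is
    brought to; only relative calibration is possible because the label's
    absolute size in mm is a property of the deposited labels, not of the
    algorithm.
    """

    label_real_size_mm: float = 50.0
    target_label_px: int = 96
    model_input_hw: tuple[int, int] = (128, 512)
    white_ref_quantile: float = 0.90  # brightness quantile locating the white patch

    def __post_init__(self) -> None:
        if self.label_real_size_mm <= 0:
            raise ValueError("label_real_size_mm must be positive")
        if self.target_label_px <= 0 or min(self.model_input_hw) <= 0:
            raise ValueError("pixel dimensions must be positive")


@dataclass
class AugmentParams:
    """Magnitudes and probabilities of the runtime augmentation families."""

    max_rotation_deg: float = 15.0
    max_shift_frac: float = 0.05
    scale_range: tuple[float, float] = (0.9, 1.1)
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    brightness_delta: float = 0.2
    contrast_delta: float = 0.2
    saturation_delta: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_hflip <= 1 and 0 <= self.p_vflip <= 1):
            raise ValueError("flip probabilities must lie in [0, 1]")
        if min(self.max_rotation_deg, self.max_shift_frac, self.brightness_delta,
               self.contrast_delta, self.saturation_delta) < 0:
            raise ValueError("magnitudes must be non-negative")

    @classmethod
    def identity(cls) -> "AugmentParams":
        return cls(max_rotation_deg=0, max_shift_frac=0, scale_range=(1.0, 1.0),
                   p_hflip=0, p_vflip=0, brightness_delta=0, contrast_delta=0,
                   saturation_delta=0)


def _region_pixels(image: NsrImage, white_ref_region) -> np.ndarray:
    """Pixels of ``image`` inside a BinaryMask or (r0, c0, r1, c1) rectangle."""
    if isinstance(white_ref_region, BinaryMask):
        sel = white_ref_region.pixels
        if sel.shape != image.shape_hw:
            raise ValueError("white reference mask shape does not match image")
        return image.pixels[sel]
    r0, c0, r1, c1 = white_ref_region
    return image.pixels[r0:r1, c0:c1].reshape(-1, 3)


def white_balance(image: NsrImage, white_ref_region) -> NsrImage:
    """Perfect-reflector colour correction against a known white region.

    Each channel c is scaled by ``g_c = 255 / mean_c(region)`` and clipped to
    [0, 255], so the corrected region averages pure white.  Idempotent up to
    rounding.  ``white_ref_region`` is a :class:`BinaryMask` or an
    ``(r0, c0, r1, c1)`` rectangle.
    """
    px = _region_pixels(image, white_ref_region)
    if px.size == 0:
        raise ValueError("white reference region is empty")
    means = px.reshape(-1, 3).mean(axis=0)
    if np.any(means <= 0):
        raise ValueError(f"white reference has a zero-mean channel: means={means}")
    gains = 255.0 / means
    corrected = np.clip(np.round(image.pixels.astype(np.float64) * gains), 0, 255)
    return replace(image, pixels=corrected.astype(np.uint8))


def find_white_reference(image: NsrImage, label_mask: BinaryMask,
                         quantile: float = 0.90) -> BinaryMask:
    """Locate the label's white patch as its brightest connected subregion.

    Label pixels whose luminance reaches the given within-label quantile are
    thresholded and the largest connected component is returned.
    """
    if label_mask.area_px == 0:
        raise ValueError("label mask is empty")
    lum = image.pixels.astype(np.float64).mean(axis=2)
    thresh = np.quantile(lum[label_mask.pixels], quantile)
    bright = label_mask.pixels & (lum >= thresh)
    comps = cc_label(bright)
    if comps.max() == 0:
        raise ValueError("no bright region found inside the label")
    sizes = np.bincount(comps.ravel())[1:]
    keep = comps == (int(np.argmax(sizes)) + 1)
    return BinaryMask(pixels=keep, kind="white_ref")


def measure_label_px(label_mask: BinaryMask) -> float:
    """Label size in pixels: the major-axis length of its bounding box."""
    if label_mask.area_px < 9:
        raise ValueError(f"degenerate label mask (area {label_mask.area_px} px)")
    rows = np.any(label_mask.pixels, axis=1)
    cols = np.any(label_mask.pixels, axis=0)
    h = int(rows.nonzero()[0].max() - rows.nonzero()[0].min() + 1)
    w = int(cols.nonzero()[0].max() - cols.nonzero()[0].min() + 1)
    return float(max(h, w))


def rescale_image(image: NsrImage, factor: float) -> NsrImage:
    if abs(factor - 1.0) < 1e-12:
        return image
    out = rescale(image.pixels.astype(np.float64) / 255.0, factor, channel_axis=2,
                  order=1, anti_aliasing=factor < 1, preserve_range=True)
    return replace(image, pixels=np.clip(np.round(out * 255), 0, 255).astype(np.uint8))


def rescale_mask(mask: BinaryMask, factor: float) -> BinaryMask:
    if abs(factor - 1.0) < 1e-12:
        return mask
    out = rescale(mask.pixels.astype(np.float64), factor, order=0,
                  anti_aliasing=False, preserve_range=True)
    return BinaryMask(pixels=out > 0.5, kind=mask.kind)


def calibrate_scale(image: NsrImage, label_mask: BinaryMask,
                    spec: CalibrationSpec) -> NsrImage:
    """Rescale so the label's major axis measures ``spec.target_label_px``."""
    factor = spec.target_label_px / measure_label_px(label_mask)
    return rescale_image(image, factor)


def scale_factor(label_mask: BinaryMask, spec: CalibrationSpec) -> float:
    return spec.target_label_px / measure_label_px(label_mask)


def resize_to_input(
    image: NsrImage, mask: BinaryMask | None = None,
    spec: CalibrationSpec | None = None,
) -> NsrImage | tuple[NsrImage, BinaryMask]:
    """Resize to the model input shape: bilinear for the image, nearest for masks."""
    spec = spec or CalibrationSpec()
    h, w = spec.model_input_hw
    if image.shape_hw == (h, w):
        img_out = image
    else:
        out = resize(image.pixels.astype(np.float64) / 255.0, (h, w), order=1,
                     anti_aliasing=True, preserve_range=True)
        img_out = replace(image, pixels=np.clip(np.round(out * 255), 0, 255).astype(np.uint8))
    if mask is None:
        return img_out
    if mask.pixels.shape == (h, w):
        mask_out = mask
    else:
        m = resize(mask.pixels.astype(np.float64), (h, w), order=0,
                   anti_aliasing=False, preserve_range=True)
        mask_out = BinaryMask(pixels=m > 0.5, kind=mask.kind)
    return img_out, mask_out


def preprocess_pair(
    image: NsrImage,
    label_mask: BinaryMask,
    flush_mask: BinaryMask | None = None,
    spec: CalibrationSpec | None = None,
) -> tuple[NsrImage, BinaryMask, BinaryMask | None]:
    """Full calibration pipeline: white balance, scale, resize.

    Returns the calibrated image at model input shape, the label mask and
    (if given) the flushing mask transformed identically.
    """
    spec = spec or CalibrationSpec()
    white = find_white_reference(image, label_mask, spec.white_ref_quantile)
    image = white_balance(image, white)
    s = scale_factor(label_mask, spec)
    image = rescale_image(image, s)
    label_mask = rescale_mask(label_mask, s)
    image, label_mask = resize_to_input(image, label_mask, spec)
    if flush_mask is None:
        return image, label_mask, None
    flush = rescale_mask(flush_mask, s)
    _, flush = resize_to_input(image, flush, spec)
    return image, label_mask, flush


# --------------------------------------------------------------------------
# runtime augmentation


def _saturate(img: np.ndarray, factor: float) -> np.ndarray:
    gray = img.mean(axis=2, keepdims=True)
    return gray + factor * (img - gray)


def augment_pair(
    image: NsrImage, mask: BinaryMask, params: AugmentParams, draw_seed: int,
) -> tuple[NsrImage, BinaryMask]:
    """One random paired augmentation draw, fully determined by ``draw_seed``.

    Geometric transforms (flips, then one affine rotation/shift/scale) are
    applied identically to image and mask; photometric jitter touches the
    image only.  Zero magnitudes and probabilities give an exact identity.
    """
    rng = np.random.default_rng(draw_seed)
    img = image.pixels.astype(np.float64)
    msk = mask.pixels

    # flips are exact array ops so an identity/involution stays bit-exact
    if rng.random() < params.p_hflip:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < params.p_vflip:
        img, msk = img[::-1, :], msk[::-1, :]

    angle = rng.uniform(-params.max_rotation_deg, params.max_rotation_deg) \
        if params.max_rotation_deg > 0 else 0.0
    h, w = msk.shape
    shift = (rng.uniform(-params.max_shift_frac, params.max_shift_frac, size=2)
             * np.array([w, h]) if params.max_shift_frac > 0 else np.zeros(2))
    lo, hi = params.scale_range
    scale = rng.uniform(lo, hi) if hi > lo else float(lo)

    if angle != 0.0 or np.any(shift != 0) or scale != 1.0:
        center = np.array([(w - 1) / 2, (h - 1) / 2])
        tf = (AffineTransform(translation=-center)
              + AffineTransform(rotation=np.deg2rad(angle), scale=scale)
              + AffineTransform(translation=center + shift))
        img = warp(img / 255.0, tf.inverse, order=1, preserve_range=True) * 255.0
        msk = warp(msk.astype(np.float64), tf.inverse, order=0,
                   preserve_range=True) > 0.5

    if params.brightness_delta > 0:
        img = img + rng.uniform(-params.brightness_delta, params.brightness_delta) * 255.0
    if params.contrast_delta > 0:
        f = 1.0 + rng.uniform(-params.contrast_delta, params.contrast_delta)
        img = img.mean() + f * (img - img.mean())
    if params.saturation_delta > 0:
        f = 1.0 + rng.uniform(-params.saturation_delta, params.saturation_delta)
        img = _saturate(img, f)

    out_img = replace(image, pixels=np.clip(np.round(img), 0, 255).astype(np.uint8))
    return out_img, BinaryMask(pixels=np.ascontiguousarray(msk), kind=mask.kind)
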