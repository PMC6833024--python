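"""Two-stage segmentation flow: disc first, then cup inside a disc ROI.

The full image is resized to the disc network's input side and segmented;
the resulting disc mask (restored to source resolution) defines a square
region of interest, which is cropped, resized to the cup network's input
side, segmented, and the cup mask is pasted back into source coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "RoiBox",
    "binarize",
    "detect_roi",
    "crop_resize",
    "restore_mask",
    "resize_image",
    "resize_mask",
    "segment_fundus",
]


@dataclass(frozen=True)
class RoiBox:
    """A square crop window in source coordinates (0-based, half-open)."""

    top: int
    left: int
    side: int
    source_height: int
    source_width: int

    def __post_init__(self):
        if self.side < 1:
            raise ValueError("ROI side must be >= 1")
        if (
            self.top < 0
            or self.left < 0
            or self.top + self.side > self.source_height
            or self.left + self.side > self.source_width
        ):
            raise ValueError("ROI box must lie fully inside the source image")


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map: pixel -> 1 iff P >= threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    return (np.asarray(prob) >= threshold).astype(np.uint8)


def resize_image(image: np.ndarray, out_hw) -> np.ndarray:
    """Bilinear resize of an RGB image, preserving the dtype range."""
    img = np.asarray(image)
    if img.shape[:2] == tuple(out_hw):
        return img.copy()
    out = _sk_resize(img.astype(np.float64), (*out_hw, img.shape[2]), order=1, preserve_range=True, anti_aliasing=False)
    if np.issubdtype(img.dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255)
    return out.astype(img.dtype)


def resize_mask(mask: np.ndarray, out_hw) -> np.ndarray:
    """Nearest-neighbour resize of a binary mask (stays binary)."""
    m = np.asarray(mask)
    if m.shape == tuple(out_hw):
        return m.copy()
    out = _sk_resize(m.astype(np.float64), out_hw, order=0, preserve_range=True, anti_aliasing=False)
    return (out > 0.5).astype(m.dtype)


def detect_roi(od_mask: np.ndarray, margin: float = 0.5) -> RoiBox:
    """Square ROI around the disc mask.

    The tight bounding box is expanded by ``margin`` times its larger
    side on every side, then clipped to the image (shifting inward to
    stay square where possible).  An empty mask falls back to a centred
    box of half the (smaller) image side.
    """
    mask = np.asarray(od_mask)
    h, w = mask.shape
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        side = max(min(h, w) // 2, 1)
        return RoiBox(top=(h - side) // 2, left=(w - side) // 2, side=side, source_height=h, source_width=w)
    r0, r1 = int(rows[0]), int(rows[-1])
    c0, c1 = int(cols[0]), int(cols[-1])
    extent = max(r1 - r0 + 1, c1 - c0 + 1)
    side = int(round(extent * (1.0 + 2.0 * margin)))
    side = min(side, h, w)
    centre_r = (r0 + r1) / 2.0
    centre_c = (c0 + c1) / 2.0
    top = int(round(centre_r - (side - 1) / 2.0))
    left = int(round(centre_c - (side - 1) / 2.0))
    top = min(max(top, 0), h - side)
    left = min(max(left, 0), w - side)
    return RoiBox(top=top, left=left, side=side, source_height=h, source_width=w)


def crop_resize(array: np.ndarray, roi: RoiBox, out_side: int = 256, kind: str = "image") -> np.ndarray:
    """Crop the ROI then resize to ``out_side``; bilinear for images,
    nearest for masks.  When the ROI side equals ``out_side`` the crop is
    returned bit-identically."""
    a = np.asarray(array)
    if a.shape[0] != roi.source_height or a.shape[1] != roi.source_width:
        raise ValueError("array does not match the ROI's source size")
    crop = a[roi.top : roi.top + roi.side, roi.left : roi.left + roi.side]
    if roi.side == out_side:
        return crop.copy()
    if kind == "image":
        return resize_image(crop, (out_side, out_side))
    return resize_mask(crop, (out_side, out_side))


def restore_mask(oc_roi_mask: np.ndarray, roi: RoiBox) -> np.ndarray:
    """Paste an ROI-space cup mask back into a zero source-size canvas."""
    m = np.asarray(oc_roi_mask)
    if m.shape[0] != m.shape[1]:
        raise ValueError("ROI masks must be square")
    if m.shape[0] != roi.side:
        m = resize_mask(m, (roi.side, roi.side))
    out = np.zeros((roi.source_height, roi.source_width), dtype=np.uint8)
    out[roi.top : roi.top + roi.side, roi.left : roi.left + roi.side] = m
    return out


def segment_fundus(image, od_net, oc_net, threshold: float = 0.5, margin: float = 0.5, intersect: bool = False):
    """Run the full two-stage pipeline on one RGB image.

    Returns ``(od_mask, oc_mask)`` at the original image resolution.
    ``intersect=True`` additionally clips the cup mask to the disc mask
    (off by default; no anatomical constraint is imposed otherwise).
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    od_side = od_net.config.input_side
    oc_side = oc_net.config.input_side
    od_prob = od_net.predict(resize_image(img, (od_side, od_side)))
    od_mask = resize_mask(binarize(od_prob, threshold), (h, w))
    roi = detect_roi(od_mask, margin=margin)
    roi_img = crop_resize(img, roi, out_side=oc_side, kind="image")
    oc_prob = oc_net.predict(roi_img)
    oc_mask = restore_mask(binarize(oc_prob, threshold), roi)
    if intersect:
        oc_mask = (oc_mask & od_mask).astype(np.uint8)
    return od_mask, oc_mask
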