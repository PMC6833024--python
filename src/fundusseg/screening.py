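"""Glaucoma-screening indicators computed from disc and cup masks.

The vertical cup-to-disc ratio (VCDR) is the ratio of the vertical pixel
extents of the cup and disc masks.  Rim widths are measured by casting
rays from the disc centroid at one-degree steps: on each ray the rim
width is the distance from the last cup pixel to the last disc pixel.
Quadrant means (90-degree sectors centred on image-down, image-up, and
the two horizontal directions) give the inferior, superior, nasal and
temporal rim widths; which horizontal quadrant is nasal depends on the
eye's laterality.  The ISNT score counts how many of the healthy-eye
orderings I > S, S > N, N > T hold strictly (3 = fully ISNT-consistent,
0 = none).

The quadrant-ray construction is this package's concrete realisation of
the qualitative clinical rule; it is not a standardised formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import roc_auc

__all__ = [
    "ScreeningRecord",
    "vertical_diameter",
    "compute_vcdr",
    "rim_widths",
    "isnt_score",
    "screening_score",
    "vcdr_difference",
    "screen_masks",
    "screening_auc",
]


@dataclass(frozen=True)
class ScreeningRecord:
    """Per-eye screening indicators."""

    vcd: int
    vdd: int
    vcdr: float
    rim_i: float
    rim_s: float
    rim_n: float
    rim_t: float
    isnt: int
    score: float
    label: int | None = None


def vertical_diameter(mask: np.ndarray) -> int:
    """Vertical pixel extent (max row - min row + 1); 0 for an empty mask."""
    rows = np.flatnonzero(np.asarray(mask).any(axis=1))
    if rows.size == 0:
        return 0
    return int(rows[-1] - rows[0] + 1)


def compute_vcdr(od_mask: np.ndarray, oc_mask: np.ndarray) -> float:
    """Vertical cup-to-disc ratio; 0 when the cup mask is empty."""
    od = np.asarray(od_mask)
    oc = np.asarray(oc_mask)
    if od.shape != oc.shape:
        raise ValueError("masks must have identical shape")
    vdd = vertical_diameter(od)
    if vdd == 0:
        raise ValueError("disc mask is empty")
    return vertical_diameter(oc) / vdd


def rim_widths(od_mask: np.ndarray, oc_mask: np.ndarray, eye: str = "right", n_rays: int = 360, step: float = 0.5):
    """Mean radial rim width per ISNT sector.

    Rays start at the disc centroid; per ray the rim width is the radial
    distance between the outermost cup pixel (the centroid itself when
    the cup is absent on that ray) and the outermost disc pixel.  The cup
    is intersected with the disc first.  ``eye`` is ``"right"`` (nasal =
    image-left), ``"left"`` (nasal = image-right) or ``"unknown"``
    (nasal/temporal assigned as max/min of the two horizontal sectors).

    Returns ``(I, S, N, T)`` in pixels.
    """
    od = np.asarray(od_mask).astype(bool)
    oc = np.asarray(oc_mask).astype(bool) & od
    if not od.any():
        raise ValueError("disc mask is empty")
    h, w = od.shape
    rr, cc = np.nonzero(od)
    cy, cx = float(rr.mean()), float(cc.mean())
    r_max = float(np.sqrt(h * h + w * w))
    radii = np.arange(0.0, r_max, step)
    angles = np.deg2rad(np.arange(n_rays) * (360.0 / n_rays))
    # direction: angle measured from image-down (row+), counter-clockwise through image-right
    dr = np.cos(angles)
    dc = np.sin(angles)
    rays_r = cy + radii[None, :] * dr[:, None]
    rays_c = cx + radii[None, :] * dc[:, None]
    ri = np.rint(rays_r).astype(int)
    ci = np.rint(rays_c).astype(int)
    inside = (ri >= 0) & (ri < h) & (ci >= 0) & (ci < w)
    ri_c = np.clip(ri, 0, h - 1)
    ci_c = np.clip(ci, 0, w - 1)
    on_od = od[ri_c, ci_c] & inside
    on_oc = oc[ri_c, ci_c] & inside

    def outermost(hits):
        idx = np.where(hits, np.arange(len(radii))[None, :], -1).max(axis=1)
        return np.where(idx >= 0, radii[np.clip(idx, 0, None)], 0.0)

    r_od = outermost(on_od)
    r_oc = outermost(on_oc)
    width = np.clip(r_od - r_oc, 0.0, None)

    deg = np.rad2deg(angles) % 360.0
    inferior = (deg < 45) | (deg >= 315)
    right_side = (deg >= 45) & (deg < 135)  # positive col direction = image-right
    superior = (deg >= 135) & (deg < 225)
    left_side = (deg >= 225) & (deg < 315)
    mean_i = float(width[inferior].mean())
    mean_s = float(width[superior].mean())
    mean_left = float(width[left_side].mean())
    mean_right = float(width[right_side].mean())
    if eye == "right":
        nasal, temporal = mean_left, mean_right
    elif eye == "left":
        nasal, temporal = mean_right, mean_left
    elif eye == "unknown":
        nasal, temporal = max(mean_left, mean_right), min(mean_left, mean_right)
    else:
        raise ValueError("eye must be 'right', 'left' or 'unknown'")
    return mean_i, mean_s, nasal, temporal


def isnt_score(widths) -> int:
    """Count of strict inequalities among I > S, S > N, N > T."""
    i, s, n, t = widths
    if min(i, s, n, t) < 0:
        raise ValueError("rim widths must be non-negative")
    return int(i > s) + int(s > n) + int(n > t)


def screening_score(vcdr: float, isnt: int, gamma: float = 0.0) -> float:
    """Screening statistic: VCDR plus gamma-weighted ISNT violation.

    ``vcdr + gamma * (3 - isnt) / 3``; the default gamma of 0 uses VCDR
    alone, which is the primary indicator.
    """
    return vcdr + gamma * (3 - isnt) / 3.0


def vcdr_difference(true_vcdr: float, pred_vcdr: float) -> float:
    """Absolute VCDR error |true - pred|."""
    return abs(true_vcdr - pred_vcdr)


def screen_masks(od_mask, oc_mask, eye: str = "right", gamma: float = 0.0, label=None) -> ScreeningRecord:
    """Full screening record for one disc/cup mask pair."""
    vdd = vertical_diameter(od_mask)
    vcd = vertical_diameter(oc_mask)
    vcdr = compute_vcdr(od_mask, oc_mask)
    widths = rim_widths(od_mask, oc_mask, eye=eye)
    isnt = isnt_score(widths)
    return ScreeningRecord(
        vcd=vcd,
        vdd=vdd,
        vcdr=vcdr,
        rim_i=widths[0],
        rim_s=widths[1],
        rim_n=widths[2],
        rim_t=widths[3],
        isnt=isnt,
        score=screening_score(vcdr, isnt, gamma=gamma),
        label=label,
    )


def screening_auc(records) -> float:
    """ROC-AUC of the screening scores against the labels."""
    scores = [r.score for r in records]
    labels = [r.label for r in records]
    if any(l is None for l in labels):
        raise ValueError("all records need labels for AUC")
    return roc_auc(scores, labels)
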