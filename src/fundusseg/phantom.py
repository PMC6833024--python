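"""Synthetic fundus phantoms with analytic optic-disc / optic-cup truth.

A phantom is a square RGB image containing a bright elliptical optic disc
on a reddish retinal background, a brighter elliptical optic cup inside
the disc, a few dark vessel strokes crossing the disc, and Gaussian pixel
noise.  The ground-truth masks are the exact ellipse interiors, so the
vertical cup-to-disc ratio (VCDR) is known analytically.

Two rare styles emulate the hard minority of clinical datasets: a cup of
very small vertical extent (``small_cup``) and a cup whose colour barely
differs from the disc (``low_contrast``).  Generated populations are
labelled glaucomatous when the analytic VCDR exceeds 0.6, which makes a
perfect screening pipeline separate the classes exactly.

Everything is deterministic in the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .training import TrainingPair

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "ground_truth_vcdr",
    "generate_dataset",
    "od_pairs",
    "oc_pairs",
]

STYLES = ("typical", "small_cup", "low_contrast")
GLAUCOMA_VCDR_THRESHOLD = 0.6

_BACKGROUND = np.array([168.0, 78.0, 48.0])
_DISC = np.array([232.0, 178.0, 108.0])
_CUP_BRIGHT = np.array([252.0, 230.0, 170.0])
_VESSEL = np.array([110.0, 30.0, 25.0])


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, colours and style of one phantom.

    Cup semi-axes are fractions of the disc semi-axes; the cup centre
    offset is in pixels relative to the disc centre.  ``contrast`` in
    [0, 1] scales the colour difference between cup and disc (0 means the
    cup is invisible in the image although still present in the mask).
    """

    side: int = 64
    disc_center: tuple = (32.0, 32.0)
    disc_axes: tuple = (20.0, 18.0)  # (row semi-axis, col semi-axis)
    cup_fractions: tuple = (0.5, 0.5)
    cup_offset: tuple = (0.0, 0.0)
    contrast: float = 0.7
    vessel_count: int = 4
    noise_sigma: float = 6.0
    style: str = "typical"
    seed: int = 0

    def __post_init__(self):
        if self.style not in STYLES:
            raise ValueError(f"unknown style {self.style!r}")
        fr, fc = self.cup_fractions
        if not (0.0 < fr < 1.0 and 0.0 < fc < 1.0):
            raise ValueError("cup fractions must lie in (0, 1)")
        if self.style == "small_cup" and fr > 0.2:
            raise ValueError("small_cup style requires cup vertical fraction <= 0.2")
        if self.style == "low_contrast" and self.contrast > 0.15:
            raise ValueError("low_contrast style requires contrast <= 0.15")
        if not self._cup_inside_disc():
            raise ValueError("cup ellipse must lie fully inside the disc ellipse")

    def _cup_inside_disc(self) -> bool:
        (ar, ac) = self.disc_axes
        car, cac = self.cup_axes
        orr, occ = self.cup_offset
        # sufficient check: offset plus cup semi-axis within disc semi-axis
        return abs(orr) + car <= ar and abs(occ) + cac <= ac

    @property
    def cup_axes(self) -> tuple:
        return (self.cup_fractions[0] * self.disc_axes[0], self.cup_fractions[1] * self.disc_axes[1])

    @property
    def cup_center(self) -> tuple:
        return (self.disc_center[0] + self.cup_offset[0], self.disc_center[1] + self.cup_offset[1])


@dataclass(frozen=True)
class PhantomSample:
    """A rendered phantom with its masks, spec, style and screening label."""

    image: np.ndarray
    od_mask: np.ndarray
    oc_mask: np.ndarray
    spec: PhantomSpec
    label: int  # 1 = glaucoma (analytic VCDR > 0.6)

    @property
    def style(self) -> str:
        return self.spec.style


def _ellipse_mask(side, center, axes) -> np.ndarray:
    rr, cc = np.mgrid[0:side, 0:side]
    return (((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0).astype(np.uint8)


def _ellipse_soft(side, center, axes, width=1.5) -> np.ndarray:
    """Smooth [0, 1] interior indicator with a ~width-pixel soft edge."""
    rr, cc = np.mgrid[0:side, 0:side]
    d = np.sqrt(((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2)
    # convert normalised distance to approximate pixel distance from the rim
    scale = (axes[0] + axes[1]) / 2.0
    edge = (1.0 - d) * scale
    return np.clip(edge / width + 0.5, 0.0, 1.0)


def _bezier(p0, p1, p2, n=80):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 2) * p0 + 2 * (1 - t) * t * p1 + (t**2) * p2


def _draw_vessels(img: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> None:
    """Dark quadratic Bezier strokes crossing the disc; cosmetic only."""
    side = spec.side
    cy, cx = spec.disc_center
    for _ in range(spec.vessel_count):
        ang = rng.uniform(0, 2 * math.pi)
        r0 = side * 0.7
        p0 = np.array([cy + r0 * math.sin(ang), cx + r0 * math.cos(ang)])
        p2 = np.array([cy - r0 * math.sin(ang), cx - r0 * math.cos(ang)])
        p1 = np.array([cy, cx]) + rng.uniform(-side * 0.15, side * 0.15, size=2)
        pts = _bezier(p0, p1, p2, n=3 * side)
        thickness = rng.uniform(0.6, 1.4)
        for r, c in pts:
            ri, ci = int(round(r)), int(round(c))
            rad = int(math.ceil(thickness))
            for dr in range(-rad, rad + 1):
                for dc in range(-rad, rad + 1):
                    rr, cc = ri + dr, ci + dc
                    if 0 <= rr < side and 0 <= cc < side and dr * dr + dc * dc <= thickness * thickness:
                        img[rr, cc] = 0.65 * img[rr, cc] + 0.35 * _VESSEL


def generate_phantom(spec: PhantomSpec):
    """Render one phantom: returns ``(image uint8 HxWx3, od_mask, oc_mask)``.

    Masks are exact ellipse interiors (uint8 {0, 1}); the image gets soft
    colour edges, vessels and noise but the masks do not.
    """
    rng = np.random.default_rng(spec.seed)
    side = spec.side
    od_mask = _ellipse_mask(side, spec.disc_center, spec.disc_axes)
    oc_mask = _ellipse_mask(side, spec.cup_center, spec.cup_axes)

    img = np.empty((side, side, 3), dtype=np.float64)
    img[:] = _BACKGROUND
    # radial background shading
    rr, cc = np.mgrid[0:side, 0:side]
    rad = np.sqrt((rr - side / 2.0) ** 2 + (cc - side / 2.0) ** 2) / side
    img *= (1.0 - 0.25 * rad)[..., None]

    disc_soft = _ellipse_soft(side, spec.disc_center, spec.disc_axes)
    img = img * (1 - disc_soft[..., None]) + _DISC * disc_soft[..., None]
    cup_color = _DISC + spec.contrast * (_CUP_BRIGHT - _DISC)
    cup_soft = _ellipse_soft(side, spec.cup_center, spec.cup_axes)
    img = img * (1 - cup_soft[..., None]) + cup_color * cup_soft[..., None]

    _draw_vessels(img, spec, rng)
    img += rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), od_mask, oc_mask


def ground_truth_vcdr(spec: PhantomSpec) -> float:
    """Analytic vertical cup-to-disc ratio: cup vertical fraction."""
    return (2.0 * spec.cup_axes[0]) / (2.0 * spec.disc_axes[0])


def _random_spec(side: int, style: str, seed: int, rng: np.random.Generator) -> PhantomSpec:
    ar = rng.uniform(0.28, 0.36) * side
    ac = ar * rng.uniform(0.85, 1.05)
    ac = min(ac, 0.38 * side)
    centre = (
        side / 2.0 + rng.uniform(-0.04, 0.04) * side,
        side / 2.0 + rng.uniform(-0.04, 0.04) * side,
    )
    if style == "small_cup":
        fr = rng.uniform(0.08, 0.2)
        fc = fr * rng.uniform(0.9, 1.3)
        contrast = rng.uniform(0.45, 0.9)
    elif style == "low_contrast":
        fr = rng.uniform(0.3, 0.8)
        fc = fr * rng.uniform(0.85, 1.15)
        contrast = rng.uniform(0.05, 0.15)
    else:
        fr = rng.uniform(0.3, 0.8)
        fc = fr * rng.uniform(0.85, 1.15)
        contrast = rng.uniform(0.45, 0.9)
    fc = min(fc, 0.95)
    max_or = (1.0 - fr) * ar
    max_oc = (1.0 - fc) * ac
    offset = (
        rng.uniform(-0.4, 0.4) * max_or,
        rng.uniform(-0.4, 0.4) * max_oc,
    )
    return PhantomSpec(
        side=side,
        disc_center=centre,
        disc_axes=(ar, ac),
        cup_fractions=(fr, fc),
        cup_offset=offset,
        contrast=contrast,
        vessel_count=int(rng.integers(3, 7)),
        noise_sigma=6.0,
        style=style,
        seed=seed,
    )


def generate_dataset(n: int, rare_fraction: float, side: int = 64, seed: int = 0):
    """Generate ``n`` phantoms with a rare-style minority.

    ``ceil(rare_fraction * n)`` samples are drawn from the rare styles
    (``small_cup`` / ``low_contrast`` alternating), the rest are typical;
    rare samples are spread over the list deterministically.  Labels are
    1 iff the analytic VCDR exceeds 0.6.
    """
    if not (0.0 <= rare_fraction < 1.0):
        raise ValueError("rare_fraction must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xFA11)))
    n_rare = math.ceil(rare_fraction * n)
    rare_positions = set(rng.choice(n, size=n_rare, replace=False).tolist()) if n_rare else set()
    samples = []
    rare_counter = 0
    for i in range(n):
        if i in rare_positions:
            style = "small_cup" if rare_counter % 2 == 0 else "low_contrast"
            rare_counter += 1
        else:
            style = "typical"
        spec = _random_spec(side, style, seed=int(rng.integers(0, 2**31 - 1)), rng=rng)
        image, od, oc = generate_phantom(spec)
        label = int(ground_truth_vcdr(spec) > GLAUCOMA_VCDR_THRESHOLD)
        samples.append(PhantomSample(image=image, od_mask=od, oc_mask=oc, spec=spec, label=label))
    return samples


def od_pairs(samples) -> list:
    """Training pairs (image, disc mask) for stage-1 segmentation."""
    return [TrainingPair(image=s.image, mask=s.od_mask, index=i) for i, s in enumerate(samples)]


def oc_pairs(samples) -> list:
    """Training pairs (image, cup mask) for single-stage cup segmentation."""
    return [TrainingPair(image=s.image, mask=s.oc_mask, index=i) for i, s in enumerate(samples)]
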