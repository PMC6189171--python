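"""Fluorescence quantification operators for time-lapse stacks.

These are the ratio-style measurements used to describe lipid and protein
recruitment at particle–membrane contact sites:

* line profiles and kymographs along a user-chosen line;
* normalized fluorescence NF(t) = mean(contact)/mean(reference) per frame,
  quantifying enrichment at the contact site relative to the rest of the
  membrane;
* pattern fold change FC = mean(pattern)/mean(non-pattern vesicle), the
  enrichment of a labeled lipid on a micropattern-contacting region;
* generalized polarization GP = (I_o - I_d)/(I_o + I_d), a per-pixel
  lipid-order index in [-1, 1].

Pixel coordinates are 0-based with x to the right and y down.  Lines are
sampled at unit-pixel spacing with bilinear interpolation and averaged over
a perpendicular band of the requested width, mirroring how line tools in
interactive image software behave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class ProfileLine:
    """A directed measurement line with an averaging band width (px)."""

    x0: float
    y0: float
    x1: float
    y1: float
    width: int = 1

    def __post_init__(self):
        if (self.x0, self.y0) == (self.x1, self.y1):
            raise ValueError("line endpoints must differ")
        if self.width < 1:
            raise ValueError("band width must be >= 1")


def _sample_points(line: ProfileLine) -> tuple[np.ndarray, np.ndarray]:
    """(ys, xs) arrays of shape (width, n_samples) covering the band."""
    dx, dy = line.x1 - line.x0, line.y1 - line.y0
    length = float(np.hypot(dx, dy))
    n = int(np.floor(length)) + 1
    ts = np.arange(n, dtype=float)  # unit-pixel spacing from p0 towards p1
    ux, uy = dx / length, dy / length  # unit along-line vector
    px, py = -uy, ux  # unit perpendicular
    offsets = np.arange(line.width, dtype=float) - (line.width - 1) / 2.0
    xs = line.x0 + ts[None, :] * ux + offsets[:, None] * px
    ys = line.y0 + ts[None, :] * uy + offsets[:, None] * py
    return ys, xs


def line_profile(frame: np.ndarray, line: ProfileLine) -> np.ndarray:
    """Intensity samples along ``line``, averaged across its width band."""
    frame = np.asarray(frame, dtype=float)
    ys, xs = _sample_points(line)
    h, w = frame.shape
    if ys.min() < 0 or xs.min() < 0 or ys.max() > h - 1 or xs.max() > w - 1:
        raise ValueError("profile line (with band) extends outside the frame")
    samples = ndimage.map_coordinates(frame, [ys.ravel(), xs.ravel()], order=1)
    return samples.reshape(ys.shape).mean(axis=0)


def kymograph(stack: np.ndarray, line: ProfileLine) -> np.ndarray:
    """T x L matrix whose row t is the line profile of frame t."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a nonempty T x H x W array")
    return np.stack([line_profile(frame, line) for frame in stack])


def _masked_mean(frame: np.ndarray, mask: np.ndarray) -> float:
    return float(frame[mask].mean())


def normalized_fluorescence(
    stack: np.ndarray,
    contact: np.ndarray,
    reference: np.ndarray,
    background: np.ndarray | None = None,
    floor_fraction: float = 1e-6,
) -> np.ndarray:
    """NF(t) = mean contact intensity / mean reference intensity, per frame.

    If a background mask is given, its per-frame mean is subtracted from both
    the numerator and denominator means.  Frames whose denominator falls
    below ``floor_fraction`` x the global mean intensity yield NaN rather
    than an unstable spike.
    """
    stack = np.asarray(stack, dtype=float)
    contact = np.asarray(contact, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if contact.sum() == 0 or reference.sum() == 0:
        raise ValueError("contact and reference masks must be nonempty")
    if (contact & reference).any():
        raise ValueError("contact and reference masks overlap")
    floor = floor_fraction * float(stack.mean())
    out = np.empty(stack.shape[0])
    for t, frame in enumerate(stack):
        num = _masked_mean(frame, contact)
        den = _masked_mean(frame, reference)
        if background is not None:
            bg = _masked_mean(frame, np.asarray(background, dtype=bool))
            num -= bg
            den -= bg
        out[t] = np.nan if den < floor else num / den
    return out


def pattern_fold_change(
    image: np.ndarray,
    pattern: np.ndarray,
    vesicle: np.ndarray | None = None,
    background: float = 0.0,
) -> float:
    """FC = mean(pattern pixels) / mean(non-pattern vesicle pixels).

    ``vesicle`` restricts the complement to the vesicle footprint (defaults
    to the whole image).  ``background`` is an optional constant subtracted
    from both means before the ratio.
    """
    image = np.asarray(image, dtype=float)
    pattern = np.asarray(pattern, dtype=bool)
    vesicle = np.ones_like(pattern) if vesicle is None else np.asarray(vesicle, dtype=bool)
    complement = vesicle & ~pattern
    inside = vesicle & pattern
    if inside.sum() == 0:
        raise ValueError("pattern region is empty within the vesicle")
    if complement.sum() == 0:
        raise ValueError("non-pattern vesicle region is empty")
    return (_masked_mean(image, inside) - background) / (
        _masked_mean(image, complement) - background
    )


def gp_ratio(
    channel_ordered: np.ndarray,
    channel_disordered: np.ndarray,
    floor: float = 1e-12,
) -> np.ndarray:
    """Per-pixel generalized polarization (I_o - I_d)/(I_o + I_d).

    Pixels whose total intensity falls below ``floor`` are NaN.  Values are
    in [-1, 1] wherever defined.
    """
    io = np.asarray(channel_ordered, dtype=float)
    idis = np.asarray(channel_disordered, dtype=float)
    if io.shape != idis.shape:
        raise ValueError(f"channel shapes differ: {io.shape} vs {idis.shape}")
    if (io < 0).any() or (idis < 0).any():
        raise ValueError("channel intensities must be nonnegative")
    total = io + idis
    with np.errstate(invalid="ignore", divide="ignore"):
        gp = (io - idis) / total
    gp[total < floor] = np.nan
    return gp
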