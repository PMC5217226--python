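"""Comparison geometries around a placed prey.

All camouflage metrics compare the prey to one of two background regions:
the *local* region — every pixel within a Euclidean radius of one body
length (126 px) of the prey's outline — or the *global* region, the entire
background image.  The Canny-based disruption ratios additionally use an
outline band 4 px inside / 8 px outside the prey's outline; that outer 8-px
ring is excluded from the local and global background regions when the bands
are in play.

Coordinates are 0-based, row-major (y, x); distances are Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "RegionSet",
    "outline_pixels",
    "outline_mask",
    "local_region",
    "canny_band_regions",
    "make_region_set",
]

_EIGHT = np.ones((3, 3), dtype=bool)
_FOUR = ndimage.generate_binary_structure(2, 1)


def outline_mask(mask: np.ndarray) -> np.ndarray:
    """Inner boundary: prey pixels edge-adjacent to a non-prey pixel (pixels
    beyond the image edge count as non-prey).

    This is the thin rasterized contour — diagonal steps contribute one
    pixel, so a 45-degree edge yields one outline pixel per row, matching
    the pixel chain that contour following walks.
    """
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=_FOUR, border_value=0)
    return mask & ~eroded


# Moore neighbourhood in clockwise order starting from west.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def outline_pixels(mask: np.ndarray) -> list[tuple[int, int]]:
    """Ordered (y, x) outline pixels by Moore contour following.

    Requires a non-empty, single 8-connected component.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n != 1:
        raise ValueError(f"mask must be a single connected component, got {n}")
    boundary = outline_mask(mask)
    ys, xs = np.nonzero(boundary)
    if len(ys) == 1:
        return [(int(ys[0]), int(xs[0]))]

    h, w = mask.shape

    def inside(p):
        y, x = p
        return 0 <= y < h and 0 <= x < w and mask[y, x]

    start = (int(ys[0]), int(xs[0]))  # topmost, then leftmost boundary pixel
    contour = [start]
    seen = {start}
    visited_states = set()
    # Enter from the west (the pixel above the start is outside the mask).
    prev_dir = 0
    cur = start
    while True:
        found = False
        for i in range(8):
            d = (prev_dir + 1 + i) % 8
            dy, dx = _MOORE[d]
            nxt = (cur[0] + dy, cur[1] + dx)
            if inside(nxt):
                state = (cur, d)
                if state in visited_states:
                    found = False
                    break
                visited_states.add(state)
                # Back-direction for the next step: opposite of arrival.
                prev_dir = (d + 4) % 8
                cur = nxt
                found = True
                break
        if not found:
            break  # isolated or fully traced
        if cur == start:
            break
        if cur not in seen:
            contour.append(cur)
            seen.add(cur)
    # The trace can pass through non-boundary pixels at reflex corners and
    # (rarely) skip spur pixels; reconcile with the boundary set while
    # keeping the walked order.
    contour = [p for p in contour if boundary[p]]
    traced = set(contour)
    for y, x in zip(ys, xs):
        p = (int(y), int(x))
        if p not in traced:
            contour.append(p)
    return contour


def local_region(mask: np.ndarray, body_length: int = 126) -> np.ndarray:
    """All pixels within ``body_length`` px (Euclidean) of the prey outline.

    Includes the prey interior: for prey shallower than a body length every
    interior pixel lies within range of the outline.  Clipped to the canvas.
    """
    if body_length < 0:
        raise ValueError("body_length must be >= 0")
    outline = outline_mask(mask)
    if not outline.any():
        raise ValueError("mask is empty")
    dist = ndimage.distance_transform_edt(~outline)
    return dist <= body_length


def canny_band_regions(
    mask: np.ndarray, inner: int = 4, outer: int = 8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split the canvas for the Canny ratios.

    Returns ``(moth_region, outline_band, background_region)``: the prey
    interior deeper than ``inner`` px from the outline, the band ``inner`` px
    inside / ``outer`` px outside the outline, and everything else.  The
    three masks are disjoint and tile the canvas.
    """
    mask = np.asarray(mask, dtype=bool)
    d_in = ndimage.distance_transform_edt(mask)  # 1 on boundary pixels
    d_out = ndimage.distance_transform_edt(~mask)
    inner_band = mask & (d_in <= inner)
    outer_band = (~mask) & (d_out <= outer)
    outline_band = inner_band | outer_band
    moth_region = mask & ~inner_band
    if not moth_region.any():
        raise ValueError("prey too small: interior vanishes inside the band")
    background_region = ~(mask | outline_band)
    return moth_region, outline_band, background_region


@dataclass
class RegionSet:
    """All region masks for one placed prey on one canvas."""

    prey: np.ndarray
    outline: np.ndarray
    moth_region: np.ndarray
    outline_band: np.ndarray
    local: np.ndarray  # <= body_length of the outline, prey included
    local_bg: np.ndarray  # local background: local minus prey minus band
    global_bg: np.ndarray  # whole image minus prey minus band
    body_length: int

    @property
    def global_region(self) -> np.ndarray:
        """Whole image minus the prey (the 2.1-million-px global zone)."""
        return ~self.prey


def make_region_set(
    prey_mask: np.ndarray, body_length: int = 126, inner: int = 4, outer: int = 8
) -> RegionSet:
    """Build every comparison region from a placed prey mask.

    Distance transforms run on a window of the prey's bounding box padded by
    the largest radius, then are embedded back into the full canvas — exact,
    since every band/local pixel lies within that window.
    """
    prey_mask = np.asarray(prey_mask, dtype=bool)
    h, w = prey_mask.shape
    pad = int(max(body_length, outer)) + 2
    ys, xs = np.nonzero(prey_mask)
    if len(ys) == 0:
        raise ValueError("mask is empty")
    y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, h)
    x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, w)
    win = prey_mask[y0:y1, x0:x1]

    def embed(sub: np.ndarray) -> np.ndarray:
        out = np.zeros((h, w), dtype=bool)
        out[y0:y1, x0:x1] = sub
        return out

    loc = embed(local_region(win, body_length))
    moth_w, band_w, _ = canny_band_regions(win, inner, outer)
    moth, band = embed(moth_w), embed(band_w)
    bg = ~(prey_mask | band)
    return RegionSet(
        prey=prey_mask,
        outline=outline_mask(prey_mask),
        moth_region=moth,
        outline_band=band,
        local=loc,
        local_bg=loc & bg,
        global_bg=bg,
        body_length=body_length,
    )
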