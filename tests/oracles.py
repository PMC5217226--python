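"""Independent brute-force reference implementations used only by tests.

Everything here avoids the library's vectorised/FFT code paths: kernels are
built loop-wise from the defining formulas, responses are direct dot
products, and region distances are explicit nearest-outline searches.
"""

import numpy as np
from scipy.spatial.distance import cdist


def brute_outline(mask: np.ndarray) -> list[tuple[int, int]]:
    """Mask pixels with an edge-adjacent (4-neighbour) pixel outside the
    mask (out-of-canvas counts as outside) — the thin rasterized contour."""
    h, w = mask.shape
    out = []
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ny, nx = y + dy, x + dx
                if not (0 <= ny < h and 0 <= nx < w) or not mask[ny, nx]:
                    out.append((y, x))
                    break
    return out


def brute_local_region(mask: np.ndarray, body_length: float) -> np.ndarray:
    """Pixels within body_length of the nearest outline pixel, by explicit
    pairwise distances."""
    outline = np.array(brute_outline(mask), dtype=float)
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    d = cdist(pts, outline).min(axis=1).reshape(h, w)
    return d <= body_length


def brute_band_regions(mask: np.ndarray, inner: int = 4, outer: int = 8):
    """Inner/outer band split by explicit nearest-opposite-pixel distances."""
    h, w = mask.shape
    inside = np.argwhere(mask).astype(float)
    outside = np.argwhere(~mask).astype(float)
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    d_to_out = cdist(pts, outside).min(axis=1).reshape(h, w)
    d_to_in = cdist(pts, inside).min(axis=1).reshape(h, w)
    inner_band = mask & (d_to_out <= inner)
    outer_band = ~mask & (d_to_in <= outer)
    band = inner_band | outer_band
    moth = mask & ~inner_band
    background = ~(mask | band)
    return moth, band, background


def brute_gabor_kernel(sigma: float, angle: float) -> np.ndarray:
    """Even Gabor kernel built pixel by pixel from the defining formula."""
    r = int(np.floor(3 * sigma))
    d = 2 * r + 1
    lam = d / 4.0
    k = np.empty((d, d))
    for yy in range(d):
        for xx in range(d):
            y, x = yy - r, xx - r
            u = -x * np.sin(angle) + y * np.cos(angle)
            v = x * np.cos(angle) + y * np.sin(angle)
            k[yy, xx] = np.exp(-(v * v + u * u) / (2 * sigma**2)) * np.cos(
                2 * np.pi * u / lam
            )
    return k - k.mean()


def brute_gabrat(image: np.ndarray, mask: np.ndarray, sigma: float) -> float:
    """GabRat by direct per-pixel kernel dot products (no convolution)."""
    angles = np.deg2rad([0.0, 45.0, 90.0, 135.0])
    kernels = [brute_gabor_kernel(sigma, a) for a in angles]
    r = int(np.floor(3 * sigma))
    d = 2 * r + 1
    pad_img = np.pad(image.astype(float), r, mode="reflect")
    pad_mask = np.pad(mask.astype(float), r, mode="reflect")
    ratios = []
    for y, x in brute_outline(mask):
        win_m = pad_mask[y : y + d, x : x + d]
        resp_m = np.round([abs((k * win_m).sum()) for k in kernels], 8)
        par = int(np.argmax(resp_m))
        win = pad_img[y : y + d, x : x + d]
        e_p = abs((kernels[par] * win).sum())
        e_o = abs((kernels[(par + 2) % 4] * win).sum())
        ratios.append(0.0 if e_p + e_o < 1e-12 else e_o / (e_o + e_p))
    return float(np.mean(ratios))
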