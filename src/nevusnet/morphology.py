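"""Lesion boundary morphometrics.

Quantitative descriptors of lesion-mask geometry used to characterise
border irregularity and asymmetry:

* **Skeleton topology** — Zhang-Suen thinning of the mask followed by an
  8-neighbour census of branch (>= 3 neighbours) and terminal (exactly 1
  neighbour) nodes.  High branch density signals lobulated, spiculated
  outgrowth.
* **Scale-resolved fractal dimension** — windows of several sizes slide
  along the boundary; within each window the boundary pixels are
  box-counted over dyadic sub-box sizes and the regression slope of
  log N vs log(1/eps) gives a local dimension in [1, 2].
* **Elliptic Fourier descriptors** — harmonic decomposition of the closed
  contour under arc-length parameterisation; magnitudes are normalised to
  harmonic 1.  Smooth (elliptical) contours concentrate energy in the
  first harmonic; serrated contours keep high-harmonic power.
* **Radial-distance profile** — the polar trace r(phi) around the mask
  centroid, its oscillation amplitude relative to the mean radius, and the
  fraction of boundary points deviating from the mean radius by more than
  a threshold (benign controls rarely exceed 15% of points past the 10%
  deviation mark).

All analyses operate on the largest connected component; holes are filled
for the skeleton and centroid, while the boundary is the outer contour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = ["SkeletonStats", "FDSpectrum", "EFDSpectrum", "RadialProfile",
           "largest_component", "mask_to_contour", "zhang_suen",
           "local_fd_spectrum", "efd_coefficients", "efd_magnitudes",
           "radial_profile", "benign_criteria_report",
           "DEFAULT_FD_WINDOWS"]

DEFAULT_FD_WINDOWS = (16, 32, 64, 128, 256)

_N8 = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


@dataclass
class SkeletonStats:
    skeleton: np.ndarray
    branch_points: int
    terminal_points: int
    branch_density: float    # branch points per 100 skeleton pixels


@dataclass
class FDSpectrum:
    windows: np.ndarray
    fd: np.ndarray           # local fractal dimension per window size


@dataclass
class EFDSpectrum:
    harmonics: np.ndarray    # 1..N
    magnitudes: np.ndarray   # normalised so magnitudes[0] == 1


@dataclass
class RadialProfile:
    angles: np.ndarray       # bin centres, radians in [0, 2*pi)
    radii: np.ndarray        # r(phi) per bin
    mean_radius: float
    oscillation: float       # (max - min) / mean
    deviations: np.ndarray   # (r_i - mean)/mean per contour point

    def frac_over(self, threshold: float) -> float:
        """Fraction of boundary points with |Delta r| / r-bar > threshold."""
        return float(np.mean(np.abs(self.deviations) > threshold))


# ---------------------------------------------------------------------------
# mask utilities
# ---------------------------------------------------------------------------

def largest_component(mask: np.ndarray, fill_holes: bool = True) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return mask


def mask_to_contour(mask: np.ndarray) -> np.ndarray:
    """Ordered closed outer boundary of the largest component as (x, y)
    points (sub-pixel, from a marching-squares trace)."""
    m = largest_component(mask)
    contours = measure.find_contours(m.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no traceable boundary")
    c = max(contours, key=len)          # (row, col)
    return np.stack([c[:, 1], c[:, 0]], axis=1)


# ---------------------------------------------------------------------------
# Zhang-Suen thinning
# ---------------------------------------------------------------------------

def _zs_pass(img: np.ndarray, first: bool) -> np.ndarray:
    """One sub-iteration; returns the deletion mask."""
    p = np.pad(img, 1).astype(np.uint8)
    p2 = p[:-2, 1:-1]; p3 = p[:-2, 2:]; p4 = p[1:-1, 2:]; p5 = p[2:, 2:]
    p6 = p[2:, 1:-1]; p7 = p[2:, :-2]; p8 = p[1:-1, :-2]; p9 = p[:-2, :-2]
    ring = [p2, p3, p4, p5, p6, p7, p8, p9]
    b = sum(ring)
    a = sum(((ring[i] == 0) & (ring[(i + 1) % 8] == 1)).astype(np.uint8)
            for i in range(8))
    cond = (img == 1) & (b >= 2) & (b <= 6) & (a == 1)
    if first:
        cond &= (p2 * p4 * p6 == 0) & (p4 * p6 * p8 == 0)
    else:
        cond &= (p2 * p4 * p8 == 0) & (p2 * p6 * p8 == 0)
    return cond


def zhang_suen(mask: np.ndarray) -> SkeletonStats:
    """Iterative two-subcycle thinning to a 1-px skeleton, plus node census.

    The skeleton is a subset of the (largest-component, hole-filled) mask
    and preserves its connectivity.
    """
    img = largest_component(mask).astype(np.uint8)
    while True:
        d1 = _zs_pass(img, True)
        img[d1] = 0
        d2 = _zs_pass(img, False)
        img[d2] = 0
        if not (d1.any() or d2.any()):
            break
    skel = img.astype(bool)
    ncount = ndimage.convolve(skel.astype(np.uint8), _N8, mode="constant")
    terminals = int(np.sum(skel & (ncount == 1)))
    # adjacent branch pixels belong to one junction: count 8-connected
    # components of the branch-pixel set as branch nodes
    _, branches = ndimage.label(skel & (ncount >= 3),
                                structure=np.ones((3, 3)))
    npx = int(skel.sum())
    density = 100.0 * branches / npx if npx else 0.0
    return SkeletonStats(skeleton=skel, branch_points=branches,
                         terminal_points=terminals, branch_density=density)


# ---------------------------------------------------------------------------
# scale-resolved fractal dimension
# ---------------------------------------------------------------------------

def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    m = largest_component(mask, fill_holes=False)
    er = ndimage.binary_erosion(m)
    rr, cc = np.nonzero(m & ~er)
    return np.stack([rr, cc], axis=1)


def _box_count_fd(points: np.ndarray, window: int) -> float | None:
    """Box-count dimension of a point set inside one window."""
    if len(points) < 8:
        return None
    eps_list = []
    eps = window
    while eps >= 2:
        eps_list.append(eps)
        eps //= 2
    if len(eps_list) < 3:
        return None
    counts = []
    origin = points.min(axis=0)
    rel = points - origin
    for eps in eps_list:
        cells = rel // eps
        counts.append(len(np.unique(cells[:, 0] * 100000 + cells[:, 1])))
    slope = np.polyfit(np.log(1.0 / np.asarray(eps_list, float)),
                       np.log(np.asarray(counts, float)), 1)[0]
    return float(slope)


def local_fd_spectrum(mask: np.ndarray,
                      windows=DEFAULT_FD_WINDOWS,
                      max_windows_per_scale: int = 64) -> FDSpectrum:
    """Mean local box-count dimension of the boundary at several window
    sizes, clipped to [1, 2].  Windows larger than the image are skipped."""
    pts = _boundary_pixels(mask)
    h, w = np.asarray(mask).shape
    out_w, out_fd = [], []
    for s in windows:
        if s > max(h, w):
            continue
        stride = max(1, len(pts) // max_windows_per_scale)
        centres = pts[::stride]
        vals = []
        for c in centres:
            lo = c - s // 2
            sel = np.all((pts >= lo) & (pts < lo + s), axis=1)
            fd = _box_count_fd(pts[sel], s)
            if fd is not None:
                vals.append(fd)
        if vals:
            out_w.append(s)
            out_fd.append(float(np.clip(np.mean(vals), 1.0, 2.0)))
    return FDSpectrum(windows=np.asarray(out_w),
                      fd=np.asarray(out_fd))


# ---------------------------------------------------------------------------
# elliptic Fourier descriptors
# ---------------------------------------------------------------------------

def efd_coefficients(contour: np.ndarray, n_harmonics: int = 20) -> np.ndarray:
    """(N, 4) elliptic Fourier coefficients (a, b, c, d) per harmonic from a
    closed polygonal contour under arc-length parameterisation."""
    pts = np.asarray(contour, dtype=np.float64)
    if len(pts) < 4:
        raise ValueError("contour too short")
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    d = np.diff(pts, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    t = np.concatenate([[0.0], np.cumsum(dt)])
    big_t = t[-1]
    if big_t <= 0:
        raise ValueError("degenerate contour")
    coeffs = np.zeros((n_harmonics, 4))
    phi = 2.0 * np.pi * t / big_t
    for n in range(1, n_harmonics + 1):
        const = big_t / (2.0 * n ** 2 * np.pi ** 2)
        dcos = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
        dsin = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
        coeffs[n - 1, 0] = const * np.sum(d[:, 0] / dt * dcos)
        coeffs[n - 1, 1] = const * np.sum(d[:, 0] / dt * dsin)
        coeffs[n - 1, 2] = const * np.sum(d[:, 1] / dt * dcos)
        coeffs[n - 1, 3] = const * np.sum(d[:, 1] / dt * dsin)
    return coeffs


def efd_magnitudes(contour: np.ndarray, n_harmonics: int = 20) -> EFDSpectrum:
    """Harmonic magnitude spectrum sqrt(a^2+b^2+c^2+d^2), normalised so the
    first harmonic equals 1."""
    pts = np.asarray(contour, dtype=np.float64)
    if len(pts) >= 2 and not np.allclose(pts[0], pts[-1]):
        gap = np.hypot(*(pts[0] - pts[-1]))
        perim = np.sum(np.hypot(*np.diff(pts, axis=0).T))
        if perim > 0 and gap > 0.05 * perim:
            raise ValueError("contour is not closed")
    c = efd_coefficients(contour, n_harmonics)
    mags = np.sqrt(np.sum(c ** 2, axis=1))
    if mags[0] <= 0:
        raise ValueError("degenerate first harmonic")
    return EFDSpectrum(harmonics=np.arange(1, n_harmonics + 1),
                       magnitudes=mags / mags[0])


# ---------------------------------------------------------------------------
# radial profile
# ---------------------------------------------------------------------------

def radial_profile(contour: np.ndarray, n_bins: int = 360,
                   centroid: tuple[float, float] | None = None
                   ) -> RadialProfile:
    """Polar radial-distance trace around the centroid.

    Bins take the maximum radius of their contour points (star-shaped
    reduction); empty bins are interpolated circularly.  The per-point
    deviation array drives the frac_over statistic.
    """
    pts = np.asarray(contour, dtype=np.float64)
    if len(pts) < 3:
        raise ValueError("degenerate contour")
    if centroid is None:
        centroid = pts.mean(axis=0)
    dx = pts[:, 0] - centroid[0]
    dy = pts[:, 1] - centroid[1]
    r = np.hypot(dx, dy)
    phi = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    bins = (phi / (2.0 * np.pi) * n_bins).astype(int) % n_bins
    radii = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = bins == b
        if sel.any():
            radii[b] = r[sel].max()
    if np.isnan(radii).any():
        good = np.flatnonzero(~np.isnan(radii))
        if len(good) == 0:
            raise ValueError("degenerate contour")
        # circular interpolation
        xp = np.concatenate([good, good[:1] + n_bins])
        fp = np.concatenate([radii[good], radii[good][:1]])
        bad = np.flatnonzero(np.isnan(radii))
        radii[bad] = np.interp(np.where(bad < good[0], bad + n_bins, bad),
                               xp, fp)
    mean_r = float(r.mean())
    osc = float((radii.max() - radii.min()) / mean_r)
    dev = (r - mean_r) / mean_r
    angles = (np.arange(n_bins) + 0.5) * 2.0 * np.pi / n_bins
    return RadialProfile(angles=angles, radii=radii, mean_radius=mean_r,
                         oscillation=osc, deviations=dev)


# ---------------------------------------------------------------------------
# aggregate report
# ---------------------------------------------------------------------------

def _colour_variance(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean per-channel variance of pixels inside the mask ([0,1] scale)."""
    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1.5:
        img = img / 255.0
    inside = img[mask.astype(bool)]
    return float(inside.var(axis=0).mean())


def _border_gradient(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean luminance gradient magnitude on the boundary, normalised by the
    inside-outside contrast (1 for a step edge, lower for blurred)."""
    from skimage.filters import sobel
    from skimage.color import rgb2gray
    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1.5:
        img = img / 255.0
    grey = rgb2gray(img) if img.ndim == 3 else img
    m = largest_component(mask)
    border = m & ~ndimage.binary_erosion(m)
    ring_out = ndimage.binary_dilation(m, iterations=4) & ~m
    inner = ndimage.binary_erosion(m, iterations=4)
    contrast = abs(float(grey[inner].mean()) - float(grey[ring_out].mean())) \
        if inner.any() and ring_out.any() else 0.0
    if contrast <= 1e-9:
        return 0.0
    g = sobel(grey)
    return float(g[border].mean() / contrast)


def benign_criteria_report(mask: np.ndarray,
                           image: np.ndarray | None = None,
                           fd_windows=DEFAULT_FD_WINDOWS,
                           n_harmonics: int = 20) -> dict:
    """Bundle all morphometric views plus colour/border statistics into one
    JSON-ready report."""
    m = largest_component(mask)
    contour = mask_to_contour(m)
    skel = zhang_suen(m)
    fd = local_fd_spectrum(m, fd_windows)
    efd = efd_magnitudes(contour, n_harmonics)
    rp = radial_profile(contour, centroid=tuple(
        np.flip(ndimage.center_of_mass(m))))
    report = {
        "skeleton": {
            "branch_points": skel.branch_points,
            "terminal_points": skel.terminal_points,
            "branch_density": skel.branch_density,
        },
        "fractal_dimension": {int(w): float(v)
                              for w, v in zip(fd.windows, fd.fd)},
        "efd_magnitudes": efd.magnitudes.tolist(),
        "radial": {
            "mean_radius": rp.mean_radius,
            "oscillation": rp.oscillation,
            "frac_over_10pct": rp.frac_over(0.10),
            "frac_over_15pct": rp.frac_over(0.15),
        },
    }
    if image is not None:
        report["colour_variance"] = _colour_variance(image, m)
        report["border_gradient"] = _border_gradient(image, m)
    return report
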