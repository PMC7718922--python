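"""Density maps: I/O, simulation, blurring, metrics, masks and zoning.

Maps are 3-D scalar grids with isotropic voxels and a world-space
origin, stored in MRC/CCP4 mode-2 files via gemmi.  Simulated maps are
sums of isotropic Gaussians with the standard resolution convention
``sigma = 0.225 * resolution``, which keeps map simulation, the blur
cascade and Fourier-shell-correlation estimates mutually consistent.

The dissection utilities mirror how multilayer-origami maps are taken
apart in practice: soft-edged body masks for multibody-style analyses,
design-indexed zoning (helix/slot selections cut from the map through
the fitted model), per-lattice-layer segmentation, focal-scan body
pairs, and Frankenstein compositing of separately refined pieces.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .model import BeadModel

__all__ = [
    "SIGMA_PER_RESOLUTION",
    "DensityMap",
    "BodyMask",
    "FSCCurve",
    "read_map",
    "write_map",
    "simulate_map",
    "blur_map",
    "blur_cascade",
    "density_and_gradient",
    "masked_ccc",
    "fsc",
    "transfer_function",
    "make_body_mask",
    "zone_map",
    "segment_layers",
    "focal_scan_bodies",
    "composite_frankenstein",
    "parse_selection",
]

#: Gaussian width per unit resolution for simulated maps and blurs.
SIGMA_PER_RESOLUTION = 0.225


@dataclass
class DensityMap:
    """A scalar grid: ``values[ix, iy, iz]`` at world position
    ``origin + (ix, iy, iz) * voxel_size``."""

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    resolution: float | None = None  # nominal resolution, Å
    is_mask: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a non-empty 3-D grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite map values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "DensityMap":
        return replace(self, values=self.values.copy(),
                       origin=self.origin.copy())

    def same_grid(self, other: "DensityMap") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.voxel_size, other.voxel_size,
                             rel_tol=1e-9)
            and np.allclose(self.origin, other.origin, atol=1e-6)
        )

    def total_mass(self) -> float:
        return float(self.values.sum()) * self.voxel_size ** 3

    def world_to_grid(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) / self.voxel_size

    def grid_points(self) -> np.ndarray:
        """World coordinates of all voxel centres, shape (n, 3)."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.origin + idx * self.voxel_size

    def resample_onto(self, target: "DensityMap") -> "DensityMap":
        """Trilinear resampling onto another map's grid (lossy)."""
        if self.same_grid(target):
            return self.copy()
        pts = target.grid_points()
        g = self.world_to_grid(pts).T
        vals = ndimage.map_coordinates(self.values, g, order=1,
                                       mode="constant", cval=0.0)
        return DensityMap(
            vals.reshape(target.shape), target.voxel_size,
            target.origin.copy(), resolution=self.resolution,
            is_mask=self.is_mask,
        )


class BodyMask(DensityMap):
    """A DensityMap with values in [0, 1] and a provenance note."""

    def __init__(self, values, voxel_size, origin, provenance: str = ""):
        super().__init__(values, voxel_size, origin, is_mask=True)
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("mask values must lie in [0, 1]")
        self.provenance = provenance

    def copy(self) -> "BodyMask":
        return BodyMask(self.values.copy(), self.voxel_size,
                        self.origin.copy(), self.provenance)


# -- I/O -----------------------------------------------------------------

def read_map(path: str | Path) -> DensityMap:
    """Read an MRC/CCP4 map (isotropic voxels required)."""
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"not a readable MRC/CCP4 map: {exc}") from exc
    sx, sy, sz = m.grid.spacing
    if not (math.isclose(sx, sy, rel_tol=1e-4)
            and math.isclose(sx, sz, rel_tol=1e-4)):
        raise ValueError(
            f"anisotropic voxels ({sx:.4f}, {sy:.4f}, {sz:.4f} Å) are not "
            "supported; resample to an isotropic grid first"
        )
    origin = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=float)
    if not origin.any():
        nstart = np.array([m.header_i32(w) for w in (5, 6, 7)], dtype=float)
        origin = nstart * sx
    values = np.array(m.grid, copy=True, dtype=np.float64)
    return DensityMap(values, float(sx), origin)


def write_map(dmap: DensityMap, path: str | Path) -> None:
    """Write as MRC/CCP4 2014, mode-2 float, origin in the header."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(
        np.ascontiguousarray(dmap.values, dtype=np.float32)
    )
    nx, ny, nz = dmap.shape
    v = dmap.voxel_size
    m.grid.set_unit_cell(gemmi.UnitCell(nx * v, ny * v, nz * v, 90, 90, 90))
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for w, val in zip((50, 51, 52), dmap.origin):
        m.set_header_float(w, float(val))
    m.write_ccp4_map(str(path))


# -- simulation and blurring --------------------------------------------

def simulate_map(
    model: BeadModel | np.ndarray,
    resolution: float,
    voxel_size: float,
    weights: np.ndarray | None = None,
    pad_sigmas: float = 6.0,
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
) -> DensityMap:
    """Sum of isotropic Gaussians at the bead positions.

    Each bead contributes a normalised Gaussian of width
    ``sigma = 0.225 * resolution`` scaled by its weight, so the map
    integral equals the total weight.  The grid is padded by
    ``pad_sigmas`` standard deviations beyond the bounding box unless an
    explicit grid (origin and shape) is given.
    """
    coords = getattr(model, "coords", model)
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise ValueError("cannot simulate a map from an empty model")
    if resolution < 2.0 * voxel_size:
        raise ValueError("resolution must be at least twice the voxel size")
    sigma = SIGMA_PER_RESOLUTION * resolution
    if weights is None:
        weights = np.ones(len(coords))
    weights = np.asarray(weights, dtype=float)

    if origin is None:
        pad = pad_sigmas * sigma
        origin = coords.min(axis=0) - pad
        extent = coords.max(axis=0) + pad - origin
        shape = tuple(int(np.ceil(e / voxel_size)) + 1 for e in extent)
    else:
        origin = np.asarray(origin, dtype=float)
        if shape is None:
            raise ValueError("shape is required with an explicit origin")

    values = np.zeros(shape)
    norm = 1.0 / ((2.0 * math.pi) ** 1.5 * sigma ** 3)
    radius = pad_sigmas * sigma
    rv = int(math.ceil(radius / voxel_size))
    grid = coords - origin
    axes = [np.arange(n) * voxel_size for n in shape]
    for (cx, cy, cz), w in zip(grid, weights):
        i0 = max(int((cx - radius) / voxel_size), 0)
        j0 = max(int((cy - radius) / voxel_size), 0)
        k0 = max(int((cz - radius) / voxel_size), 0)
        i1 = min(i0 + 2 * rv + 2, shape[0])
        j1 = min(j0 + 2 * rv + 2, shape[1])
        k1 = min(k0 + 2 * rv + 2, shape[2])
        gx = np.exp(-((axes[0][i0:i1] - cx) ** 2) / (2 * sigma ** 2))
        gy = np.exp(-((axes[1][j0:j1] - cy) ** 2) / (2 * sigma ** 2))
        gz = np.exp(-((axes[2][k0:k1] - cz) ** 2) / (2 * sigma ** 2))
        values[i0:i1, j0:j1, k0:k1] += (
            w * norm * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
        )
    return DensityMap(values, voxel_size, origin, resolution=resolution)


def blur_map(dmap: DensityMap, target_resolution: float,
             map_resolution: float | None = None) -> DensityMap:
    """Gaussian low-pass bringing the effective resolution to the target.

    The added width is ``sigma = 0.225 * sqrt(R_target^2 - R_map^2)``;
    requesting the map's own resolution returns an identical copy.
    """
    r_map = map_resolution if map_resolution is not None else dmap.resolution
    if r_map is None:
        raise ValueError("map has no nominal resolution; pass map_resolution")
    if target_resolution < r_map - 1e-9:
        raise ValueError(
            f"target {target_resolution} Å is better than the nominal "
            f"resolution {r_map} Å"
        )
    out = dmap.copy()
    out.resolution = target_resolution
    if abs(target_resolution - r_map) < 1e-12:
        return out
    sigma = SIGMA_PER_RESOLUTION * math.sqrt(
        target_resolution ** 2 - r_map ** 2
    )
    # periodic convolution with the normalised kernel preserves total
    # mass exactly; simulated maps are padded far beyond the model, so
    # wrap-around contributions are negligible
    out.values = ndimage.gaussian_filter(
        dmap.values, sigma / dmap.voxel_size, mode="wrap", truncate=6.0
    )
    return out


def blur_cascade(
    dmap: DensityMap,
    resolutions: list[float],
    map_resolution: float | None = None,
) -> list[DensityMap]:
    """Blur to each target in a worst→best resolution ladder."""
    res = list(resolutions)
    if any(b > a + 1e-9 for a, b in zip(res, res[1:])):
        raise ValueError("resolutions must be sorted worst (largest) first")
    return [blur_map(dmap, r, map_resolution) for r in res]


# -- interpolation -------------------------------------------------------

def normalized_values(dmap: DensityMap) -> np.ndarray:
    """Min–max normalisation over the positive region: clip(v, 0)/max,
    yielding the bounded attractive potential for flexible fitting."""
    vmax = float(dmap.values.max())
    if vmax <= 0:
        return np.zeros_like(dmap.values)
    return np.clip(dmap.values, 0.0, None) / vmax


def trilinear(values: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear interpolation of a grid at fractional grid coordinates,
    with the analytic gradient (per grid unit).  Coordinates are clamped
    to the grid, so outside points take the boundary value and their
    gradient points along the interpolant at the boundary."""
    nx, ny, nz = values.shape
    g = np.clip(
        g,
        0.0,
        np.array([nx, ny, nz], dtype=float) - 1.0 - 1e-9,
    )
    i = np.floor(g).astype(int)
    # keep the cell index valid for 1-voxel axes
    i = np.minimum(i, np.maximum(np.array(values.shape) - 2, 0))
    t = g - i
    ix, iy, iz = i[:, 0], i[:, 1], i[:, 2]
    x1 = np.minimum(ix + 1, nx - 1)
    y1 = np.minimum(iy + 1, ny - 1)
    z1 = np.minimum(iz + 1, nz - 1)
    c000 = values[ix, iy, iz]
    c100 = values[x1, iy, iz]
    c010 = values[ix, y1, iz]
    c110 = values[x1, y1, iz]
    c001 = values[ix, iy, z1]
    c101 = values[x1, iy, z1]
    c011 = values[ix, y1, z1]
    c111 = values[x1, y1, z1]
    tx, ty, tz = t[:, 0], t[:, 1], t[:, 2]

    c00 = c000 + (c100 - c000) * tx
    c01 = c001 + (c101 - c001) * tx
    c10 = c010 + (c110 - c010) * tx
    c11 = c011 + (c111 - c011) * tx
    c0 = c00 + (c10 - c00) * ty
    c1 = c01 + (c11 - c01) * ty
    val = c0 + (c1 - c0) * tz

    dx00 = c100 - c000
    dx01 = c101 - c001
    dx10 = c110 - c010
    dx11 = c111 - c011
    gx = ((dx00 + (dx10 - dx00) * ty) * (1 - tz)
          + (dx01 + (dx11 - dx01) * ty) * tz)
    gy = ((c10 - c00) * (1 - tz) + (c11 - c01) * tz)
    gz = c1 - c0
    return val, np.stack([gx, gy, gz], axis=1)


def density_and_gradient(
    dmap: DensityMap, points: np.ndarray, normalized: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated (normalised) density and its gradient in 1/Å at
    world-space points."""
    points = np.atleast_2d(points)
    if points.size == 0:
        raise ValueError("empty point list")
    values = normalized_values(dmap) if normalized else dmap.values
    val, grad = trilinear(values, dmap.world_to_grid(points))
    return val, grad / dmap.voxel_size


# -- metrics -------------------------------------------------------------

def masked_ccc(
    map_a: DensityMap, map_b: DensityMap, mask: BodyMask | None = None
) -> float:
    """Mask-weighted Pearson correlation over voxels with mask > 0.5."""
    if not map_a.same_grid(map_b):
        map_b = map_b.resample_onto(map_a)
    a = map_a.values.ravel()
    b = map_b.values.ravel()
    if mask is not None:
        if not map_a.same_grid(mask):
            mask = mask.resample_onto(map_a)
        w = np.where(mask.values.ravel() > 0.5, mask.values.ravel(), 0.0)
        if w.sum() <= 0:
            raise ValueError("mask selects no voxels")
    else:
        w = np.ones_like(a)
    wsum = w.sum()
    am = a - np.sum(w * a) / wsum
    bm = b - np.sum(w * b) / wsum
    num = np.sum(w * am * bm)
    den = math.sqrt(np.sum(w * am * am) * np.sum(w * bm * bm))
    if den == 0:
        raise ValueError("zero variance inside the mask")
    return float(num / den)


@dataclass
class FSCCurve:
    """Fourier shell correlation per radial frequency shell."""

    frequencies: np.ndarray  # shell centres, 1/Å, strictly increasing
    values: np.ndarray

    def resolution_at(self, threshold: float = 0.5) -> float | None:
        """Resolution (Å) where the curve first drops through the
        threshold (linear interpolation); None if it never does.
        Conventional thresholds: 0.143 for half-map pairs, 0.5 for
        map-vs-model."""
        f, v = self.frequencies, self.values
        for i in range(1, len(v)):
            if v[i] < threshold <= v[i - 1]:
                t = (v[i - 1] - threshold) / (v[i - 1] - v[i])
                freq = f[i - 1] + t * (f[i] - f[i - 1])
                return 1.0 / freq if freq > 0 else None
        return None

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"frequency_inv_A": self.frequencies, "fsc": self.values}
        ).to_csv(path, index=False)


def _shell_sums(map_a: DensityMap, map_b: DensityMap):
    if not map_a.same_grid(map_b):
        raise ValueError("maps must share one grid for FSC")
    n = map_a.shape[0]
    if map_a.shape != (n, n, n):
        raise ValueError("FSC requires a cubic grid")
    if not map_a.values.any() or not map_b.values.any():
        raise ValueError("FSC of an all-zero map is undefined")
    fa = np.fft.fftn(map_a.values)
    fb = np.fft.fftn(map_b.values)
    freq = np.fft.fftfreq(n, d=map_a.voxel_size)
    fx, fy, fz = np.meshgrid(freq, freq, freq, indexing="ij")
    radius = np.sqrt(fx ** 2 + fy ** 2 + fz ** 2)
    shell_width = 1.0 / (n * map_a.voxel_size)
    shell = np.rint(radius / shell_width).astype(int)
    n_shells = n // 2 + 1
    keep = shell < n_shells
    s = shell[keep]
    num = np.bincount(s, weights=(fa * np.conj(fb)).real[keep],
                      minlength=n_shells)
    pa = np.bincount(s, weights=np.abs(fa[keep]) ** 2, minlength=n_shells)
    pb = np.bincount(s, weights=np.abs(fb[keep]) ** 2, minlength=n_shells)
    return np.arange(n_shells) * shell_width, num, pa, pb


def fsc(map_a: DensityMap, map_b: DensityMap) -> FSCCurve:
    """FSC over radial shells: Re<Fa Fb*> / sqrt(<|Fa|^2><|Fb|^2>).

    Being a per-shell correlation, this is invariant under any
    shell-constant rescaling of either map — in particular a Gaussian
    blur leaves it unchanged.  Use :func:`transfer_function` to measure
    attenuation (e.g. the effective resolution of a blurred copy).
    """
    freqs, num, pa, pb = _shell_sums(map_a, map_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / np.sqrt(pa * pb)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    return FSCCurve(freqs, corr)


def transfer_function(reference: DensityMap, filtered: DensityMap) -> FSCCurve:
    """Reference-normalised cross-power per shell,
    ``Re<F_ref F_filt*> / <|F_ref|^2>``: for ``filtered = kernel *
    reference`` this is exactly the kernel\'s Fourier transform, so its
    0.5 crossing reads off the effective blur resolution."""
    freqs, num, pa, _ = _shell_sums(reference, filtered)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / pa
    corr = np.where(np.isfinite(corr), corr, 0.0)
    return FSCCurve(freqs, corr)


# -- masks ---------------------------------------------------------------

def _soft_edge(binary: np.ndarray, soft_layers: int) -> np.ndarray:
    """Add ``soft_layers`` dilation layers with a raised-cosine profile:
    layer k (k = 1..L) takes the value (1 + cos(pi k / L)) / 2."""
    out = binary.astype(float)
    if soft_layers <= 0:
        return out
    current = binary.copy()
    for k in range(1, soft_layers + 1):
        grown = ndimage.binary_dilation(current)
        shell = grown & ~current
        out[shell] = 0.5 * (1.0 + math.cos(math.pi * k / soft_layers))
        current = grown
    return out


def make_body_mask(
    dmap: DensityMap,
    region: np.ndarray | None = None,
    lp_resolution: float = 20.0,
    threshold: float = 0.1,
    soft_layers: int = 3,
) -> BodyMask:
    """Low-pass filter, binarise, and add soft-edge voxel layers.

    ``region`` is an optional boolean voxel selection restricting the
    input; ``threshold`` is a fraction of the filtered map's maximum.
    """
    vals = dmap.values.copy()
    if region is not None:
        region = np.asarray(region, dtype=bool)
        if region.shape != dmap.shape:
            raise ValueError("region selection must match the grid")
        if not region.any():
            raise ValueError("empty region")
        vals = np.where(region, vals, 0.0)
    sigma = SIGMA_PER_RESOLUTION * lp_resolution / dmap.voxel_size
    lp = ndimage.gaussian_filter(vals, sigma, mode="constant")
    vmax = lp.max()
    if vmax <= 0:
        raise ValueError("filtered region has no positive density")
    binary = lp >= threshold * vmax
    if not binary.any():
        raise ValueError("threshold excludes all voxels")
    return BodyMask(
        _soft_edge(binary, soft_layers),
        dmap.voxel_size,
        dmap.origin.copy(),
        provenance=f"lp={lp_resolution}A thr={threshold} soft={soft_layers}",
    )


# -- zoning --------------------------------------------------------------

_SEL_TOKEN = re.compile(r"^h(\d+):(?:\*|(\d+)-(\d+))$")


def parse_selection(text: str) -> dict[int, tuple[int, int] | None]:
    """Parse the tiny selection grammar ``"h3:10-42,h5:*"`` into a
    ``{helix: (lo, hi) | None}`` mapping (hi inclusive)."""
    out: dict[int, tuple[int, int] | None] = {}
    for token in text.split(","):
        token = token.strip()
        m = _SEL_TOKEN.match(token)
        if not m:
            raise ValueError(f"bad selection token {token!r}")
        helix = int(m.group(1))
        if m.group(2) is None:
            out[helix] = None
        else:
            out[helix] = (int(m.group(2)), int(m.group(3)))
    return out


def _sphere_mask(
    dmap: DensityMap, points: np.ndarray, radius: float, soft_layers: int,
    provenance: str,
) -> BodyMask:
    """Union of spheres around points, soft-edged; bit-exact for a fixed
    model and selection (pure geometry, no density dependence)."""
    centers = dmap.grid_points()
    tree = cKDTree(points)
    d, _ = tree.query(centers, k=1, distance_upper_bound=radius)
    binary = (d <= radius).reshape(dmap.shape)
    return BodyMask(_soft_edge(binary, soft_layers), dmap.voxel_size,
                    dmap.origin.copy(), provenance)


def zone_map(
    dmap: DensityMap,
    model: BeadModel,
    selection: dict[int, tuple[int, int] | None] | str,
    r_zone: float = 8.0,
    soft_layers: int = 2,
) -> tuple[BodyMask, DensityMap, np.ndarray]:
    """Cut the map region belonging to a helix/slot selection.

    The mask is the soft-edged union of spheres (radius ``r_zone``)
    around the beads of the selected nucleotides; the cropped map is
    ``map * mask`` restricted to the mask's bounding box.  Returns
    (mask, cropped map, selected nucleotide ids).
    """
    if isinstance(selection, str):
        selection = parse_selection(selection)
    nucs = model.nucleotides_for(selection)
    if nucs.size == 0:
        raise ValueError("selection matches no nucleotides")
    beads = model.beads_for_nucleotides(nucs)
    mask = _sphere_mask(
        dmap, model.coords[beads], r_zone, soft_layers,
        provenance=f"zone r={r_zone}A of {len(nucs)} nucleotides",
    )
    product = dmap.values * mask.values
    nz = np.nonzero(mask.values > 0)
    lo = [int(a.min()) for a in nz]
    hi = [int(a.max()) + 1 for a in nz]
    cropped = DensityMap(
        product[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]],
        dmap.voxel_size,
        dmap.origin + np.array(lo) * dmap.voxel_size,
        resolution=dmap.resolution,
    )
    return mask, cropped, nucs


def segment_layers(design, model: BeadModel, dmap: DensityMap,
                   r_zone: float = 8.0, soft_layers: int = 2) -> list[BodyMask]:
    """One zoning mask per lattice row (layer), ordered by row."""
    rows = sorted({h.row for h in design.helices})
    masks = []
    for row in rows:
        sel = {h.num: None for h in design.helices if h.row == row}
        mask, _, _ = zone_map(dmap, model, sel, r_zone, soft_layers)
        mask.provenance = f"layer row={row}"
        masks.append(mask)
    return masks


def _windows(lo: int, hi: int, width: int, stride: int) -> list[int]:
    """Window start positions covering [lo, hi] inclusive."""
    if width > hi - lo + 1:
        raise ValueError("window wider than the available range")
    starts = list(range(lo, hi - width + 2, stride))
    if starts[-1] + width - 1 < hi:
        starts.append(hi - width + 1)
    return starts


def focal_scan_bodies(
    design,
    model: BeadModel,
    dmap: DensityMap,
    focal_shape: tuple[int, int] = (2, 2),
    focal_length: int | None = None,
    stride: int | None = None,
    r_zone: float = 8.0,
    soft_layers: int = 2,
) -> list[tuple[BodyMask, BodyMask]]:
    """Enumerate focal/remainder body pairs for scanning refinement.

    Every lattice-aligned ``h x w`` helix block (all block sites present
    in the design) is combined with every slot window of
    ``focal_length`` slots at the given stride; for each, the focal mask
    zones the block and the remainder mask zones everything else.  The
    union of focal elements over the scan covers every nucleotide.
    """
    hh, ww = focal_shape
    rows = sorted({h.row for h in design.helices})
    cols = sorted({h.col for h in design.helices})
    if hh > len(rows) or ww > len(cols):
        raise ValueError("focal block larger than the cross-section")
    by_pos = {(h.row, h.col): h.num for h in design.helices}
    slots = model.nuc_slot
    lo, hi = int(slots.min()), int(slots.max())
    if focal_length is None:
        focal_length = hi - lo + 1
    if stride is None:
        stride = focal_length
    lattice_stride = min(stride, max(hh, ww))

    blocks = []
    for r0 in _windows(rows[0], rows[-1], hh, lattice_stride):
        for c0 in _windows(cols[0], cols[-1], ww, lattice_stride):
            sites = [(r0 + dr, c0 + dc) for dr in range(hh) for dc in range(ww)]
            if all(s in by_pos for s in sites):
                blocks.append([by_pos[s] for s in sites])
    if not blocks:
        raise ValueError("no complete focal block fits the design")

    pairs = []
    all_helices = [h.num for h in design.helices]
    for block in blocks:
        for s0 in _windows(lo, hi, focal_length, stride):
            window = (s0, s0 + focal_length - 1)
            focal_sel = {h: window for h in block}
            focal, _, focal_nucs = zone_map(
                dmap, model, focal_sel, r_zone, soft_layers
            )
            focal.provenance = f"focal block={block} slots={window}"
            rest = np.setdiff1d(np.arange(model.n_nucleotides), focal_nucs)
            if rest.size:
                beads = model.beads_for_nucleotides(rest)
                remainder = _sphere_mask(
                    dmap, model.coords[beads], r_zone, soft_layers,
                    provenance=f"remainder of block={block} slots={window}",
                )
            else:
                remainder = BodyMask(
                    np.zeros(dmap.shape), dmap.voxel_size,
                    dmap.origin.copy(), "empty remainder",
                )
            pairs.append((focal, remainder))
    return pairs


# -- compositing ---------------------------------------------------------

def composite_frankenstein(
    maps: list[DensityMap], masks: list[BodyMask]
) -> DensityMap:
    """Merge separately refined pieces: the mask-weighted mean
    ``sum(m_i * map_i) / sum(m_i)`` where any mask is positive, else 0."""
    if len(maps) != len(masks) or not maps:
        raise ValueError("need one mask per map")
    ref = maps[0]
    num = np.zeros(ref.shape)
    den = np.zeros(ref.shape)
    for dmap, mask in zip(maps, masks):
        if not ref.same_grid(dmap):
            dmap = dmap.resample_onto(ref)
        if not ref.same_grid(mask):
            mask = mask.resample_onto(ref)
        num += mask.values * dmap.values
        den += mask.values
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, 0.0)
    return DensityMap(out, ref.voxel_size, ref.origin.copy(),
                      resolution=ref.resolution)
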